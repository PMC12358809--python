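"""SFCN architecture, parameter accounting, feature extraction, training."""

import dataclasses

import numpy as np
import pytest

from braingap.errors import ConfigurationError, ShapeError, ValidationError
from braingap.sfcn import (
    DESK_FILTERS,
    HEAD_CLASSIFICATION,
    HEAD_REGRESSION,
    REFERENCE_FILTERS,
    SFCNConfig,
    TrainConfig,
    build_sfcn,
    calibrate_batchnorm,
    count_trainable_parameters,
    extract_features,
    lr_schedule,
    pretrain_brainage,
    train_model,
)


def closed_form_count(filters, head_width):
    """Sum over blocks of conv weights+biases plus batch-norm scale/shift,
    plus the fully connected head."""
    total, c_in = 0, 1
    for i, c_out in enumerate(filters):
        k3 = 27 if i < len(filters) - 1 else 1
        total += k3 * c_in * c_out + c_out  # conv weights + biases
        total += 2 * c_out                  # batch-norm gamma + beta
        c_in = c_out
    total += filters[-1] * head_width + head_width
    return total


class TestArchitecture:
    def test_tiny_config_parameter_count_matches_hand_tally(self):
        # filters [2,3], 2-class head:
        #   block1: 27*1*2+2 = 56 conv, +4 BN        = 60
        #   appended: 1*2*3+3 = 9 conv, +6 BN        = 15
        #   head: 3*2+2                              = 8
        cfg = SFCNConfig(filters=(2, 3), input_shape=(8, 8, 8))
        assert count_trainable_parameters(build_sfcn(cfg)) == 60 + 15 + 8

    def test_reference_classification_head_logits(self):
        cfg = SFCNConfig(filters=REFERENCE_FILTERS, input_shape=(32, 40, 32),
                         head=HEAD_CLASSIFICATION)
        model = build_sfcn(cfg, seed=0)
        out = model.forward(np.zeros((1, 32, 40, 32), dtype=np.float32))
        assert out.shape == (1, 2)

    def test_feature_length_equals_last_filter_count(self):
        cfg = SFCNConfig(filters=(4, 8, 16), input_shape=(16, 16, 16))
        model = build_sfcn(cfg)
        feats = model.features(np.zeros((2, 16, 16, 16), dtype=np.float32))
        assert feats.shape == (2, 16)

    def test_parameter_count_invariant_to_input_shape(self):
        c1 = SFCNConfig(filters=DESK_FILTERS, input_shape=(32, 40, 32))
        c2 = SFCNConfig(filters=DESK_FILTERS, input_shape=(64, 64, 64))
        assert (count_trainable_parameters(build_sfcn(c1))
                == count_trainable_parameters(build_sfcn(c2)))

    def test_closed_form_count_identity_on_random_configs(self, rng):
        for _ in range(20):
            depth = int(rng.integers(2, 5))
            filters = tuple(int(rng.integers(1, 9)) for _ in range(depth))
            head = HEAD_CLASSIFICATION if rng.random() < 0.5 else HEAD_REGRESSION
            size = 2 ** (depth - 1) * int(rng.integers(1, 3))
            cfg = SFCNConfig(filters=filters, input_shape=(size, size, size), head=head)
            assert count_trainable_parameters(build_sfcn(cfg)) == \
                closed_form_count(filters, cfg.head_width)

    def test_five_poolings_reduce_reference_shape_to_5_6_5(self):
        cfg = SFCNConfig()
        assert cfg.feature_map_shape((167, 212, 160)) == (5, 6, 5)

    def test_too_small_input_rejected(self):
        with pytest.raises(ShapeError):
            SFCNConfig(filters=(2, 3, 4, 5), input_shape=(4, 4, 4)).feature_map_shape()

    @pytest.mark.parametrize("kwargs", [
        {"filters": (8,)}, {"filters": (8, 0)}, {"head": "multiclass"},
        {"dropout_rate": 1.5},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SFCNConfig(**{"input_shape": (8, 8, 8), **kwargs})


class TestFeatureExtraction:
    def test_deterministic_in_eval_mode(self, rng):
        cfg = SFCNConfig(filters=(3, 4), input_shape=(8, 8, 8))
        model = build_sfcn(cfg, seed=2)
        x = rng.standard_normal((8, 8, 8)).astype(np.float32)
        f1 = extract_features(model, x, "s")
        f2 = extract_features(model, x, "s")
        assert np.array_equal(f1.values, f2.values)
        assert len(f1.values) == 4

    def test_equals_brute_force_spatial_mean(self, rng):
        """GAP output equals an explicit loop over spatial positions of the
        appended block's activation maps."""
        cfg = SFCNConfig(filters=(3, 5), input_shape=(8, 8, 8))
        model = build_sfcn(cfg, seed=3)
        x = rng.standard_normal((1, 8, 8, 8)).astype(np.float32)
        # run through all layers except the final pooling
        h = x[:, None]
        for layer in model.backbone[:-1]:
            h = layer.forward(h, train=False)
        n, c, d, hh, w = h.shape
        brute = np.zeros(c)
        for ci in range(c):
            acc = 0.0
            for i in range(d):
                for j in range(hh):
                    for kk in range(w):
                        acc += h[0, ci, i, j, kk]
            brute[ci] = acc / (d * hh * w)
        feats = model.features(x)
        assert np.allclose(feats[0], brute, atol=1e-5)


class TestTraining:
    def test_lr_schedule_drops_tenfold_every_30_epochs(self):
        cfg = TrainConfig(initial_lr=0.1)
        assert lr_schedule(0, cfg) == pytest.approx(0.1)
        assert lr_schedule(29, cfg) == pytest.approx(0.1)
        assert lr_schedule(30, cfg) == pytest.approx(0.01)
        assert lr_schedule(60, cfg) == pytest.approx(0.001)

    def test_separable_blobs_reach_validation_auc_1(self, rng):
        """On linearly separable two-blob volumes the selected epoch has
        validation AUC 1.0; a logistic fit on blob-mean intensity confirms
        separability independently."""
        shape = (12, 14, 12)
        pattern = np.zeros(shape)
        pattern[3:7, 4:9, 3:7] = 1.0
        n = 32
        x = rng.normal(0.3, 0.03, size=(n,) + shape).astype(np.float32)
        y = np.tile([0, 1], n // 2)
        x += 0.3 * pattern * y[:, None, None, None]
        from sklearn.linear_model import LogisticRegression
        from braingap.stats import auc
        means = x[:, 3:7, 4:9, 3:7].mean(axis=(1, 2, 3)).reshape(-1, 1)
        oracle = LogisticRegression().fit(means[:24], y[:24])
        assert auc(oracle.decision_function(means[24:]), y[24:]) == 1.0

        cfg = SFCNConfig(filters=(4, 8), input_shape=shape, dropout_rate=0.25)
        model = build_sfcn(cfg, seed=0)
        tcfg = TrainConfig(initial_lr=0.1, epochs=6, batch_size=8, seed=0)
        model, trace = train_model(model, x[:24], y[:24], x[24:], y[24:], tcfg)
        assert trace.attrs["best_metric"] == 1.0

    def test_single_epoch_returns_that_checkpoint(self, rng):
        shape = (8, 8, 8)
        x = rng.normal(0.5, 0.1, size=(12,) + shape).astype(np.float32)
        y = np.tile([0, 1], 6)
        cfg = SFCNConfig(filters=(2, 3), input_shape=shape)
        model = build_sfcn(cfg, seed=1)
        _, trace = train_model(model, x[:8], y[:8], x[8:], y[8:],
                               TrainConfig(epochs=1, batch_size=4, seed=0))
        assert len(trace) == 1
        assert trace.attrs["best_epoch"] == 0

    def test_single_class_training_set_rejected(self, rng):
        shape = (8, 8, 8)
        x = rng.normal(size=(8,) + shape).astype(np.float32)
        cfg = SFCNConfig(filters=(2, 3), input_shape=shape)
        with pytest.raises(ValidationError):
            train_model(build_sfcn(cfg), x[:4], np.zeros(4, int), x[4:],
                        np.ones(4, int), TrainConfig(epochs=1, batch_size=4))

    def test_training_is_seed_reproducible(self, rng):
        shape = (8, 8, 8)
        x = rng.normal(0.5, 0.2, size=(16,) + shape).astype(np.float32)
        y = np.tile([0, 1], 8)
        cfg = SFCNConfig(filters=(2, 3), input_shape=shape)
        tcfg = TrainConfig(initial_lr=0.05, epochs=2, batch_size=4, seed=9)
        m1, t1 = train_model(build_sfcn(cfg, seed=4), x[:12], y[:12], x[12:], y[12:], tcfg)
        m2, t2 = train_model(build_sfcn(cfg, seed=4), x[:12], y[:12], x[12:], y[12:], tcfg)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p1.value, p2.value)
        assert t1["train_loss"].tolist() == t2["train_loss"].tolist()


class TestPretraining:
    def _healthy_cohort(self, n, age_amplitude, seed=17):
        from braingap.preprocess import normalize_intensity
        from braingap.synthetic_data import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(volume_shape=(12, 14, 12),
                              n_per_group={"CN": n, "AD": 0, "sMCI": 0, "pMCI": 0},
                              datasets=(("P", ("p1",)),),
                              age_amplitude=age_amplitude, aging_variability_sd=0.0,
                              noise_sd=2.0, site_offset_sd=0.0, site_gain_sd=0.0,
                              seed=seed)
        records, vols = generate_cohort(cfg)
        x = {k: normalize_intensity(v) for k, v in vols.items()}
        return records, x

    def test_strong_age_signal_beats_constant_predictor(self):
        # amplitude 15 keeps rendering clip-free at this volume size
        records, x = self._healthy_cohort(n=80, age_amplitude=15.0)
        model_cfg = SFCNConfig(filters=(4, 8), input_shape=(12, 14, 12),
                               head=HEAD_REGRESSION, dropout_rate=0.25)
        tcfg = TrainConfig(initial_lr=0.1, epochs=50, batch_size=8,
                           lr_decay_every=40, seed=0)
        model, trace = pretrain_brainage(model_cfg, records, x, tcfg)
        ages = np.array([r.age for r in records])
        const_mae = np.abs(ages - ages.mean()).mean()
        assert trace.attrs["best_metric"] < const_mae * 0.75

    def test_zero_age_signal_cannot_beat_constant_predictor(self):
        records, x = self._healthy_cohort(n=40, age_amplitude=0.0)
        model_cfg = SFCNConfig(filters=(4, 8), input_shape=(12, 14, 12),
                               head=HEAD_REGRESSION, dropout_rate=0.25)
        tcfg = TrainConfig(initial_lr=0.1, epochs=10, batch_size=8, seed=0)
        _, trace = pretrain_brainage(model_cfg, records, x, tcfg)
        ages = np.array([r.age for r in records])
        const_mae = np.abs(ages - ages.mean()).mean()
        assert trace.attrs["best_metric"] > const_mae * 0.6

    def test_diseased_subjects_trigger_warning(self, make_subject, rng):
        records = [make_subject(f"s{i}", group="AD" if i == 0 else "CN",
                                severity=1.0 if i == 0 else 0.0, age=60.0 + i)
                   for i in range(10)]
        x = {r.subject_id: rng.normal(0.5, 0.1, (8, 8, 8)).astype(np.float32)
             for r in records}
        cfg = SFCNConfig(filters=(2, 3), input_shape=(8, 8, 8), head=HEAD_REGRESSION)
        with pytest.warns(UserWarning, match="non-CN"):
            pretrain_brainage(cfg, records, x, TrainConfig(epochs=1, batch_size=4, seed=0))


class TestBatchNormCalibration:
    def test_running_stats_match_new_domain_statistics(self, rng):
        cfg = SFCNConfig(filters=(3, 4), input_shape=(8, 8, 8))
        model = build_sfcn(cfg, seed=0)
        x = rng.normal(2.0, 3.0, size=(16, 8, 8, 8)).astype(np.float32)
        calibrate_batchnorm(model, x, batch_size=16)  # single full batch
        from braingap.nn import BatchNorm3d
        bn0 = next(l for l in model.backbone if isinstance(l, BatchNorm3d))
        conv0 = model.backbone[0]
        h = conv0.forward(x[:, None])
        assert np.allclose(bn0.running_mean, h.mean(axis=(0, 2, 3, 4)), atol=1e-4)
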