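"""BAG computation, logistic ridge stage, approach runners, leakage audit."""

import dataclasses

import numpy as np
import pytest

from braingap.approaches import (
    ApproachConfigs,
    ApproachResult,
    RidgeConfig,
    TaskData,
    audit_leakage,
    compute_bag,
    fit_logistic_ridge,
    run_ad_approach,
    run_learning_curve,
    run_mci_approach,
)
from braingap.cohort_prep import make_splits
from braingap.errors import ConfigurationError, UsageError, ValidationError
from braingap.sfcn import (
    HEAD_CLASSIFICATION,
    HEAD_REGRESSION,
    SFCNConfig,
    TrainConfig,
    build_sfcn,
    count_trainable_parameters,
)
from braingap.stats import auc
from tests_helpers import build_matched

SHAPE = (8, 8, 8)


def tiny_task_data(matched, rng, signal=0.3):
    """Volumes with a class-dependent blob, labels, ages."""
    pattern = np.zeros(SHAPE)
    pattern[2:6, 2:6, 2:6] = 1.0
    labels = matched.labels()
    volumes, ages = {}, {}
    for sid, lab in labels.items():
        vol = rng.normal(0.4, 0.05, SHAPE).astype(np.float32) + signal * lab * pattern
        volumes[sid] = vol.astype(np.float32)
        ages[sid] = matched.records[sid].age
    return TaskData(volumes=volumes, labels=labels, ages=ages)


@pytest.fixture
def reg_model():
    cfg = SFCNConfig(filters=(2, 3), input_shape=SHAPE, head=HEAD_REGRESSION)
    return build_sfcn(cfg, seed=5)


class TestComputeBag:
    def test_bag_is_prediction_minus_chronological_age(self, reg_model, rng):
        x = rng.normal(0.5, 0.1, size=(4,) + SHAPE).astype(np.float32)
        ages = np.array([70.0, 75.0, 60.0, 82.0], dtype=np.float32)
        pred = reg_model.predict(x)
        bag = compute_bag(reg_model, x, ages)
        assert np.allclose(bag, pred - ages)
        assert np.allclose(compute_bag(reg_model, x, pred), 0.0)

    def test_classification_model_rejected(self, rng):
        cfg = SFCNConfig(filters=(2, 3), input_shape=SHAPE, head=HEAD_CLASSIFICATION)
        model = build_sfcn(cfg)
        with pytest.raises(UsageError):
            compute_bag(model, rng.normal(size=(2,) + SHAPE), [70.0, 71.0])

    def test_constant_prediction_shift_leaves_auc_unchanged(self, rng):
        """Adding c to every prediction shifts every BAG by c; AUC is a rank
        statistic and is invariant."""
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auc(scores + 3.7, labels) == auc(scores, labels)


class TestLogisticRidge:
    def test_parameter_count_is_weights_plus_intercept(self, rng):
        f = rng.normal(size=(40, 64))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        model = fit_logistic_ridge(f[:30], y[:30], f[30:], y[30:])
        assert model.n_trainable_parameters == 65
        assert count_trainable_parameters(model.clf) == 65

    def test_separable_toy_in_64d_reaches_training_auc_1(self, rng):
        """A separable 2-D problem embedded in 64-D (62 zero coordinates)
        with the weakest penalty; a margin check confirms separability."""
        n = 30
        f = np.zeros((n, 64))
        y = np.tile([0, 1], n // 2)
        f[:, 0] = y + rng.normal(0, 0.05, n)
        f[:, 1] = -y + rng.normal(0, 0.05, n)
        margin = f[y == 1, 0].min() - f[y == 0, 0].max()
        assert margin > 0  # separable by construction
        cfg = RidgeConfig(lambda_grid=(1000.0,))
        model = fit_logistic_ridge(f[:20], y[:20], f[20:], y[20:], cfg)
        assert auc(model.scores(f[:20]), y[:20]) == 1.0

    def test_lambda_tie_break_prefers_strongest_penalty(self, rng):
        f = rng.normal(size=(24, 4))
        y = np.tile([0, 1], 12)
        f[:, 0] += 3.0 * y  # easy problem: every lambda gets val AUC 1.0
        grids = [(0.001, 1.0, 1000.0), (1000.0, 0.001, 1.0)]
        lams = []
        for grid in grids:
            m = fit_logistic_ridge(f[:16], y[:16], f[16:], y[16:],
                                   RidgeConfig(lambda_grid=grid))
            lams.append(m.lam)
        assert lams[0] == lams[1] == 0.001

    def test_single_class_rejected(self, rng):
        f = rng.normal(size=(10, 4))
        with pytest.raises(ValidationError):
            fit_logistic_ridge(f, np.zeros(10, int), f, np.zeros(10, int))

    def test_extreme_penalty_degrades_toward_chance(self, rng):
        """When class information needs feature reweighting, the maximal
        penalty shrinks the rule toward the noisy mean-difference direction
        and AUC degrades."""
        n = 400
        z = rng.normal(0, 3.0, n)                 # shared nuisance factor
        y = np.tile([0, 1], n // 2)
        f = np.stack([z + 0.5 * y + rng.normal(0, 0.05, n), z], axis=1)
        f = np.hstack([f, rng.normal(0, 1.0, (n, 6))])
        strong = fit_logistic_ridge(f[:200], y[:200], f[200:300], y[200:300],
                                    RidgeConfig(lambda_grid=(1e-4,)))
        weak = fit_logistic_ridge(f[:200], y[:200], f[200:300], y[200:300],
                                  RidgeConfig(lambda_grid=(1000.0,)))
        auc_strong = auc(strong.scores(f[300:]), y[300:])
        auc_weak = auc(weak.scores(f[300:]), y[300:])
        assert auc_weak > 0.9
        assert auc_strong < auc_weak - 0.2


@pytest.fixture(scope="module")
def small_setup():
    rng = np.random.default_rng(3)
    matched = build_matched(n_pairs=24, seed=3)
    data = tiny_task_data(matched, rng)
    plan = make_splits(matched, k=2, seed=3)
    model_cfg = SFCNConfig(filters=(2, 3), input_shape=SHAPE, dropout_rate=0.25)
    pre = build_sfcn(dataclasses.replace(model_cfg, head=HEAD_REGRESSION), seed=8)
    cfgs = ApproachConfigs(
        model=model_cfg,
        train=TrainConfig(initial_lr=0.1, epochs=2, batch_size=8, seed=0),
        finetune=TrainConfig(initial_lr=0.05, epochs=2, batch_size=8,
                             update_bn_stats=False, seed=0),
        pretrained=pre, seed=17)
    return data, plan, cfgs


class TestRunAdApproach:
    def test_bag_consumes_no_development_data(self, small_setup):
        data, plan, cfgs = small_setup
        results = run_ad_approach("bag", data, plan, cfgs)
        assert all(r.train_ids == () and r.val_ids == () for r in results)
        assert len(results) == plan.k

    def test_all_approaches_produce_valid_results(self, small_setup):
        data, plan, cfgs = small_setup
        for name in ("direct", "bag_finetune", "brainage64d", "brainage64d_finetune"):
            results = run_ad_approach(name, data, plan, cfgs)
            assert len(results) == plan.k
            assert all(0.0 <= r.auc <= 1.0 for r in results)
            assert all(r.approach == name and r.task == "AD_CN" for r in results)

    def test_bag_finetune_trains_on_cn_subjects_only(self, small_setup):
        data, plan, cfgs = small_setup
        results = run_ad_approach("bag_finetune", data, plan, cfgs)
        for r in results:
            assert all(data.labels[i] == 0 for i in r.train_ids)
            assert all(data.labels[i] == 0 for i in r.val_ids)

    def test_missing_pretrained_model_rejected(self, small_setup):
        data, plan, cfgs = small_setup
        bare = dataclasses.replace(cfgs, pretrained=None)
        with pytest.raises(ConfigurationError):
            run_ad_approach("bag", data, plan, bare)

    def test_unknown_approach_rejected(self, small_setup):
        data, plan, cfgs = small_setup
        with pytest.raises(ConfigurationError):
            run_ad_approach("mystery", data, plan, cfgs)


class TestRunMciApproach:
    def test_ad2prog_requires_matching_ad_models(self, small_setup):
        data, plan, cfgs = small_setup
        with pytest.raises(ConfigurationError):
            run_mci_approach("direct_ad2prog", data, plan, cfgs, ad_models=None)

    def test_ad2prog_logistic_stage_runs_on_frozen_features(self, small_setup):
        data, plan, cfgs = small_setup
        frozen = {rep: build_sfcn(cfgs.model, seed=30 + rep) for rep in range(plan.k)}
        results = run_mci_approach("direct_ad2prog", data, plan, cfgs, ad_models=frozen)
        assert len(results) == plan.k
        assert all("lambda" in r.selected for r in results)

    def test_random_features_on_permuted_labels_stay_near_chance(self):
        """An untrained frozen backbone scored on label-permuted data gives
        test AUC within the permutation-null band around 0.5."""
        rng = np.random.default_rng(11)
        matched = build_matched(n_pairs=40, seed=11)
        data = tiny_task_data(matched, rng, signal=0.25)
        perm_ids = list(data.labels)
        perm_labels = rng.permutation([data.labels[i] for i in perm_ids])
        data = TaskData(volumes=data.volumes,
                        labels=dict(zip(perm_ids, (int(v) for v in perm_labels))),
                        ages=data.ages)
        plan = make_splits(matched, k=5, seed=11)
        model_cfg = SFCNConfig(filters=(2, 3), input_shape=SHAPE)
        cfgs = ApproachConfigs(model=model_cfg,
                               train=TrainConfig(epochs=1, batch_size=8),
                               finetune=TrainConfig(epochs=1, batch_size=8),
                               seed=23)
        frozen = {rep: build_sfcn(model_cfg, seed=60 + rep) for rep in range(plan.k)}
        results = run_mci_approach("direct_ad2prog", data, plan, cfgs, ad_models=frozen)
        aucs = np.array([r.auc for r in results])
        n_side = len(results[0].test_ids) // 2
        null_sd = np.sqrt((2 * n_side + 1) / (12 * n_side * n_side))
        assert abs(aucs.mean() - 0.5) < 2.6 * null_sd / np.sqrt(len(aucs)) + 0.1


class TestLearningCurve:
    def test_max_size_reproduces_main_analysis_exactly(self, small_setup):
        data, plan, cfgs = small_setup
        main = run_ad_approach("brainage64d", data, plan, cfgs)
        curve = run_learning_curve("AD_CN", ["brainage64d"], data, plan, cfgs,
                                   sizes=[plan.n_dev])
        assert [r.auc for r in curve] == [r.auc for r in main]

    def test_larger_development_sets_do_not_hurt_on_average(self):
        rng = np.random.default_rng(29)
        matched = build_matched(n_pairs=40, seed=29)
        data = tiny_task_data(matched, rng, signal=0.06)
        plan = make_splits(matched, k=5, seed=29)
        model_cfg = SFCNConfig(filters=(2, 3), input_shape=SHAPE)
        pre = build_sfcn(dataclasses.replace(model_cfg, head=HEAD_REGRESSION), seed=31)
        cfgs = ApproachConfigs(model=model_cfg,
                               train=TrainConfig(epochs=1, batch_size=8),
                               finetune=TrainConfig(epochs=1, batch_size=8),
                               pretrained=pre, seed=37)
        curve = run_learning_curve("AD_CN", ["brainage64d"], data, plan, cfgs,
                                   sizes=[16, plan.n_dev])
        small = np.mean([r.auc for r in curve if r.dev_size == 16])
        full = np.mean([r.auc for r in curve if r.dev_size == plan.n_dev])
        assert full >= small - 0.05

    def test_oversized_request_rejected(self, small_setup):
        data, plan, cfgs = small_setup
        with pytest.raises(ValidationError):
            run_learning_curve("AD_CN", ["brainage64d"], data, plan, cfgs, sizes=[10**4])


class TestLeakageAudit:
    def test_clean_results_pass(self, small_setup):
        data, plan, cfgs = small_setup
        results = run_ad_approach("brainage64d", data, plan, cfgs)
        assert audit_leakage(results)

    def test_contaminated_result_detected(self):
        bad = ApproachResult(task="AD_CN", approach="direct", repetition=0,
                             dev_size=4, auc=0.9, n_dev=4, n_test=2,
                             train_ids=("a", "b"), val_ids=("c",),
                             test_ids=("a", "d"))
        assert not audit_leakage([bad])
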