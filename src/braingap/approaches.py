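"""The five AD-classification and three MCI-progression approaches.

AD task (CN = 0, AD = 1):
  * direct               — SFCN 2-class trained from scratch.
  * bag                  — brain age gap (predicted minus chronological age)
                           from the pretrained regression model; no training.
  * bag_finetune         — regression model finetuned on CN development
                           subjects (MAE, low learning rate), then BAG.
  * brainage64d          — logistic ridge on the pretrained model's
                           global-average-pooling features.
  * brainage64d_finetune — the brainage64d model finetuned end to end.

MCI task (sMCI = 0, pMCI = 1):
  * direct                          — SFCN 2-class from scratch.
  * direct_ad2prog                  — logistic ridge on features from the
                                      frozen Direct AD model.
  * brainage64d_finetune_ad2prog    — same, from the frozen finetuned model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .cohort_prep import SplitPlan, subsample_development
from .errors import ConfigurationError, UsageError, ValidationError
from .sfcn import (
    HEAD_CLASSIFICATION,
    HEAD_REGRESSION,
    SFCN,
    SFCNConfig,
    TrainConfig,
    build_sfcn,
    calibrate_batchnorm,
    train_model,
)
from .stats import auc

AD_APPROACHES = ("direct", "bag", "bag_finetune", "brainage64d", "brainage64d_finetune")
MCI_APPROACHES = ("direct", "direct_ad2prog", "brainage64d_finetune_ad2prog")

LAMBDA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class RidgeConfig:
    """Inverse-regularization grid for the logistic ridge stage
    (larger lambda = weaker penalty)."""

    lambda_grid: tuple[float, ...] = LAMBDA_GRID
    refit_on_dev: bool = True

    def __post_init__(self) -> None:
        if not self.lambda_grid or any(l <= 0 for l in self.lambda_grid):
            raise ConfigurationError("lambda_grid: must be nonempty and positive")


@dataclass
class ApproachResult:
    task: str
    approach: str
    repetition: int
    dev_size: int
    auc: float
    n_dev: int
    n_test: int
    selected: dict = field(default_factory=dict)
    train_ids: tuple[str, ...] = ()
    val_ids: tuple[str, ...] = ()
    test_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError(f"AUC out of range: {self.auc}")


@dataclass
class TaskData:
    """Preprocessed task inputs keyed by subject id."""

    volumes: dict[str, np.ndarray]      # normalized float volumes
    labels: dict[str, int]              # 0/1 class per subject
    ages: dict[str, float]

    def stack(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = np.stack([self.volumes[i] for i in ids]).astype(np.float32)
        y = np.array([self.labels[i] for i in ids], dtype=np.int64)
        a = np.array([self.ages[i] for i in ids], dtype=np.float32)
        return x, y, a


def compute_bag(age_model: SFCN, volumes: np.ndarray, ages) -> np.ndarray:
    """Brain age gap: predicted age minus chronological age, in years."""
    if age_model.head_type != HEAD_REGRESSION:
        raise UsageError("compute_bag requires a regression-head model")
    pred = age_model.predict(np.asarray(volumes, dtype=np.float32))
    return pred - np.asarray(ages, dtype=np.float32)


# ---------------------------------------------------------------------------
# Logistic ridge on GAP features
# ---------------------------------------------------------------------------

@dataclass
class LogisticRidgeModel:
    scaler: StandardScaler
    clf: LogisticRegression
    lam: float

    def scores(self, features: np.ndarray) -> np.ndarray:
        return self.clf.decision_function(self.scaler.transform(features))

    @property
    def n_trainable_parameters(self) -> int:
        return int(self.clf.coef_.size + self.clf.intercept_.size)

    def folded_head(self) -> tuple[np.ndarray, float]:
        """Weights/intercept on raw (unstandardized) features."""
        w = self.clf.coef_.ravel() / self.scaler.scale_
        b = float(self.clf.intercept_[0] - np.dot(w, self.scaler.mean_))
        return w.astype(np.float32), b


def _fit_at(features, labels, lam) -> tuple[StandardScaler, LogisticRegression]:
    scaler = StandardScaler().fit(features)
    clf = LogisticRegression(C=lam, solver="lbfgs", max_iter=2000)  # l2 penalty
    clf.fit(scaler.transform(features), labels)
    return scaler, clf


def fit_logistic_ridge(f_train, y_train, f_val, y_val,
                       cfg: RidgeConfig | None = None) -> LogisticRidgeModel:
    """Grid-select lambda by validation AUC, then refit on train+validation.

    Features are z-scored with the statistics of the set being fit.  Ties on
    validation AUC resolve to the smallest lambda (strongest penalty).
    """
    cfg = cfg or RidgeConfig()
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValidationError("logistic ridge requires both classes in training labels")
    best_lam, best_auc = None, -np.inf
    for lam in sorted(cfg.lambda_grid):
        scaler, clf = _fit_at(f_train, y_train, lam)
        val_auc = auc(clf.decision_function(scaler.transform(f_val)), y_val)
        if val_auc > best_auc:
            best_lam, best_auc = lam, val_auc
    if cfg.refit_on_dev:
        f_dev = np.vstack([f_train, f_val])
        y_dev = np.concatenate([y_train, np.asarray(y_val)])
        scaler, clf = _fit_at(f_dev, y_dev, best_lam)
    else:
        scaler, clf = _fit_at(f_train, y_train, best_lam)
    return LogisticRidgeModel(scaler=scaler, clf=clf, lam=best_lam)


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _batched_features(model: SFCN, x: np.ndarray, batch: int = 8) -> np.ndarray:
    out = [model.features(x[i:i + batch], train=False) for i in range(0, len(x), batch)]
    return np.vstack(out)


def _rep_seed(base_seed: int, rep: int, salt: int) -> int:
    return int(np.random.SeedSequence([base_seed, salt, rep]).generate_state(1)[0] % (2**31))


def _init_head_from_logistic(model: SFCN, ridge: LogisticRidgeModel) -> None:
    """Unfold the 65-parameter logistic stage into an antisymmetric 2-output
    head so end-to-end finetuning starts from the trained decision rule.

    The logistic decision rule is scale-free for ranking, so the head is
    normalized to unit weight norm (a softmax temperature choice) to keep
    initial logits in a trainable range."""
    w, b = ridge.folded_head()
    scale = float(np.linalg.norm(w * ridge.scaler.scale_))  # norm in z-space
    w, b = w / max(scale, 1e-8), b / max(scale, 1e-8)
    model.replace_head(HEAD_CLASSIFICATION)
    model.head.weight.value = np.stack([-w / 2.0, w / 2.0]).astype(np.float32)
    model.head.bias.value = np.array([-b / 2.0, b / 2.0], dtype=np.float32)


@dataclass
class ApproachConfigs:
    """Everything one repetition of an approach needs besides the data."""

    model: SFCNConfig
    train: TrainConfig
    finetune: TrainConfig
    ridge: RidgeConfig = field(default_factory=RidgeConfig)
    pretrained: SFCN | None = None          # brain-age regression model
    seed: int = 0


def _finetune_cfg(cfg: TrainConfig, seed: int) -> TrainConfig:
    return dc_replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# AD approaches
# ---------------------------------------------------------------------------

def run_ad_approach(name: str, data: TaskData, plan: SplitPlan,
                    cfgs: ApproachConfigs,
                    return_models: bool = False):
    """Run one AD approach over every repetition of the split plan.

    Returns a list of ApproachResult (and, if requested, the per-repetition
    trained models for downstream feature transfer)."""
    if name not in AD_APPROACHES:
        raise ConfigurationError(f"unknown AD approach {name!r}")
    needs_pretrained = name in ("bag", "bag_finetune", "brainage64d", "brainage64d_finetune")
    if needs_pretrained and cfgs.pretrained is None:
        raise ConfigurationError(f"approach {name!r} requires a pretrained brain-age model")
    results, models = [], {}
    dev_size = plan.dev_size if plan.dev_size is not None else plan.n_dev
    for rep in range(plan.k):
        train_ids = plan.ids_by_role(rep, "train")
        val_ids = plan.ids_by_role(rep, "validation")
        test_ids = plan.ids_by_role(rep, "test")
        x_tr, y_tr, a_tr = data.stack(train_ids)
        x_va, y_va, a_va = data.stack(val_ids)
        x_te, y_te, a_te = data.stack(test_ids)
        selected: dict = {}
        model = None
        used_train: tuple[str, ...] = tuple(train_ids)
        used_val: tuple[str, ...] = tuple(val_ids)

        if name == "direct":
            cls_cfg = dc_replace(cfgs.model, head=HEAD_CLASSIFICATION)
            model = build_sfcn(cls_cfg, seed=_rep_seed(cfgs.seed, rep, 0xD12))
            tcfg = dc_replace(cfgs.train, seed=_rep_seed(cfgs.seed, rep, 0xD13))
            model, trace = train_model(model, x_tr, y_tr, x_va, y_va, tcfg)
            scores = model.predict(x_te)
            selected["best_epoch"] = int(trace.attrs["best_epoch"])
        elif name == "bag":
            # development set deliberately unused: zero trained parameters
            scores = compute_bag(cfgs.pretrained, x_te, a_te)
            used_train, used_val = (), ()
        elif name == "bag_finetune":
            cn_tr = [i for i in train_ids if data.labels[i] == 0]
            cn_va = [i for i in val_ids if data.labels[i] == 0]
            xc_tr, _, ac_tr = data.stack(cn_tr)
            xc_va, _, ac_va = data.stack(cn_va)
            model = cfgs.pretrained.copy()
            fcfg = _finetune_cfg(cfgs.finetune, _rep_seed(cfgs.seed, rep, 0xBF7))
            model, trace = train_model(model, xc_tr, ac_tr, xc_va, ac_va, fcfg)
            scores = compute_bag(model, x_te, a_te)
            selected["best_epoch"] = int(trace.attrs["best_epoch"])
            used_train, used_val = tuple(cn_tr), tuple(cn_va)
        elif name == "brainage64d":
            # normalization statistics adapted to the task domain (dev only)
            base = calibrate_batchnorm(cfgs.pretrained.copy(),
                                       np.concatenate([x_tr, x_va]))
            f_tr = _batched_features(base, x_tr)
            f_va = _batched_features(base, x_va)
            f_te = _batched_features(base, x_te)
            ridge = fit_logistic_ridge(f_tr, y_tr, f_va, y_va, cfgs.ridge)
            scores = ridge.scores(f_te)
            selected["lambda"] = ridge.lam
            model = ridge
        else:  # brainage64d_finetune
            base = calibrate_batchnorm(cfgs.pretrained.copy(),
                                       np.concatenate([x_tr, x_va]))
            f_tr = _batched_features(base, x_tr)
            f_va = _batched_features(base, x_va)
            ridge = fit_logistic_ridge(f_tr, y_tr, f_va, y_va, cfgs.ridge)
            model = base
            _init_head_from_logistic(model, ridge)
            fcfg = _finetune_cfg(cfgs.finetune, _rep_seed(cfgs.seed, rep, 0xB64))
            model, trace = train_model(model, x_tr, y_tr, x_va, y_va, fcfg)
            scores = model.predict(x_te)
            selected["lambda"] = ridge.lam
            selected["best_epoch"] = int(trace.attrs["best_epoch"])

        results.append(ApproachResult(
            task="AD_CN", approach=name, repetition=rep, dev_size=dev_size,
            auc=auc(scores, y_te), n_dev=plan.n_dev, n_test=len(test_ids),
            selected=selected, train_ids=used_train, val_ids=used_val,
            test_ids=tuple(test_ids)))
        if return_models:
            models[rep] = model
    return (results, models) if return_models else results


# ---------------------------------------------------------------------------
# MCI approaches
# ---------------------------------------------------------------------------

def run_mci_approach(name: str, data: TaskData, plan: SplitPlan,
                     cfgs: ApproachConfigs,
                     ad_models: dict[int, SFCN] | None = None):
    """Run one MCI-progression approach over every repetition.

    The AD2prog variants extract features from the frozen AD-classification
    model of the same repetition (``ad_models[rep]``)."""
    if name not in MCI_APPROACHES:
        raise ConfigurationError(f"unknown MCI approach {name!r}")
    if name != "direct" and not ad_models:
        raise ConfigurationError(f"approach {name!r} requires trained AD models per repetition")
    results = []
    dev_size = plan.dev_size if plan.dev_size is not None else plan.n_dev
    for rep in range(plan.k):
        train_ids = plan.ids_by_role(rep, "train")
        val_ids = plan.ids_by_role(rep, "validation")
        test_ids = plan.ids_by_role(rep, "test")
        x_tr, y_tr, _ = data.stack(train_ids)
        x_va, y_va, _ = data.stack(val_ids)
        x_te, y_te, _ = data.stack(test_ids)
        selected: dict = {}
        if name == "direct":
            cls_cfg = dc_replace(cfgs.model, head=HEAD_CLASSIFICATION)
            model = build_sfcn(cls_cfg, seed=_rep_seed(cfgs.seed, rep, 0x3C1))
            tcfg = dc_replace(cfgs.train, seed=_rep_seed(cfgs.seed, rep, 0x3C2))
            model, trace = train_model(model, x_tr, y_tr, x_va, y_va, tcfg)
            scores = model.predict(x_te)
            selected["best_epoch"] = int(trace.attrs["best_epoch"])
        else:
            if rep not in ad_models:
                raise ConfigurationError(f"missing AD model for repetition {rep}")
            frozen = ad_models[rep]
            f_tr = _batched_features(frozen, x_tr)
            f_va = _batched_features(frozen, x_va)
            f_te = _batched_features(frozen, x_te)
            ridge = fit_logistic_ridge(f_tr, y_tr, f_va, y_va, cfgs.ridge)
            scores = ridge.scores(f_te)
            selected["lambda"] = ridge.lam
        results.append(ApproachResult(
            task="MCI_PROG", approach=name, repetition=rep, dev_size=dev_size,
            auc=auc(scores, y_te), n_dev=plan.n_dev, n_test=len(test_ids),
            selected=selected, train_ids=tuple(train_ids),
            val_ids=tuple(val_ids), test_ids=tuple(test_ids)))
    return results


# ---------------------------------------------------------------------------
# Learning curves
# ---------------------------------------------------------------------------

AD_DEV_SIZE_SCHEDULE = (50, 100, 200, 300, 400, 500, 600, 700, 800, 900, 997)
MCI_DEV_SIZE_SCHEDULE = (50, 100, 150, 200, 250, 300, 350, 400, 448)


def run_learning_curve(task: str, names, data: TaskData, plan: SplitPlan,
                       cfgs: ApproachConfigs, sizes,
                       ad_models: dict[int, SFCN] | None = None) -> list[ApproachResult]:
    """Re-run approaches on development subsamples against the fixed test set.

    For MCI AD2prog variants, ``ad_models`` must be the models trained at the
    full AD sample size; only the logistic stage sees the subsample."""
    results: list[ApproachResult] = []
    for size in sizes:
        if size > plan.n_dev:
            raise ValidationError(f"development size {size} exceeds available {plan.n_dev}")
        sub = subsample_development(plan, size) if size < plan.n_dev else plan
        if sub.dev_size is None:
            sub = dc_replace(sub, dev_size=size)
        for name in names:
            if task == "AD_CN":
                results.extend(run_ad_approach(name, data, sub, cfgs))
            else:
                results.extend(run_mci_approach(name, data, sub, cfgs, ad_models=ad_models))
    return results


def audit_leakage(results: list[ApproachResult]) -> bool:
    """True iff no test subject ever appears in a training/validation stage."""
    for r in results:
        test = set(r.test_ids)
        if test & set(r.train_ids) or test & set(r.val_ids):
            return False
    return True
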