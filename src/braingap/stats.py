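"""AUC, corrected resampled t-test, FDR, balance checks, and summaries.

The corrected resampled t-test (Nadeau & Bengio) compares two approaches
evaluated on k repeated random development/test splits.  Because the k
development sets overlap, the naive paired t-test is anti-conservative; the
corrected statistic inflates the variance term:

    t = d_bar / sqrt((1/k + n2/n1) * s_d^2),   df = k - 1

where d_j are the per-repetition AUC differences, s_d^2 the unbiased sample
variance, n1 the development (train + validation) size and n2 the test size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def auc(scores, labels) -> float:
    """Area under the ROC curve: P(score+ > score-) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


@dataclass
class PairedAUCSeries:
    approach_a: str
    approach_b: str
    auc_a: np.ndarray
    auc_b: np.ndarray
    n_dev: int          # n1: development (train + validation) size
    n_test: int         # n2: test size

    def __post_init__(self) -> None:
        self.auc_a = np.asarray(self.auc_a, dtype=float)
        self.auc_b = np.asarray(self.auc_b, dtype=float)
        if self.auc_a.shape != self.auc_b.shape:
            raise ValidationError("AUC series must have equal length")

    @property
    def k(self) -> int:
        return len(self.auc_a)


def corrected_resampled_ttest(series: PairedAUCSeries) -> tuple[float, float]:
    """Two-sided corrected resampled t-test over k repeated splits."""
    k = series.k
    if k < 2:
        raise ValidationError(f"need k >= 2 repetitions, got {k}")
    if series.n_dev <= 0 or series.n_test <= 0:
        raise ValidationError("n_dev and n_test must be positive")
    d = series.auc_a - series.auc_b
    d_bar = d.mean()
    s2 = d.var(ddof=1)
    if s2 == 0.0:
        # degenerate: identical series -> no evidence of a difference
        return (0.0, 1.0) if d_bar == 0.0 else (np.inf * np.sign(d_bar), 0.0)
    t = d_bar / np.sqrt((1.0 / k + series.n_test / series.n_dev) * s2)
    p = 2.0 * sps.t.sf(abs(t), df=k - 1)
    return float(t), float(p)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def check_match_balance(matched) -> tuple[float, float]:
    """(paired-t p for within-pair age differences, chi-square GoF p for sex).

    The sex test compares group-a sex counts against the group-b counts as
    the expected distribution.
    """
    if len(matched.pairs) < 2:
        raise ValidationError("need at least 2 matched pairs")
    rec = matched.records
    ages_a = np.array([rec[a].age for a, b, _ in matched.pairs])
    ages_b = np.array([rec[b].age for a, b, _ in matched.pairs])
    diffs = ages_a - ages_b
    if np.allclose(diffs.var(ddof=1), 0.0):
        p_age = 1.0 if np.allclose(diffs.mean(), 0.0) else 0.0
    else:
        p_age = float(sps.ttest_rel(ages_a, ages_b).pvalue)
    obs = np.array([sum(rec[a].sex == s for a, b, _ in matched.pairs) for s in ("F", "M")])
    exp = np.array([sum(rec[b].sex == s for a, b, _ in matched.pairs) for s in ("F", "M")])
    keep = exp > 0
    if np.array_equal(obs, exp):
        p_sex = 1.0
    else:
        p_sex = float(sps.chisquare(obs[keep], f_exp=exp[keep]).pvalue)
    return p_age, p_sex


def box_summary(values) -> dict[str, float]:
    """Median, quartiles (linear interpolation), 1.5*IQR whisker bounds,
    and outlier count."""
    v = np.sort(np.asarray(values, dtype=float))
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_bound) & (v <= hi_bound)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
            "n_outliers": int(np.sum((v < lo_bound) | (v > hi_bound)))}


def summarize(results, q: float = 0.05) -> dict[str, pd.DataFrame]:
    """Per-approach mean +/- std AUCs, all pairwise corrected t-tests with
    BH flags, and box-plot summary statistics.

    ``results`` is an iterable of ApproachResult-like objects (fields:
    approach, repetition, dev_size, auc, plus n_dev/n_test via the plan
    recorded on the result).
    """
    rows = [{"task": r.task, "approach": r.approach, "repetition": r.repetition,
             "dev_size": r.dev_size, "auc": r.auc,
             "n_dev": r.n_dev, "n_test": r.n_test} for r in results]
    df = pd.DataFrame(rows)
    desc_rows, comp_rows, box_rows = [], [], []
    for (task, dev_size), g in df.groupby(["task", "dev_size"], dropna=False):
        approaches = sorted(g["approach"].unique())
        for ap in approaches:
            vals = g.loc[g["approach"] == ap].sort_values("repetition")["auc"].to_numpy()
            if len(vals) == 1:
                warnings.warn(f"single repetition for {ap}; std reported as 0")
            desc_rows.append({"task": task, "dev_size": dev_size, "approach": ap,
                              "mean_auc": vals.mean(),
                              "std_auc": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                              "k": len(vals)})
            box_rows.append({"task": task, "dev_size": dev_size, "approach": ap,
                             **box_summary(vals)})
        pair_ps = []
        for i, a in enumerate(approaches):
            for b in approaches[i + 1:]:
                ga = g.loc[g["approach"] == a].sort_values("repetition")
                gb = g.loc[g["approach"] == b].sort_values("repetition")
                if len(ga) < 2 or len(ga) != len(gb):
                    continue
                series = PairedAUCSeries(
                    a, b, ga["auc"].to_numpy(), gb["auc"].to_numpy(),
                    n_dev=int(ga["n_dev"].iloc[0]), n_test=int(ga["n_test"].iloc[0]))
                t, p = corrected_resampled_ttest(series)
                comp_rows.append({"task": task, "dev_size": dev_size,
                                  "approach_a": a, "approach_b": b,
                                  "mean_diff": series.auc_a.mean() - series.auc_b.mean(),
                                  "t": t, "p": p})
                pair_ps.append(p)
        if pair_ps:  # FDR family: all pairs within one (task, dev_size) table
            flags = bh_fdr(pair_ps, q=q)
            for row, f in zip(comp_rows[-len(pair_ps):], flags):
                row["fdr_significant"] = bool(f)
    return {"descriptives": pd.DataFrame(desc_rows),
            "comparisons": pd.DataFrame(comp_rows),
            "box": pd.DataFrame(box_rows)}
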