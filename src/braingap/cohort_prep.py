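"""Trajectory labeling, per-scanner age/sex matching, and repeated splits.

The three exclusion rules for the MCI-progression task are: more than one
diagnosis change, reversion to CN, and missing diagnoses that leave the
stable/progressive call indeterminate within the 36-month window.
Matching pairs the two diagnostic groups within each scanner model by exact
sex and nearest age; splits are nested 80:20 development:test then 80:20
train:validation, stratified per scanner and class, repeated k times.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ValidationError
from .synthetic_data import PMCI_WINDOW_MONTHS, SubjectRecord

log = logging.getLogger(__name__)


class TrajectoryLabel(str, Enum):
    sMCI = "sMCI"
    pMCI = "pMCI"
    excluded_multichange = "excluded_multichange"
    excluded_reversion = "excluded_reversion"
    excluded_missing = "excluded_missing"
    CN = "CN"
    AD = "AD"


def label_trajectory(visits: list[tuple[int, str]],
                     window_months: int = PMCI_WINDOW_MONTHS) -> TrajectoryLabel:
    """Classify one subject's visit sequence.

    pMCI: first AD diagnosis at month <= 36 with exactly one diagnosis
    change.  sMCI: remained MCI with observed follow-up reaching month 36.
    Exclusions: more than one diagnosis change; reversion to CN; missing
    or short follow-up that leaves the call indeterminate.
    """
    if not visits:
        raise ValidationError("empty visit list")
    visits = sorted(visits, key=lambda v: v[0])
    if visits[0][0] != 0:
        raise ValidationError(f"baseline visit must be at month 0, got {visits[0][0]}")
    baseline = visits[0][1]
    if baseline == "CN":
        return TrajectoryLabel.CN
    if baseline == "AD":
        return TrajectoryLabel.AD
    if baseline != "MCI":
        raise ValidationError(f"unrecognized baseline diagnosis {baseline!r}")

    observed = [(m, dx) for m, dx in visits if dx != "missing"]
    seq = [dx for _, dx in observed]
    changes = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    if changes > 1:
        return TrajectoryLabel.excluded_multichange
    if "CN" in seq[1:]:
        return TrajectoryLabel.excluded_reversion

    ad_months = [m for m, dx in observed if dx == "AD"]
    mci_months = [m for m, dx in observed if dx == "MCI"]
    first_ad = min(ad_months) if ad_months else None
    last_mci = max(mci_months)
    if first_ad is not None and first_ad <= window_months:
        return TrajectoryLabel.pMCI
    # no conversion within the window; stable only if MCI status is
    # observed through the full window, otherwise indeterminate
    if last_mci >= window_months:
        return TrajectoryLabel.sMCI
    return TrajectoryLabel.excluded_missing


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedCohort:
    task: str
    group_a: str
    group_b: str
    pairs: list[tuple[str, str, str]]           # (id_a, id_b, scanner_id)
    excluded: list[str]
    records: dict[str, SubjectRecord] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [i for a, b, _ in self.pairs for i in (a, b)]

    def labels(self) -> dict[str, int]:
        """0 for group_a members, 1 for group_b members."""
        out = {}
        for a, b, _ in self.pairs:
            out[a] = 0
            out[b] = 1
        return out


def match_groups(records: list[SubjectRecord], group_a: str, group_b: str,
                 labels: dict[str, str] | None = None,
                 task: str = "") -> MatchedCohort:
    """Pair the two diagnostic groups by exact sex and nearest age, per scanner.

    Within each scanner model, every member of the smaller group is greedily
    paired (ascending age, ties by subject id) to the unmatched same-sex
    member of the larger group with minimal absolute age difference; excess
    members of the larger group are excluded.  A minority member with no
    same-sex candidate left is dropped with a logged warning.
    """
    labels = labels or {r.subject_id: r.intended_label or r.group for r in records}
    by_scanner: dict[str, dict[str, list[SubjectRecord]]] = {}
    for r in records:
        lab = labels.get(r.subject_id)
        if lab not in (group_a, group_b):
            continue
        by_scanner.setdefault(r.scanner_id, {group_a: [], group_b: []})[lab].append(r)

    pairs: list[tuple[str, str, str]] = []
    excluded: list[str] = []
    kept: dict[str, SubjectRecord] = {}
    for sc in sorted(by_scanner):
        a_list = by_scanner[sc][group_a]
        b_list = by_scanner[sc][group_b]
        minority, majority = (a_list, b_list) if len(a_list) <= len(b_list) else (b_list, a_list)
        minority_is_a = minority is a_list
        available = {r.subject_id: r for r in majority}
        for m in sorted(minority, key=lambda r: (r.age, r.subject_id)):
            candidates = [r for r in available.values() if r.sex == m.sex]
            if not candidates:
                log.warning("no same-sex match for %s (sex=%s) in scanner %s; dropped",
                            m.subject_id, m.sex, sc)
                excluded.append(m.subject_id)
                continue
            best = min(candidates, key=lambda r: (abs(r.age - m.age), r.subject_id))
            del available[best.subject_id]
            a, b = (m, best) if minority_is_a else (best, m)
            pairs.append((a.subject_id, b.subject_id, sc))
            kept[a.subject_id] = a
            kept[b.subject_id] = b
        excluded.extend(sorted(available))
    return MatchedCohort(task=task, group_a=group_a, group_b=group_b,
                         pairs=pairs, excluded=excluded, records=kept)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitPlan:
    """k repetitions of {train, validation, test} roles for matched subjects."""

    assignments: list[dict[str, str]]       # per repetition: subject_id -> role
    labels: dict[str, int]                  # subject_id -> class (0/1)
    scanners: dict[str, str]
    k: int
    seed: int
    dev_size: int | None = None             # None = full development set

    def ids_by_role(self, rep: int, role: str) -> list[str]:
        return sorted(i for i, r in self.assignments[rep].items() if r == role)

    def dev_ids(self, rep: int) -> list[str]:
        return sorted(i for i, r in self.assignments[rep].items()
                      if r in ("train", "validation"))

    @property
    def n_test(self) -> int:
        return len(self.ids_by_role(0, "test"))

    @property
    def n_dev(self) -> int:
        return len(self.dev_ids(0))


def make_splits(matched: MatchedCohort, k: int = 50, seed: int = 0) -> SplitPlan:
    """Nested 80:20 development:test then 80:20 train:validation splits.

    Applied independently per scanner and per class; repeated k times with
    fresh shuffles.  Stratum counts use half-up rounding: test = round(0.2 n),
    validation = round(0.2 (n - test)), remainder train.
    """
    if not matched.pairs:
        raise ValidationError("matched cohort is empty")
    labels = matched.labels()
    scanners = {i: sc for a, b, sc in matched.pairs for i in (a, b)}
    strata: dict[tuple[str, int], list[str]] = {}
    for sid, lab in labels.items():
        strata.setdefault((scanners[sid], lab), []).append(sid)
    for (sc, lab), ids in strata.items():
        if len(ids) < 5:
            warnings.warn(f"stratum (scanner={sc}, class={lab}) has only "
                          f"{len(ids)} participants; 80:20 rounding is coarse")
    assignments: list[dict[str, str]] = []
    for rep in range(k):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B11, rep]))
        roles: dict[str, str] = {}
        for key in sorted(strata):
            ids = sorted(strata[key])
            rng.shuffle(ids)
            n = len(ids)
            n_test = _round_half_up(0.2 * n)
            n_val = _round_half_up(0.2 * (n - n_test))
            for sid in ids[:n_test]:
                roles[sid] = "test"
            for sid in ids[n_test:n_test + n_val]:
                roles[sid] = "validation"
            for sid in ids[n_test + n_val:]:
                roles[sid] = "train"
        assignments.append(roles)
    return SplitPlan(assignments=assignments, labels=labels, scanners=scanners,
                     k=k, seed=seed)


def subsample_development(plan: SplitPlan, size: int) -> SplitPlan:
    """Subsample each repetition's development set to ``size`` participants.

    Class-balanced: size/2 per class, drawn from the development set; the
    test set is untouched.  The subsample is re-split 80:20 into train and
    validation per class.  An odd size falls back to size - 1 with a warning.
    """
    if size > plan.n_dev:
        raise ValidationError(f"requested size {size} exceeds development size {plan.n_dev}")
    if size == plan.n_dev:  # identity: same membership and roles
        return SplitPlan(assignments=[dict(a) for a in plan.assignments],
                         labels=plan.labels, scanners=plan.scanners,
                         k=plan.k, seed=plan.seed, dev_size=size)
    if size % 2:
        warnings.warn(f"odd development size {size}; using {size - 1}")
        size -= 1
    per_class = size // 2
    assignments: list[dict[str, str]] = []
    for rep in range(plan.k):
        rng = np.random.default_rng(
            np.random.SeedSequence([plan.seed, 0x50B5, rep, size]))
        roles: dict[str, str] = {
            i: "test" for i in plan.ids_by_role(rep, "test")}
        dev = plan.dev_ids(rep)
        for lab in (0, 1):
            ids = sorted(i for i in dev if plan.labels[i] == lab)
            if per_class > len(ids):
                raise ValidationError(
                    f"class {lab} has only {len(ids)} development subjects; "
                    f"cannot subsample {per_class}")
            chosen = list(rng.choice(ids, size=per_class, replace=False))
            rng.shuffle(chosen)
            n_val = _round_half_up(0.2 * per_class)
            for sid in chosen[:n_val]:
                roles[sid] = "validation"
            for sid in chosen[n_val:]:
                roles[sid] = "train"
        assignments.append(roles)
    return SplitPlan(assignments=assignments, labels=plan.labels,
                     scanners=plan.scanners, k=plan.k, seed=plan.seed,
                     dev_size=size)
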