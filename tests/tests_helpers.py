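"""Shared builders for the test suite."""

import numpy as np

from braingap.cohort_prep import MatchedCohort
from braingap.synthetic_data import SubjectRecord


def build_matched(n_pairs: int, scanner: str = "s1", seed: int = 0) -> MatchedCohort:
    """A matched cohort of n_pairs (group-a, group-b) pairs on one scanner."""
    rng = np.random.default_rng(seed)
    pairs, records = [], {}
    for i in range(n_pairs):
        age = float(rng.uniform(55, 90))
        sex = "F" if i % 2 else "M"
        a = SubjectRecord(subject_id=f"a{i:04d}", dataset_id="D", scanner_id=scanner,
                          sex=sex, age=age, group="CN", severity=0.0)
        b = SubjectRecord(subject_id=f"b{i:04d}", dataset_id="D", scanner_id=scanner,
                          sex=sex, age=age + float(rng.normal(0, 0.5)), group="AD",
                          severity=1.0)
        pairs.append((a.subject_id, b.subject_id, scanner))
        records[a.subject_id] = a
        records[b.subject_id] = b
    return MatchedCohort(task="AD_CN", group_a="CN", group_b="AD",
                         pairs=pairs, excluded=[], records=records)
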