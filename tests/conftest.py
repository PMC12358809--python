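import numpy as np
import pytest

from braingap.synthetic_data import GeneratorConfig, SubjectRecord


@pytest.fixture
def tiny_config():
    """A fast, deterministic generator config for unit tests."""
    return GeneratorConfig(
        volume_shape=(12, 14, 12),
        n_per_group={"CN": 6, "AD": 6, "sMCI": 4, "pMCI": 4},
        datasets=(("D1", ("s1",)),),
        seed=7,
    )


def make_record(subject_id="S0", scanner="s1", sex="F", age=70.0, group="CN",
                severity=0.0, dataset="D1", label=None, offset=0.0):
    return SubjectRecord(
        subject_id=subject_id, dataset_id=dataset, scanner_id=scanner,
        sex=sex, age=age, group=group, severity=severity,
        brain_age_offset=offset,
        intended_label=label or group)


@pytest.fixture
def make_subject():
    return make_record


@pytest.fixture
def rng():
    return np.random.default_rng(0)
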