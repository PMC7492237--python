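import numpy as np
import pytest

from mmdtl.features import SubjectRecord
from mmdtl.network import ArchitectureSpec, default_architectures, init_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_stage1_arch():
    """A 6-input classifier small enough for finite-difference checks."""
    return ArchitectureSpec(
        "stage1", [6, 5, 4, 3, 2], ["relu", "relu", "relu"],
        [True, True, False], task_count=1,
    )


@pytest.fixture
def small_archs():
    """All three stage architectures on a 10-ROI (45-edge) connectome."""
    return default_architectures(45, widths=(16, 8, 6, 4), task_count=3)


def make_records(n, n_roi, seed, cohort="target", task_names=("a", "b", "c"),
                 n_pos=None, site_cycle=("s0", "s1")):
    """Random valid records with balanced-ish labels for training smoke tests."""
    rng = np.random.default_rng(seed)
    m = n_roi * (n_roi - 1) // 2
    X = np.tanh(rng.normal(0, 0.7, (n, m)))
    records = []
    for i in range(n):
        if cohort == "intermediate":
            labels = None
        elif cohort == "source":
            labels = {"src": int(i % 2)}
        else:
            if n_pos is None:
                labels = {t: int(rng.random() < 0.4) for t in task_names}
            else:
                labels = {t: int(i < n_pos) for t in task_names}
        records.append(
            SubjectRecord(f"r{i:03d}", site_cycle[i % len(site_cycle)], cohort,
                          X[i], labels=labels)
        )
    return records


@pytest.fixture
def toy_weights(toy_stage1_arch):
    return init_weights(toy_stage1_arch, 7)
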