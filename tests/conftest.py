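import numpy as np
import pytest

from twindiff.io import CohortDesign, ProbeMatrix, SampleRecord


def build_design(
    n_pairs: int = 4, n_ctrl: int = 2, n_batches: int = 2, subtype: str = "SLE"
) -> CohortDesign:
    """Hand-built valid cohort design for unit tests."""
    recs = []
    for k in range(n_pairs):
        batch = f"b{k % n_batches}"
        recs.append(
            SampleRecord(f"tw{k}P", "P", f"pr{k}", f"st{k}", subtype, batch, 30.0, "F", "Caucasian")
        )
        recs.append(
            SampleRecord(f"tw{k}U", "U", f"pr{k}", f"st{k}", subtype, batch, 30.0, "F", "Caucasian")
        )
        for c in range(n_ctrl):
            recs.append(
                SampleRecord(
                    f"ct{k}{c}", "C", "", f"st{k}", "NONE", batch, 31.0, "F", "Caucasian"
                )
            )
    return CohortDesign(recs)


def matrix_for(design: CohortDesign, values) -> ProbeMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    probe_ids = [f"g{i}" for i in range(values.shape[0])]
    return ProbeMatrix(probe_ids, design.subject_ids, values)


@pytest.fixture
def tiny_design() -> CohortDesign:
    return build_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
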