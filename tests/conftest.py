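import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from spcquant import ExperimentDesign, PSMRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def design() -> ExperimentDesign:
    """The emulated study layout: 2 conditions x 3 biological replicates."""
    return ExperimentDesign(
        conditions={
            "control": ("ctrl_1", "ctrl_2", "ctrl_3"),
            "treatment": ("trt_1", "trt_2", "trt_3"),
        }
    )


def psm(
    peptide: str = "PEPTIDEK",
    proteins=("A",),
    score: float = 30.0,
    sample: str = "ctrl_1",
    spectrum: str = "s1",
    decoy: bool = False,
) -> PSMRecord:
    return PSMRecord(
        sample_id=sample,
        spectrum_id=spectrum,
        peptide=peptide,
        proteins=tuple(proteins),
        score=score,
        is_decoy=decoy,
    )


@pytest.fixture
def psm_factory():
    return psm


@pytest.fixture
def small_counts(design) -> pd.DataFrame:
    """Hand-sized SpC matrix over the 2x3 design."""
    return pd.DataFrame(
        {
            "ctrl_1": [10, 10, 2, 0],
            "ctrl_2": [12, 9, 3, 0],
            "ctrl_3": [8, 11, 2, 1],
            "trt_1": [10, 10, 0, 5],
            "trt_2": [11, 10, 0, 9],
            "trt_3": [9, 10, 1, 7],
        },
        index=["P1", "P2", "P3", "P4"],
    )
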