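import numpy as np
import pandas as pd
import pytest

from metskip.io_counts import Codeset, MetRole, ProbeClass, ProbeDefinition, RawCountMatrix
from metskip.synthetic_cohort import CohortSimConfig, default_codeset, simulate_cohort


@pytest.fixture(scope="session")
def codeset5() -> Codeset:
    """Minimal valid panel: one wt, one junction, one housekeeper, controls."""
    return Codeset((
        ProbeDefinition("MET_wt", ProbeClass.ENDOGENOUS, MetRole.MET_WT),
        ProbeDefinition("MET_d14", ProbeClass.ENDOGENOUS, MetRole.MET_DEX14),
        ProbeDefinition("ACTB", ProbeClass.HOUSEKEEPING),
        ProbeDefinition("NEG_A", ProbeClass.NEGATIVE_CONTROL),
        ProbeDefinition("POS_A", ProbeClass.POSITIVE_CONTROL),
    ))


@pytest.fixture(scope="session")
def sim_codeset() -> Codeset:
    return default_codeset()


@pytest.fixture(scope="session")
def cohort7(sim_codeset):
    """The default study-composition cohort at a fixed seed."""
    matrix, truth = simulate_cohort(CohortSimConfig(seed=7))
    return matrix, truth


def make_matrix(codeset: Codeset, rows: dict[str, list[int]]) -> RawCountMatrix:
    """Build a RawCountMatrix from {sample_id: counts in codeset order}."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=codeset.names)
    df.index.name = "sample_id"
    return RawCountMatrix(counts=df)


@pytest.fixture()
def make_uniform_matrix(codeset5):
    """Cohorts where normalization is trivial: controls/housekeepers constant."""

    def _make(wt: list[int], d14: list[int]) -> RawCountMatrix:
        n = len(wt)
        rows = {
            f"S{i:04d}": [wt[i], d14[i], 500, 5, 1000]
            for i in range(n)
        }
        return make_matrix(codeset5, rows)

    return _make
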