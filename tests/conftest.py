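import numpy as np
import pandas as pd
import pytest

from glycocc import (
    CohortSpec,
    GlycanAnnotation,
    GlycanMatrix,
    SimulationConfig,
    simulate_multi_cohort,
)
from glycocc.panel import PEAKS


@pytest.fixture(scope="session")
def panel() -> GlycanAnnotation:
    return GlycanAnnotation.default()


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort (default effect pattern), raw-area scale."""
    cfg = SimulationConfig(
        seed=7,
        cohorts=(CohortSpec("small", 60, 60, 3),),
        cohort_effect_scale=(1.0,),
    )
    table, truth = simulate_multi_cohort(cfg)[0]
    return table, truth


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SimulationConfig.null(
        seed=11, cohorts=(CohortSpec("null", 50, 50, 2),), cohort_effect_scale=(1.0,)
    )
    table, truth = simulate_multi_cohort(cfg)[0]
    return table, truth


def percent_matrix(rows: np.ndarray, sample_prefix: str = "s") -> GlycanMatrix:
    """Build a percent-scale GlycanMatrix from a (n, 24) array of percentages."""
    rows = np.asarray(rows, dtype=float)
    idx = [f"{sample_prefix}{i}" for i in range(rows.shape[0])]
    return GlycanMatrix(pd.DataFrame(rows, index=idx, columns=list(PEAKS)),
                        "percent_total")


@pytest.fixture
def toy_percent_matrix():
    """Four-structure toy profile: all mass on FA2 / FA2G2 / FA2BG2 / FA2G2S2."""
    row = np.zeros(24)
    row[[3, 13, 14, 22]] = [40.0, 30.0, 20.0, 10.0]  # GP4, GP14, GP15, GP23
    return percent_matrix(row[None, :])
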