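import numpy as np
import pandas as pd
import pytest

from flyspan import simulate
from flyspan.io import ALT, MISSING, REF, GenotypeMatrix


@pytest.fixture
def small_config():
    """A fast-but-realistic panel: 60 lines, 50 markers, a planted DR effect."""
    return simulate.SimulationConfig(
        n_lines=60,
        n_markers=50,
        causal_marker_index=10,
        effect_dr=4.0,
        seed=7,
    )


@pytest.fixture
def small_study(small_config):
    genotypes = simulate.simulate_genotypes(small_config)
    deaths, phenotypes, truth = simulate.simulate_lifespans(genotypes, small_config)
    return genotypes, deaths, phenotypes, truth


@pytest.fixture
def toy_matrix():
    """Hand-built 4-line x 3-marker matrix covering all call states."""
    calls = np.array(
        [
            [REF, ALT, MISSING],
            [ALT, ALT, REF],
            [REF, REF, REF],
            [ALT, MISSING, ALT],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        ["L1", "L2", "L3", "L4"],
        ["M1", "M2", "M3"],
        calls,
        np.array(["2L", "2L", "3R"], dtype=object),
        np.array([100, 200, 500], dtype=np.int64),
    )


@pytest.fixture
def toy_phenotypes():
    rows = []
    for i, m in enumerate([30, 35, 40, 41, 42, 50]):
        rows.append((f"L{i + 1}", "DR", float(m)))
        rows.append((f"L{i + 1}", "AL", float(m - 2)))
    return pd.DataFrame(rows, columns=["line_id", "diet", "median_lifespan"])
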