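import numpy as np
import pytest

from cellspan import CellLifeHistory, LifeHistoryDataset, SyntheticConfig, generate_population


def make_cell(cell_id="c1", sizes=(20.0, 24.0, 30.0), times=(0.0, 1.5, 3.1), fluor=None, **kw):
    return CellLifeHistory(
        cell_id=cell_id,
        sizes=np.asarray(sizes, dtype=float),
        times=np.asarray(times, dtype=float),
        avg_fluor=None if fluor is None else np.asarray(fluor, dtype=float),
        **kw,
    )


@pytest.fixture
def tiny_dataset():
    """Two hand-written cells, enough to exercise parsing and summaries."""
    return LifeHistoryDataset(
        cells=[
            make_cell("A", sizes=[20, 24, 30], times=[0, 1.5, 3.1]),
            make_cell("B", sizes=[15, 18, 22, 27, 35], times=[0, 1.2, 2.6, 4.1, 6.5]),
        ],
        name="tiny",
        source="memory",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter synthetic cohort at the standard cohort size."""
    return generate_population(SyntheticConfig(n_cells=119, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """1000-cell cohort for calibration and distributional checks."""
    return generate_population(SyntheticConfig(n_cells=1000, seed=11))
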