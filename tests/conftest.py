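import numpy as np
import pandas as pd
import pytest

from sadscale import SimConfig, TransectTable, paired_transect_tables, run_simulation


@pytest.fixture
def small_table() -> TransectTable:
    """Four collinear transects with hand-checkable distances.

    Centres at A(0,0), B(2,0), C(-2.5,0), D(3,0): concentric order from A
    is (A,B,C,D) (distances 0, 2, 2.5, 3) while the sequential chain is
    (A,B,D,C) (from B the nearest remaining transect is D at distance 1).
    """
    rows = []
    coords = {"A": (0.0, 0.0), "B": (2.0, 0.0), "C": (-2.5, 0.0), "D": (3.0, 0.0)}
    community = {
        "A": {"sp1": 1, "sp2": 4, "sp5": 2},
        "B": {"sp1": 2, "sp3": 1, "sp5": 1},
        "C": {"sp2": 8, "sp4": 3, "sp6": 1},
        "D": {"sp1": 1, "sp4": 2, "sp6": 5},
    }
    classes = {
        "sp1": "high",
        "sp2": "high",
        "sp3": "high",
        "sp4": "low",
        "sp5": "low",
        "sp6": "low",
    }
    for t, (x, y) in coords.items():
        for sp, n in community[t].items():
            rows.append(
                {
                    "transect_id": t,
                    "site": "s1",
                    "x": x,
                    "y": y,
                    "species_id": sp,
                    "abundance": n,
                    "dispersal_class": classes[sp],
                }
            )
    return TransectTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def paired_landscapes():
    """One well-mixed and one aggregated community, desk scale (L = 256)."""
    high = run_simulation(SimConfig(kernel="global", seed=1), track_richness=False)
    low = run_simulation(
        SimConfig(kernel="gaussian", sigma=1.0, seed=2), track_richness=False
    )
    return high, low


@pytest.fixture(scope="session")
def sim_table(paired_landscapes) -> TransectTable:
    """24 paired transect windows (256 cells each) from the two communities."""
    high, low = paired_landscapes
    return paired_transect_tables(high, low, n_transects=24, transect_cells=256, seed=5)


@pytest.fixture(scope="session")
def dispersal_panel():
    """Replicated high/low dispersal contrast over 10 seeds at L = 256."""
    from sadscale import dispersal_experiment

    return dispersal_experiment(seeds=range(10), square_exponents=(2, 3, 4, 5, 6))
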