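import numpy as np
import pytest

from dungproxy import SimConfig, run_virtual_study


def tiny_config(**overrides) -> SimConfig:
    """A scaled-down virtual study for fast unit tests.

    Keeps the full May-October season and the spatial layout but shrinks
    the herd, the calendar and the grid so a run takes well under a second.
    """
    base = dict(
        seed=0,
        herd_size=25,
        days_in_month={m: 6 for m in range(5, 11)},
        monitored_days_range=(2, 3),
        snapshots_per_day_range=(3, 4),
        grazing_hours_per_day=4.0,
        waypoint_grid=(4, 4),
        study_cell_size_m=40.0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def tiny_study():
    """One deterministic small virtual study shared across tests."""
    with pytest.warns(UserWarning):  # off-design monitored-day count is logged
        return run_virtual_study(tiny_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
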