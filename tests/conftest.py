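import numpy as np
import pytest

from mitoagree.annotations import CaseAnnotations, StudyDataset
from mitoagree.simulate import ObserverProfile, SimulationParams, simulate_study


def make_dataset(case_points: dict[str, dict[str, list[tuple[float, float]]]]) -> StudyDataset:
    """Build a StudyDataset from {case_id: {observer_id: [(x, y), ...]}}."""
    ds = StudyDataset()
    for case_id, per_obs in case_points.items():
        for observer_id, pts in per_obs.items():
            ds.add(CaseAnnotations(case_id, observer_id, list(pts)))
    return ds


@pytest.fixture
def two_observer_dataset() -> StudyDataset:
    """Three cases, two observers, hand-checkable match structure."""
    return make_dataset(
        {
            "c1": {"a": [(0, 0), (100, 100)], "b": [(5, 5), (300, 300)]},
            "c2": {"a": [], "b": []},
            "c3": {"a": [(50, 50)], "b": [(50, 80), (400, 10)]},
        }
    )


@pytest.fixture
def small_sim_params() -> SimulationParams:
    """A compact noiseless two-observer study for recovery checks."""
    return SimulationParams(
        n_cases=40,
        count_mean=6.0,
        region_width_px=2000,
        region_height_px=2000,
        n_incomplete_cases=0,
        profiles=(
            ObserverProfile("a", base_sensitivity=0.8, size_slope=0.0,
                            fp_rate=0.0, jitter_sigma=2.0),
            ObserverProfile("b", base_sensitivity=0.8, size_slope=0.0,
                            fp_rate=0.0, jitter_sigma=2.0),
        ),
        seed=11,
    )


@pytest.fixture
def small_study(small_sim_params):
    return simulate_study(small_sim_params)
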