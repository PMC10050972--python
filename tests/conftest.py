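import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from nirchar.geometry import WellPlateGeometry
from nirchar.records import SyncedSeries

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def plate() -> WellPlateGeometry:
    return WellPlateGeometry()


def make_series(
    t, intensity, distance, angle=None, velocity=None, direction=None
) -> SyncedSeries:
    """Assemble a SyncedSeries from raw channels for metric-level tests."""
    t = np.asarray(t, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if velocity is None:
        velocity = np.zeros_like(t)
        if t.size > 1:
            velocity[1:] = np.abs(np.diff(distance)) / np.diff(t)
    if angle is None:
        angle = np.full_like(t, 90.0)
    if direction is None:
        direction = np.array(["static"] * t.size, dtype=object)
    return SyncedSeries(
        data=pd.DataFrame(
            {
                "t": t,
                "intensity": np.asarray(intensity, dtype=float),
                "distance": distance,
                "velocity": np.asarray(velocity, dtype=float),
                "angle": np.asarray(angle, dtype=float),
                "direction": direction,
            }
        )
    )
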