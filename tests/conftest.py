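import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from planatox.synthetic_plate import PhaseSchedule, Trajectory, WELL_RADIUS_MM

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phototaxis_schedule():
    return PhaseSchedule.phototaxis()


def make_speed_trajectory(speeds, phases, dt=0.2, well_radius=WELL_RADIUS_MM):
    """Trajectory whose per-frame displacement magnitudes realize ``speeds``.

    Headings cycle through +x, +y, -x, -y so the path stays near the origin
    regardless of length.  ``speeds[k]`` is realized as the displacement
    into frame k (so instantaneous_speed reproduces it; speeds[0] is
    overwritten by the convention that frame 0 copies frame 1).
    """
    speeds = np.asarray(speeds, float)
    n = len(speeds)
    dirs = np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
    steps = speeds[1:, None] * dt * dirs[np.arange(n - 1) % 4]
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Trajectory(
        t=np.arange(n) * dt,
        xy=xy,
        body_length=np.full(n, 4.0),
        phase=np.asarray(phases, dtype=object),
        well_radius_mm=well_radius,
    )


def make_phototaxis_trajectory(
    dark1_speed=1.0, light_speed=1.0, dark2_speed=1.0, dt=0.2
):
    """Constant-speed-per-phase trajectory on the standard assay schedule."""
    n1, n2, n3 = int(60 / dt), int(120 / dt), int(120 / dt)
    speeds = np.concatenate(
        [
            np.full(n1, dark1_speed),
            np.full(n2, light_speed),
            np.full(n3, dark2_speed),
        ]
    )
    phases = np.concatenate(
        [
            np.full(n1, "dark1"),
            np.full(n2, "light"),
            np.full(n3, "dark2"),
        ]
    ).astype(object)
    return make_speed_trajectory(speeds, phases, dt=dt)


def make_heat_trajectory(body_length, dt=0.2):
    """Stationary heat-assay trajectory with a prescribed body-length series."""
    n = len(body_length)
    return Trajectory(
        t=np.arange(n) * dt,
        xy=np.zeros((n, 2)),
        body_length=np.asarray(body_length, float),
        phase=np.full(n, "heat", dtype=object),
        assay="heat",
    )
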