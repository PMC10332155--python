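"""Endpoint extraction rules on constructed trajectories."""

import numpy as np
import pandas as pd
import pytest

from planatox import behavior_endpoints as be
from planatox.synthetic_plate import Trajectory, WELL_RADIUS_MM

from conftest import (
    make_heat_trajectory,
    make_phototaxis_trajectory,
    make_speed_trajectory,
)


# ------------------------------------------------------------------ speed ---

def test_static_animal_has_zero_speed():
    traj = make_speed_trajectory(np.zeros(50), np.full(50, "dark2"))
    assert np.all(be.instantaneous_speed(traj) == 0.0)


def test_straight_line_speed():
    # 1 mm/s straight line sampled at 5 Hz: 0.2 mm displacement per frame
    n = 16
    xy = np.column_stack([-1.5 + 0.2 * np.arange(n), np.zeros(n)])
    traj = Trajectory(
        t=np.arange(n) * 0.2, xy=xy, body_length=np.ones(n),
        phase=np.full(n, "dark2", dtype=object),
    )
    assert be.instantaneous_speed(traj) == pytest.approx(np.ones(n), rel=1e-12)


def test_circular_path_speed_matches_geometry():
    period, r, dt = 20.0, 2.0, 0.2
    t = np.arange(0, 60, dt)
    xy = np.column_stack(
        [r * np.cos(2 * np.pi * t / period), r * np.sin(2 * np.pi * t / period)]
    )
    traj = Trajectory(
        t=t, xy=xy, body_length=np.ones(len(t)),
        phase=np.full(len(t), "dark2", dtype=object),
    )
    expected = 2 * np.pi * r / period
    got = be.instantaneous_speed(traj)[1:]
    assert np.allclose(got, expected, rtol=0.01)  # chord vs arc discretization


def test_non_uniform_timestamps_error():
    traj = make_speed_trajectory(np.ones(10), np.full(10, "dark2"))
    traj.t = traj.t.copy()
    traj.t[5] += 0.05
    with pytest.raises(ValueError, match="non-uniform"):
        be.instantaneous_speed(traj)


# -------------------------------------------------------- gliding / resting ---

def test_gliding_speed_constant():
    traj = make_speed_trajectory(np.ones(100), np.full(100, "dark2"))
    assert be.gliding_speed(traj).value == pytest.approx(1.0)


def test_gliding_speed_excludes_resting_frames():
    speeds = np.array([0.1] * 50 + [1.0] * 50)
    traj = make_speed_trajectory(speeds, np.full(100, "dark2"))
    gs = be.gliding_speed(traj)
    assert gs.value == pytest.approx(1.0)
    assert not gs.all_resting
    # all-frame mean mode for comparison
    assert be.gliding_speed(traj, exclude_resting=False).value < 1.0


def test_gliding_speed_all_resting_flag():
    traj = make_speed_trajectory(np.full(60, 0.05), np.full(60, "dark2"))
    gs = be.gliding_speed(traj)
    assert gs.value == 0.0 and gs.all_resting


def test_gliding_speed_missing_phase_errors():
    traj = make_speed_trajectory(np.ones(10), np.full(10, "light"))
    with pytest.raises(ValueError):
        be.gliding_speed(traj, phase="dark2")


@pytest.mark.parametrize(
    "speeds, expected",
    [(np.ones(40), 0.0), (np.zeros(40), 100.0),
     (np.array([0.1] * 20 + [0.5] * 20), 50.0)],
)
def test_percent_resting(speeds, expected):
    traj = make_speed_trajectory(speeds, np.full(len(speeds), "dark2"))
    assert be.percent_resting(traj, "dark2") == pytest.approx(expected)


def test_percent_resting_rejects_other_phases():
    traj = make_speed_trajectory(np.ones(10), np.full(10, "dark1"))
    with pytest.raises(ValueError):
        be.percent_resting(traj, "dark1")


# -------------------------------------------------------------- phototaxis ---

def test_phototaxis_floor_rule():
    # both means below the 0.1 mm/s floor -> ratio 1.0, not phototaxing
    traj = make_phototaxis_trajectory(dark1_speed=0.05, light_speed=0.05)
    res = be.phototaxis_response(traj)
    assert res.ratio == pytest.approx(1.0)
    assert not res.phototaxing


def test_phototaxis_boundary_is_strict():
    traj = make_phototaxis_trajectory(dark1_speed=1.0, light_speed=1.1)
    res = be.phototaxis_response(traj)
    assert res.ratio == pytest.approx(1.1)
    assert not res.phototaxing  # exactly 1.1 does not exceed 1.1


def test_phototaxis_clear_response():
    traj = make_phototaxis_trajectory(dark1_speed=0.5, light_speed=1.0)
    res = be.phototaxis_response(traj)
    assert res.ratio == pytest.approx(2.0)
    assert res.phototaxing


def test_phototaxis_uses_second_minute_of_light():
    """Speeds in the first light minute are irrelevant to the score."""
    dt = 0.2
    n1, n2, n3 = int(60 / dt), int(120 / dt), int(120 / dt)
    speeds = np.concatenate(
        [np.full(n1, 0.5), np.full(n2 // 2, 5.0), np.full(n2 // 2, 1.0),
         np.full(n3, 0.5)]
    )
    phases = np.concatenate(
        [np.full(n1, "dark1"), np.full(n2, "light"), np.full(n3, "dark2")]
    ).astype(object)
    traj = make_speed_trajectory(speeds, phases, dt=dt)
    assert be.phototaxis_response(traj).ratio == pytest.approx(2.0, rel=0.02)


def test_phototaxis_invariant_to_subfloor_changes():
    a = make_phototaxis_trajectory(dark1_speed=0.02, light_speed=0.5)
    b = make_phototaxis_trajectory(dark1_speed=0.08, light_speed=0.5)
    assert be.phototaxis_response(a).ratio == pytest.approx(
        be.phototaxis_response(b).ratio
    )


# ------------------------------------------------------------------ bursts ---

def test_burst_counting():
    dt = 0.2
    n = 200
    base = np.full(n, 0.5)
    traj = make_speed_trajectory(base, np.full(n, "dark2"), dt=dt)
    assert be.count_locomotor_bursts(traj) == 0

    burst = base.copy()
    burst[50:61] = 2.0  # one 2.2 s episode
    traj = make_speed_trajectory(burst, np.full(n, "dark2"), dt=dt)
    assert be.count_locomotor_bursts(traj) == 1

    two = base.copy()
    two[50:60] = 2.0
    two[61:71] = 2.0  # one sub-threshold frame between episodes
    traj = make_speed_trajectory(two, np.full(n, "dark2"), dt=dt)
    assert be.count_locomotor_bursts(traj) == 2

    short = base.copy()
    short[50:53] = 2.0  # 0.6 s < 1 s minimum
    traj = make_speed_trajectory(short, np.full(n, "dark2"), dt=dt)
    assert be.count_locomotor_bursts(traj) == 0


# ----------------------------------------------------------------- anxiety ---

def _positions_trajectory(xy):
    n = len(xy)
    return Trajectory(
        t=np.arange(n) * 0.2, xy=xy, body_length=np.ones(n),
        phase=np.full(n, "dark2", dtype=object),
    )


def test_anxiety_extremes():
    R = WELL_RADIUS_MM
    wall = np.column_stack([np.full(100, 0.99 * R), np.zeros(100)])
    center = np.zeros((100, 2))
    area_frac = 1 - 0.75**2
    assert be.anxiety_score(_positions_trajectory(wall)) == pytest.approx(1 / area_frac)
    assert be.anxiety_score(_positions_trajectory(center)) == 0.0


def test_anxiety_uniform_occupancy_is_one():
    rng = np.random.default_rng(42)
    n = 200_000
    r = WELL_RADIUS_MM * np.sqrt(rng.random(n))
    a = rng.uniform(0, 2 * np.pi, n)
    xy = np.column_stack([r * np.cos(a), r * np.sin(a)])
    assert be.anxiety_score(_positions_trajectory(xy)) == pytest.approx(1.0, abs=0.02)


# -------------------------------------------------------------- scrunching ---

def _sine_length(amp_frac, period, n_cycles, latency=60.0, dt=0.2, L0=4.0,
                 total=510.0):
    t = np.arange(0, total, dt)
    L = np.full_like(t, L0)
    active = (t >= latency) & (t < latency + n_cycles * period)
    L[active] += L0 * amp_frac / 2 * np.sin(2 * np.pi * (t[active] - latency) / period)
    return L


def test_scrunching_constant_length_false():
    traj = make_heat_trajectory(np.full(2550, 4.0))
    assert not be.detect_scrunching(traj)


def test_scrunching_detected_for_valid_oscillation():
    traj = make_heat_trajectory(_sine_length(0.3, 3.0, 5))
    assert be.detect_scrunching(traj)


def test_scrunching_below_amplitude_threshold():
    traj = make_heat_trajectory(_sine_length(0.10, 3.0, 5))
    assert not be.detect_scrunching(traj)


def test_scrunching_period_out_of_band():
    traj = make_heat_trajectory(_sine_length(0.3, 9.0, 5))
    assert not be.detect_scrunching(traj)


def test_noxious_metrics_no_reaction():
    traj = make_heat_trajectory(np.full(2550, 4.0))
    assert be.noxious_response_metrics(traj) == (0.0, 0.0)


def test_noxious_metrics_onset_and_strength():
    traj = make_heat_trajectory(_sine_length(0.3, 3.0, 6, latency=100.0))
    rate, strength = be.noxious_response_metrics(traj)
    # onset detected near the first oscillation peak (latency + period/4)
    assert rate == pytest.approx(1.0 / 100.0, rel=0.06)
    assert strength == pytest.approx(0.3, rel=0.15)


def test_noxious_rate_monotone_in_onset():
    early = be.noxious_response_metrics(
        make_heat_trajectory(_sine_length(0.3, 3.0, 6, latency=50.0))
    )
    late = be.noxious_response_metrics(
        make_heat_trajectory(_sine_length(0.3, 3.0, 6, latency=200.0))
    )
    assert early.ns_rate > late.ns_rate > 0


# ------------------------------------------------------------- compilation ---

def _records_frame(rows):
    return pd.DataFrame(rows)


def _basic_record(rid, alive=True, day=7, conc=0.0):
    return {
        "record_id": rid, "chemical": "x", "concentration_uM": conc,
        "worm_type": "adult", "day": day, "run": 1,
        "alive": alive, "abnormal_shape": False,
        "stickiness_A": True, "stickiness_Z": False,
    }


def test_compile_dead_animals_only_contribute_lethality():
    records = _records_frame(
        [_basic_record("a"), _basic_record("b", alive=False)]
    )
    trajs = {"a": make_phototaxis_trajectory()}
    table = be.compile_endpoints(records, trajs)
    assert set(table.loc[table.record_id == "b", "endpoint"]) == {"lethality"}
    assert table.loc[(table.record_id == "b") & (table.endpoint == "lethality"),
                     "value"].iloc[0] == 1.0
    assert "speed" in set(table.loc[table.record_id == "a", "endpoint"])


def test_compile_day7_has_no_heat_endpoints():
    records = _records_frame([_basic_record("a", day=7)])
    table = be.compile_endpoints(
        records, {"a": make_phototaxis_trajectory()},
        {"a": make_heat_trajectory(np.full(2550, 4.0))},
    )
    assert not {"scrunching", "ns_rate", "ns_strength"} & set(table.endpoint)


def test_compile_day12_includes_heat_endpoints():
    records = _records_frame([_basic_record("a", day=12)])
    table = be.compile_endpoints(
        records, {"a": make_phototaxis_trajectory()},
        {"a": make_heat_trajectory(_sine_length(0.3, 3.0, 5))},
    )
    assert {"scrunching", "ns_rate", "ns_strength"} <= set(table.endpoint)


def test_compile_reduced_n_after_deaths():
    """3 dead of 24 at one concentration -> n = 21 for behavioral endpoints."""
    rows = []
    for i in range(24):
        rows.append(_basic_record(f"w{i}", alive=i >= 3, conc=316.0))
    records = _records_frame(rows)
    trajs = {f"w{i}": make_phototaxis_trajectory() for i in range(3, 24)}
    table = be.compile_endpoints(records, trajs)
    assert (table.endpoint == "lethality").sum() == 24
    assert (table.endpoint == "speed").sum() == 21


def test_compile_orphan_errors():
    records = _records_frame([_basic_record("a")])
    with pytest.raises(ValueError, match="without records"):
        be.compile_endpoints(
            records,
            {"a": make_phototaxis_trajectory(), "ghost": make_phototaxis_trajectory()},
        )
    with pytest.raises(ValueError, match="without trajectories"):
        be.compile_endpoints(records, {})


def test_compile_empty_input():
    assert be.compile_endpoints(pd.DataFrame(), {}).empty


def test_endpoint_class_lists():
    assert {k for k, v in be.ENDPOINT_CLASSES.items() if v == "normal"} == {
        "speed", "locomotor_bursts", "ns_rate", "ns_strength"
    }
    assert {k for k, v in be.ENDPOINT_CLASSES.items() if v == "skewed"} == {
        "resting_dark", "resting_blue", "anxiety"
    }
    assert {k for k, v in be.ENDPOINT_CLASSES.items() if v == "binary"} == {
        "lethality", "body_shape", "stickiness_A", "stickiness_Z",
        "phototaxis", "scrunching",
    }
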