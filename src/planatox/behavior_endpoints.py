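"""Per-animal behavioral endpoints from well trajectories.

Endpoints and their analysis classes:

========== =========================================================== ========
endpoint    definition                                                  class
========== =========================================================== ========
lethality   manual viability label (dead animals carry nothing else)    binary
body_shape  manual abnormal-shape label (pass-through)                  binary
stickiness  stuck/unstuck when shaken, before (A) / after (Z) assay     binary
phototaxis  light/dark speed ratio > 1.1 (strict), speeds floored        binary
speed       mean gliding (non-resting) speed in the second dark cycle   normal
resting_*   % of frames below 0.2 mm/s (dark2 and blue phases)          skewed
locomotor_bursts  episodes of >=1.5 mm/s sustained >=1 s, whole assay   normal
anxiety     wall-annulus occupancy normalized by annulus area fraction  skewed
scrunching  >=3 consecutive body-length oscillation cycles under heat   binary
ns_rate     1 / latency to scrunching onset (0 if none)                 normal
ns_strength mean normalized oscillation amplitude (0 if none)           normal
========== =========================================================== ========

Key numeric rules: resting threshold 0.2 mm/s; speed floor 0.1 mm/s applied
to the phototaxis phase means; phototaxis requires the ratio to *exceed*
1.1; the "second minute of the light cycle" is the half-open [60 s, 120 s)
window within the blue phase.
"""

from __future__ import annotations

from typing import Dict, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic_plate import Trajectory

__all__ = [
    "REST_THRESHOLD_MM_S",
    "SPEED_FLOOR_MM_S",
    "PHOTOTAXIS_RATIO",
    "BURST_THRESHOLD_MM_S",
    "BURST_MIN_DURATION_S",
    "ANXIETY_ANNULUS_WIDTH",
    "ENDPOINT_CLASSES",
    "DEFAULT_TAILS",
    "GlidingSpeed",
    "PhotoResponse",
    "NoxiousResponse",
    "instantaneous_speed",
    "gliding_speed",
    "percent_resting",
    "phototaxis_response",
    "count_locomotor_bursts",
    "anxiety_score",
    "detect_scrunching",
    "noxious_response_metrics",
    "compile_endpoints",
]

REST_THRESHOLD_MM_S = 0.2
SPEED_FLOOR_MM_S = 0.1
PHOTOTAXIS_RATIO = 1.1
BURST_THRESHOLD_MM_S = 1.5
BURST_MIN_DURATION_S = 1.0
ANXIETY_ANNULUS_WIDTH = 0.25
SCRUNCH_MIN_CYCLES = 3
SCRUNCH_AMPLITUDE_FRAC = 0.2
SCRUNCH_PERIOD_BAND_S = (1.0, 6.0)

#: Statistical family of each endpoint (fixed lookup; drives test selection).
ENDPOINT_CLASSES: Dict[str, str] = {
    "lethality": "binary",
    "body_shape": "binary",
    "stickiness_A": "binary",
    "stickiness_Z": "binary",
    "phototaxis": "binary",
    "scrunching": "binary",
    "speed": "normal",
    "locomotor_bursts": "normal",
    "ns_rate": "normal",
    "ns_strength": "normal",
    "resting_dark": "skewed",
    "resting_blue": "skewed",
    "anxiety": "skewed",
}

#: Test direction per endpoint: toxicity raises death/shape/stickiness/resting
#: and lowers speed and light/heat responsiveness; exploratory endpoints stay
#: two-sided.  Overridable wherever a tail argument is accepted.
DEFAULT_TAILS: Dict[str, str] = {
    "lethality": "one_sided_increase",
    "body_shape": "one_sided_increase",
    "stickiness_A": "one_sided_increase",
    "stickiness_Z": "one_sided_increase",
    "phototaxis": "one_sided_decrease",
    "scrunching": "one_sided_decrease",
    "speed": "one_sided_decrease",
    "resting_dark": "one_sided_increase",
    "resting_blue": "one_sided_increase",
    "locomotor_bursts": "two_sided",
    "anxiety": "two_sided",
    "ns_rate": "two_sided",
    "ns_strength": "two_sided",
}


class GlidingSpeed(NamedTuple):
    value: float
    all_resting: bool


class PhotoResponse(NamedTuple):
    ratio: float
    phototaxing: bool


class NoxiousResponse(NamedTuple):
    ns_rate: float      # 1/s; 0 when no scrunching detected
    ns_strength: float  # mean peak-to-trough amplitude / median length


def instantaneous_speed(traj: Trajectory) -> np.ndarray:
    """Per-frame speed (mm/s) from successive displacements.

    The first frame carries the second frame's value so the series has the
    same length as the trajectory.  Requires uniform sampling.
    """
    if len(traj.t) < 2:
        raise ValueError("need at least 2 frames")
    dts = np.diff(traj.t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform timestamps")
    disp = np.hypot(*np.diff(traj.xy, axis=0).T)
    speed = disp / dts[0]
    return np.concatenate([[speed[0]], speed])


def _phase_mask(traj: Trajectory, phase: str) -> np.ndarray:
    mask = traj.phase == phase
    if not mask.any():
        raise ValueError(f"phase {phase!r} not present in trajectory")
    return mask


def gliding_speed(
    traj: Trajectory, phase: str = "dark2", exclude_resting: bool = True
) -> GlidingSpeed:
    """Mean gliding speed (mm/s) within a phase.

    Frames below the resting threshold (0.2 mm/s) are excluded by default —
    the endpoint measures the speed *while gliding*.  If every frame is
    resting the value is 0 with the ``all_resting`` flag set.  Set
    ``exclude_resting=False`` for the plain all-frame mean.
    """
    speeds = instantaneous_speed(traj)[_phase_mask(traj, phase)]
    if exclude_resting:
        moving = speeds[speeds >= REST_THRESHOLD_MM_S]
        if moving.size == 0:
            return GlidingSpeed(0.0, True)
        return GlidingSpeed(float(moving.mean()), False)
    return GlidingSpeed(float(speeds.mean()), bool((speeds < REST_THRESHOLD_MM_S).all()))


def percent_resting(traj: Trajectory, phase: str) -> float:
    """Percent of frames in ``phase`` with speed below 0.2 mm/s."""
    if phase not in ("dark2", "light"):
        raise ValueError("resting is scored in the dark2 or light phase")
    speeds = instantaneous_speed(traj)[_phase_mask(traj, phase)]
    return 100.0 * float((speeds < REST_THRESHOLD_MM_S).mean())


def phototaxis_response(traj: Trajectory) -> PhotoResponse:
    """Light/dark speed ratio and the strict > 1.1 phototaxis call.

    Mean speed over the *second minute* of the blue phase ([60, 120) s into
    the phase) is divided by the mean speed in the first dark cycle; both
    means are floored at 0.1 mm/s to suppress tracking noise in non-moving
    animals.  A ratio of exactly 1.1 does not count as phototaxing.
    """
    speeds = instantaneous_speed(traj)
    dark1 = _phase_mask(traj, "dark1")
    light = _phase_mask(traj, "light")
    t_light = traj.t[light] - traj.t[light][0]
    second_min = light.copy()
    second_min[light] = (t_light >= 60.0) & (t_light < 120.0)
    if not second_min.any():
        raise ValueError("light phase shorter than two minutes")
    dark_mean = max(float(speeds[dark1].mean()), SPEED_FLOOR_MM_S)
    light_mean = max(float(speeds[second_min].mean()), SPEED_FLOOR_MM_S)
    ratio = light_mean / dark_mean
    return PhotoResponse(ratio, ratio > PHOTOTAXIS_RATIO)


def count_locomotor_bursts(
    traj: Trajectory,
    threshold: float = BURST_THRESHOLD_MM_S,
    min_duration_s: float = BURST_MIN_DURATION_S,
) -> int:
    """Number of maximal episodes with speed >= threshold for >= min duration,
    counted over the whole assay (all phases)."""
    speeds = instantaneous_speed(traj)
    dt = traj.t[1] - traj.t[0]
    above = np.concatenate([[False], speeds >= threshold, [False]])
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    min_frames = int(np.ceil(min_duration_s / dt))
    return int(np.sum((ends - starts) >= min_frames))


def anxiety_score(
    traj: Trajectory,
    phase: str = "dark2",
    annulus_width: float = ANXIETY_ANNULUS_WIDTH,
) -> float:
    """Wall-preference score: occupancy of the outer annulus divided by its
    area fraction, so 1.0 means no wall preference and higher means
    thigmotaxis (the 'anxiety' phenotype)."""
    mask = _phase_mask(traj, phase)
    r = np.hypot(traj.xy[mask, 0], traj.xy[mask, 1])
    inner = (1.0 - annulus_width) * traj.well_radius_mm
    occupancy = float((r > inner).mean())
    area_fraction = 1.0 - (1.0 - annulus_width) ** 2
    return occupancy / area_fraction


def _scrunch_cycles(
    traj: Trajectory,
    amplitude_frac: float = SCRUNCH_AMPLITUDE_FRAC,
    period_band_s: Tuple[float, float] = SCRUNCH_PERIOD_BAND_S,
    smooth_s: float = 0.6,
):
    """Consecutive valid oscillation cycles of the body-length series.

    A cycle is a peak->trough->next-peak triple of the smoothed series with
    peak-to-trough amplitude >= ``amplitude_frac`` of the animal's median
    length and peak-to-peak period inside ``period_band_s``.  Returns the
    longest run of consecutive valid cycles as a list of
    (onset_time_s, amplitude_frac, period_s).
    """
    L = traj.body_length.astype(float)
    dt = traj.t[1] - traj.t[0]
    w = max(1, int(round(smooth_s / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        L = np.convolve(L, kernel, mode="same")
    med = float(np.median(traj.body_length))
    min_prominence = 0.5 * amplitude_frac * med
    min_dist = max(1, int(round(period_band_s[0] / dt)))
    peaks, _ = find_peaks(L, prominence=min_prominence, distance=min_dist)
    troughs, _ = find_peaks(-L, prominence=min_prominence, distance=min_dist)
    if len(peaks) < 2 or len(troughs) < 1:
        return []

    cycles = []
    for p0, p1 in zip(peaks, peaks[1:]):
        between = troughs[(troughs > p0) & (troughs < p1)]
        if between.size == 0:
            cycles.append(None)
            continue
        trough = between[np.argmin(L[between])]
        amp = (L[p0] - L[trough]) / med
        period = traj.t[p1] - traj.t[p0]
        ok = amp >= amplitude_frac and period_band_s[0] <= period <= period_band_s[1]
        cycles.append((traj.t[p0], amp, period) if ok else None)

    best, cur = [], []
    for c in cycles:
        if c is None:
            cur = []
        else:
            cur.append(c)
            if len(cur) > len(best):
                best = list(cur)
    return best


def detect_scrunching(traj: Trajectory, min_cycles: int = SCRUNCH_MIN_CYCLES) -> bool:
    """True iff the heat trajectory shows >= ``min_cycles`` consecutive valid
    body-length oscillation cycles (the scrunching gait)."""
    return len(_scrunch_cycles(traj)) >= min_cycles


def noxious_response_metrics(traj: Trajectory) -> NoxiousResponse:
    """Rate (1/latency to oscillation onset) and strength (mean normalized
    amplitude) of the heat response; both 0 when no scrunching is detected."""
    run = _scrunch_cycles(traj)
    if len(run) < SCRUNCH_MIN_CYCLES:
        return NoxiousResponse(0.0, 0.0)
    onset = run[0][0]
    rate = 1.0 / onset if onset > 0 else 0.0
    strength = float(np.mean([c[1] for c in run]))
    return NoxiousResponse(rate, strength)


def compile_endpoints(
    records: pd.DataFrame,
    trajectories: Dict[str, Trajectory],
    heat_trajectories: Optional[Dict[str, Trajectory]] = None,
    tails: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Long per-animal endpoint table from records + trajectories.

    One row per animal per applicable endpoint with columns
    (record_id, chemical, concentration_uM, worm_type, day, run, endpoint,
    value, endpoint_class, tail).  Dead animals contribute only lethality;
    heat-assay endpoints exist only for day-12 records.  Unknown trajectory
    ids, or living records without a phototaxis trajectory, raise with the
    offending identifiers listed.
    """
    heat_trajectories = heat_trajectories or {}
    tails = tails or DEFAULT_TAILS
    if records.empty:
        return pd.DataFrame(
            columns=[
                "record_id", "chemical", "concentration_uM", "worm_type",
                "day", "run", "endpoint", "value", "endpoint_class", "tail",
            ]
        )

    known = set(records["record_id"])
    orphans = (set(trajectories) | set(heat_trajectories)) - known
    if orphans:
        raise ValueError(f"trajectories without records: {sorted(orphans)}")
    alive_ids = set(records.loc[records["alive"], "record_id"])
    missing = alive_ids - set(trajectories)
    if missing:
        raise ValueError(f"living records without trajectories: {sorted(missing)}")

    rows = []
    for rec in records.itertuples(index=False):
        ident = {
            "record_id": rec.record_id,
            "chemical": rec.chemical,
            "concentration_uM": rec.concentration_uM,
            "worm_type": rec.worm_type,
            "day": rec.day,
            "run": rec.run,
        }

        def add(endpoint: str, value: float) -> None:
            rows.append(
                {
                    **ident,
                    "endpoint": endpoint,
                    "value": float(value),
                    "endpoint_class": ENDPOINT_CLASSES[endpoint],
                    "tail": tails[endpoint],
                }
            )

        add("lethality", not rec.alive)
        if not rec.alive:
            continue
        add("body_shape", rec.abnormal_shape)
        add("stickiness_A", rec.stickiness_A)
        add("stickiness_Z", rec.stickiness_Z)

        traj = trajectories[rec.record_id]
        add("speed", gliding_speed(traj).value)
        add("resting_dark", percent_resting(traj, "dark2"))
        add("resting_blue", percent_resting(traj, "light"))
        add("phototaxis", phototaxis_response(traj).phototaxing)
        add("locomotor_bursts", count_locomotor_bursts(traj))
        add("anxiety", anxiety_score(traj))

        if rec.day == 12 and rec.record_id in heat_trajectories:
            heat = heat_trajectories[rec.record_id]
            add("scrunching", detect_scrunching(heat))
            ns = noxious_response_metrics(heat)
            add("ns_rate", ns.ns_rate)
            add("ns_strength", ns.ns_strength)

    return pd.DataFrame(rows)
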