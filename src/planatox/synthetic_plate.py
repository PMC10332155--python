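"""Seeded simulator of complete 96-well planarian screening datasets.

The screen this package analyzes exposes one animal per well, one
concentration per row (7 half-log doses + an in-plate water control row,
12 animals per row), in duplicate runs with the row assignment cyclically
shifted down 3 rows in the second run to control for edge effects, for
n = 24 animals per concentration per developmental stage (adult and
regenerating).  Behavior is recorded in two assays:

* phototaxis — 1 min red (dark 1), 2 min blue (light), 2 min red (dark 2);
* noxious heat — a 510 s ramp (peltier 65 °C, switched to 54 °C at 330 s),
  assayed on day 12 only, eliciting the oscillatory "scrunching" gait.

This module generates everything downstream stages consume without any raw
video: per-animal 2-D trajectories inside a circular well (two-state
rest/glide Markov speed process, bounded-random-walk heading, reflective
wall with a configurable wall-following bias, a blue-light speed factor and
a heat-triggered body-length oscillation), plus Bernoulli outcomes for
lethality, abnormal body shape, stickiness and photo/scrunch competence.
Dose dependence enters through per-effect Hill curves.  Everything is
reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_CONC",
    "WELL_RADIUS_MM",
    "SAMPLE_RATE_HZ",
    "STICKINESS_RPM",
    "Phase",
    "PhaseSchedule",
    "PlateDesign",
    "EffectCurve",
    "DoseEffectConfig",
    "BehaviorBaseline",
    "BehaviorParams",
    "Trajectory",
    "ScreenDataset",
    "build_layout",
    "simulate_trajectory",
    "simulate_trajectory_batch",
    "simulate_heat_batch",
    "simulate_screen",
    "simulate_control_bank",
    "DEFAULT_CONCENTRATIONS_UM",
]

#: Concentration sentinel for the in-plate water control row.
CONTROL_CONC = 0.0
#: Standard 96-well inner radius (mm); the tracking arena.
WELL_RADIUS_MM = 3.2
#: Default trajectory sampling rate (Hz).
SAMPLE_RATE_HZ = 5.0
#: Plate-shaking speeds (RPM) for the stickiness assay, recorded as metadata:
#: (worm_type, day) -> RPM.
STICKINESS_RPM = {
    ("adult", 7): 1097,
    ("regenerating", 7): 1200,
    ("adult", 12): 1350,
    ("regenerating", 12): 1350,
}

#: Canonical tested half-log series (µM ae), ascending.
DEFAULT_CONCENTRATIONS_UM = (1.0, 3.16, 10.0, 31.6, 100.0, 316.0, 1000.0)


# --------------------------------------------------------------------------
# Assay schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    name: str
    start_s: float
    end_s: float
    light: str  # "red" (dark to planarians) or "blue"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhaseSchedule:
    """Contiguous, non-overlapping assay phases plus sampling parameters."""

    phases: Tuple[Phase, ...]
    sample_rate_hz: float = SAMPLE_RATE_HZ
    # heat-ramp metadata (None for the phototaxis assay)
    peltier_initial_C: Optional[float] = None
    peltier_switch_s: Optional[float] = None
    peltier_final_C: Optional[float] = None

    def __post_init__(self) -> None:
        prev_end = 0.0
        for ph in self.phases:
            if ph.duration_s <= 0:
                raise ValueError(f"phase {ph.name} has non-positive duration")
            if abs(ph.start_s - prev_end) > 1e-9:
                raise ValueError("phases must be contiguous from t=0")
            prev_end = ph.end_s

    @property
    def duration_s(self) -> float:
        return self.phases[-1].end_s

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate_hz

    def frame_phases(self) -> np.ndarray:
        t = self.frame_times()
        out = np.empty(self.n_frames, dtype=object)
        for ph in self.phases:
            out[(t >= ph.start_s) & (t < ph.end_s)] = ph.name
        return out

    @classmethod
    def phototaxis(cls, sample_rate_hz: float = SAMPLE_RATE_HZ) -> "PhaseSchedule":
        """dark1 (60 s red) / light (120 s blue) / dark2 (120 s red)."""
        return cls(
            phases=(
                Phase("dark1", 0.0, 60.0, "red"),
                Phase("light", 60.0, 180.0, "blue"),
                Phase("dark2", 180.0, 300.0, "red"),
            ),
            sample_rate_hz=sample_rate_hz,
        )

    @classmethod
    def heat(cls, sample_rate_hz: float = SAMPLE_RATE_HZ) -> "PhaseSchedule":
        """Single 510 s ramp phase; peltier 65 °C switched to 54 °C at 330 s."""
        return cls(
            phases=(Phase("heat", 0.0, 510.0, "red"),),
            sample_rate_hz=sample_rate_hz,
            peltier_initial_C=65.0,
            peltier_switch_s=330.0,
            peltier_final_C=54.0,
        )


# --------------------------------------------------------------------------
# Plate design and layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateDesign:
    """One 96-well plate: 7 concentrations + control, one row each."""

    concentrations_uM: Tuple[float, ...] = DEFAULT_CONCENTRATIONS_UM
    n_rows: int = 8
    n_cols: int = 12
    run_index: int = 1
    worm_type: str = "adult"
    day: int = 7

    def __post_init__(self) -> None:
        if self.run_index not in (1, 2):
            raise ValueError("run_index must be 1 or 2")
        if self.worm_type not in ("adult", "regenerating"):
            raise ValueError("worm_type must be 'adult' or 'regenerating'")
        if self.day not in (7, 12):
            raise ValueError("assessment day must be 7 or 12")


def build_layout(design: PlateDesign) -> Dict[int, float]:
    """Row -> concentration map for one plate.

    Run 1 canonical order: row 0 is the in-plate control, rows 1..7 carry the
    test concentrations ascending.  Run 2 is run 1 cyclically shifted down 3
    rows (row r of run 2 receives run 1's row (r - 3) mod 8), so every
    concentration changes rows between replicates (edge-effect control).
    """
    if len(design.concentrations_uM) != design.n_rows - 1:
        raise ValueError(
            f"need exactly {design.n_rows - 1} test concentrations + control; "
            f"got {len(design.concentrations_uM)}"
        )
    base = [CONTROL_CONC] + sorted(design.concentrations_uM)
    if design.run_index == 1:
        return {r: base[r] for r in range(design.n_rows)}
    return {r: base[(r - 3) % design.n_rows] for r in range(design.n_rows)}


# --------------------------------------------------------------------------
# Dose-effect configuration (Hill curves)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectCurve:
    """Hill interpolation between a control baseline and a max-dose asymptote.

    value(c) = baseline + (max_effect - baseline) * c^h / (EC50^h + c^h)

    For probability effects both endpoints must lie in [0, 1]; for multiplier
    effects both must be positive.
    """

    baseline: float
    max_effect: float
    ec50_uM: float = 100.0
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0:
            raise ValueError("EC50 must be positive")
        if self.hill <= 0:
            raise ValueError("Hill slope must be positive")

    def value(self, conc_uM) -> np.ndarray:
        c = np.asarray(conc_uM, dtype=float)
        frac = np.where(
            c > 0, c**self.hill / (self.ec50_uM**self.hill + c**self.hill), 0.0
        )
        return self.baseline + (self.max_effect - self.baseline) * frac


PROBABILITY_EFFECTS = frozenset(
    {"lethality_prob", "shape_prob", "phototaxis_prob", "stickiness_shift",
     "scrunch_prob"}
)
MULTIPLIER_EFFECTS = frozenset(
    {"speed_multiplier", "rest_multiplier", "ns_latency_multiplier"}
)
EFFECT_NAMES = tuple(sorted(PROBABILITY_EFFECTS | MULTIPLIER_EFFECTS))


def _null_curves() -> Dict[str, EffectCurve]:
    return {
        "lethality_prob": EffectCurve(0.01, 0.01),
        "shape_prob": EffectCurve(0.005, 0.005),
        "speed_multiplier": EffectCurve(1.0, 1.0),
        "rest_multiplier": EffectCurve(1.0, 1.0),
        "phototaxis_prob": EffectCurve(0.9, 0.9),
        # probability of remaining stuck at the assay RPM
        "stickiness_shift": EffectCurve(0.8, 0.8),
        "scrunch_prob": EffectCurve(0.9, 0.9),
        "ns_latency_multiplier": EffectCurve(1.0, 1.0),
    }


@dataclass(frozen=True)
class DoseEffectConfig:
    """Per-effect Hill curves, with optional (effect, worm_type, day) overrides."""

    curves: Dict[str, EffectCurve] = field(default_factory=_null_curves)
    overrides: Dict[Tuple[str, str, int], EffectCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(EFFECT_NAMES) - set(self.curves)
        if missing:
            raise ValueError(f"missing effect curves: {sorted(missing)}")
        for name, curve in list(self.curves.items()) + [
            (k[0], v) for k, v in self.overrides.items()
        ]:
            if name in PROBABILITY_EFFECTS:
                for v in (curve.baseline, curve.max_effect):
                    if not 0.0 <= v <= 1.0:
                        raise ValueError(f"{name}: probabilities must be in [0, 1]")
            elif name in MULTIPLIER_EFFECTS:
                if curve.baseline <= 0 or curve.max_effect <= 0:
                    raise ValueError(f"{name}: multipliers must be positive")
            else:
                raise ValueError(f"unknown effect {name!r}")

    def curve(self, effect: str, worm_type: str, day: int) -> EffectCurve:
        return self.overrides.get((effect, worm_type, day), self.curves[effect])

    # ---- presets used throughout the tests and the reproduction scripts ----

    @classmethod
    def null(cls) -> "DoseEffectConfig":
        """No dose dependence anywhere (negative-control chemical)."""
        return cls()

    @classmethod
    def glyphosate_like(cls) -> "DoseEffectConfig":
        """Lethality confined to the top dose; no sublethal effects."""
        curves = _null_curves()
        curves["lethality_prob"] = EffectCurve(0.01, 0.9, ec50_uM=950.0, hill=9.0)
        return cls(curves=curves)

    @classmethod
    def rc_like(cls) -> "DoseEffectConfig":
        """Strong formulation: locomotor suppression from tens of µM in
        adults, lethality at 316+ µM in adults / 1 mM in regenerating
        animals, and abnormal shapes in regenerating animals at the top
        sublethal dose."""
        curves = _null_curves()
        curves["lethality_prob"] = EffectCurve(0.01, 0.95, ec50_uM=400.0, hill=3.5)
        curves["speed_multiplier"] = EffectCurve(1.0, 0.25, ec50_uM=20.0, hill=2.0)
        curves["rest_multiplier"] = EffectCurve(1.0, 6.0, ec50_uM=20.0, hill=2.0)
        curves["shape_prob"] = EffectCurve(0.005, 0.05, ec50_uM=500.0, hill=4.0)
        curves["phototaxis_prob"] = EffectCurve(0.9, 0.3, ec50_uM=150.0, hill=2.0)
        overrides = {
            ("lethality_prob", "regenerating", 7): EffectCurve(
                0.01, 0.9, ec50_uM=900.0, hill=6.0
            ),
            ("lethality_prob", "regenerating", 12): EffectCurve(
                0.01, 0.9, ec50_uM=900.0, hill=6.0
            ),
            ("shape_prob", "regenerating", 7): EffectCurve(
                0.0, 0.85, ec50_uM=250.0, hill=4.0
            ),
            ("shape_prob", "regenerating", 12): EffectCurve(
                0.0, 0.75, ec50_uM=250.0, hill=4.0
            ),
        }
        return cls(curves=curves, overrides=overrides)


# --------------------------------------------------------------------------
# Behavioral baselines and per-animal parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehaviorBaseline:
    """Stage-specific control behavior.

    Gliding speed ~1 mm/s for adults and roughly half that for regenerating
    tails keeps the analysis thresholds (0.2 mm/s resting, 0.1 mm/s floor)
    meaningful.  Bout-duration means set the rest/glide Markov rates.
    """

    glide_speed_mm_s: float
    speed_noise_sd: float
    rest_speed_sd: float
    glide_bout_s: float
    rest_bout_s: float
    heading_sd_rad: float
    wall_bias: float
    photo_factor: float
    body_length_mm: float
    length_noise_rel_sd: float
    scrunch_latency_s: float
    scrunch_amplitude: float  # peak-to-trough, relative to median length
    scrunch_period_s: float
    animal_cv: float = 0.15  # lognormal animal-to-animal speed variation

    @classmethod
    def adult(cls) -> "BehaviorBaseline":
        return cls(
            glide_speed_mm_s=1.0, speed_noise_sd=0.18, rest_speed_sd=0.04,
            glide_bout_s=25.0, rest_bout_s=2.5, heading_sd_rad=0.35,
            wall_bias=0.25, photo_factor=1.6, body_length_mm=4.0,
            length_noise_rel_sd=0.01, scrunch_latency_s=90.0,
            scrunch_amplitude=0.3, scrunch_period_s=3.0,
        )

    @classmethod
    def regenerating(cls) -> "BehaviorBaseline":
        return cls(
            glide_speed_mm_s=0.55, speed_noise_sd=0.12, rest_speed_sd=0.04,
            glide_bout_s=12.0, rest_bout_s=5.0, heading_sd_rad=0.45,
            wall_bias=0.25, photo_factor=1.6, body_length_mm=2.0,
            length_noise_rel_sd=0.012, scrunch_latency_s=120.0,
            scrunch_amplitude=0.28, scrunch_period_s=3.0,
        )

    @classmethod
    def for_worm_type(cls, worm_type: str) -> "BehaviorBaseline":
        return cls.adult() if worm_type == "adult" else cls.regenerating()


@dataclass(frozen=True)
class BehaviorParams:
    """Fully resolved per-animal simulation parameters."""

    glide_speed_mm_s: float = 1.0
    speed_noise_sd: float = 0.18
    rest_speed_sd: float = 0.04
    p_glide_to_rest: float = 0.008
    p_rest_to_glide: float = 0.08
    heading_sd_rad: float = 0.35
    wall_bias: float = 0.25
    photo_factor: float = 1.6
    body_length_mm: float = 4.0
    length_noise_rel_sd: float = 0.01
    scrunch: bool = True
    scrunch_latency_s: float = 90.0
    scrunch_amplitude: float = 0.3
    scrunch_period_s: float = 3.0


# --------------------------------------------------------------------------
# Trajectory container
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-stamped 2-D positions and body lengths inside a circular well."""

    t: np.ndarray           # (F,) seconds, uniform
    xy: np.ndarray          # (F, 2) mm, |p| <= well radius
    body_length: np.ndarray  # (F,) mm
    phase: np.ndarray       # (F,) phase names
    well_radius_mm: float = WELL_RADIUS_MM
    assay: str = "phototaxis"

    def __post_init__(self) -> None:
        r = np.hypot(self.xy[:, 0], self.xy[:, 1])
        if np.any(r > self.well_radius_mm + 1e-9):
            raise ValueError("positions outside the well radius")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.body_length <= 0):
            raise ValueError("body lengths must be positive")

    def to_frame(self, record_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": record_id,
                "t": self.t,
                "x": self.xy[:, 0],
                "y": self.xy[:, 1],
                "body_length": self.body_length,
                "phase": self.phase,
            }
        )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def simulate_trajectory_batch(
    params: Sequence[BehaviorParams],
    schedule: PhaseSchedule,
    rng: np.random.Generator,
    well_radius_mm: float = WELL_RADIUS_MM,
) -> List[Trajectory]:
    """Simulate ``len(params)`` phototaxis-style trajectories in lock-step.

    Speed follows a two-state (rest/glide) Markov chain; gliding speed is
    multiplied by the animal's photo-response factor during the blue phase.
    Heading performs a bounded random walk with an optional wall-following
    bias near the wall; the boundary is reflective.
    """
    n = len(params)
    F = schedule.n_frames
    dt = 1.0 / schedule.sample_rate_hz
    phases = schedule.frame_phases()
    is_light = np.array(
        [ph is not None and str(ph) == "light" for ph in phases]
    )

    def arr(attr: str) -> np.ndarray:
        return np.array([getattr(p, attr) for p in params], dtype=float)

    glide = arr("glide_speed_mm_s")
    noise = arr("speed_noise_sd")
    rest_sd = arr("rest_speed_sd")
    p_gr = arr("p_glide_to_rest")
    p_rg = arr("p_rest_to_glide")
    head_sd = arr("heading_sd_rad")
    wall_bias = arr("wall_bias")
    photo = arr("photo_factor")
    L0 = arr("body_length_mm")
    len_sd = arr("length_noise_rel_sd")

    R = well_radius_mm
    pos = np.empty((F, n, 2))
    # start uniform over the inner 90% of the disk
    r0 = 0.9 * R * np.sqrt(rng.random(n))
    a0 = rng.uniform(0, 2 * np.pi, n)
    pos[0] = np.column_stack([r0 * np.cos(a0), r0 * np.sin(a0)])
    heading = rng.uniform(0, 2 * np.pi, n)
    gliding = rng.random(n) >= p_gr / np.maximum(p_gr + p_rg, 1e-12)  # ~stationary

    for k in range(1, F):
        u = rng.random(n)
        gliding = np.where(gliding, u >= p_gr, u < p_rg)
        mult = np.where(is_light[k], photo, 1.0)
        sp_glide = np.maximum(rng.normal(glide * mult, noise), 0.0)
        sp_rest = np.abs(rng.normal(0.0, rest_sd))
        speed = np.where(gliding, sp_glide, sp_rest)

        heading = heading + rng.normal(0.0, head_sd, n)
        p = pos[k - 1]
        r = np.hypot(p[:, 0], p[:, 1])
        near = r > 0.8 * R
        if near.any():
            phi = np.arctan2(p[near, 1], p[near, 0])
            t1 = phi + np.pi / 2
            t2 = phi - np.pi / 2
            d1 = _wrap_angle(t1 - heading[near])
            d2 = _wrap_angle(t2 - heading[near])
            dd = np.where(np.abs(d1) <= np.abs(d2), d1, d2)
            heading[near] = heading[near] + wall_bias[near] * dd

        new = p + dt * speed[:, None] * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        rn = np.hypot(new[:, 0], new[:, 1])
        out = rn > R
        if out.any():
            scale = (2 * R - rn[out]) / rn[out]
            new[out] *= scale[:, None]
            phi = np.arctan2(new[out, 1], new[out, 0])
            heading[out] = 2 * phi + np.pi - heading[out]
        pos[k] = new

    lengths = L0[None, :] * (1.0 + rng.normal(0.0, 1.0, (F, n)) * len_sd[None, :])
    lengths = np.maximum(lengths, 0.05)
    t = schedule.frame_times()
    return [
        Trajectory(
            t=t.copy(), xy=pos[:, i].copy(), body_length=lengths[:, i].copy(),
            phase=phases.copy(), well_radius_mm=R, assay="phototaxis",
        )
        for i in range(n)
    ]


def simulate_heat_batch(
    params: Sequence[BehaviorParams],
    schedule: PhaseSchedule,
    rng: np.random.Generator,
    well_radius_mm: float = WELL_RADIUS_MM,
) -> List[Trajectory]:
    """Heat-ramp trajectories: small positional jitter, body-length series
    that oscillates (scrunching) after the animal's latency if competent."""
    n = len(params)
    F = schedule.n_frames
    t = schedule.frame_times()
    phases = schedule.frame_phases()
    R = well_radius_mm

    L0 = np.array([p.body_length_mm for p in params])
    len_sd = np.array([p.length_noise_rel_sd for p in params])
    amp = np.array([p.scrunch_amplitude for p in params])
    period = np.array([p.scrunch_period_s for p in params])
    latency = np.array([p.scrunch_latency_s for p in params])
    competent = np.array([p.scrunch for p in params])

    lengths = L0[None, :] * (1.0 + rng.normal(0.0, 1.0, (F, n)) * len_sd[None, :])
    tt = t[:, None] - latency[None, :]
    osc = (amp[None, :] / 2.0) * np.sin(2 * np.pi * tt / period[None, :])
    active = (tt >= 0) & competent[None, :] & (latency[None, :] < t[-1])
    lengths = lengths + np.where(active, L0[None, :] * osc, 0.0)
    lengths = np.maximum(lengths, 0.05)

    # low-amplitude positional jitter around a random start, clamped to the well
    r0 = 0.8 * R * np.sqrt(rng.random(n))
    a0 = rng.uniform(0, 2 * np.pi, n)
    start = np.column_stack([r0 * np.cos(a0), r0 * np.sin(a0)])
    steps = rng.normal(0.0, 0.03, (F, n, 2))
    steps[0] = 0.0
    pos = start[None, :, :] + np.cumsum(steps, axis=0)
    rr = np.hypot(pos[..., 0], pos[..., 1])
    scale = np.minimum(1.0, 0.98 * R / np.maximum(rr, 1e-12))
    pos = pos * scale[..., None]

    return [
        Trajectory(
            t=t.copy(), xy=pos[:, i].copy(), body_length=lengths[:, i].copy(),
            phase=phases.copy(), well_radius_mm=R, assay="heat",
        )
        for i in range(n)
    ]


def simulate_trajectory(
    params: BehaviorParams,
    schedule: PhaseSchedule,
    seed: int,
    well_radius_mm: float = WELL_RADIUS_MM,
) -> Trajectory:
    """Single-animal convenience wrapper (fully reproducible from ``seed``)."""
    rng = np.random.default_rng(seed)
    if schedule.peltier_initial_C is not None:
        return simulate_heat_batch([params], schedule, rng, well_radius_mm)[0]
    return simulate_trajectory_batch([params], schedule, rng, well_radius_mm)[0]


# --------------------------------------------------------------------------
# Whole-screen simulation
# --------------------------------------------------------------------------

@dataclass
class ScreenDataset:
    """One chemical's screening dataset: records table + trajectories."""

    records: pd.DataFrame
    trajectories: Dict[str, Trajectory]
    heat_trajectories: Dict[str, Trajectory]
    meta: dict

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(path / "records.csv", index=False)
        if self.trajectories:
            pd.concat(
                [tr.to_frame(rid) for rid, tr in self.trajectories.items()]
            ).to_csv(path / "trajectories.csv", index=False)
        if self.heat_trajectories:
            pd.concat(
                [tr.to_frame(rid) for rid, tr in self.heat_trajectories.items()]
            ).to_csv(path / "heat_trajectories.csv", index=False)
        (path / "manifest.json").write_text(json.dumps(self.meta, indent=2))

    @classmethod
    def from_dir(cls, path) -> "ScreenDataset":
        path = Path(path)
        records = pd.read_csv(path / "records.csv")
        meta = json.loads((path / "manifest.json").read_text())
        R = meta.get("well_radius_mm", WELL_RADIUS_MM)

        def load(fname: str, assay: str) -> Dict[str, Trajectory]:
            f = path / fname
            if not f.exists():
                return {}
            df = pd.read_csv(f)
            out = {}
            for rid, grp in df.groupby("record_id", sort=False):
                out[str(rid)] = Trajectory(
                    t=grp["t"].to_numpy(),
                    xy=grp[["x", "y"]].to_numpy(),
                    body_length=grp["body_length"].to_numpy(),
                    phase=grp["phase"].to_numpy(dtype=object),
                    well_radius_mm=R,
                    assay=assay,
                )
            return out

        return cls(
            records=records,
            trajectories=load("trajectories.csv", "phototaxis"),
            heat_trajectories=load("heat_trajectories.csv", "heat"),
            meta=meta,
        )


def _resolve_params(
    base: BehaviorBaseline,
    conc: float,
    effects: DoseEffectConfig,
    worm_type: str,
    day: int,
    rng: np.random.Generator,
    photo_competent: bool,
    scrunch_competent: bool,
) -> BehaviorParams:
    dt = 1.0 / SAMPLE_RATE_HZ
    speed_mult = float(effects.curve("speed_multiplier", worm_type, day).value(conc))
    rest_mult = float(effects.curve("rest_multiplier", worm_type, day).value(conc))
    lat_mult = float(
        effects.curve("ns_latency_multiplier", worm_type, day).value(conc)
    )
    animal_var = float(rng.lognormal(0.0, base.animal_cv))
    p_gr = min(0.5, max(1e-4, dt / base.glide_bout_s * rest_mult))
    p_rg = min(0.5, max(1e-4, dt / base.rest_bout_s / rest_mult))
    return BehaviorParams(
        glide_speed_mm_s=base.glide_speed_mm_s * speed_mult * animal_var,
        speed_noise_sd=base.speed_noise_sd,
        rest_speed_sd=base.rest_speed_sd,
        p_glide_to_rest=p_gr,
        p_rest_to_glide=p_rg,
        heading_sd_rad=base.heading_sd_rad,
        wall_bias=base.wall_bias,
        photo_factor=base.photo_factor if photo_competent else 1.0,
        body_length_mm=base.body_length_mm * float(rng.lognormal(0.0, 0.08)),
        length_noise_rel_sd=base.length_noise_rel_sd,
        scrunch=scrunch_competent,
        scrunch_latency_s=base.scrunch_latency_s
        * lat_mult
        * float(rng.lognormal(0.0, 0.15)),
        scrunch_amplitude=base.scrunch_amplitude,
        scrunch_period_s=base.scrunch_period_s,
    )


def _simulate_plate(
    design: PlateDesign,
    schedule: PhaseSchedule,
    effects: DoseEffectConfig,
    chemical: str,
    rng: np.random.Generator,
    abnormal_speed_factor: float = 0.4,
) -> Tuple[List[dict], Dict[str, Trajectory], Dict[str, Trajectory]]:
    layout = build_layout(design)
    worm, day, run = design.worm_type, design.day, design.run_index
    base = BehaviorBaseline.for_worm_type(worm)

    records: List[dict] = []
    alive_params: List[BehaviorParams] = []
    alive_ids: List[str] = []
    for row in range(design.n_rows):
        conc = layout[row]
        p_dead = float(effects.curve("lethality_prob", worm, day).value(conc))
        p_shape = float(effects.curve("shape_prob", worm, day).value(conc))
        p_stuck = float(effects.curve("stickiness_shift", worm, day).value(conc))
        p_photo = float(effects.curve("phototaxis_prob", worm, day).value(conc))
        p_scr = float(effects.curve("scrunch_prob", worm, day).value(conc))
        for col in range(design.n_cols):
            rid = f"{chemical}-{worm}-d{day}-r{run}-{chr(65 + row)}{col + 1:02d}"
            alive = rng.random() >= p_dead
            abnormal = bool(alive and rng.random() < p_shape)
            rec = {
                "record_id": rid,
                "chemical": chemical,
                "concentration_uM": conc,
                "worm_type": worm,
                "day": day,
                "run": run,
                "plate_row": row,
                "plate_col": col,
                "alive": alive,
                "abnormal_shape": abnormal,
                "stickiness_A": bool(alive and rng.random() < p_stuck),
                "stickiness_Z": bool(alive and rng.random() < p_stuck),
            }
            records.append(rec)
            if alive:
                params = _resolve_params(
                    base, conc, effects, worm, day, rng,
                    photo_competent=rng.random() < p_photo,
                    scrunch_competent=rng.random() < p_scr,
                )
                if abnormal and abnormal_speed_factor is not None:
                    # abnormal shapes co-occur with impaired locomotion
                    params = replace(
                        params,
                        glide_speed_mm_s=params.glide_speed_mm_s
                        * abnormal_speed_factor,
                    )
                alive_params.append(params)
                alive_ids.append(rid)

    trajs = dict(
        zip(alive_ids, simulate_trajectory_batch(alive_params, schedule, rng))
    )
    heat: Dict[str, Trajectory] = {}
    if day == 12:
        heat_schedule = PhaseSchedule.heat(schedule.sample_rate_hz)
        heat = dict(
            zip(alive_ids, simulate_heat_batch(alive_params, heat_schedule, rng))
        )
    return records, trajs, heat


def simulate_screen(
    design: PlateDesign,
    schedule: PhaseSchedule,
    effects: DoseEffectConfig,
    chemical: str,
    seed: int,
    worm_types: Sequence[str] = ("adult", "regenerating"),
) -> ScreenDataset:
    """Full duplicate screen: two runs x worm types, 24 animals/concentration.

    Deterministic given (configs, seed).  ``design`` supplies the
    concentration series and assessment day; runs and worm types are
    enumerated internally with independent child seeds.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(worm_types) * 2)
    all_records: List[dict] = []
    trajs: Dict[str, Trajectory] = {}
    heats: Dict[str, Trajectory] = {}
    idx = 0
    for worm in worm_types:
        for run in (1, 2):
            plate = replace(design, worm_type=worm, run_index=run)
            rng = np.random.default_rng(children[idx])
            idx += 1
            rec, tr, ht = _simulate_plate(plate, schedule, effects, chemical, rng)
            all_records.extend(rec)
            trajs.update(tr)
            heats.update(ht)
    records = pd.DataFrame(all_records)
    meta = {
        "chemical": chemical,
        "seed": int(seed),
        "day": design.day,
        "concentrations_uM": list(design.concentrations_uM),
        "well_radius_mm": WELL_RADIUS_MM,
        "sample_rate_hz": schedule.sample_rate_hz,
        "stickiness_rpm": {
            f"{w},{design.day}": STICKINESS_RPM[(w, design.day)] for w in worm_types
        },
    }
    return ScreenDataset(records, trajs, heats, meta)


def simulate_control_bank(
    design: PlateDesign,
    schedule: PhaseSchedule,
    n_populations: int,
    seed: int,
    effects: Optional[DoseEffectConfig] = None,
    worm_types: Sequence[str] = ("adult", "regenerating"),
    n_per_population: int = 24,
) -> List[ScreenDataset]:
    """Independent control-only populations for relevancy-cutoff estimation.

    Each population contributes ``n_per_population`` water-control animals
    per worm type (split over two nominal runs of 12, mirroring the plate
    replication scheme).
    """
    if n_populations < 2:
        raise ValueError("need at least 2 control populations")
    effects = effects or DoseEffectConfig.null()
    ss = np.random.SeedSequence(seed)
    pops: List[ScreenDataset] = []
    for p, child in enumerate(ss.spawn(n_populations)):
        rng = np.random.default_rng(child)
        records: List[dict] = []
        trajs: Dict[str, Trajectory] = {}
        heats: Dict[str, Trajectory] = {}
        for worm in worm_types:
            base = BehaviorBaseline.for_worm_type(worm)
            day = design.day
            p_dead = float(effects.curve("lethality_prob", worm, day).value(0.0))
            p_shape = float(effects.curve("shape_prob", worm, day).value(0.0))
            p_stuck = float(effects.curve("stickiness_shift", worm, day).value(0.0))
            p_photo = float(effects.curve("phototaxis_prob", worm, day).value(0.0))
            p_scr = float(effects.curve("scrunch_prob", worm, day).value(0.0))
            ids, params_list = [], []
            for i in range(n_per_population):
                rid = f"ctrl{p}-{worm}-d{day}-{i:03d}"
                alive = rng.random() >= p_dead
                rec = {
                    "record_id": rid,
                    "chemical": "control",
                    "concentration_uM": CONTROL_CONC,
                    "worm_type": worm,
                    "day": day,
                    "run": 1 + (i % 2),
                    "plate_row": 0,
                    "plate_col": i,
                    "alive": alive,
                    "abnormal_shape": bool(alive and rng.random() < p_shape),
                    "stickiness_A": bool(alive and rng.random() < p_stuck),
                    "stickiness_Z": bool(alive and rng.random() < p_stuck),
                }
                records.append(rec)
                if alive:
                    ids.append(rid)
                    params_list.append(
                        _resolve_params(
                            base, 0.0, effects, worm, day, rng,
                            photo_competent=rng.random() < p_photo,
                            scrunch_competent=rng.random() < p_scr,
                        )
                    )
            trajs.update(
                zip(ids, simulate_trajectory_batch(params_list, schedule, rng))
            )
            if day == 12:
                heats.update(
                    zip(
                        ids,
                        simulate_heat_batch(
                            params_list, PhaseSchedule.heat(schedule.sample_rate_hz),
                            rng,
                        ),
                    )
                )
        meta = {"population": p, "seed": int(seed), "day": design.day}
        pops.append(ScreenDataset(pd.DataFrame(records), trajs, heats, meta))
    return pops
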