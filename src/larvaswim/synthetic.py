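"""Synthetic scenes and trials with known ground truth.

Laboratory photographs of backlit larvae are emulated as bright, roughly
uniform frames with dark, semi-transparent elliptical bodies moving
through them. Because every larva's true centroid and velocity are
recorded frame by frame, the whole detection → linking → kinematics
pipeline can be validated against programmed truth, which real
photographs never provide. The same module simulates the incremental
swim-chamber protocol so the U_max arithmetic and the ontogeny
regressions can be exercised on cohorts with known parameters.

Rendering is deliberately minimal: the downstream detector consumes only
contrast, scale and position, so anatomy, lighting gradients and the
physical calibration grid are not modelled (scale is passed as a
number). Frames are float grayscale in [0, 1]; image coordinates follow
the package convention (origin top-left, rows grow downward, physical
"up" = negative row direction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chamber import ChamberProtocol, ChamberTrialRecord
from .io import FrameSequence

__all__ = [
    "LarvaSpec",
    "SceneSpec",
    "TruthSet",
    "render_sequence",
    "make_speed_survey_scene",
    "make_vertical_cohort_scene",
    "simulate_chamber_trial",
    "simulate_chamber_dataset",
    "ONTOGENY_LINES",
]

_TRAJECTORY_KINDS = ("constant_velocity", "random_walk", "vertical_drift")


@dataclass(frozen=True)
class LarvaSpec:
    """One simulated larva.

    The body is a filled ellipse of ``length_px`` × ``width_px`` oriented
    along its instantaneous direction of travel, alpha-composited onto
    the background with the given opacity (1 = fully dark, values below
    1 emulate the translucency of young larvae).

    ``trajectory_kind`` ∈ {constant_velocity, random_walk, vertical_drift}
    with kind-specific ``trajectory_params``:

    - constant_velocity: ``velocity_cm_s`` = (vx, vy), world frame, vy up.
    - random_walk: ``step_sd_cm`` — isotropic Gaussian step per frame.
    - vertical_drift: ``drift_cm_s`` (signed, up positive) and optional
      ``lateral_sd_cm`` jitter.
    """

    start_px: tuple[float, float]  # (x, y) image coordinates
    length_px: float = 12.0
    width_px: float = 3.0
    opacity: float = 0.7
    trajectory_kind: str = "constant_velocity"
    trajectory_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.opacity <= 1):
            raise ValueError(f"opacity must be in (0, 1], got {self.opacity}")
        if self.trajectory_kind not in _TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind {self.trajectory_kind!r}")
        if self.length_px <= 0 or self.width_px <= 0:
            raise ValueError("larva dimensions must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic image sequence.

    Frame rates of 2–7 fps cover the still-camera capture range used for
    larval carps; ``timestamp_jitter_sd`` (seconds) perturbs the nominal
    uniform k/fps stamps to emulate variable-interval capture.
    """

    width_px: int = 640
    height_px: int = 480
    n_frames: int = 10
    fps: float = 6.0
    cm_per_px: float = 0.05
    background_level: float = 0.85
    noise_sigma: float = 0.0
    larvae: tuple[LarvaSpec, ...] = ()
    seed: int = 0
    timestamp_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.cm_per_px <= 0:
            raise ValueError("cm_per_px must be positive")
        if not (0 <= self.background_level <= 1):
            raise ValueError("background_level must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "larvae", tuple(self.larvae))
        for i, lv in enumerate(self.larvae):
            x, y = lv.start_px
            if not (0 <= x < self.width_px and 0 <= y < self.height_px):
                raise ValueError(f"larva {i} starts outside the frame: {lv.start_px}")


@dataclass
class TruthSet:
    """Per-larva, per-frame true centroids and velocities.

    ``records`` columns: larva_id, frame, x_px, y_px, vx_cm_s, vy_cm_s.
    Positions are image coordinates; velocities are world coordinates
    (vy positive = upward). Only frames in which the larva's centre lies
    inside the frame are recorded.
    """

    records: pd.DataFrame

    def for_larva(self, larva_id: int) -> pd.DataFrame:
        return self.records[self.records.larva_id == larva_id].reset_index(drop=True)

    @property
    def larva_ids(self) -> list[int]:
        return sorted(self.records.larva_id.unique())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.records.to_dict(orient="records"), indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(pd.DataFrame(json.loads(Path(path).read_text())))


def _trajectory(
    lv: LarvaSpec, timestamps: np.ndarray, cm_per_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Continuous (x, y) pixel positions of one larva at each timestamp."""
    n = len(timestamps)
    pos = np.empty((n, 2))
    pos[0] = lv.start_px
    kind, p = lv.trajectory_kind, lv.trajectory_params
    if kind == "constant_velocity":
        vx, vy = p.get("velocity_cm_s", (0.0, 0.0))
        # world → pixel: up (positive vy) is the negative row direction
        step = np.array([vx / cm_per_px, -vy / cm_per_px])
        for k in range(1, n):
            pos[k] = pos[0] + step * (timestamps[k] - timestamps[0])
    elif kind == "random_walk":
        sd_px = p.get("step_sd_cm", 0.1) / cm_per_px
        steps = rng.normal(0.0, sd_px, size=(n - 1, 2))
        pos[1:] = pos[0] + np.cumsum(steps, axis=0)
    else:  # vertical_drift
        drift = p.get("drift_cm_s", -1.0)  # default sinking
        lat_sd_px = p.get("lateral_sd_cm", 0.0) / cm_per_px
        for k in range(1, n):
            dt = timestamps[k] - timestamps[k - 1]
            lateral = rng.normal(0.0, lat_sd_px) if lat_sd_px > 0 else 0.0
            pos[k] = pos[k - 1] + np.array([lateral, -drift / cm_per_px * dt])
    return pos


def _draw_ellipse(
    frame: np.ndarray,
    center: tuple[float, float],
    a: float,
    b: float,
    theta: float,
    opacity: float,
    supersample: int = 3,
) -> None:
    """Alpha-composite one dark anti-aliased ellipse onto ``frame`` in place.

    Coverage per pixel is estimated on a supersample grid; the composite
    is ``pixel *= 1 - opacity * coverage`` (object color = black).
    """
    cx, cy = center
    h, w = frame.shape
    r = max(a, b) + 1.0
    c0, c1 = int(max(0, math.floor(cx - r))), int(min(w, math.ceil(cx + r) + 1))
    r0, r1 = int(max(0, math.floor(cy - r))), int(min(h, math.ceil(cy + r) + 1))
    if c1 <= c0 or r1 <= r0:
        return
    ss = supersample
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    xs = np.arange(c0, c1)[:, None] + offs[None, :]  # (W, ss)
    ys = np.arange(r0, r1)[:, None] + offs[None, :]
    ct, st = math.cos(theta), math.sin(theta)
    X = xs.reshape(-1)  # flattened subsample columns
    Y = ys.reshape(-1)
    u = (X[None, :] - cx) * ct + (Y[:, None] - cy) * st
    v = -(X[None, :] - cx) * st + (Y[:, None] - cy) * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    nrow, ncol = r1 - r0, c1 - c0
    cov = (
        inside.reshape(nrow, ss, ncol, ss).mean(axis=(1, 3))
        if inside.any()
        else np.zeros((nrow, ncol))
    )
    frame[r0:r1, c0:c1] *= 1.0 - opacity * cov


def render_sequence(spec: SceneSpec) -> tuple[FrameSequence, TruthSet]:
    """Render a scene to frames + ground truth. Deterministic given the seed.

    True centroids are the ellipse centres; true velocities are the
    forward finite differences of the world-coordinate positions (the
    last frame repeats the previous velocity), which for constant-velocity
    larvae equals the programmed velocity exactly.
    """
    rng = np.random.default_rng(spec.seed)

    ts = np.arange(spec.n_frames) / spec.fps
    if spec.timestamp_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.timestamp_jitter_sd, size=spec.n_frames)
        ts = np.sort(ts + jitter)
        ts -= ts[0]
        # enforce strict monotonicity even under extreme jitter draws
        eps = 1e-6
        for k in range(1, spec.n_frames):
            if ts[k] <= ts[k - 1]:
                ts[k] = ts[k - 1] + eps

    paths = [_trajectory(lv, ts, spec.cm_per_px, rng) for lv in spec.larvae]

    frames = np.full(
        (spec.n_frames, spec.height_px, spec.width_px), spec.background_level
    )
    records = []
    for i, (lv, pos) in enumerate(zip(spec.larvae, paths)):
        # world-frame velocities from pixel-position finite differences
        dt = np.diff(ts)
        vx = np.diff(pos[:, 0]) / dt * spec.cm_per_px
        vy = -np.diff(pos[:, 1]) / dt * spec.cm_per_px
        vx = np.append(vx, vx[-1])
        vy = np.append(vy, vy[-1])
        for k in range(spec.n_frames):
            x, y = pos[k]
            heading = math.atan2(
                pos[min(k + 1, spec.n_frames - 1), 1] - pos[max(k - 1, 0), 1],
                pos[min(k + 1, spec.n_frames - 1), 0] - pos[max(k - 1, 0), 0],
            )
            if math.hypot(vx[k], vy[k]) < 1e-12:
                heading = 0.0
            _draw_ellipse(
                frames[k], (x, y), lv.length_px / 2, lv.width_px / 2, heading, lv.opacity
            )
            if 0 <= x < spec.width_px and 0 <= y < spec.height_px:
                records.append(
                    {
                        "larva_id": i,
                        "frame": k,
                        "x_px": float(x),
                        "y_px": float(y),
                        "vx_cm_s": float(vx[k]),
                        "vy_cm_s": float(vy[k]),
                    }
                )

    if spec.noise_sigma > 0:
        frames += rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    np.clip(frames, 0.0, 1.0, out=frames)

    seq = FrameSequence(
        frames,
        ts,
        acquisition={"fps_nominal": spec.fps, "cm_per_px": spec.cm_per_px,
                     "synthetic": True},
    )
    cols = ["larva_id", "frame", "x_px", "y_px", "vx_cm_s", "vy_cm_s"]
    truth = TruthSet(pd.DataFrame(records, columns=cols))
    return seq, truth


def make_speed_survey_scene(
    n_larvae: int = 20,
    n_frames: int = 60,
    fps: float = 6.0,
    speed_range_cm_s: tuple[float, float] = (0.5, 5.0),
    noise_sigma: float = 0.02,
    cm_per_px: float = 0.05,
    width_px: int = 1100,
    height_px: int = 900,
    seed: int = 0,
) -> SceneSpec:
    """A cohort of constant-velocity larvae with random headings.

    Speeds are drawn uniformly from ``speed_range_cm_s``; start positions
    sit in the central region so most larvae stay in view for many frames.
    This is the standard pipeline-validation scene.
    """
    rng = np.random.default_rng(seed)
    larvae = []
    for _ in range(n_larvae):
        speed = rng.uniform(*speed_range_cm_s)
        theta = rng.uniform(0, 2 * math.pi)
        larvae.append(
            LarvaSpec(
                start_px=(
                    rng.uniform(0.25 * width_px, 0.75 * width_px),
                    rng.uniform(0.25 * height_px, 0.75 * height_px),
                ),
                trajectory_kind="constant_velocity",
                trajectory_params={
                    "velocity_cm_s": (speed * math.cos(theta), speed * math.sin(theta))
                },
            )
        )
    return SceneSpec(
        width_px=width_px,
        height_px=height_px,
        n_frames=n_frames,
        fps=fps,
        cm_per_px=cm_per_px,
        noise_sigma=noise_sigma,
        larvae=tuple(larvae),
        seed=seed,
    )


def make_vertical_cohort_scene(
    n_larvae: int = 12,
    down_up_ratio: float = 2.0,
    base_speed_cm_s: float = 1.5,
    n_frames: int = 40,
    fps: float = 6.0,
    cm_per_px: float = 0.05,
    noise_sigma: float = 0.0,
    width_px: int = 800,
    height_px: int = 1000,
    seed: int = 0,
) -> SceneSpec:
    """A pre-gas-bladder-inflation cohort: purely vertical swimmers whose
    downward speed is ``down_up_ratio`` times the upward speed, emulating
    the sink-and-swim behaviour of larvae before the gas bladder inflates.

    Alternate larvae move up at ``base_speed_cm_s`` and down at
    ``ratio × base_speed_cm_s``; start rows are placed so each stays in
    view for the whole sequence.
    """
    rng = np.random.default_rng(seed)
    duration = (n_frames - 1) / fps
    larvae = []
    for i in range(n_larvae):
        up = i % 2 == 0
        speed = base_speed_cm_s * (1.0 if up else down_up_ratio)
        travel_px = speed * duration / cm_per_px
        x = rng.uniform(0.1 * width_px, 0.9 * width_px)
        # upward larvae start low (large row), downward start high
        if up:
            y = rng.uniform(min(travel_px + 10, height_px - 2), height_px - 1)
            vy = speed
        else:
            y = rng.uniform(1, max(2.0, height_px - travel_px - 10))
            vy = -speed
        larvae.append(
            LarvaSpec(
                start_px=(x, y),
                trajectory_kind="constant_velocity",
                trajectory_params={"velocity_cm_s": (0.0, vy)},
            )
        )
    return SceneSpec(
        width_px=width_px,
        height_px=height_px,
        n_frames=n_frames,
        fps=fps,
        cm_per_px=cm_per_px,
        noise_sigma=noise_sigma,
        larvae=tuple(larvae),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Swim-chamber simulation
# ---------------------------------------------------------------------------

def simulate_chamber_trial(
    true_umax: float,
    protocol: ChamberProtocol = ChamberProtocol(),
    seed: int = 0,
    mode: str = "deterministic",
    logistic_scale_cm_s: float = 0.2,
    fish_id: str = "sim",
    **metadata,
) -> ChamberTrialRecord:
    """Simulate one incremental-velocity trial for a fish of known U_max.

    Deterministic mode (the default): the fish holds position at every
    chamber speed ≤ ``true_umax`` and fails immediately (t = 0) at the
    first increment exceeding it, so the recorded final speed is the
    smallest protocol step strictly above the true maximum. Stochastic
    mode draws failure per increment with probability
    ``logistic(speed − true_umax; scale)`` and a uniform failure time
    within the increment.

    A fish whose true maximum lies below the starting speed cannot hold
    at all; the record is returned flagged ``failed_at_start``.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    if true_umax < protocol.start_speed:
        return ChamberTrialRecord(
            fish_id=fish_id,
            final_reported_speed=protocol.start_speed,
            t_final=0.0,
            failed_at_start=True,
            **metadata,
        )
    rng = np.random.default_rng(seed)
    speed = protocol.start_speed
    while True:
        speed += protocol.u_i
        if mode == "deterministic":
            if speed > true_umax:
                return ChamberTrialRecord(
                    fish_id=fish_id, final_reported_speed=speed, t_final=0.0, **metadata
                )
        else:
            p_fail = 1.0 / (1.0 + math.exp(-(speed - true_umax) / logistic_scale_cm_s))
            if rng.random() < p_fail:
                return ChamberTrialRecord(
                    fish_id=fish_id,
                    final_reported_speed=speed,
                    t_final=float(rng.uniform(0, protocol.t_i)),
                    **metadata,
                )


@dataclass(frozen=True)
class OntogenyLine:
    """Affine relation U_max = slope·x + intercept for one predictor."""

    slope: float
    intercept: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, u: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(u, dtype=float) - self.intercept) / self.slope


#: Default ontogeny of maximum swimming speed for the three carp species:
#: U_max (cm/s) as affine functions of days post-hatch, mean total length
#: (mm) and mean developmental stage. These coefficient sets are the
#: generator's ground truth; length and stage trajectories over age are
#: derived by inverting the corresponding lines so a simulated cohort is
#: internally consistent across all three predictors.
ONTOGENY_LINES: dict[str, dict[str, OntogenyLine]] = {
    "bighead": {
        "dph": OntogenyLine(0.73, 16.60),
        "length_mm": OntogenyLine(1.05, 14.17),
        "stage": OntogenyLine(2.07, -58.90),
    },
    "grass": {
        "dph": OntogenyLine(1.68, 7.45),
        "length_mm": OntogenyLine(1.72, 6.75),
        "stage": OntogenyLine(3.39, -114.25),
    },
    "silver": {
        "dph": OntogenyLine(0.75, 4.07),
        "length_mm": OntogenyLine(1.26, 1.86),
        "stage": OntogenyLine(3.71, -134.56),
    },
}

#: Measurement spans (days post-hatch): daily for two weeks from first
#: horizontal swimming at 4 DPH, then weekly until the developmental
#: series tops out at squamation (stage 48) under each species' default
#: ontogeny lines.
_SPECIES_SPANS: dict[str, list[int]] = {}
for _sp, _lines in ONTOGENY_LINES.items():
    _last = int(_lines["dph"].invert(_lines["stage"](48.0)))
    _days = list(range(4, min(18, _last + 1))) + list(range(21, _last + 1, 7))
    _SPECIES_SPANS[_sp] = _days


def simulate_chamber_dataset(
    seed: int = 0,
    species: tuple[str, ...] = ("bighead", "grass", "silver"),
    fish_per_day: tuple[int, int] = (10, 20),
    umax_cv: float = 0.15,
    tl_cv: float = 0.04,
    stage_sd: float = 0.4,
    protocol: ChamberProtocol = ChamberProtocol(),
) -> pd.DataFrame:
    """Simulate a full multi-species chamber campaign.

    For each species and measurement day, 10–20 fish are drawn. Each
    fish's true U_max is the species' age line plus lognormal-free
    Gaussian variation (coefficient of variation ``umax_cv``); total
    length and stage come from inverting the species' length and stage
    lines at the day's mean U_max, with individual variation. Every fish
    is then run through the deterministic step protocol, so recorded
    final speeds carry the protocol's quantization.

    Returns the bench-sheet table: fish_id, species, dph, stage, tl_cm,
    final_reported_speed, t_final.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        lines = ONTOGENY_LINES[sp]
        for dph in _SPECIES_SPANS[sp]:
            u_day = float(lines["dph"](dph))
            tl_day_mm = float(lines["length_mm"].invert(u_day))
            stage_day = float(np.clip(lines["stage"].invert(u_day), 31, 48))
            n_fish = int(rng.integers(fish_per_day[0], fish_per_day[1] + 1))
            day_protocol = ChamberProtocol(
                u_i=protocol.u_i,
                t_i=protocol.t_i,
                # start well below the day's typical fish, as at the bench
                start_speed=max(0.0, 0.5 * u_day),
            )
            for j in range(n_fish):
                true_u = max(protocol.u_i, rng.normal(u_day, umax_cv * u_day))
                rec = simulate_chamber_trial(
                    true_u,
                    day_protocol,
                    seed=int(rng.integers(2**31)),
                    fish_id=f"{sp}-{dph:02d}-{j:02d}",
                    species=sp,
                    dph=dph,
                    stage=float(np.clip(rng.normal(stage_day, stage_sd), 31, 48)),
                    tl_cm=max(0.1, rng.normal(tl_day_mm, tl_cv * tl_day_mm)) / 10.0,
                )
                if not rec.failed_at_start:
                    rows.append(rec)
    return pd.DataFrame(
        {
            "fish_id": [r.fish_id for r in rows],
            "species": [r.species for r in rows],
            "dph": [r.dph for r in rows],
            "stage": [r.stage for r in rows],
            "tl_cm": [r.tl_cm for r in rows],
            "final_reported_speed": [r.final_reported_speed for r in rows],
            "t_final": [r.t_final for r in rows],
        }
    )
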