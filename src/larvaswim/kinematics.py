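"""Calibrated movement steps and routine-swimming-speed summaries.

A *movement* is the displacement of one larva between two consecutive
frames of its track: pixel displacement × cm/px scale, divided by the
inter-frame interval. Vertical and horizontal travel are accounted by
vector components — each step contributes its signed vertical component
to the upward or downward group and its horizontal magnitude to the
horizontal group (leftward and rightward travel are pooled). Summaries
report mean ± sample SD, range and the number of movements n.

Speeds are square-root transformed for plotting only; statistics are
always computed on the raw cm/s values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Calibration
from .tracking import Track

__all__ = [
    "MovementStep",
    "SpeedSummary",
    "compute_steps",
    "compute_all_steps",
    "summarize",
    "sqrt_transform",
    "plot_daily_speeds",
    "steps_to_frame",
]


@dataclass(frozen=True)
class MovementStep:
    """One inter-frame displacement of one larva, in physical units.

    ``dy_cm`` is signed with *up positive* (image rows grow downward, so
    the row displacement is negated). ``vertical_speed_cm_s`` keeps that
    sign; ``horizontal_speed_cm_s`` is the unsigned |dx|/dt.
    """

    track_id: int
    frame_from: int
    frame_to: int
    dt: float
    dx_cm: float
    dy_cm: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"non-positive dt {self.dt} between frames "
                             f"{self.frame_from} and {self.frame_to}")

    @property
    def speed_cm_s(self) -> float:
        return math.hypot(self.dx_cm, self.dy_cm) / self.dt

    @property
    def vertical_speed_cm_s(self) -> float:
        return self.dy_cm / self.dt

    @property
    def horizontal_speed_cm_s(self) -> float:
        return abs(self.dx_cm) / self.dt


@dataclass(frozen=True)
class SpeedSummary:
    """Mean ± SD / range / n of one direction group of movements."""

    direction: str  # upward | downward | horizontal | overall
    mean_cm_s: float
    sd_cm_s: float
    min_cm_s: float
    max_cm_s: float
    n_movements: int
    group: dict = field(default_factory=dict, compare=False)  # e.g. species, DPH


def compute_steps(
    track: Track, calibration: Calibration, timestamps: Sequence[float]
) -> list[MovementStep]:
    """One :class:`MovementStep` per consecutive detection pair of a track.

    Zero-displacement steps are retained: a motionless larva is a real
    observation (near-zero speeds appear in routine-speed minima).
    """
    if len(track) < 2:
        raise ValueError(f"track {track.track_id} has fewer than 2 detections")
    ts = np.asarray(timestamps, dtype=float)
    steps = []
    for a, b in zip(track.detections, track.detections[1:]):
        dt = float(ts[b.frame_index] - ts[a.frame_index])
        dx_px = b.centroid_px[0] - a.centroid_px[0]
        drow_px = b.centroid_px[1] - a.centroid_px[1]
        steps.append(
            MovementStep(
                track_id=track.track_id,
                frame_from=a.frame_index,
                frame_to=b.frame_index,
                dt=dt,
                dx_cm=dx_px * calibration.cm_per_px,
                dy_cm=-drow_px * calibration.cm_per_px,  # up = negative row
            )
        )
    return steps


def compute_all_steps(
    tracks: Iterable[Track], calibration: Calibration, timestamps: Sequence[float]
) -> list[MovementStep]:
    """Steps of every track with >= 2 detections, concatenated."""
    out: list[MovementStep] = []
    for t in tracks:
        if len(t) >= 2:
            out.extend(compute_steps(t, calibration, timestamps))
    return out


def _summary(direction: str, values: np.ndarray, group: dict) -> SpeedSummary:
    return SpeedSummary(
        direction=direction,
        mean_cm_s=float(values.mean()),
        sd_cm_s=float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
        min_cm_s=float(values.min()),
        max_cm_s=float(values.max()),
        n_movements=int(len(values)),
        group=group,
    )


def summarize(
    steps: Sequence[MovementStep], group: dict | None = None
) -> list[SpeedSummary]:
    """Directional speed summaries of a set of movements.

    Upward = steps whose vertical component is positive, summarised on
    |vertical speed|; downward analogously on negative components;
    horizontal on |dx|/dt over all steps with nonzero horizontal travel;
    overall on the full vector speed of every step. Empty groups are
    omitted, never zero-filled. SD uses the n−1 denominator.
    """
    if not steps:
        raise ValueError("no movements to summarize")
    group = group or {}
    vert = np.array([s.vertical_speed_cm_s for s in steps])
    horiz = np.array([s.horizontal_speed_cm_s for s in steps])
    total = np.array([s.speed_cm_s for s in steps])

    out = []
    up = vert[vert > 0]
    if len(up):
        out.append(_summary("upward", up, group))
    down = -vert[vert < 0]
    if len(down):
        out.append(_summary("downward", down, group))
    h = horiz[horiz > 0]
    if len(h):
        out.append(_summary("horizontal", h, group))
    out.append(_summary("overall", total, group))
    return out


def sqrt_transform(speeds: Sequence[float] | np.ndarray) -> np.ndarray:
    """Element-wise square root, for plotting daily speeds on a compressed
    scale. Rejects negative input; never used for statistics."""
    arr = np.asarray(speeds, dtype=float)
    if np.any(arr < 0):
        raise ValueError("speeds must be non-negative")
    return np.sqrt(arr)


def plot_daily_speeds(daily: pd.DataFrame, ax=None):
    """Square-root-scale scatter of daily routine speeds by direction.

    ``daily`` needs columns ``dph``, ``direction`` and ``speed_cm_s``
    (one row per movement or per daily summary point). Speeds are
    square-root transformed for display only.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    markers = {"upward": "^", "downward": "v", "horizontal": "o", "overall": "."}
    for direction, g in daily.groupby("direction"):
        ax.scatter(
            g["dph"],
            sqrt_transform(g["speed_cm_s"].to_numpy()),
            label=direction,
            marker=markers.get(direction, "x"),
            alpha=0.6,
            s=14,
        )
    ax.set_xlabel("days post-hatch")
    ax.set_ylabel("√speed (cm/s)$^{1/2}$")
    ax.legend()
    return ax


def steps_to_frame(steps: Sequence[MovementStep]) -> pd.DataFrame:
    """Tabulate movements (one row per step) for CSV export."""
    return pd.DataFrame(
        {
            "track_id": [s.track_id for s in steps],
            "frame_from": [s.frame_from for s in steps],
            "frame_to": [s.frame_to for s in steps],
            "dt_s": [s.dt for s in steps],
            "dx_cm": [s.dx_cm for s in steps],
            "dy_cm": [s.dy_cm for s in steps],
            "speed_cm_s": [s.speed_cm_s for s in steps],
            "vertical_speed_cm_s": [s.vertical_speed_cm_s for s in steps],
            "horizontal_speed_cm_s": [s.horizontal_speed_cm_s for s in steps],
        }
    )
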