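"""Swim-chamber maximum-speed protocol: pump calibration and U_max.

Maximum speed (U_max) is measured by placing a larva in a swim chamber
and raising water velocity in small fixed increments (default 0.218
cm/s) on a fixed interval (default 2 s) until the fish can no longer
hold position. The failure increment's speed U_f and the time t survived
inside it give

    U_max = U + (t / t_i) * U_i,     U = U_f - U_i  (penultimate speed)

so with the conventional t = 0 the estimate collapses to the penultimate
speed. Chamber speed is set by pump frequency through an affine
calibration line, U = slope·Hz + intercept, fitted against a flow meter.

Relative speed U_maxrel = U_max / TL (total lengths per second) is
computed against the *group mean* total length by default — lengths are
measured post-mortem on a daily sample, so a per-fish pairing of length
and speed is not generally available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PumpCalibration",
    "ChamberProtocol",
    "ChamberTrialRecord",
    "UmaxResult",
    "hz_to_velocity",
    "compute_umax",
    "relative_speed",
    "daily_means",
]


@dataclass(frozen=True)
class PumpCalibration:
    """Affine pump-frequency → water-velocity line (cm/s = slope·Hz + intercept).

    Defaults are the flow-meter calibration of a 5 L Loligo-type chamber.
    Near 0 Hz the line goes negative; such values are non-physical and
    are returned as-is but flagged by :func:`hz_to_velocity`.
    """

    slope: float = 0.0218
    intercept: float = -0.0731

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")

    @property
    def zero_crossing_hz(self) -> float:
        """Frequency at which the calibrated velocity is exactly zero."""
        return -self.intercept / self.slope


@dataclass(frozen=True)
class ChamberProtocol:
    """Incremental-velocity step protocol.

    ``u_i`` — speed increment per step, cm/s (default 0.218, i.e. ~0.1 Hz
    on the default pump line scale); ``t_i`` — step duration, s;
    ``start_speed`` — velocity already flowing when the fish is placed in
    the chamber (kept below the slowest fish of the previous day).
    """

    u_i: float = 0.218
    t_i: float = 2.0
    start_speed: float = 0.0

    def __post_init__(self) -> None:
        if self.u_i <= 0 or self.t_i <= 0:
            raise ValueError("u_i and t_i must be > 0")
        if self.start_speed < 0:
            raise ValueError("start_speed must be >= 0")


@dataclass(frozen=True)
class ChamberTrialRecord:
    """One fish's chamber trial as recorded at the bench.

    ``final_reported_speed`` is the velocity of the increment in which the
    fish failed; ``t_final`` the seconds it survived inside that increment
    (protocol convention: 0). ``stage`` is an ordinal developmental-series
    number (31–48, squamation = 48), supplied as metadata.
    """

    fish_id: str
    final_reported_speed: float
    t_final: float = 0.0
    dph: Optional[int] = None
    stage: Optional[float] = None
    tl_cm: Optional[float] = None
    species: Optional[str] = None
    failed_at_start: bool = False

    def __post_init__(self) -> None:
        if self.t_final < 0:
            raise ValueError("t_final must be >= 0")
        if self.stage is not None and not (31 <= self.stage <= 48):
            raise ValueError(f"stage {self.stage} outside the 31-48 series")


@dataclass(frozen=True)
class UmaxResult:
    """Maximum speed and, when a length is supplied, its length-relative form."""

    u_max: float
    u_max_rel: Optional[float] = None  # total lengths per second


def hz_to_velocity(x: float, cal: PumpCalibration = PumpCalibration()) -> tuple[float, bool]:
    """Water velocity (cm/s) at pump frequency ``x`` (Hz).

    Returns ``(velocity, physical)`` where ``physical`` is False when the
    line evaluates negative (below its ~3.35 Hz zero crossing); the value
    is never clamped, preserving the calibration exactly.
    """
    if x < 0:
        raise ValueError("pump frequency must be >= 0")
    u = cal.slope * x + cal.intercept
    return u, u >= 0


def compute_umax(
    trial: ChamberTrialRecord, protocol: ChamberProtocol = ChamberProtocol()
) -> UmaxResult:
    """Maximum speed of one trial: penultimate speed plus the fractional
    credit for time survived in the failure increment.

    With the t_final = 0 convention this is simply
    ``final_reported_speed − u_i``.
    """
    if trial.final_reported_speed < protocol.u_i:
        raise ValueError(
            f"final speed {trial.final_reported_speed} below one increment "
            f"({protocol.u_i}): penultimate speed would be negative"
        )
    if not (trial.t_final < protocol.t_i):
        raise ValueError(
            f"t_final={trial.t_final} not below the step interval {protocol.t_i}: "
            "the fish would have survived into the next increment"
        )
    u_penultimate = trial.final_reported_speed - protocol.u_i
    u_max = u_penultimate + (trial.t_final / protocol.t_i) * protocol.u_i
    u_rel = u_max / trial.tl_cm if trial.tl_cm else None
    return UmaxResult(u_max=u_max, u_max_rel=u_rel)


def relative_speed(u_max: float, mean_tl_cm: float) -> float:
    """Length-relative maximum speed, in total lengths per second."""
    if mean_tl_cm <= 0:
        raise ValueError(f"total length must be > 0 cm, got {mean_tl_cm}")
    return u_max / mean_tl_cm


def daily_means(
    trials: list[ChamberTrialRecord] | pd.DataFrame,
    protocol: ChamberProtocol = ChamberProtocol(),
    per_fish_relative: bool = False,
) -> pd.DataFrame:
    """Per species × DPH means of U_max, relative speed, length and stage.

    ``u_max_rel_mean`` divides each day's mean U_max by that day's *mean*
    total length (the protocol's convention, robust to the length sample
    and the speed sample being different fish). ``per_fish_relative=True``
    instead averages per-fish U_max/TL ratios; this variant requires a
    length for every fish and is not the standard convention.

    SD uses the n−1 denominator; single-trial groups emit NaN SDs.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame(
            {
                "fish_id": [t.fish_id for t in trials],
                "species": [t.species for t in trials],
                "dph": [t.dph for t in trials],
                "stage": [t.stage for t in trials],
                "tl_cm": [t.tl_cm for t in trials],
                "final_reported_speed": [t.final_reported_speed for t in trials],
                "t_final": [t.t_final for t in trials],
            }
        )
    df["u_max"] = [
        compute_umax(
            ChamberTrialRecord(fish_id=str(r.fish_id),
                               final_reported_speed=r.final_reported_speed,
                               t_final=r.t_final),
            protocol,
        ).u_max
        for r in df.itertuples()
    ]

    rows = []
    for (species, dph), g in df.groupby(["species", "dph"], dropna=False):
        mean_tl = g["tl_cm"].mean()
        row = {
            "species": species,
            "dph": dph,
            "n": len(g),
            "u_max_mean": g["u_max"].mean(),
            "u_max_sd": g["u_max"].std(ddof=1),
            "tl_cm_mean": mean_tl,
            "tl_cm_sd": g["tl_cm"].std(ddof=1),
            "stage_mean": g["stage"].mean(),
        }
        if per_fish_relative:
            rel = g["u_max"] / g["tl_cm"]
            row["u_max_rel_mean"] = rel.mean()
            row["u_max_rel_sd"] = rel.std(ddof=1)
        else:
            row["u_max_rel_mean"] = (
                relative_speed(row["u_max_mean"], mean_tl) if mean_tl and mean_tl > 0
                else math.nan
            )
            # daily spread of per-fish U_max on the day's mean-length scale
            row["u_max_rel_sd"] = (
                row["u_max_sd"] / mean_tl if mean_tl and mean_tl > 0 else math.nan
            )
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["species", "dph"]).reset_index(drop=True)
    return out
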