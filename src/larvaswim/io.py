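"""Image-sequence loading and pixel↔physical calibration.

A sequence of backlit still photographs is the raw observation unit:
ordered grayscale frames plus capture times. Physical scale comes from a
reference object of known size photographed in the tank (e.g. a 1 cm
grid); the user supplies either two pixel points spanning a known
distance or ``cm_per_px`` directly — no automatic grid detection is
attempted.

Coordinate convention (used everywhere in this package): image origin is
the top-left corner, ``x`` is the column index increasing rightward,
``y`` is the row index increasing *downward*. Physical "up" is therefore
the negative row direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameSequence",
    "Calibration",
    "load_sequence",
    "write_sequence",
    "calibrate_from_points",
]

#: ITU-R BT.601 luminance weights, the standard still-photo gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with capture times.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, float values in [0, 1].
    timestamps
        Capture time of each frame in seconds, strictly increasing.
    acquisition
        Optional free-form camera metadata (shutter, ISO, aperture, focal
        length, frame rate ...), carried through unmodified.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, height, width) stack, got shape {self.frames.shape}"
            )
        if len(self.frames) < 2:
            raise ValueError(
                "a sequence needs at least 2 frames to measure movement"
            )
        if len(self.timestamps) != len(self.frames):
            raise ValueError(
                f"{len(self.timestamps)} timestamps for {len(self.frames)} frames"
            )
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of every frame."""
        return self.frames.shape[1:]

    def dt(self, i: int, j: int) -> float:
        """Elapsed seconds between frame ``i`` and frame ``j``."""
        return float(self.timestamps[j] - self.timestamps[i])


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-physical scale.

    ``y_up_is_negative_row`` records the fixed convention that physical
    "up" corresponds to decreasing row index; it exists so downstream
    code can assert it rather than silently assume it.
    """

    cm_per_px: float
    y_up_is_negative_row: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.cm_per_px) and self.cm_per_px > 0):
            raise ValueError(f"cm_per_px must be finite and > 0, got {self.cm_per_px}")


def _to_gray01(img: np.ndarray) -> np.ndarray:
    """Convert a decoded image to float grayscale in [0, 1]."""
    arr = np.asarray(img)
    if arr.ndim == 3:  # RGB(A) → luminance
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(float)
    if arr.max() > 1.0:  # integer-coded image
        info_max = 255.0 if arr.max() <= 255 else 65535.0
        arr = arr / info_max
    return np.clip(arr, 0.0, 1.0)


def load_sequence(
    paths: Sequence[str | Path],
    *,
    fps: float | None = None,
    timestamps: Sequence[float] | None = None,
    acquisition: dict | None = None,
) -> FrameSequence:
    """Load an ordered list of image files into a :class:`FrameSequence`.

    Exactly one of ``fps`` or ``timestamps`` must be given. With ``fps``,
    frame *k* is stamped ``k / fps`` seconds. RGB inputs are converted to
    luminance grayscale; all frames must share one dimension.
    """
    if (fps is None) == (timestamps is None):
        raise ValueError("give exactly one of fps= or timestamps=")
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise ValueError("a sequence needs at least 2 frames to measure movement")

    frames = []
    shape: tuple[int, int] | None = None
    for p in paths:
        gray = _to_gray01(iio.imread(p))
        if shape is None:
            shape = gray.shape
        elif gray.shape != shape:
            raise ValueError(
                f"frame dimensions differ: {p} is {gray.shape}, expected {shape}"
            )
        frames.append(gray)

    if timestamps is None:
        if fps <= 0:
            raise ValueError(f"fps must be positive, got {fps}")
        ts = np.arange(len(frames)) / float(fps)
    else:
        ts = np.asarray(timestamps, dtype=float)

    return FrameSequence(np.stack(frames), ts, acquisition or {})


def write_sequence(seq: FrameSequence, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Write frames as numbered 8-bit grayscale images; returns the paths."""
    if fmt not in ("png", "tiff", "tif"):
        raise ValueError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, frame in enumerate(seq.frames):
        u8 = np.round(np.clip(frame, 0, 1) * 255).astype(np.uint8)
        p = out_dir / f"frame_{k:05d}.{fmt}"
        iio.imwrite(p, u8)
        paths.append(p)
    return paths


def calibrate_from_points(
    p1: tuple[float, float], p2: tuple[float, float], known_cm: float
) -> Calibration:
    """Build a :class:`Calibration` from two pixel points a known distance apart.

    The scale is the euclidean pixel distance between the points divided
    into the known physical distance, so it is rotation-invariant: any
    orientation of the reference object gives the same answer.
    """
    if known_cm <= 0:
        raise ValueError(f"known_cm must be > 0, got {known_cm}")
    d = math.dist(p1, p2)
    if d == 0:
        raise ValueError("calibration points coincide")
    return Calibration(cm_per_px=known_cm / d)
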