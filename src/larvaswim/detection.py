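"""Per-frame segmentation of dark larvae on a bright backlit background.

The chain is: threshold the frame to a binary mask, label connected
components, discard sub-threshold specks
(the noise-reduction step), then merge nearby components so that a single
larva fragmented by its translucency is still counted once. Each merged
group emits one detection whose centroid is the unweighted mean of its
foreground pixel coordinates — the binary mass centroid.

Three threshold modes exist. ``background`` (default) estimates the
backlit background by the median and its spread by the MAD and takes
everything darker than ``median − max(k·MAD, contrast_floor)``; it is
robust when larvae cover a tiny fraction of the frame, which is the
normal case for tank photographs. ``otsu`` is the classic bimodal
split — appropriate when foreground occupies an appreciable pixel
fraction, but it places the threshold inside the background noise when
the dark class is very sparse. ``fixed`` applies a user level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _graph_components
from skimage.filters import threshold_otsu
from skimage.measure import label as _label
from skimage.morphology import binary_opening

__all__ = ["DetectionParams", "Detection", "binarize", "detect_larvae", "detect_sequence"]

# Below this full-scale intensity range a frame is treated as featureless:
# Otsu on a (near-)degenerate histogram would otherwise split noise in half.
_BLANK_RANGE = 1e-3


@dataclass(frozen=True)
class DetectionParams:
    """Segmentation knobs.

    ``merge_distance_px`` should be set near the expected larval body
    length in pixels: fragments of one fish are at most a body length
    apart, while distinct fish swimming normally are further.
    """

    threshold_mode: str = "background"  # "background" | "otsu" | "fixed"
    fixed_threshold: Optional[float] = None
    min_area_px: int = 1
    merge_distance_px: float = 0.0
    roi: Optional[tuple[int, int, int, int]] = None  # (row0, col0, row1, col1), half-open
    opening_radius: int = 0  # optional morphological opening; 0 = off
    bg_k_mad: float = 6.0  # background mode: threshold = median − max(k·MAD, floor)
    contrast_floor: float = 0.08

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("background", "otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if (self.threshold_mode == "fixed") != (self.fixed_threshold is not None):
            raise ValueError("fixed_threshold must be given iff threshold_mode='fixed'")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.merge_distance_px < 0:
            raise ValueError("merge_distance_px must be >= 0")


@dataclass(frozen=True)
class Detection:
    """One segmented larva candidate in one frame.

    ``centroid_px`` is (x, y) = (column, row) in image coordinates.
    ``n_merged_components`` counts the connected components fused into
    this detection (1 = no merging happened).
    """

    frame_index: int
    centroid_px: tuple[float, float]
    area_px: int
    n_merged_components: int = 1

    @property
    def x(self) -> float:
        return self.centroid_px[0]

    @property
    def y(self) -> float:
        return self.centroid_px[1]


def binarize(frame: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Threshold a [0, 1] grayscale frame; foreground = darker than threshold.

    Larvae are photographed against backlight, so foreground pixels are
    the *dark* ones. Outside the ROI everything is background. A frame
    whose intensity range is degenerate (blank scene) yields an empty
    mask rather than an arbitrary Otsu split.
    """
    frame = np.asarray(frame, dtype=float)
    if params.roi is not None:
        r0, c0, r1, c1 = params.roi
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"empty ROI {params.roi}")
        region = frame[r0:r1, c0:c1]
    else:
        region = frame

    if params.threshold_mode == "fixed":
        sub = region < params.fixed_threshold
    elif params.threshold_mode == "otsu":
        if region.size == 0 or (region.max() - region.min()) < _BLANK_RANGE:
            sub = np.zeros(region.shape, dtype=bool)
        else:
            sub = region < threshold_otsu(region)
    else:  # background statistics
        bg = float(np.median(region))
        mad = float(np.median(np.abs(region - bg))) * 1.4826
        thresh = bg - max(params.bg_k_mad * mad, params.contrast_floor)
        sub = region < thresh

    if params.opening_radius > 0:
        footprint = np.ones((2 * params.opening_radius + 1,) * 2, dtype=bool)
        sub = binary_opening(sub, footprint)

    mask = np.zeros(frame.shape, dtype=bool)
    if params.roi is not None:
        mask[r0:r1, c0:c1] = sub
    else:
        mask = sub
    return mask


def _merge_groups(centroids: np.ndarray, max_dist: float) -> np.ndarray:
    """Single-linkage grouping: component i,j joined iff centroid distance
    <= max_dist, closed transitively. Returns a group label per component."""
    n = len(centroids)
    if n == 0:
        return np.empty(0, dtype=int)
    diff = centroids[:, None, :] - centroids[None, :, :]
    close = (diff ** 2).sum(-1) <= max_dist ** 2
    graph = coo_matrix(close)
    _, labels = _graph_components(graph, directed=False)
    return labels


def detect_larvae(
    mask: np.ndarray, params: DetectionParams, frame_index: int = 0
) -> list[Detection]:
    """Turn a binary mask into larva detections.

    Steps: 8-connectivity labelling; area filter at ``min_area_px``;
    single-linkage transitive merging of components whose centroids are
    within ``merge_distance_px``; one detection per merged group, centred
    on the unweighted mean of the group's foreground pixels.
    """
    labels = _label(mask, connectivity=2)
    n_comp = labels.max()
    if n_comp == 0:
        return []

    # per-component pixel-count and coordinate sums in one pass
    flat = labels.ravel()
    counts = np.bincount(flat, minlength=n_comp + 1)[1:]
    rows, cols = np.nonzero(labels)
    lab = labels[rows, cols]
    row_sum = np.bincount(lab, weights=rows, minlength=n_comp + 1)[1:]
    col_sum = np.bincount(lab, weights=cols, minlength=n_comp + 1)[1:]

    keep = np.nonzero(counts >= params.min_area_px)[0]
    if keep.size == 0:
        return []
    counts, row_sum, col_sum = counts[keep], row_sum[keep], col_sum[keep]
    centroids_rc = np.stack([row_sum / counts, col_sum / counts], axis=1)

    groups = _merge_groups(centroids_rc, params.merge_distance_px)
    detections = []
    for g in np.unique(groups):
        members = groups == g
        area = int(counts[members].sum())
        # group centroid = mean over all member pixels, i.e. summed sums / summed counts
        cy = row_sum[members].sum() / area
        cx = col_sum[members].sum() / area
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid_px=(float(cx), float(cy)),
                area_px=area,
                n_merged_components=int(members.sum()),
            )
        )
    detections.sort(key=lambda d: (d.centroid_px[1], d.centroid_px[0]))
    return detections


def detect_sequence(frames: np.ndarray, params: DetectionParams) -> list[list[Detection]]:
    """Run binarize + detect on every frame of a stack; one list per frame."""
    return [
        detect_larvae(binarize(f, params), params, frame_index=k)
        for k, f in enumerate(frames)
    ]
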