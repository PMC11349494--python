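"""Threshold-based particle detection.

A particle candidate is one connected component of the super-threshold voxel
set (26-connected in 3D; with a single z-plane this degenerates to
8-connectivity). Each component's tight bounding box is padded by a
user-controlled buffer fraction before fitting, mirroring the bounding-box
buffer of interactive bead-analysis tools (default 0.3). Multi-thresholding
commits detections pass by pass, masking committed particles out so that a
lower threshold can pick up dimmer beads without re-detecting bright ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError
from .iolayer import ImageStack

__all__ = [
    "ParticleBox",
    "DetectionConfig",
    "detect_particles",
    "auto_threshold",
    "multi_threshold_detect",
    "filter_by_size",
    "exclude_overlapping",
    "boxes_intersect",
]

Box = tuple[tuple[int, int, int], tuple[int, int, int]]  # half-open (lo, hi), zyx


@dataclass(frozen=True)
class ParticleBox:
    """A detected candidate's bounding boxes in voxel coordinates (z, y, x).

    ``tight_lo/hi`` bound the connected component exactly; ``buf_lo/hi`` add
    the buffer padding, clipped to the image (or ROI). ``border`` flags
    components whose buffer was clipped — their intensity tails are truncated
    and they are excluded from size statistics downstream.
    """

    channel: int
    tight_lo: tuple[int, int, int]
    tight_hi: tuple[int, int, int]
    buf_lo: tuple[int, int, int]
    buf_hi: tuple[int, int, int]
    threshold_used: float
    component_id: int
    border: bool = False

    @property
    def tight_extent(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.tight_lo, self.tight_hi))

    @property
    def buf_extent(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.buf_lo, self.buf_hi))

    @property
    def max_lateral_extent_px(self) -> int:
        ez, ey, ex = self.tight_extent
        return max(ey, ex)

    def buf_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.buf_lo, self.buf_hi))

    def tight_slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.tight_lo, self.tight_hi))


@dataclass
class DetectionConfig:
    """Detection options.

    buffer_b
        Fractional bounding-box padding per side (default 0.3); the pad is
        ``round(b * extent)`` voxels, at least 1, per side per dimension.
    size_min_px / size_max_px
        Lateral-extent filter bounds in pixels (inclusive).
    exclude_overlaps
        Drop every particle whose buffered box intersects another's.
    roi
        Optional half-open voxel box ((z0, y0, x0), (z1, y1, x1)) restricting
        the analysis.
    """

    buffer_b: float = 0.3
    size_min_px: int = 1
    size_max_px: int | None = None
    exclude_overlaps: bool = True
    roi: Box | None = None

    def __post_init__(self) -> None:
        if self.buffer_b < 0:
            raise ValueError("buffer_b must be >= 0")
        if self.size_min_px < 1:
            raise ValueError("size_min_px must be >= 1")
        if self.size_max_px is not None and self.size_max_px < self.size_min_px:
            raise ValueError("size_max_px must be >= size_min_px")


def _pad_amount(b: float, extent: int) -> int:
    return max(1, int(round(b * extent))) if b > 0 else 0


def _buffered(
    tight_lo: np.ndarray,
    tight_hi: np.ndarray,
    b: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    single_plane: bool,
) -> tuple[np.ndarray, np.ndarray, bool]:
    extent = tight_hi - tight_lo
    pad = np.array([_pad_amount(b, e) for e in extent])
    if single_plane:
        pad[0] = 0
    lo = tight_lo - pad
    hi = tight_hi + pad
    clipped = bool(np.any(lo < bounds_lo) or np.any(hi > bounds_hi))
    return np.maximum(lo, bounds_lo), np.minimum(hi, bounds_hi), clipped


def _label_volume(volume: np.ndarray, threshold: float) -> tuple[np.ndarray, int]:
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    return ndimage.label(volume >= threshold, structure=structure)


def detect_particles(
    stack: ImageStack,
    channel: int,
    threshold: float,
    cfg: DetectionConfig | None = None,
) -> list[ParticleBox]:
    """Detect particles in one channel as super-threshold connected components.

    Returns one :class:`ParticleBox` per component inside the ROI (whole image
    by default). A threshold above the image maximum yields an empty list.
    """
    cfg = cfg or DetectionConfig()
    volume = np.asarray(stack.channel(channel), dtype=float)
    return _detect_on_volume(volume, channel, threshold, cfg)


def _detect_on_volume(
    volume: np.ndarray, channel: int, threshold: float, cfg: DetectionConfig
) -> list[ParticleBox]:
    bounds_lo = np.zeros(3, dtype=int)
    bounds_hi = np.array(volume.shape, dtype=int)
    if cfg.roi is not None:
        roi_lo = np.array(cfg.roi[0], dtype=int)
        roi_hi = np.array(cfg.roi[1], dtype=int)
        if np.any(roi_lo < 0) or np.any(roi_hi > bounds_hi) or np.any(roi_lo >= roi_hi):
            raise ValueError(f"roi {cfg.roi} outside image bounds {volume.shape}")
        work = np.full_like(volume, -np.inf)
        sl = tuple(slice(l, h) for l, h in zip(roi_lo, roi_hi))
        work[sl] = volume[sl]
        bounds_lo, bounds_hi = roi_lo, roi_hi
    else:
        work = volume
    labels, n = _label_volume(work, threshold)
    single_plane = volume.shape[0] == 1
    boxes: list[ParticleBox] = []
    for cid, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:  # pragma: no cover - find_objects keeps order
            continue
        tight_lo = np.array([s.start for s in sl])
        tight_hi = np.array([s.stop for s in sl])
        buf_lo, buf_hi, clipped = _buffered(
            tight_lo, tight_hi, cfg.buffer_b, bounds_lo, bounds_hi, single_plane
        )
        boxes.append(
            ParticleBox(
                channel=channel,
                tight_lo=tuple(int(v) for v in tight_lo),
                tight_hi=tuple(int(v) for v in tight_hi),
                buf_lo=tuple(int(v) for v in buf_lo),
                buf_hi=tuple(int(v) for v in buf_hi),
                threshold_used=float(threshold),
                component_id=cid,
                border=clipped,
            )
        )
    return boxes


def auto_threshold(stack: ImageStack, channel: int,
                   max_foreground_fraction: float = 0.1) -> float:
    """Otsu threshold of the channel's intensity histogram.

    Bead fields are extremely foreground-sparse, a regime where a single
    Otsu pass can split the background mode instead of separating the spots.
    When the first split leaves more than ``max_foreground_fraction`` of the
    voxels above threshold, Otsu is re-applied to the super-threshold tail
    (recursive Otsu for unbalanced histograms) until the foreground is
    sparse. Deterministic for fixed input. Raises
    :class:`DegenerateHistogramError` on a constant image, where no
    threshold separates anything.
    """
    volume = np.asarray(stack.channel(channel), dtype=float)
    if np.ptp(volume) == 0:
        raise DegenerateHistogramError("constant image has no Otsu threshold")
    t = float(threshold_otsu(volume))
    for _ in range(8):
        tail = volume[volume > t]
        if tail.size / volume.size <= max_foreground_fraction:
            break
        if tail.size < 2 or np.ptp(tail) == 0:
            break
        t = float(threshold_otsu(tail))
    return t


def multi_threshold_detect(
    stack: ImageStack,
    channel: int,
    thresholds: Sequence[float],
    cfg: DetectionConfig | None = None,
) -> list[ParticleBox]:
    """Iterative multi-pass detection.

    Detect at the first threshold and commit those boxes; at each later
    threshold, components overlapping an already-committed particle's core
    are suppressed (a bright bead's footprint only grows as the threshold
    drops, so it is recognized and skipped rather than re-detected or left
    as a ring of tails). Typically the passes go from high to low so bright
    beads are committed first and a lower threshold can then reach dim
    beads. Committed tight boxes never share a voxel.
    """
    if not thresholds:
        raise ValueError("need at least one threshold")
    cfg = cfg or DetectionConfig()
    volume = np.asarray(stack.channel(channel), dtype=float)
    committed: list[ParticleBox] = []
    for t in thresholds:
        for box in _detect_on_volume(volume, channel, t, cfg):
            if any(boxes_intersect(box.tight_lo, box.tight_hi,
                                   c.tight_lo, c.tight_hi) for c in committed):
                continue
            committed.append(box)
    for i, box in enumerate(committed, start=1):
        object.__setattr__(box, "component_id", i)
    return committed


def filter_by_size(
    boxes: Sequence[ParticleBox], cfg: DetectionConfig
) -> list[ParticleBox]:
    """Keep boxes whose max lateral tight extent lies in [size_min, size_max] px."""
    lo = cfg.size_min_px
    hi = cfg.size_max_px if cfg.size_max_px is not None else np.inf
    return [b for b in boxes if lo <= b.max_lateral_extent_px <= hi]


def boxes_intersect(
    lo_a: Sequence[int], hi_a: Sequence[int], lo_b: Sequence[int], hi_b: Sequence[int]
) -> bool:
    """True when two half-open boxes share at least one voxel."""
    return all(la < hb and lb < ha for la, ha, lb, hb in zip(lo_a, hi_a, lo_b, hi_b))


def exclude_overlapping(boxes: Sequence[ParticleBox]) -> list[ParticleBox]:
    """Remove every particle whose buffered box intersects another's.

    Both members of each intersecting pair go; the decision is evaluated on
    the original set (order-independent), so a chain A-B-C with A and C
    disjoint still removes all three — each intersects something.
    """
    n = len(boxes)
    bad = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            if boxes_intersect(
                boxes[i].buf_lo, boxes[i].buf_hi, boxes[j].buf_lo, boxes[j].buf_hi
            ):
                bad[i] = bad[j] = True
    return [b for b, flag in zip(boxes, bad) if not flag]
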