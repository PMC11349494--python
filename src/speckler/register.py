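"""Cross-channel bead matching and chromatic-aberration calibration.

Chromatic aberration is measured as the center-to-center offset of the same
physical bead imaged in different channels. Matching is mutual-nearest-
neighbor between the reference channel and every other channel within a
search radius; beads not matched in *all* channels are dropped everywhere
(they cannot contribute a complete offset row). A calibration maps each
channel's coordinates onto the reference channel, either as a full 3D affine
transform or as per-axis polynomial surfaces of the shift over lateral field
position; calibrations round-trip through a JSON text file so a calibration
acquired on a bead slide can be applied to later experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .errors import (
    CalibrationMismatchError,
    EmptyMatchingError,
    InsufficientBeadsError,
    ParseError,
)
from .iolayer import ImageStack

__all__ = [
    "MatchedSet",
    "AberrationModel",
    "match_points",
    "distance_matrices",
    "aberration_stats",
    "fit_aberration",
    "apply_aberration_points",
    "apply_aberration_image",
    "save_calibration",
    "load_calibration",
]

DEFAULT_MAX_DIST_NM = 500.0


def _centers(records: Sequence) -> np.ndarray:
    """(n, 3) array of fitted centers in nm from records or raw arrays."""
    if isinstance(records, np.ndarray):
        return np.atleast_2d(np.asarray(records, dtype=float))
    out = []
    for r in records:
        c = getattr(r, "center_nm", r)
        out.append(np.asarray(c, dtype=float))
    return np.array(out).reshape(-1, 3)


@dataclass
class MatchedSet:
    """Correspondence of the same physical bead across channels.

    ``rows[c]`` gives, for each matched bead (row), the record index in
    channel ``c``; a record index appears in at most one row.
    """

    rows: dict[int, np.ndarray]  # channel -> (n_matched,) record indices
    ref_channel: int
    unmatched_removed: dict[int, int]

    @property
    def n_matched(self) -> int:
        return len(self.rows[self.ref_channel])

    @property
    def channels(self) -> list[int]:
        return sorted(self.rows)


def _mutual_nn(a: np.ndarray, b: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbor pairs between point sets a and b within radius."""
    if len(a) == 0 or len(b) == 0:
        return []
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    d_ab, nn_ab = tree_b.query(a, k=1)
    d_ba, nn_ba = tree_a.query(b, k=1)
    pairs = []
    for i, (j, d) in enumerate(zip(nn_ab, d_ab)):
        if d <= max_dist and nn_ba[j] == i:
            pairs.append((i, int(j)))
    return pairs


def match_points(
    per_channel_records: dict[int, Sequence],
    ref_channel: int = 0,
    max_dist_nm: float = DEFAULT_MAX_DIST_NM,
) -> MatchedSet:
    """Match beads across channels by mutual nearest neighbors.

    A bead survives only if the reference-channel record finds a mutual
    nearest neighbor within ``max_dist_nm`` in *every* other channel; all
    other records are removed and counted per channel.

    Raises :class:`EmptyMatchingError` (with the median nearest-neighbor
    distance as a diagnostic) when nothing matches.
    """
    channels = sorted(per_channel_records)
    if len(channels) < 2:
        raise ValueError("matching needs at least two channels")
    if ref_channel not in per_channel_records:
        raise ValueError(f"ref_channel {ref_channel} not among {channels}")
    ref_pts = _centers(per_channel_records[ref_channel])
    per_pair: dict[int, dict[int, int]] = {}
    for c in channels:
        if c == ref_channel:
            continue
        pts = _centers(per_channel_records[c])
        per_pair[c] = dict(_mutual_nn(ref_pts, pts, max_dist_nm))
    surviving_ref = [
        i for i in range(len(ref_pts)) if all(i in per_pair[c] for c in per_pair)
    ]
    if not surviving_ref:
        diags = []
        for c in per_pair:
            pts = _centers(per_channel_records[c])
            if len(pts) and len(ref_pts):
                d, _ = cKDTree(pts).query(ref_pts, k=1)
                diags.append(f"ch{c}: median NN {np.median(d):.1f} nm")
        raise EmptyMatchingError(
            "no bead matched in all channels (" + "; ".join(diags) + ")"
        )
    rows = {ref_channel: np.array(surviving_ref, dtype=int)}
    removed = {ref_channel: len(ref_pts) - len(surviving_ref)}
    for c in per_pair:
        rows[c] = np.array([per_pair[c][i] for i in surviving_ref], dtype=int)
        removed[c] = len(_centers(per_channel_records[c])) - len(surviving_ref)
    return MatchedSet(rows=rows, ref_channel=ref_channel, unmatched_removed=removed)


def distance_matrices(
    records_a: Sequence, records_b: Sequence, dims: int = 3
) -> np.ndarray:
    """Pairwise Euclidean distances (nm) between two sets of fitted centers.

    ``dims=2`` uses X and Y only. With ``records_a is records_b`` the matrix
    is symmetric with a zero diagonal.
    """
    a = _centers(records_a)
    b = _centers(records_b)
    if dims == 2:
        a, b = a[:, :2], b[:, :2]
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def aberration_stats(
    matched: MatchedSet, per_channel_records: dict[int, Sequence]
) -> dict[int, dict]:
    """Per-bead and mean chromatic offsets of each channel vs the reference.

    For every non-reference channel: per-bead ``delta = center_c - center_ref``
    (nm) along each axis, the 2D and 3D distances, and their means/SDs over
    beads. Export converts to um; internally everything stays nm.
    """
    ref = _centers(per_channel_records[matched.ref_channel])[
        matched.rows[matched.ref_channel]
    ]
    out: dict[int, dict] = {}
    for c in matched.channels:
        pts = _centers(per_channel_records[c])[matched.rows[c]]
        delta = pts - ref
        with np.errstate(invalid="ignore"):
            d2 = np.sqrt((delta[:, :2] ** 2).sum(axis=1))
            d3 = np.sqrt((delta**2).sum(axis=1))
        out[c] = {
            "delta_nm": delta,
            "d2d_nm": d2,
            "d3d_nm": d3,
            "mean_delta_nm": delta.mean(axis=0),
            "sd_delta_nm": delta.std(axis=0, ddof=1) if len(delta) > 1 else np.zeros(3),
            "mean_d2d_nm": float(d2.mean()),
            "mean_d3d_nm": float(d3.mean()),
        }
    return out


# ---------------------------------------------------------------------------
# aberration models


def _poly_terms(xy: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of monomials x^i y^j, i + j <= degree, over field position."""
    x, y = xy[:, 0], xy[:, 1]
    cols = [x**i * y**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.stack(cols, axis=1)


def _poly_exponents(degree: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(degree + 1) for j in range(degree + 1 - i)]


@dataclass
class AberrationModel:
    """Mapping of each channel's coordinates onto the reference channel.

    kind "affine": per channel a 3x4 matrix ``M`` with
    ``corrected = M @ [x, y, z, 1]``. kind "poly_surface": per channel and
    per axis, 2D polynomial coefficients (over lateral field position, in
    the order of ``x^i y^j`` with ``i + j <= degree``) predicting the shift
    ``center_c - center_ref``; ``corrected = point - shift(point)``. The
    reference channel always maps identically.
    """

    kind: str
    ref_channel: int
    params: dict[int, np.ndarray]  # channel -> 3x4 (affine) or 3xT (poly)
    degree: int | None
    fit_rms_nm: dict[int, float]

    def correct(self, channel: int, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if channel == self.ref_channel:
            return pts.copy()
        if channel not in self.params:
            raise CalibrationMismatchError(
                f"calibration has no channel {channel} (has {sorted(self.params)})"
            )
        if self.kind == "affine":
            m = self.params[channel]
            homo = np.hstack([pts, np.ones((len(pts), 1))])
            return homo @ m.T
        terms = _poly_terms(pts[:, :2], self.degree)
        shift = terms @ self.params[channel].T  # (n, 3)
        return pts - shift

    def shift_at(self, channel: int, points: np.ndarray) -> np.ndarray:
        """Predicted shift (center_c - center_ref) at the given points, nm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts - self.correct(channel, pts)


def fit_aberration(
    matched: MatchedSet,
    per_channel_records: dict[int, Sequence],
    kind: str = "affine",
    degree: int = 2,
) -> AberrationModel:
    """Least-squares calibration mapping each channel onto the reference.

    "affine" fits a full 3D affine transform (12 parameters) from the
    channel's centers to the reference centers; "poly_surface" fits, per
    axis, a polynomial of the shift over lateral field position (default
    degree 2 — the axial shift varies slowly over the field). Requires at
    least ``max(4, #params per axis)`` matched beads.
    """
    if kind not in ("affine", "poly_surface"):
        raise ValueError(f"unknown model kind {kind!r}")
    ref = _centers(per_channel_records[matched.ref_channel])[
        matched.rows[matched.ref_channel]
    ]
    n = len(ref)
    params: dict[int, np.ndarray] = {}
    rms: dict[int, float] = {}
    for c in matched.channels:
        if c == matched.ref_channel:
            continue
        pts = _centers(per_channel_records[c])[matched.rows[c]]
        if kind == "affine":
            need = max(4, 4)
            if n < need:
                raise InsufficientBeadsError(
                    f"affine needs >= {need} matched beads, got {n}"
                )
            homo = np.hstack([pts, np.ones((n, 1))])
            m, *_ = np.linalg.lstsq(homo, ref, rcond=None)
            params[c] = m.T  # 3x4
            resid = homo @ m - ref
        else:
            if degree < 1:
                raise ValueError("poly_surface degree must be >= 1")
            terms = _poly_terms(pts[:, :2], degree)
            need = max(4, terms.shape[1])
            if n < need:
                raise InsufficientBeadsError(
                    f"poly_surface degree {degree} needs >= {need} beads, got {n}"
                )
            shift = pts - ref
            coef, *_ = np.linalg.lstsq(terms, shift, rcond=None)
            params[c] = coef.T  # 3 x n_terms
            resid = terms @ coef - shift
        rms[c] = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AberrationModel(
        kind=kind,
        ref_channel=matched.ref_channel,
        params=params,
        degree=degree if kind == "poly_surface" else None,
        fit_rms_nm=rms,
    )


def apply_aberration_points(
    model: AberrationModel, points: np.ndarray, channel: int
) -> np.ndarray:
    """Map a channel's fitted centers into the reference frame (nm)."""
    return model.correct(channel, points)


def apply_aberration_image(model: AberrationModel, stack: ImageStack) -> ImageStack:
    """Resample non-reference channels so they overlay the reference channel.

    The corrected image at output position ``p`` samples the original at the
    inverse-mapped position (exact matrix inverse for affine; for polynomial
    surfaces the local shift is small and slowly varying, so ``p + shift(p)``
    serves as the inverse). Trilinear interpolation; the reference channel is
    untouched.
    """
    for c in model.params:
        if c >= stack.n_channels:
            raise CalibrationMismatchError(
                f"calibration channel {c} not in stack with {stack.n_channels} channels"
            )
    dz, dy, dx = stack.pitch_nm
    nz, ny, nx = stack.shape_zyx
    zz, yy, xx = np.meshgrid(
        (np.arange(nz) + 0.5) * dz,
        (np.arange(ny) + 0.5) * dy,
        (np.arange(nx) + 0.5) * dx,
        indexing="ij",
    )
    out_pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    voxels = np.array(stack.voxels, dtype=float, copy=True)
    for c in range(stack.n_channels):
        if c == model.ref_channel or c not in model.params:
            continue
        if model.kind == "affine":
            m = np.vstack([model.params[c], [0.0, 0.0, 0.0, 1.0]])
            inv = np.linalg.inv(m)[:3]
            homo = np.hstack([out_pts, np.ones((len(out_pts), 1))])
            src = homo @ inv.T
        else:
            src = out_pts + model.shift_at(c, out_pts)
        coords = np.stack(
            [src[:, 2] / dz - 0.5, src[:, 1] / dy - 0.5, src[:, 0] / dx - 0.5]
        )
        voxels[c] = map_coordinates(
            np.asarray(stack.voxels[c], dtype=float), coords, order=1, mode="nearest"
        ).reshape(nz, ny, nx)
    if np.issubdtype(stack.voxels.dtype, np.integer):
        info = np.iinfo(stack.voxels.dtype)
        voxels = np.clip(np.round(voxels), info.min, info.max).astype(stack.voxels.dtype)
    return stack.with_voxels(voxels)


# ---------------------------------------------------------------------------
# persistence


def save_calibration(model: AberrationModel, path: str | Path) -> Path:
    """Write a calibration as JSON text (lossless roundtrip)."""
    path = Path(path)
    payload = {
        "format": "speckler-aberration-calibration",
        "version": 1,
        "kind": model.kind,
        "ref_channel": model.ref_channel,
        "degree": model.degree,
        "params": {str(c): m.tolist() for c, m in model.params.items()},
        "fit_rms_nm": {str(c): v for c, v in model.fit_rms_nm.items()},
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_calibration(path: str | Path) -> AberrationModel:
    """Read a calibration written by :func:`save_calibration`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot parse calibration {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("kind") not in (
        "affine",
        "poly_surface",
    ):
        raise ParseError(f"unknown calibration kind in {path}")
    try:
        return AberrationModel(
            kind=payload["kind"],
            ref_channel=int(payload["ref_channel"]),
            params={int(c): np.array(m, dtype=float)
                    for c, m in payload["params"].items()},
            degree=None if payload.get("degree") is None else int(payload["degree"]),
            fit_rms_nm={int(c): float(v)
                        for c, v in payload.get("fit_rms_nm", {}).items()},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed calibration {path}: {exc}") from exc
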