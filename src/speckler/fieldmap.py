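"""Field-dependence surfaces and illumination flatness.

Bead measurements (intensity, FWHM) are binned by lateral center position
into an n x n tile grid over the field of view; per-tile means expose
vignetting and off-axis PSF degradation. The flatness score — the dimmest
populated tile as a percentage of the brightest — is this package's own
summary statistic for illumination uniformity and is labeled as such in
reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptySummaryError

__all__ = ["FieldSurface", "field_surface", "flatness_score", "save_surface"]

#: quantity label -> attribute/column on a ParticleRecord
QUANTITIES = {
    "integrated_intensity": "integrated_intensity",
    "max_intensity": "max_intensity",
    "tFWHM_X": ("tfwhm_nm", 0),
    "tFWHM_Y": ("tfwhm_nm", 1),
    "iFWHM_Z": ("ifwhm_nm", 2),
}


@dataclass
class FieldSurface:
    """Per-tile means of one quantity over an n x n grid covering the FOV."""

    means: np.ndarray  # (n, n), NaN where count == 0; [iy, ix]
    counts: np.ndarray  # (n, n) int
    quantity: str
    channel: int
    fov_x_nm: float
    fov_y_nm: float


def _quantity_values(records: Sequence, quantity: str) -> np.ndarray:
    spec = QUANTITIES.get(quantity, quantity)
    out = []
    for r in records:
        if isinstance(spec, tuple):
            attr, idx = spec
            out.append(float(np.asarray(getattr(r, attr))[idx]))
        else:
            out.append(float(getattr(r, spec)))
    return np.array(out)


def field_surface(
    records: Sequence,
    quantity: str,
    grid_n: int = 8,
    fov_xy_nm: tuple[float, float] | None = None,
    channel: int = 0,
) -> FieldSurface:
    """Bin beads by lateral (x, y) center into ``grid_n**2`` tiles.

    Tiles are half-open so each bead bins into exactly one tile; the tile
    counts sum to the number of input beads. ``fov_xy_nm`` gives the field
    extent (x, y); when omitted it is taken from the bead positions.
    """
    if not len(records):
        raise EmptySummaryError("no records to build a field surface from")
    centers = np.array(
        [np.asarray(getattr(r, "center_nm", r), dtype=float)[:2] for r in records]
    )
    values = _quantity_values(records, quantity)
    if fov_xy_nm is None:
        fov_x = float(centers[:, 0].max()) * 1.0000001 + 1e-9
        fov_y = float(centers[:, 1].max()) * 1.0000001 + 1e-9
    else:
        fov_x, fov_y = float(fov_xy_nm[0]), float(fov_xy_nm[1])
    ix = np.clip((centers[:, 0] / fov_x * grid_n).astype(int), 0, grid_n - 1)
    iy = np.clip((centers[:, 1] / fov_y * grid_n).astype(int), 0, grid_n - 1)
    counts = np.zeros((grid_n, grid_n), dtype=int)
    sums = np.zeros((grid_n, grid_n))
    keep = np.isfinite(values)
    np.add.at(counts, (iy, ix), 1)
    np.add.at(sums, (iy[keep], ix[keep]), values[keep])
    valid = np.zeros((grid_n, grid_n), dtype=int)
    np.add.at(valid, (iy[keep], ix[keep]), 1)
    with np.errstate(invalid="ignore"):
        means = np.where(valid > 0, sums / np.maximum(valid, 1), np.nan)
    return FieldSurface(
        means=means, counts=counts, quantity=quantity, channel=channel,
        fov_x_nm=fov_x, fov_y_nm=fov_y,
    )


def flatness_score(surface: FieldSurface) -> float:
    """Illumination flatness: 100 * min / max over populated tile means.

    100% is perfectly uniform; a vignetted field scores roughly the corner-
    to-center intensity ratio. Scale-invariant. Requires at least two
    populated tiles.
    """
    vals = surface.means[np.isfinite(surface.means)]
    if vals.size < 2:
        raise EmptySummaryError("flatness needs >= 2 populated tiles")
    return float(100.0 * vals.min() / vals.max())


def save_surface(surface: FieldSurface, outdir, stem: str | None = None) -> tuple:
    """Write a surface as CSV (tile means) and a rendered PNG heat map."""
    import csv
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"ch{surface.channel}_{surface.quantity}"
    csv_path = outdir / f"{stem}.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"tile_x{j}" for j in range(surface.means.shape[1])])
        for row in surface.means:
            writer.writerow([f"{v:.6f}" if np.isfinite(v) else "" for v in row])
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(surface.means, origin="lower", cmap="viridis",
                   extent=(0, surface.fov_x_nm / 1000, 0, surface.fov_y_nm / 1000))
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"ch{surface.channel} {surface.quantity}")
    fig.colorbar(im, ax=ax)
    png_path = outdir / f"{stem}.png"
    fig.savefig(png_path, dpi=110)
    plt.close(fig)
    return csv_path, png_path
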