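"""Result export/import in the calibration-workbook schema.

One XLSX workbook with a sheet per channel (columns A..Y: id, Gauss center,
Theta, STD, base, peak, ResNorm, wavelength, integrated and max intensity in
columns O/P, tFWHM in Q-S, iFWHM in T-V, gFWHM in W-Y, then flag columns),
an ``aberration_<wavelength>`` sheet per non-reference channel (dx, dy, dz,
2D and 3D distances, in um), an annotated bead-ID overlay PNG per channel,
and a "Field Dependence Plots" subfolder of per-quantity CSV + PNG surfaces.
Every sheet is mirrored as CSV with a fixed numeric format so exports are
byte-reproducible; ``import_results`` reads either format back losslessly.
Lengths are um in all files and nm in memory.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .fieldmap import QUANTITIES, field_surface, flatness_score, save_surface
from .iolayer import ImageStack
from .pipeline import PipelineResult
from .records import RECORD_COLUMNS, ParticleRecord

__all__ = ["records_to_frame", "frame_to_records", "export_results",
           "import_results"]

_NM_TO_UM = 1e-3
_LENGTH_COLUMNS = [
    "Gauss_X", "Gauss_Y", "Gauss_Z", "STD_X", "STD_Y", "STD_Z",
    "tFWHM_X", "tFWHM_Y", "tFWHM_Z", "iFWHM_X", "iFWHM_Y", "iFWHM_Z",
    "gFWHM_X", "gFWHM_Y", "gFWHM_Z",
]


def records_to_frame(records: Sequence[ParticleRecord]) -> pd.DataFrame:
    """Records (nm) -> exportable DataFrame (um) in the fixed column order."""
    rows = []
    for r in records:
        row = {
            "ID": r.id,
            "Gauss_X": r.center_nm[0], "Gauss_Y": r.center_nm[1],
            "Gauss_Z": r.center_nm[2],
            "Theta_X": r.theta_rad[0], "Theta_Y": r.theta_rad[1],
            "Theta_Z": r.theta_rad[2],
            "STD_X": r.sigma_nm[0], "STD_Y": r.sigma_nm[1],
            "STD_Z": r.sigma_nm[2],
            "GaussBase": r.gauss_base,
            "GaussPeak": r.gauss_peak,
            "ResNorm": r.resnorm,
            "Wavelength": r.wavelength_nm,
            "IntegratedIntensity": r.integrated_intensity,
            "MaxIntensity": r.max_intensity,
            "tFWHM_X": r.tfwhm_nm[0], "tFWHM_Y": r.tfwhm_nm[1],
            "tFWHM_Z": r.tfwhm_nm[2],
            "iFWHM_X": r.ifwhm_nm[0], "iFWHM_Y": r.ifwhm_nm[1],
            "iFWHM_Z": r.ifwhm_nm[2],
            "gFWHM_X": r.gfwhm_nm[0], "gFWHM_Y": r.gfwhm_nm[1],
            "gFWHM_Z": r.gfwhm_nm[2],
            "Border": int(r.border),
            "Unmeasurable": int(r.unmeasurable),
        }
        rows.append(row)
    frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if len(frame):
        frame[_LENGTH_COLUMNS] = frame[_LENGTH_COLUMNS] * _NM_TO_UM
    return frame


def frame_to_records(frame: pd.DataFrame, channel: int) -> list[ParticleRecord]:
    """Inverse of :func:`records_to_frame` (um -> nm)."""
    for col in RECORD_COLUMNS:
        if col not in frame.columns:
            raise ParseError(f"results table is missing column {col}")
    records = []
    for _, row in frame.iterrows():
        def nm3(prefix, suffixes=("_X", "_Y", "_Z")):
            return np.array([row[prefix + s] for s in suffixes], dtype=float) / _NM_TO_UM

        records.append(
            ParticleRecord(
                id=int(row["ID"]),
                channel=channel,
                wavelength_nm=float(row["Wavelength"]),
                center_nm=nm3("Gauss"),
                theta_rad=np.array(
                    [row["Theta_X"], row["Theta_Y"], row["Theta_Z"]], dtype=float
                ),
                sigma_nm=nm3("STD"),
                gauss_base=float(row["GaussBase"]),
                gauss_peak=float(row["GaussPeak"]),
                resnorm=float(row["ResNorm"]),
                integrated_intensity=float(row["IntegratedIntensity"]),
                max_intensity=float(row["MaxIntensity"]),
                tfwhm_nm=nm3("tFWHM"),
                ifwhm_nm=nm3("iFWHM"),
                gfwhm_nm=nm3("gFWHM"),
                border=bool(row["Border"]),
                unmeasurable=bool(row["Unmeasurable"]),
            )
        )
    return records


def _sheet_name(wavelength_nm: float, channel: int) -> str:
    return f"ch{channel}_{wavelength_nm:g}nm"


def _aberration_frame(stats: dict) -> pd.DataFrame:
    delta_um = stats["delta_nm"] * _NM_TO_UM
    return pd.DataFrame(
        {
            "dX": delta_um[:, 0],
            "dY": delta_um[:, 1],
            "dZ": delta_um[:, 2],
            "Dist2D": stats["d2d_nm"] * _NM_TO_UM,
            "Dist3D": stats["d3d_nm"] * _NM_TO_UM,
        }
    )


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def _overlay_png(stack: ImageStack, channel: int,
                 records: Sequence[ParticleRecord], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    proj = np.asarray(stack.channel(channel), dtype=float).max(axis=0)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(proj, cmap="gray", origin="lower")
    for r in records:
        x = r.center_nm[0] / stack.dx_nm - 0.5
        y = r.center_nm[1] / stack.dy_nm - 0.5
        ax.annotate(str(r.id), (x, y), color="yellow", fontsize=6,
                    ha="center", va="center")
    ax.set_title(f"channel {channel} ({stack.wavelengths_nm[channel]:g} nm)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def export_results(
    result: PipelineResult,
    outdir: str | Path,
    stack: ImageStack | None = None,
    field_quantities: Sequence[str] = ("integrated_intensity", "max_intensity"),
    config_dict: dict | None = None,
) -> Path:
    """Write the full results folder; returns the folder path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_dir = outdir / "csv"
    csv_dir.mkdir(exist_ok=True)
    xlsx_path = outdir / "results.xlsx"
    manifest: dict = {
        "software": f"speckler3d {__version__}",
        "config": config_dict or {},
        "channels": {},
    }
    with pd.ExcelWriter(xlsx_path, engine="openpyxl") as writer:
        wrote_any = False
        for c, records in sorted(result.per_channel_records.items()):
            frame = records_to_frame(records)
            name = _sheet_name(
                records[0].wavelength_nm if records
                else (stack.wavelengths_nm[c] if stack else float(c)),
                c,
            )
            frame.to_excel(writer, sheet_name=name, index=False)
            _write_csv(frame, csv_dir / f"{name}.csv")
            wrote_any = True
            log = result.logs.get(c)
            manifest["channels"][str(c)] = {
                "sheet": name,
                "n_exported": len(records),
                "log": None if log is None else vars(log),
            }
        if result.aberration_stats and result.matched is not None:
            for c, stats in sorted(result.aberration_stats.items()):
                if c == result.matched.ref_channel:
                    continue
                wl = None
                recs = result.per_channel_records.get(c)
                wl = recs[0].wavelength_nm if recs else float(c)
                name = f"aberration_{wl:g}nm"
                frame = _aberration_frame(stats)
                frame.to_excel(writer, sheet_name=name, index=False)
                _write_csv(frame, csv_dir / f"{name}.csv")
        if not wrote_any:  # keep a valid workbook even with zero channels
            pd.DataFrame(columns=RECORD_COLUMNS).to_excel(
                writer, sheet_name="empty", index=False
            )

    if stack is not None:
        for c, records in result.per_channel_records.items():
            _overlay_png(stack, c, records, outdir / f"beads_ch{c}.png")

    if result.aberration_model is not None:
        from .register import save_calibration

        save_calibration(result.aberration_model, outdir / "aberration_calibration.json")

    # field-dependence plots
    plots_dir = outdir / "Field Dependence Plots"
    fov = None
    if stack is not None:
        fov = (stack.shape_zyx[2] * stack.dx_nm, stack.shape_zyx[1] * stack.dy_nm)
    flatness: dict = {}
    for c, records in result.per_channel_records.items():
        if not records:
            continue
        for quantity in field_quantities:
            surface = field_surface(records, quantity, fov_xy_nm=fov, channel=c)
            save_surface(surface, plots_dir)
            if quantity == "integrated_intensity":
                try:
                    flatness[str(c)] = flatness_score(surface)
                except Exception:
                    pass
    if flatness:
        # min/max populated-tile ratio; this summary statistic is our own,
        # not part of the original workbook schema
        manifest["illumination_flatness_percent"] = flatness

    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return outdir


def import_results(path: str | Path) -> dict[int, list[ParticleRecord]]:
    """Read a results workbook (or a CSV mirror folder) back into records.

    Returns ``{channel: [ParticleRecord, ...]}``. Raises :class:`ParseError`
    naming the first missing column on schema mismatch.
    """
    path = Path(path)
    frames: dict[int, pd.DataFrame] = {}
    if path.is_dir():
        for csv_file in sorted(path.glob("ch*_*.csv")):
            channel = int(csv_file.stem.split("_")[0][2:])
            frames[channel] = pd.read_csv(csv_file)
    elif path.suffix.lower() in (".xlsx", ".xls"):
        book = pd.read_excel(path, sheet_name=None)
        for name, frame in book.items():
            if name.startswith("ch") and "_" in name:
                channel = int(name.split("_")[0][2:])
                frames[channel] = frame
    elif path.suffix.lower() == ".csv":
        name = path.stem
        channel = int(name.split("_")[0][2:]) if name.startswith("ch") else 0
        frames[channel] = pd.read_csv(path)
    else:
        raise ParseError(f"unsupported results format: {path}")
    if not frames:
        raise ParseError(f"no channel sheets found in {path}")
    return {c: frame_to_records(f, c) for c, f in sorted(frames.items())}
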