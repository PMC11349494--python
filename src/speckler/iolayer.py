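"""Image stack I/O.

Everything downstream works on one in-memory representation, :class:`ImageStack`:
a ``(channel, z, y, x)`` voxel array plus its physical calibration. Lengths are
nanometers everywhere inside the package; micrometer conversion happens only in
file metadata and exported tables. The physical coordinate of voxel index ``i``
along an axis with pitch ``p`` is ``(i + 0.5) * p`` (center-of-voxel convention).

Supported on disk: OME-TIFF (read/write, with PhysicalSizeX/Y/Z and per-channel
emission wavelengths honored) and plain multi-page TIFF (read; treated as a
single channel, calibration must be supplied by the caller).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import CalibrationMissingError, FormatError, IncompatibleStacksError

__all__ = ["ImageStack", "load_stack", "merge_channels", "write_stack"]

_UM_TO_NM = 1000.0

#: unit multipliers to nm for the OME PhysicalSize*Unit attribute
_UNIT_TO_NM = {
    "nm": 1.0,
    "µm": 1000.0,
    "um": 1000.0,
    "µm": 1000.0,
    "μm": 1000.0,
    "mm": 1e6,
    "m": 1e9,
    "Å": 0.1,
}


@dataclass
class ImageStack:
    """A multi-channel 3D image with physical calibration.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(channel, z, y, x)``. A 2D image has z-depth 1.
    dx_nm, dy_nm
        Lateral voxel size in nm (square pixels: dx == dy).
    dz_nm
        Axial step in nm; may be ``None`` for single-plane images.
    wavelengths_nm
        One emission-wavelength label per channel; labels must be unique.
    source_path
        Provenance string (file the stack came from, or a simulator tag).
    """

    voxels: np.ndarray
    dx_nm: float
    dy_nm: float
    dz_nm: float | None
    wavelengths_nm: tuple[float, ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be indexed (channel, z, y, x)")
        self.wavelengths_nm = tuple(float(w) for w in self.wavelengths_nm)
        if len(self.wavelengths_nm) != self.voxels.shape[0]:
            raise ValueError("need exactly one wavelength per channel")
        if len(set(self.wavelengths_nm)) != len(self.wavelengths_nm):
            raise ValueError("channel wavelengths must be unique")
        if not (self.dx_nm > 0 and self.dy_nm > 0):
            raise ValueError("lateral voxel sizes must be positive")
        if self.voxels.shape[1] > 1:
            if self.dz_nm is None or not self.dz_nm > 0:
                raise ValueError("dz_nm must be positive for z-stacks")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be non-negative")

    # -- conveniences -------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def is_3d(self) -> bool:
        return self.voxels.shape[1] > 1

    @property
    def pitch_nm(self) -> np.ndarray:
        """Voxel pitch as (z, y, x) in nm; z pitch is 1 for single planes."""
        dz = self.dz_nm if self.dz_nm is not None else 1.0
        return np.array([dz, self.dy_nm, self.dx_nm], dtype=float)

    def channel(self, index: int) -> np.ndarray:
        return self.voxels[index]

    def with_voxels(self, voxels: np.ndarray) -> "ImageStack":
        return replace(self, voxels=voxels)


# ---------------------------------------------------------------------------
# reading


def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand a tifffile series into (C, Z, Y, X)."""
    axes = axes.upper()
    # Samples axis (RGB) is not a fluorescence channel layout we support.
    if "S" in axes and data.shape[axes.index("S")] > 1:
        raise FormatError("RGB/interleaved-sample TIFFs are not supported")
    # a plain multi-page TIFF reports an anonymous page axis (Q or I):
    # treat the pages as z-planes of a single channel
    for anon in "QI":
        if anon in axes:
            target = "Z" if "Z" not in axes else ("C" if "C" not in axes else None)
            if target is None and data.shape[axes.index(anon)] > 1:
                raise FormatError(f"unsupported TIFF axis layout {axes!r}")
            if target is not None:
                axes = axes.replace(anon, target, 1)
    keep = []
    for ax in "CZYX":
        if ax in axes:
            keep.append(axes.index(ax))
        else:
            data = data[np.newaxis]
            axes = ax + axes
            keep = [0] + [k + 1 for k in keep]
    drop = [i for i, ax in enumerate(axes) if ax not in "CZYX"]
    for i in sorted(drop, reverse=True):
        if data.shape[i] != 1:
            raise FormatError(f"unsupported TIFF axis {axes[i]!r} with length > 1")
        data = np.squeeze(data, axis=i)
        axes = axes[:i] + axes[i + 1 :]
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(data, order)


def _parse_ome(xml_text: str) -> dict:
    """Pull pixel sizes (nm) and channel wavelengths out of OME XML."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError as exc:  # pragma: no cover - defensive
        raise FormatError(f"invalid OME XML: {exc}") from exc

    def _local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    pixels = None
    for elem in root.iter():
        if _local(elem.tag) == "Pixels":
            pixels = elem
            break
    if pixels is None:
        return {}
    out: dict = {}
    for axis in "XYZ":
        size = pixels.get(f"PhysicalSize{axis}")
        if size is not None:
            unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
            out[f"d{axis.lower()}_nm"] = float(size) * _UNIT_TO_NM.get(unit, 1000.0)
    wavelengths = []
    for elem in pixels:
        if _local(elem.tag) == "Channel":
            wl = elem.get("EmissionWavelength")
            wavelengths.append(None if wl is None else float(wl))
    if wavelengths and all(w is not None for w in wavelengths):
        out["wavelengths_nm"] = wavelengths
    return out


def load_stack(
    path: str | Path,
    scale_override: Mapping[str, float] | None = None,
    wavelengths_nm: Sequence[float] | None = None,
) -> ImageStack:
    """Read a TIFF / OME-TIFF file into an :class:`ImageStack`.

    Voxel sizes come from the OME metadata when present; otherwise they must be
    supplied through ``scale_override`` (keys ``dx_nm`` and, for stacks,
    ``dz_nm``) — the override also wins over metadata when both are given.
    A plain multi-page TIFF with no channel axis is treated as one channel.

    Raises
    ------
    FormatError
        The file is unreadable or has an unsupported axis layout.
    CalibrationMissingError
        Neither metadata nor override provides the voxel sizes.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            data = series.asarray()
            axes = series.axes
            ome_xml = tif.ome_metadata
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc

    voxels = _axes_to_czyx(np.asarray(data), axes)
    meta = _parse_ome(ome_xml) if ome_xml else {}

    override = dict(scale_override or {})
    dx = override.get("dx_nm", meta.get("dx_nm"))
    dy = override.get("dx_nm", meta.get("dy_nm", meta.get("dx_nm")))
    dz = override.get("dz_nm", meta.get("dz_nm"))
    if dx is None:
        raise CalibrationMissingError(
            f"{path} carries no pixel-size metadata; pass scale_override="
            "{'dx_nm': ..., 'dz_nm': ...}"
        )
    if voxels.shape[1] > 1 and dz is None:
        raise CalibrationMissingError(
            f"{path} is a z-stack without axial step metadata; pass "
            "scale_override={'dz_nm': ...}"
        )

    if wavelengths_nm is not None:
        wl = tuple(float(w) for w in wavelengths_nm)
    elif "wavelengths_nm" in meta:
        wl = tuple(meta["wavelengths_nm"])
    else:
        # Channel order is file order; synthesize distinct placeholder labels.
        wl = tuple(float(i + 1) for i in range(voxels.shape[0]))
    return ImageStack(
        voxels=voxels,
        dx_nm=float(dx),
        dy_nm=float(dy),
        dz_nm=None if dz is None else float(dz),
        wavelengths_nm=wl,
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# merging and writing


def merge_channels(stacks: Sequence[ImageStack]) -> ImageStack:
    """Stack single-channel images into one multi-channel ImageStack.

    All inputs must share voxel grid shape and voxel sizes; channel order is
    the order given.
    """
    if not stacks:
        raise IncompatibleStacksError("nothing to merge")
    first = stacks[0]
    for s in stacks[1:]:
        if s.voxels.shape[1:] != first.voxels.shape[1:]:
            raise IncompatibleStacksError(
                f"shape mismatch: {s.voxels.shape[1:]} vs {first.voxels.shape[1:]}"
            )
        if (s.dx_nm, s.dy_nm, s.dz_nm) != (first.dx_nm, first.dy_nm, first.dz_nm):
            raise IncompatibleStacksError("voxel-size mismatch between stacks")
    voxels = np.concatenate([s.voxels for s in stacks], axis=0)
    wl = tuple(w for s in stacks for w in s.wavelengths_nm)
    return ImageStack(
        voxels=voxels,
        dx_nm=first.dx_nm,
        dy_nm=first.dy_nm,
        dz_nm=first.dz_nm,
        wavelengths_nm=wl,
        source_path=";".join(s.source_path for s in stacks if s.source_path),
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as OME-TIFF with calibration and channel metadata.

    Single-plane stacks are written without a Z axis so readers report a 2D
    image; integer data is preserved bit-for-bit, floats are written as
    float32.
    """
    path = Path(path)
    voxels = stack.voxels
    if np.issubdtype(voxels.dtype, np.floating):
        voxels = voxels.astype(np.float32)
    metadata = {
        "PhysicalSizeX": stack.dx_nm / _UM_TO_NM,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.dy_nm / _UM_TO_NM,
        "PhysicalSizeYUnit": "µm",
        "Channel": {
            "Name": [f"ch{w:g}nm" for w in stack.wavelengths_nm],
            "EmissionWavelength": list(stack.wavelengths_nm),
            "EmissionWavelengthUnit": ["nm"] * stack.n_channels,
        },
    }
    if stack.voxels.shape[1] > 1:
        metadata["axes"] = "CZYX"
        metadata["PhysicalSizeZ"] = stack.dz_nm / _UM_TO_NM
        metadata["PhysicalSizeZUnit"] = "µm"
        data = voxels
    else:
        metadata["axes"] = "CYX"
        data = voxels[:, 0]
    try:
        tifffile.imwrite(path, data, ome=True, metadata=metadata)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
    return path
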