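"""Per-particle result records.

A :class:`ParticleRecord` gathers everything measured for one bead in one
channel: the fitted Gaussian (center, angles, sigmas, base, peak, residual),
the intensity measurements, and the three FWHM triples. Internally all
lengths are nm; the exporter converts to um.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ParticleRecord", "RECORD_COLUMNS"]

#: exported column order (sheet columns A..Y, then flags)
RECORD_COLUMNS = [
    "ID",           # A
    "Gauss_X", "Gauss_Y", "Gauss_Z",        # B-D
    "Theta_X", "Theta_Y", "Theta_Z",        # E-G
    "STD_X", "STD_Y", "STD_Z",              # H-J
    "GaussBase",    # K
    "GaussPeak",    # L
    "ResNorm",      # M
    "Wavelength",   # N
    "IntegratedIntensity",  # O
    "MaxIntensity",         # P
    "tFWHM_X", "tFWHM_Y", "tFWHM_Z",        # Q-S
    "iFWHM_X", "iFWHM_Y", "iFWHM_Z",        # T-V
    "gFWHM_X", "gFWHM_Y", "gFWHM_Z",        # W-Y
    "Border", "Unmeasurable",
]


@dataclass
class ParticleRecord:
    """One bead's full measurement set (lengths nm, angles rad)."""

    id: int
    channel: int
    wavelength_nm: float
    center_nm: np.ndarray       # (x, y, z); z NaN for 2D fits
    theta_rad: np.ndarray
    sigma_nm: np.ndarray
    gauss_base: float
    gauss_peak: float
    resnorm: float
    integrated_intensity: float
    max_intensity: float
    tfwhm_nm: np.ndarray        # (X, Y, Z)
    ifwhm_nm: np.ndarray
    gfwhm_nm: np.ndarray
    border: bool = False
    unmeasurable: bool = False

    def sorted_fwhm(self) -> "ParticleRecord":
        """Copy with each FWHM triple's defined entries sorted ascending."""
        import copy

        rec = copy.deepcopy(self)
        for attr in ("tfwhm_nm", "ifwhm_nm", "gfwhm_nm"):
            v = np.asarray(getattr(rec, attr), dtype=float)
            finite = np.isfinite(v)
            v[finite] = np.sort(v[finite])
            setattr(rec, attr, v)
        return rec
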