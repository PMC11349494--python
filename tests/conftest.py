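"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import speckler as sp

# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def flood_fill_components(volume: np.ndarray, threshold: float) -> list[set]:
    """Brute-force 26-connected components of {voxel >= threshold} via BFS."""
    mask = volume >= threshold
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    idx = np.argwhere(mask)
    shape = volume.shape
    for start in map(tuple, idx):
        if seen[start]:
            continue
        comp = set()
        queue = [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.add(v)
            z, y, x = v
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        if dz == dy == dx == 0:
                            continue
                        w = (z + dz, y + dy, x + dx)
                        if (0 <= w[0] < shape[0] and 0 <= w[1] < shape[1]
                                and 0 <= w[2] < shape[2]
                                and mask[w] and not seen[w]):
                            seen[w] = True
                            queue.append(w)
        comps.append(comp)
    return comps


def render_gaussian(shape_zyx, pitch_zyx, center_xyz, sigma_xyz, base, peak,
                    theta_z=0.0):
    """Direct evaluation of the Gaussian spot model on the voxel grid."""
    dz, dy, dx = pitch_zyx
    z = (np.arange(shape_zyx[0]) + 0.5) * dz
    y = (np.arange(shape_zyx[1]) + 0.5) * dy
    x = (np.arange(shape_zyx[2]) + 0.5) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    cx, cy, cz = center_xyz
    sx, sy, sz = sigma_xyz
    # Rz(theta) applied to the offset vector, as the fit module documents
    c, s = np.cos(theta_z), np.sin(theta_z)
    u = (c * (xx - cx) - s * (yy - cy)) / sx
    v = (s * (xx - cx) + c * (yy - cy)) / sy
    w = (zz - cz) / sz
    return base + peak * np.exp(-0.5 * (u * u + v * v + w * w))


def stack_from_array(volume: np.ndarray, dx_nm=65.0, dz_nm=100.0,
                     wavelengths=(510.0,)) -> sp.ImageStack:
    """Wrap a (z, y, x) or (c, z, y, x) array as an ImageStack."""
    if volume.ndim == 3:
        volume = volume[np.newaxis]
    return sp.ImageStack(
        voxels=volume, dx_nm=dx_nm, dy_nm=dx_nm,
        dz_nm=dz_nm if volume.shape[1] > 1 else None,
        wavelengths_nm=wavelengths[: volume.shape[0]],
    )


# ---------------------------------------------------------------------------
# shared simulations (module-expensive, computed once)


@pytest.fixture(scope="session")
def small_field():
    """A modest 3D bead field at the standard noise conditions, with truth."""
    stack, truth = sp.simulate_bead_field(
        n_beads=40, diameter_nm=100.0, shape=(26, 256, 256),
        dx_nm=65.0, dz_nm=100.0, psf_sigma_xy_nm=80.0, psf_sigma_z_nm=200.0,
        snr=100.0, read_noise_sd=5.0, background_photons=400.0, seed=7,
    )
    return stack, truth


@pytest.fixture(scope="session")
def small_field_result(small_field):
    stack, truth = small_field
    result = sp.run_pipeline(stack, sp.PipelineConfig())
    return stack, truth, result


@pytest.fixture(scope="session")
def two_channel_field():
    """Two-channel field with a known constant chromatic shift on channel 1."""
    shift = (30.0, -20.0, 50.0)
    stack, truth = sp.simulate_bead_field(
        n_beads=25, diameter_nm=100.0, shape=(26, 256, 256),
        dx_nm=65.0, dz_nm=100.0, wavelengths_nm=(510.0, 610.0),
        psf_sigma_xy_nm=80.0, psf_sigma_z_nm=200.0,
        chromatic_shift_nm={1: shift},
        snr=100.0, read_noise_sd=5.0, background_photons=400.0, seed=8,
    )
    return stack, truth, shift


@pytest.fixture(scope="session")
def two_channel_result(two_channel_field):
    stack, truth, shift = two_channel_field
    result = sp.run_pipeline(
        stack, sp.PipelineConfig(match=True, aberration="affine")
    )
    return stack, truth, shift, result
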