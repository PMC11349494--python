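"""Sub-pixel Gaussian fitting, local background and intensity measurement.

Each detected particle is fit with a rotated anisotropic Gaussian

    I(v) = base + peak * exp(-1/2 (v - c)^T R^T diag(1/sigma^2) R (v - c))

over its buffered bounding box, in physical (x, y, z) nanometer coordinates
(voxel index i maps to (i + 0.5) * pitch). Rotation uses intrinsic Euler
angles applied z-y-x, ``R = Rz(theta_z) @ Ry(theta_y) @ Rx(theta_x)``; a 2D
fit on a 3D image is performed on the particle's best-focus plane and fits
only theta_z. Calibration beads are axisymmetric, so angle fitting is off by
default and theta is reported as 0.

Local background follows the enlarged-shell convention: the measurement box
grown by a fraction ``p`` per dimension (``p = 1`` doubles every extent), with
voxels belonging to any other particle's box excluded from the shell before
taking the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .detect import ParticleBox
from .iolayer import ImageStack

__all__ = [
    "GaussianFit",
    "BackgroundConfig",
    "fit_gaussian",
    "best_focus_plane",
    "local_background",
    "measure_intensities",
]


@dataclass
class BackgroundConfig:
    """Local background options.

    bg_buffer_p
        Fractional enlargement of the measurement box per dimension used to
        build the background shell (default 0.15, i.e. 15% larger; 1 doubles
        the box).
    estimator
        "median" (default, robust to residual bead tails) or "mean".
    """

    enabled: bool = True
    bg_buffer_p: float = 0.15
    estimator: str = "median"

    def __post_init__(self) -> None:
        if self.bg_buffer_p <= 0:
            raise ValueError("bg_buffer_p must be > 0")
        if self.estimator not in ("median", "mean"):
            raise ValueError("estimator must be 'median' or 'mean'")


@dataclass
class GaussianFit:
    """Fitted Gaussian parameters for one particle.

    Coordinates and widths are nm; entries along unfitted axes (z for a 2D
    fit) are NaN. ``resnorm = SSR / (N * peak^2)`` is a dimensionless,
    SNR-comparable residual. ``ok`` is False when the optimizer failed or the
    data were degenerate; such particles are excluded downstream.
    """

    center_nm: np.ndarray  # (x, y, z)
    theta_rad: np.ndarray  # (theta_x, theta_y, theta_z)
    sigma_nm: np.ndarray  # (sx, sy, sz)
    base: float
    peak: float
    resnorm: float
    dims: int
    box: ParticleBox
    focus_z: int | None = None  # absolute z index used for a 2D fit
    ok: bool = True


def _rotation_matrix(tx: float, ty: float, tz: float) -> np.ndarray:
    cx, sx = math.cos(tx), math.sin(tx)
    cy, sy = math.cos(ty), math.sin(ty)
    cz, sz = math.cos(tz), math.sin(tz)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _voxel_coords_nm(
    stack: ImageStack, lo: Sequence[int], hi: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical (x, y, z) center coordinates of every voxel in a zyx box."""
    dz, dy, dx = stack.pitch_nm
    z = (np.arange(lo[0], hi[0]) + 0.5) * dz
    y = (np.arange(lo[1], hi[1]) + 0.5) * dy
    x = (np.arange(lo[2], hi[2]) + 0.5) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    return xx.ravel(), yy.ravel(), zz.ravel()


def best_focus_plane(stack: ImageStack, box: ParticleBox) -> int:
    """Absolute z index of the plane maximizing in-plane integrated intensity.

    Ties break toward the lower index.
    """
    sl = box.buf_slices()
    sub = np.asarray(stack.channel(box.channel)[sl], dtype=float)
    sums = sub.sum(axis=(1, 2))
    return box.buf_lo[0] + int(np.argmax(sums))


def _gauss_model_3d(params, xx, yy, xc0, fit_theta, zz=None):
    if zz is None:  # 2D
        if fit_theta:
            cx, cy, sx, sy, tz, base, peak = params
        else:
            cx, cy, sx, sy, base, peak = params
            tz = 0.0
        c, s = math.cos(tz), math.sin(tz)
        u = (c * (xx - cx) + s * (yy - cy)) / sx
        v = (-s * (xx - cx) + c * (yy - cy)) / sy
        q = u * u + v * v
    else:
        if fit_theta:
            cx, cy, cz, sx, sy, sz_, tx, ty, tz = params[:9]
            base, peak = params[9:]
            rot = _rotation_matrix(tx, ty, tz)
        else:
            cx, cy, cz, sx, sy, sz_, base, peak = params
            rot = None
        dxv = xx - cx
        dyv = yy - cy
        dzv = zz - cz
        if rot is not None:
            dxv, dyv, dzv = (
                rot[0, 0] * dxv + rot[0, 1] * dyv + rot[0, 2] * dzv,
                rot[1, 0] * dxv + rot[1, 1] * dyv + rot[1, 2] * dzv,
                rot[2, 0] * dxv + rot[2, 1] * dyv + rot[2, 2] * dzv,
            )
        q = (dxv / sx) ** 2 + (dyv / sy) ** 2 + (dzv / sz_) ** 2
    return base + peak * np.exp(-0.5 * q)


def fit_gaussian(
    stack: ImageStack,
    box: ParticleBox,
    dims: int = 3,
    bg: BackgroundConfig | None = None,
    fit_theta: bool = False,
    max_restarts: int = 2,
) -> GaussianFit:
    """Least-squares Gaussian fit over the particle's buffered box.

    For ``dims=2`` on a 3D stack the fit runs on the best-focus plane.
    Initialization: center at the background-subtracted intensity centroid of
    the tight box, sigma at a quarter of the tight extent, base at the
    box-edge median, peak at max - base. The center is bounded inside the
    buffered box. Failure (degenerate data or no convergence after bounded
    jittered restarts) is reported via ``ok=False`` rather than an exception.
    """
    volume = np.asarray(stack.channel(box.channel), dtype=float)
    dz_pitch, dy_pitch, dx_pitch = stack.pitch_nm
    lo, hi = list(box.buf_lo), list(box.buf_hi)
    focus_z: int | None = None
    if dims == 2 and stack.is_3d:
        focus_z = best_focus_plane(stack, box)
        lo[0], hi[0] = focus_z, focus_z + 1
    elif dims == 2:
        focus_z = 0

    data = volume[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].ravel()
    xx, yy, zz = _voxel_coords_nm(stack, lo, hi)
    nparams = (7 if fit_theta else 6) if dims == 2 else (11 if fit_theta else 8)

    def _failed() -> GaussianFit:
        nanv = np.full(3, np.nan)
        return GaussianFit(
            center_nm=nanv.copy(), theta_rad=np.zeros(3), sigma_nm=nanv.copy(),
            base=float("nan"), peak=float("nan"), resnorm=float("nan"),
            dims=dims, box=box, focus_z=focus_z, ok=False,
        )

    if data.size < nparams + 5 or np.ptp(data) == 0:
        return _failed()

    # --- initialization from the tight box --------------------------------
    tlo, thi = list(box.tight_lo), list(box.tight_hi)
    if dims == 2 and stack.is_3d:
        tlo[0], thi[0] = lo[0], hi[0]
    tight = volume[tlo[0] : thi[0], tlo[1] : thi[1], tlo[2] : thi[2]]
    edge = np.concatenate([data[: max(1, data.size // 10)],
                           data[-max(1, data.size // 10):]])
    base0 = float(np.median(edge))
    w = np.clip(tight - base0, 0, None)
    if w.sum() <= 0:
        w = tight - tight.min() + 1e-12
    txx, tyy, tzz = _voxel_coords_nm(stack, tlo, thi)
    wflat = w.ravel()
    cx0 = float((txx * wflat).sum() / wflat.sum())
    cy0 = float((tyy * wflat).sum() / wflat.sum())
    cz0 = float((tzz * wflat).sum() / wflat.sum())
    ext = np.array(
        [(thi[2] - tlo[2]) * dx_pitch, (thi[1] - tlo[1]) * dy_pitch,
         (thi[0] - tlo[0]) * dz_pitch]
    )
    sx0, sy0, sz0 = (max(e / 4.0, p * 0.5) for e, p in
                     zip(ext, (dx_pitch, dy_pitch, dz_pitch)))
    peak0 = max(float(data.max() - base0), 1e-9)

    # --- bounds ------------------------------------------------------------
    xlo, xhi = lo[2] * dx_pitch, hi[2] * dx_pitch
    ylo, yhi = lo[1] * dy_pitch, hi[1] * dy_pitch
    zlo, zhi = lo[0] * dz_pitch, hi[0] * dz_pitch
    big = float(np.ptp(data)) * 10 + 1.0
    smax_xy = max((xhi - xlo), (yhi - ylo))
    smax_z = max(zhi - zlo, dz_pitch)
    if dims == 2:
        p0 = [cx0, cy0, sx0, sy0, base0, peak0]
        lb = [xlo, ylo, dx_pitch * 0.2, dy_pitch * 0.2, data.min() - big, 1e-12]
        ub = [xhi, yhi, smax_xy, smax_xy, data.max() + big, big]
        if fit_theta:
            p0.insert(4, 0.0); lb.insert(4, -math.pi); ub.insert(4, math.pi)
    else:
        p0 = [cx0, cy0, cz0, sx0, sy0, sz0, base0, peak0]
        lb = [xlo, ylo, zlo, dx_pitch * 0.2, dy_pitch * 0.2, dz_pitch * 0.2,
              data.min() - big, 1e-12]
        ub = [xhi, yhi, zhi, smax_xy, smax_xy, smax_z * 2, data.max() + big, big]
        if fit_theta:
            p0 = p0[:6] + [0.0, 0.0, 0.0] + p0[6:]
            lb = lb[:6] + [-math.pi] * 3 + lb[6:]
            ub = ub[:6] + [math.pi] * 3 + ub[6:]
    p0 = np.minimum(np.maximum(p0, lb), ub)

    zz_arg = None if dims == 2 else zz

    def resid(params):
        return _gauss_model_3d(params, xx, yy, None, fit_theta, zz_arg) - data

    rng = np.random.default_rng(0)
    result = None
    for attempt in range(max_restarts + 1):
        start = np.array(p0, dtype=float)
        if attempt > 0:
            jitter = rng.normal(0, 0.05, size=start.shape) * (np.array(ub) - np.array(lb))
            start = np.clip(start + jitter, lb, ub)
        try:
            res = least_squares(resid, start, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
        except Exception:
            continue
        if res.success and np.isfinite(res.cost):
            result = res
            break
        if result is None or (np.isfinite(res.cost) and res.cost < result.cost):
            result = res
    if result is None:
        return _failed()

    p = result.x
    if dims == 2:
        if fit_theta:
            cx, cy, sx, sy, tz, base, peak = p
        else:
            (cx, cy, sx, sy, base, peak), tz = p, 0.0
        center = np.array([cx, cy, np.nan])
        sigma = np.array([sx, sy, np.nan])
        theta = np.array([0.0, 0.0, tz])
        if focus_z is not None:
            center[2] = (focus_z + 0.5) * dz_pitch
    else:
        if fit_theta:
            cx, cy, cz, sx, sy, sz_, tx, ty, tz = p[:9]
            base, peak = p[9:]
            theta = np.array([tx, ty, tz])
        else:
            cx, cy, cz, sx, sy, sz_, base, peak = p
            theta = np.zeros(3)
        center = np.array([cx, cy, cz])
        sigma = np.array([sx, sy, sz_])
    # axisymmetric degeneracy: a near-circular lateral profile carries no
    # orientation information; report theta = 0
    if fit_theta and abs(sigma[0] - sigma[1]) < 1e-6 * max(sigma[0], sigma[1]):
        theta = np.zeros(3)
    peak = float(peak)
    if not np.isfinite(peak) or peak <= 0:
        return _failed()
    ssr = float(2 * result.cost)  # least_squares cost = 1/2 sum r^2
    resnorm = ssr / (data.size * peak**2)
    return GaussianFit(
        center_nm=center, theta_rad=theta, sigma_nm=sigma, base=float(base),
        peak=peak, resnorm=float(resnorm), dims=dims, box=box,
        focus_z=focus_z, ok=True,
    )


def _shell_pad(extent: np.ndarray, p: float, single_plane: bool) -> np.ndarray:
    pad = np.maximum(1, np.round(p * extent / 2.0).astype(int))
    if single_plane:
        pad[0] = 0
    return pad


def local_background(
    stack: ImageStack,
    box: ParticleBox,
    all_boxes: Sequence[ParticleBox],
    bg: BackgroundConfig,
) -> tuple[float | None, bool]:
    """Median (or mean) intensity of the background shell around a particle.

    The shell is the buffered box enlarged by ``(1 + p)`` per dimension,
    minus the box itself and minus any voxel inside another particle's
    buffered box (exception handling for close neighbors). Returns
    ``(value, True)`` or ``(None, False)`` when the shell is empty — the
    caller then falls back to the fitted Gaussian base.
    """
    if not bg.enabled:
        raise ValueError("local_background called with bg.enabled=False")
    volume = np.asarray(stack.channel(box.channel), dtype=float)
    shape = np.array(volume.shape)
    lo = np.array(box.buf_lo)
    hi = np.array(box.buf_hi)
    pad = _shell_pad(hi - lo, bg.bg_buffer_p, volume.shape[0] == 1)
    elo = np.maximum(lo - pad, 0)
    ehi = np.minimum(hi + pad, shape)
    mask = np.ones(tuple(ehi - elo), dtype=bool)
    # carve out this particle's own box
    inner = tuple(slice(l - el, h - el) for l, h, el in zip(lo, hi, elo))
    mask[inner] = False
    # carve out every other particle's buffered box
    for other in all_boxes:
        if other is box or other.channel != box.channel:
            continue
        olo = np.maximum(np.array(other.buf_lo), elo)
        ohi = np.minimum(np.array(other.buf_hi), ehi)
        if np.all(olo < ohi):
            sl = tuple(slice(a - el, b - el) for a, b, el in zip(olo, ohi, elo))
            mask[sl] = False
    shell = volume[tuple(slice(a, b) for a, b in zip(elo, ehi))][mask]
    if shell.size == 0:
        return None, False
    value = float(np.median(shell) if bg.estimator == "median" else np.mean(shell))
    return value, True


def measure_intensities(
    stack: ImageStack,
    box: ParticleBox,
    fitres: GaussianFit,
    bg: BackgroundConfig | None = None,
    all_boxes: Sequence[ParticleBox] = (),
) -> dict:
    """Integrated and maximum signal intensity for one fitted particle.

    ``max`` is the largest raw voxel in the tight box. ``integrated`` sums the
    buffered box and subtracts ``N * B`` where ``B`` is the local-background
    shell estimate when enabled (falling back to the fitted base when the
    shell is empty), or 0 in uncorrected mode.
    """
    volume = np.asarray(stack.channel(box.channel), dtype=float)
    max_int = float(volume[box.tight_slices()].max())
    sub = volume[box.buf_slices()]
    n = sub.size
    bg_used = 0.0
    bg_fallback = False
    if bg is not None and bg.enabled:
        value, valid = local_background(stack, box, all_boxes, bg)
        if valid:
            bg_used = value
        else:
            bg_used = fitres.base
            bg_fallback = True
    integrated = float(sub.sum() - n * bg_used)
    return {
        "integrated": integrated,
        "max": max_int,
        "background_used": bg_used,
        "background_fallback": bg_fallback,
    }
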