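"""Image-side morphometry: dF/F0 hotspots, 2D Gaussian fits, 3D profiles.

Quantifies fluorescence hotspots (Ca2+-influx sites, channel clusters) by
rotated 2D Gaussian fitting — reporting center, FWHM along the short and
long principal axes, rotation and integral — and measures structure
lengths in image stacks by interpolated 3D line profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import differential_evolution, least_squares

__all__ = [
    "HotspotImage",
    "Gaussian2DFit",
    "LineProfile3D",
    "FitFailureError",
    "MeasurementError",
    "compute_dff",
    "fit_gaussian_2d",
    "line_profile_fwhm",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class FitFailureError(RuntimeError):
    """Hotspot fit did not converge or the image lacks a usable peak."""


class MeasurementError(RuntimeError):
    """Profile does not support a FWHM measurement."""


@dataclass
class HotspotImage:
    """A 2D frame (counts) with its pixel size in nm."""

    pixels: np.ndarray
    pixel_nm: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be > 0")
        if not np.isfinite(self.pixels).all():
            raise ValueError("image contains non-finite values")


@dataclass
class Gaussian2DFit:
    """Rotated 2D Gaussian parameters in physical units.

    ``angle_deg`` is measured from the image x-axis to the long axis, in
    [0, 180).  ``integral`` is amplitude * 2*pi*sigma_x*sigma_y (counts).
    """

    center_nm: tuple[float, float]
    fwhm_short_nm: float
    fwhm_long_nm: float
    angle_deg: float
    amplitude: float
    offset: float
    integral: float


def compute_dff(
    frames: np.ndarray,
    depol_frames: list[int],
    background_frames: list[int],
    center: tuple[int, int],
) -> tuple[float, np.ndarray]:
    """dF/F0 of a hotspot and the background-subtracted hotspot image.

    F0 is the mean of the background frames; the hotspot value averages
    the central pixel and its eight neighbors of the (depolarized minus
    F0) image, divided by the same 3x3 average of F0.
    """
    frames = np.asarray(frames, dtype=float)
    dset, bset = set(depol_frames), set(background_frames)
    if dset & bset:
        raise ValueError("depolarization and background frames overlap")
    if max(dset | bset) >= frames.shape[0]:
        raise ValueError("frame index out of range")
    f0 = frames[sorted(bset)].mean(axis=0)
    depol = frames[sorted(dset)].mean(axis=0)
    diff = depol - f0
    r, c = center
    if not (1 <= r < frames.shape[1] - 1 and 1 <= c < frames.shape[2] - 1):
        raise ValueError("center must have a full 3x3 neighborhood")
    patch = np.s_[r - 1:r + 2, c - 1:c + 2]
    f0_patch = f0[patch].mean()
    if f0_patch <= 0:
        raise ValueError("non-positive background in the 3x3 patch")
    return float(diff[patch].mean() / f0_patch), diff


def _gauss2d(params, xx, yy):
    x0, y0, sx, sy, theta, amp, off = params
    ct, st = math.cos(theta), math.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    return off + amp * np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sy) ** 2))


def fit_gaussian_2d(
    img: HotspotImage,
    seed: int = 0,
    global_stage: bool = True,
) -> Gaussian2DFit:
    """Fit a rotated 2D Gaussian plus offset to a hotspot image.

    A seeded differential-evolution global stage (standing in for the
    genetic optimizers traditionally used on such data) is refined by
    local least squares.  Axes are sorted so short <= long and converted
    to FWHM in nm.
    """
    z = img.pixels
    ny, nx = z.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    zmin, zmax = float(z.min()), float(z.max())
    if zmax - zmin <= 0 or not _has_dominant_peak(z):
        raise FitFailureError("image lacks a dominant peak above the offset")

    def cost(p):
        return float(((z - _gauss2d(p, xx, yy)) ** 2).sum())

    peak = np.unravel_index(int(np.argmax(z)), z.shape)
    bounds = [
        (0.0, nx - 1.0), (0.0, ny - 1.0),
        (0.3, max(nx, ny)), (0.3, max(nx, ny)),
        (0.0, math.pi),
        (1e-9 * (zmax - zmin), 2.0 * (zmax - zmin)),
        (zmin - 0.5 * (zmax - zmin), zmax),
    ]
    x0 = np.array([peak[1], peak[0], max(nx / 8, 1), max(ny / 8, 1), 0.0,
                   zmax - zmin, zmin])
    if global_stage:
        de = differential_evolution(
            cost, bounds, seed=seed, init="sobol", maxiter=60, tol=1e-8,
            popsize=12, polish=False, x0=x0)
        x0 = de.x
    res = least_squares(
        lambda p: (z - _gauss2d(p, xx, yy)).ravel(), x0,
        bounds=tuple(zip(*bounds)))
    if not res.success:
        raise FitFailureError(f"local refinement failed: {res.message}")
    x0c, y0c, sx, sy, theta, amp, off = res.x
    if not (0 < x0c < nx - 1 and 0 < y0c < ny - 1):
        raise FitFailureError("fitted peak lies on the image border")
    # sort axes, fold angle onto the long axis in [0, 180)
    if sx >= sy:
        s_long, s_short, ang = sx, sy, theta
    else:
        s_long, s_short, ang = sy, sx, theta + math.pi / 2
    ang = math.degrees(ang % math.pi)
    px = img.pixel_nm
    return Gaussian2DFit(
        center_nm=(float(x0c * px), float(y0c * px)),
        fwhm_short_nm=float(s_short * FWHM_PER_SIGMA * px),
        fwhm_long_nm=float(s_long * FWHM_PER_SIGMA * px),
        angle_deg=float(ang),
        amplitude=float(amp),
        offset=float(off),
        integral=float(amp * 2 * math.pi * sx * sy),
    )


def _has_dominant_peak(z: np.ndarray) -> bool:
    spread = z.max() - z.min()
    if spread <= 0:
        return False
    # demand clear contrast against the background level (median)
    return (z.max() - np.median(z)) > 0.2 * spread


@dataclass
class LineProfile3D:
    """Intensity profile along a 3D segment, with its FWHM."""

    positions_nm: np.ndarray
    intensities: np.ndarray
    fwhm_nm: float


def line_profile_fwhm(
    stack: np.ndarray,
    p0: tuple[float, float, float],
    p1: tuple[float, float, float],
    voxel_nm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_samples: int = 64,
) -> LineProfile3D:
    """FWHM along an arbitrary 3D segment through an image stack.

    Intensities are trilinearly interpolated at ``n_samples`` (>= 16)
    points; the baseline is the minimum of the profile's two end values,
    and the half-max crossings are located by linear interpolation.
    Endpoints are in voxel coordinates (axis order matching the stack).
    """
    stack = np.asarray(stack, dtype=float)
    if n_samples < 16:
        raise ValueError("need at least 16 samples")
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    for p in (p0, p1):
        if (p < 0).any() or (p > np.array(stack.shape) - 1).any():
            raise ValueError("segment endpoint outside the stack")
    ts = np.linspace(0.0, 1.0, n_samples)
    coords = p0[:, None] + (p1 - p0)[:, None] * ts[None, :]
    prof = map_coordinates(stack, coords, order=1, mode="nearest")
    seg_nm = np.linalg.norm((p1 - p0) * np.asarray(voxel_nm))
    pos = ts * seg_nm

    i_max = int(np.argmax(prof))
    if i_max in (0, n_samples - 1):
        raise MeasurementError("profile peak at segment end")
    base = min(prof[0], prof[-1])
    half = base + 0.5 * (prof[i_max] - base)
    left = right = None
    for i in range(i_max, 0, -1):
        if prof[i - 1] < half <= prof[i]:
            f = (prof[i] - half) / (prof[i] - prof[i - 1])
            left = pos[i] - f * (pos[i] - pos[i - 1])
            break
    for i in range(i_max, n_samples - 1):
        if prof[i + 1] < half <= prof[i]:
            f = (prof[i] - half) / (prof[i] - prof[i + 1])
            right = pos[i] + f * (pos[i + 1] - pos[i])
            break
    if left is None or right is None:
        raise MeasurementError("profile lacks two half-maximum crossings")
    return LineProfile3D(positions_nm=pos, intensities=prof,
                         fwhm_nm=float(right - left))
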