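"""Weighted back projection, Fourier shell correlation and resolution readout.

Reconstruction uses the classical weighted back projection: each image is
ramp-filtered (|s| weighting in 2D Fourier space, capped at Nyquist) and
smeared back along its viewing axis with the adjoint of the projection
operator.  Resolution is read off the FSC curve at a threshold crossing
(0.5 throughout the package, map-versus-ground-truth convention), linearly
interpolated in frequency between shells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from . import _kernels
from .errors import InvalidParameterError, ShapeMismatchError
from .geometry import OrientationParams, euler_matrix
from .volume_ops import DensityVolume, ModuleMask, _vol_grid


@dataclass
class FSCCurve:
    """Per-shell correlation between the Fourier transforms of two volumes."""

    shell_freq: np.ndarray  # cycles/A
    correlation: np.ndarray


class ResolutionResult(NamedTuple):
    resolution: float  # Angstrom
    crossed: bool  # False when the curve never falls below the threshold


def _ramp_filter(n: int) -> np.ndarray:
    f = np.fft.fftfreq(n)
    w = np.hypot(f[:, None], f[None, :])
    return np.minimum(w, 0.5)


def wbp_reconstruct(images, params: Sequence[OrientationParams] | None = None,
                    pixel_size: float = 1.0) -> DensityVolume:
    """Weighted back projection of aligned particle images.

    ``images`` may be a ParticleStack (its records' current parameters are
    used unless ``params`` is given) or an (n, N, N) array.  The output is
    normalized by the particle count, so reconstruction is linear in the
    stack up to that convention.
    """
    if hasattr(images, "images"):  # ParticleStack
        stack = images
        arr = np.asarray(stack.images, dtype=np.float64)
        pixel_size = stack.pixel_size
        if params is None:
            params = stack.params_list()
    else:
        arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if params is None:
        raise InvalidParameterError("params are required for a bare image array")
    if len(params) != arr.shape[0]:
        raise InvalidParameterError("one parameter set per image is required")
    if arr.shape[0] == 0:
        raise InvalidParameterError("empty stack")
    n = arr.shape[1]
    ramp = _ramp_filter(n)
    out = np.zeros((n, n, n), dtype=np.float64)
    for img, prm in zip(arr, params):
        p = OrientationParams(*prm)
        filtered = np.fft.ifft2(np.fft.fft2(img) * ramp).real
        R = np.ascontiguousarray(euler_matrix(p.phi, p.theta, p.psi))
        _kernels.backproject3d(out, filtered, R, float(p.x), float(p.y))
    out /= arr.shape[0]
    return DensityVolume(out, pixel_size)


def fsc(vol1, vol2, shell_width: int = 1) -> FSCCurve:
    """Fourier shell correlation, shells of integer Fourier-voxel radius."""
    g1, g2 = _vol_grid(vol1), _vol_grid(vol2)
    if g1.shape != g2.shape:
        raise ShapeMismatchError("volume shapes differ")
    apix1 = getattr(vol1, "pixel_size", 1.0)
    apix2 = getattr(vol2, "pixel_size", apix1)
    if abs(apix1 - apix2) > 1e-9:
        raise InvalidParameterError("pixel sizes differ")
    n = g1.shape[0]
    f1 = np.fft.fftn(g1)
    f2 = np.fft.fftn(g2)
    k = np.fft.fftfreq(n) * n
    r = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2)
    shells = np.round(r / shell_width).astype(np.int64).ravel()
    nsh = n // 2 // shell_width + 1
    sel = shells < nsh
    shells = shells[sel]
    num = np.bincount(shells, weights=(f1 * np.conj(f2)).real.ravel()[sel], minlength=nsh)
    p1 = np.bincount(shells, weights=(np.abs(f1) ** 2).ravel()[sel], minlength=nsh)
    p2 = np.bincount(shells, weights=(np.abs(f2) ** 2).ravel()[sel], minlength=nsh)
    denom = np.sqrt(p1 * p2)
    corr = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    freq = np.arange(nsh) * shell_width / (n * apix1)
    return FSCCurve(shell_freq=freq, correlation=np.clip(corr, -1.0, 1.0))


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.5,
                            pixel_size: float | None = None) -> ResolutionResult:
    """Resolution (Å) at the first crossing below the threshold.

    Linearly interpolated in frequency between the adjacent shells; when the
    curve never crosses, Nyquist (2 x pixel size) is returned with
    ``crossed=False``.
    """
    c = np.asarray(curve.correlation, dtype=float)
    f = np.asarray(curve.shell_freq, dtype=float)
    if c.size == 0:
        raise InvalidParameterError("empty FSC curve")
    for i in range(1, c.size):
        if c[i] < threshold:
            if c[i - 1] <= threshold:
                fx = f[i - 1] if f[i - 1] > 0 else f[i]
            else:
                frac = (c[i - 1] - threshold) / (c[i - 1] - c[i])
                fx = f[i - 1] + frac * (f[i] - f[i - 1])
            return ResolutionResult(1.0 / fx, True)
    if pixel_size is None:
        # infer Nyquist from the last shell frequency
        pixel_size = 1.0 / (2.0 * f[-1]) if f[-1] > 0 else 1.0
    return ResolutionResult(2.0 * pixel_size, False)


def lowpass_filter(vol, resolution_A: float, soft_edge: float = 2.0) -> DensityVolume:
    """Fourier low-pass with a cosine edge ending at the cutoff; DC preserved.

    ``soft_edge`` is the taper width in Fourier voxels (0 for a hard edge).
    The cutoff must not exceed Nyquist (resolution >= 2 x pixel size).
    """
    g = _vol_grid(vol)
    apix = getattr(vol, "pixel_size", 1.0)
    n = g.shape[0]
    if resolution_A < 2.0 * apix - 1e-9:
        raise InvalidParameterError("cutoff beyond Nyquist")
    rc = n * apix / resolution_A  # cutoff radius in Fourier voxels
    if soft_edge <= 0 and rc >= n / 2.0:
        # a hard cutoff at (or beyond) Nyquist keeps every sample, including
        # the Cartesian corners beyond the radial Nyquist sphere
        return DensityVolume(g.copy(), apix)
    k = np.fft.fftfreq(n) * n
    r = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2)
    if soft_edge > 0:
        w = 0.5 * (1.0 + np.cos(np.pi * (r - (rc - soft_edge)) / soft_edge))
        w[r <= rc - soft_edge] = 1.0
        w[r >= rc] = 0.0
    else:
        w = (r <= rc).astype(np.float64)
    w.flat[0] = 1.0  # DC
    out = np.fft.ifftn(np.fft.fftn(g) * w).real
    return DensityVolume(out, apix)


def soft_shape_mask(mask: ModuleMask, edge_width: float) -> ModuleMask:
    """Cosine-tapered dilation of a binary module mask (for FSC segmentation).

    Weights fall from 1 at the binary boundary to 0 at ``edge_width`` voxels
    outside it, monotonically along any outward ray.
    """
    if mask.kind != "binary":
        raise InvalidParameterError("soft_shape_mask expects a binary input mask")
    g = mask.grid > 0.5
    if edge_width <= 0:
        return ModuleMask(g.astype(np.float64), "binary")
    if g.all():
        return ModuleMask(np.ones_like(mask.grid), "soft")
    dist = ndimage.distance_transform_edt(~g)
    w = np.where(g, 1.0, np.where(dist <= edge_width,
                                  0.5 * (1.0 + np.cos(np.pi * dist / edge_width)), 0.0))
    return ModuleMask(w, "soft")
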