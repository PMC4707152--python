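"""Cross-correlation objective and its numerator decomposition.

The alignment objective is the normalized cross-correlation coefficient

    rho_12 = sum[(f1 - <f1>)(f2 - <f2>)] / sqrt(sum[(f1 - <f1>)^2] sum[(f2 - <f2>)^2])

optionally restricted to a 2D mask around the target module.  Soft mask
weights enter as frequency weights in the weighted means and covariances
(never as a pre-multiplication of the images), so the score stays invariant
to positive affine rescaling of either image; binary masks reduce to pixel
selection.  All accumulations are double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateImageError, InvalidParameterError, ShapeMismatchError
from .volume_ops import Image2D, _img_grid, subtract_nontarget


@dataclass
class Mask2D:
    """2D weights in [0, 1]; build circular masks with :meth:`circular`."""

    weights: np.ndarray
    descriptor: str = "arbitrary"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.min() < 0 or w.max() > 1.0 + 1e-12:
            raise InvalidParameterError("mask weights must lie in [0, 1]")
        if not (w > 0).any():
            raise InvalidParameterError("mask must have at least one positive weight")
        self.weights = np.clip(w, 0.0, 1.0)

    @classmethod
    def circular(cls, n: int, diameter: float, center: tuple[float, float] | None = None):
        """Round binary mask of the given pixel diameter (the usual
        target-module mask), centered on the box centre by default."""
        cy, cx = center if center is not None else (n // 2, n // 2)
        yy, xx = np.mgrid[0:n, 0:n]
        w = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (diameter / 2.0) ** 2
        return cls(w.astype(np.float64), descriptor=f"circular(d={diameter})")


def _weights(mask, shape) -> np.ndarray | None:
    if mask is None:
        return None
    w = mask.weights if isinstance(mask, Mask2D) else np.asarray(mask, dtype=np.float64)
    if w.shape != shape:
        raise ShapeMismatchError("mask shape differs from image shape")
    return w


def ccc(img1, img2, mask=None) -> float:
    """Masked cross-correlation coefficient in [-1, 1].

    Raises :class:`DegenerateImageError` when either image has zero variance
    under the mask (a silent 0 could corrupt an argmax search).
    """
    a = _img_grid(img1).astype(np.float64, copy=False)
    b = _img_grid(img2).astype(np.float64, copy=False)
    if a.shape != b.shape:
        raise ShapeMismatchError("image shapes differ")
    w = _weights(mask, a.shape)
    if w is None:
        wa, wb = a.ravel(), b.ravel()
        wsum = float(a.size)
        ma, mb = wa.mean(), wb.mean()
        da, db = wa - ma, wb - mb
        va = float(np.dot(da, da))
        vb = float(np.dot(db, db))
        num = float(np.dot(da, db))
    else:
        if np.count_nonzero(w) < 2:
            raise InvalidParameterError("mask must select at least 2 pixels")
        wf = w.ravel()
        wsum = float(wf.sum())
        ma = float(np.dot(wf, a.ravel())) / wsum
        mb = float(np.dot(wf, b.ravel())) / wsum
        da, db = a.ravel() - ma, b.ravel() - mb
        va = float(np.dot(wf, da * da))
        vb = float(np.dot(wf, db * db))
        num = float(np.dot(wf * da, db))
    scale = max(float(np.abs(a).max()), 1.0) * max(float(np.abs(b).max()), 1.0)
    if va <= 0.0 or vb <= 0.0 or va < 1e-30 * scale or vb < 1e-30 * scale:
        raise DegenerateImageError("zero variance under the mask; CCC undefined")
    return num / np.sqrt(va * vb)


def ccc_numerator_terms(f1a, f1b, f2a, f2b) -> tuple[float, float, float, float]:
    """The four cross terms of the CCC numerator for two-component images.

    Each term is the unnormalized covariance of one experimental component
    against one simulated component, centred on that component's own mean:
    (experimental A x simulated A, experimental A x simulated B,
    experimental B x simulated B, experimental B x simulated A).  Their sum
    equals the numerator of ccc(f1a + f1b, f2a + f2b) computed with
    component-mean centering.  Diagnostic only: the first term is the one the
    module-wise search maximizes, and the last is the interference term that
    an appropriate target mask suppresses.
    """
    g = [_img_grid(x).astype(np.float64, copy=False) for x in (f1a, f1b, f2a, f2b)]
    if len({x.shape for x in g}) != 1:
        raise ShapeMismatchError("all four images must share one shape")
    d = [x - x.mean() for x in g]
    t_aa = float((d[0] * d[2]).sum())
    t_ab = float((d[0] * d[3]).sum())
    t_bb = float((d[1] * d[3]).sum())
    t_ba = float((d[1] * d[2]).sum())
    return t_aa, t_ab, t_bb, t_ba


def ccc_target(exp_img, nontarget_sim, target_sim, mask=None,
               k_mode: str = "least_squares", support=None) -> float:
    """CCC against the target module only, after scaled subtraction of the
    simulated non-target signal from the experimental image.

    A zero non-target projection degenerates to the plain masked CCC.
    """
    s = _img_grid(nontarget_sim)
    if not np.any(s):
        return ccc(exp_img, target_sim, mask)
    residual, _ = subtract_nontarget(exp_img, nontarget_sim, k_mode=k_mode, support=support)
    return ccc(residual, target_sim, mask)
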