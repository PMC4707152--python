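"""Local-optimization (LO) refinement of per-particle module parameters.

Each particle's five projection parameters (phi, theta, psi, x, y) for one
rigid module are re-optimized inside a small neighbourhood of their
preliminary values: projection directions within a cone of ``alpha0``
degrees drawn from a global quasi-uniform set, in-plane angles on a
parallel-transported grid of step ``d1``, and shifts on a grid of step
``d2``.  The objective is the masked cross-correlation coefficient between
the experimental image and a composite simulated projection — the target
module at the candidate parameters plus the remainder of the model frozen at
the preliminary parameters.

Two search strategies are provided: ``simultaneous`` exhausts the full
angles x shifts grid; ``separate`` first optimizes shifts on a small random
subset of the angle grid, averages the optimal shifts (sub-pixel), and then
exhausts the angle grid at that fixed shift — far fewer grid evaluations for
the same sampling extents.

The hot path shares one batch of simulated projections per particle: one
Fourier-slice projection per candidate direction (at the transported central
in-plane angle), in-plane rotations for the remaining psi samples, and
integer-pixel shifts realized by rolling the experimental-side mask sums, so
CCC values over the whole grid come from a handful of matrix products.  All
score accumulations are double precision.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .errors import (
    DegenerateImageError,
    InvalidParameterError,
    RefinementFailedError,
    ShapeMismatchError,
)
from .geometry import (
    OrientationParams,
    SearchRange,
    constrain_directions,
    generate_direction_set,
    span_angle,
    span_angles_to,
    transported_psi,
)
from .particles import ParticleRecord, ParticleStack
from .reconstruct import wbp_reconstruct
from .scoring import Mask2D
from .volume_ops import (
    DensityVolume,
    FourierProjector,
    _img_grid,
    _vol_grid,
    ctf_evaluate,
    ctf_grid,
    project,
    recenter_model,
    split_volume,
    subtract_nontarget,
    transform_particle_params,
    translate_volume,
)

_DEGENERATE = -2.0  # sentinel below any true CCC


def default_search_range(alpha0: float = 10.0, d1: float = 2.0, t1: int = 3,
                         d2: float = 1.0, t2: int = 4,
                         direction_spacing: float | None = None) -> SearchRange:
    """The default local search: 10-degree cone, 2-degree angular step with a
    +/- 3-step in-plane extent, 1-pixel shift step over -4..4 pixels."""
    directions = generate_direction_set(direction_spacing if direction_spacing else d1)
    return SearchRange(alpha0, d1, t1, d2, t2, directions)


@dataclass
class RefinementConfig:
    """Settings of one LO-refinement pass."""

    search: SearchRange = field(default_factory=default_search_range)
    strategy: str = "separate"  # or "simultaneous"
    n_trial_angles: int = 10
    mask_diameter: float | None = 36.0  # pixels; None disables masking
    k_mode: str = "none"  # "none": composite projection; else subtract k x remainder
    k_value: float | None = None
    rng_seed: int = 0
    use_fourier_projector: bool = True
    lowpass_A: float | None = 16.0  # scoring band limit (Angstrom); None disables

    def __post_init__(self):
        if self.strategy not in ("simultaneous", "separate"):
            raise InvalidParameterError(f"unknown strategy {self.strategy!r}")
        if self.n_trial_angles < 1:
            raise InvalidParameterError("n_trial_angles must be >= 1")
        if self.k_mode not in ("none", "least_squares", "fixed"):
            raise InvalidParameterError(f"unknown k_mode {self.k_mode!r}")
        if int(self.rng_seed) < 0:
            raise InvalidParameterError("rng_seed must be non-negative")


def predicted_grid_evaluations(n_grid_angles: int, n_shifts: int, strategy: str,
                               n_trial_angles: int = 10) -> int:
    """Grid-evaluation count of each strategy for given grid sizes.

    ``simultaneous`` scores every angle at every shift; ``separate`` scores
    the shift grid only on the random angle subset and then each angle once
    (plus one guard evaluation at the preliminary parameters).
    """
    if strategy == "simultaneous":
        return n_grid_angles * n_shifts
    if strategy == "separate":
        return min(n_trial_angles, n_grid_angles) * n_shifts + n_grid_angles + 1
    raise InvalidParameterError(f"unknown strategy {strategy!r}")


class _RealSpaceProjector:
    """Reference projection backend: real-space trilinear rotation per image."""

    def __init__(self, vol):
        self.vol = DensityVolume(_vol_grid(vol).copy(),
                                 getattr(vol, "pixel_size", 1.0))
        self.n = self.vol.grid.shape[0]
        self.pixel_size = self.vol.pixel_size

    def project_many(self, params_list) -> np.ndarray:
        return np.stack([project(self.vol, p).grid for p in params_list])


def _as_projector(obj, use_fourier: bool = True):
    if hasattr(obj, "project_many"):
        return obj
    # pad 3 keeps central-slice interpolation error well below the CCC
    # contrast between neighbouring grid orientations
    return FourierProjector(obj, pad=3) if use_fourier else _RealSpaceProjector(obj)


def _ctf_filter(imgs: np.ndarray, tf: np.ndarray) -> np.ndarray:
    """Apply a Fourier multiplier to a stack (or single) of real images."""
    return np.fft.ifft2(np.fft.fft2(imgs, axes=(-2, -1)) * tf, axes=(-2, -1)).real


def _lowpass_tf(n: int, pixel_size: float, resolution_A: float) -> np.ndarray:
    """2D radial low-pass multiplier, cosine edge two Fourier voxels wide."""
    if resolution_A < 2.0 * pixel_size - 1e-9:
        raise InvalidParameterError("scoring band limit beyond Nyquist")
    k = np.fft.fftfreq(n) * n
    r = np.hypot(k[:, None], k[None, :])
    rc = n * pixel_size / resolution_A
    edge = 2.0
    w = 0.5 * (1.0 + np.cos(np.pi * (r - (rc - edge)) / edge))
    w[r <= rc - edge] = 1.0
    w[r >= rc] = 0.0
    return w


class _ParticleScorer:
    """Masked-CCC evaluation over the local candidate grid of one particle.

    Candidate simulated projections are the target module at the candidate
    parameters plus the remainder frozen at the preliminary parameters;
    integer shift steps are realized by rolling the experimental-side sums,
    fractional parts by resampling the target projections, so the whole
    grid reduces to matrix products over precomputed sufficient statistics.
    """

    def __init__(self, exp_img, target_proj, remainder_proj,
                 center: OrientationParams, prelim: OrientationParams,
                 search: SearchRange, mask: np.ndarray | None,
                 ctf_tf: np.ndarray | None = None,
                 k_mode: str = "none", k_value: float | None = None):
        self.exp = _img_grid(exp_img).astype(np.float64, copy=False)
        self.n = self.exp.shape[0]
        if self.exp.shape != (self.n, self.n):
            raise ShapeMismatchError("experimental image must be square")
        self.center = OrientationParams(*center)
        self.prelim = OrientationParams(*prelim)
        self.search = search
        self.nevals = 0

        # ---- angle grid: constrained directions x transported psi steps ----
        dirs = constrain_directions(search.directions, self.center.direction,
                                    search.alpha0)
        self.dirs = dirs
        nd = len(dirs)
        n1 = 2 * search.t1 + 1
        spans = span_angles_to(dirs, self.center.direction)
        psi_c = np.empty(nd)
        idx0 = -1
        for i, (phi_i, theta_i) in enumerate(dirs):
            if phi_i == self.center.phi and theta_i == self.center.theta:
                psi_c[i] = self.center.psi  # keep the preliminary point exact
                idx0 = i
            else:
                psi_c[i] = transported_psi(self.center.direction, self.center.psi,
                                           (phi_i, theta_i))
        if idx0 < 0:  # pragma: no cover - constrain_directions guarantees inclusion
            raise InvalidParameterError("preliminary direction missing from grid")
        dpsi = search.d1 * np.arange(-search.t1, search.t1 + 1)
        self.na = nd * n1
        self.ang_dir = np.repeat(np.arange(nd), n1).astype(np.int64)
        self.ang_dpsi = np.tile(dpsi, nd)
        self.ang_psi = psi_c[self.ang_dir] + self.ang_dpsi
        self.ang_span = spans[self.ang_dir]
        self.prelim_angle = idx0 * n1 + search.t1

        # ---- shift grid -----------------------------------------------------
        steps = np.arange(-search.t2, search.t2 + 1)
        jx, jy = np.meshgrid(steps, steps, indexing="ij")
        self.off_x = (search.d2 * jx).ravel()
        self.off_y = (search.d2 * jy).ravel()
        self.ns = self.off_x.size
        self.shift_mag = np.hypot(self.off_x, self.off_y)
        self.prelim_shift = int(np.flatnonzero((jx.ravel() == 0) & (jy.ravel() == 0))[0])

        # ---- base projections (one per direction, transported psi) ---------
        base_params = [OrientationParams(phi_i, theta_i, pc)
                       for (phi_i, theta_i), pc in zip(dirs, psi_c)]
        bases = np.ascontiguousarray(target_proj.project_many(base_params))
        if ctf_tf is not None:
            # the CTF model has no astigmatism, so modulation commutes with
            # the in-plane rotations and integer shifts applied later
            bases = np.ascontiguousarray(_ctf_filter(bases, ctf_tf))
        self.bases = bases
        self._deltas = np.radians(self.ang_dpsi)

        # ---- remainder at the preliminary parameters ------------------------
        if remainder_proj is not None:
            rm = remainder_proj.project_many([self.prelim])[0]
            if ctf_tf is not None:
                rm = _ctf_filter(rm, ctf_tf)
            if not np.any(rm):
                rm = None
        else:
            rm = None
        if rm is not None and k_mode != "none":
            sup = None if mask is None else mask > 0
            res, _ = subtract_nontarget(self.exp, rm, k_mode=k_mode, k=k_value,
                                        support=sup)
            self.exp = _img_grid(res)
            rm = None
        self.rm = rm

        # ---- sufficient statistics of the experimental side -----------------
        w = np.ones_like(self.exp) if mask is None else np.asarray(mask, np.float64)
        if w.shape != self.exp.shape:
            raise ShapeMismatchError("mask shape differs from image shape")
        self.w = w
        self.W = float(w.sum())
        self.we = w * self.exp
        self.Se = float(self.we.sum())
        self.See = float((self.we * self.exp).sum())
        self.varE = self.See - self.Se * self.Se / self.W
        escale = max(float(np.abs(self.exp).max()), 1.0) ** 2
        if self.varE <= 1e-30 * escale:
            raise DegenerateImageError("experimental image constant under the mask")
        if rm is not None:
            self.wr = w * rm
            self.Sr = float(self.wr.sum())
            self.Srr = float((self.wr * rm).sum())
            self.Ser = float((self.wr * self.exp).sum())
        else:
            self.wr = None
            self.Sr = self.Srr = self.Ser = 0.0

        # ---- fast integer-step path ----------------------------------------
        d2r = round(search.d2)
        self._int_d2 = abs(search.d2 - d2r) < 1e-9 and d2r >= 1
        if self._int_d2:
            x0i = int(round(self.center.x))
            y0i = int(round(self.center.y))
            self._fx = self.center.x - x0i
            self._fy = self.center.y - y0i
            npx = self.n * self.n
            rx = (x0i + self.off_x.astype(int))
            ry = (y0i + self.off_y.astype(int))
            self._Mst = np.empty((npx, self.ns))
            self._MEst = np.empty((npx, self.ns))
            self._MRst = np.empty((npx, self.ns)) if rm is not None else None
            for s in range(self.ns):
                sh = (-int(ry[s]), -int(rx[s]))
                self._Mst[:, s] = np.roll(w, sh, axis=(0, 1)).ravel()
                self._MEst[:, s] = np.roll(self.we, sh, axis=(0, 1)).ravel()
                if rm is not None:
                    self._MRst[:, s] = np.roll(self.wr, sh, axis=(0, 1)).ravel()
            self._T = None  # built lazily

    # -- candidate target images -------------------------------------------
    def _target_images(self, angle_sel: np.ndarray, fx: float, fy: float) -> np.ndarray:
        imgs = _kernels.rotate_shift2d_batch(
            self.bases, self.ang_dir[angle_sel],
            np.ascontiguousarray(self._deltas[angle_sel]), float(fx), float(fy))
        return imgs.reshape(len(angle_sel), -1)

    def _full_T(self) -> np.ndarray:
        if self._T is None:
            self._T = self._target_images(np.arange(self.na), self._fx, self._fy)
        return self._T

    # -- CCC from sufficient statistics -------------------------------------
    def _ccc(self, T: np.ndarray, Mst, MEst, MRst) -> np.ndarray:
        S1 = T @ Mst + self.Sr
        S12 = T @ MEst + self.Ser
        S2 = (T * T) @ Mst + self.Srr
        if MRst is not None:
            S2 += 2.0 * (T @ MRst)
        num = S12 - self.Se * S1 / self.W
        var_s = S2 - S1 * S1 / self.W
        tscale = max(float(np.abs(T).max()), 1.0) ** 2
        good = var_s > 1e-30 * max(tscale, 1.0)
        out = np.full(num.shape, _DEGENERATE)
        np.divide(num, np.sqrt(var_s * self.varE, where=good, out=np.ones_like(var_s)),
                  out=out, where=good)
        self.nevals += num.size
        return out

    def score_grid(self, angle_sel=None) -> np.ndarray:
        """CCC of every (angle, shift) candidate; shape (n_angles, n_shifts)."""
        if angle_sel is None:
            angle_sel = np.arange(self.na)
        angle_sel = np.asarray(angle_sel, dtype=np.int64)
        if self._int_d2:
            T = (self._full_T() if len(angle_sel) == self.na
                 else self._target_images(angle_sel, self._fx, self._fy))
            return self._ccc(T, self._Mst, self._MEst, self._MRst)
        out = np.empty((len(angle_sel), self.ns))
        for s in range(self.ns):
            out[:, s] = self.score_at_shift(self.center.x + self.off_x[s],
                                            self.center.y + self.off_y[s],
                                            angle_sel)
        return out

    def score_at_shift(self, sx: float, sy: float, angle_sel=None) -> np.ndarray:
        """CCC of the selected angles at one (possibly fractional) shift."""
        if angle_sel is None:
            angle_sel = np.arange(self.na)
        angle_sel = np.asarray(angle_sel, dtype=np.int64)
        rx, ry = int(round(sx)), int(round(sy))
        T = self._target_images(angle_sel, sx - rx, sy - ry)
        sh = (-ry, -rx)
        m = np.roll(self.w, sh, axis=(0, 1)).ravel()
        me = np.roll(self.we, sh, axis=(0, 1)).ravel()
        mr = (np.roll(self.wr, sh, axis=(0, 1)).ravel()[:, None]
              if self.wr is not None else None)
        return self._ccc(T, m[:, None], me[:, None], mr)[:, 0]

    # -- candidate bookkeeping ----------------------------------------------
    def params_at(self, angle: int, sx: float, sy: float) -> OrientationParams:
        phi_i, theta_i = self.dirs[self.ang_dir[angle]]
        return OrientationParams(float(phi_i), float(theta_i),
                                 float(self.ang_psi[angle]), float(sx), float(sy))

    def pick_grid(self, scores: np.ndarray, angle_sel=None):
        """Argmax with the closest-to-preliminary tie break.

        Exact score ties are resolved lexicographically on (direction span
        from the preliminary direction, |psi offset|, shift distance).
        """
        if angle_sel is None:
            angle_sel = np.arange(self.na)
        best = scores.max()
        if best <= _DEGENERATE + 0.5:
            raise RefinementFailedError("CCC degenerate on every grid point")
        ties = np.argwhere(scores == best)
        keys = [(self.ang_span[angle_sel[a]], abs(self.ang_dpsi[angle_sel[a]]),
                 self.shift_mag[s], int(a), int(s)) for a, s in ties]
        _, _, _, a, s = min(keys)
        angle = int(angle_sel[a])
        return angle, s, float(best)

    def pick_angles(self, scores: np.ndarray):
        """Argmax over an angle-only score vector, same tie break."""
        best = scores.max()
        if best <= _DEGENERATE + 0.5:
            raise RefinementFailedError("CCC degenerate on every grid point")
        ties = np.flatnonzero(scores == best)
        keys = [(self.ang_span[a], abs(self.ang_dpsi[a]), int(a)) for a in ties]
        return int(min(keys)[2]), float(best)


def _make_scorer(exp_img, target, remainder, record: ParticleRecord,
                 cfg: RefinementConfig, ctf_tf=None,
                 pixel_size: float | None = None) -> _ParticleScorer:
    tp = _as_projector(target, cfg.use_fourier_projector)
    rp = _as_projector(remainder, cfg.use_fourier_projector) if remainder is not None else None
    g = _img_grid(exp_img)
    sim_tf = ctf_tf
    if cfg.lowpass_A is not None:
        apix = pixel_size if pixel_size is not None else getattr(exp_img, "pixel_size", 1.0)
        lp = _lowpass_tf(g.shape[0], apix, cfg.lowpass_A)
        # band-limit both sides of the correlation; a radial multiplier
        # commutes with the in-plane rotations and shifts applied downstream
        g = _ctf_filter(g, lp)
        sim_tf = lp if sim_tf is None else sim_tf * lp
    mask = None
    if cfg.mask_diameter is not None:
        c = g.shape[0] // 2
        p0 = OrientationParams(*record.params)
        mask = Mask2D.circular(g.shape[0], cfg.mask_diameter,
                               center=(c + p0.y, c + p0.x)).weights
    return _ParticleScorer(g, tp, rp, record.params, record.params_preliminary,
                           cfg.search, mask, ctf_tf=sim_tf,
                           k_mode=cfg.k_mode, k_value=cfg.k_value)


def optimize_particle_simultaneous(exp_img, target, remainder,
                                   record: ParticleRecord, cfg: RefinementConfig,
                                   *, ctf_tf=None, pixel_size=None,
                                   scorer: _ParticleScorer | None = None,
                                   ) -> ParticleRecord:
    """Exhaustive masked-CCC search over the full angles x shifts grid.

    The grid contains the preliminary parameters, so the returned score never
    falls below the preliminary one.  A particle whose CCC is degenerate on
    every grid point keeps its preliminary parameters and is flagged failed.
    """
    try:
        sc = scorer or _make_scorer(exp_img, target, remainder, record, cfg,
                                    ctf_tf, pixel_size)
        scores = sc.score_grid()
        angle, s, best = sc.pick_grid(scores)
    except (DegenerateImageError, RefinementFailedError):
        return replace(record, failed=True, best_ccc=None)
    params = sc.params_at(angle, sc.center.x + sc.off_x[s], sc.center.y + sc.off_y[s])
    return record.with_params(params, best)


def optimize_particle_separate(exp_img, target, remainder,
                               record: ParticleRecord, cfg: RefinementConfig,
                               *, ctf_tf=None, pixel_size=None,
                               scorer: _ParticleScorer | None = None,
                               ) -> ParticleRecord:
    """Two-stage search: shifts on a random angle subset, then all angles.

    Stage 1 draws ``n_trial_angles`` angle triples without replacement from
    the constrained grid (RNG stream keyed by the config seed and the
    particle index), exhausts the shift grid for each, refines each argmax to
    sub-step precision by parabolic interpolation of the sampled scores, and
    averages the refined shifts component-wise.  Stage 2 exhausts
    the angle grid at that fixed shift.  The preliminary parameters are
    evaluated as a guard so the returned score never falls below them.
    """
    try:
        sc = scorer or _make_scorer(exp_img, target, remainder, record, cfg,
                                    ctf_tf, pixel_size)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.rng_seed), int(record.image_index)]))
        ntr = min(cfg.n_trial_angles, sc.na)
        trial = np.sort(rng.choice(sc.na, size=ntr, replace=False))
        s1 = sc.score_grid(angle_sel=trial)
        n1 = 2 * sc.search.t2 + 1
        sxs, sys_ = [], []
        for row in s1:
            m = row.max()
            if m <= _DEGENERATE + 0.5:
                continue
            ties = np.flatnonzero(row == m)
            s = int(min(ties, key=lambda j: (sc.shift_mag[j], j)))
            # sub-step refinement of the argmax (the direction/shift
            # trade-off makes the angle pass sensitive to fractions of a
            # shift step); interior cells only, same grid evaluations
            i, j = divmod(s, n1)
            fx = (_parabolic_offset(row[(i - 1) * n1 + j], row[s], row[(i + 1) * n1 + j])
                  if 0 < i < n1 - 1 else 0.0)
            fy = (_parabolic_offset(row[i * n1 + j - 1], row[s], row[i * n1 + j + 1])
                  if 0 < j < n1 - 1 else 0.0)
            sxs.append(sc.center.x + sc.off_x[s] + fx * sc.search.d2)
            sys_.append(sc.center.y + sc.off_y[s] + fy * sc.search.d2)
        if not sxs:
            raise RefinementFailedError("all stage-1 trials degenerate")
        xa, ya = float(np.mean(sxs)), float(np.mean(sys_))
        s2 = sc.score_at_shift(xa, ya)
        angle, best = sc.pick_angles(s2)
        pre = sc.score_at_shift(sc.center.x, sc.center.y,
                                angle_sel=[sc.prelim_angle])[0]
    except (DegenerateImageError, RefinementFailedError):
        return replace(record, failed=True, best_ccc=None)
    if pre >= best:
        return record.with_params(record.params, float(pre))
    return record.with_params(sc.params_at(angle, xa, ya), best)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Sub-step offset of a quadratic through three equispaced samples.

    Returns 0 unless the points bracket a maximum; the offset is clamped to
    half a step so the refined position stays inside the sampled cell.
    """
    d = cm - 2.0 * c0 + cp
    if d >= -1e-30:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / d, -0.5, 0.5))


_OPTIMIZERS = {"simultaneous": optimize_particle_simultaneous,
               "separate": optimize_particle_separate}


def _group_ctf_filters(stack: ParticleStack) -> list[np.ndarray] | None:
    """|CTF| modulation per defocus group.

    The supported CTF-correction dialect is phase flipping of the
    experimental images, after which their signal is modulated by |CTF|; the
    simulated projections are modulated to match.  The modulation is radially
    symmetric (no astigmatism), so it commutes with the scorer's in-plane
    rotations and shifts.
    """
    groups = stack.extra.get("defocus_groups")
    if not groups:
        return None
    sgrid = ctf_grid(stack.n, stack.pixel_size)
    return [np.abs(ctf_evaluate(c, sgrid)) for c in groups]


def refine_module(stack: ParticleStack, model, target_mask, cfg: RefinementConfig,
                  ) -> tuple[ParticleStack, DensityVolume]:
    """One LO-refinement pass of one module over a whole particle stack.

    The model is recentered on the target module (whole-voxel shift, so the
    translation is lossless), all particle parameters are mapped into the
    recentered frame, every particle is optimized with the configured
    strategy, and a new reconstruction is computed from the refined
    parameters.  Returned parameters and reconstruction are mapped back to
    the input frame.  Per-particle failures are flagged, not raised; the pass
    aborts only when more than half the particles fail.  ``extra['refine_stats']``
    of the returned stack records grid-evaluation and failure counts.
    """
    t_start = time.perf_counter()
    shifted, _, shift3d = recenter_model(model, target_mask, integer=True)
    target, remainder = split_volume(shifted, translate_volume(target_mask.grid, shift3d).grid)
    tp = _as_projector(target, cfg.use_fourier_projector)
    rp = _as_projector(remainder, cfg.use_fourier_projector)
    ctf_tfs = _group_ctf_filters(stack)
    optimize = _OPTIMIZERS[cfg.strategy]

    nevals = 0
    refined: list[ParticleRecord] = []
    for rec, img in zip(stack.records, stack.images):
        local = replace(rec,
                        params=transform_particle_params(rec.params, shift3d),
                        params_preliminary=transform_particle_params(
                            rec.params_preliminary, shift3d))
        ctf_tf = (ctf_tfs[rec.defocus_group]
                  if ctf_tfs is not None and rec.defocus_group is not None else None)
        try:
            sc = _make_scorer(img.astype(np.float64), tp, rp, local, cfg, ctf_tf,
                              pixel_size=stack.pixel_size)
        except DegenerateImageError:
            refined.append(replace(local, failed=True, best_ccc=None))
            continue
        out = optimize(img, tp, rp, local, cfg, ctf_tf=ctf_tf, scorer=sc)
        nevals += sc.nevals
        refined.append(out)
    n_failed = sum(r.failed for r in refined)
    if n_failed * 2 > len(refined):
        raise RefinementFailedError(
            f"{n_failed}/{len(refined)} particles failed; aborting the pass")

    recon_local = wbp_reconstruct(np.asarray(stack.images, dtype=np.float64),
                                  [r.params for r in refined],
                                  pixel_size=stack.pixel_size)
    recon = translate_volume(recon_local, -shift3d)

    back = [replace(r,
                    params=transform_particle_params(r.params, -shift3d),
                    params_preliminary=transform_particle_params(
                        r.params_preliminary, -shift3d))
            for r in refined]
    out_stack = stack.with_records(back)
    out_stack.extra["refine_stats"] = {
        "grid_evaluations": int(nevals),
        "n_failed": int(n_failed),
        "wall_time_s": time.perf_counter() - t_start,
    }
    return out_stack, recon


@dataclass
class ModuleRefinementResult:
    """Outcome of an LO pass over every module of the model."""

    module_stacks: list[ParticleStack]  # one refined stack per module
    module_reconstructions: list[DensityVolume]
    combined_model: DensityVolume
    stats: list[dict]


def refine_all_modules(stack: ParticleStack, model, masks: Sequence,
                       cfg: RefinementConfig, n_iterations: int = 1,
                       ) -> ModuleRefinementResult:
    """Refine every module independently and combine the results.

    Each module is refined from the same input parameters (each particle ends
    with one parameter set per module); every module's own refined
    reconstruction contributes its masked region to the combined model, and
    regions covered by no mask keep the input model's density.  With
    ``n_iterations > 1`` the combined model and the per-module parameters
    feed the next iteration.
    """
    if n_iterations < 1:
        raise InvalidParameterError("n_iterations must be >= 1")
    total = np.zeros_like(_vol_grid(model))
    for m in masks:
        total += m.grid
    if total.max() > 1.0 + 1e-6:
        raise InvalidParameterError("module masks overlap beyond tolerance")
    leftover = np.clip(1.0 - total, 0.0, None)

    current_model = model
    module_stacks = [stack] * len(masks)
    recons: list[DensityVolume] = []
    stats: list[dict] = []
    for _ in range(n_iterations):
        recons, stats = [], []
        new_stacks = []
        for m, s_in in zip(masks, module_stacks):
            s_out, recon = refine_module(s_in, current_model, m, cfg)
            new_stacks.append(s_out)
            recons.append(recon)
            stats.append(s_out.extra["refine_stats"])
        module_stacks = new_stacks
        combined = leftover * _vol_grid(current_model)
        for m, recon in zip(masks, recons):
            combined += m.grid * recon.grid
        current_model = DensityVolume(combined, getattr(model, "pixel_size", 1.0))
    return ModuleRefinementResult(module_stacks, recons, current_model, stats)


def conventional_global_refine(stack: ParticleStack, model,
                               angular_spacing: float = 2.0,
                               shift_range: float = 4.0, *,
                               coarse_spacing: float = 15.0,
                               cone: float | None = None,
                               max_rounds: int = 3,
                               use_fourier_projector: bool = True,
                               lowpass_A: float | None = 16.0,
                               ) -> ParticleStack:
    """Conventional whole-model projection matching (the baseline procedure).

    Stage 1 matches every particle against an exhaustive reference library of
    whole-model projections on a global quasi-uniform direction set of
    ``coarse_spacing`` degrees (in-plane angle sampled at the same step,
    shifts at zero).  Subsequent rounds localize each particle with an
    exhaustive cone search, alternating a shift pass and an angle pass and
    re-reconstructing the model between rounds.  The first local round runs
    at twice the final angular step over the full hand-off cone; later rounds
    run at ``angular_spacing`` degrees over a cone narrowed to what the
    previous round can leave behind (1-pixel shifts up to ``shift_range``
    throughout).  Iteration stops when the mean parameter change falls below
    half a sampling step.  Deterministic: no random numbers are involved.
    """
    if angular_spacing <= 0 or shift_range < 0:
        raise InvalidParameterError("angular_spacing must be > 0, shift_range >= 0")
    if max_rounds < 1:
        raise InvalidParameterError("max_rounds must be >= 1")
    cone = coarse_spacing * 0.75 if cone is None else cone
    n = stack.n
    npx = n * n
    imgs = np.asarray(stack.images, dtype=np.float64)
    # scoring uses band-limited copies; reconstruction uses the originals
    lp = (_lowpass_tf(n, stack.pixel_size, lowpass_A)
          if lowpass_A is not None else None)
    simgs = imgs if lp is None else _ctf_filter(imgs, lp)

    # ---- stage 1: exhaustive coarse library matching (zero shift) ----------
    proj = _as_projector(model, use_fourier_projector)
    lib_dirs = generate_direction_set(coarse_spacing)
    lib_psi = np.arange(0.0, 360.0, coarse_spacing)
    bases = np.ascontiguousarray(
        proj.project_many([OrientationParams(p, t, 0.0) for p, t in lib_dirs]))
    if lp is not None:
        bases = np.ascontiguousarray(_ctf_filter(bases, lp))
    idx = np.repeat(np.arange(len(lib_dirs)), len(lib_psi)).astype(np.int64)
    deltas = np.ascontiguousarray(np.tile(np.radians(lib_psi), len(lib_dirs)))
    refs = _kernels.rotate_shift2d_batch(bases, idx, deltas, 0.0, 0.0)
    refs = refs.reshape(len(idx), npx).astype(np.float32)
    refs -= refs.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(refs, axis=1, keepdims=True)
    refs /= np.maximum(nrm, 1e-30)
    E = simgs.reshape(len(stack), npx).astype(np.float32)
    E -= E.mean(axis=1, keepdims=True)
    E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-30)
    match = np.argmax(refs @ E.T, axis=0)
    params = [OrientationParams(float(lib_dirs[idx[m], 0]), float(lib_dirs[idx[m], 1]),
                                float(lib_psi[m % len(lib_psi)]), 0.0, 0.0)
              for m in match]

    # ---- local rounds: one coarse-to-fine pass, then final-step rounds -----
    t2 = int(round(shift_range))
    d1_first = 2.0 * angular_spacing if coarse_spacing > 2.0 * angular_spacing \
        else angular_spacing
    searches = {}
    for d1, cone_r in ((d1_first, cone),
                       (angular_spacing, max(3.0 * angular_spacing,
                                             1.5 * d1_first))):
        if d1 not in searches:
            t1 = max(1, int(math.ceil(0.5 * coarse_spacing / d1)) if d1 == d1_first
                     else 2)
            searches[d1] = SearchRange(cone_r, d1, t1, 1.0, t2,
                                       generate_direction_set(d1))
    current_model = model
    for rnd in range(max_rounds):
        search = searches[d1_first if rnd == 0 else angular_spacing]
        proj = _as_projector(current_model, use_fourier_projector)
        new_params: list[OrientationParams] = []
        best_ccc: list[float | None] = []
        for i in range(len(stack)):
            p0 = params[i]
            try:
                sc = _ParticleScorer(simgs[i], proj, None, p0, p0, search, None,
                                     ctf_tf=lp)
                # shift pass at the current angles, then angle pass at that shift
                row = sc.score_grid(angle_sel=[sc.prelim_angle])[0]
                m = row.max()
                if m <= _DEGENERATE + 0.5:
                    raise RefinementFailedError("degenerate shift pass")
                ties = np.flatnonzero(row == m)
                s = int(min(ties, key=lambda j: (sc.shift_mag[j], j)))
                sx, sy = p0.x + sc.off_x[s], p0.y + sc.off_y[s]
                scores = sc.score_at_shift(sx, sy)
                angle, best = sc.pick_angles(scores)
                new_params.append(sc.params_at(angle, sx, sy))
                best_ccc.append(best)
            except (DegenerateImageError, RefinementFailedError):
                new_params.append(p0)
                best_ccc.append(None)
        dir_change = np.mean([span_angle(p.direction, q.direction)
                              for p, q in zip(params, new_params)])
        shift_change = np.mean([math.hypot(p.x - q.x, p.y - q.y)
                                for p, q in zip(params, new_params)])
        params = new_params
        if dir_change < 0.5 * angular_spacing and shift_change < 0.5:
            break
        current_model = wbp_reconstruct(imgs, params, pixel_size=stack.pixel_size)

    records = [replace(r, params=p, params_preliminary=p, best_ccc=c)
               for r, p, c in zip(stack.records, params, best_ccc)]
    return stack.with_records(records)
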