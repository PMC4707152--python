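"""Synthetic two-module benchmark data with continuous conformational spread.

The generator emulates the validation protocol for module-wise refinement:
a complex made of two rigid modules (a large and a small one, default mass
ratio 2:1 mimicking ribosomal subunits) is perturbed per particle by rotating
each module about a random axis through its own centre of density (rotation
angle ~ N(0°, 1.67°)) and translating it by an independent
N(0 px, 1 px) shift per axis.  The perturbed complex is projected once in a
random orientation and degraded either with additive white Gaussian noise at
a prescribed variance SNR or with a weak-phase CTF across round-robin
defocus groups followed by noise.  Every transform is recorded as ground
truth, and all randomness derives from a single master seed with
per-particle substreams, so datasets are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .geometry import OrientationParams, euler_matrix, matrix_to_euler
from .particles import GroundTruth, ModuleGroundTruth, ParticleRecord, ParticleStack
from .volume_ops import (
    CTFParams,
    DensityVolume,
    Image2D,
    ModuleMask,
    affine_resample,
    apply_ctf,
    center_of_density,
    phase_flip,
    project,
    split_volume,
    _img_grid,
    _vol_grid,
)


@dataclass
class PerturbationModel:
    """Distribution of the per-particle rigid module transforms.

    sigma_rot : SD of the rotation angle about a uniformly random axis, degrees
    sigma_shift : per-axis SD of the 3D shift, pixels
    """

    sigma_rot: float = 1.67
    sigma_shift: float = 1.0

    def __post_init__(self):
        if self.sigma_rot < 0 or self.sigma_shift < 0:
            raise InvalidParameterError("perturbation SDs must be non-negative")


# blob table of the default phantom: (cx, cy, cz) voxel offsets at N=64,
# Gaussian sigma (voxels), amplitude.  Module A (large) left of the x = 1.5
# partition plane, module B (small) right of it; the layout is deliberately
# irregular so the phantom has no point symmetry.  The clusters are sized so
# each module subtends a substantial fraction of the box (radii ~13 and ~10
# voxels) with feature widths of 1.3-2.6 voxels: a module must carry enough
# high-frequency structure within Nyquist that degree-scale orientation
# changes are distinguishable in its projections — a compact smooth blob
# yields a nearly flat orientation objective and an uninformative benchmark.
_MODULE_A_BLOBS = [
    (-10.99, 2.16, -1.98, 1.59, 0.58),
    (-18.16, 0.43, 9.68, 2.34, 0.68),
    (-7.46, 2.58, 0.76, 1.88, 0.7),
    (-5.98, -9.71, -3.31, 2.11, 0.99),
    (-9.04, 1.13, -1.35, 1.91, 0.95),
    (-11.35, 0.82, -11.05, 1.62, 0.41),
    (-18.07, -5.84, 7.66, 1.78, 0.4),
    (-4.61, -4.21, -0.81, 2.44, 0.71),
    (-22.17, 6.21, 0.86, 2.43, 0.62),
    (-5.49, -8.66, 0.54, 1.72, 0.49),
    (-6.07, -0.48, 4.82, 2.07, 0.76),
    (-9.53, -3.35, 0.92, 1.87, 0.54),
    (-12.42, 6.49, 8.27, 1.58, 0.8),
    (-11.7, 9.08, 4.98, 2.48, 0.74),
    (-12.81, 11.0, -3.09, 2.02, 0.51),
    (-11.87, -1.42, -8.05, 1.79, 0.65),
    (-6.17, -2.45, 7.6, 2.28, 0.42),
    (-15.51, 1.48, 3.56, 1.97, 0.86),
    (-5.93, 3.75, -7.47, 1.31, 0.85),
    (-18.62, 1.88, -6.2, 2.36, 0.41),
    (-10.36, -4.27, -0.86, 2.24, 0.54),
    (-5.37, 0.95, -11.1, 1.88, 0.99),
    (-11.48, -1.98, -1.15, 2.27, 0.75),
    (-14.92, -0.37, -5.73, 2.5, 0.44),
    (-10.9, -5.02, -2.36, 2.23, 0.78),
    (-15.85, -7.61, 2.44, 1.92, 0.76),
]
_MODULE_B_BLOBS = [
    (15.88, -0.12, 0.38, 1.54, 0.44),
    (9.15, -0.75, -5.85, 2.25, 0.47),
    (9.32, 1.54, -0.18, 1.98, 0.95),
    (15.33, -1.59, -0.8, 1.63, 0.55),
    (15.59, 2.02, -2.97, 2.07, 0.5),
    (17.1, -0.74, 2.86, 2.52, 0.72),
    (5.42, 4.55, 2.61, 2.34, 0.98),
    (16.31, -5.36, -0.07, 2.34, 0.59),
    (10.7, 0.2, -4.54, 2.05, 0.78),
    (11.68, 2.15, -5.22, 1.73, 0.83),
    (7.32, 1.03, -4.13, 1.33, 0.79),
    (11.53, -0.07, -7.65, 2.15, 0.46),
    (11.56, 0.43, -1.53, 2.38, 0.63),
    (12.25, -6.19, -4.96, 1.4, 0.86),
]
_PARTITION_X = 1.5  # voxels right of centre at N=64, scaled with N


def _blob_volume(n: int, blobs, scale: float) -> np.ndarray:
    ax = np.arange(n) - n // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    out = np.zeros((n, n, n))
    for cx, cy, cz, s, amp in blobs:
        cx, cy, cz, s = cx * scale, cy * scale, cz * scale, s * scale
        out += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2) / (2 * s * s))
    return out


def make_two_module_phantom(
    n: int = 64, pixel_size: float = 4.0, mass_ratio: float = 2.0
) -> tuple[DensityVolume, list[ModuleMask]]:
    """Deterministic two-module phantom with disjoint binary masks.

    Two compact, asymmetric, adjoining blob clusters of unequal integrated
    density (``mass_ratio`` = large:small, default 2:1).  The masks partition
    the box along a plane between the modules, so they are voxel-wise
    disjoint and sum to one everywhere.
    """
    if n < 32:
        raise InvalidParameterError("phantom requires n >= 32")
    scale = n / 64.0
    a = _blob_volume(n, _MODULE_A_BLOBS, scale)
    b = _blob_volume(n, _MODULE_B_BLOBS, scale)
    ax = np.arange(n) - n // 2
    cut = _PARTITION_X * scale
    in_a = ax[None, None, :] < cut  # broadcast over x axis
    mask_a = np.broadcast_to(in_a, (n, n, n)).astype(np.float64)
    mask_b = 1.0 - mask_a
    if (a * mask_b).sum() > 0.01 * a.sum() or (b * mask_a).sum() > 0.01 * b.sum():
        raise InvalidParameterError("modules overlap the partition plane")
    # scale module A so the *masked* densities hold the requested mass ratio
    a *= mass_ratio * (b * mask_b).sum() / (a * mask_a).sum()
    vol = DensityVolume(a + b, pixel_size)
    return vol, [ModuleMask(mask_a, "binary"), ModuleMask(mask_b, "binary")]


def load_pdb_derived_volume(path) -> DensityVolume:
    """Optional pathway for externally generated maps (e.g. from atomic models)."""
    from .io import read_mrc

    vol = read_mrc(path)
    if not isinstance(vol, DensityVolume):
        raise InvalidParameterError(f"{path} is not a cubic volume")
    return vol


def rodrigues(axis, angle_deg: float) -> np.ndarray:
    """Active rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    t = math.radians(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def sample_module_perturbation(model: PerturbationModel, rng: np.random.Generator):
    """Draw one rigid module transform: (unit axis, angle in degrees, 3D shift).

    The axis is uniform on the sphere (normalized Gaussian draw); the angle
    and each shift component are zero-mean normal draws.
    """
    axis = rng.normal(size=3)
    nrm = np.linalg.norm(axis)
    while nrm < 1e-12:  # pragma: no cover - measure-zero event
        axis = rng.normal(size=3)
        nrm = np.linalg.norm(axis)
    axis /= nrm
    angle = float(rng.normal(0.0, model.sigma_rot)) if model.sigma_rot > 0 else 0.0
    shift = rng.normal(0.0, model.sigma_shift, size=3) if model.sigma_shift > 0 else np.zeros(3)
    return axis, angle, np.asarray(shift, dtype=np.float64)


def apply_module_perturbation(module: DensityVolume, centroid, axis, angle_deg: float,
                              shift3d) -> DensityVolume:
    """Rotate a module density about its own centre and translate it, in one
    interpolation pass."""
    c = np.asarray(centroid, dtype=np.float64)
    s = np.asarray(shift3d, dtype=np.float64)
    q = rodrigues(axis, angle_deg)
    if abs(angle_deg) < 1e-15 and not s.any():
        return DensityVolume(_vol_grid(module).copy(), module.pixel_size)
    A = q.T
    b = c - A @ (c + s)
    return affine_resample(module, A, b)


def module_ground_truth(global_params: OrientationParams, centroid, axis,
                        angle_deg: float, shift3d) -> OrientationParams:
    """Exact five-parameter pose of a perturbed module in the frame where the
    module's unperturbed centre of density sits at the box centre.

    If the whole particle is viewed at global rotation R_g and the module was
    rotated by Q about its centre c and shifted by s, the module appears at
    orientation R_g Q with an in-plane offset equal to the camera-frame (x, y)
    components of R_g (s + c).
    """
    g = OrientationParams(*global_params)
    rg = euler_matrix(g.phi, g.theta, g.psi)
    r_true = rg @ rodrigues(axis, angle_deg)
    phi, theta, psi = matrix_to_euler(r_true)
    t = rg @ (np.asarray(shift3d, dtype=np.float64) + np.asarray(centroid, dtype=np.float64))
    return OrientationParams(phi, theta, psi, g.x + t[0], g.y + t[1])


def generate_particle(modules, centroids, perturbations, global_params: OrientationParams,
                      degradation=None, rng: np.random.Generator | None = None,
                      ) -> tuple[Image2D, GroundTruth]:
    """Build one particle image: perturb each module about its own centre,
    sum, project at the global pose, then degrade.

    ``modules`` are the split module densities, ``centroids`` their centres of
    density, ``perturbations`` a list of (axis, angle, shift3d).
    ``degradation`` is None, ("gaussian", snr) or ("ctf", CTFParams, snr).
    """
    total = None
    truth_modules = []
    for mod, c, (axis, angle, shift) in zip(modules, centroids, perturbations):
        moved = apply_module_perturbation(mod, c, axis, angle, shift)
        total = moved.grid if total is None else total + moved.grid
        truth_modules.append(ModuleGroundTruth(np.asarray(axis, float), float(angle),
                                               np.asarray(shift, float)))
    img = project(DensityVolume(total, modules[0].pixel_size), global_params)
    if degradation is not None:
        kind = degradation[0]
        if kind == "ctf":
            _, ctf, snr = degradation
            img = apply_ctf(img, ctf)
            if snr is not None:
                img = add_gaussian_noise(img, snr, rng)
        elif kind == "gaussian":
            img = add_gaussian_noise(img, degradation[1], rng)
        else:
            raise InvalidParameterError(f"unknown degradation {kind!r}")
    return img, GroundTruth(OrientationParams(*global_params), truth_modules)


def add_gaussian_noise(img, snr: float, rng: np.random.Generator) -> Image2D:
    """Additive zero-mean Gaussian noise with variance var(signal) / snr.

    SNR is the variance ratio over the full image frame.
    """
    if not snr > 0:
        raise InvalidParameterError("snr must be positive")
    g = _img_grid(img)
    var = float(g.var())
    if var <= 0:
        raise InvalidParameterError("constant image: SNR is undefined")
    noise = rng.normal(0.0, math.sqrt(var / snr), size=g.shape)
    return Image2D(g + noise, getattr(img, "pixel_size", 1.0))


DEFAULT_SNR_LEVELS = (0.25, 0.11, 0.06)
DEFAULT_DEFOCUS_GROUPS = (2.0, 2.3, 2.6, 2.8, 3.0, 3.2, 3.4, 3.7, 4.0)  # um


def default_ctf(pixel_size: float, defocus: float) -> CTFParams:
    """200 kV / Cs 2.7 mm weak-phase CTF used by the ctf-mode generator."""
    return CTFParams(voltage=200.0, spherical_aberration=2.7, defocus=defocus,
                     amplitude_contrast=0.07, pixel_size=pixel_size)


@dataclass
class DatasetSpec:
    """Conditions of the standard benchmark dataset."""

    n_particles: int = 300
    n: int = 64
    pixel_size: float = 4.0
    mass_ratio: float = 2.0
    perturbation: PerturbationModel = field(default_factory=PerturbationModel)
    degradation: tuple | None = ("gaussian", 0.25)
    defocus_groups: tuple = DEFAULT_DEFOCUS_GROUPS


def generate_dataset(spec: DatasetSpec | None = None, rng_seed: int = 0,
                     phantom: DensityVolume | None = None,
                     masks: list[ModuleMask] | None = None) -> ParticleStack:
    """Generate the two-module benchmark stack with ground truth.

    Global orientations are uniform over the sphere (phi uniform, cos(theta)
    uniform, psi uniform in [0, 360)); each module receives an independent
    perturbation draw.  In CTF mode defocus groups are assigned round-robin.
    Fully reproducible from ``rng_seed``: particle i uses the substream
    seeded by (rng_seed, i).
    """
    spec = spec or DatasetSpec()
    if spec.n_particles < 1:
        raise InvalidParameterError("need at least one particle")
    if phantom is None:
        phantom, masks = make_two_module_phantom(spec.n, spec.pixel_size, spec.mass_ratio)
    modules = []
    centroids = []
    remaining = phantom
    for m in masks:
        mod, _ = split_volume(phantom, m)
        modules.append(mod)
        centroids.append(center_of_density(mod))
    ctf_mode = spec.degradation is not None and spec.degradation[0] == "ctf"
    images = np.empty((spec.n_particles, spec.n, spec.n), dtype=np.float32)
    records: list[ParticleRecord] = []
    truths: list[GroundTruth] = []
    for i in range(spec.n_particles):
        rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), i]))
        phi = rng.uniform(0.0, 360.0)
        theta = math.degrees(math.acos(rng.uniform(-1.0, 1.0)))
        psi = rng.uniform(0.0, 360.0)
        gparams = OrientationParams(phi, theta, psi, 0.0, 0.0)
        perts = [sample_module_perturbation(spec.perturbation, rng) for _ in modules]
        group = None
        if ctf_mode:
            group = i % len(spec.defocus_groups)
            snr = spec.degradation[1] if len(spec.degradation) > 1 else None
            degr = ("ctf", default_ctf(spec.pixel_size, spec.defocus_groups[group]), snr)
        else:
            degr = spec.degradation
        img, truth = generate_particle(modules, centroids, perts, gparams, degr, rng)
        images[i] = img.grid.astype(np.float32)
        records.append(ParticleRecord(i, gparams, gparams, defocus_group=group))
        truths.append(truth)
    extra = {"spec": spec, "centroids": centroids}
    if ctf_mode:
        extra["defocus_groups"] = [default_ctf(spec.pixel_size, d) for d in spec.defocus_groups]
    return ParticleStack(images, spec.pixel_size, records, truths, extra)
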