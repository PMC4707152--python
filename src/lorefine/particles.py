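"""Particle stack and per-particle record containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidParameterError
from .geometry import OrientationParams


@dataclass
class ParticleRecord:
    """Alignment state of one particle image."""

    image_index: int
    params: OrientationParams
    params_preliminary: OrientationParams
    defocus_group: int | None = None
    best_ccc: float | None = None
    failed: bool = False

    def with_params(self, params: OrientationParams, best_ccc: float | None = None):
        return replace(self, params=OrientationParams(*params), best_ccc=best_ccc)


@dataclass
class ModuleGroundTruth:
    """Rigid perturbation applied to one module of one particle."""

    axis: np.ndarray  # unit 3-vector
    angle: float  # degrees
    shift3d: np.ndarray  # voxels, (x, y, z)


@dataclass
class GroundTruth:
    """Per-particle generation record: global pose plus per-module transforms."""

    global_params: OrientationParams
    modules: list[ModuleGroundTruth]


@dataclass
class ParticleStack:
    """2D images with their per-particle parameter records.

    ``truth`` is filled by the synthetic-data generator and holds the exact
    transforms each image was generated with.
    """

    images: np.ndarray  # (n, N, N) float32
    pixel_size: float
    records: list[ParticleRecord]
    truth: list[GroundTruth] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        imgs = np.asarray(self.images)
        if imgs.ndim != 3 or imgs.shape[1] != imgs.shape[2]:
            raise InvalidParameterError("images must be a (n, N, N) array")
        if len(self.records) != imgs.shape[0]:
            raise InvalidParameterError("record count differs from image count")
        idx = [r.image_index for r in self.records]
        if len(set(idx)) != len(idx):
            raise InvalidParameterError("particle indices must be unique")
        self.images = imgs.astype(np.float32, copy=False)

    def __len__(self) -> int:
        return self.images.shape[0]

    @property
    def n(self) -> int:
        return self.images.shape[1]

    def params_list(self) -> list[OrientationParams]:
        return [r.params for r in self.records]

    def with_records(self, records: Sequence[ParticleRecord]) -> "ParticleStack":
        return ParticleStack(self.images, self.pixel_size, list(records), self.truth,
                             dict(self.extra))
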