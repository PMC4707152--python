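"""Shared fixtures: phantom, benchmark datasets and LO-refinement runs.

The acceptance benchmark (N=64 two-module phantom, 300 particles, SNR 0.25,
cone 10 degrees, steps 2 degrees / 1 px, preliminary parameters = ground-truth
global pose) is expensive, so it is generated once per session and the
refinement runs over it are shared between the acceptance tests that grade
different aspects of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from lorefine.geometry import span_angle
from lorefine.lo_refine import RefinementConfig, refine_module
from lorefine.particles import ParticleStack
from lorefine.synthetic_data import (
    DatasetSpec,
    generate_dataset,
    make_two_module_phantom,
    module_ground_truth,
)

BENCHMARK_SEED = 0


@pytest.fixture(scope="session")
def phantom_masks():
    return make_two_module_phantom()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@dataclass
class BenchmarkRun:
    stack: ParticleStack           # input stack (prelim = ground-truth global)
    refined: dict                  # strategy -> refined ParticleStack
    recon: dict                    # strategy -> module reconstruction
    dir_errors: dict               # strategy -> per-particle direction error (deg)
    grid_evaluations: dict         # strategy -> measured total grid evaluations


def _target_truth_directions(stack: ParticleStack):
    cents = stack.extra["centroids"]
    return [module_ground_truth(t.global_params, cents[0], t.modules[0].axis,
                                t.modules[0].angle, t.modules[0].shift3d).direction
            for t in stack.truth]


def _run_benchmark(degradation, phantom, masks,
                   strategies=("separate", "simultaneous")) -> BenchmarkRun:
    spec = DatasetSpec(degradation=degradation)
    stack = generate_dataset(spec, rng_seed=BENCHMARK_SEED,
                             phantom=phantom, masks=masks)
    truth_dirs = _target_truth_directions(stack)
    refined, recon, errors, evals = {}, {}, {}, {}
    for strategy in strategies:
        cfg = RefinementConfig(strategy=strategy, rng_seed=BENCHMARK_SEED)
        out, rec = refine_module(stack, phantom, masks[0], cfg)
        refined[strategy] = out
        recon[strategy] = rec
        errors[strategy] = np.array(
            [span_angle(r.params.direction, d)
             for r, d in zip(out.records, truth_dirs)])
        evals[strategy] = out.extra["refine_stats"]["grid_evaluations"]
    return BenchmarkRun(stack, refined, recon, errors, evals)


@pytest.fixture(scope="session")
def benchmark_noisy(phantom_masks) -> BenchmarkRun:
    phantom, masks = phantom_masks
    return _run_benchmark(("gaussian", 0.25), phantom, masks)


@pytest.fixture(scope="session")
def benchmark_noise_free(phantom_masks) -> BenchmarkRun:
    phantom, masks = phantom_masks
    return _run_benchmark(None, phantom, masks, strategies=("separate",))
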