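"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tibind.observables import AnalysisParams, binding_profile
from tibind.surface import build_anatase_slab, hydroxylate
from tibind.synthetic import SyntheticSpec, generate_trajectory
from tibind.topology import classify_atoms

BENCHMARK_SEED = 1234


def benchmark_spec(n_frames: int = 2000) -> SyntheticSpec:
    """The fixed-seed recovery benchmark: stationary bound probability 0.8,
    compact/extended conformers (EED 0.65 / 1.40 nm) used 70/30 in the bound
    state, planted anchor contact at 0.28 nm and Na+ bridge at 0.23 nm."""
    return SyntheticSpec(n_frames=n_frames, p_bind=0.08, p_unbind=0.02,
                         template_eeds=(0.65, 1.40), bound_weights=(0.7, 0.3),
                         unbound_weights=(0.0, 1.0), contact_distance=0.28,
                         bridge_distance=0.23)


@pytest.fixture(scope="session")
def benchmark():
    spec = benchmark_spec()
    topo, frames, truth = generate_trajectory(spec, seed=BENCHMARK_SEED)
    return spec, topo, frames, truth


@pytest.fixture(scope="session")
def benchmark_classes(benchmark):
    _, topo, frames, _ = benchmark
    return classify_atoms(topo, frames[0])


@pytest.fixture(scope="session")
def benchmark_profile(benchmark, benchmark_classes):
    _, topo, frames, _ = benchmark
    return binding_profile(frames, topo, AnalysisParams(), classes=benchmark_classes)


@pytest.fixture(scope="session")
def small_system():
    """A short, cheap trajectory for I/O and plumbing tests."""
    spec = SyntheticSpec(n_frames=30)
    topo, frames, truth = generate_trajectory(spec, seed=7)
    return spec, topo, frames, truth


@pytest.fixture(scope="session")
def small_slab():
    return build_anatase_slab(2, 3, 2)


@pytest.fixture(scope="session")
def hydroxylated_slab(small_slab):
    return hydroxylate(small_slab, 0.3, seed=11)
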