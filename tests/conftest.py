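"""Shared fixtures: synthetic ensembles and hand-built contact graphs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from foldprobe import FixtureSpec, generate_fixture, two_helix_ensemble
from foldprobe.structures import Residue, SSEAnnotation, StructuralModel
from foldprobe.topology import SSEContactGraph


def ideal_helix(n: int, start_index: int = 1, radius: float = 2.3,
                rise: float = 1.5, twist_deg: float = 100.0,
                offset=(0.0, 0.0, 0.0)) -> list[Residue]:
    """Ideal α-helix Cα trace with radially displaced Cβ."""
    out = []
    for k in range(n):
        theta = math.radians(twist_deg) * k
        ca = np.array([radius * math.cos(theta) + offset[0],
                       radius * math.sin(theta) + offset[1],
                       rise * k + offset[2]])
        cb = np.array([(radius + 1.53) * math.cos(theta) + offset[0],
                       (radius + 1.53) * math.sin(theta) + offset[1],
                       rise * k + offset[2]])
        out.append(Residue(index=start_index + k, aa="A", ca=ca, cb=cb))
    return out


def extended_chain(n: int, start_index: int = 1, rise: float = 3.3) -> list[Residue]:
    out = []
    for k in range(n):
        ca = np.array([0.0, 0.0, rise * k])
        cb = ca + np.array([1.53, 0.0, 0.0])
        out.append(Residue(index=start_index + k, aa="A", ca=ca, cb=cb))
    return out


def graphs_from_states(states: np.ndarray, n_sses: int) -> list[SSEContactGraph]:
    """Contact graphs from a models × pairs binary state matrix.

    Pairs are the lexicographic unordered pairs over SSE ids 1..n_sses.
    """
    ids = list(range(1, n_sses + 1))
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    assert states.shape[1] == len(pairs)
    graphs = []
    for m, row in enumerate(states):
        g = SSEContactGraph(model_id=f"m{m}", sse_ids=ids)
        for p, s in zip(pairs, row):
            if s:
                g.contacts.add(frozenset(p))
        graphs.append(g)
    return graphs


@pytest.fixture(scope="session")
def two_helix():
    return two_helix_ensemble(n_models=10, separation=8.0, length=12, seed=1)


@pytest.fixture(scope="session")
def basic_fixture():
    """8 models, 4 helices, 2 packing variants, noiseless."""
    spec = FixtureSpec(n_models=8, topology_variants=2, seed=7)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def jittered_fixture():
    spec = FixtureSpec(n_models=8, topology_variants=2, boundary_jitter=2, seed=11)
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def distinct_fold_fixture():
    """One model per packing variant: every model a distinct fold."""
    spec = FixtureSpec(n_models=5, topology_variants=5, seed=3)
    return generate_fixture(spec)
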