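"""Shared fixtures: meshes and simulated cohorts (session-scoped, seeded)."""

from __future__ import annotations

import numpy as np
import pytest

from lgmfp import make_icosphere
from lgmfp.fingerprint import LgmSet
from lgmfp.synthetic import CohortSpec, simulate_lgm_cohort


@pytest.fixture(scope="session")
def mesh2():
    return make_icosphere(2)


@pytest.fixture(scope="session")
def mesh3():
    return make_icosphere(3)


@pytest.fixture(scope="session")
def mesh4():
    return make_icosphere(4)


@pytest.fixture(scope="session")
def cohort_default():
    """The standard evaluation cohort: n=20, level 3, k=6, jitter 2, sigma 0.1."""
    return simulate_lgm_cohort(CohortSpec(master_seed=0))


@pytest.fixture(scope="session")
def lgm_sets_default(cohort_default):
    targets = LgmSet(cohort_default.lgm_set_entries("S1"), "target")
    bases = LgmSet(cohort_default.lgm_set_entries("S2"), "base")
    return targets, bases


def bfs_hops(mesh, sources):
    """Independent brute-force hop-distance oracle (used by several tests)."""
    from collections import deque

    dist = {int(s): 0 for s in np.atleast_1d(sources)}
    q = deque(dist)
    while q:
        v = q.popleft()
        for u in mesh.neighbor_rings[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    out = np.full(mesh.n_vertices, -1)
    for v, d in dist.items():
        out[v] = d
    return out
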