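"""Icosahedral spherical meshes and local neighborhood operations.

The unit icosphere is the coordinate system for every map in this package:
a recursively subdivided icosahedron whose standard levels give the vertex
counts 12, 42, 162, 642, 2562, 10242 and 40962 (``10 * 4**level + 2``).
Subdivision keeps the parent level's vertices as a prefix of the child's
index range, so any lower resolution is a plain index prefix of a higher
one ("nested" sampling).

Besides construction, this module provides the neighborhood primitives the
rest of the pipeline is built from: cyclically ordered 1-rings, r-ring
patches, patch rotation and translation (the deformable-matching moves),
mask dilation and nested uniform subsampling.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "SphericalMesh",
    "make_icosphere",
    "icosphere_vertex_count",
    "level_for_vertex_count",
    "r_ring_indices",
    "rotate_ring",
    "translate_center",
    "dilate_mask",
    "uniform_subsample",
]

# Golden-ratio icosahedron; faces wound counter-clockwise seen from outside.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        (-1, _PHI, 0), (1, _PHI, 0), (-1, -_PHI, 0), (1, -_PHI, 0),
        (0, -1, _PHI), (0, 1, _PHI), (0, -1, -_PHI), (0, 1, -_PHI),
        (_PHI, 0, -1), (_PHI, 0, 1), (-_PHI, 0, -1), (-_PHI, 0, 1),
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ],
    dtype=np.int64,
)


def icosphere_vertex_count(level: int) -> int:
    """Vertex count of the level-``level`` icosphere: ``10 * 4**level + 2``."""
    return 10 * 4**level + 2


def level_for_vertex_count(n: int) -> int:
    """Inverse of :func:`icosphere_vertex_count`; raises if ``n`` is not valid."""
    level = 0
    while icosphere_vertex_count(level) < n:
        level += 1
    if icosphere_vertex_count(level) != n:
        raise ValueError(f"{n} is not an icosphere vertex count (10*4^L + 2)")
    return level


@dataclass(frozen=True)
class SphericalMesh:
    """Subdivided icosahedron on the unit sphere.

    Attributes
    ----------
    vertex_coords : (V, 3) float array of unit vectors.
    triangles : (F, 3) int array, counter-clockwise seen from outside.
    neighbor_rings : per-vertex cyclically ordered 1-hop neighbor indices,
        each ring starting at its lowest-index member.  Length 5 at the 12
        original icosahedron vertices, 6 elsewhere.
    level : subdivision depth (0 = icosahedron).
    """

    vertex_coords: np.ndarray
    triangles: np.ndarray
    neighbor_rings: tuple[tuple[int, ...], ...]
    level: int

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    def degree(self, vertex: int) -> int:
        return len(self.neighbor_rings[vertex])

    # Padded neighbor table for vectorized stencil operations: row v holds
    # the ring of v, pentagons padded by repeating the vertex itself (the
    # pad contributes zero to any difference stencil).
    @property
    def _neighbor_table(self) -> tuple[np.ndarray, np.ndarray]:
        if not hasattr(self, "_nbr_cache"):
            max_deg = max(len(r) for r in self.neighbor_rings)
            idx = np.empty((self.n_vertices, max_deg), dtype=np.int64)
            valid = np.zeros((self.n_vertices, max_deg), dtype=bool)
            for v, ring in enumerate(self.neighbor_rings):
                d = len(ring)
                idx[v, :d] = ring
                idx[v, d:] = v
                valid[v, :d] = True
            object.__setattr__(self, "_nbr_cache", (idx, valid))
        return self._nbr_cache  # type: ignore[attr-defined]


def _cyclic_rings(n_vertices: int, triangles: np.ndarray) -> tuple[tuple[int, ...], ...]:
    """Order each vertex's neighbors by walking the oriented triangle fan."""
    succ: list[dict[int, int]] = [dict() for _ in range(n_vertices)]
    for a, b, c in triangles:
        succ[a][b] = c
        succ[b][c] = a
        succ[c][a] = b
    rings = []
    for v in range(n_vertices):
        nxt = succ[v]
        start = min(nxt)
        ring = [start]
        cur = nxt[start]
        while cur != start:
            ring.append(cur)
            cur = nxt[cur]
        rings.append(tuple(ring))
    return tuple(rings)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One midpoint subdivision: parents keep their indices, midpoints are
    appended in sorted-edge order so that nesting is deterministic."""
    n = verts.shape[0]
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq = np.unique(edges, axis=0)  # lexicographically sorted
    mid_index = {(int(a), int(b)): n + i for i, (a, b) in enumerate(uniq)}
    mids = verts[uniq[:, 0]] + verts[uniq[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    new_verts = np.vstack([verts, mids])

    def m(a: int, b: int) -> int:
        return mid_index[(a, b) if a < b else (b, a)]

    new_faces = np.empty((faces.shape[0] * 4, 3), dtype=np.int64)
    for i, (a, b, c) in enumerate(faces):
        ab, bc, ca = m(a, b), m(b, c), m(c, a)
        new_faces[4 * i : 4 * i + 4] = [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
    return new_verts, new_faces


@lru_cache(maxsize=None)
def make_icosphere(level: int) -> SphericalMesh:
    """Build the level-``level`` icosphere (deterministic; cached).

    Raises
    ------
    ValueError
        If ``level`` is negative.
    """
    if level < 0:
        raise ValueError(f"level must be >= 0, got {level}")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES
    for _ in range(level):
        verts, faces = _subdivide(verts, faces)
    rings = _cyclic_rings(verts.shape[0], faces)
    verts.setflags(write=False)
    faces.setflags(write=False)
    return SphericalMesh(vertex_coords=verts, triangles=faces, neighbor_rings=rings, level=level)


def r_ring_indices(mesh: SphericalMesh, center: int, r: int) -> np.ndarray:
    """Ordered r-ring patch: center first, then hop-1..hop-r vertices.

    Ring 1 is the cyclic neighbor ring; each further ring is collected by
    walking the previous ring in order and appending each member's still
    unseen neighbors in their own cyclic order.  The ordering is therefore
    a deterministic function of (mesh, center, r).
    """
    if not 1 <= r <= 7:
        raise ValueError(f"r must be in 1..7, got {r}")
    if not 0 <= center < mesh.n_vertices:
        raise ValueError(f"invalid center {center}")
    out = [center]
    seen = {center}
    ring = list(mesh.neighbor_rings[center])
    for _ in range(r):
        out.extend(ring)
        seen.update(ring)
        nxt: list[int] = []
        for w in ring:
            for u in mesh.neighbor_rings[w]:
                if u not in seen:
                    seen.add(u)
                    nxt.append(u)
        ring = nxt
    return np.asarray(out, dtype=np.int64)


def rotate_ring(mesh: SphericalMesh, center: int, steps: int) -> np.ndarray:
    """Patch rotation about the center: cyclic shift of the 1-ring.

    One step is one ring position — 60° at hexagonal vertices, 72° at the
    twelve pentagonal ones.  ``steps`` must be −1, 0 or +1.  Returns the
    full patch index list (center first) with the ring permuted.
    """
    if steps not in (-1, 0, 1):
        raise ValueError(f"steps must be -1, 0 or +1, got {steps}")
    ring = np.asarray(mesh.neighbor_rings[center], dtype=np.int64)
    return np.concatenate([[center], np.roll(ring, steps)])


def translate_center(mesh: SphericalMesh, center: int, direction: int) -> int:
    """Slide a patch one hop: the ``direction``-th neighbor in cyclic order."""
    ring = mesh.neighbor_rings[center]
    if not 0 <= direction < len(ring):
        raise ValueError(
            f"direction {direction} out of range for degree-{len(ring)} vertex {center}"
        )
    return ring[direction]


def dilate_mask(mesh: SphericalMesh, mask: np.ndarray, iterations: int) -> np.ndarray:
    """Morphological dilation on the mesh graph: each pass marks every
    vertex adjacent to a marked vertex."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = np.asarray(mask, dtype=bool).copy()
    if out.shape != (mesh.n_vertices,):
        raise ValueError("mask length must equal vertex count")
    idx, valid = mesh._neighbor_table
    for _ in range(iterations):
        if out.all():
            break
        out |= (out[idx] & valid).any(axis=1)
    return out


def uniform_subsample(mesh: SphericalMesh, target_count: int) -> np.ndarray:
    """Indices of the embedded lower-level icosphere with ``target_count``
    vertices — by the nesting property, simply the index prefix."""
    k = level_for_vertex_count(target_count)
    if k > mesh.level:
        raise ValueError(
            f"target {target_count} exceeds mesh vertex count {mesh.n_vertices}"
        )
    return np.arange(target_count, dtype=np.int64)


def hop_distances(mesh: SphericalMesh, sources: np.ndarray | list[int]) -> np.ndarray:
    """Multi-source BFS hop distance from ``sources`` to every vertex."""
    dist = np.full(mesh.n_vertices, -1, dtype=np.int64)
    q: deque[int] = deque()
    for s in np.atleast_1d(np.asarray(sources, dtype=np.int64)):
        dist[s] = 0
        q.append(int(s))
    while q:
        v = q.popleft()
        for u in mesh.neighbor_rings[v]:
            if dist[u] < 0:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist
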