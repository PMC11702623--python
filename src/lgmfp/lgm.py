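"""Local gradient maps (LGMs) from surface-mapped BOLD signal.

An LGM summarizes where a scan's functional connectivity changes sharply
on the cortical surface.  The pipeline, per scan:

1. vertex-wise resting-state functional connectivity (RSFC): Pearson
   correlation of every BOLD time-series pair;
2. Fisher r-to-z transform of the RSFC entries;
3. second-order correlation (RSFC-2nd): Pearson correlation between every
   pair of z-scored connectivity rows — transitions are sharper here than
   in the raw RSFC;
4. for each RSFC-2nd row: a surface gradient magnitude map, then
   watershed-by-flooding boundary detection;
5. the LGM is the fraction of rows whose boundary mask marks each vertex.

Maps from anterior-posterior and posterior-anterior acquisitions of one
session are averaged vertex-wise at the end.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .mesh import SphericalMesh, icosphere_vertex_count, level_for_vertex_count

__all__ = [
    "BoldMatrix",
    "VertexMap",
    "LgmProvenance",
    "compute_rsfc",
    "fisher_z",
    "second_order_corr",
    "surface_gradient",
    "watershed_boundaries",
    "compute_lgm",
    "average_session_lgm",
]

#: vertex-count threshold above which compute_lgm streams RSFC-2nd rows
#: in float32 instead of materializing the full matrix (~13 GB at 40k).
STREAMING_THRESHOLD = 8192


@dataclass
class BoldMatrix:
    """One scan's surface-mapped signal: vertices x timepoints.

    ``ped`` tags the phase-encoding direction ("AP", "PA" or "NA").
    """

    values: np.ndarray
    subject_id: str = ""
    session_id: str = ""
    ped: str = "NA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("BOLD matrix must be 2-D with >= 2 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError("BOLD matrix contains non-finite entries")
        if self.ped not in ("AP", "PA", "NA"):
            raise ValueError(f"ped must be AP, PA or NA, got {self.ped!r}")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass
class VertexMap:
    """One scalar per mesh vertex; the universal currency between stages."""

    values: np.ndarray
    kind: str = "generic"
    mesh_level: int = -1

    _KINDS = ("gradient", "lgm", "lcm", "uniqueness", "dp", "generic")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.mesh_level < 0:
            self.mesh_level = level_for_vertex_count(self.values.size)
        elif self.values.size != icosphere_vertex_count(self.mesh_level):
            raise ValueError(
                f"expected {icosphere_vertex_count(self.mesh_level)} values "
                f"for level {self.mesh_level}, got {self.values.size}"
            )
        if self.kind == "lgm" and ((self.values < 0).any() or (self.values > 1).any()):
            raise ValueError("lgm values must lie in [0, 1]")


@dataclass
class LgmProvenance:
    """Degenerate inputs encountered while building an LGM."""

    zero_variance_rows: list[int] = field(default_factory=list)


def compute_rsfc(bold: BoldMatrix, flagged: list[int] | None = None) -> np.ndarray:
    """Vertex-by-vertex Pearson correlation of BOLD time series.

    Zero-variance rows get off-diagonal correlations of 0 (shape is kept);
    their indices are appended to ``flagged`` when a list is passed.
    """
    x = bold.values
    sd = x.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size and flagged is not None:
        flagged.extend(int(i) for i in degenerate)
    xs = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xs, axis=1)
    norm[norm == 0] = 1.0
    xs /= norm[:, None]
    r = xs @ xs.T
    np.clip(r, -1.0, 1.0, out=r)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z: ``0.5 * ln((1+r)/(1-r))`` with |r| clipped to 1 - 1e-7."""
    r_clipped = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    return np.arctanh(r_clipped)


def _standardize_rows(m: np.ndarray, flagged: list[int] | None = None) -> np.ndarray:
    """Center each row and scale to unit norm; constant rows become zero."""
    out = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(out, axis=1)
    degenerate = np.flatnonzero(norm == 0)
    if degenerate.size and flagged is not None:
        flagged.extend(int(i) for i in degenerate)
    norm[norm == 0] = 1.0
    out /= norm[:, None]
    return out


def second_order_corr(z_rsfc: np.ndarray, flagged: list[int] | None = None) -> np.ndarray:
    """Pearson correlation between every pair of connectivity rows.

    Constant rows are flagged and their correlations set to 0 (diagonal 1).
    """
    s = _standardize_rows(np.asarray(z_rsfc, dtype=float), flagged)
    r = s @ s.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def _gradient_arrays(mesh: SphericalMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Padded neighbor table plus inverse chord lengths, cached on the mesh."""
    if not hasattr(mesh, "_grad_cache"):
        idx, valid = mesh._neighbor_table
        chord = np.linalg.norm(
            mesh.vertex_coords[idx] - mesh.vertex_coords[:, None, :], axis=2
        )
        chord[~valid] = 1.0  # pad entries never contribute
        object.__setattr__(mesh, "_grad_cache", (idx, valid, 1.0 / chord))
    return mesh._grad_cache  # type: ignore[attr-defined]


def surface_gradient(values: np.ndarray | VertexMap, mesh: SphericalMesh) -> VertexMap:
    """Per-vertex gradient magnitude of a scalar map.

    Root-mean-square over the 1-ring of the edge-wise finite difference
    ``(f(u) - f(v)) / ||x_u - x_v||``, scaled by sqrt(2): for ring
    directions distributed evenly around the tangent plane the mean squared
    directional derivative is half the squared gradient magnitude, so the
    sqrt(2) factor makes the estimator consistent with the analytic
    tangential gradient.  Rotation-agnostic and strictly local.
    """
    f = values.values if isinstance(values, VertexMap) else np.asarray(values, dtype=float)
    if f.size != mesh.n_vertices:
        raise ValueError("map length must equal mesh vertex count")
    idx, valid, inv_chord = _gradient_arrays(mesh)
    diff = (f[idx] - f[:, None]) * inv_chord
    sq = np.where(valid, diff * diff, 0.0)
    mag = np.sqrt(2.0 * sq.sum(axis=1) / valid.sum(axis=1))
    return VertexMap(mag, kind="gradient", mesh_level=mesh.level)


def watershed_boundaries(
    gradient: np.ndarray | VertexMap, mesh: SphericalMesh
) -> tuple[np.ndarray, np.ndarray]:
    """Watershed by flooding from local minima of a gradient map.

    A vertex is a seed minimum if no neighbor is strictly lower; minima on
    one equal-valued plateau merge into a single seed.  Flooding proceeds in
    increasing (value, vertex index) order; a vertex flooded while its
    already-basin-labeled neighbors carry two or more distinct labels is a
    boundary vertex and joins no basin.

    Returns ``(labels, boundary)`` where ``labels[v]`` is the basin id or
    -1 for boundary vertices and ``boundary`` is the binary boundary mask.
    """
    g = gradient.values if isinstance(gradient, VertexMap) else np.asarray(gradient, dtype=float)
    if not np.isfinite(g).all():
        raise ValueError("gradient map contains non-finite values")
    n = mesh.n_vertices
    rings = mesh.neighbor_rings

    # seed minima, merged across equal-value plateaus (union-find on
    # equal-valued edges)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    is_min = np.ones(n, dtype=bool)
    for v in range(n):
        gv = g[v]
        for u in rings[v]:
            if g[u] < gv:
                is_min[v] = False
            elif g[u] == gv and u < v:
                ra, rb = find(u), find(v)
                if ra != rb:
                    parent[rb] = ra

    labels = np.full(n, -2, dtype=np.int64)  # -2 unvisited, -1 boundary
    seed_label: dict[int, int] = {}
    for v in np.flatnonzero(is_min):
        root = find(int(v))
        if root not in seed_label:
            seed_label[root] = len(seed_label)
        labels[v] = seed_label[root]

    heap: list[tuple[float, int]] = []
    for v in np.flatnonzero(labels >= 0):
        for u in rings[int(v)]:
            if labels[u] == -2:
                heapq.heappush(heap, (g[u], int(u)))
    while heap:
        _, v = heapq.heappop(heap)
        if labels[v] != -2:
            continue
        neighbor_labels = {labels[u] for u in rings[v] if labels[u] >= 0}
        labels[v] = neighbor_labels.pop() if len(neighbor_labels) == 1 else -1
        for u in rings[v]:
            if labels[u] == -2:
                heapq.heappush(heap, (g[u], u))
    return labels, labels == -1


def compute_lgm(
    bold: BoldMatrix,
    mesh: SphericalMesh,
    streaming_threshold: int = STREAMING_THRESHOLD,
    provenance: LgmProvenance | None = None,
) -> VertexMap:
    """Full LGM pipeline for one scan.

    RSFC -> Fisher z -> RSFC-2nd -> per-row gradient + watershed ->
    mean binary boundary map.  Above ``streaming_threshold`` vertices the
    RSFC-2nd matrix is never materialized: its rows are produced one at a
    time from the float32 standardized z-RSFC.
    """
    if bold.n_vertices != mesh.n_vertices:
        raise ValueError(
            f"BOLD has {bold.n_vertices} rows but mesh has {mesh.n_vertices} vertices"
        )
    flags: list[int] = []
    rsfc = compute_rsfc(bold, flagged=flags)
    z = fisher_z(rsfc)
    del rsfc
    stream = mesh.n_vertices > streaming_threshold
    s = _standardize_rows(z.astype(np.float32) if stream else z, flagged=flags)
    del z
    n = mesh.n_vertices
    counts = np.zeros(n, dtype=np.int64)
    if stream:
        for i in range(n):
            row = np.clip(s @ s[i], -1.0, 1.0).astype(float)
            row[i] = 1.0
            grad = surface_gradient(row, mesh)
            _, boundary = watershed_boundaries(grad, mesh)
            counts += boundary
    else:
        r2 = np.clip(s @ s.T, -1.0, 1.0)
        np.fill_diagonal(r2, 1.0)
        for i in range(n):
            grad = surface_gradient(r2[i], mesh)
            _, boundary = watershed_boundaries(grad, mesh)
            counts += boundary
    if provenance is not None:
        provenance.zero_variance_rows = sorted(set(flags))
    return VertexMap(counts / n, kind="lgm", mesh_level=mesh.level)


def average_session_lgm(
    lgm_ap: VertexMap | None, lgm_pa: VertexMap | None
) -> VertexMap:
    """Vertex-wise mean of the AP and PA maps of one session.

    If one acquisition is missing the other map is returned unchanged (the
    single-PED session case).
    """
    if lgm_ap is None and lgm_pa is None:
        raise ValueError("at least one LGM is required")
    if lgm_ap is None:
        return lgm_pa  # type: ignore[return-value]
    if lgm_pa is None:
        return lgm_ap
    if lgm_ap.mesh_level != lgm_pa.mesh_level:
        raise ValueError("mesh levels differ")
    return VertexMap(
        (lgm_ap.values + lgm_pa.values) / 2.0, kind="lgm", mesh_level=lgm_ap.mesh_level
    )
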