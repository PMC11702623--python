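"""Individual identification from local gradient maps.

Two LGMs are compared through a local correlation map (LCM): at every
sampled center vertex v, the Pearson correlation between the two maps'
r-ring patches, C_ij(v) = Corr(P_i^t(v), P_j^b(v)).  Stacking the LCMs of
every target-subject / base-subject pair gives a tensor from which identity
is read out either vertex-wise (each center votes for the base subject with
the highest local correlation; majority vote decides) or by comparing the
mean LCM values.

The deformable variant absorbs residual surface misregistration by taking,
per center, the maximum correlation over the vanilla patch pairing, the
base patch rotated by one ring step in either direction (±60° at hexagonal
vertices) and the base patch translated to each 1-ring neighbor (six
directions at hexagonal vertices).

A conventional connectome fingerprinting baseline (upper-triangle ROI-level
functional connectivity, nearest correlation match) is included for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .lgm import BoldMatrix, VertexMap
from .mesh import SphericalMesh, r_ring_indices

__all__ = [
    "LgmSet",
    "LcmTensor",
    "IdentificationReport",
    "compute_lcm",
    "deformable_lcm",
    "build_lcm_tensor",
    "identify_vertexwise",
    "identify_average",
    "identification_rate",
    "identify_by_network",
    "connectome_vector",
    "identify_connectome",
]


@dataclass
class LgmSet:
    """A role-tagged collection of per-subject LGMs (one session per set)."""

    entries: list[tuple[str, str, VertexMap]]  # (subject_id, session_id, map)
    role: str = "target"

    def __post_init__(self) -> None:
        if self.role not in ("target", "base"):
            raise ValueError(f"role must be 'target' or 'base', got {self.role!r}")
        subjects = [s for s, _, _ in self.entries]
        if len(set(subjects)) != len(subjects):
            raise ValueError("duplicate subject_id within one set")
        levels = {m.mesh_level for _, _, m in self.entries}
        if len(levels) > 1:
            raise ValueError("all maps in a set must share one mesh level")

    @property
    def subject_ids(self) -> list[str]:
        return [s for s, _, _ in self.entries]

    @property
    def maps(self) -> list[VertexMap]:
        return [m for _, _, m in self.entries]


@dataclass
class LcmTensor:
    """n_targets x n_bases x n_centers local correlations C_ij(v)."""

    values: np.ndarray
    centers: np.ndarray
    r: int
    deformable: bool
    target_ids: list[str] = field(default_factory=list)
    base_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.centers = np.asarray(self.centers, dtype=np.int64)
        if self.values.ndim != 3:
            raise ValueError("LCM tensor must be 3-D")
        if self.values.shape[2] != self.centers.size:
            raise ValueError("third axis must match the number of centers")
        if not self.target_ids:
            self.target_ids = [str(i) for i in range(self.values.shape[0])]
        if not self.base_ids:
            self.base_ids = [str(j) for j in range(self.values.shape[1])]


@dataclass
class IdentificationReport:
    """Outcome of one identification run."""

    target_ids: list[str]
    base_ids: list[str]
    predicted_ids: list[str]
    vote_fractions: np.ndarray  # n_targets x n_bases, rows sum to 1
    correct: np.ndarray  # bool per target
    rate_percent: float
    tie_flags: np.ndarray  # bool per target: global vote tie resolved by index
    method: str = "vertex"

    @property
    def n_correct(self) -> int:
        return int(self.correct.sum())

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rate_percent": self.rate_percent,
            "n_targets": len(self.target_ids),
            "n_correct": self.n_correct,
            "targets": [
                {
                    "subject_id": t,
                    "predicted_id": p,
                    "correct": bool(c),
                    "tie": bool(f),
                    "vote_fractions": {
                        b: float(v) for b, v in zip(self.base_ids, row)
                    },
                }
                for t, p, c, f, row in zip(
                    self.target_ids,
                    self.predicted_ids,
                    self.correct,
                    self.tie_flags,
                    self.vote_fractions,
                )
            ],
        }


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation along the last axis; constant rows give 0."""
    ac = a - a.mean(axis=-1, keepdims=True)
    bc = b - b.mean(axis=-1, keepdims=True)
    na = np.linalg.norm(ac, axis=-1)
    nb = np.linalg.norm(bc, axis=-1)
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=-1) / denom
    r = np.where(denom == 0, 0.0, r)
    return np.clip(r, -1.0, 1.0)


def _patch_table(mesh: SphericalMesh, centers: np.ndarray, r: int) -> list[np.ndarray]:
    return [r_ring_indices(mesh, int(c), r) for c in centers]


def compute_lcm(
    lgm_t: VertexMap,
    lgm_b: VertexMap,
    mesh: SphericalMesh,
    centers: np.ndarray,
    r: int = 1,
) -> np.ndarray:
    """Vanilla LCM: per center, Pearson correlation of the two r-ring patches.

    A constant patch on either side yields 0 at that center.
    """
    if lgm_t.mesh_level != lgm_b.mesh_level or lgm_t.mesh_level != mesh.level:
        raise ValueError("mesh levels of the two maps and the mesh must match")
    patches = _patch_table(mesh, np.asarray(centers), r)
    out = np.empty(len(patches))
    for k, idx in enumerate(patches):
        out[k] = _rowwise_pearson(lgm_t.values[idx], lgm_b.values[idx])
    return out


def _deformable_candidates(
    mesh: SphericalMesh, centers: np.ndarray
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate base-patch index tables for the 1-ring deformable strategy.

    Candidates per center are the vanilla patch, the ring rotated one step
    either way (±60° at hexagonal centers), and the 1-ring patch of each
    ring neighbor (patch translation).  A translation candidate whose patch
    length differs from the center's own (pentagon/hexagon mismatch) is
    dropped — the Pearson pairing needs equal-length vectors; its slot is
    padded with the vanilla patch, which never changes the maximum.

    Returns per degree class a pair ``(positions, idx)`` where ``positions``
    indexes into ``centers`` and ``idx`` has shape
    (n_members, n_candidates, patch_len).
    """
    centers = np.asarray(centers, dtype=np.int64)
    degrees = np.array([mesh.degree(int(c)) for c in centers])
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    for d in np.unique(degrees):
        pos = np.flatnonzero(degrees == d)
        idx = np.empty((pos.size, 3 + d, d + 1), dtype=np.int64)
        for m, p in enumerate(pos):
            c = int(centers[p])
            ring = np.asarray(mesh.neighbor_rings[c], dtype=np.int64)
            vanilla = np.concatenate([[c], ring])
            idx[m, 0] = vanilla
            idx[m, 1] = np.concatenate([[c], np.roll(ring, 1)])
            idx[m, 2] = np.concatenate([[c], np.roll(ring, -1)])
            for k, u in enumerate(ring, start=3):
                u_ring = np.asarray(mesh.neighbor_rings[int(u)], dtype=np.int64)
                if u_ring.size == d:
                    idx[m, k] = np.concatenate([[u], u_ring])
                else:
                    idx[m, k] = vanilla
        groups.append((pos, idx))
    return groups


def deformable_lcm(
    lgm_t: VertexMap,
    lgm_b: VertexMap,
    mesh: SphericalMesh,
    centers: np.ndarray,
    r: int = 1,
    _candidates: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> np.ndarray:
    """Deformable LCM: per center, max correlation over the candidate set.

    Defined for 1-ring patches only; by construction never below the
    vanilla LCM at any center.
    """
    if r != 1:
        raise ValueError("the deformable strategy is defined for r = 1 patches")
    if lgm_t.mesh_level != lgm_b.mesh_level or lgm_t.mesh_level != mesh.level:
        raise ValueError("mesh levels of the two maps and the mesh must match")
    centers = np.asarray(centers)
    groups = _candidates if _candidates is not None else _deformable_candidates(mesh, centers)
    t = lgm_t.values
    b = lgm_b.values
    out = np.empty(centers.size)
    for pos, idx in groups:
        target_patches = t[idx[:, 0, :]]  # (m, L): the center's own patch
        base_patches = b[idx]  # (m, n_cand, L)
        out[pos] = _rowwise_pearson(target_patches[:, None, :], base_patches).max(axis=1)
    return out


def build_lcm_tensor(
    targets: LgmSet,
    bases: LgmSet,
    mesh: SphericalMesh,
    centers: np.ndarray,
    r: int = 1,
    deformable: bool = False,
) -> LcmTensor:
    """LCMs for every (target subject, base subject) pair."""
    if not targets.entries or not bases.entries:
        raise ValueError("both sets must be nonempty")
    centers = np.asarray(centers, dtype=np.int64)
    nt, nb = len(targets.entries), len(bases.entries)
    values = np.empty((nt, nb, centers.size))
    if deformable:
        cands = _deformable_candidates(mesh, centers)
        for i, tm in enumerate(targets.maps):
            for j, bm in enumerate(bases.maps):
                values[i, j] = deformable_lcm(tm, bm, mesh, centers, r, _candidates=cands)
    else:
        # vectorized over centers: stack patch values into (n_centers, L)
        # matrices per degree class
        patches = _patch_table(mesh, centers, r)
        lengths = np.array([p.size for p in patches])
        groups = [(L, np.flatnonzero(lengths == L)) for L in np.unique(lengths)]
        for i, tm in enumerate(targets.maps):
            for j, bm in enumerate(bases.maps):
                row = np.empty(centers.size)
                for L, sel in groups:
                    idx = np.stack([patches[k] for k in sel])
                    row[sel] = _rowwise_pearson(tm.values[idx], bm.values[idx])
                values[i, j] = row
    return LcmTensor(
        values=values,
        centers=centers,
        r=r,
        deformable=deformable,
        target_ids=targets.subject_ids,
        base_ids=bases.subject_ids,
    )


def identification_rate(correct: int, total: int) -> float:
    """Percentage of correctly identified targets, half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie in [0, total]")
    pct = Decimal(100 * correct) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _finalize(
    tensor: LcmTensor, votes: np.ndarray, method: str
) -> IdentificationReport:
    """Turn per-target vote counts into a report (argmax, lowest index on tie)."""
    fractions = votes / votes.sum(axis=1, keepdims=True)
    predicted_idx = votes.argmax(axis=1)
    best = votes.max(axis=1)
    ties = (votes == best[:, None]).sum(axis=1) > 1
    predicted = [tensor.base_ids[j] for j in predicted_idx]
    correct = np.array(
        [t == p for t, p in zip(tensor.target_ids, predicted)], dtype=bool
    )
    return IdentificationReport(
        target_ids=list(tensor.target_ids),
        base_ids=list(tensor.base_ids),
        predicted_ids=predicted,
        vote_fractions=fractions,
        correct=correct,
        rate_percent=identification_rate(int(correct.sum()), len(predicted)),
        tie_flags=ties,
        method=method,
    )


def identify_vertexwise(
    tensor: LcmTensor, mask: np.ndarray | None = None
) -> IdentificationReport:
    """Vertex-wise identification: each selected center votes for the base
    subject with the highest local correlation; per-center ties split the
    vote fractionally; majority vote decides (global ties -> lowest index,
    flagged)."""
    vals = tensor.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != vals.shape[2]:
            raise ValueError("mask length must equal the number of centers")
        if not mask.any():
            raise ValueError("mask selects no centers")
        vals = vals[:, :, mask]
    best = vals.max(axis=1, keepdims=True)
    winners = vals == best  # n_t x n_b x n_c
    votes = (winners / winners.sum(axis=1, keepdims=True)).sum(axis=2)
    return _finalize(tensor, votes, "vertex")


def identify_average(tensor: LcmTensor) -> IdentificationReport:
    """Average-based identification: argmax of the mean LCM value."""
    means = tensor.values.mean(axis=2)
    best = means.max(axis=1, keepdims=True)
    votes = (means == best).astype(float)
    votes /= votes.sum(axis=1, keepdims=True)
    return _finalize(tensor, votes, "average")


def identify_by_network(
    tensor: LcmTensor, labels: np.ndarray, network: int
) -> IdentificationReport:
    """Vertex-wise identification restricted to centers in one network."""
    labels = np.asarray(labels)
    mask = labels[tensor.centers] == network
    if not mask.any():
        raise ValueError(f"network {network!r} has no sampled centers")
    report = identify_vertexwise(tensor, mask=mask)
    report.method = f"network:{network}"
    return report


def connectome_vector(bold: BoldMatrix, roi_labels: np.ndarray) -> np.ndarray:
    """Upper-triangle functional connectome of ROI-mean time series.

    ROI order follows sorted label values; the strict upper triangle is
    flattened row-major, giving a length m(m-1)/2 vector for m ROIs.
    """
    roi_labels = np.asarray(roi_labels)
    if roi_labels.size != bold.n_vertices:
        raise ValueError("roi_labels length must equal vertex count")
    regions = np.unique(roi_labels)
    if regions.size < 2:
        raise ValueError("need at least 2 regions")
    series = np.stack([bold.values[roi_labels == g].mean(axis=0) for g in regions])
    fc = np.corrcoef(series)
    iu = np.triu_indices(regions.size, k=1)
    return fc[iu]


def identify_connectome(
    target_vectors: np.ndarray,
    base_vectors: np.ndarray,
    target_ids: list[str] | None = None,
    base_ids: list[str] | None = None,
) -> IdentificationReport:
    """Connectome baseline: nearest base vector by Pearson correlation."""
    t = np.atleast_2d(np.asarray(target_vectors, dtype=float))
    b = np.atleast_2d(np.asarray(base_vectors, dtype=float))
    if t.shape[1] != b.shape[1]:
        raise ValueError("target and base vectors must have equal length")
    target_ids = target_ids or [str(i) for i in range(t.shape[0])]
    base_ids = base_ids or [str(j) for j in range(b.shape[0])]
    sims = _rowwise_pearson(t[:, None, :], b[None, :, :])
    const_t = t.std(axis=1) == 0
    const_b = b.std(axis=1) == 0
    sims[const_t, :] = -np.inf
    sims[:, const_b] = -np.inf
    best = np.nanmax(sims, axis=1, keepdims=True)
    votes = (sims == best).astype(float)
    votes /= np.maximum(votes.sum(axis=1, keepdims=True), 1.0)
    tensor = LcmTensor(
        values=sims[:, :, None],
        centers=np.array([0]),
        r=0,
        deformable=False,
        target_ids=target_ids,
        base_ids=base_ids,
    )
    report = _finalize(tensor, votes, "connectome")
    return report
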