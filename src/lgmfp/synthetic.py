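"""Ground-truthed synthetic cohorts on the icosphere.

The generator emulates the structure the fingerprinting method relies on,
without any imaging data: each subject carries a subject-specific geodesic
Voronoi parcellation of the sphere (individuality comes from jittering the
shared parcel seeds by a few hops), the subject's LGM template is a
smoothed indicator of their parcel borders, and each session's observed
LGM is the template plus independent Gaussian session noise, clipped to
[0, 1].  An optional phase-encoding channel adds a second, tagged noise
draw so AP/PA averaging has something to average.  Parcel-driven BOLD
matrices (shared latent signal per parcel plus vertex noise) exercise the
full RSFC pipeline, and cognitive scores can be coupled linearly to chosen
boundary features for prediction-recovery experiments.

Every quantity is a deterministic function of the cohort spec and its
master seed (seed derivation uses ``numpy.random.SeedSequence`` spawning).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lgm import BoldMatrix, VertexMap
from .mesh import SphericalMesh, hop_distances, make_icosphere
from .prediction import BoundaryAtlas, Boundary, boundary_features

__all__ = [
    "CohortSpec",
    "SimulatedSubject",
    "SimulatedCohort",
    "simulate_parcellation",
    "simulate_bold",
    "simulate_lgm_cohort",
    "simulate_scores",
]


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults follow the desk-scale evaluation conditions used throughout
    the test suite: 20 subjects, two sessions, a level-3 sphere (642
    vertices), six parcels, 2-hop seed jitter between subjects and session
    noise of 0.1 on the unit-amplitude template.
    """

    n_subjects: int = 20
    sessions_per_subject: int = 2
    mesh_level: int = 3
    n_parcels: int = 6
    subject_jitter_hops: int = 2
    session_noise_sigma: float = 0.1
    ped_noise_sigma: float = 0.0  # > 0 adds tagged AP/PA noise draws
    bold_timepoints: int = 200
    bold_snr: float = 5.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.sessions_per_subject, self.n_parcels) < 1:
            raise ValueError("counts must be positive")
        if self.sessions_per_subject < 2:
            raise ValueError("at least two sessions per subject are required")
        if self.session_noise_sigma < 0 or self.ped_noise_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")


@dataclass
class SimulatedSubject:
    subject_id: str
    labels: np.ndarray  # true parcellation
    boundary_mask: np.ndarray  # true parcel-border vertices
    template: VertexMap  # noise-free LGM
    sessions: dict[str, dict[str, VertexMap]]  # session -> ped tag -> map
    bold: dict[str, BoldMatrix] = field(default_factory=dict)


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    subjects: list[SimulatedSubject]
    base_labels: np.ndarray  # jitter-free shared parcellation
    manifest: dict

    def lgm_set_entries(self, session_id: str) -> list[tuple[str, str, VertexMap]]:
        """(subject, session, map) triplets; AP/PA maps averaged per session."""
        out = []
        for s in self.subjects:
            maps = list(s.sessions[session_id].values())
            mean = np.mean([m.values for m in maps], axis=0)
            out.append(
                (s.subject_id, session_id, VertexMap(np.clip(mean, 0, 1), kind="lgm"))
            )
        return out

    def scans(self) -> list[tuple[str, str, VertexMap]]:
        """All (subject, session, session-averaged map) scans, subject-major."""
        out = []
        for s in self.subjects:
            for ses in sorted(s.sessions):
                maps = list(s.sessions[ses].values())
                mean = np.mean([m.values for m in maps], axis=0)
                out.append((s.subject_id, ses, VertexMap(np.clip(mean, 0, 1), kind="lgm")))
        return out


def _voronoi_labels(mesh: SphericalMesh, seeds: np.ndarray) -> np.ndarray:
    """Geodesic (hop-distance) Voronoi labels; equidistant ties go to the
    lowest seed index (multi-source BFS with seeds enqueued in order)."""
    from collections import deque

    labels = np.full(mesh.n_vertices, -1, dtype=np.int64)
    q: deque[int] = deque()
    for i, s in enumerate(seeds):
        labels[s] = i
        q.append(int(s))
    while q:
        v = q.popleft()
        for u in mesh.neighbor_rings[v]:
            if labels[u] < 0:
                labels[u] = labels[v]
                q.append(u)
    return labels


def simulate_parcellation(
    mesh: SphericalMesh,
    k: int,
    seed: int | np.random.Generator,
    jitter_hops: int = 0,
    base_seed_vertices: np.ndarray | None = None,
) -> np.ndarray:
    """Geodesic Voronoi parcellation from k random (optionally jittered) seeds.

    With ``base_seed_vertices`` given, only the jitter is drawn — this is
    how subjects of one cohort share parcel layout while differing locally.
    """
    if k < 2:
        raise ValueError("need at least 2 parcels")
    if k > mesh.n_vertices:
        raise ValueError("more parcels than vertices")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if base_seed_vertices is None:
        seeds = rng.choice(mesh.n_vertices, size=k, replace=False)
    else:
        seeds = np.asarray(base_seed_vertices, dtype=np.int64).copy()
        if seeds.size != k:
            raise ValueError("base_seed_vertices must have length k")
    if jitter_hops > 0:
        for attempt in range(100):
            jittered = np.array(
                [
                    rng.choice(np.flatnonzero(hop_distances(mesh, [s]) <= jitter_hops))
                    for s in seeds
                ]
            )
            if np.unique(jittered).size == k:
                seeds = jittered
                break
        else:
            raise RuntimeError("could not draw distinct jittered seeds")
    return _voronoi_labels(mesh, seeds)


def simulate_bold(
    mesh: SphericalMesh,
    labels: np.ndarray,
    T: int,
    snr: float,
    seed: int | np.random.Generator,
    subject_id: str = "",
    session_id: str = "",
    ped: str = "NA",
) -> BoldMatrix:
    """Parcel-driven BOLD: shared standard-Gaussian latent series per parcel
    plus independent vertex noise with standard deviation 1/snr."""
    if T < 10:
        raise ValueError("need at least 10 timepoints")
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    regions = np.unique(labels)
    latent = rng.standard_normal((regions.size, T))
    region_index = np.searchsorted(regions, labels)
    values = latent[region_index] + rng.standard_normal((labels.size, T)) / snr
    return BoldMatrix(values, subject_id=subject_id, session_id=session_id, ped=ped)


def _boundary_mask(mesh: SphericalMesh, labels: np.ndarray) -> np.ndarray:
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    for v in range(mesh.n_vertices):
        for u in mesh.neighbor_rings[v]:
            if labels[u] != labels[v]:
                mask[v] = True
                break
    return mask


def _smooth(mesh: SphericalMesh, values: np.ndarray, passes: int = 2) -> np.ndarray:
    """1-ring mean filtering (vertex plus its ring), ``passes`` times."""
    idx, valid = mesh._neighbor_table
    out = values.astype(float)
    for _ in range(passes):
        acc = out + np.where(valid, out[idx], 0.0).sum(axis=1)
        out = acc / (1 + valid.sum(axis=1))
    return out


def simulate_lgm_cohort(
    spec: CohortSpec, generate_bold: bool = False
) -> SimulatedCohort:
    """Build a full cohort of subject templates and noisy session maps.

    The subject template is the true parcel-border indicator smoothed by
    two passes of 1-ring averaging and rescaled to [0, 1]; session maps add
    Gaussian noise of ``session_noise_sigma`` and are clipped back to
    [0, 1].  With ``ped_noise_sigma > 0`` each session holds an AP and a PA
    map, each with an extra tagged noise draw.  With ``generate_bold`` each
    (subject, session) also gets a parcel-driven BOLD matrix.
    """
    mesh = make_icosphere(spec.mesh_level)
    root = np.random.SeedSequence(spec.master_seed)
    cohort_rng = np.random.default_rng(root.spawn(1)[0])
    base_seeds = cohort_rng.choice(mesh.n_vertices, size=spec.n_parcels, replace=False)
    base_labels = _voronoi_labels(mesh, base_seeds)

    subjects = []
    subject_seqs = root.spawn(spec.n_subjects)
    for s in range(spec.n_subjects):
        sub_rng = np.random.default_rng(subject_seqs[s])
        labels = simulate_parcellation(
            mesh,
            spec.n_parcels,
            sub_rng,
            jitter_hops=spec.subject_jitter_hops,
            base_seed_vertices=base_seeds,
        )
        border = _boundary_mask(mesh, labels)
        template = _smooth(mesh, border.astype(float), passes=2)
        peak = template.max()
        if peak > 0:
            template = template / peak
        sessions: dict[str, dict[str, VertexMap]] = {}
        bold: dict[str, BoldMatrix] = {}
        for t in range(spec.sessions_per_subject):
            ses = f"S{t + 1}"
            per_ped: dict[str, VertexMap] = {}
            peds = ("AP", "PA") if spec.ped_noise_sigma > 0 else ("NA",)
            session_noise = sub_rng.normal(0.0, spec.session_noise_sigma, mesh.n_vertices)
            for ped in peds:
                values = template + session_noise
                if spec.ped_noise_sigma > 0:
                    values = values + sub_rng.normal(
                        0.0, spec.ped_noise_sigma, mesh.n_vertices
                    )
                per_ped[ped] = VertexMap(
                    np.clip(values, 0.0, 1.0), kind="lgm", mesh_level=spec.mesh_level
                )
            sessions[ses] = per_ped
            if generate_bold:
                bold[ses] = simulate_bold(
                    mesh,
                    labels,
                    spec.bold_timepoints,
                    spec.bold_snr,
                    sub_rng,
                    subject_id=f"sub{s:03d}",
                    session_id=ses,
                )
        subjects.append(
            SimulatedSubject(
                subject_id=f"sub{s:03d}",
                labels=labels,
                boundary_mask=border,
                template=VertexMap(template, kind="lgm", mesh_level=spec.mesh_level),
                sessions=sessions,
                bold=bold,
            )
        )
    manifest = {
        "spec": spec.__dict__.copy(),
        "base_seed_vertices": [int(v) for v in base_seeds],
    }
    return SimulatedCohort(
        spec=spec, subjects=subjects, base_labels=base_labels, manifest=manifest
    )


def design_prediction_study(
    labels: np.ndarray,
    mesh: SphericalMesh,
    n_networks: int = 4,
    dilation_iters: int = 3,
) -> tuple[BoundaryAtlas, list[Boundary], list[Boundary]]:
    """Choose a causal-boundary layout for prediction-recovery experiments.

    Two adjacent region pairs with non-overlapping dilated boundary bands
    become the causal positive and causal negative boundary; their four
    regions form the causal network (network 0) so that all causal signal
    lives in one network, and the remaining regions are distributed
    round-robin over networks 1..n_networks-1.  This gives a ground truth
    in which leaving out network 0 removes the causal boundaries while the
    other networks carry none.
    """
    from .prediction import build_boundary_atlas

    plain = build_boundary_atlas(labels, mesh, dilation_iters=dilation_iters)
    bounds = plain.boundaries
    if len(bounds) < 2:
        raise ValueError("need at least two boundaries to design a causal layout")
    a, b = bounds[0]
    m_ab = plain.boundary_masks[(a, b)]
    candidates = [
        (int((plain.boundary_masks[p] & m_ab).sum()), p)
        for p in bounds
        if not ({*p} & {a, b})
    ]
    if not candidates:
        raise ValueError("no second causal pair disjoint from the first")
    overlap, (e, f) = min(candidates)
    if overlap > 0:
        raise ValueError("causal bands overlap; use more regions or a finer mesh")
    network_of_region = {r: 0 for r in (a, b, e, f)}
    rest = [int(r) for r in np.unique(labels) if int(r) not in (a, b, e, f)]
    for i, r in enumerate(rest):
        network_of_region[r] = 1 + (i % (n_networks - 1))
    atlas = build_boundary_atlas(
        labels, mesh, network_of_region=network_of_region, dilation_iters=dilation_iters
    )
    return atlas, [(a, b)], [(e, f)]


def simulate_scores(
    cohort: SimulatedCohort,
    atlas: BoundaryAtlas,
    causal_positive: list[Boundary],
    causal_negative: list[Boundary],
    effect: float,
    seed: int,
    noise_sd: float | None = None,
    target_r2: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Cognitive scores linearly coupled to chosen boundary features.

    score = effect * (sum of causal positive features) - effect * (sum of
    causal negative features) + Gaussian noise.  Either ``noise_sd`` is
    given directly or ``target_r2`` sets it from the cohort's signal
    variance so the population variance explained equals the target.
    Returns one score per scan (in :meth:`SimulatedCohort.scans` order)
    plus a truth record for recovery tests.
    """
    for b in causal_positive + causal_negative:
        if b not in atlas.boundary_masks:
            raise ValueError(f"unknown boundary {b!r}")
    scans = cohort.scans()
    signal = np.empty(len(scans))
    for i, (_, _, lgm) in enumerate(scans):
        feats = boundary_features(lgm, atlas)
        signal[i] = effect * (
            sum(feats[b] for b in causal_positive)
            - sum(feats[b] for b in causal_negative)
        )
    if noise_sd is None:
        if target_r2 is None or not 0 < target_r2 < 1:
            raise ValueError("give noise_sd or a target_r2 in (0, 1)")
        noise_sd = float(np.sqrt(signal.var() * (1 - target_r2) / target_r2))
    rng = np.random.default_rng(seed)
    scores = signal + rng.normal(0.0, noise_sd, signal.size)
    truth = {
        "causal_positive": causal_positive,
        "causal_negative": causal_negative,
        "effect": effect,
        "noise_sd": noise_sd,
        "signal_variance": float(signal.var()),
        "seed": seed,
    }
    return scores, truth
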