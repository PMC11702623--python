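"""Cognitive score prediction from LGM boundary features.

Features are the mean LGM values over inter-region boundary bands of a
reference parcellation (each band dilated, by default three times, to
absorb residual misalignment between the parcellation and individual
gradients).  Within each training fold, boundaries whose feature correlates
with the score at p < 0.01 are kept and split by correlation sign; the sums
of the positive-set and negative-set features form a two-dimensional
feature on which a small random-forest regressor (20 trees, minimum leaf
size 5) is fitted.  Accuracy is the Pearson correlation between observed
scores and predictions averaged over 10 iterations of 10-fold
cross-validation.  Network contributions count the boundary-band vertices
of selected boundaries per network (a boundary between two networks counts
for both), and a leave-one-network-out rerun measures how much each
network's boundaries matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .lgm import VertexMap
from .mesh import SphericalMesh, dilate_mask

__all__ = [
    "BoundaryAtlas",
    "FeatureTable",
    "CvResult",
    "build_boundary_atlas",
    "boundary_features",
    "select_boundaries",
    "two_dim_feature",
    "rf_cv_predict",
    "network_contribution",
    "leave_one_network_out",
]

Boundary = tuple[int, int]  # unordered region pair, stored (low, high)


@dataclass
class BoundaryAtlas:
    """Parcellation-derived boundary bands and their network assignment."""

    region_labels: np.ndarray
    boundary_masks: dict[Boundary, np.ndarray]
    network_of_region: dict[int, int]
    dilation_iters: int
    mesh_level: int

    @property
    def boundaries(self) -> list[Boundary]:
        return sorted(self.boundary_masks)

    def networks_of_boundary(self, boundary: Boundary) -> set[int]:
        a, b = boundary
        return {self.network_of_region[a], self.network_of_region[b]}

    @property
    def networks(self) -> list[int]:
        return sorted(set(self.network_of_region.values()))


@dataclass
class FeatureTable:
    """Per-scan boundary features plus the cognitive score to predict."""

    features: pd.DataFrame  # rows: scans; columns: Boundary tuples
    scores: np.ndarray  # one score per scan

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if len(self.features) != self.scores.size:
            raise ValueError("one score per scan is required")
        if self.features.isna().any().any() or not np.isfinite(self.scores).all():
            raise ValueError("missing values are not allowed")


@dataclass
class FoldRecord:
    """Audit record of one cross-validation fold."""

    iteration: int
    fold: int
    train_index: np.ndarray
    test_index: np.ndarray
    positive: list[Boundary]
    negative: list[Boundary]
    fallback: bool  # no boundary selected; predicted the training mean


@dataclass
class CvResult:
    """Cross-validated predictions with the full selection audit trail."""

    predictions: np.ndarray  # per-scan, averaged over iterations
    observed: np.ndarray
    r_value: float
    folds: list[FoldRecord]
    candidates: list[Boundary]
    seed: int
    params: dict = field(default_factory=dict)


def build_boundary_atlas(
    labels: np.ndarray,
    mesh: SphericalMesh,
    network_of_region: dict[int, int] | None = None,
    dilation_iters: int = 3,
) -> BoundaryAtlas:
    """Extract the boundary band of every adjacent region pair.

    The undilated band of pair (a, b) contains every vertex of region a or
    b with a 1-ring neighbor in the other region; each band is then dilated
    ``dilation_iters`` times.  Regions without a network map default to one
    network per region.
    """
    labels = np.asarray(labels)
    if labels.size != mesh.n_vertices:
        raise ValueError("labels length must equal mesh vertex count")
    regions = np.unique(labels)
    if regions.size < 2:
        raise ValueError("need at least 2 regions to form boundaries")
    masks: dict[Boundary, np.ndarray] = {}
    for v in range(mesh.n_vertices):
        lv = labels[v]
        for u in mesh.neighbor_rings[v]:
            lu = labels[u]
            if lu != lv:
                key = (int(min(lu, lv)), int(max(lu, lv)))
                if key not in masks:
                    masks[key] = np.zeros(mesh.n_vertices, dtype=bool)
                masks[key][v] = True
                masks[key][u] = True
    masks = {
        k: dilate_mask(mesh, m, dilation_iters) for k, m in sorted(masks.items())
    }
    if network_of_region is None:
        network_of_region = {int(g): int(g) for g in regions}
    return BoundaryAtlas(
        region_labels=labels,
        boundary_masks=masks,
        network_of_region=network_of_region,
        dilation_iters=dilation_iters,
        mesh_level=mesh.level,
    )


def boundary_features(lgm: VertexMap, atlas: BoundaryAtlas) -> dict[Boundary, float]:
    """Mean LGM value over each boundary band."""
    if lgm.mesh_level != atlas.mesh_level:
        raise ValueError("mesh levels of map and atlas differ")
    return {
        b: float(lgm.values[mask].mean())
        for b, mask in atlas.boundary_masks.items()
        if mask.any()
    }


def feature_table(
    lgms: list[VertexMap], scores: np.ndarray, atlas: BoundaryAtlas
) -> FeatureTable:
    """Assemble the scan x boundary feature matrix."""
    rows = [boundary_features(m, atlas) for m in lgms]
    df = pd.DataFrame(rows, columns=atlas.boundaries)
    return FeatureTable(features=df, scores=np.asarray(scores, dtype=float))


def select_boundaries(
    features: pd.DataFrame,
    scores: np.ndarray,
    p_threshold: float = 0.01,
) -> tuple[list[Boundary], list[Boundary]]:
    """Training-set feature selection by correlation significance.

    Each boundary's feature is correlated with the score; boundaries
    reaching two-sided p < ``p_threshold`` (t transform, n - 2 df, no
    multiple-testing correction) are kept and split by correlation sign.
    Constant feature columns are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    if len(features) < 3:
        raise ValueError("need at least 3 training scans")
    if scores.std() == 0:
        raise ValueError("training scores are constant")
    positive: list[Boundary] = []
    negative: list[Boundary] = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        r, p = stats.pearsonr(x, scores)
        if p < p_threshold:
            (positive if r > 0 else negative).append(col)
    return positive, negative


def two_dim_feature(
    features: pd.DataFrame,
    positive: list[Boundary],
    negative: list[Boundary],
) -> np.ndarray:
    """Per scan: (sum of positive-set features, sum of negative-set features)."""
    if not positive and not negative:
        raise ValueError("both selected sets are empty")
    pos = features[positive].sum(axis=1).to_numpy() if positive else np.zeros(len(features))
    neg = features[negative].sum(axis=1).to_numpy() if negative else np.zeros(len(features))
    return np.column_stack([pos, neg])


def rf_cv_predict(
    table: FeatureTable,
    iterations: int = 10,
    folds: int = 10,
    trees: int = 20,
    min_leaf: int = 5,
    seed: int = 0,
    p_threshold: float = 0.01,
    candidates: list[Boundary] | None = None,
) -> CvResult:
    """Repeated k-fold cross-validated random-forest score prediction.

    Per fold, boundary selection and the two-dimensional sum feature are
    computed on training rows only; a regression forest (``trees``
    estimators, ``min_leaf`` minimum samples per leaf) predicts the
    held-out rows.  A fold that selects no boundary falls back to the
    training-mean score.  Per-scan predictions are averaged over
    iterations; ``r_value`` is their Pearson correlation with the observed
    scores.  Fully seeded and bit-reproducible.
    """
    n = len(table.features)
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds number of scans ({n})")
    if np.std(table.scores) == 0:
        raise ValueError("observed scores are constant; r undefined")
    cand = list(candidates) if candidates is not None else list(table.features.columns)
    if not cand:
        raise ValueError("candidate boundary set is empty")
    feats = table.features[cand]
    rng = np.random.default_rng(seed)
    per_iter = np.empty((iterations, n))
    records: list[FoldRecord] = []
    for it in range(iterations):
        iter_seed = int(rng.integers(2**31))
        splitter = KFold(n_splits=folds, shuffle=True, random_state=iter_seed)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
            forest_seed = int(rng.integers(2**31))
            train_feats = feats.iloc[train_idx]
            train_scores = table.scores[train_idx]
            pos, neg = select_boundaries(train_feats, train_scores, p_threshold)
            fallback = not pos and not neg
            if fallback:
                per_iter[it, test_idx] = train_scores.mean()
            else:
                x_train = two_dim_feature(train_feats, pos, neg)
                x_test = two_dim_feature(feats.iloc[test_idx], pos, neg)
                model = RandomForestRegressor(
                    n_estimators=trees,
                    min_samples_leaf=min_leaf,
                    bootstrap=True,
                    random_state=forest_seed,
                )
                model.fit(x_train, train_scores)
                per_iter[it, test_idx] = model.predict(x_test)
            records.append(
                FoldRecord(
                    iteration=it,
                    fold=fold,
                    train_index=train_idx.copy(),
                    test_index=test_idx.copy(),
                    positive=pos,
                    negative=neg,
                    fallback=fallback,
                )
            )
    predictions = per_iter.mean(axis=0)
    if predictions.std() == 0:
        r_value = 0.0
    else:
        r_value = float(stats.pearsonr(predictions, table.scores)[0])
    return CvResult(
        predictions=predictions,
        observed=table.scores.copy(),
        r_value=r_value,
        folds=records,
        candidates=cand,
        seed=seed,
        params={
            "iterations": iterations,
            "folds": folds,
            "trees": trees,
            "min_leaf": min_leaf,
            "p_threshold": p_threshold,
        },
    )


def network_contribution(
    cv: CvResult, atlas: BoundaryAtlas
) -> dict[int, dict[str, float]]:
    """Fraction of each network's boundary-band vertices selected, averaged
    over folds, for the positive and negative sets separately.

    A boundary between two networks contributes its band vertex count to
    both networks' numerators (and denominators).  Networks with no
    boundary-band vertices among the candidates are omitted.
    """
    sizes = {b: int(atlas.boundary_masks[b].sum()) for b in cv.candidates}
    totals: dict[int, int] = {}
    for b in cv.candidates:
        for net in atlas.networks_of_boundary(b):
            totals[net] = totals.get(net, 0) + sizes[b]
    out: dict[int, dict[str, float]] = {}
    for net, total in sorted(totals.items()):
        if total == 0:
            continue
        fracs = {"positive": [], "negative": []}
        for rec in cv.folds:
            for key, selected in (("positive", rec.positive), ("negative", rec.negative)):
                count = sum(
                    sizes[b] for b in selected if net in atlas.networks_of_boundary(b)
                )
                fracs[key].append(count / total)
        out[net] = {k: float(np.mean(v)) for k, v in fracs.items()}
    return out


def leave_one_network_out(
    table: FeatureTable,
    atlas: BoundaryAtlas,
    held_out_network: int,
    **rf_kwargs,
) -> float:
    """r-value with every boundary touching one network removed.

    A lower value than the full model indicates the held-out network's
    boundaries carry predictive information.
    """
    if held_out_network not in atlas.networks:
        raise ValueError(f"network {held_out_network!r} not in atlas")
    keep = [
        b
        for b in table.features.columns
        if held_out_network not in atlas.networks_of_boundary(b)
    ]
    if not keep:
        raise ValueError("holding out this network removes every boundary")
    return rf_cv_predict(table, candidates=keep, **rf_kwargs).r_value
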