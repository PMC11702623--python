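"""Vertex-wise contributions to identification: uniqueness and
differential power.

Both statistics consume a paired-cohort LCM tensor: entry (i, j, v) is the
local correlation at center v between subject i's target-session LGM and
subject j's base-session LGM, with the same subject order on both axes, so
the diagonal holds the within-subject (intra) correlations.

Uniqueness regresses the inter-individual variability 1 - C_inter(v) on the
intra-individual variability 1 - C_intra(v) across centers by ordinary
least squares; the residual U(v) is high where subjects differ from each
other yet agree with themselves across sessions.

Differential power at center v for subject i counts how often the
self-match C_ii(v) is beaten by a cross-subject correlation C_ij(v) or
C_ji(v) over the 2(N-1) comparisons, and takes the negative log of that
empirical probability; perfectly separating centers (zero count) use a 0.5
continuity correction instead of an infinite value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fingerprint import LcmTensor

__all__ = [
    "UniquenessResult",
    "mean_intra",
    "mean_inter",
    "uniqueness_map",
    "differential_power",
    "network_summary",
]


def _paired_values(tensor: LcmTensor | np.ndarray) -> np.ndarray:
    vals = tensor.values if isinstance(tensor, LcmTensor) else np.asarray(tensor, dtype=float)
    if vals.ndim != 3 or vals.shape[0] != vals.shape[1]:
        raise ValueError("paired cohort tensor must be n x n x n_centers")
    if isinstance(tensor, LcmTensor) and tensor.target_ids != tensor.base_ids:
        raise ValueError("subject order must be identical on both axes")
    return vals


@dataclass
class UniquenessResult:
    """Uniqueness map with its fitted regression parameters."""

    u: np.ndarray  # per-center residual
    alpha: float  # slope on 1 - C_intra
    beta: float  # intercept


def mean_intra(tensor: LcmTensor | np.ndarray) -> np.ndarray:
    """C_intra(v): mean of the within-subject (diagonal) LCMs."""
    vals = _paired_values(tensor)
    n = vals.shape[0]
    return vals[np.arange(n), np.arange(n), :].mean(axis=0)


def mean_inter(tensor: LcmTensor | np.ndarray) -> np.ndarray:
    """C_inter(v): mean of the n(n-1) between-subject LCMs."""
    vals = _paired_values(tensor)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for inter-individual maps")
    total = vals.sum(axis=(0, 1)) - vals[np.arange(n), np.arange(n), :].sum(axis=0)
    return total / (n * (n - 1))


def uniqueness_map(tensor: LcmTensor | np.ndarray) -> UniquenessResult:
    """OLS residual of inter- on intra-individual variability.

    Regresses y(v) = 1 - C_inter(v) on x(v) = 1 - C_intra(v) across
    centers; U(v) = y(v) - alpha * x(v) - beta.
    """
    x = 1.0 - mean_intra(tensor)
    y = 1.0 - mean_inter(tensor)
    if np.ptp(x) == 0:
        raise ValueError("1 - C_intra is constant across centers; slope undefined")
    xc = x - x.mean()
    alpha = float((xc * (y - y.mean())).sum() / (xc * xc).sum())
    beta = float(y.mean() - alpha * x.mean())
    return UniquenessResult(u=y - alpha * x - beta, alpha=alpha, beta=beta)


def differential_power(
    tensor: LcmTensor | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject and population differential power maps.

    DP_i(v) = -ln[(c1 + c2) / (2(N-1))] with c1 = #{j != i : C_ii(v) <
    C_ij(v)} and c2 = #{j != i : C_ii(v) < C_ji(v)}; a zero count is
    replaced by 0.5 before the division.  The population map is the sum of
    the per-subject maps.
    """
    vals = _paired_values(tensor)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for differential power")
    diag = vals[np.arange(n), np.arange(n), :]  # n x c
    # diagonal terms compare a value with itself (strict <, never counted)
    c1 = (diag[:, None, :] < vals).sum(axis=1)
    c2 = (diag[:, None, :] < vals.transpose(1, 0, 2)).sum(axis=1)
    counts = (c1 + c2).astype(float)
    counts[counts == 0] = 0.5
    dp_i = -np.log(counts / (2 * (n - 1)))
    return dp_i, dp_i.sum(axis=0)


def network_summary(
    values: np.ndarray, labels: np.ndarray
) -> dict[object, tuple[float, float]]:
    """Per-network mean and standard deviation of a per-center map.

    ``labels`` gives the network id of each sampled center.  Networks
    without members simply do not appear in the result.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    out: dict[object, tuple[float, float]] = {}
    for g in np.unique(labels):
        member = values[labels == g]
        key = g.item() if hasattr(g, "item") else g
        out[key] = (float(member.mean()), float(member.std()))
    return out
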