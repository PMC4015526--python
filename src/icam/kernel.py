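"""Gaussian affinity graphs and column-stochastic transition matrices.

Both classification channels share the same construction: pairwise node
affinities a_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)) computed from some
per-node feature vectors (attribute vectors for one channel, neighbor-label
count vectors for the other), followed by column normalization into a
Markov transition matrix whose columns are outgoing transition
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = ["AffinityMatrix", "gaussian_affinity", "column_normalize", "median_bandwidth"]


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric nonnegative affinity matrix together with the bandwidth used."""

    A: np.ndarray
    sigma: float


def _standardize(X: np.ndarray) -> np.ndarray:
    # z-score per feature; constant features are centered only
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def median_bandwidth(X: np.ndarray) -> float:
    """Median of the nonzero pairwise Euclidean distances (median heuristic).

    Raises if every pairwise distance is zero (all rows identical): the
    Gaussian kernel is then undefined under the heuristic and an explicit
    bandwidth must be supplied.
    """
    d = pdist(X)
    nz = d[d > 0]
    if nz.size == 0:
        raise ValueError(
            "all feature rows are identical; the median-distance heuristic is "
            "undefined — pass an explicit sigma"
        )
    return float(np.median(nz))


def gaussian_affinity(
    X,
    sigma: float | str = "auto",
    sparsify_k: int | None = None,
    standardize: bool = True,
    self_affinity: bool = False,
) -> AffinityMatrix:
    """Pairwise Gaussian-kernel affinities between feature rows.

    Parameters
    ----------
    X
        ``m x p`` array (or :class:`~icam.graph_io.FeatureMatrix`).
    sigma
        Kernel bandwidth, or ``"auto"`` for the median of nonzero pairwise
        distances.
    sparsify_k
        If given, keep only the ``k`` largest entries of each column and
        symmetrize by elementwise max; the dense matrix is quadratic in
        memory so this matters for large graphs.
    standardize
        Z-score each feature before computing distances.  The Euclidean
        distance is scale-sensitive; leave off for features already on a
        common scale (e.g. normalized sparse features or label counts).
    self_affinity
        Keep the exp(0) = 1 diagonal instead of zeroing it.  With a zero
        diagonal the restart walk cannot idle on a node, which empirically
        propagates labels further; this is the default.
    """
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an m x p feature array with m >= 2")
    if standardize:
        X = _standardize(X)
    if sigma == "auto":
        sigma = median_bandwidth(X)
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    sq = squareform(pdist(X, metric="sqeuclidean"))
    A = np.exp(-sq / (2.0 * sigma**2))
    if not self_affinity:
        np.fill_diagonal(A, 0.0)

    if sparsify_k is not None:
        m = A.shape[0]
        k = int(sparsify_k)
        if k < 1:
            raise ValueError("sparsify_k must be >= 1")
        k = min(k, m - 1)
        keep = np.zeros_like(A, dtype=bool)
        # k largest per column, then symmetrize by max (here: union of masks,
        # identical because A is symmetric)
        idx = np.argpartition(-A, kth=k - 1, axis=0)[:k, :]
        keep[idx, np.arange(m)[None, :]] = True
        keep |= keep.T
        A = np.where(keep, A, 0.0)

    return AffinityMatrix(A=A, sigma=sigma)


def column_normalize(A) -> np.ndarray:
    """Normalize columns of a nonnegative matrix to sum to one.

    Zero columns (isolated nodes after sparsification) are replaced by the
    uniform distribution 1/m so the result is always column-stochastic.
    """
    A = np.asarray(getattr(A, "A", A), dtype=float)
    if (A < 0).any():
        raise ValueError("affinity matrix must be nonnegative")
    m = A.shape[0]
    colsum = A.sum(axis=0)
    zero = colsum == 0.0
    if zero.any():
        logger.warning("replacing %d zero column(s) with the uniform distribution", int(zero.sum()))
    P = np.empty_like(A)
    nzcols = ~zero
    P[:, nzcols] = A[:, nzcols] / colsum[nzcols]
    P[:, zero] = 1.0 / m
    return P
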