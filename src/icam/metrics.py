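"""Multi-label ranking metrics: coverage, ranking loss, one-error, average
precision (reported as 1 - AP), plus ROC AUC for binary tasks.

All four ranking metrics are "smaller is better" once average precision is
reported as its complement.  Conventions, applied exactly:

* rank 1 is the highest score; rank assignment breaks score ties toward
  the lower class index so every ranking is deterministic;
* ranking loss counts a (true, false) label pair as mis-ordered when the
  true label's score is <= the false label's score — ties count against
  the ranking;
* rows without a true label (or, for ranking loss, without both a true and
  a false label) cannot be scored and are excluded with an explicit count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph_io import LabelTable

__all__ = [
    "EvalResult",
    "ranks_from_scores",
    "coverage",
    "ranking_loss",
    "one_error",
    "average_precision",
    "roc_auc",
    "evaluate",
]


@dataclass(frozen=True)
class EvalResult:
    coverage: float
    ranking_loss: float
    one_error: float
    one_minus_avg_precision: float
    n: int
    n_excluded: int

    def as_dict(self) -> dict:
        return {
            "coverage": self.coverage,
            "ranking_loss": self.ranking_loss,
            "one_error": self.one_error,
            "one_minus_avg_precision": self.one_minus_avg_precision,
            "n": self.n,
            "n_excluded": self.n_excluded,
        }


def _truth_matrix(truth) -> np.ndarray:
    if isinstance(truth, LabelTable):
        return truth.Y.astype(bool)
    return np.asarray(truth).astype(bool)


def ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    """1-based rank of every class per row; rank 1 = highest score.

    Ties broken by lower class index, so ranks within a row are always a
    permutation of 1..c.
    """
    scores = np.asarray(scores, dtype=float)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    m, c = scores.shape
    # stable argsort of -scores puts equal scores in class-index order
    order = np.argsort(-scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(m)[:, None]
    ranks[rows, order] = np.arange(1, c + 1)[None, :]
    return ranks


def coverage(scores, truth) -> float:
    """Mean depth down the ranked list needed to cover all true labels.

    Per instance: (max rank among true labels) - 1; a perfect single-label
    ranking scores 0.
    """
    Y = _truth_matrix(truth)
    keep = Y.any(axis=1)
    if not keep.any():
        raise ValueError("no instance has a true label")
    ranks = ranks_from_scores(np.asarray(scores, dtype=float)[keep])
    Yk = Y[keep]
    worst = np.where(Yk, ranks, 0).max(axis=1)
    return float(np.mean(worst - 1))


def ranking_loss(scores, truth) -> float:
    """Mean fraction of (true, false) label pairs ordered incorrectly.

    A pair counts when score(true) <= score(false).  Instances lacking
    either a true or a false label are skipped.
    """
    S = np.asarray(scores, dtype=float)
    Y = _truth_matrix(truth)
    keep = Y.any(axis=1) & (~Y).any(axis=1)
    if not keep.any():
        raise ValueError("no instance has both a true and a false label")
    vals = []
    for i in np.flatnonzero(keep):
        t = S[i, Y[i]]
        f = S[i, ~Y[i]]
        bad = (t[:, None] <= f[None, :]).sum()
        vals.append(bad / (t.size * f.size))
    return float(np.mean(vals))


def one_error(scores, truth) -> float:
    """Fraction of instances whose top-ranked label is not a true label."""
    S = np.asarray(scores, dtype=float)
    Y = _truth_matrix(truth)
    keep = Y.any(axis=1)
    if not keep.any():
        raise ValueError("no instance has a true label")
    ranks = ranks_from_scores(S[keep])
    top = np.argmin(ranks, axis=1)  # the rank-1 class (tie rule already applied)
    hit = Y[keep][np.arange(keep.sum()), top]
    return float(np.mean(~hit))


def average_precision(scores, truth) -> float:
    """Multi-label average precision (larger is better).

    Per instance, for each true label l: the fraction of labels ranked at
    or above l that are themselves true, i.e. |P_i(l)| / rank(l); averaged
    over the true labels and then over instances.  Reports are usually
    given as 1 - AP so that smaller is better, see :func:`evaluate`.
    """
    S = np.asarray(scores, dtype=float)
    Y = _truth_matrix(truth)
    keep = Y.any(axis=1)
    if not keep.any():
        raise ValueError("no instance has a true label")
    ranks = ranks_from_scores(S[keep])
    Yk = Y[keep]
    vals = []
    for i in range(Yk.shape[0]):
        r_true = ranks[i][Yk[i]]
        prec = [(r_true <= r).sum() / r for r in r_true]
        vals.append(np.mean(prec))
    return float(np.mean(vals))


def roc_auc(scores, truth) -> float:
    """Area under the ROC curve via the midrank (Mann-Whitney) statistic."""
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(truth).astype(bool).ravel()
    if s.shape != y.shape:
        raise ValueError("scores and truth must have the same length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present")
    r = rankdata(s)  # midranks on ties
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(scores, truth, per_instance: bool = False):
    """All four ranking metrics in one report.

    Rows without any true label are excluded from every metric (counted in
    ``n_excluded``); rows that are all-true additionally drop out of the
    ranking-loss average.  With ``per_instance=True`` also returns a
    DataFrame of per-instance metric values.
    """
    S = np.asarray(scores, dtype=float)
    Y = _truth_matrix(truth)
    keep = Y.any(axis=1)
    n_excluded = int((~keep).sum())
    res = EvalResult(
        coverage=coverage(S[keep], Y[keep]),
        ranking_loss=ranking_loss(S[keep], Y[keep]),
        one_error=one_error(S[keep], Y[keep]),
        one_minus_avg_precision=1.0 - average_precision(S[keep], Y[keep]),
        n=int(keep.sum()),
        n_excluded=n_excluded,
    )
    if not per_instance:
        return res
    rows = []
    for i in np.flatnonzero(keep):
        yi = Y[i : i + 1]
        si = S[i : i + 1]
        row = {"instance": int(i), "coverage": coverage(si, yi), "one_error": one_error(si, yi), "avg_precision": average_precision(si, yi)}
        row["ranking_loss"] = ranking_loss(si, yi) if (~yi).any() else np.nan
        rows.append(row)
    return res, pd.DataFrame(rows)
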