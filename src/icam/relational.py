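"""Relational feature construction: summarizing neighbor label information.

The classic iterative-classification aggregation step.  For each node the
relational feature vector holds, per class, the evidence carried by its
direct neighbors: in hard mode the count of neighbors currently bearing
that class (a node with two positive and two negative neighbors in a
binary task gets the row <2, 2>); in soft mode the sum of the neighbors'
row-normalized score distributions, which avoids committing to hard labels
early in the inference loop.
"""

from __future__ import annotations

import numpy as np

from .graph_io import LabelTable, Network

__all__ = ["aggregate", "harden", "row_normalize"]


def row_normalize(S: np.ndarray) -> np.ndarray:
    """Scale each row to sum to one; all-zero rows are left as zeros."""
    S = np.asarray(S, dtype=float)
    rs = S.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rs > 0, S / np.where(rs == 0, 1.0, rs), 0.0)
    return out


def aggregate(network: Network, labels_current, mode: str = "hard", normalize_by_degree: bool = False) -> np.ndarray:
    """Aggregate neighbor label evidence into an ``m x c`` relational matrix.

    Parameters
    ----------
    network
        The interaction graph; only direct (1-hop) neighbors contribute.
    labels_current
        Hard mode: a :class:`LabelTable` (or 0/1 array) covering all m
        nodes — known labels fixed, unknown nodes carrying the current
        predictions.  Soft mode: an ``m x c`` score matrix; rows are
        normalized to distributions before summation.
    mode
        ``"hard"`` counts neighbors per class; ``"soft"`` sums neighbor
        score distributions.
    normalize_by_degree
        Divide each row by the node degree (isolated nodes untouched);
        counts are raw by default.
    """
    if mode not in ("hard", "soft"):
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    if isinstance(labels_current, LabelTable):
        M = labels_current.Y.astype(float)
    else:
        M = np.asarray(labels_current, dtype=float)
    if M.shape[0] != network.m:
        raise ValueError("labels_current must cover all nodes")
    if mode == "soft":
        M = row_normalize(M)
    adj = network.adjacency()
    X_R = np.asarray(adj @ M)
    if normalize_by_degree:
        deg = network.degrees().astype(float)
        deg[deg == 0] = 1.0
        X_R = X_R / deg[:, None]
    return X_R


def harden(scores: np.ndarray, labels: LabelTable, k_policy: str = "topk", k_or_tau=1) -> LabelTable:
    """Turn ranked scores into hard label sets for the unknown nodes.

    Known nodes keep their true labels untouched — collective inference
    only ever updates the unknown part.  Policies:

    * ``topk``: each unknown node receives its k top-scoring classes,
      score ties broken toward the lower class index.
    * ``threshold``: classes whose row-normalized score is >= tau, with a
      minimum of one class (the argmax).
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    m, c = scores.shape
    if (m, c) != (labels.m, labels.c):
        raise ValueError("scores shape must match the label table")
    Y = labels.Y.copy()
    unknown = ~labels.known_mask

    if k_policy == "topk":
        k = int(k_or_tau)
        if k < 1:
            raise ValueError("k must be >= 1")
        k = min(k, c)
        # stable sort on -scores: equal scores keep ascending class order
        order = np.argsort(-scores, axis=1, kind="stable")
        hard = np.zeros_like(Y)
        rows = np.arange(m)[:, None]
        hard[rows, order[:, :k]] = 1
    elif k_policy == "threshold":
        tau = float(k_or_tau)
        if not 0.0 < tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        norm = row_normalize(scores)
        hard = (norm >= tau).astype(np.int8)
        top = np.argmax(scores, axis=1)  # first max = lowest class index on ties
        hard[np.arange(m), top] = 1
    else:
        raise ValueError(f"unknown hardening policy {k_policy!r}")

    Y[unknown] = hard[unknown]
    return LabelTable(Y=Y, known_mask=labels.known_mask)
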