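"""Walktrap community detection and weighted modularity.

Symptom clusters are read off the estimated network as communities: groups
of nodes a short random walk tends to stay inside.  Random walks need
non-negative capacities, so absolute edge weights are used; the number of
sign-flipped edges is reported so the caller can judge whether that
mattered (estimated symptom networks typically contain only a handful of
negative edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .datatypes import ValidationError
from .centrality import _validate_weights


def modularity(weights: np.ndarray, labels: np.ndarray | dict) -> float:
    """Newman weighted modularity Q = sum_c (e_c/m - (d_c/2m)^2) on
    absolute edge weights; m is the total absolute edge weight."""
    w = np.abs(_validate_weights(weights))
    p = w.shape[0]
    if isinstance(labels, dict):
        missing = [k for k in labels if not (0 <= int(k) < p)]
        if missing:
            raise ValidationError(f"labels name unknown node(s): {missing}")
        if len(labels) != p:
            raise ValidationError("labels must cover all nodes")
        lab = np.array([labels[i] for i in range(p)])
    else:
        lab = np.asarray(labels)
        if lab.shape != (p,):
            raise ValidationError("labels must cover all nodes")
    m = w.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(lab):
        mask = lab == c
        e_c = w[np.ix_(mask, mask)].sum() / 2.0
        d_c = w[mask].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


@dataclass
class CommunityPartition:
    """Result of walktrap clustering: node labels, merge history, and the
    modularity of the returned cut."""

    labels: np.ndarray  # node -> community id (0-based, order of appearance)
    n_communities: int
    merge_history: list[tuple[int, int, float]]
    modularity: float
    steps: int
    metadata: dict = field(default_factory=dict)


def _canonical_labels(membership: list[int]) -> np.ndarray:
    seen: dict[int, int] = {}
    out = np.empty(len(membership), dtype=np.int64)
    for i, c in enumerate(membership):
        if c not in seen:
            seen[c] = len(seen)
        out[i] = seen[c]
    return out


def walktrap_partition(weights: np.ndarray, steps: int = 4) -> CommunityPartition:
    """Walktrap clustering of a weighted network.

    Absolute weights serve as random-walk capacities; the merge-history
    cut maximizing weighted modularity is returned.  Isolated nodes come
    out as singleton communities.
    """
    w = _validate_weights(weights)
    absw = np.abs(w)
    if not np.any(absw > 0):
        raise ValidationError("all-zero weight matrix: no random walk defined")
    n_negative = int(np.sum(np.triu(w, 1) < 0))

    g = ig.Graph.Weighted_Adjacency(
        absw.tolist(), mode="undirected", attr="weight", loops=False
    )
    dend = g.community_walktrap(weights="weight", steps=steps)
    clustering = dend.as_clustering()  # cut at maximum modularity
    labels = _canonical_labels(clustering.membership)
    merges = []
    for a, b in dend.merges:
        merges.append((int(a), int(b), float("nan")))
    q = modularity(w, labels)
    return CommunityPartition(
        labels=labels,
        n_communities=int(labels.max()) + 1,
        merge_history=merges,
        modularity=q,
        steps=steps,
        metadata={"n_negative_edges_absed": n_negative},
    )
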