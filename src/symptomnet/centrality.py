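"""Weighted centrality indices: strength, closeness, betweenness.

Edge weights in an estimated network measure association strength;
shortest paths are therefore computed on reciprocal absolute weights
(stronger association = shorter distance), the convention of the weighted
network literature.  Strength is the sum of absolute incident weights;
closeness the inverse of the summed shortest-path distance to all
reachable nodes (0 for isolated nodes); betweenness the number of
shortest paths through a node, with fractional credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ValidationError


def _validate_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValidationError("weight matrix must be symmetric")
    if not np.allclose(np.diag(w), 0.0):
        raise ValidationError("weight matrix must have a zero diagonal")
    return w


def weights_to_distances(weights: np.ndarray) -> np.ndarray:
    """Distance matrix 1/|w_jk| (infinite where there is no edge, zero on
    the diagonal)."""
    w = _validate_weights(weights)
    with np.errstate(divide="ignore"):
        d = 1.0 / np.abs(w)
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class CentralityTable:
    """Per-node centralities plus z-standardized versions."""

    table: pd.DataFrame  # columns: strength, closeness, betweenness, z_*

    @property
    def nodes(self) -> list[str]:
        return list(self.table.index)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.table[column].to_numpy()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def centrality_indices(
    weights: np.ndarray, node_names: list[str] | None = None
) -> CentralityTable:
    w = _validate_weights(weights)
    p = w.shape[0]
    names = node_names if node_names is not None else [f"s{i:02d}" for i in range(p)]
    strength = np.abs(w).sum(axis=1)

    G = nx.Graph()
    G.add_nodes_from(range(p))
    jj, kk = np.nonzero(np.triu(w, 1))
    for j, k in zip(jj, kk):
        G.add_edge(int(j), int(k), distance=1.0 / abs(w[j, k]))

    closeness = np.zeros(p)
    for j in range(p):
        lengths = nx.single_source_dijkstra_path_length(G, j, weight="distance")
        total = sum(d for node, d in lengths.items() if node != j)
        closeness[j] = 1.0 / total if total > 0 else 0.0

    bet = nx.betweenness_centrality(G, weight="distance", normalized=False)
    betweenness = np.array([bet[j] for j in range(p)])

    df = pd.DataFrame(
        {
            "strength": strength,
            "closeness": closeness,
            "betweenness": betweenness,
            "z_strength": _zscore(strength),
            "z_closeness": _zscore(closeness),
            "z_betweenness": _zscore(betweenness),
        },
        index=pd.Index(names, name="node"),
    )
    return CentralityTable(table=df)
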