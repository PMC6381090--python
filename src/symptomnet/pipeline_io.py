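"""File I/O and end-to-end orchestration of one dimension analysis.

A run reads (or receives) an item-response matrix, dispatches to the
estimator the dimension calls for — eLasso Ising for binary occurrence
data, polychoric + glasso for ordinal severity/distress data — and then
computes density, centralities and, on request, walktrap communities,
bootstrap stability and a force-directed layout.  Every output is a pure
function of (input data, config), so a rerun with the same seed
reproduces results byte-for-byte.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .centrality import CentralityTable, centrality_indices, _validate_weights
from .community import CommunityPartition, walktrap_partition
from .datatypes import (
    CATEGORY_RANGE,
    AnalysisConfig,
    ItemResponseMatrix,
    ValidationError,
)
from .ising_net import IsingNetwork, fit_ising
from .ordinal_net import GaussianNetwork, fit_ggm, polychoric_matrix
from .stability import StabilityReport, bootstrap_edges, subset_stability

logger = logging.getLogger("symptomnet")


class ParseError(ValueError):
    """Raised when a response CSV cannot be parsed."""


def read_responses(path: str | Path, dimension: str) -> ItemResponseMatrix:
    """Read a respondents x symptoms CSV (header row of symptom codes,
    integer cells).  Rows containing any missing cell are dropped and the
    count logged; non-integer or out-of-range cells raise errors naming
    the offending row and column."""
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate header names {dupes}")
    lo, hi = CATEGORY_RANGE[dimension]
    parsed: list[list[int]] = []
    n_dropped = 0
    for r, row in enumerate(rows[1:], start=2):  # 1-based incl. header
        if len(row) != len(header):
            raise ParseError(f"{path}: row {r} has {len(row)} cells, expected {len(header)}")
        cells = [c.strip() for c in row]
        if any(c == "" or c.upper() in ("NA", "NAN") for c in cells):
            n_dropped += 1
            continue
        out = []
        for c, cell in enumerate(cells):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-integer cell at row {r}, column {header[c]!r}: {cell!r}"
                ) from None
            if v != int(v):
                raise ParseError(
                    f"{path}: non-integer cell at row {r}, column {header[c]!r}: {cell!r}"
                )
            v = int(v)
            if not lo <= v <= hi:
                raise ValidationError(
                    f"{path}: value {v} at row {r}, column {header[c]!r} outside "
                    f"the {dimension} range [{lo}, {hi}]"
                )
            out.append(v)
        parsed.append(out)
    if n_dropped:
        logger.info("%s: dropped %d row(s) with missing cells", path, n_dropped)
    return ItemResponseMatrix(
        np.asarray(parsed, dtype=np.int64), header, dimension
    )


def layout_fr(weights: np.ndarray, seed: int) -> np.ndarray:
    """Deterministic Fruchterman-Reingold coordinates (p x 2); absolute
    weights act as attraction strengths, so strongly connected nodes land
    close together."""
    w = _validate_weights(weights)
    p = w.shape[0]
    if p == 1:
        return np.zeros((1, 2))
    G = nx.Graph()
    G.add_nodes_from(range(p))
    jj, kk = np.nonzero(np.triu(w, 1))
    for j, k in zip(jj, kk):
        G.add_edge(int(j), int(k), absweight=abs(w[j, k]))
    pos = nx.spring_layout(G, weight="absweight", seed=seed)
    return np.array([pos[i] for i in range(p)])


@dataclass
class DimensionResult:
    """Everything computed for one symptom dimension."""

    dimension: str
    network: IsingNetwork | GaussianNetwork
    centrality: CentralityTable
    density: float
    symptom_codes: list[str]
    partition: CommunityPartition | None = None
    stability: dict[str, object] = field(default_factory=dict)
    layout: np.ndarray | None = None
    config: AnalysisConfig | None = None

    @property
    def weights(self) -> np.ndarray:
        if isinstance(self.network, IsingNetwork):
            return self.network.weights
        return self.network.partial_corr


def network_density(weights: np.ndarray) -> float:
    """Fraction of the p(p-1)/2 possible edges with nonzero weight."""
    p = weights.shape[0]
    iu = np.triu_indices(p, 1)
    return float(np.count_nonzero(weights[iu]) / (p * (p - 1) / 2))


def run_dimension_analysis(
    data: ItemResponseMatrix,
    config: AnalysisConfig,
    communities: bool = True,
    layout: bool = True,
    bootstrap: bool = False,
    stability_modes: tuple[str, ...] = (),
) -> DimensionResult:
    """Estimate the network for one dimension and assemble the result.

    Occurrence data go through eLasso Ising estimation; severity and
    distress through polychoric correlations + EBIC-selected graphical
    lasso.  Optional stages: walktrap communities, FR layout, edge
    bootstrap, and case/node subsetting stability.
    """
    if data.dimension == "occurrence":
        network: IsingNetwork | GaussianNetwork = fit_ising(
            data,
            gamma=config.gamma,
            rule=config.rule,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        weights = network.weights
    else:
        missing = 0 if config.absent_policy == "pairwise" else None
        if config.absent_policy == "zero":
            logger.info(
                "%s: absent symptoms coded as category 0 (absent_policy='zero')",
                data.dimension,
            )
        S = polychoric_matrix(data, missing_category=missing)
        network = fit_ggm(
            S,
            n=data.n_respondents,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        weights = network.partial_corr

    result = DimensionResult(
        dimension=data.dimension,
        network=network,
        centrality=centrality_indices(weights, data.symptom_codes),
        density=network_density(weights),
        symptom_codes=list(data.symptom_codes),
        config=config,
    )
    if communities and np.any(weights != 0):
        result.partition = walktrap_partition(weights, steps=config.walktrap_steps)
    if layout:
        result.layout = layout_fr(weights, seed=config.seed)
    if bootstrap:
        eb, ed = bootstrap_edges(data, config)
        result.stability["edges"] = eb
        result.stability["edge_differences"] = ed
    for mode in stability_modes:
        result.stability[mode] = subset_stability(data, config, mode=mode)
    return result


def _float_str(x: float) -> str:
    return repr(float(x))


def write_network(result: DimensionResult, out_dir: str | Path) -> list[Path]:
    """Write adjacency CSV, edge list CSV, GraphML, and a JSON summary.

    Edge sign is stored separately from magnitude ("positive" iff
    weight > 0) so downstream visualization can reproduce the usual
    green/red + thickness convention.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    codes = result.symptom_codes
    w = result.weights
    written: list[Path] = []

    adj_path = out_dir / f"{result.dimension}_adjacency.csv"
    pd.DataFrame(w, index=codes, columns=codes).to_csv(adj_path, float_format="%.12g")
    written.append(adj_path)

    edge_path = out_dir / f"{result.dimension}_edges.csv"
    with edge_path.open("w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["node_a", "node_b", "weight", "sign"])
        jj, kk = np.nonzero(np.triu(w, 1))
        for j, k in zip(jj, kk):
            sign = "positive" if w[j, k] > 0 else "negative"
            wr.writerow([codes[j], codes[k], _float_str(w[j, k]), sign])
    written.append(edge_path)

    G = nx.Graph()
    for i, c in enumerate(codes):
        G.add_node(c)
        if result.layout is not None:
            G.nodes[c]["x"] = float(result.layout[i, 0])
            G.nodes[c]["y"] = float(result.layout[i, 1])
        if result.partition is not None:
            G.nodes[c]["community"] = int(result.partition.labels[i])
    jj, kk = np.nonzero(np.triu(w, 1))
    for j, k in zip(jj, kk):
        G.add_edge(
            codes[j],
            codes[k],
            weight=float(w[j, k]),
            sign="positive" if w[j, k] > 0 else "negative",
        )
    gml_path = out_dir / f"{result.dimension}_network.graphml"
    nx.write_graphml(G, gml_path)
    written.append(gml_path)

    summary: dict = {
        "dimension": result.dimension,
        "density": result.density,
        "centrality": {
            col: {c: float(v) for c, v in result.centrality.table[col].items()}
            for col in result.centrality.table.columns
        },
    }
    if result.partition is not None:
        summary["partition"] = {
            c: int(result.partition.labels[i]) for i, c in enumerate(codes)
        }
        summary["n_communities"] = result.partition.n_communities
        summary["modularity"] = result.partition.modularity
    for mode in ("case", "node"):
        rep = result.stability.get(mode)
        if isinstance(rep, StabilityReport):
            summary.setdefault("cs_coefficients", {})[mode] = rep.cs
    if result.config is not None:
        summary["config"] = result.config.to_dict()
    json_path = out_dir / f"{result.dimension}_summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(json_path)
    return written


def read_adjacency(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read back an adjacency CSV written by :func:`write_network`."""
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), list(df.columns)
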