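"""Bootstrap accuracy and stability of estimated networks.

Three procedures, all nonparametric over respondents:

* edge-weight accuracy — resample rows with replacement, re-estimate the
  network, and form per-edge quantile confidence intervals; pairs of
  edges are compared by whether the bootstrap distribution of their
  difference excludes zero at level alpha;
* case-/node-dropping subsetting bootstrap — repeatedly drop a fixed
  proportion of respondents (or symptoms), re-estimate, and correlate the
  subset centralities with the full-sample ones; summarized by the
  correlation-stability (CS) coefficient: the largest drop proportion at
  which, with 95% certainty, the correlation stays at or above 0.7;
* split replication — partition respondents into k equal groups, estimate
  a network per group, and correlate node-strength vectors across groups.

Every routine accepts an ``estimator`` seam (ItemResponseMatrix -> weight
matrix) so that the machinery can be exercised and tested independently
of any particular network estimator; the default dispatches on the data's
dimension exactly as the end-to-end pipeline does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .centrality import centrality_indices
from .datatypes import AnalysisConfig, ItemResponseMatrix, ValidationError
from .ising_net import fit_ising
from .ordinal_net import fit_ggm, polychoric_matrix

logger = logging.getLogger("symptomnet")

CENTRALITY_INDICES = ("strength", "closeness", "betweenness")
DEFAULT_B_SUB = 250  # subsetting-bootstrap iterations per drop proportion

Estimator = Callable[[ItemResponseMatrix], np.ndarray]


def default_estimator(config: AnalysisConfig) -> Estimator:
    """Weight-matrix estimator matching the pipeline's dispatch:
    occurrence -> eLasso Ising weights, ordinal -> polychoric + glasso
    partial correlations."""

    def estimate(data: ItemResponseMatrix) -> np.ndarray:
        if data.dimension == "occurrence":
            net = fit_ising(
                data,
                gamma=config.gamma,
                rule=config.rule,
                n_lambda=config.n_lambda,
                lambda_min_ratio=config.lambda_min_ratio,
            )
            return net.weights
        missing = 0 if config.absent_policy == "pairwise" else None
        S = polychoric_matrix(data, missing_category=missing)
        net = fit_ggm(
            S,
            n=data.n_respondents,
            gamma=config.gamma,
            n_lambda=config.n_lambda,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        return net.partial_corr

    return estimate


def _subset_rows(data: ItemResponseMatrix, idx: np.ndarray) -> ItemResponseMatrix:
    return ItemResponseMatrix(
        data.values[idx], list(data.symptom_codes), data.dimension
    )


def _subset_cols(data: ItemResponseMatrix, idx: np.ndarray) -> ItemResponseMatrix:
    return ItemResponseMatrix(
        data.values[:, idx], [data.symptom_codes[i] for i in idx], data.dimension
    )


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 0.0 when undefined (either vector constant),
    since a constant centrality profile cannot certify order retention."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class EdgeBootstrap:
    """Per-edge bootstrap summaries over all p(p-1)/2 edges."""

    edges: list[tuple[int, int]]
    estimates: np.ndarray  # full-sample edge weights
    samples: np.ndarray  # B x E bootstrap edge weights
    boot_mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    B: int
    alpha: float


@dataclass
class EdgeDifferenceMatrix:
    """Pairwise significance of edge-weight differences among nonzero
    full-sample edges; no multiple-testing correction (per-comparison
    alpha)."""

    edges: list[tuple[int, int]]
    significant: np.ndarray  # E' x E' bool, symmetric, False diagonal
    alpha: float


def bootstrap_edges(
    data: ItemResponseMatrix,
    config: AnalysisConfig,
    estimator: Estimator | None = None,
) -> tuple[EdgeBootstrap, EdgeDifferenceMatrix]:
    """Nonparametric bootstrap of edge weights with quantile CIs and an
    edge-difference significance matrix."""
    B = config.bootstrap_B
    if B < 50:
        raise ValidationError("bootstrap_B < 50 yields uninterpretable quantiles")
    est = estimator or default_estimator(config)
    rng = np.random.default_rng(config.seed)
    n, p = data.values.shape
    iu = np.triu_indices(p, 1)
    edges = list(zip(iu[0].tolist(), iu[1].tolist()))

    full = est(data)
    full_w = full[iu]
    samples = np.empty((B, len(edges)))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        samples[b] = est(_subset_rows(data, idx))[iu]

    lo = np.quantile(samples, config.alpha / 2, axis=0)
    hi = np.quantile(samples, 1 - config.alpha / 2, axis=0)
    eb = EdgeBootstrap(
        edges=edges,
        estimates=full_w,
        samples=samples,
        boot_mean=samples.mean(axis=0),
        ci_lower=lo,
        ci_upper=hi,
        B=B,
        alpha=config.alpha,
    )

    nz = np.nonzero(full_w)[0]
    k = nz.size
    sig = np.zeros((k, k), dtype=bool)
    for a in range(k):
        for c in range(a + 1, k):
            diff = samples[:, nz[a]] - samples[:, nz[c]]
            dlo = np.quantile(diff, config.alpha / 2)
            dhi = np.quantile(diff, 1 - config.alpha / 2)
            # a degenerate (zero-variance) bootstrap distribution carries
            # no sampling-variability evidence, so it cannot flag a pair
            sig[a, c] = sig[c, a] = dhi > dlo and ((dlo > 0) or (dhi < 0))
    ed = EdgeDifferenceMatrix(
        edges=[edges[i] for i in nz], significant=sig, alpha=config.alpha
    )
    return eb, ed


def cs_coefficient(
    correlations: dict[float, np.ndarray],
    cs_correlation: float = 0.7,
    cs_certainty: float = 0.95,
) -> float:
    """CS coefficient of one centrality index: the largest drop proportion
    q whose bootstrap correlations reach ``cs_correlation`` in at least a
    ``cs_certainty`` fraction of iterations; 0.0 if none qualifies."""
    qualifying = [
        q
        for q, corrs in correlations.items()
        if np.mean(np.asarray(corrs) >= cs_correlation) >= cs_certainty
    ]
    return max(qualifying) if qualifying else 0.0


@dataclass
class StabilityReport:
    """Subsetting-bootstrap correlations and CS coefficients per index."""

    mode: str  # "case" | "node"
    drop_proportions: tuple[float, ...]
    correlations: dict[str, dict[float, np.ndarray]]
    cs: dict[str, float]
    B_sub: int
    metadata: dict = field(default_factory=dict)


def subset_stability(
    data: ItemResponseMatrix,
    config: AnalysisConfig,
    mode: str = "case",
    estimator: Estimator | None = None,
    B_sub: int = DEFAULT_B_SUB,
) -> StabilityReport:
    """Case- or node-dropping subsetting bootstrap with CS coefficients."""
    if mode not in ("case", "node"):
        raise ValidationError("mode must be 'case' or 'node'")
    n, p = data.values.shape
    if mode == "node" and p <= 3:
        raise ValidationError("node-dropping needs p > 3")
    est = estimator or default_estimator(config)
    rng = np.random.default_rng(config.seed)

    full_cent = centrality_indices(est(data), data.symptom_codes).table
    corrs: dict[str, dict[float, np.ndarray]] = {
        idx: {} for idx in CENTRALITY_INDICES
    }
    for q in config.drop_proportions:
        vals = {idx: np.empty(B_sub) for idx in CENTRALITY_INDICES}
        n_drop = int(q * n) if mode == "case" else int(q * p)
        for b in range(B_sub):
            if mode == "case":
                keep = rng.choice(n, size=n - n_drop, replace=False)
                sub = _subset_rows(data, np.sort(keep))
                node_idx = np.arange(p)
            else:
                keep = np.sort(rng.choice(p, size=p - n_drop, replace=False))
                sub = _subset_cols(data, keep)
                node_idx = keep
            sub_cent = centrality_indices(est(sub), sub.symptom_codes).table
            for idx in CENTRALITY_INDICES:
                vals[idx][b] = _safe_pearson(
                    full_cent[idx].to_numpy()[node_idx],
                    sub_cent[idx].to_numpy(),
                )
        for idx in CENTRALITY_INDICES:
            corrs[idx][q] = vals[idx]

    cs = {
        idx: cs_coefficient(corrs[idx], config.cs_correlation, config.cs_certainty)
        for idx in CENTRALITY_INDICES
    }
    return StabilityReport(
        mode=mode,
        drop_proportions=config.drop_proportions,
        correlations=corrs,
        cs=cs,
        B_sub=B_sub,
        metadata={
            # the drop grid and per-proportion iteration count are
            # implementation defaults, not part of the source protocol
            "drop_grid_is_default": True,
            "cs_correlation": config.cs_correlation,
            "cs_certainty": config.cs_certainty,
        },
    )


def split_replication(
    data: ItemResponseMatrix,
    config: AnalysisConfig,
    k: int = 4,
    estimator: Estimator | None = None,
    partition: np.ndarray | None = None,
) -> np.ndarray:
    """Split respondents into k equal random groups, estimate a network
    per group, and return the k x k matrix of node-strength correlations.

    ``partition`` (length-n integer array with values 0..k-1, -1 = drop)
    overrides the random assignment; used for controlled replication
    checks.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    n = data.n_respondents
    if n < 20 * k:
        raise ValidationError(f"need n >= {20 * k} for k={k} groups")
    est = estimator or default_estimator(config)
    if partition is None:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(n)
        size = n // k
        dropped = n - size * k
        if dropped:
            logger.info("split_replication: dropped %d remainder rows", dropped)
        partition = np.full(n, -1, dtype=np.int64)
        for g in range(k):
            partition[perm[g * size : (g + 1) * size]] = g

    strengths = []
    for g in range(k):
        sub = _subset_rows(data, np.nonzero(partition == g)[0])
        strengths.append(np.abs(est(sub)).sum(axis=1))
    out = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = _safe_pearson(strengths[a], strengths[b])
    return out
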