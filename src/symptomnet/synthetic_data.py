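"""Synthetic generators with known ground truth.

Binary data come from a pairwise Ising model (exact sampling by state
enumeration for small p, parallel-chain Gibbs sampling for large p);
ordinal data come from a discretized latent multivariate normal — the
generative model that polychoric correlation assumes.  A gated
three-dimension fixture emulates the structure of an MSAS-style symptom
instrument: binary occurrence plus severity/distress ratings that exist
only when the symptom occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .datatypes import ItemResponseMatrix, ValidationError

#: MSAS symptom short codes (38 items) used for the default fixture.
MSAS_SYMPTOM_CODES = [
    "difcon", "pain", "energy", "cough", "nervous", "hotflash", "drymouth",
    "nausea", "drowsy", "numb", "chest", "difbreath", "difsleep", "bloat",
    "urinate", "vomit", "sob", "diarrhea", "sad", "sweats", "sexual",
    "worry", "itch", "appetite", "abdominal", "increaseapp", "wtgain",
    "dizzy", "swallow", "irritable", "mouthsore", "wtloss", "hairloss",
    "constipat", "swelling", "taste", "myself", "skin",
]

EXACT_SAMPLING_MAX_P = 20
GIBBS_BURN_IN = 1000


def _check_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValidationError(f"{name} must be symmetric")
    return m


@dataclass
class IsingParams:
    """Pairwise Ising model on {0,1}^p.

    ``couplings[j, k]`` is the interaction strength beta_jk between
    symptoms j and k; ``thresholds[j]`` is tau_j, the autonomous
    disposition of symptom j to take the value 1.
    """

    couplings: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.couplings = _check_symmetric(self.couplings, "couplings")
        if np.any(np.diag(self.couplings) != 0):
            raise ValidationError("couplings must have a zero diagonal")
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (self.couplings.shape[0],):
            raise ValidationError("thresholds length must match couplings")
        if not (np.all(np.isfinite(self.couplings)) and np.all(np.isfinite(self.thresholds))):
            raise ValidationError("parameters must be finite")

    @property
    def p(self) -> int:
        return self.couplings.shape[0]


@dataclass
class LatentOrdinalParams:
    """Latent-Gaussian ordinal model: MVN(0, correlation) discretized
    per variable by strictly increasing thresholds into K categories."""

    correlation: np.ndarray
    thresholds: list[np.ndarray]

    def __post_init__(self) -> None:
        self.correlation = _check_symmetric(self.correlation, "correlation")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise ValidationError("correlation must have a unit diagonal")
        eigmin = float(np.linalg.eigvalsh(self.correlation)[0])
        if eigmin <= 0:
            raise ValidationError(
                f"correlation is not positive-definite (smallest eigenvalue {eigmin:.3e})"
            )
        self.thresholds = [np.asarray(t, dtype=float) for t in self.thresholds]
        if len(self.thresholds) != self.correlation.shape[0]:
            raise ValidationError("one threshold vector per variable required")
        for j, t in enumerate(self.thresholds):
            if t.size < 1:
                raise ValidationError(f"variable {j}: need >= 1 threshold (K >= 2)")
            if np.any(np.diff(t) <= 0):
                raise ValidationError(f"variable {j}: thresholds must be strictly increasing")

    @property
    def p(self) -> int:
        return self.correlation.shape[0]


@dataclass
class SyntheticSpec:
    """Reproducible recipe for one synthetic sample."""

    n: int
    seed: int
    truth: IsingParams | LatentOrdinalParams
    planted_partition: np.ndarray | None = None


def enumerate_ising_states(params: IsingParams) -> tuple[np.ndarray, np.ndarray]:
    """All 2^p states and their exact probabilities under the model.

    P(x) is proportional to exp(sum_j tau_j x_j + sum_{j<k} beta_jk x_j x_k).
    """
    p = params.p
    if p > EXACT_SAMPLING_MAX_P:
        raise ValidationError(f"enumeration limited to p <= {EXACT_SAMPLING_MAX_P}")
    states = ((np.arange(2**p)[:, None] >> np.arange(p)) & 1).astype(np.int8)
    xs = states.astype(float)
    energy = xs @ params.thresholds + 0.5 * np.einsum(
        "ij,jk,ik->i", xs, params.couplings, xs
    )
    energy -= energy.max()
    w = np.exp(energy)
    return states, w / w.sum()


def _gibbs_sample(params: IsingParams, n: int, rng: np.random.Generator) -> np.ndarray:
    # n independent chains, random start, fixed burn-in; vectorized over chains.
    p = params.p
    states = (rng.random((n, p)) < 0.5).astype(np.int8)
    beta = params.couplings
    tau = params.thresholds
    for _ in range(GIBBS_BURN_IN):
        for j in range(p):
            eta = tau[j] + states @ beta[:, j]
            states[:, j] = rng.random(n) < expit(eta)
    return states


def sample_ising(
    params: IsingParams, n: int, seed: int, method: str = "auto"
) -> np.ndarray:
    """Draw n rows from the Ising model.

    ``method="exact"`` enumerates all 2^p states (p <= 20) and samples
    i.i.d.; ``"gibbs"`` runs n parallel Gibbs chains with a 1000-sweep
    burn-in and is approximate.  ``"auto"`` picks exact when feasible.
    """
    if method not in ("auto", "exact", "gibbs"):
        raise ValidationError(f"unknown sampling method {method!r}")
    if method == "auto":
        method = "exact" if params.p <= EXACT_SAMPLING_MAX_P else "gibbs"
    rng = np.random.default_rng(seed)
    if method == "exact":
        states, probs = enumerate_ising_states(params)
        idx = rng.choice(states.shape[0], size=n, p=probs)
        return states[idx].copy()
    return _gibbs_sample(params, n, rng)


def sample_latent_ordinal(
    params: LatentOrdinalParams, n: int, seed: int
) -> np.ndarray:
    """Draw n rows: latent MVN(0, correlation), each coordinate cut into
    categories 0..K-1 by that variable's thresholds."""
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(params.correlation)
    z = rng.standard_normal((n, params.p)) @ chol.T
    out = np.empty_like(z, dtype=np.int64)
    for j, cuts in enumerate(params.thresholds):
        out[:, j] = np.searchsorted(cuts, z[:, j])
    return out


# ---------------------------------------------------------------------------
# Planted-structure fixture emulating the three MSAS dimensions
# ---------------------------------------------------------------------------


def _block_sizes(p: int, n_blocks: int) -> list[int]:
    base = p // n_blocks
    rem = p % n_blocks
    return [base + (1 if b < rem else 0) for b in range(n_blocks)]


def planted_block_graph(p: int, n_blocks: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Chain-of-communities adjacency pattern: complete within each block,
    consecutive blocks joined by a single bridge edge.

    Returns (adjacency 0/1 matrix, block labels).
    """
    if p < 4:
        raise ValidationError("planted graph needs p >= 4")
    n_blocks = min(n_blocks, p // 2)
    sizes = _block_sizes(p, n_blocks)
    labels = np.repeat(np.arange(n_blocks), sizes)
    adj = (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(adj, 0.0)
    bounds = np.cumsum(sizes)
    for b in range(n_blocks - 1):
        i, j = bounds[b] - 1, bounds[b]  # last node of block b, first of b+1
        adj[i, j] = adj[j, i] = 1.0
    return adj, labels


def planted_ising_truth(
    p: int, n_blocks: int = 5, within: float = 0.8, between: float = 0.1
) -> tuple[IsingParams, np.ndarray]:
    """Ising parameters on the planted block graph: coupling ``within`` on
    within-block edges, ``between`` on bridges; thresholds balance each
    node (tau_j = -sum_k beta_jk / 2) so marginals sit near 0.5."""
    adj, labels = planted_block_graph(p, n_blocks)
    beta = adj * between
    same = labels[:, None] == labels[None, :]
    beta[same & (adj > 0)] = within
    tau = -0.5 * beta.sum(axis=1)
    return IsingParams(couplings=beta, thresholds=tau), labels


def planted_gaussian_truth(
    p: int,
    n_blocks: int = 5,
    within_partial: float = 0.12,
    between_partial: float = 0.03,
    cumulative_probs: tuple[float, ...] = (0.35, 0.65, 0.85, 0.95),
) -> tuple[LatentOrdinalParams, np.ndarray, np.ndarray]:
    """Latent-Gaussian parameters sharing the planted zero pattern.

    Builds precision Theta = I - A with A carrying the block pattern, so
    the true partial correlation of a present edge equals its A entry;
    A is shrunk if needed to keep Theta positive-definite.  Returns
    (params, block labels, true partial-correlation matrix).
    """
    from scipy.stats import norm

    adj, labels = planted_block_graph(p, n_blocks)
    a = adj * between_partial
    same = labels[:, None] == labels[None, :]
    a[same & (adj > 0)] = within_partial
    lam = np.max(np.abs(np.linalg.eigvalsh(a)))
    if lam >= 0.95:
        a *= 0.95 / lam
    theta = np.eye(p) - a
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    cuts = norm.ppf(np.asarray(cumulative_probs))
    params = LatentOrdinalParams(correlation=corr, thresholds=[cuts.copy() for _ in range(p)])
    return params, labels, a


def make_msas_fixture(
    n: int = 1328, p: int = 38, seed: int = 0
) -> tuple[ItemResponseMatrix, ItemResponseMatrix, ItemResponseMatrix]:
    """Generate a gated occurrence/severity/distress triple.

    Occurrence is sampled from an Ising model on a planted
    chain-of-communities graph; severity and distress from latent-Gaussian
    models sharing the planted pattern, discretized to 5 categories, then
    gated: wherever occurrence is 0 the rating is forced to 0, so
    "severity > 0 implies occurrence = 1" holds cell-wise.
    """
    if n < 10:
        raise ValidationError("fixture needs n >= 10 to be usable")
    if p < 4:
        raise ValidationError("fixture needs p >= 4")
    codes = MSAS_SYMPTOM_CODES if p == 38 else [f"s{i:02d}" for i in range(p)]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)

    ising, _ = planted_ising_truth(p)
    occ = sample_ising(ising, n, seed=int(seeds[0]))

    sev_params, _, _ = planted_gaussian_truth(p)
    dis_params, _, _ = planted_gaussian_truth(
        p, cumulative_probs=(0.30, 0.55, 0.75, 0.90)
    )
    sev = sample_latent_ordinal(sev_params, n, seed=int(seeds[1]))
    dis = sample_latent_ordinal(dis_params, n, seed=int(seeds[2]))
    sev[occ == 0] = 0
    dis[occ == 0] = 0

    return (
        ItemResponseMatrix(occ.astype(np.int64), list(codes), "occurrence"),
        ItemResponseMatrix(sev, list(codes), "severity"),
        ItemResponseMatrix(dis, list(codes), "distress"),
    )
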