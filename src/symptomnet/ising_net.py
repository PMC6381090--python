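"""Binary-data network estimation: the eLasso / IsingFit procedure.

Each symptom is regressed on all others by l1-penalized logistic
regression over a descending lambda path; the neighborhood minimizing the
extended BIC is kept, and the p nodewise fits are combined into one
symmetric weight matrix under the AND or OR rule.  The penalized solver is
a glmnet-style proximal-Newton scheme: iteratively reweighted least
squares with coordinate descent on the working quadratic, intercept never
penalized, warm starts along the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ItemResponseMatrix, ValidationError

CD_TOL = 1e-6  # convergence tolerance on coefficient change
CD_MAX_OUTER = 100
CD_MAX_SWEEPS = 1000
MIN_IRLS_WEIGHT = 1e-5


def count_parameters(p: int) -> int:
    """Free-parameter count of a saturated pairwise Ising model on p nodes:
    p thresholds plus p(p-1)/2 pairwise couplings (741 at p = 38)."""
    if p < 1:
        raise ValidationError("p must be >= 1")
    return p + p * (p - 1) // 2


def ebic_logistic(loglik: float, J_size: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC of one nodewise logistic fit:

        -2*loglik + |J| log n + 2 gamma |J| log(p - 1)

    with |J| the neighborhood size and p - 1 the number of candidate
    predictors.
    """
    if p < 2:
        raise ValidationError("p must be >= 2 (log(p-1) undefined otherwise)")
    if n < 1:
        raise ValidationError("n must be >= 1")
    if J_size < 0:
        raise ValidationError("J_size must be non-negative")
    return -2.0 * loglik + J_size * np.log(n) + 2.0 * gamma * J_size * np.log(p - 1)


def _logistic_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float) -> float:
    eta = b0 + X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    tol: float = CD_TOL,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve min_{b0,beta} (1/n) sum log(1 + exp(eta)) - y*eta + lam*||beta||_1
    for each lam in ``lambdas`` (descending), warm-starting along the path.

    Returns (coefs with shape (L, m), intercepts with shape (L,)).
    """
    n, m = X.shape
    beta = np.zeros(m)
    ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    b0 = float(np.log(ybar / (1 - ybar)))
    coefs = np.empty((len(lambdas), m))
    intercepts = np.empty(len(lambdas))
    for li, lam in enumerate(lambdas):
        nlam = n * lam
        for _ in range(CD_MAX_OUTER):
            eta = b0 + X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = np.clip(mu * (1.0 - mu), MIN_IRLS_WEIGHT, None)
            z = eta + (y - mu) / w
            # weighted Gram caching makes each coordinate update O(m)
            sw = w.sum()
            Xw = X.T @ w
            G = X.T @ (w[:, None] * X)
            c = X.T @ (w * z)
            zw = float(w @ z)
            beta_old_outer = beta.copy()
            full_sweep = True
            for _ in range(CD_MAX_SWEEPS):
                delta = 0.0
                b0_new = (zw - Xw @ beta) / sw
                delta = max(delta, abs(b0_new - b0))
                b0 = b0_new
                active = range(m) if full_sweep else np.nonzero(beta)[0]
                for j in active:
                    r = c[j] - b0 * Xw[j] - (G[j] @ beta - G[j, j] * beta[j])
                    bj = np.sign(r) * max(abs(r) - nlam, 0.0) / G[j, j]
                    delta = max(delta, abs(bj - beta[j]))
                    beta[j] = bj
                if delta < 0.1 * tol:
                    if full_sweep:
                        break
                    full_sweep = True  # verify convergence on all coords
                else:
                    full_sweep = False  # iterate the active set only
            if np.max(np.abs(beta - beta_old_outer)) < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts


@dataclass
class IsingNetwork:
    """Estimated binary-data pairwise Markov random field."""

    weights: np.ndarray  # p x p symmetric, zero diagonal
    thresholds: np.ndarray  # intercepts tau-hat
    gamma: float
    rule: str
    selected_neighbors: list[set[int]]
    lambda_grid: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.weights.shape[0]


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int, ratio: float) -> np.ndarray:
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
    if lam_max <= 0:
        lam_max = 1e-3
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def fit_ising(
    data: ItemResponseMatrix | np.ndarray,
    gamma: float = 0.25,
    rule: str = "OR",
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    symptom_codes: list[str] | None = None,
) -> IsingNetwork:
    """Estimate the Ising network by nodewise EBIC-selected l1 logistic
    regression.

    For each node j the lasso path of X_j on the remaining nodes
    generates candidate neighborhoods (the distinct nonzero patterns along
    the path); each candidate is refit by unpenalized logistic regression
    and the one with the lowest EBIC (|J| = neighborhood size) is
    selected, ties going to the sparser (larger-lambda) set.  Directed
    selections combine into an undirected weight matrix:
    under OR an edge exists when either direction is nonzero, under AND
    only when both are; the weight is the mean of the two directed
    coefficients, a selected zero counting as 0.
    """
    if rule not in ("AND", "OR"):
        raise ValidationError("rule must be 'AND' or 'OR'")
    if isinstance(data, ItemResponseMatrix):
        if data.dimension != "occurrence":
            raise ValidationError(
                f"fit_ising requires binary occurrence data, got dimension "
                f"{data.dimension!r}; use the ordinal estimator instead"
            )
        codes = data.symptom_codes
        Xfull = data.values
    else:
        Xfull = np.asarray(data)
        codes = symptom_codes or [f"s{i:02d}" for i in range(Xfull.shape[1])]
    if not np.isin(Xfull, (0, 1)).all():
        raise ValidationError("fit_ising requires strictly binary {0,1} data")
    Xfull = Xfull.astype(float)
    n, p = Xfull.shape
    if p < 2:
        raise ValidationError("need p >= 2 nodes")
    col_means = Xfull.mean(axis=0)
    const = np.where((col_means == 0) | (col_means == 1))[0]
    if const.size:
        raise ValidationError(
            "constant column(s) "
            + ", ".join(codes[j] for j in const)
            + ": threshold parameter unidentifiable"
        )

    directed = np.zeros((p, p))
    thresholds = np.zeros(p)
    neighbors: list[set[int]] = []
    grids: list[np.ndarray] = []
    others_idx = [np.delete(np.arange(p), j) for j in range(p)]
    for j in range(p):
        idx = others_idx[j]
        X = Xfull[:, idx]
        y = Xfull[:, j]
        lambdas = _lambda_grid(X, y, n_lambda, lambda_min_ratio)
        coefs, _ = logistic_lasso_path(X, y, lambdas)
        # the path generates candidate neighborhoods; Eq.-style EBIC is
        # evaluated on the unpenalized ML refit of each distinct set, so
        # selection is not distorted by lasso shrinkage of the loglik
        # the empty neighborhood (lambda = +inf solution) is always a
        # candidate; at exactly lambda_max the borderline coefficient can
        # round to a tiny nonzero value and hide it from the path
        seen: set[frozenset] = {frozenset()}
        candidates: list[np.ndarray] = [np.empty(0, dtype=np.int64)]
        for li in range(len(lambdas)):
            pattern = frozenset(np.nonzero(np.abs(coefs[li]) > 0)[0].tolist())
            if pattern not in seen:
                seen.add(pattern)
                candidates.append(np.fromiter(sorted(pattern), dtype=np.int64))
        best = None
        for cols in candidates:  # lambda-descending: sparser wins EBIC ties
            if cols.size:
                cf, ic = logistic_lasso_path(X[:, cols], y, np.array([0.0]))
                beta_fit, b0_fit = cf[0], float(ic[0])
                ll = _logistic_loglik(X[:, cols], y, beta_fit, b0_fit)
            else:
                ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
                beta_fit, b0_fit = np.empty(0), float(np.log(ybar / (1 - ybar)))
                ll = n * (ybar * b0_fit - np.logaddexp(0.0, b0_fit))
            crit = ebic_logistic(ll, cols.size, n, p, gamma)
            if best is None or crit < best[0] - 1e-9:
                best = (crit, cols, beta_fit, b0_fit)
        _, cols, beta_fit, b0_fit = best
        directed[j, idx[cols]] = beta_fit
        thresholds[j] = b0_fit
        neighbors.append(set(idx[cols].tolist()))
        grids.append(lambdas)

    if rule == "OR":
        mask = (directed != 0) | (directed.T != 0)
    else:
        mask = (directed != 0) & (directed.T != 0)
    weights = np.where(mask, 0.5 * (directed + directed.T), 0.0)
    np.fill_diagonal(weights, 0.0)
    return IsingNetwork(
        weights=weights,
        thresholds=thresholds,
        gamma=gamma,
        rule=rule,
        selected_neighbors=neighbors,
        lambda_grid=grids,
        metadata={
            "estimator": "eLasso",
            "ebic_on_ml_refit": True,
            "n": n,
            "n_lambda": n_lambda,
            "lambda_min_ratio": lambda_min_ratio,
            "cd_tol": CD_TOL,
        },
    )
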