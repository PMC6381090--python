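"""Ordinal-data network estimation: polychoric correlations + glasso.

Severity and distress items are treated as discretizations of a latent
multivariate normal.  Step one estimates the polychoric correlation of
every pair by the two-step method (thresholds from marginal proportions,
then the latent correlation by maximum likelihood on the contingency
table).  Step two runs the graphical lasso

    argmin_{Theta >= 0}  tr(S Theta) - log det(Theta) + lam * sum_{j!=k} |Theta_jk|

over a descending lambda path and selects lam by the Gaussian extended
BIC; edge weights are the partial correlations -Theta_jk / sqrt(Theta_jj
Theta_kk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .datatypes import ItemResponseMatrix, ValidationError

BVN_CDF_ABS_TOL = 1e-7
RHO_BOUND = 0.999
PD_EIG_FLOOR = 1e-6
PRECISION_ZERO_TOL = 1e-8


@dataclass
class PolychoricEstimate:
    rho: float
    thresholds_x: np.ndarray
    thresholds_y: np.ndarray
    loglik: float
    converged: bool


def _marginal_thresholds(v: np.ndarray, n_cat: int) -> np.ndarray:
    counts = np.bincount(v, minlength=n_cat)
    cum = np.cumsum(counts)[:-1] / v.size
    return stats.norm.ppf(cum)


def _bvn_rectangle_probs(
    cuts_x: np.ndarray, cuts_y: np.ndarray, rho: float
) -> np.ndarray:
    """Cell probabilities of a bivariate standard normal over the grid
    defined by interior thresholds (implicit +-inf at the ends)."""
    ax = np.concatenate(([-np.inf], cuts_x, [np.inf]))
    ay = np.concatenate(([-np.inf], cuts_y, [np.inf]))
    kx, ky = ax.size, ay.size
    F = np.zeros((kx, ky))
    # CDF at every grid point; infinite coordinates reduce to the
    # univariate normal CDF of the other coordinate.
    F[-1, :] = stats.norm.cdf(ay)
    F[:, -1] = stats.norm.cdf(ax)
    fin_x, fin_y = ax[1:-1], ay[1:-1]
    if fin_x.size and fin_y.size:
        pts = np.column_stack(
            [np.repeat(fin_x, fin_y.size), np.tile(fin_y, fin_x.size)]
        )
        vals = np.atleast_1d(
            stats.multivariate_normal.cdf(
                pts,
                mean=[0.0, 0.0],
                cov=[[1.0, rho], [rho, 1.0]],
                allow_singular=True,
                abseps=BVN_CDF_ABS_TOL,
            )
        )
        F[1:-1, 1:-1] = vals.reshape(fin_x.size, fin_y.size)
    cells = np.diff(np.diff(F, axis=0), axis=1)
    return np.clip(cells, 1e-12, None)


def estimate_polychoric_pair(x: np.ndarray, y: np.ndarray) -> PolychoricEstimate:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds are standard-normal quantiles of the cumulative marginal
    proportions; rho then maximizes the bivariate-normal contingency-table
    likelihood with thresholds held fixed.  Tables containing an empty
    cell get a 0.5 continuity correction on every cell.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if x.size < 10:
        raise ValidationError("need n >= 10 observations")
    ux, uy = np.unique(x), np.unique(y)
    if ux.size < 2 or uy.size < 2:
        raise ValidationError(
            "each variable needs >= 2 observed categories (thresholds undefined)"
        )
    # compress to consecutive codes 0..K-1 of observed categories
    xc = np.searchsorted(ux, x)
    yc = np.searchsorted(uy, y)
    kx, ky = ux.size, uy.size
    table = np.zeros((kx, ky))
    np.add.at(table, (xc, yc), 1.0)
    if np.any(table == 0):
        table = table + 0.5
    tx = _marginal_thresholds(xc, kx)
    ty = _marginal_thresholds(yc, ky)

    def negll(rho: float) -> float:
        return -float(np.sum(table * np.log(_bvn_rectangle_probs(tx, ty, rho))))

    res = optimize.minimize_scalar(
        negll,
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-7},
    )
    rho = float(np.clip(res.x, -RHO_BOUND, RHO_BOUND))
    return PolychoricEstimate(
        rho=rho,
        thresholds_x=tx,
        thresholds_y=ty,
        loglik=-float(res.fun),
        converged=bool(res.success),
    )


def nearest_pd_correlation(R: np.ndarray, eig_floor: float = PD_EIG_FLOOR) -> np.ndarray:
    """Clip eigenvalues at ``eig_floor`` and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, eig_floor, None)
    M = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 1.0)
    return M


def polychoric_matrix(
    data: ItemResponseMatrix | np.ndarray,
    missing_category: int | None = None,
    return_info: bool = False,
):
    """Pairwise polychoric correlation matrix of an ordinal item matrix.

    If ``missing_category`` is given, rows where either member of a pair
    equals that category are excluded from that pair's table
    (pairwise-complete treatment of e.g. "symptom absent" codes).  A
    non-positive-definite assembled matrix is replaced with the nearest
    positive-definite correlation matrix (eigenvalue clipping at 1e-6,
    rescaled to unit diagonal); ``return_info=True`` additionally returns
    a dict flagging whether that correction was applied.
    """
    values = data.values if isinstance(data, ItemResponseMatrix) else np.asarray(data)
    n, p = values.shape
    R = np.eye(p)
    for j in range(p):
        for k in range(j + 1, p):
            xj, xk = values[:, j], values[:, k]
            if missing_category is not None:
                keep = (xj != missing_category) & (xk != missing_category)
                xj, xk = xj[keep], xk[keep]
            try:
                est = estimate_polychoric_pair(xj, xk)
            except ValidationError as exc:
                raise ValidationError(f"pair ({j}, {k}): {exc}") from exc
            R[j, k] = R[k, j] = est.rho
    eigmin = float(np.linalg.eigvalsh(R)[0])
    corrected = eigmin < PD_EIG_FLOOR
    if corrected:
        R = nearest_pd_correlation(R)
    if return_info:
        return R, {"pd_corrected": corrected, "min_eigenvalue_raw": eigmin}
    return R


@dataclass
class GaussianNetwork:
    """EBIC-selected graphical-lasso network over a correlation matrix."""

    S: np.ndarray
    precision: np.ndarray
    partial_corr: np.ndarray
    lam: float
    gamma: float
    lambda_grid: np.ndarray
    ebic_path: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.S.shape[0]


def precision_to_partial_corr(theta: np.ndarray) -> np.ndarray:
    """Partial correlations -Theta_jk / sqrt(Theta_jj Theta_kk), zero
    diagonal."""
    d = np.sqrt(np.diag(theta))
    pc = -theta / np.outer(d, d)
    pc = 0.5 * (pc + pc.T)
    np.fill_diagonal(pc, 0.0)
    return np.clip(pc, -1.0, 1.0)


def gaussian_ebic(theta: np.ndarray, S: np.ndarray, n: int, p: int, gamma: float) -> float:
    """Gaussian EBIC of a precision estimate (constant terms dropped):
    -2 l(Theta) + E log n + 4 gamma E log p, with
    l(Theta) = (n/2)(log det Theta - tr(S Theta)) and E the nonzero
    upper-triangle off-diagonal count."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return np.inf
    ll = 0.5 * n * (logdet - float(np.sum(S * theta)))
    iu = np.triu_indices(p, 1)
    E = int(np.sum(np.abs(theta[iu]) > PRECISION_ZERO_TOL))
    return -2.0 * ll + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def constrained_gaussian_mle(
    S: np.ndarray,
    support: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Gaussian MLE of the precision matrix under a fixed zero pattern
    (covariance selection), by iterative proportional scaling.

    The MLE Theta satisfies (Theta^-1)_jk = S_jk on the diagonal and the
    support, and Theta_jk = 0 elsewhere; each column update solves the
    stationarity condition for one node's neighborhood exactly.
    """
    p = S.shape[0]
    support = support | support.T
    W = S.copy()
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            N = np.nonzero(support[:, j])[0]
            N = N[N != j]
            if N.size:
                beta = np.linalg.solve(W[np.ix_(N, N)], S[N, j])
                w12 = W[:, N] @ beta
            else:
                w12 = np.zeros(p)
            w12[j] = S[j, j]
            W[:, j] = w12
            W[j, :] = w12
        if np.max(np.abs(W - W_old)) < tol:
            break
    theta = np.linalg.inv(W)
    theta = 0.5 * (theta + theta.T)
    theta[(~support) & (~np.eye(p, dtype=bool))] = 0.0
    return theta


def glasso_kkt_residual(theta: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Max violation of the glasso stationarity conditions
    S - Theta^{-1} + lam * sign(Theta_offdiag) = 0 (subgradient form)."""
    W = np.linalg.inv(theta)
    G = S - W
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    nz = off & (np.abs(theta) > PRECISION_ZERO_TOL)
    zero = off & ~nz
    res = 0.0
    if nz.any():
        res = max(res, float(np.max(np.abs(G[nz] + lam * np.sign(theta[nz])))))
    if zero.any():
        res = max(res, float(np.max(np.abs(G[zero]) - lam)))
    res = max(res, float(np.max(np.abs(np.diag(G)))))
    return res


def fit_ggm(
    S: np.ndarray,
    n: int,
    gamma: float = 0.25,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> GaussianNetwork:
    """Graphical lasso over a log-spaced lambda path with Gaussian-EBIC
    penalty selection; ties go to the sparser (larger-lambda) solution.

    The EBIC of each path point is evaluated on the constrained Gaussian
    MLE for that point's support (covariance-selection refit), so the
    selection is not distorted by the shrinkage of the loglik; the
    returned precision is the penalized glasso solution at the selected
    lambda, which satisfies the glasso stationarity conditions.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValidationError("S must be symmetric")
    eigmin = float(np.linalg.eigvalsh(S)[0])
    if eigmin <= 0:
        raise ValidationError(
            f"S is not positive-definite (smallest eigenvalue {eigmin:.3e}); "
            "apply polychoric_matrix's nearest-PD correction first"
        )
    if n < p:
        warnings.warn(f"n={n} < p={p}: glasso estimates may be unstable", UserWarning)
    S = 0.5 * (S + S.T)
    iu = np.triu_indices(p, 1)
    lam_max = float(np.max(np.abs(S[iu]))) if p > 1 else 0.0
    if lam_max <= 0:
        theta = np.diag(1.0 / np.diag(S))
        return GaussianNetwork(
            S=S, precision=theta, partial_corr=np.zeros((p, p)),
            lam=0.0, gamma=gamma, lambda_grid=np.array([]),
            ebic_path=np.array([]), metadata={"degenerate_grid": True, "n": n},
        )
    grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    best = None
    ebics = np.empty(n_lambda)
    off = ~np.eye(p, dtype=bool)
    refit_cache: dict[frozenset, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for li, lam in enumerate(grid):
            # a tight inner (enet) tolerance is what actually drives the
            # KKT residual of the returned precision down
            _, theta = _sk_graphical_lasso(
                S, alpha=float(lam), tol=1e-8, enet_tol=1e-9, max_iter=500
            )
            theta = 0.5 * (theta + theta.T)
            theta[off & (np.abs(theta) <= PRECISION_ZERO_TOL)] = 0.0
            support = np.abs(theta) > PRECISION_ZERO_TOL
            np.fill_diagonal(support, False)
            key = frozenset(zip(*np.nonzero(np.triu(support, 1))))
            if key not in refit_cache:
                refit = constrained_gaussian_mle(S, support)
                refit_cache[key] = gaussian_ebic(refit, S, n, p, gamma)
            ebics[li] = refit_cache[key]
            if best is None or ebics[li] < best[0] - 1e-9:
                best = (ebics[li], li, lam, theta)
    _, _, lam_sel, theta_sel = best
    pc = precision_to_partial_corr(theta_sel)
    pc[np.abs(theta_sel) <= PRECISION_ZERO_TOL] = 0.0
    np.fill_diagonal(pc, 0.0)
    return GaussianNetwork(
        S=S,
        precision=theta_sel,
        partial_corr=pc,
        lam=float(lam_sel),
        gamma=gamma,
        lambda_grid=grid,
        ebic_path=ebics,
        metadata={"estimator": "polychoric+glasso", "ebic_on_mle_refit": True, "n": n,
                  "n_lambda": n_lambda, "lambda_min_ratio": lambda_min_ratio},
    )
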