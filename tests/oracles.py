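"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: shortest paths by
Floyd-Warshall with explicit path counting (the package uses Dijkstra /
Brandes via networkx), simple-path enumeration for tiny graphs,
exhaustive EBIC neighborhood search (the package uses a lasso path), and
exhaustive max-modularity partitioning (the package uses walktrap).
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.linear_model import LogisticRegression

from symptomnet.ising_net import ebic_logistic


def floyd_warshall_centrality(weights: np.ndarray):
    """Closeness and betweenness from Floyd-Warshall distances plus
    shortest-path counting by dynamic programming."""
    p = weights.shape[0]
    with np.errstate(divide="ignore"):
        d = 1.0 / np.abs(weights)
    np.fill_diagonal(d, 0.0)
    dist = d.copy()
    for k in range(p):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    # sigma[s, t]: number of shortest s-t paths
    sigma = np.zeros((p, p))
    np.fill_diagonal(sigma, 1.0)
    order = []  # pairs ordered by distance so counts build up correctly
    for s in range(p):
        for t in range(p):
            if s != t and np.isfinite(dist[s, t]):
                order.append((dist[s, t], s, t))
    order.sort()
    for _, s, t in order:
        # predecessors k of t on shortest s-t paths have strictly smaller
        # dist[s, k], so processing pairs by increasing distance is safe
        total = 0.0
        for k in range(p):
            if k == t or not np.isfinite(d[k, t]):
                continue
            if np.isclose(dist[s, k] + d[k, t], dist[s, t]):
                total += sigma[s, k]
        sigma[s, t] = total

    closeness = np.zeros(p)
    for j in range(p):
        reach = [dist[j, t] for t in range(p) if t != j and np.isfinite(dist[j, t])]
        closeness[j] = 1.0 / sum(reach) if reach else 0.0

    betweenness = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(p):
                if v in (s, t):
                    continue
                if np.isclose(dist[s, v] + dist[v, t], dist[s, t]):
                    betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return closeness, betweenness


def simple_path_centrality(weights: np.ndarray):
    """Closeness/betweenness by enumerating every simple path (tiny p)."""
    p = weights.shape[0]
    with np.errstate(divide="ignore"):
        d = 1.0 / np.abs(weights)
    best: dict[tuple[int, int], tuple[float, list[tuple[int, ...]]]] = {}
    for s in range(p):
        for t in range(p):
            if s == t:
                continue
            bl, paths = np.inf, []
            for r in range(p - 1):
                for mid in itertools.permutations(
                    [x for x in range(p) if x not in (s, t)], r
                ):
                    nodes = (s, *mid, t)
                    length = sum(d[a, b] for a, b in zip(nodes, nodes[1:]))
                    if not np.isfinite(length):
                        continue
                    if length < bl - 1e-12:
                        bl, paths = length, [nodes]
                    elif abs(length - bl) <= 1e-12:
                        paths.append(nodes)
            if paths:
                best[(s, t)] = (bl, paths)
    closeness = np.zeros(p)
    for j in range(p):
        tot = sum(best[(j, t)][0] for t in range(p) if (j, t) in best)
        closeness[j] = 1.0 / tot if tot > 0 else 0.0
    betweenness = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if (s, t) not in best:
                continue
            _, paths = best[(s, t)]
            for v in range(p):
                if v in (s, t):
                    continue
                thru = sum(1 for nodes in paths if v in nodes[1:-1])
                betweenness[v] += thru / len(paths)
    return closeness, betweenness


def exhaustive_ebic_neighborhoods(X: np.ndarray, gamma: float) -> list[set[int]]:
    """Per-node EBIC-minimizing neighborhood over every predictor subset,
    fit by unpenalized logistic regression."""
    n, p = X.shape
    out = []
    for j in range(p):
        others = [k for k in range(p) if k != j]
        y = X[:, j]
        best = None
        for r in range(len(others) + 1):
            for sub in map(list, itertools.combinations(others, r)):
                if sub:
                    lr = LogisticRegression(
                        C=np.inf, solver="lbfgs", tol=1e-12, max_iter=10000
                    ).fit(X[:, sub], y)
                    eta = lr.intercept_[0] + X[:, sub] @ lr.coef_[0]
                else:
                    ybar = y.mean()
                    eta = np.full(n, np.log(ybar / (1 - ybar)))
                ll = float(np.sum(y * eta - np.logaddexp(0, eta)))
                crit = ebic_logistic(ll, len(sub), n, p, gamma)
                if best is None or crit < best[0] - 1e-9:
                    best = (crit, set(sub))
        out.append(best[1])
    return out


def all_set_partitions(items: list[int]):
    """Every partition of a list (Bell-number many; tiny inputs only)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def max_modularity_partition(weights: np.ndarray):
    """Exhaustive maximum-modularity partition of a tiny graph, scored by
    a direct evaluation of Q on absolute weights."""
    w = np.abs(weights)
    p = w.shape[0]
    m = w.sum() / 2.0
    best_q, best_labels = -np.inf, None
    for part in all_set_partitions(list(range(p))):
        q = 0.0
        for block in part:
            mask = np.zeros(p, dtype=bool)
            mask[block] = True
            e_c = w[np.ix_(mask, mask)].sum() / 2.0
            d_c = w[mask].sum()
            q += e_c / m - (d_c / (2 * m)) ** 2
        if q > best_q + 1e-12:
            best_q = q
            labels = np.empty(p, dtype=int)
            for ci, block in enumerate(sorted(part, key=min)):
                labels[block] = ci
            best_labels = labels
    return best_labels, best_q


def gaussian_mle_by_optimization(S: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Covariance-selection MLE by direct convex optimization (BFGS over
    the free precision entries); independent of the package's iterative
    proportional scaling solver."""
    from scipy.optimize import minimize

    p = S.shape[0]
    jj, kk = np.nonzero(np.triu(support, 1))

    def unpack(x):
        theta = np.diag(np.exp(x[:p]))
        theta[jj, kk] = x[p:]
        theta[kk, jj] = x[p:]
        return theta

    def negll(x):
        theta = unpack(x)
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            return 1e12
        return float(np.sum(S * theta)) - logdet

    res = minimize(negll, np.zeros(p + len(jj)), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    return unpack(res.x)
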