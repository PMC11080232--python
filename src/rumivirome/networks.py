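"""Compositional co-occurrence networks: CLR transform, sparse graphical
lasso with StARS model selection, and the microbe-only vs virus-microbe
comparison metrics.

The precision-matrix estimator is implemented here (proximal-gradient /
soft-thresholding on the penalized Gaussian log-likelihood) because the
network inference is the one computation this comparison depends on; a
Meinshausen-Buhlmann neighborhood-selection fallback sits behind the same
interface. Desk-scale problems (<= a few hundred nodes) are the design
point. Edge signs (partial-correlation signs) are stored, but all reported
metrics use the unweighted simple graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import AbundanceTable

__all__ = [
    "EcologyNetwork",
    "filter_network_nodes",
    "clr_transform",
    "graphical_lasso",
    "infer_network_glasso",
    "node_metrics",
    "fastgreedy_modularity",
    "modularity_q",
    "categorical_assortativity",
    "compare_networks",
    "keystone_nodes",
]


@dataclass
class EcologyNetwork:
    """An undirected co-occurrence network with typed, categorized nodes."""

    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("node_type") == node_type]

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}


def filter_network_nodes(
    micro: AbundanceTable,
    viral: AbundanceTable | None = None,
    micro_abund: float = 1e-4,
    micro_prev: float = 0.5,
    viral_cov: float = 1.0,
    viral_prev: float = 0.5,
) -> tuple[list[str], list[str]]:
    """Pre-network node filters.

    Microbes are kept when their relative abundance strictly exceeds
    ``micro_abund`` (default 0.01%) in at least ``micro_prev`` of samples;
    vOTUs when their trimmed-mean coverage strictly exceeds ``viral_cov``
    (default 1) in at least ``viral_prev`` of samples.
    """
    rel = micro.relative().values
    micro_keep = list(rel.columns[(rel > micro_abund).mean(axis=0) >= micro_prev])
    viral_keep: list[str] = []
    if viral is not None:
        vv = viral.values
        viral_keep = list(vv.columns[(vv > viral_cov).mean(axis=0) >= viral_prev])
    if not micro_keep and not viral_keep:
        warnings.warn("node filters removed every feature")
    return micro_keep, viral_keep


def clr_transform(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform per sample: log(x+pc) minus its row mean."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logx = np.log(np.asarray(counts, dtype=float) + pseudocount)
    return logx - logx.mean(axis=1, keepdims=True)


def _soft_threshold_offdiag(theta: np.ndarray, thresh: float) -> np.ndarray:
    diag = np.diag(theta).copy()
    out = np.sign(theta) * np.maximum(np.abs(theta) - thresh, 0.0)
    np.fill_diagonal(out, diag)
    return out


def _logdet_chol(theta: np.ndarray) -> float | None:
    try:
        chol = np.linalg.cholesky(theta)
    except np.linalg.LinAlgError:
        return None
    return 2.0 * float(np.log(np.diag(chol)).sum())


def graphical_lasso(
    S: np.ndarray,
    lam: float,
    theta0: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> np.ndarray:
    """L1-penalized precision estimation by proximal gradient descent.

    Minimizes ``tr(S @ Theta) - logdet(Theta) + lam * ||offdiag(Theta)||_1``
    with backtracking line search; the soft-threshold proximal step produces
    exact off-diagonal zeros, so the support is the edge set directly.
    """
    S = np.asarray(S, dtype=float)
    if not np.isfinite(S).all():
        raise ValueError("non-finite covariance input")
    p = S.shape[0]
    theta = (
        theta0.copy()
        if theta0 is not None
        else np.diag(1.0 / (np.diag(S) + lam))
    )
    step = 1.0
    logdet = _logdet_chol(theta)
    if logdet is None:
        theta = np.diag(1.0 / (np.diag(S) + lam))
        logdet = _logdet_chol(theta)
    g_cur = float((S * theta).sum()) - logdet

    for _ in range(max_iter):
        w = np.linalg.inv(theta)
        grad = S - w
        while True:
            cand = _soft_threshold_offdiag(theta - step * grad, step * lam)
            cand = (cand + cand.T) / 2.0
            logdet_cand = _logdet_chol(cand)
            if logdet_cand is not None:
                g_cand = float((S * cand).sum()) - logdet_cand
                diff = cand - theta
                bound = g_cur + float((grad * diff).sum()) + float(
                    (diff**2).sum()
                ) / (2 * step)
                if g_cand <= bound + 1e-10:
                    break
            step *= 0.5
            if step < 1e-12:
                return theta
        delta = float(np.max(np.abs(cand - theta)))
        theta, g_cur = cand, g_cand
        step = min(step * 1.2, 1e3)
        if delta < tol:
            break
    return theta


def _adjacency(theta: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    adj = np.abs(theta) > eps
    np.fill_diagonal(adj, False)
    return adj


def _default_lambda_path(S: np.ndarray, n_lambda: int = 30, ratio: float = 1e-2) -> np.ndarray:
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = max(off.max(), 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fit_path(S: np.ndarray, lambdas: np.ndarray, method: str, X: np.ndarray | None = None):
    """Adjacencies along a decreasing lambda path (warm-started for glasso)."""
    adjs = []
    theta = None
    for lam in lambdas:
        if method == "glasso":
            theta = graphical_lasso(S, lam, theta0=theta)
            adjs.append(_adjacency(theta))
        elif method == "mb":
            adjs.append(_mb_adjacency(X, lam))
        else:
            raise ValueError(f"unknown method {method!r}")
    return adjs


def _mb_adjacency(X: np.ndarray, lam: float) -> np.ndarray:
    """Meinshausen-Buhlmann neighborhood selection (OR rule)."""
    from sklearn.linear_model import Lasso

    n, p = X.shape
    adj = np.zeros((p, p), dtype=bool)
    for j in range(p):
        y = X[:, j]
        others = np.delete(np.arange(p), j)
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[:, others], y)
        nz = others[np.abs(model.coef_) > 1e-8]
        adj[j, nz] = True
    return adj | adj.T


def infer_network_glasso(
    clr_matrix,
    lambda_path=None,
    stars_subsamples: int = 20,
    stars_ratio: float = 0.8,
    stars_beta: float = 0.05,
    seed: int = 0,
    node_names: list[str] | None = None,
    node_types: list[str] | None = None,
    categories: list[str] | None = None,
    is_core: list[bool] | None = None,
    method: str = "glasso",
) -> EcologyNetwork:
    """Infer a sparse co-occurrence network from CLR-transformed abundances.

    The regularization level is chosen by StARS: the penalty path is fitted
    on ``stars_subsamples`` row subsamples of size ``stars_ratio * n``, and
    the smallest penalty whose monotonized edge-instability stays within
    ``stars_beta`` is selected. When no penalty meets the bound the largest
    (sparsest) one is used with a warning. Deterministic given ``seed``.
    """
    X = np.asarray(clr_matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite input")
    n, p = X.shape
    names = node_names if node_names is not None else [f"n{j:03d}" for j in range(p)]
    S = np.cov(X, rowvar=False)
    lambdas = (
        np.asarray(lambda_path, dtype=float)
        if lambda_path is not None
        else _default_lambda_path(S)
    )
    if np.any(np.diff(lambdas) >= 0):
        raise ValueError("lambda_path must be strictly decreasing")

    rng = np.random.default_rng(seed)
    # canonical StARS subsample size: b(n) = 10*sqrt(n) for large n, capped
    # by the small-n ratio rule — subsamples must be near-independent for
    # edge instability to be informative
    b = max(2, min(int(np.floor(stars_ratio * n)), int(np.floor(10 * np.sqrt(n)))))
    freq = np.zeros((len(lambdas), p, p))
    for _ in range(stars_subsamples):
        rows = rng.choice(n, size=b, replace=False)
        Xs = X[rows]
        Ss = np.cov(Xs, rowvar=False)
        for li, adj in enumerate(_fit_path(Ss, lambdas, method, Xs)):
            freq[li] += adj
    freq /= stars_subsamples
    iu = np.triu_indices(p, 1)
    instability = np.array([(2 * f * (1 - f))[iu].mean() for f in freq])
    mono = np.maximum.accumulate(instability)  # sparse (large lambda) end first
    ok = np.flatnonzero(mono <= stars_beta)
    if len(ok) == 0:
        warnings.warn("no lambda meets the StARS instability bound; using the largest")
        sel = 0
    else:
        sel = int(ok[-1])

    final_adjs = _fit_path(S, lambdas[: sel + 1], method, X)
    adj = final_adjs[-1]
    if method == "glasso":
        theta = None
        th = None
        for lam in lambdas[: sel + 1]:
            th = graphical_lasso(S, lam, theta0=th)
        signs = -np.sign(th)  # partial correlation sign = -sign(precision)
    else:
        signs = np.ones((p, p))

    g = nx.Graph()
    for j, name in enumerate(names):
        g.add_node(
            name,
            node_type=(node_types[j] if node_types else "microbe"),
            category=(categories[j] if categories else ""),
            is_core=(bool(is_core[j]) if is_core else False),
        )
    for i in range(p):
        for j in range(i + 1, p):
            if adj[i, j]:
                g.add_edge(names[i], names[j], sign=int(signs[i, j]))

    return EcologyNetwork(
        graph=g,
        provenance={
            "method": method,
            "lambda_path": lambdas.tolist(),
            "selected_lambda": float(lambdas[sel]),
            "selected_index": sel,
            "stars_subsamples": stars_subsamples,
            "stars_ratio": stars_ratio,
            "stars_beta": stars_beta,
            "instability": instability.tolist(),
            "seed": seed,
        },
    )


def node_metrics(net: EcologyNetwork | nx.Graph) -> pd.DataFrame:
    """Per-node degree and unnormalized Brandes betweenness centrality."""
    g = net.graph if isinstance(net, EcologyNetwork) else net
    betweenness = nx.betweenness_centrality(g, normalized=False)
    return pd.DataFrame(
        {
            "degree": {n: d for n, d in g.degree()},
            "betweenness": betweenness,
        }
    )


def modularity_q(g: nx.Graph, partition: dict) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2) of a given partition."""
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    comms = set(partition.values())
    e = dict.fromkeys(comms, 0.0)
    a = dict.fromkeys(comms, 0.0)
    for u, v in g.edges:
        cu, cv = partition[u], partition[v]
        if cu == cv:
            e[cu] += 1.0 / m
        a[cu] += 0.5 / m
        a[cv] += 0.5 / m
    return sum(e[c] - a[c] ** 2 for c in comms)


def fastgreedy_modularity(net: EcologyNetwork | nx.Graph) -> tuple[dict, float]:
    """Greedy agglomerative (CNM-style) modularity maximization.

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest modularity gain (ties broken by the smallest
    community-index pair), returning the partition at the Q maximum along
    the merge path.
    """
    g = net.graph if isinstance(net, EcologyNetwork) else net
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    nodes = sorted(g.nodes, key=str)
    cid = {node: i for i, node in enumerate(nodes)}

    # between-community edge fractions and degree fractions
    b: dict[int, dict[int, float]] = {i: {} for i in range(len(nodes))}
    a = np.zeros(len(nodes))
    e_internal = np.zeros(len(nodes))
    for u, v in g.edges:
        cu, cv = cid[u], cid[v]
        a[cu] += 0.5 / m
        a[cv] += 0.5 / m
        if cu == cv:
            e_internal[cu] += 1.0 / m
        else:
            b[cu][cv] = b[cu].get(cv, 0.0) + 1.0 / m
            b[cv][cu] = b[cv].get(cu, 0.0) + 1.0 / m

    q = float(e_internal.sum() - (a**2).sum())
    best_q = q
    best_partition = dict(cid)

    alive = set(range(len(nodes)))
    while len(alive) > 1:
        best = None
        for i in sorted(alive):
            for j in sorted(b[i]):
                if j <= i:
                    continue
                dq = b[i][j] - 2 * a[i] * a[j]
                if best is None or dq > best[0] + 1e-15:
                    best = (dq, i, j)
        if best is None:
            break  # remaining communities are disconnected
        dq, i, j = best
        # merge j into i
        e_internal[i] += e_internal[j] + b[i].get(j, 0.0)
        a[i] += a[j]
        for k, w in b[j].items():
            if k == i:
                continue
            b[i][k] = b[i].get(k, 0.0) + w
            b[k][i] = b[k].get(i, 0.0) + w
        for k in b[j]:
            b[k].pop(j, None)
        b[i].pop(j, None)
        b[j] = {}
        alive.discard(j)
        for node, c in cid.items():
            if c == j:
                cid[node] = i
        q += dq
        if q > best_q + 1e-12:
            best_q = q
            best_partition = dict(cid)

    # renumber communities densely
    remap = {c: k for k, c in enumerate(sorted(set(best_partition.values())))}
    return {node: remap[c] for node, c in best_partition.items()}, float(best_q)


def categorical_assortativity(
    net: EcologyNetwork | nx.Graph, category: str | dict = "category"
) -> float:
    """Newman's categorical assortativity r = (sum e_ii - sum a_i b_i) /
    (1 - sum a_i b_i) over the edge mixing matrix; NaN (with a warning) for a
    single-category graph where the denominator vanishes.
    """
    g = net.graph if isinstance(net, EcologyNetwork) else net
    if g.number_of_edges() == 0:
        raise ValueError("assortativity undefined for an edgeless graph")
    if isinstance(category, dict):
        cat = category
    else:
        cat = nx.get_node_attributes(g, category)
    cats = sorted({cat[n] for n in g.nodes})
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    mix = np.zeros((k, k))
    for u, v in g.edges:
        cu, cv = idx[cat[u]], idx[cat[v]]
        mix[cu, cv] += 1
        mix[cv, cu] += 1
    mix /= mix.sum()
    trace = np.trace(mix)
    ab = float(mix.sum(axis=0) @ mix.sum(axis=1))
    if abs(1 - ab) < 1e-12:
        warnings.warn("single-category graph: assortativity undefined")
        return float("nan")
    return float((trace - ab) / (1 - ab))


def keystone_nodes(
    metrics: pd.DataFrame, degree_min: float = 15, betweenness_min: float = 15000
) -> set[str]:
    """Nodes strictly exceeding both the degree and betweenness thresholds."""
    keep = (metrics["degree"] > degree_min) & (metrics["betweenness"] > betweenness_min)
    return set(metrics.index[keep])


def compare_networks(micro_net: EcologyNetwork, combined_net: EcologyNetwork) -> dict:
    """Microbe-only vs virus-microbe network comparison.

    Tests whether microbial nodes are better connected in the combined
    network (paired one-tailed t-test on per-node degree, alternative:
    combined > microbe-only) and reports modularity, categorical
    assortativity, mean +- sd degree and isolated-microbial-node counts side
    by side. The microbial node sets of the two networks must be identical.
    """
    micro_nodes = sorted(micro_net.graph.nodes)
    combined_micro = sorted(combined_net.nodes_of_type("microbe"))
    if micro_nodes != combined_micro:
        missing = set(micro_nodes) ^ set(combined_micro)
        raise ValueError(f"microbial node sets differ: {sorted(missing)}")

    deg_micro = np.array([micro_net.graph.degree(n) for n in micro_nodes], dtype=float)
    deg_comb = np.array([combined_net.graph.degree(n) for n in micro_nodes], dtype=float)
    diffs = deg_comb - deg_micro
    if np.allclose(diffs, 0):
        t_stat, p = 0.0, 0.5
    else:
        t_stat, p = stats.ttest_rel(deg_comb, deg_micro, alternative="greater")

    def _net_summary(net: EcologyNetwork, degrees: np.ndarray) -> dict:
        g = net.graph
        try:
            _, q = fastgreedy_modularity(g)
        except ValueError:
            q = float("nan")
        try:
            r = categorical_assortativity(g)
        except ValueError:
            r = float("nan")
        return {
            "modularity": q,
            "assortativity": r,
            "mean_microbial_degree": float(degrees.mean()),
            "sd_microbial_degree": float(degrees.std(ddof=1)) if len(degrees) > 1 else 0.0,
            "isolated_microbial_nodes": int((degrees == 0).sum()),
        }

    return {
        "micro_only": _net_summary(micro_net, deg_micro),
        "combined": _net_summary(combined_net, deg_comb),
        "paired_t": float(t_stat),
        "p_one_tailed": float(p),
        "n_microbial_nodes": len(micro_nodes),
    }
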