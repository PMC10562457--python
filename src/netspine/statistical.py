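"""Statistical edge-significance methods.

Each method tests every edge weight against a null model of weight formation
and annotates the graph with a per-edge p-value (Multiple Linkage Analysis,
which selects a substructure directly, attaches a boolean flag instead).
Methods with a *local* scope build one null per node; an edge then receives
the **minimum** of its two endpoint p-values — an edge is retained when it is
significant from the viewpoint of at least one of the nodes it connects.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, stats

from .backbone import FILTER_COMPATIBILITY, BackboneResult
from .graphio import require_integer_weights

__all__ = [
    "disparity",
    "marginal_likelihood",
    "noise_corrected",
    "ECMParameters",
    "ecm_fit",
    "ecm_filter",
    "lans",
    "mla",
]


def _check_nonempty(net: nx.Graph) -> None:
    if net.number_of_edges() == 0:
        raise ValueError("graph has no edges")


def _strengths(net: nx.Graph) -> dict:
    return {n: float(s) for n, s in net.degree(weight="weight")}


# ---------------------------------------------------------------------------
# disparity filter
# ---------------------------------------------------------------------------

def disparity(net: nx.Graph) -> BackboneResult:
    """Disparity filter: per-node uniform null on normalized weights.

    Under the null, the k_i weights of node i split the node's strength as
    k_i - 1 uniform break points split the unit interval.  The survival
    probability of an observed normalized weight p_ij = w_ij / s_i is then
    ``(1 - p_ij)**(k_i - 1)``.  Endpoints of degree one are uninformative and
    contribute a p-value of 1; the edge keeps the smaller endpoint value.
    """
    _check_nonempty(net)
    g = net.copy()
    s = _strengths(g)
    k = dict(g.degree())
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        ps = []
        for node in (u, v):
            if k[node] < 2:
                ps.append(1.0)
            else:
                ps.append((1.0 - w / s[node]) ** (k[node] - 1))
        d["endpoint_p_values"] = (ps[0], ps[1]) if u <= v else (ps[1], ps[0])
        d["p_value"] = float(min(ps))
    return BackboneResult(
        graph=g,
        method_name="Disparity Filter",
        property_name="p_value",
        is_pvalue=True,
        compatible_filters=FILTER_COMPATIBILITY["Disparity Filter"],
    )


# ---------------------------------------------------------------------------
# marginal likelihood filter
# ---------------------------------------------------------------------------

def _binomial_null(net: nx.Graph) -> dict:
    """Per-edge binomial survival P(X >= w), X ~ Binomial(T, s_i s_j / 2T^2).

    T is the total weight of the network, read as a number of unit edges each
    of which picks its two endpoints with probability proportional to the
    endpoint strengths.
    """
    s = _strengths(net)
    T = round(sum(s.values()) / 2.0)
    out = {}
    for u, v, d in net.edges(data=True):
        w = round(d["weight"])
        pi = s[u] * s[v] / (2.0 * T * T)
        out[(u, v)] = float(np.clip(stats.binom.sf(w - 1, T, pi), 0.0, 1.0))
    return out


def marginal_likelihood(net: nx.Graph) -> BackboneResult:
    """Marginal likelihood filter (integer weights required).

    An integer weight w_ij is read as w_ij unit edges out of the T unit edges
    of the whole network; the p-value is the binomial probability of drawing
    at least w_ij of them between i and j when each unit edge chooses its
    endpoint pair with probability s_i s_j / 2T².
    """
    _check_nonempty(net)
    require_integer_weights(net, "marginal_likelihood")
    g = net.copy()
    pvals = _binomial_null(g)
    for (u, v), p in pvals.items():
        g[u][v]["p_value"] = p
    return BackboneResult(
        graph=g,
        method_name="Marginal Likelihood Filter",
        property_name="p_value",
        is_pvalue=True,
        compatible_filters=FILTER_COMPATIBILITY["Marginal Likelihood Filter"],
    )


# ---------------------------------------------------------------------------
# noise corrected filter
# ---------------------------------------------------------------------------

def noise_corrected(net: nx.Graph, delta: float = 1.64, mode: str = "score") -> BackboneResult:
    """Noise-corrected filter.

    ``mode="pvalue"`` evaluates the same binomial null as the marginal
    likelihood filter.  ``mode="score"`` standardizes each weight against a
    Bayesian estimate of its null expectation: the null propensity
    π_ij = s_i s_j / 2T² is smoothed by a conjugate uniform Beta(1, 1) prior,
    π̃ = (Tπ + 1)/(T + 2), and the score is (w - Tπ̃) / sd with the binomial
    standard deviation sd = sqrt(Tπ̃(1 - π̃)).  An edge counts as "δ standard
    deviations stronger than expected" when its score exceeds ``delta``
    (apply a threshold filter at δ); the default δ = 1.64 corresponds to a
    one-sided 95% band.
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if mode not in ("score", "pvalue"):
        raise ValueError("mode must be 'score' or 'pvalue'")
    _check_nonempty(net)
    g = net.copy()
    if mode == "pvalue":
        require_integer_weights(net, "noise_corrected(mode='pvalue')")
        for (u, v), p in _binomial_null(g).items():
            g[u][v]["p_value"] = p
        return BackboneResult(
            graph=g,
            method_name="Noise Corrected Filter",
            property_name="p_value",
            is_pvalue=True,
            compatible_filters=FILTER_COMPATIBILITY["Noise Corrected Filter"],
        )
    s = _strengths(g)
    T = sum(s.values()) / 2.0
    for u, v, d in g.edges(data=True):
        w = d["weight"]
        pi = s[u] * s[v] / (2.0 * T * T)
        pi_post = (T * pi + 1.0) / (T + 2.0)
        expected = T * pi_post
        sd = np.sqrt(T * pi_post * (1.0 - pi_post))
        d["expected_weight"] = float(expected)
        d["score"] = float((w - expected) / sd)
    return BackboneResult(
        graph=g,
        method_name="Noise Corrected Filter",
        property_name="score",
        is_pvalue=False,
        compatible_filters=FILTER_COMPATIBILITY["Noise Corrected Filter"],
    )


# ---------------------------------------------------------------------------
# enhanced configuration model filter
# ---------------------------------------------------------------------------

@dataclass
class ECMParameters:
    """Fitted node parameters of the enhanced configuration model.

    ``x[i] > 0`` controls node i's expected degree, ``y[i] ∈ (0, 1)`` its
    expected strength; under the fitted canonical ensemble the expected
    degree and strength of every node match the observed values.
    """

    x: dict
    y: dict
    residual: float
    n_iterations: int

    def connection_probability(self, i, j) -> float:
        t = self.y[i] * self.y[j]
        z = self.x[i] * self.x[j]
        return z * t / (1.0 - t + z * t)

    def expected_degree(self, i) -> float:
        return sum(self.connection_probability(i, j) for j in self.x if j != i)

    def expected_strength(self, i) -> float:
        return sum(
            self.connection_probability(i, j) / (1.0 - self.y[i] * self.y[j])
            for j in self.x
            if j != i
        )


def _ecm_expectations(u: np.ndarray, v: np.ndarray):
    """Vectorized ensemble expectations for log/logit-parametrized (x, y)."""
    x = np.exp(u)
    y = 1.0 / (1.0 + np.exp(-v))
    t = np.outer(y, y)
    z = np.outer(x, x)
    p = z * t / (1.0 - t + z * t)
    np.fill_diagonal(p, 0.0)
    k_exp = p.sum(axis=1)
    s_exp = (p / (1.0 - t + np.eye(len(u)))).sum(axis=1)
    return k_exp, s_exp, p, y


def _ecm_jacobian(theta: np.ndarray, n: int, scale_k: np.ndarray, scale_s: np.ndarray):
    """Analytic Jacobian of the scaled moment residuals.

    With x = e^u, y = σ(v), t = y_i y_j, z = x_i x_j, D = 1 - t + zt:
    ∂p/∂u_{i or j} = zt(1-t)/D², ∂p/∂t = z/D², ∂q/∂u = zt/D² and
    ∂q/∂t = z(D - tA(z-1))/(A²D²) with q = p/(1-t), A = 1 - t; the chain
    rule adds ∂t/∂v_i = t(1-y_i).
    """
    u, vv = theta[:n], theta[n:]
    x = np.exp(u)
    y = 1.0 / (1.0 + np.exp(-vv))
    t = np.outer(y, y)
    z = np.outer(x, x)
    A = 1.0 - t
    D = A + z * t
    off = 1.0 - np.eye(n)
    pu = z * t * A / D**2 * off          # ∂p_ij/∂u_i = ∂p_ij/∂u_j
    pt = z * t / D**2 * off              # ∂p_ij/∂t · t  (chain rule below)
    qu = z * t / D**2 * off              # ∂q_ij/∂u_i
    qt = z * t * (D - t * A * (z - 1.0)) / (A**2 * D**2) * off  # ∂q_ij/∂t · t
    omy = 1.0 - y
    j_ku = pu + np.diag(pu.sum(axis=1))
    j_kv = pt * omy[None, :] + np.diag(omy * pt.sum(axis=1))
    j_su = qu + np.diag(qu.sum(axis=1))
    j_sv = qt * omy[None, :] + np.diag(omy * qt.sum(axis=1))
    top = np.hstack([j_ku, j_kv]) / scale_k[:, None]
    bottom = np.hstack([j_su, j_sv]) / scale_s[:, None]
    return np.vstack([top, bottom])


def ecm_fit(net: nx.Graph, tol: float = 1e-8, max_iter: int = 10_000) -> ECMParameters:
    """Fit the maximum-entropy ensemble matching degrees and strengths.

    Solves the 2n nonlinear moment conditions ⟨k_i⟩ = k_i, ⟨s_i⟩ = s_i for
    per-node parameters (x_i, y_i) by trust-region least squares on
    log/logit-transformed variables.  Raises when the maximum relative
    residual stays above ``tol``.
    """
    _check_nonempty(net)
    require_integer_weights(net, "ecm")
    nodes = list(net.nodes)
    n = len(nodes)
    k_obs = np.array([net.degree(i) for i in nodes], dtype=float)
    s_obs = np.array([net.degree(i, weight="weight") for i in nodes], dtype=float)
    if np.any(k_obs == 0):
        isolated = [nodes[i] for i in np.where(k_obs == 0)[0]]
        raise ValueError(f"isolated nodes cannot be fitted: {isolated[:5]}")
    scale_k = np.maximum(k_obs, 1.0)
    scale_s = np.maximum(s_obs, 1.0)

    def residuals(theta):
        k_exp, s_exp, _, _ = _ecm_expectations(theta[:n], theta[n:])
        return np.concatenate(
            [(k_exp - k_obs) / scale_k, (s_exp - s_obs) / scale_s]
        )

    # moment-inspired starting point
    x0 = k_obs / np.sqrt(k_obs.sum())
    y0 = s_obs / (s_obs + s_obs.mean())
    theta0 = np.concatenate([np.log(x0), np.log(y0 / (1.0 - y0))])
    sol = optimize.least_squares(
        residuals,
        theta0,
        jac=lambda th: _ecm_jacobian(th, n, scale_k, scale_s),
        method="trf",
        xtol=2.3e-16,
        ftol=2.3e-16,
        gtol=1e-14,
        max_nfev=max_iter,
    )
    res = np.max(np.abs(sol.fun))
    if res > tol:
        raise RuntimeError(
            f"ECM fit did not converge: max relative residual {res:.3e} > {tol:.1e}"
        )
    x = np.exp(sol.x[:n])
    y = 1.0 / (1.0 + np.exp(-sol.x[n:]))
    return ECMParameters(
        x=dict(zip(nodes, x.tolist())),
        y=dict(zip(nodes, y.tolist())),
        residual=float(res),
        n_iterations=int(sol.nfev),
    )


def ecm_filter(net: nx.Graph, params: ECMParameters | None = None) -> BackboneResult:
    """Enhanced configuration model filter.

    Given the fitted ensemble, the weight on a node pair follows a geometric
    law above zero: P(W_ij ≥ w) = p_ij (y_i y_j)^(w-1) for integer w ≥ 1,
    with connection probability p_ij.  The p-value of an observed edge is
    that survival probability.
    """
    if params is None:
        params = ecm_fit(net)
    g = net.copy()
    for u, v, d in g.edges(data=True):
        w = round(d["weight"])
        p_con = params.connection_probability(u, v)
        t = params.y[u] * params.y[v]
        d["p_value"] = float(np.clip(p_con * t ** (w - 1), 0.0, 1.0))
    return BackboneResult(
        graph=g,
        method_name="Enhanced Configuration Model Filter",
        property_name="p_value",
        is_pvalue=True,
        compatible_filters=FILTER_COMPATIBILITY["Enhanced Configuration Model Filter"],
    )


# ---------------------------------------------------------------------------
# locally adaptive network sparsification
# ---------------------------------------------------------------------------

def lans(net: nx.Graph) -> BackboneResult:
    """LANS: empirical survival of fractional edge weights, per node.

    No parametric null: from node i's viewpoint the p-value of edge (i, j)
    is the fraction of i's edges whose fractional weight w_iu/s_i is at
    least w_ij/s_i (inclusive, so a node's strongest edge gets 1/k_i, never
    0).  The edge keeps the smaller endpoint value.
    """
    _check_nonempty(net)
    g = net.copy()
    s = _strengths(g)
    for u, v, d in g.edges(data=True):
        ps = []
        for node, other in ((u, v), (v, u)):
            w = d["weight"] / s[node]
            neigh = [g[node][x]["weight"] / s[node] for x in g[node]]
            ps.append(sum(1 for f in neigh if f >= w - 1e-12) / len(neigh))
        d["endpoint_p_values"] = (ps[0], ps[1]) if u <= v else (ps[1], ps[0])
        d["p_value"] = float(min(ps))
    return BackboneResult(
        graph=g,
        method_name="Locally Adaptive Network Sparsification Filter",
        property_name="p_value",
        is_pvalue=True,
        compatible_filters=FILTER_COMPATIBILITY[
            "Locally Adaptive Network Sparsification Filter"
        ],
    )


# ---------------------------------------------------------------------------
# multiple linkage analysis
# ---------------------------------------------------------------------------

def _mla_optimal_m(weights: np.ndarray) -> int:
    """Number of top edges to keep for one node.

    Compares the observed descending weight vector against hypothetical
    vectors that spread the node's strength evenly over the top m positions
    (m = 1..n), scoring each by Pearson correlation; returns the smallest m
    attaining the maximum.  A zero-variance observed vector (all weights
    equal) matches the full uniform hypothesis exactly, so all edges are
    kept.
    """
    n = len(weights)
    if n == 1:
        return 1
    obs = np.sort(weights)[::-1]
    if np.ptp(obs) == 0:
        return n
    s = obs.sum()
    best_m, best_r = 1, -np.inf
    for m in range(1, n + 1):
        hyp = np.zeros(n)
        hyp[:m] = s / m
        if np.ptp(hyp) == 0:  # m == n: constant hypothesis, correlation undefined
            continue
        r = np.corrcoef(obs, hyp)[0, 1]
        if r > best_r + 1e-12:
            best_m, best_r = m, r
    return best_m


def mla(net: nx.Graph) -> BackboneResult:
    """Multiple linkage analysis: per-node optimal top-m edge retention.

    The backbone is the union over nodes of each node's top-m* edges by
    weight, where m* maximizes the Pearson correlation between the observed
    sorted weight vector and an even-spread hypothetical vector.  Degree-one
    nodes keep their single edge.  Boolean filtering only.
    """
    _check_nonempty(net)
    g = net.copy()
    keep: set = set()
    for node in g.nodes:
        nbrs = sorted(
            g[node], key=lambda x: (-g[node][x]["weight"], x)
        )
        if not nbrs:
            continue
        weights = np.array([g[node][x]["weight"] for x in nbrs])
        m = _mla_optimal_m(weights)
        for x in nbrs[:m]:
            keep.add(frozenset((node, x)))
    for u, v, d in g.edges(data=True):
        d["in_backbone"] = frozenset((u, v)) in keep
    return BackboneResult(
        graph=g,
        method_name="Multiple Linkage Analysis",
        property_name="in_backbone",
        is_pvalue=False,
        compatible_filters=FILTER_COMPATIBILITY["Multiple Linkage Analysis"],
        boolean_attribute="in_backbone",
    )
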