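"""Network statistics: centrality indices, random-graph nulls, structure
classification, bootstrap uncertainty, and rank correlations.

Conventions fixed here (and relied on throughout):

* betweenness and closeness treat edge weight as a distance;
* strength and eigenvector centrality treat edge weight as connection mass;
* the clustering coefficient is binary (unweighted), NA for degree < 2;
* characteristic path length is computed on unweighted hops;
* closeness is 1 / (sum of weighted shortest-path distances), larger = more
  central;
* eigenvector centrality is the principal eigenvector of the weighted
  adjacency scaled so its maximum is 1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from lekgraph.errors import ValidationError
from lekgraph.popgraph import PopGraph

logger = logging.getLogger(__name__)

CENTRALITY_INDICES = (
    "degree", "strength", "betweenness", "closeness", "clustering", "eigenvector",
)


def _as_graph(pg: PopGraph | nx.Graph) -> nx.Graph:
    return pg.to_networkx() if isinstance(pg, PopGraph) else pg


# ---------------------------------------------------------------------------
# centrality suite
# ---------------------------------------------------------------------------

def eigenvector_centrality(graph: nx.Graph) -> dict:
    """Principal eigenvector of the weighted adjacency, scaled to max 1."""
    ids = list(graph.nodes)
    if not ids:
        return {}
    A = nx.to_numpy_array(graph, nodelist=ids, weight="weight")
    if not A.any():
        return {n: np.nan for n in ids}
    vals, vecs = np.linalg.eigh(A)
    v = np.abs(vecs[:, np.argmax(vals)])
    v = v / v.max()
    return {n: float(v[i]) for i, n in enumerate(ids)}


def closeness_centrality(graph: nx.Graph) -> dict:
    """1 / (summed weighted shortest-path distance to all reachable nodes).

    Computed per connected component (with a warning when the graph is
    disconnected); isolated nodes get NaN.
    """
    if graph.number_of_nodes() > 1 and not nx.is_connected(graph):
        logger.warning("graph disconnected; closeness computed per component")
    out = {}
    for node in graph.nodes:
        dists = nx.single_source_dijkstra_path_length(graph, node, weight="weight")
        total = sum(d for other, d in dists.items() if other != node)
        out[node] = 1.0 / total if total > 0 else np.nan
    return out


def centrality_suite(pg: PopGraph | nx.Graph) -> pd.DataFrame:
    """All six node centrality indices as one table.

    Columns: degree, strength, betweenness, closeness, clustering,
    eigenvector.  The clustering coefficient is NaN for nodes of degree
    below 2 (no neighbor pair to close a triangle).
    """
    graph = _as_graph(pg)
    if graph.number_of_nodes() == 0:
        raise ValidationError("graph has no nodes")
    ids = list(graph.nodes)
    degree = dict(graph.degree())
    strength = dict(graph.degree(weight="weight"))
    betweenness = nx.betweenness_centrality(graph, normalized=False, weight="weight")
    closeness = closeness_centrality(graph)
    clustering = nx.clustering(graph)  # unweighted
    eigen = eigenvector_centrality(graph)
    df = pd.DataFrame({
        "degree": [degree[n] for n in ids],
        "strength": [float(strength[n]) for n in ids],
        "betweenness": [betweenness[n] for n in ids],
        "closeness": [closeness[n] for n in ids],
        "clustering": [clustering[n] if degree[n] >= 2 else np.nan for n in ids],
        "eigenvector": [eigen[n] for n in ids],
    }, index=pd.Index(ids, name="node_id"))
    return df


def mean_clustering_coefficient(graph: nx.Graph) -> float:
    """Network mean of the unweighted local clustering coefficient,
    excluding NA (degree < 2) nodes."""
    degree = dict(graph.degree())
    values = [c for n, c in nx.clustering(graph).items() if degree[n] >= 2]
    return float(np.mean(values)) if values else np.nan


def characteristic_path_length(pg: PopGraph | nx.Graph) -> float:
    """Mean unweighted shortest-path hop count over connected node pairs.

    Unreachable pairs are excluded with a warning.
    """
    graph = _as_graph(pg)
    n = graph.number_of_nodes()
    if n < 2:
        return np.nan
    total = 0.0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        total += sum(dists.values())
        count += len(dists) - 1  # exclude self
    if count < n * (n - 1):
        logger.warning("unreachable pairs excluded from characteristic path length")
    if count == 0:
        return np.nan
    return total / count  # ordered pairs; symmetric so equals unordered mean


# ---------------------------------------------------------------------------
# random-network null ensemble
# ---------------------------------------------------------------------------

@dataclass
class NullComparison:
    """Observed structure statistics vs a matched Erdos-Renyi ensemble."""

    observed: dict[str, float]
    observed_degrees: np.ndarray
    null_clustering: np.ndarray
    null_cpl: np.ndarray
    ks_vs_observed: np.ndarray  # KS(replicate degrees, observed degrees)
    ks_null_pairs: np.ndarray   # KS(replicate degrees, partner replicate degrees)
    p_values: dict[str, float]
    B: int
    seed: int

    def summary(self) -> dict:
        return {
            "observed": self.observed,
            "null_clustering_mean": float(np.nanmean(self.null_clustering)),
            "null_cpl_mean": float(np.nanmean(self.null_cpl)),
            "p_values": self.p_values,
            "B": self.B,
            "seed": self.seed,
        }


def er_null_ensemble(pg: PopGraph | nx.Graph, B: int = 1000, seed: int = 0) -> NullComparison:
    """Compare the observed network to B uniform G(k, m) random graphs.

    Each replicate has the observed node and edge counts with the observed
    edge weights randomly permuted onto its edges.  Per replicate we record
    the mean clustering coefficient, the characteristic path length, and
    the two-sample KS statistic between replicate and observed degree
    sequences.  One-sided permutation p-values use (1 + #{null >= obs}) /
    (B + 1); the degree-distribution p compares each replicate's distance
    from the observed graph to its distance from a partner replicate.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    graph = _as_graph(pg)
    k = graph.number_of_nodes()
    m = graph.number_of_edges()
    if m > k * (k - 1) // 2:
        raise ValidationError(f"impossible graph: {m} edges on {k} nodes")
    weights = np.array([d.get("weight", 1.0) for _, _, d in graph.edges(data=True)])
    obs_degrees = np.array([d for _, d in graph.degree()])
    observed = {
        "mean_clustering": mean_clustering_coefficient(graph),
        "characteristic_path_length": characteristic_path_length(graph),
    }

    children = np.random.SeedSequence(seed).spawn(B)
    null_cc = np.empty(B)
    null_cpl = np.empty(B)
    null_degrees: list[np.ndarray] = []
    ks_obs = np.empty(B)
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep = nx.gnm_random_graph(k, m, seed=int(child.generate_state(1)[0]))
        perm = rng.permutation(weights)
        for w, (u, v) in zip(perm, rep.edges()):
            rep[u][v]["weight"] = float(w)
        null_cc[b] = mean_clustering_coefficient(rep)
        null_cpl[b] = characteristic_path_length(rep)
        deg = np.array([d for _, d in rep.degree()])
        null_degrees.append(deg)
        ks_obs[b] = stats.ks_2samp(deg, obs_degrees, method="asymp").statistic

    ks_pairs = np.array([
        stats.ks_2samp(null_degrees[b], null_degrees[(b + 1) % B], method="asymp").statistic
        for b in range(B)
    ])
    with np.errstate(invalid="ignore"):
        p_cc = (1 + np.sum(null_cc >= observed["mean_clustering"])) / (B + 1)
        p_cpl = (1 + np.sum(null_cpl >= observed["characteristic_path_length"])) / (B + 1)
        p_deg = (1 + np.sum(ks_pairs >= ks_obs)) / (B + 1)
    return NullComparison(
        observed=observed,
        observed_degrees=obs_degrees,
        null_clustering=null_cc,
        null_cpl=null_cpl,
        ks_vs_observed=ks_obs,
        ks_null_pairs=ks_pairs,
        p_values={
            "mean_clustering": float(p_cc),
            "characteristic_path_length": float(p_cpl),
            "degree_distribution": float(p_deg),
        },
        B=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# structure classification
# ---------------------------------------------------------------------------

def _powerlaw_loglik(alpha: float, data: np.ndarray, xmin: int) -> float:
    return -data.size * math.log(special.zeta(alpha, xmin)) - alpha * np.sum(np.log(data))


def _fit_discrete_powerlaw(data: np.ndarray, xmin: int) -> float:
    res = optimize.minimize_scalar(
        lambda a: -_powerlaw_loglik(a, data, xmin), bounds=(1.01, 8.0), method="bounded"
    )
    return float(res.x)


def _powerlaw_ks(data: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, data.max() + 1)
    pmf = xs.astype(float) ** -alpha / special.zeta(alpha, xmin)
    cdf = np.cumsum(pmf)
    emp = np.searchsorted(np.sort(data), xs, side="right") / data.size
    return float(np.max(np.abs(emp - cdf)))


def powerlaw_gof(
    degrees: np.ndarray, n_boot: int = 50, seed: int = 0
) -> tuple[float, float, float]:
    """Discrete power-law fit with a parametric-bootstrap goodness of fit.

    Returns (alpha_hat, ks_statistic, bootstrap_p).  Degrees of zero are
    excluded; xmin is the smallest positive degree.  A p below ~0.1 rejects
    the power law (Clauset-style convention).
    """
    data = np.asarray(degrees)
    data = data[data > 0]
    if data.size < 10 or np.unique(data).size < 3:
        return np.nan, np.nan, 0.0  # too little variation: treat as rejected
    xmin = int(data.min())
    alpha_hat = _fit_discrete_powerlaw(data, xmin)
    ks_obs = _powerlaw_ks(data, alpha_hat, xmin)
    rng = np.random.default_rng(seed)
    support = np.arange(xmin, max(int(data.max()) * 5, xmin + 100))
    pmf = support.astype(float) ** -alpha_hat
    pmf /= pmf.sum()
    count = 0
    for _ in range(n_boot):
        synth = rng.choice(support, size=data.size, p=pmf)
        a = _fit_discrete_powerlaw(synth, xmin)
        if _powerlaw_ks(synth, a, xmin) >= ks_obs:
            count += 1
    return alpha_hat, ks_obs, count / n_boot


def classify_structure(
    nc: NullComparison,
    alpha: float = 0.05,
    cpl_factor: float = 2.0,
    powerlaw_boot: int = 50,
    seed: int = 0,
) -> tuple[str, dict]:
    """Classify the network as regular / random / small_world / scale_free.

    small_world: clustering significantly above the null and a short
    characteristic path length (observed <= null 97.5th percentile x
    ``cpl_factor``).  scale_free is the small-world sub-case where a
    discrete power-law fit to the degree distribution is not rejected.
    regular: (near) zero degree variance.  random: neither clustering nor
    the degree distribution deviates from the ensemble.  The evidence dict
    records every sub-decision.
    """
    deg = np.asarray(nc.observed_degrees, dtype=float)
    evidence: dict = {"p_values": dict(nc.p_values)}
    evidence["degree_variance"] = float(deg.var()) if deg.size else 0.0
    if deg.size and evidence["degree_variance"] < 1e-12:
        evidence["decision"] = "constant degree"
        return "regular", evidence

    clustering_sig = nc.p_values["mean_clustering"] < alpha
    degree_sig = nc.p_values["degree_distribution"] < alpha
    cpl_obs = nc.observed["characteristic_path_length"]
    cpl_q975 = float(np.nanquantile(nc.null_cpl, 0.975))
    cpl_short = bool(np.isfinite(cpl_obs) and cpl_obs <= cpl_factor * cpl_q975)
    evidence.update({
        "clustering_significant": bool(clustering_sig),
        "degree_significant": bool(degree_sig),
        "cpl_observed": float(cpl_obs) if np.isfinite(cpl_obs) else None,
        "cpl_null_q975": cpl_q975,
        "cpl_short": cpl_short,
    })
    if clustering_sig and cpl_short:
        pl_alpha, pl_ks, pl_p = powerlaw_gof(deg, n_boot=powerlaw_boot, seed=seed)
        evidence["powerlaw"] = {"alpha": pl_alpha, "ks": pl_ks, "p": pl_p}
        if pl_p >= 0.1:
            evidence["decision"] = "clustered, short paths, power-law degree"
            return "scale_free", evidence
        evidence["decision"] = "clustered, short paths, non-power-law degree"
        return "small_world", evidence
    if not clustering_sig and not degree_sig:
        evidence["decision"] = "no deviation from the matched random ensemble"
        return "random", evidence
    evidence["decision"] = "mixed signals; defaulting to random"
    return "random", evidence


# ---------------------------------------------------------------------------
# bootstrap uncertainty
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """SE and percentile 95% CIs of each index's mean and median over
    node-resampled networks."""

    table: pd.DataFrame  # indexed by centrality index
    f: float
    B: int
    mode: str
    seed: int
    replicate_size: int
    n_disconnected: int = 0


def _replicate_stats(suite: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.array([np.nanmean(suite[c].to_numpy(float)) for c in CENTRALITY_INDICES])
        medians = np.array([np.nanmedian(suite[c].to_numpy(float)) for c in CENTRALITY_INDICES])
    return means, medians


def bootstrap_centrality(
    means_or_pg,
    f: float = 0.75,
    B: int = 1000,
    seed: int = 0,
    mode: str = "rebuild",
    params=None,
) -> BootstrapSummary:
    """Bootstrap centrality indices over networks of a node subset.

    ``means_or_pg``: for ``mode="rebuild"`` (default) pass a tuple
    ``(node_ids, mean_vectors)`` — the per-node mean encoding vectors —
    and each replicate refits the conditional graph on ``floor(f * k)``
    nodes sampled without replacement.  For ``mode="subgraph"`` pass a
    fitted :class:`PopGraph` (or graph) and each replicate takes the
    induced subgraph.  Replicates with a disconnected graph contribute
    per-component statistics and are counted in ``n_disconnected``.
    """
    from lekgraph.popgraph import fit_conditional_graph, gower_covariance

    if not 0 < f <= 1:
        raise ValidationError("f must be in (0, 1]")
    if mode not in ("rebuild", "subgraph"):
        raise ValidationError(f"unknown mode {mode!r}")

    if mode == "subgraph":
        graph = _as_graph(means_or_pg)
        node_ids = list(graph.nodes)
    else:
        node_ids, means = means_or_pg
        node_ids = list(node_ids)
        means = np.asarray(means, dtype=float)
    k = len(node_ids)
    size = int(f * k + 1e-9)
    if size < 2:
        raise ValidationError("replicate size below 2; increase f")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    rep_means = np.empty((B, len(CENTRALITY_INDICES)))
    rep_medians = np.empty((B, len(CENTRALITY_INDICES)))
    n_disc = 0
    for b in range(B):
        pick = np.sort(rng.choice(k, size=size, replace=False))
        picked_ids = [node_ids[i] for i in pick]
        if mode == "subgraph":
            sub = graph.subgraph(picked_ids)
        else:
            sub_means = means[pick]
            sq = np.sum(sub_means**2, axis=1)
            D = np.maximum(sq[:, None] + sq[None, :] - 2 * sub_means @ sub_means.T, 0.0)
            np.fill_diagonal(D, 0.0)
            C, R = gower_covariance((D + D.T) / 2, picked_ids)
            sub = fit_conditional_graph(R, C, picked_ids, params).to_networkx()
        if sub.number_of_nodes() and not nx.is_connected(sub):
            n_disc += 1
        suite = centrality_suite(sub)
        rep_means[b], rep_medians[b] = _replicate_stats(suite)

    def _summ(arr: np.ndarray) -> dict[str, np.ndarray]:
        return {
            "value": np.nanmean(arr, axis=0),
            "se": np.nanstd(arr, axis=0, ddof=1) if B > 1 else np.zeros(arr.shape[1]),
            "lo": np.nanpercentile(arr, 2.5, axis=0),
            "hi": np.nanpercentile(arr, 97.5, axis=0),
        }

    sm, sd = _summ(rep_means), _summ(rep_medians)
    table = pd.DataFrame({
        "mean": sm["value"], "se_mean": sm["se"],
        "ci_mean_lo": sm["lo"], "ci_mean_hi": sm["hi"],
        "median": sd["value"], "se_median": sd["se"],
        "ci_median_lo": sd["lo"], "ci_median_hi": sd["hi"],
    }, index=pd.Index(CENTRALITY_INDICES, name="index"))
    if n_disc:
        logger.warning("%d of %d bootstrap replicates were disconnected", n_disc, B)
    return BootstrapSummary(table, f, B, mode, seed, size, n_disc)


# ---------------------------------------------------------------------------
# rank correlations
# ---------------------------------------------------------------------------

def spearman_correlation_matrix(
    columns: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rank correlations with two-sided p-values.

    Ties receive average ranks; p-values use the t approximation.
    Constant columns (after pairwise deletion) yield NaN with a warning.
    """
    names = list(columns.columns)
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            pair = columns[[a, b]].dropna()
            if len(pair) < 3:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("constant column in pair (%s, %s); r_s undefined", a, b)
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.spearmanr(x, y)
            r.loc[a, b] = r.loc[b, a] = float(res.statistic)
            p.loc[a, b] = p.loc[b, a] = float(res.pvalue)
    return r, p
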