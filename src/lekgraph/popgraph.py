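"""Conditional genetic covariance network construction.

The estimator follows the classic population-graph recipe: encode
individual genotypes as per-allele contribution vectors, compute squared
Euclidean distances between node mean vectors, double-center (Gower) to a
covariance matrix, invert the implied correlation matrix, and keep only
edges whose partial correlation survives an edge-exclusion deviance test.
Edge weights are the Gower inter-node distances, which downstream code
treats as path lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

from lekgraph.clustering import NodeAssignment
from lekgraph.errors import ValidationError
from lekgraph.io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)

RIDGE_LADDER = (0.0, 1e-8, 1e-6, 1e-4, 1e-2, 1.0)


@dataclass
class GraphFitParams:
    """Edge-pruning parameters for the conditional graph fit."""

    alpha: float = 0.05
    tolerance: float = 1e-4
    n_eff: int | None = None  # deviance sample size; None -> number of nodes

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        if self.tolerance < 0:
            raise ValidationError("tolerance must be >= 0")


@dataclass
class MultivariateEncoding:
    """Per-individual allele-contribution vectors over all (locus, allele) columns.

    Each non-missing locus block holds 0.5/0.5 for a heterozygote or 1.0
    for a homozygote; missing blocks are imputed with the node's (or,
    failing that, the global) allele-frequency vector, so every block sums
    to 1.
    """

    matrix: np.ndarray  # (n_rows, n_cols)
    columns: list[tuple[str, int]]  # (locus, allele length)
    rows: np.ndarray  # indices into the source GenotypeTable
    row_nodes: np.ndarray  # node id per matrix row


@dataclass
class PopGraph:
    """The fitted conditional genetic covariance network."""

    node_ids: list[str]
    D: np.ndarray  # squared-distance matrix among node mean vectors
    C: np.ndarray  # Gower-centered covariance
    R: np.ndarray  # correlation (unit diagonal)
    omega: np.ndarray  # precision matrix (possibly ridge-regularized inverse)
    pcorr: np.ndarray  # partial correlations
    edges: pd.DataFrame  # node_a, node_b, weight, pcorr, deviance
    ridge_lambda: float
    params: GraphFitParams = field(default_factory=GraphFitParams)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        graph.add_nodes_from(self.node_ids)
        for row in self.edges.itertuples(index=False):
            graph.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        return graph


def encode_multivariate(g: GenotypeTable, nodes: NodeAssignment) -> MultivariateEncoding:
    """Encode retained individuals as concatenated per-allele vectors."""
    if not nodes.node_ids:
        raise ValidationError("node assignment is empty")
    rows = nodes.retained_rows()
    row_node = np.empty(rows.size, dtype=object)
    pos_of = {r: i for i, r in enumerate(rows)}
    for node in nodes.node_ids:
        for r in nodes.sample_rows[node]:
            row_node[pos_of[r]] = node

    calls = g.calls[rows]
    columns: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for j, locus in enumerate(g.loci):
        lc = calls[:, j, :]
        present = lc[:, 0] != MISSING
        alleles = np.unique(lc[present])
        if alleles.size == 0:
            logger.warning("locus %s has no observed alleles; skipped", locus)
            continue
        col_of = {int(a): k for k, a in enumerate(alleles)}
        block = np.zeros((rows.size, alleles.size))
        for i in np.nonzero(present)[0]:
            block[i, col_of[int(lc[i, 0])]] += 0.5
            block[i, col_of[int(lc[i, 1])]] += 0.5
        # impute missing blocks with node allele frequencies (global fallback)
        global_freq = block[present].mean(axis=0)
        for node in nodes.node_ids:
            node_pos = np.array([pos_of[r] for r in nodes.sample_rows[node]])
            node_present = node_pos[present[node_pos]]
            fill = block[node_present].mean(axis=0) if node_present.size else global_freq
            for i in node_pos[~present[node_pos]]:
                block[i] = fill
        blocks.append(block)
        columns.extend((locus, int(a)) for a in alleles)
    if not blocks:
        raise ValidationError("no locus has observed alleles")
    return MultivariateEncoding(np.hstack(blocks), columns, rows, row_node)


def node_distance_matrix(enc: MultivariateEncoding, nodes: NodeAssignment) -> np.ndarray:
    """Squared Euclidean distance between node mean encoding vectors."""
    if nodes.n_nodes < 2:
        raise ValidationError("need >= 2 nodes for a distance matrix")
    means = np.vstack([
        enc.matrix[enc.row_nodes == node].mean(axis=0) for node in nodes.node_ids
    ])
    sq = np.sum(means**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * means @ means.T
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def gower_covariance(
    D: np.ndarray, node_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Double-center a squared-distance matrix into covariance + correlation.

    C = -1/2 J D J with J = I - 11'/k; rows and columns of C sum to zero.
    R rescales C to unit diagonal.  A node with (numerically) zero
    variance makes the correlation undefined and raises.
    """
    D = np.asarray(D, dtype=float)
    k = D.shape[0]
    if D.shape != (k, k) or not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("D must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValidationError("D must have a zero diagonal")
    J = np.eye(k) - np.ones((k, k)) / k
    C = -0.5 * J @ D @ J
    C = (C + C.T) / 2.0
    diag = np.diag(C)
    bad = np.nonzero(diag <= 1e-12)[0]
    if bad.size:
        names = [node_ids[i] if node_ids else str(i) for i in bad]
        raise ValidationError(f"zero-variance node(s): {names}")
    scale = np.sqrt(diag)
    R = C / np.outer(scale, scale)
    np.fill_diagonal(R, 1.0)
    return C, R


def _stable_inverse(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Invert R on the complement of its structural null space.

    Double-centering leaves the correlation matrix with one exact null
    direction (the image of the all-ones vector); that direction is a
    deterministic constraint, not noise, so it is projected out before
    inversion.  If the remaining spectrum is still ill-conditioned a ridge
    penalty is escalated until the inverse is stable.
    """
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    top = vals[-1]
    if top <= 0:
        raise ValidationError("correlation matrix has no positive spectrum")
    null = vals < top * 1e-10  # structural/exact null directions only
    for lam in RIDGE_LADDER:
        kept = vals[~null] + lam
        if kept.min() <= 0 or kept.max() / kept.min() > 1e10:
            continue
        V = vecs[:, ~null]
        omega = V @ np.diag(1.0 / kept) @ V.T
        return (omega + omega.T) / 2.0, lam
    raise ValidationError(
        "correlation matrix is numerically singular even after ridge "
        "regularization; more samples per node (or fewer nodes) are needed"
    )


def fit_conditional_graph(
    R: np.ndarray,
    C: np.ndarray,
    node_ids: list[str],
    params: GraphFitParams | None = None,
) -> PopGraph:
    """Prune the saturated correlation model to its minimal edge set.

    An edge (i, j) is retained iff |rho_ij| > tolerance and the
    edge-exclusion deviance -n_eff * ln(1 - rho_ij^2) exceeds the
    chi-square(1) critical value at alpha, where rho_ij is the partial
    correlation -omega_ij / sqrt(omega_ii * omega_jj).  The edge weight is
    the Gower distance sqrt(C_ii + C_jj - 2 C_ij) between the two nodes.
    """
    params = params or GraphFitParams()
    k = len(node_ids)
    if R.shape != (k, k):
        raise ValidationError("R shape does not match node_ids")
    n_eff = params.n_eff if params.n_eff is not None else k
    omega, lam = _stable_inverse(R)
    if lam > 0:
        logger.info("ridge lambda %g applied to invert R", lam)
    d = np.sqrt(np.diag(omega))
    pcorr = -omega / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    pcorr = np.clip(pcorr, -1.0, 1.0)

    crit = chi2.isf(params.alpha, df=1)
    records = []
    for i in range(k):
        for j in range(i + 1, k):
            rho = pcorr[i, j]
            if abs(rho) <= params.tolerance:
                continue
            rho2 = min(rho * rho, 1.0 - 1e-15)
            deviance = -n_eff * np.log1p(-rho2)
            if deviance <= crit:
                continue
            weight = float(np.sqrt(max(C[i, i] + C[j, j] - 2.0 * C[i, j], 0.0)))
            records.append((node_ids[i], node_ids[j], weight, float(rho), float(deviance)))
    edges = pd.DataFrame(
        records, columns=["node_a", "node_b", "weight", "pcorr", "deviance"]
    )
    logger.info("retained %d of %d possible edges (alpha=%g, n_eff=%d, lambda=%g)",
                len(edges), k * (k - 1) // 2, params.alpha, n_eff, lam)
    return PopGraph(
        node_ids=list(node_ids),
        D=np.zeros((k, k)),  # filled by build_popgraph when available
        C=C, R=R, omega=omega, pcorr=pcorr,
        edges=edges, ridge_lambda=lam, params=params,
    )


def build_popgraph(
    g: GenotypeTable,
    nodes: NodeAssignment,
    params: GraphFitParams | None = None,
) -> PopGraph:
    """Full pipeline: encode, distance, Gower-center, fit, in one call.

    When ``params.n_eff`` is unset, the deviance sample size is the number
    of genotyped individuals behind the node centroids (the convention
    consistent with edge-dense networks on real data); pass an explicit
    ``n_eff`` to override.  The choice is logged prominently.
    """
    from dataclasses import replace

    enc = encode_multivariate(g, nodes)
    params = params or GraphFitParams()
    if params.n_eff is None:
        params = replace(params, n_eff=enc.matrix.shape[0])
        logger.info(
            "n_eff defaulted to the number of genotyped individuals (%d)",
            params.n_eff,
        )
    D = node_distance_matrix(enc, nodes)
    C, R = gower_covariance(D, nodes.node_ids)
    pg = fit_conditional_graph(R, C, nodes.node_ids, params)
    pg.D = D
    return pg


def minimum_spanning_tree(pg: PopGraph | nx.Graph) -> nx.Graph:
    """Minimum-total-length spanning tree of the retained edges.

    Minimizing summed edge length is equivalent to keeping the maximum
    genetic covariance without cycles.  On a disconnected graph a spanning
    forest is returned with a warning.
    """
    graph = pg.to_networkx() if isinstance(pg, PopGraph) else pg
    if graph.number_of_nodes() and not nx.is_connected(graph):
        logger.warning("graph is disconnected; returning a spanning forest")
    return nx.minimum_spanning_tree(graph, weight="weight")


def conditional_genetic_distance(pg: PopGraph | nx.Graph) -> pd.DataFrame:
    """All-pairs weighted shortest-path distance through retained edges.

    Unreachable pairs are +inf.  This is the conditional genetic distance:
    path length conditioned on the fitted network structure.
    """
    graph = pg.to_networkx() if isinstance(pg, PopGraph) else pg
    ids = list(graph.nodes)
    out = pd.DataFrame(np.inf, index=ids, columns=ids)
    for src, dists in nx.all_pairs_dijkstra_path_length(graph, weight="weight"):
        for dst, d in dists.items():
            out.loc[src, dst] = d
    np.fill_diagonal(out.values, 0.0)
    return out


def write_edges_csv(pg: PopGraph, path) -> None:
    pg.edges[["node_a", "node_b", "weight"]].to_csv(path, index=False)


def write_graphml(pg: PopGraph, path) -> None:
    nx.write_graphml(pg.to_networkx(), path)
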