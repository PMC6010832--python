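"""Pipeline orchestration: configurable stages with deterministic manifests.

Stages (qc -> cluster -> graph -> analyze -> prioritize) communicate
through CSV/JSON files in the output directory, so each is re-runnable
individually from the previous stage's outputs.  A single YAML config is
the source of truth; the effective config is always dumped alongside the
outputs together with a run manifest recording seeds and per-stage counts.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import lekgraph
from lekgraph.clustering import (
    NodeAssignment,
    cluster_leks_to_nodes,
    great_circle_distance_matrix,
    mean_peak_male_count,
    node_table,
    range_centrality,
)
from lekgraph.errors import FormatError, ValidationError
from lekgraph.io import (
    LocusPanel,
    read_genotype_table,
    read_lek_counts,
    write_genotype_table,
)
from lekgraph.netstats import (
    bootstrap_centrality,
    centrality_suite,
    classify_structure,
    er_null_ensemble,
    spearman_correlation_matrix,
)
from lekgraph.popgraph import (
    GraphFitParams,
    build_popgraph,
    conditional_genetic_distance,
    encode_multivariate,
    minimum_spanning_tree,
    write_edges_csv,
    write_graphml,
)
from lekgraph.prioritize import prioritize
from lekgraph.qc import diversity_stats, qc_report
from lekgraph.simulate import make_fixture

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "inputs": {"genotypes": None, "lek_counts": None},
    "panel": {"loci": None, "motif_length": 4},
    "simulate": {"scale": "tiny"},
    "qc": {"max_failed_loci": 5, "max_mismatch_loci": 0},
    "clustering": {"cut_km": 15.0, "min_node_size": 4, "method": "complete"},
    "graph": {"alpha": 0.05, "tolerance": 1.0e-4, "n_eff": None},
    "analysis": {
        "null_B": 1000,
        "bootstrap_B": 1000,
        "bootstrap_fraction": 0.75,
        "bootstrap_mode": "rebuild",
        "cpl_factor": 2.0,
        "structure_alpha": 0.05,
    },
    "prioritization": {
        "hub_fraction": 0.01,
        "cross_percentile": 0.5,
        "cent_pct": 0.90,
        "attr_pct": 0.50,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None, seed: int | None = None) -> dict:
    """Merge a YAML config over the defaults; an explicit seed wins."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise FormatError("config must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def infer_panel(genotype_csv: str | Path, motif_length: int = 4) -> LocusPanel:
    """Infer the locus panel from paired ``<locus>_1``/``<locus>_2`` columns."""
    header = pd.read_csv(genotype_csv, nrows=0).columns
    loci = []
    for col in header:
        if col.endswith("_1") and col[:-2] + "_2" in header:
            loci.append(col[:-2])
    if not loci:
        raise FormatError("no <locus>_1/<locus>_2 column pairs found")
    return LocusPanel.from_names(loci, motif_length=motif_length)


def _panel_from_config(cfg: dict, genotype_csv: Path) -> LocusPanel:
    loci = cfg["panel"].get("loci")
    motif = cfg["panel"].get("motif_length", 4)
    if loci:
        return LocusPanel.from_names(list(loci), motif_length=motif)
    return infer_panel(genotype_csv, motif_length=motif)


class Manifest:
    """Run manifest: config hash, seeds, per-stage counts, timestamps."""

    def __init__(self, outdir: Path, cfg: dict) -> None:
        self.path = outdir / "manifest.json"
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {"stages": {}}
        self.data["config_hash"] = config_hash(cfg)
        self.data["seed"] = cfg["seed"]
        self.data["version"] = lekgraph.__version__

    def record(self, stage: str, **counts) -> None:
        self.data["stages"][stage] = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"), **counts
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, default=str)


def _dump_effective_config(cfg: dict, outdir: Path) -> None:
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dict(cfg.get("simulate") or {})
    scale = sim.pop("scale", "tiny")
    paths = make_fixture(scale, seed=cfg["seed"], outdir=outdir, **sim)
    Manifest(outdir, cfg).record("simulate", scale=scale)
    return paths


def _input_genotypes(cfg: dict, outdir: Path) -> Path:
    configured = cfg["inputs"].get("genotypes")
    if configured:
        return Path(configured)
    candidate = outdir / "genotypes.csv"
    if candidate.exists():
        return candidate
    raise ValidationError("no genotype input configured and none found in out dir")


def stage_qc(cfg: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    src = _input_genotypes(cfg, outdir)
    panel = _panel_from_config(cfg, src)
    table = read_genotype_table(src, panel)
    report, clean = qc_report(
        table,
        max_failed_loci=cfg["qc"]["max_failed_loci"],
        max_mismatch_loci=cfg["qc"]["max_mismatch_loci"],
    )
    report.to_csv(outdir / "qc_report.csv", index=False)
    write_genotype_table(clean, outdir / "genotypes_clean.csv")
    Manifest(outdir, cfg).record(
        "qc", samples_in=table.n_samples, samples_out=clean.n_samples
    )


def _load_clean(cfg: dict, outdir: Path):
    src = outdir / "genotypes_clean.csv"
    if not src.exists():
        src = _input_genotypes(cfg, outdir)
    panel = _panel_from_config(cfg, src)
    return read_genotype_table(src, panel)


def stage_cluster(cfg: dict, outdir: Path) -> None:
    table = _load_clean(cfg, outdir)
    nodes = cluster_leks_to_nodes(
        table,
        cut_km=cfg["clustering"]["cut_km"],
        min_node_size=cfg["clustering"]["min_node_size"],
        method=cfg["clustering"]["method"],
    )
    counts = None
    counts_path = cfg["inputs"].get("lek_counts") or (outdir / "lek_counts.csv")
    if Path(counts_path).exists():
        counts = read_lek_counts(counts_path)
    node_table(table, nodes, counts).to_csv(outdir / "node_table.csv", index=False)
    membership = pd.DataFrame({
        "sample_id": np.concatenate([
            table.sample_ids[nodes.sample_rows[n]] for n in nodes.node_ids
        ]) if nodes.node_ids else [],
        "node_id": np.concatenate([
            np.repeat(n, len(nodes.sample_rows[n])) for n in nodes.node_ids
        ]) if nodes.node_ids else [],
    })
    membership.to_csv(outdir / "node_membership.csv", index=False)
    # per-node diversity summary
    grouping = {n: nodes.sample_rows[n] for n in nodes.node_ids}
    div = diversity_stats(table, grouping)
    pd.DataFrame([
        {"node_id": n, "n_samples": d.n_samples, "A": d.A, "A_sd": d.A_sd,
         "Ae": d.Ae, "Ae_sd": d.Ae_sd, "He": d.He, "He_sd": d.He_sd,
         "Ho": d.Ho, "Ho_sd": d.Ho_sd, "Fis": d.Fis, "Fis_sd": d.Fis_sd,
         "Fis_multilocus": d.Fis_multilocus}
        for n, d in div.items()
    ]).to_csv(outdir / "node_diversity.csv", index=False)
    Manifest(outdir, cfg).record(
        "cluster", n_nodes=nodes.n_nodes,
        n_samples=int(sum(len(r) for r in nodes.sample_rows.values())),
        n_removed=len(nodes.removed_samples),
    )


def assignment_from_files(table, membership: pd.DataFrame) -> NodeAssignment:
    """Reconstruct a NodeAssignment from a membership table (sample -> node)."""
    sid_row = {sid: i for i, sid in enumerate(table.sample_ids)}
    node_ids = sorted(membership["node_id"].unique())
    sample_rows: dict[str, np.ndarray] = {}
    member_leks: dict[str, list[str]] = {}
    lek_to_node: dict[str, str] = {}
    centroids: dict[str, tuple[float, float]] = {}
    lek_coords = table.meta.groupby("lek_id")[["lat", "lon"]].mean()
    for node in node_ids:
        sids = membership.loc[membership["node_id"] == node, "sample_id"]
        rows = np.array(sorted(sid_row[s] for s in sids))
        sample_rows[node] = rows
        leks = sorted(set(table.meta["lek_id"].iloc[rows]))
        member_leks[node] = leks
        for lek in leks:
            lek_to_node[lek] = node
        centroids[node] = (
            float(lek_coords.loc[leks, "lat"].mean()),
            float(lek_coords.loc[leks, "lon"].mean()),
        )
    return NodeAssignment(node_ids, lek_to_node, member_leks, sample_rows, centroids)


def _load_assignment(cfg: dict, outdir: Path):
    table = _load_clean(cfg, outdir)
    membership = pd.read_csv(outdir / "node_membership.csv", dtype=str)
    return table, assignment_from_files(table, membership)


def _graph_params(cfg: dict) -> GraphFitParams:
    return GraphFitParams(
        alpha=cfg["graph"]["alpha"],
        tolerance=cfg["graph"]["tolerance"],
        n_eff=cfg["graph"]["n_eff"],
    )


def stage_graph(cfg: dict, outdir: Path) -> None:
    table, nodes = _load_assignment(cfg, outdir)
    pg = build_popgraph(table, nodes, _graph_params(cfg))
    write_edges_csv(pg, outdir / "edges.csv")
    write_graphml(pg, outdir / "network.graphml")
    ids = pg.node_ids
    pd.DataFrame(pg.C, index=ids, columns=ids).to_csv(outdir / "covariance.csv")
    pd.DataFrame(pg.pcorr, index=ids, columns=ids).to_csv(
        outdir / "partial_correlation.csv"
    )
    mst = minimum_spanning_tree(pg)
    pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in mst.edges(data=True)],
        columns=["node_a", "node_b", "weight"],
    ).to_csv(outdir / "mst_edges.csv", index=False)
    cgd = conditional_genetic_distance(pg)
    cgd.to_csv(outdir / "conditional_genetic_distance.csv")
    Manifest(outdir, cfg).record(
        "graph", n_nodes=pg.n_nodes, n_edges=pg.n_edges,
        ridge_lambda=pg.ridge_lambda,
    )


def _graph_from_files(outdir: Path):
    import networkx as nx

    node_df = pd.read_csv(outdir / "node_table.csv", dtype={"node_id": str})
    edges = pd.read_csv(outdir / "edges.csv", dtype={"node_a": str, "node_b": str})
    graph = nx.Graph()
    graph.add_nodes_from(node_df["node_id"])
    for row in edges.itertuples(index=False):
        graph.add_edge(row.node_a, row.node_b, weight=float(row.weight))
    return node_df, graph


def stage_analyze(cfg: dict, outdir: Path) -> None:
    node_df, graph = _graph_from_files(outdir)
    seed = cfg["seed"]
    acfg = cfg["analysis"]

    suite = centrality_suite(graph)
    suite_out = suite.copy()
    for col in suite.columns:
        suite_out[col + "_rank"] = suite[col].rank(ascending=False, method="min")
    suite_out.to_csv(outdir / "centrality.csv")

    nc = er_null_ensemble(graph, B=acfg["null_B"], seed=seed)
    label, evidence = classify_structure(
        nc, alpha=acfg["structure_alpha"], cpl_factor=acfg["cpl_factor"], seed=seed
    )
    with open(outdir / "null_comparison.json", "w") as fh:
        json.dump({"classification": label, "evidence": evidence,
                   **nc.summary()}, fh, indent=1, default=float)

    # MST-vs-geography correlation
    mst_path = outdir / "mst_edges.csv"
    mst_geo = None
    if mst_path.exists() and len(node_df) >= 3:
        import networkx as nx

        mst = nx.Graph()
        mst.add_nodes_from(node_df["node_id"])
        for row in pd.read_csv(mst_path, dtype={"node_a": str, "node_b": str}).itertuples():
            mst.add_edge(row.node_a, row.node_b, weight=float(row.weight))
        ids = list(node_df["node_id"])
        geo = great_circle_distance_matrix(
            node_df["lat"].to_numpy(), node_df["lon"].to_numpy()
        )
        tree_d = dict(nx.all_pairs_dijkstra_path_length(mst, weight="weight"))
        pairs_tree, pairs_geo = [], []
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                b = ids[j]
                if b in tree_d.get(a, {}):
                    pairs_tree.append(tree_d[a][b])
                    pairs_geo.append(geo[i, j])
        if len(pairs_tree) >= 3:
            from scipy import stats as _stats

            rs = _stats.spearmanr(pairs_tree, pairs_geo)
            mst_geo = {"r_s": float(rs.statistic), "p": float(rs.pvalue),
                       "n_pairs": len(pairs_tree)}
            with open(outdir / "mst_geography.json", "w") as fh:
                json.dump(mst_geo, fh, indent=1)

    # Spearman correlations among indices and node attributes
    merged = suite.join(node_df.set_index("node_id"), how="left")
    cols = list(suite.columns)
    for extra in ("n_samples", "mean_peak_male_count", "range_distance_km"):
        if extra in merged.columns:
            cols.append(extra)
    r, p = spearman_correlation_matrix(merged[cols])
    r.to_csv(outdir / "spearman_r.csv")
    p.to_csv(outdir / "spearman_p.csv")

    # bootstrap
    if acfg["bootstrap_B"] > 0:
        from dataclasses import replace

        params = _graph_params(cfg)
        if acfg["bootstrap_mode"] == "rebuild":
            table, nodes = _load_assignment(cfg, outdir)
            enc = encode_multivariate(table, nodes)
            means = np.vstack([
                enc.matrix[enc.row_nodes == n].mean(axis=0) for n in nodes.node_ids
            ])
            target = (nodes.node_ids, means)
            if params.n_eff is None:  # match the full fit's convention
                params = replace(params, n_eff=enc.matrix.shape[0])
        else:
            target = graph
        bs = bootstrap_centrality(
            target, f=acfg["bootstrap_fraction"], B=acfg["bootstrap_B"],
            seed=seed, mode=acfg["bootstrap_mode"], params=params,
        )
        bs.table.to_csv(outdir / "bootstrap.csv")

    Manifest(outdir, cfg).record(
        "analyze", classification=label,
        mst_geography_rs=None if mst_geo is None else mst_geo["r_s"],
    )


def stage_prioritize(cfg: dict, outdir: Path) -> None:
    node_df = pd.read_csv(outdir / "node_table.csv", dtype={"node_id": str})
    suite = pd.read_csv(outdir / "centrality.csv", index_col=0)
    suite.index = suite.index.astype(str)
    pcfg = cfg["prioritization"]
    attrs = node_df.set_index("node_id")
    counts = attrs.get("mean_peak_male_count", pd.Series(np.nan, index=attrs.index))
    rdist = attrs.get("range_distance_km", pd.Series(np.nan, index=attrs.index))
    report = prioritize(
        suite, counts, rdist,
        hub_fraction=pcfg["hub_fraction"],
        cross_percentile=pcfg["cross_percentile"],
        cent_pct=pcfg["cent_pct"],
        attr_pct=pcfg["attr_pct"],
    )
    report.to_frame().to_csv(outdir / "prioritization.csv", index=False)
    if not report.regressions.empty:
        report.regressions.to_csv(outdir / "keystone_regressions.csv", index=False)
    _write_summary_md(cfg, outdir, suite, report)
    Manifest(outdir, cfg).record(
        "prioritize",
        n_cross_index_hubs=len(report.cross_index_hubs),
        n_keystones=len(report.keystones),
        n_zero_betweenness=len(report.zero_betweenness),
    )


def _write_summary_md(cfg, outdir: Path, suite: pd.DataFrame, report) -> None:
    from lekgraph.netstats import CENTRALITY_INDICES

    lines = ["# Run summary", "", "## Centrality indices", "",
             "| Index | Min | Mean ± SD | Median | Max |",
             "|---|---|---|---|---|"]
    for index in CENTRALITY_INDICES:
        v = suite[index].dropna()
        if v.empty:
            continue
        lines.append(
            f"| {index} | {v.min():.4g} | {v.mean():.4g} ± {v.std():.4g} "
            f"| {v.median():.4g} | {v.max():.4g} |"
        )
    lines += ["", "## Prioritization", "",
              f"- cross-index hubs: {', '.join(report.cross_index_hubs) or 'none'}",
              f"- zero-betweenness spokes: {len(report.zero_betweenness)}",
              f"- keystone nodes: {len(report.keystones)}", ""]
    for rec in report.keystones:
        lines.append(
            f"  - {rec.node_id}: indices {', '.join(rec.indices)}; "
            f"triggers {', '.join(sorted(set(rec.triggered_by)))}"
        )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "cluster": stage_cluster,
    "graph": stage_graph,
    "analyze": stage_analyze,
    "prioritize": stage_prioritize,
}


def run_pipeline(cfg: dict, outdir: str | Path) -> Path:
    """Execute all stages in order into ``outdir`` and return it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _dump_effective_config(cfg, outdir)
    needs_sim = not cfg["inputs"].get("genotypes")
    order = (["simulate"] if needs_sim else []) + [
        "qc", "cluster", "graph", "analyze", "prioritize"
    ]
    for stage in order:
        logger.info("running stage %s", stage)
        STAGES[stage](cfg, outdir)
    return outdir
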