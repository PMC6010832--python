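"""Genotype quality control and genetic diversity statistics.

Covers sample filtering by amplification failure, duplicate-genotype
detection (a deliberately simple exact/near-match replacement for
special-purpose genotyping-error software), probability of identity,
allele-ladder consistency, and per-group diversity summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lekgraph.io import MISSING, GenotypeTable, LocusPanel

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencies:
    """Per-locus allele length -> frequency maps with gene-copy counts."""

    loci: tuple[str, ...]
    freqs: dict[str, dict[int, float]]
    n_gene_copies: dict[str, int]


def allele_frequencies(g: GenotypeTable, rows: np.ndarray | None = None) -> AlleleFrequencies:
    """Estimate allele frequencies per locus from non-missing calls."""
    calls = g.calls if rows is None else g.calls[np.asarray(rows, dtype=int)]
    freqs: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    for j, name in enumerate(g.loci):
        alleles = calls[:, j, :].ravel()
        alleles = alleles[alleles != MISSING]
        copies[name] = alleles.size
        if alleles.size == 0:
            freqs[name] = {}
            continue
        values, counts = np.unique(alleles, return_counts=True)
        freqs[name] = {int(v): c / alleles.size for v, c in zip(values, counts)}
    return AlleleFrequencies(g.loci, freqs, copies)


def filter_failed_individuals(
    g: GenotypeTable, max_failed_loci: int = 5
) -> GenotypeTable:
    """Remove samples whose amplification failed at >= ``max_failed_loci`` loci.

    The default of 5 out of a 15-locus panel removes samples missing at
    one-third or more of the loci.
    """
    if max_failed_loci < 0:
        raise ValueError("max_failed_loci must be >= 0")
    missing = g.missing_per_sample()
    keep = missing < max_failed_loci
    removed = g.sample_ids[~keep]
    if removed.size:
        logger.info("removed %d samples failing >= %d loci: %s",
                    removed.size, max_failed_loci, list(removed))
    return g.subset(np.nonzero(keep)[0])


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _genotypes_match(a: np.ndarray, b: np.ndarray, max_mismatch: int) -> bool:
    """Compare two (n_loci, 2) call arrays over loci typed in both."""
    typed = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    if not typed.any():
        return False
    sa = np.sort(a[typed], axis=1)
    sb = np.sort(b[typed], axis=1)
    mismatches = int((sa != sb).any(axis=1).sum())
    return mismatches <= max_mismatch


def find_duplicate_genotypes(
    g: GenotypeTable, max_mismatch_loci: int = 0
) -> tuple[list[set[str]], GenotypeTable]:
    """Find multiple captures of the same individual and deduplicate.

    Two samples match when their genotypes differ at no more than
    ``max_mismatch_loci`` of the loci typed in both; clusters are the
    transitive closure of pairwise matches.  The retained representative
    of each cluster is the member with the fewest missing loci (ties
    broken by lexicographic sample_id).

    Returns (clusters of size >= 2, deduplicated table).
    """
    n = g.n_samples
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if _genotypes_match(g.calls[i], g.calls[j], max_mismatch_loci):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)

    ids = g.sample_ids
    missing = g.missing_per_sample()
    clusters: list[set[str]] = []
    keep_rows: list[int] = []
    for members in groups.values():
        if len(members) > 1:
            clusters.append({ids[i] for i in members})
        rep = min(members, key=lambda i: (missing[i], ids[i]))
        keep_rows.append(rep)
    keep_rows.sort()
    if clusters:
        logger.info("found %d duplicate clusters covering %d samples",
                    len(clusters), sum(len(c) for c in clusters))
    return clusters, g.subset(keep_rows)


def probability_of_identity(f: AlleleFrequencies) -> tuple[dict[str, float], float]:
    """Probability two random individuals share a genotype, per locus and overall.

    Per locus, P_ID = sum_i p_i^4 + sum_{i<j} (2 p_i p_j)^2; the multilocus
    value is the product across loci.  Loci with no gene copies are excluded
    from the product with a warning.
    """
    per_locus: dict[str, float] = {}
    product = 1.0
    for name in f.loci:
        p = np.array(list(f.freqs[name].values()))
        if p.size == 0:
            logger.warning("locus %s has zero gene copies; excluded from P_ID", name)
            continue
        pid = float(np.sum(p**4))
        outer = np.outer(p, p)
        iu = np.triu_indices(len(p), k=1)
        pid += float(np.sum((2.0 * outer[iu]) ** 2))
        per_locus[name] = pid
        product *= pid
    return per_locus, product


def motif_consistency_check(
    g: GenotypeTable, panel: LocusPanel
) -> list[tuple[str, str, int]]:
    """Flag alleles off the repeat-motif ladder at each locus.

    An allele is flagged when its length is not congruent (modulo the
    locus motif length) with the modal congruence class at that locus.
    Nothing is corrected; the caller decides what to do with flags.
    """
    flagged: list[tuple[str, str, int]] = []
    ids = g.sample_ids
    for j, name in enumerate(g.loci):
        motif = panel[name].motif_length
        if motif == 1:
            continue
        alleles = g.calls[:, j, :]
        present = alleles[alleles != MISSING]
        if present.size == 0:
            continue
        classes, counts = np.unique(present % motif, return_counts=True)
        modal = int(classes[np.argmax(counts)])
        for i in range(g.n_samples):
            for allele in g.calls[i, j]:
                if allele != MISSING and allele % motif != modal:
                    flagged.append((ids[i], name, int(allele)))
    return flagged


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

@dataclass
class DiversitySummary:
    """Across-locus mean +/- SD of diversity indices for one group."""

    group: str
    n_samples: int
    per_locus: pd.DataFrame  # columns A, Ae, He, Ho, Fis indexed by locus
    A: float
    A_sd: float
    Ae: float
    Ae_sd: float
    He: float
    He_sd: float
    Ho: float
    Ho_sd: float
    Fis: float
    Fis_sd: float
    Fis_multilocus: float  # 1 - mean(Ho)/mean(He), the ratio-of-means variant


def _locus_stats(calls: np.ndarray, unbiased_he: bool = False) -> tuple[float, ...]:
    """A, Ae, He, Ho, Fis for one locus from (n, 2) calls; NaN where undefined."""
    typed = calls[:, 0] != MISSING
    if not typed.any():
        return (np.nan,) * 5
    obs = calls[typed]
    alleles = obs.ravel()
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / alleles.size
    ss = float(np.sum(p**2))
    a = float(len(counts))
    ae = 1.0 / ss
    he = 1.0 - ss
    if unbiased_he:
        n2 = alleles.size  # gene copies
        he *= n2 / (n2 - 1) if n2 > 1 else 1.0
    ho = float(np.mean(obs[:, 0] != obs[:, 1]))
    fis = 1.0 - ho / he if he > 0 else np.nan
    return a, ae, he, ho, fis


def diversity_stats(
    g: GenotypeTable,
    grouping: dict[str, np.ndarray] | None = None,
    unbiased_he: bool = False,
) -> dict[str, DiversitySummary]:
    """Per-group diversity summary (A, Ae, He, Ho, Fis), mean +/- SD across loci.

    ``grouping`` maps group name -> row indices; ``None`` pools all samples
    into one group named ``"pooled"``.  He defaults to the uncorrected gene
    diversity 1 - sum(p^2); set ``unbiased_he`` for the 2n/(2n-1) version.
    """
    if grouping is None:
        grouping = {"pooled": np.arange(g.n_samples)}
    out: dict[str, DiversitySummary] = {}
    for group, rows in grouping.items():
        rows = np.asarray(rows, dtype=int)
        if rows.size == 0:
            raise ValueError(f"group {group!r} has no samples")
        stats = np.array([
            _locus_stats(g.calls[rows, j, :], unbiased_he) for j in range(len(g.loci))
        ])
        per_locus = pd.DataFrame(
            stats, index=list(g.loci), columns=["A", "Ae", "He", "Ho", "Fis"]
        )
        means = per_locus.mean(skipna=True)
        sds = per_locus.std(skipna=True, ddof=1)
        mean_he = per_locus["He"].mean(skipna=True)
        mean_ho = per_locus["Ho"].mean(skipna=True)
        fis_multi = 1.0 - mean_ho / mean_he if mean_he > 0 else np.nan
        out[group] = DiversitySummary(
            group=group, n_samples=rows.size, per_locus=per_locus,
            A=means["A"], A_sd=sds["A"], Ae=means["Ae"], Ae_sd=sds["Ae"],
            He=means["He"], He_sd=sds["He"], Ho=means["Ho"], Ho_sd=sds["Ho"],
            Fis=means["Fis"], Fis_sd=sds["Fis"], Fis_multilocus=fis_multi,
        )
    return out


def qc_report(
    g: GenotypeTable,
    max_failed_loci: int = 5,
    max_mismatch_loci: int = 0,
) -> tuple[pd.DataFrame, GenotypeTable]:
    """Run the QC chain and return (per-sample report, cleaned table).

    Report columns: sample_id, missing_loci, kept, duplicate_cluster.
    """
    missing = g.missing_per_sample()
    passed = filter_failed_individuals(g, max_failed_loci)
    clusters, deduped = find_duplicate_genotypes(passed, max_mismatch_loci)
    cluster_of: dict[str, int] = {}
    for k, cluster in enumerate(clusters):
        for sid in cluster:
            cluster_of[sid] = k
    kept = set(deduped.sample_ids)
    report = pd.DataFrame({
        "sample_id": g.sample_ids,
        "missing_loci": missing,
        "kept": [sid in kept for sid in g.sample_ids],
        "duplicate_cluster": [cluster_of.get(sid, -1) for sid in g.sample_ids],
    })
    logger.info("QC: %d in, %d after failure filter, %d after dedup",
                g.n_samples, passed.n_samples, deduped.n_samples)
    return report, deduped
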