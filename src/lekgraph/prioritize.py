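"""Node prioritization: hubs, spokes, and keystone nodes.

All rules are rank-based, so hub membership is invariant under strictly
monotone transformations of an index.  Closeness is ranked with larger =
more central throughout (matching its definition in netstats).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lekgraph.errors import ValidationError
from lekgraph.netstats import CENTRALITY_INDICES

logger = logging.getLogger(__name__)


def top_hubs(ct: pd.DataFrame, fraction: float = 0.01) -> dict[str, list[str]]:
    """Per index, the ceil(fraction * k) highest-valued nodes, boundary ties
    all included (and logged)."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    k = len(ct)
    n_top = math.ceil(fraction * k)
    out: dict[str, list[str]] = {}
    for index in CENTRALITY_INDICES:
        vals = ct[index].dropna().sort_values(ascending=False)
        if len(vals) == 0:
            out[index] = []
            continue
        cutoff = vals.iloc[min(n_top, len(vals)) - 1]
        selected = vals[vals >= cutoff]
        if len(selected) > n_top:
            logger.info("%s: %d nodes tied at the top-%d boundary",
                        index, len(selected) - n_top + 1, n_top)
        out[index] = list(selected.index)
    return out


def cross_index_hubs(ct: pd.DataFrame, percentile: float = 0.5) -> list[str]:
    """Nodes at or above the given within-index percentile in every index.

    With the default 0.5 this is the set of nodes at or above the median
    of all six indices simultaneously.  Nodes with an undefined index
    value (e.g. clustering coefficient at degree < 2) cannot qualify.
    """
    if not 0 < percentile < 1:
        raise ValidationError("percentile must be in (0, 1)")
    mask = pd.Series(True, index=ct.index)
    for index in CENTRALITY_INDICES:
        vals = ct[index]
        thr = np.nanquantile(vals.to_numpy(float), 1.0 - percentile)
        mask &= vals >= thr  # NaN compares False
    return list(ct.index[mask])


def identify_spokes(ct: pd.DataFrame) -> tuple[dict[str, list[str]], list[str]]:
    """Per-index minimum-valued node(s) plus the zero-betweenness set."""
    minima: dict[str, list[str]] = {}
    for index in CENTRALITY_INDICES:
        vals = ct[index].dropna()
        if len(vals) == 0:
            minima[index] = []
            continue
        lo = vals.min()
        minima[index] = list(vals[vals == lo].index)
    zero_betweenness = list(ct.index[ct["betweenness"] == 0])
    return minima, zero_betweenness


@dataclass
class KeystoneRecord:
    node_id: str
    indices: list[str]
    centrality_percentile: dict[str, float]
    count_percentile: float
    range_percentile: float
    triggered_by: list[str]  # "low_count" and/or "peripheral_range" per index


@dataclass
class PrioritizationReport:
    top_hubs: dict[str, list[str]]
    cross_index_hubs: list[str]
    spoke_minima: dict[str, list[str]]
    zero_betweenness: list[str]
    keystones: list[KeystoneRecord]
    regressions: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for index, nodes in self.top_hubs.items():
            for n in nodes:
                rows.append({"category": "hub_top_fraction", "index": index, "node_id": n})
        for n in self.cross_index_hubs:
            rows.append({"category": "hub_cross_index", "index": "all", "node_id": n})
        for index, nodes in self.spoke_minima.items():
            for n in nodes:
                rows.append({"category": "spoke_minimum", "index": index, "node_id": n})
        for n in self.zero_betweenness:
            rows.append({"category": "spoke_zero_betweenness", "index": "betweenness",
                         "node_id": n})
        for rec in self.keystones:
            rows.append({"category": "keystone", "index": ",".join(rec.indices),
                         "node_id": rec.node_id,
                         "triggered_by": ",".join(sorted(set(rec.triggered_by)))})
        return pd.DataFrame(rows)


def _percentile_of(values: pd.Series) -> pd.Series:
    """Fractional rank in [0, 1] with average ranks for ties, NaN-preserving."""
    return values.rank(method="average", pct=True)


def _regression_diagnostics(ct: pd.DataFrame, counts: pd.Series) -> pd.DataFrame:
    """OLS of each centrality index on mean peak male count, with
    studentized residuals (diagnostic mirror of visual outlier-calling)."""
    rows = []
    for index in CENTRALITY_INDICES:
        pair = pd.DataFrame({"y": ct[index], "x": counts}).dropna()
        if len(pair) < 3 or pair["x"].nunique() < 2:
            continue
        x = pair["x"].to_numpy(float)
        y = pair["y"].to_numpy(float)
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        hat = np.sum(X * (X @ np.linalg.inv(X.T @ X)), axis=1)
        dof = len(x) - 2
        s2 = np.sum(resid**2) / dof if dof > 0 else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            student = resid / np.sqrt(s2 * (1.0 - hat))
        for node, r, sr in zip(pair.index, resid, student):
            rows.append({"index": index, "node_id": node,
                         "slope": beta[1], "intercept": beta[0],
                         "residual": r, "studentized_residual": sr})
    return pd.DataFrame(rows)


def identify_keystones(
    ct: pd.DataFrame,
    counts: pd.Series,
    range_distance: pd.Series,
    cent_pct: float = 0.90,
    attr_pct: float = 0.50,
) -> tuple[list[KeystoneRecord], pd.DataFrame]:
    """Nodes whose centrality outstrips their abundance or range position.

    For each index, a node is keystone when its centrality is at or above
    the ``cent_pct`` within-index percentile AND either its mean peak male
    count is at or below the ``attr_pct`` percentile (trigger
    ``low_count``) or its range distance is at or above the
    ``1 - attr_pct`` percentile (trigger ``peripheral_range``).  Degenerate
    (constant) attributes never trigger.  Returns the keystone records and
    the per-index regression diagnostics table.
    """
    counts = counts.reindex(ct.index)
    range_distance = range_distance.reindex(ct.index)
    if counts.isna().all() and range_distance.isna().all():
        logger.warning("all node attributes missing; no keystones identifiable")
        return [], pd.DataFrame()

    count_pct = _percentile_of(counts)
    range_pct = _percentile_of(range_distance)
    count_usable = counts.nunique(dropna=True) > 1
    range_usable = range_distance.nunique(dropna=True) > 1

    hits: dict[str, KeystoneRecord] = {}
    for index in CENTRALITY_INDICES:
        cpct = _percentile_of(ct[index])
        for node in ct.index:
            if not (cpct[node] >= cent_pct):
                continue
            triggers = []
            if count_usable and counts[node] == counts[node] and count_pct[node] <= attr_pct:
                triggers.append("low_count")
            if (range_usable and range_distance[node] == range_distance[node]
                    and range_pct[node] >= 1.0 - attr_pct):
                triggers.append("peripheral_range")
            if not triggers:
                continue
            rec = hits.get(node)
            if rec is None:
                hits[node] = KeystoneRecord(
                    node_id=node, indices=[index],
                    centrality_percentile={index: float(cpct[node])},
                    count_percentile=float(count_pct[node]) if count_pct[node] == count_pct[node] else float("nan"),
                    range_percentile=float(range_pct[node]) if range_pct[node] == range_pct[node] else float("nan"),
                    triggered_by=list(triggers),
                )
            else:
                rec.indices.append(index)
                rec.centrality_percentile[index] = float(cpct[node])
                rec.triggered_by.extend(triggers)
    regressions = _regression_diagnostics(ct, counts)
    return list(hits.values()), regressions


def prioritize(
    ct: pd.DataFrame,
    counts: pd.Series,
    range_distance: pd.Series,
    hub_fraction: float = 0.01,
    cross_percentile: float = 0.5,
    cent_pct: float = 0.90,
    attr_pct: float = 0.50,
) -> PrioritizationReport:
    """Assemble the full hub / spoke / keystone report."""
    hubs = top_hubs(ct, hub_fraction)
    cross = cross_index_hubs(ct, cross_percentile)
    minima, zero_b = identify_spokes(ct)
    keystones, regressions = identify_keystones(
        ct, counts, range_distance, cent_pct, attr_pct
    )
    return PrioritizationReport(hubs, cross, minima, zero_b, keystones, regressions)
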