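"""Geographic clustering of leks into network nodes, plus node attributes.

Leks within a dispersal-distance cut of one another are merged by
agglomerative hierarchical clustering on great-circle distances; clusters
holding too few sampled individuals are dropped.  Node attributes cover
abundance (mean peak male count) and range position (distance from the
convex-hull centroid of all nodes, i.e. inverse range centrality).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from shapely.geometry import MultiPoint

from lekgraph.errors import ValidationError
from lekgraph.io import GenotypeTable, LekCountTable

logger = logging.getLogger(__name__)

#: Default Earth radius (km), matching the geographic-distance routine of
#: the R `fields` package (rdist.earth) for comparability.
EARTH_RADIUS_KM = 6378.388


def great_circle_distance_matrix(
    lat: np.ndarray, lon: np.ndarray, radius_km: float = EARTH_RADIUS_KM
) -> np.ndarray:
    """Symmetric haversine distance matrix (km) among points, zero diagonal."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any((lat < -90) | (lat > 90)) or np.any((lon < -180) | (lon > 180)):
        raise ValidationError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (
        np.sin(dphi / 2.0) ** 2
        + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    )
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * radius_km * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return d


def great_circle_distance(
    lat1: float, lon1: float, lat2: float, lon2: float,
    radius_km: float = EARTH_RADIUS_KM,
) -> float:
    m = great_circle_distance_matrix(
        np.array([lat1, lat2]), np.array([lon1, lon2]), radius_km
    )
    return float(m[0, 1])


@dataclass
class NodeAssignment:
    """Lek -> node mapping with per-node membership and centroids.

    ``sample_rows`` indexes rows of the genotype table the assignment was
    built from; every retained sample belongs to exactly one node.
    """

    node_ids: list[str]
    lek_to_node: dict[str, str]
    member_leks: dict[str, list[str]]
    sample_rows: dict[str, np.ndarray]
    centroids: dict[str, tuple[float, float]]  # (lat, lon)
    removed_samples: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def n_samples(self) -> dict[str, int]:
        return {n: len(self.sample_rows[n]) for n in self.node_ids}

    def retained_rows(self) -> np.ndarray:
        if not self.node_ids:
            return np.array([], dtype=int)
        return np.sort(np.concatenate([self.sample_rows[n] for n in self.node_ids]))

    def centroid_array(self) -> tuple[np.ndarray, np.ndarray]:
        lat = np.array([self.centroids[n][0] for n in self.node_ids])
        lon = np.array([self.centroids[n][1] for n in self.node_ids])
        return lat, lon


def cluster_leks_to_nodes(
    g: GenotypeTable,
    cut_km: float = 15.0,
    min_node_size: int = 4,
    method: str = "complete",
    radius_km: float = EARTH_RADIUS_KM,
) -> NodeAssignment:
    """Cluster lek locations into nodes and drop under-sampled clusters.

    Hierarchical clustering (``method``, default complete linkage) on the
    great-circle distance matrix among leks, tree cut at ``cut_km``;
    clusters with fewer than ``min_node_size`` sampled individuals are
    removed and the removed samples logged.  With complete linkage the
    within-node lek diameter never exceeds the merge height.
    """
    if cut_km <= 0:
        raise ValidationError("cut_km must be > 0")
    if min_node_size < 1:
        raise ValidationError("min_node_size must be >= 1")

    # one coordinate per lek (mean of its samples' coordinates), leks sorted
    # lexicographically so the result is invariant to input row order
    lek_coords = (
        g.meta.groupby("lek_id")[["lat", "lon"]].mean().sort_index()
    )
    lek_ids = list(lek_coords.index)
    dmat = great_circle_distance_matrix(
        lek_coords["lat"].to_numpy(), lek_coords["lon"].to_numpy(), radius_km
    )
    if len(lek_ids) == 1:
        labels = np.array([1])
    else:
        tree = linkage(squareform(dmat, checks=False), method=method)
        labels = fcluster(tree, t=cut_km, criterion="distance")

    raw_members: dict[int, list[str]] = {}
    for lek, lab in zip(lek_ids, labels):
        raw_members.setdefault(int(lab), []).append(lek)

    # canonical node order: by smallest member lek id
    ordered = sorted(raw_members.values(), key=lambda leks: min(leks))
    sample_lek = g.meta["lek_id"].to_numpy()

    node_ids: list[str] = []
    lek_to_node: dict[str, str] = {}
    member_leks: dict[str, list[str]] = {}
    sample_rows: dict[str, np.ndarray] = {}
    centroids: dict[str, tuple[float, float]] = {}
    removed: list[str] = []
    width = max(3, len(str(len(ordered))))
    kept_idx = 0
    for leks in ordered:
        rows = np.nonzero(np.isin(sample_lek, leks))[0]
        if rows.size < min_node_size:
            removed.extend(g.sample_ids[rows])
            continue
        node_id = f"N{kept_idx + 1:0{width}d}"
        kept_idx += 1
        node_ids.append(node_id)
        member_leks[node_id] = sorted(leks)
        sample_rows[node_id] = rows
        for lek in leks:
            lek_to_node[lek] = node_id
        centroids[node_id] = (
            float(lek_coords.loc[leks, "lat"].mean()),
            float(lek_coords.loc[leks, "lon"].mean()),
        )
    if removed:
        logger.info(
            "dropped %d samples in clusters below min_node_size=%d",
            len(removed), min_node_size,
        )
    if not node_ids:
        raise ValidationError(
            f"no cluster holds >= {min_node_size} samples at cut {cut_km} km"
        )
    logger.info(
        "clustered %d leks into %d nodes at %g km (%d samples retained)",
        len(lek_ids), len(node_ids), cut_km,
        sum(len(r) for r in sample_rows.values()),
    )
    return NodeAssignment(
        node_ids, lek_to_node, member_leks, sample_rows, centroids, removed
    )


def mean_peak_male_count(
    nodes: NodeAssignment,
    counts: LekCountTable,
    per_lek_first: bool = False,
) -> dict[str, float]:
    """Mean peak male count per node; NaN where no member lek has counts.

    Default is a flat mean over all (lek, year) peak records of the node's
    member leks; ``per_lek_first`` averages within lek before across leks
    (equal weight per lek regardless of years counted).
    """
    df = counts.records
    out: dict[str, float] = {}
    for node in nodes.node_ids:
        sub = df[df["lek_id"].isin(nodes.member_leks[node])]
        if sub.empty:
            out[node] = float("nan")
        elif per_lek_first:
            out[node] = float(sub.groupby("lek_id")["high_male_count"].mean().mean())
        else:
            out[node] = float(sub["high_male_count"].mean())
    return out


def range_centrality(
    nodes: NodeAssignment, radius_km: float = EARTH_RADIUS_KM
) -> dict[str, float]:
    """Great-circle distance (km) of each node from the convex-hull centroid.

    The hull is planar on (lon, lat), consistent with common GIS tooling;
    larger distance means lower range centrality.
    """
    if nodes.n_nodes < 3:
        raise ValidationError("range centrality needs >= 3 nodes")
    lat, lon = nodes.centroid_array()
    hull = MultiPoint(list(zip(lon, lat))).convex_hull
    if hull.geom_type != "Polygon":
        logger.warning("node centroids are collinear; hull degenerates to %s",
                       hull.geom_type)
    c = hull.centroid
    return {
        node: great_circle_distance(lat[i], lon[i], c.y, c.x, radius_km)
        for i, node in enumerate(nodes.node_ids)
    }


def node_table(
    g: GenotypeTable,
    nodes: NodeAssignment,
    counts: LekCountTable | None = None,
) -> pd.DataFrame:
    """Per-node summary table: centroid, sizes, abundance, range position."""
    lat, lon = nodes.centroid_array()
    df = pd.DataFrame({
        "node_id": nodes.node_ids,
        "lat": lat,
        "lon": lon,
        "n_leks": [len(nodes.member_leks[n]) for n in nodes.node_ids],
        "n_samples": [len(nodes.sample_rows[n]) for n in nodes.node_ids],
    })
    if counts is not None:
        mpmc = mean_peak_male_count(nodes, counts)
        df["mean_peak_male_count"] = [mpmc[n] for n in nodes.node_ids]
    if nodes.n_nodes >= 3:
        rc = range_centrality(nodes)
        df["range_distance_km"] = [rc[n] for n in nodes.node_ids]
    return df
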