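"""Delaunay interaction graphs, cell networks and lymphoid-aggregate calls.

Directly interacting cells are defined by a centroid-to-centroid
distance of at most ``delta`` micrometres (default 10, inclusive).
The interaction graph is the Delaunay triangulation of the cell
centroids with edges longer than ``delta`` removed; a pure distance
graph (every pair within ``delta``) is available as an alternative
mode and is the automatic fallback for degenerate point sets (n < 3 or
collinear).  Connected components of the graph are *cell networks*:
a component with at least ``n_min`` (default 10) cells is a network,
with at least ``n_large`` (default 100) cells a large network.

A large T cell network colocalized with a dense B cell network (built
with the same parameters) is called a *lymphoid aggregate* (LA);
otherwise it is T-dominant.  Colocalization means intersecting convex
hulls or a minimum member-to-member distance of at most ``coloc_delta``
(default 20 um = two interaction radii, inclusive).  A k-nearest-
neighbour mixing score distinguishes mixed T/B aggregates (score near
1) from zonated ones with a central B core (score toward 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint

from ._util import Undefined
from .cellmap import CellMap, T_PHENOTYPES

DEFAULT_DELTA_UM = 10.0
DEFAULT_N_MIN = 10
DEFAULT_N_LARGE = 100
DEFAULT_COLOC_DELTA_UM = 20.0

SIZE_BELOW = "below_threshold"
SIZE_NETWORK = "network"
SIZE_LARGE = "large_network"

LABEL_T_DOMINANT = "T_DOMINANT"
LABEL_LA = "LYMPHOID_AGGREGATE"


@dataclass
class InteractionGraph:
    """Pruned-Delaunay or distance interaction graph of one phenotype class."""

    graph: nx.Graph
    coords: pd.DataFrame            # cell_id, x_um, y_um
    mode: str                       # "delaunay_pruned" | "distance_graph"
    delta_um: float
    phenotype_class: str = "T"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edges(self) -> set[tuple]:
        return {tuple(sorted(e)) for e in self.graph.edges}


@dataclass
class CellNetwork:
    """One connected component of an interaction graph."""

    network_id: str
    phenotype_class: str
    cell_ids: tuple
    coords: np.ndarray              # (n, 2) um
    size: int
    size_class: str
    hull: object                    # shapely geometry (may be degenerate)
    hull_area_um2: float

    def __post_init__(self) -> None:
        assert self.size == len(self.cell_ids) == len(self.coords)


@dataclass
class AggregateCall:
    """Classification of one large T cell network."""

    t_network_id: str
    label: str
    b_network_id: str | None
    colocalization_distance_um: float | None
    mixing_score: float | Undefined
    n_t: int
    n_b: int


@dataclass
class NetworkSummary:
    sample_id: str
    tissue_area_mm2: float
    n_networks: int                 # components with n >= n_min
    networks_per_mm2: float
    n_large_networks: int
    n_lymphoid_aggregates: int
    n_t_dominant_large: int


def _size_class(n: int, n_min: int, n_large: int) -> str:
    if n >= n_large:
        return SIZE_LARGE
    if n >= n_min:
        return SIZE_NETWORK
    return SIZE_BELOW


def build_interaction_graph(cells: pd.DataFrame,
                            delta_um: float = DEFAULT_DELTA_UM,
                            mode: str = "delaunay_pruned",
                            phenotype_class: str = "T",
                            jitter_duplicates: bool = False,
                            jitter_seed: int = 0) -> InteractionGraph:
    """Build the interaction graph of one phenotype's cells.

    ``cells`` needs columns ``cell_id, x_um, y_um``.  In
    ``delaunay_pruned`` mode, Delaunay edges longer than ``delta_um``
    are discarded (inclusive threshold); point sets with fewer than
    three cells or a degenerate (collinear) geometry fall back to the
    distance graph, which is identical for those inputs.  Exact
    duplicate coordinates are an error unless ``jitter_duplicates``
    applies a deterministic +-0.1 um perturbation.
    """
    if mode not in ("delaunay_pruned", "distance_graph"):
        raise ValueError(f"unknown mode {mode!r}")
    if delta_um <= 0:
        raise ValueError("delta_um must be > 0")
    ids = cells["cell_id"].to_numpy()
    xy = cells[["x_um", "y_um"]].to_numpy(dtype=float).copy()

    if len(xy) > 1:
        _, inverse, counts = np.unique(xy, axis=0, return_inverse=True,
                                       return_counts=True)
        if (counts > 1).any():
            if not jitter_duplicates:
                dup = ids[np.where(counts[inverse] > 1)[0][0]]
                raise ValueError(
                    f"duplicate coordinates (first at cell {dup!r}); "
                    "enable jitter_duplicates for a deterministic perturbation")
            rng = np.random.default_rng(jitter_seed)
            dup_rows = np.where(counts[inverse] > 1)[0]
            xy[dup_rows] += rng.uniform(-0.1, 0.1, size=(len(dup_rows), 2))

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    used_mode = mode

    def _add_edges(pairs: Iterable[tuple[int, int]]) -> None:
        for i, j in pairs:
            d = float(np.hypot(*(xy[i] - xy[j])))
            if d <= delta_um:
                graph.add_edge(ids[i], ids[j], length_um=d)

    if mode == "delaunay_pruned" and len(xy) >= 3:
        try:
            tri = Delaunay(xy)
        except QhullError:
            used_mode = "distance_graph"
        else:
            pairs = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((simplex[a], simplex[b]))
                        pairs.add((i, j))
            _add_edges(pairs)
    else:
        used_mode = "distance_graph"

    if used_mode == "distance_graph" or mode == "distance_graph":
        if mode == "distance_graph":
            used_mode = "distance_graph"
        if len(xy):
            tree = cKDTree(xy)
            _add_edges(tree.query_pairs(delta_um))

    coords = pd.DataFrame({"cell_id": ids, "x_um": xy[:, 0], "y_um": xy[:, 1]})
    return InteractionGraph(graph=graph, coords=coords, mode=used_mode,
                            delta_um=delta_um, phenotype_class=phenotype_class)


def graph_for_phenotype(cellmap: CellMap, phenotype_class: str = "T",
                        delta_um: float = DEFAULT_DELTA_UM,
                        mode: str = "delaunay_pruned",
                        **kwargs) -> InteractionGraph:
    """Convenience wrapper: interaction graph of one phenotype of a map.

    ``phenotype_class="T"`` selects both T and T_CD8 cells.
    """
    phenos = T_PHENOTYPES if phenotype_class == "T" else (phenotype_class,)
    cells = cellmap.coordinates(phenos)
    return build_interaction_graph(cells, delta_um=delta_um, mode=mode,
                                   phenotype_class=phenotype_class, **kwargs)


def extract_networks(graph: InteractionGraph,
                     n_min: int = DEFAULT_N_MIN,
                     n_large: int = DEFAULT_N_LARGE) -> list[CellNetwork]:
    """Connected components of the interaction graph, size-classified.

    Every cell belongs to exactly one component (isolated cells form
    singletons of class ``below_threshold``).  Convex hulls of
    components with fewer than three cells, or collinear ones, are
    degenerate with area 0 but remain usable for distance tests.
    Networks are ordered by decreasing size, ties broken by member ids.
    """
    if n_min < 1 or n_large < n_min:
        raise ValueError("need 1 <= n_min <= n_large")
    pos = {cid: (x, y) for cid, x, y in
           graph.coords[["cell_id", "x_um", "y_um"]].itertuples(index=False)}
    components = [tuple(sorted(c, key=str)) for c in nx.connected_components(graph.graph)]
    components.sort(key=lambda c: (-len(c), c))
    networks = []
    for k, comp in enumerate(components, start=1):
        coords = np.array([pos[c] for c in comp], dtype=float)
        hull = MultiPoint(coords).convex_hull
        networks.append(CellNetwork(
            network_id=f"{graph.phenotype_class}_net{k:03d}",
            phenotype_class=graph.phenotype_class,
            cell_ids=comp,
            coords=coords,
            size=len(comp),
            size_class=_size_class(len(comp), n_min, n_large),
            hull=hull,
            hull_area_um2=float(hull.area),
        ))
    return networks


def _min_member_distance(a: np.ndarray, b: np.ndarray) -> float:
    tree = cKDTree(a)
    d, _ = tree.query(b, k=1)
    return float(np.min(d))


def detect_lymphoid_aggregates(t_networks: Sequence[CellNetwork],
                               b_networks: Sequence[CellNetwork],
                               coloc_delta_um: float = DEFAULT_COLOC_DELTA_UM,
                               n_min: int = DEFAULT_N_MIN,
                               mixing_k: int = 5) -> list[AggregateCall]:
    """Classify each large T network as lymphoid aggregate or T-dominant.

    A large T network is a lymphoid aggregate iff some B network with
    at least ``n_min`` members either overlaps it (intersecting convex
    hulls) or lies within ``coloc_delta_um`` (inclusive) minimum
    member-to-member distance.  The closest qualifying B network is
    attached, along with the T/B mixing score of the combined members.
    """
    calls = []
    dense_b = [b for b in b_networks if b.size >= n_min]
    for t in t_networks:
        if t.size_class != SIZE_LARGE:
            continue
        best: tuple[float, CellNetwork] | None = None
        for b in dense_b:
            d = _min_member_distance(t.coords, b.coords)
            if d <= coloc_delta_um or t.hull.intersects(b.hull):
                if best is None or d < best[0]:
                    best = (d, b)
        if best is None:
            calls.append(AggregateCall(
                t_network_id=t.network_id, label=LABEL_T_DOMINANT,
                b_network_id=None, colocalization_distance_um=None,
                mixing_score=Undefined("no colocalized B network"),
                n_t=t.size, n_b=0))
        else:
            d, b = best
            score = mixing_score(t.coords, b.coords, k=mixing_k)
            calls.append(AggregateCall(
                t_network_id=t.network_id, label=LABEL_LA,
                b_network_id=b.network_id, colocalization_distance_um=d,
                mixing_score=score, n_t=t.size, n_b=b.size))
    return calls


def mixing_score(t_coords: np.ndarray, b_coords: np.ndarray,
                 k: int = 5) -> float | Undefined:
    """T/B intermixing of an aggregate's members, in [0, 1].

    The fraction of B cells whose ``k`` nearest aggregate members
    (T and B cells pooled, self excluded) include at least one T cell.
    Near 1 for aggregates with T and B cells mixed throughout; toward
    0 for a zonated layout with an inner B cell core ringed by T cells.
    """
    t_coords = np.asarray(t_coords, dtype=float)
    b_coords = np.asarray(b_coords, dtype=float)
    if len(b_coords) == 0:
        return Undefined("aggregate has no B cells")
    n_total = len(t_coords) + len(b_coords)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n_total:
        raise ValueError(f"k={k} not smaller than aggregate size {n_total}")
    pooled = np.vstack([t_coords, b_coords])
    is_t = np.zeros(n_total, dtype=bool)
    is_t[:len(t_coords)] = True
    tree = cKDTree(pooled)
    # query B cells; k+1 because each B cell is its own nearest neighbour
    _, idx = tree.query(b_coords, k=k + 1)
    idx = np.atleast_2d(idx)
    b_index = np.arange(len(t_coords), n_total)
    has_t = []
    for row, self_i in zip(idx, b_index):
        neighbours = [j for j in row if j != self_i][:k]
        has_t.append(bool(is_t[neighbours].any()))
    return float(np.mean(has_t))


def summarize_networks(cellmap: CellMap,
                       networks: Sequence[CellNetwork],
                       aggregates: Sequence[AggregateCall] = (),
                       n_min: int = DEFAULT_N_MIN) -> NetworkSummary:
    """Per-sample network counts: per-mm^2 for n>=n_min, raw for the rest."""
    n_networks = sum(1 for n in networks if n.size >= n_min)
    n_large = sum(1 for n in networks if n.size_class == SIZE_LARGE)
    n_la = sum(1 for a in aggregates if a.label == LABEL_LA)
    n_tdom = sum(1 for a in aggregates if a.label == LABEL_T_DOMINANT)
    return NetworkSummary(
        sample_id=cellmap.sample_id,
        tissue_area_mm2=cellmap.tissue_area_mm2,
        n_networks=n_networks,
        networks_per_mm2=n_networks / cellmap.tissue_area_mm2,
        n_large_networks=n_large,
        n_lymphoid_aggregates=n_la,
        n_t_dominant_large=n_tdom,
    )


def networks_table(networks: Sequence[CellNetwork], sample_id: str) -> pd.DataFrame:
    """Tidy export of networks (one row per component)."""
    return pd.DataFrame([
        {"network_id": n.network_id, "sample_id": sample_id,
         "phenotype": n.phenotype_class, "n": n.size,
         "size_class": n.size_class, "hull_area_um2": n.hull_area_um2}
        for n in networks])


def aggregates_table(aggregates: Sequence[AggregateCall], sample_id: str) -> pd.DataFrame:
    rows = []
    for a in aggregates:
        rows.append({
            "sample_id": sample_id, "t_network_id": a.t_network_id,
            "label": a.label, "b_network_id": a.b_network_id,
            "colocalization_distance_um": a.colocalization_distance_um,
            "mixing_score": a.mixing_score if not isinstance(a.mixing_score, Undefined) else np.nan,
            "n_t": a.n_t, "n_b": a.n_b})
    return pd.DataFrame(rows, columns=["sample_id", "t_network_id", "label",
                                       "b_network_id", "colocalization_distance_um",
                                       "mixing_score", "n_t", "n_b"])


def hulls_geojson(networks: Sequence[CellNetwork], sample_id: str) -> dict:
    """GeoJSON FeatureCollection of network convex hulls (um coordinates)."""
    features = []
    for n in networks:
        features.append({
            "type": "Feature",
            "properties": {"network_id": n.network_id, "sample_id": sample_id,
                           "phenotype": n.phenotype_class, "n": n.size,
                           "size_class": n.size_class},
            "geometry": n.hull.__geo_interface__,
        })
    return {"type": "FeatureCollection", "features": features}
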