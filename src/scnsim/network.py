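"""Two-region SCN graph construction.

Cells live in the unit square: the light-receiving, mutually unconnected
ventrolateral (VL) cells occupy the lower band y in [0, 1/3), the rhythmic
dorsomedial (DM) cells the band above.  DM cells are wired as a random
geometric graph (radius chosen so the expected degree is ``k_mean``); the
seasonal control parameter ``delta`` then adds long-range edges: each VL--DM
pair with probability delta, each same-region pair with probability
delta * intra_factor (default a ten times smaller probability).  All coupling
is bidirectional; weights default to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_models import named_rng

__all__ = [
    "NetworkConfig",
    "CellTable",
    "SCNNetwork",
    "place_cells",
    "connect_rgg",
    "add_long_range",
    "build_network",
    "scale_edge_weights",
    "subnetwork",
    "expected_long_range_count",
    "to_graphml",
    "from_graphml",
    "to_csv",
    "from_csv",
    "VL_BAND_TOP",
]

#: y-coordinate separating the VL band (below) from the DM band (above).
VL_BAND_TOP = 1.0 / 3.0


@dataclass(frozen=True)
class NetworkConfig:
    """Construction parameters of the two-region SCN graph."""

    N: int = 600
    f_VL: float = 1.0 / 3.0
    k_mean: float = 6.0
    delta: float = 0.005
    intra_factor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not (0.0 <= self.delta <= 1.0 and 0.0 <= self.intra_factor <= 1.0 and 0.0 <= self.f_VL <= 1.0):
            raise ValueError(f"probabilities out of range in {self}")


@dataclass(frozen=True)
class CellTable:
    """Cell positions and region labels; ids are 0..N-1 in array order."""

    pos: np.ndarray          # (N, 2) coordinates in the unit square
    region: np.ndarray       # (N,) strings "VL" | "DM"

    @property
    def n(self) -> int:
        return len(self.region)

    @property
    def vl_mask(self) -> np.ndarray:
        return self.region == "VL"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": np.arange(self.n), "x": self.pos[:, 0], "y": self.pos[:, 1],
             "region": self.region, "rhythmic": self.region == "DM"}
        )


@dataclass(frozen=True)
class SCNNetwork:
    """Weighted, symmetric-pattern SCN graph with short/long edge classes.

    ``edges`` holds each undirected edge once as (i, j, weight, class) with
    i < j and class in {"short", "long"}; ``degrees`` counts neighbors
    (weight-independent).
    """

    cells: CellTable
    edges: pd.DataFrame
    config: NetworkConfig | None = None

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and (e["i"] >= e["j"]).any():
            raise ValueError("edges must be stored with i < j")

    @property
    def n(self) -> int:
        return self.cells.n

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        np.add.at(deg, self.edges["i"].to_numpy(dtype=int), 1)
        np.add.at(deg, self.edges["j"].to_numpy(dtype=int), 1)
        return deg

    def adjacency(self, weighted: bool = True):
        """Dense symmetric adjacency matrix W (weights or 0/1 pattern)."""
        W = np.zeros((self.n, self.n))
        i = self.edges["i"].to_numpy(dtype=int)
        j = self.edges["j"].to_numpy(dtype=int)
        w = self.edges["weight"].to_numpy() if weighted else 1.0
        W[i, j] = w
        W[j, i] = w
        return W

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i, j, w, c in self.edges[["i", "j", "weight", "class"]].itertuples(index=False):
            g.add_edge(int(i), int(j), weight=float(w), cls=str(c))
        return g


def _edge_frame(i, j, weight, cls) -> pd.DataFrame:
    return pd.DataFrame(
        {"i": np.asarray(i, dtype=int), "j": np.asarray(j, dtype=int),
         "weight": np.asarray(weight, dtype=float), "class": cls}
    )


def place_cells(config: NetworkConfig) -> CellTable:
    """Place round(N * f_VL) VL cells uniformly in the lower band, DM above."""
    rng = named_rng(config.seed, "geometry")
    n_vl = round(config.N * config.f_VL)
    n_dm = config.N - n_vl
    pos_vl = rng.uniform([0.0, 0.0], [1.0, VL_BAND_TOP], size=(n_vl, 2))
    pos_dm = rng.uniform([0.0, VL_BAND_TOP], [1.0, 1.0], size=(n_dm, 2))
    pos = np.vstack([pos_vl, pos_dm])
    region = np.array(["VL"] * n_vl + ["DM"] * n_dm)
    return CellTable(pos=pos, region=region)


def connect_rgg(cells: CellTable, k_mean: float) -> pd.DataFrame:
    """Short-range random-geometric edges among DM cells.

    Every DM pair within Euclidean distance ``r = sqrt(k_mean / (pi rho))``
    is connected, where ``rho`` is the DM cell density in the DM band
    (area 1 x (1 - 1/3)).  VL cells receive no short-range edges.
    """
    dm_idx = np.flatnonzero(~cells.vl_mask)
    if k_mean <= 0 or len(dm_idx) < 2:
        if k_mean <= 0:
            import warnings

            warnings.warn("k_mean <= 0: no short-range edges", stacklevel=2)
        return _edge_frame([], [], [], [])
    rho = len(dm_idx) / (1.0 - VL_BAND_TOP)
    radius = math.sqrt(k_mean / (math.pi * rho))
    tree = cKDTree(cells.pos[dm_idx])
    pairs = tree.query_pairs(radius, output_type="ndarray")
    i = dm_idx[np.minimum(pairs[:, 0], pairs[:, 1])]
    j = dm_idx[np.maximum(pairs[:, 0], pairs[:, 1])]
    return _edge_frame(i, j, np.ones(len(i)), "short")


def add_long_range(
    cells: CellTable,
    existing: pd.DataFrame,
    delta: float,
    intra_factor: float,
    seed: int,
) -> pd.DataFrame:
    """Bernoulli long-range edges: VL-DM pairs with probability delta,
    same-region pairs with probability delta * intra_factor; pairs already
    connected by a short-range edge are skipped."""
    if not (0.0 <= delta <= 1.0 and 0.0 <= intra_factor <= 1.0):
        raise ValueError(f"invalid probabilities: delta={delta}, intra_factor={intra_factor}")
    if delta == 0.0:
        return _edge_frame([], [], [], [])
    rng = named_rng(seed, "long-range")
    n = cells.n
    vl = cells.vl_mask
    iu, ju = np.triu_indices(n, k=1)
    inter = vl[iu] != vl[ju]
    p = np.where(inter, delta, delta * intra_factor)
    keep = rng.random(len(iu)) < p
    if len(existing):
        taken = set(zip(existing["i"], existing["j"]))
        keep &= np.fromiter(((a, b) not in taken for a, b in zip(iu, ju)), dtype=bool, count=len(iu))
    return _edge_frame(iu[keep], ju[keep], np.ones(int(keep.sum())), "long")


def build_network(config: NetworkConfig) -> SCNNetwork:
    """Compose placement, short-range and long-range stages (reproducible)."""
    cells = place_cells(config)
    short = connect_rgg(cells, config.k_mean)
    long_ = add_long_range(cells, short, config.delta, config.intra_factor, config.seed)
    edges = pd.concat([short, long_], ignore_index=True)
    return SCNNetwork(cells=cells, edges=edges, config=config)


def scale_edge_weights(
    network: SCNNetwork,
    edge_class: str,
    fraction: float,
    factor: float,
    seed: int = 0,
) -> SCNNetwork:
    """Multiply the weights of a seeded-random ``fraction`` of the edges of
    one class by ``factor``; the edge pattern is unchanged.

    Models synaptic weakening (e.g. a 75 % weight reduction of half the
    long-range connections) without deleting links.
    """
    if edge_class not in ("short", "long"):
        raise ValueError(f"unknown edge class: {edge_class}")
    if not (0.0 <= fraction <= 1.0 and factor >= 0.0):
        raise ValueError(f"invalid fraction={fraction} or factor={factor}")
    edges = network.edges.copy()
    members = np.flatnonzero((edges["class"] == edge_class).to_numpy())
    n_pick = round(len(members) * fraction)
    picked = named_rng(seed, "weight-scaling").choice(members, size=n_pick, replace=False)
    edges.loc[edges.index[picked], "weight"] *= factor
    return replace(network, edges=edges)


def subnetwork(network: SCNNetwork, keep: np.ndarray) -> SCNNetwork:
    """Induced subgraph on the cells flagged by the boolean mask ``keep``,
    with ids relabeled to 0..sum(keep)-1."""
    keep = np.asarray(keep, dtype=bool)
    new_id = np.cumsum(keep) - 1
    e = network.edges
    sel = keep[e["i"].to_numpy(dtype=int)] & keep[e["j"].to_numpy(dtype=int)]
    edges = e[sel].copy()
    edges["i"] = new_id[edges["i"].to_numpy(dtype=int)]
    edges["j"] = new_id[edges["j"].to_numpy(dtype=int)]
    cells = CellTable(pos=network.cells.pos[keep], region=network.cells.region[keep])
    return SCNNetwork(cells=cells, edges=edges.reset_index(drop=True))


def expected_long_range_count(
    n: int, f_vl: float, delta: float, intra_factor: float = 0.1
) -> float:
    """Analytic expected number of added long-range edges.

    ``delta * (N_VL * N_DM + intra_factor * (C(N_VL, 2) + C(N_DM, 2)))``;
    short-range collisions are ignored (VL-DM short edges do not exist, and
    same-region collisions only shave an O(k_mean * N / 2) pair set whose
    contribution is negligible at the default densities).
    """
    n_vl = round(n * f_vl)
    n_dm = n - n_vl
    intra_pairs = n_vl * (n_vl - 1) / 2 + n_dm * (n_dm - 1) / 2
    return delta * (n_vl * n_dm + intra_factor * intra_pairs)


# ---------------------------------------------------------------------------
# I/O: GraphML and plain CSV edge/node lists (lossless round-trip)
# ---------------------------------------------------------------------------


def to_graphml(network: SCNNetwork, path) -> None:
    g = network.to_networkx()
    for i in range(network.n):
        g.nodes[i]["x"] = float(network.cells.pos[i, 0])
        g.nodes[i]["y"] = float(network.cells.pos[i, 1])
        g.nodes[i]["region"] = str(network.cells.region[i])
    nx.write_graphml(g, path)


def from_graphml(path) -> SCNNetwork:
    g = nx.read_graphml(path, node_type=int)
    order = sorted(g.nodes)
    pos = np.array([[g.nodes[i]["x"], g.nodes[i]["y"]] for i in order])
    region = np.array([g.nodes[i]["region"] for i in order])
    rows = [(min(i, j), max(i, j), d.get("weight", 1.0), d.get("cls", "short")) for i, j, d in g.edges(data=True)]
    rows.sort()
    edges = _edge_frame([r[0] for r in rows], [r[1] for r in rows], [r[2] for r in rows], [r[3] for r in rows])
    return SCNNetwork(cells=CellTable(pos=pos, region=region), edges=edges)


def to_csv(network: SCNNetwork, edge_path, node_path) -> None:
    network.edges.to_csv(edge_path, index=False)
    network.cells.frame().to_csv(node_path, index=False)


def from_csv(edge_path, node_path) -> SCNNetwork:
    nodes = pd.read_csv(node_path).sort_values("id")
    edges = pd.read_csv(edge_path)
    cells = CellTable(pos=nodes[["x", "y"]].to_numpy(), region=nodes["region"].to_numpy(dtype=str))
    return SCNNetwork(cells=cells, edges=edges)
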