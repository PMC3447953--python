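"""Structural and spectral diagnostics of the SCN graph.

Small-world structure is diagnosed by the global efficiency E (mean inverse
shortest-path length), the average clustering coefficient C, and their
product C*E, which peaks at the delta giving the optimal trade-off between
cliquishness and traffic capacity.  Synchronizability is probed through the
local-mean-field graph Laplacian ``L = I - D^-1 W`` (non-symmetric because
of the row normalization): near-zero singular values of L flag weakly
interconnected oscillator communities that fail to lock their phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .network import NetworkConfig, SCNNetwork, build_network

__all__ = [
    "SmallWorldSummary",
    "SpectralSummary",
    "efficiency",
    "clustering_coefficient",
    "small_world_scan",
    "laplacian",
    "singular_spectrum",
    "near_zero_singular_count",
    "spectral_scan",
]

#: Near-zero threshold for singular values of the Laplacian.
NEAR_ZERO_THRESHOLD = 1e-6


@dataclass(frozen=True)
class SmallWorldSummary:
    E: float
    C: float

    @property
    def CE(self) -> float:
        return self.E * self.C


@dataclass(frozen=True)
class SpectralSummary:
    """Ascending singular values of the pruned Laplacian plus the count of
    near-zero ones (the trivial zero of each connected component included)."""

    singular_values: np.ndarray
    near_zero_count: int
    n_pruned: int
    threshold: float = NEAR_ZERO_THRESHOLD


def _as_graph(network) -> nx.Graph:
    """Unweighted-pattern view; topology metrics ignore edge weights."""
    if isinstance(network, nx.Graph):
        return network
    return network.to_networkx()


def efficiency(network) -> float:
    """Global efficiency: mean of 1/l_ij over ordered pairs, with 1/inf = 0
    for disconnected pairs; 1 for a complete graph, 0 for an edgeless one."""
    g = _as_graph(network)
    if g.number_of_nodes() < 2:
        raise ValueError("efficiency needs >= 2 nodes")
    return nx.global_efficiency(g)


def clustering_coefficient(network) -> float:
    """Average over all nodes of the realized fraction of links among each
    node's k_i (k_i - 1) / 2 neighbor pairs (0 for nodes with k_i < 2)."""
    return nx.average_clustering(_as_graph(network))


def small_world_measures(network) -> SmallWorldSummary:
    g = _as_graph(network)
    return SmallWorldSummary(E=efficiency(g), C=clustering_coefficient(g))


def small_world_scan(
    config: NetworkConfig,
    deltas,
    replicates: int = 5,
    normalize: bool = False,
) -> pd.DataFrame:
    """E, C and C*E across a delta grid (mean and SD over seeded replicates).

    ``normalize`` min-max scales the three mean columns to the unit interval
    across the scanned grid, the convention used when the three curves are
    displayed together.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rows = []
    for delta in deltas:
        vals = []
        for rep in range(replicates):
            cfg = replace(config, delta=float(delta), seed=config.seed + 1000 * rep)
            s = small_world_measures(build_network(cfg))
            vals.append((s.E, s.C, s.CE))
        vals = np.asarray(vals)
        rows.append({
            "delta": float(delta),
            "E": vals[:, 0].mean(), "E_sd": vals[:, 0].std(),
            "C": vals[:, 1].mean(), "C_sd": vals[:, 1].std(),
            "CE": vals[:, 2].mean(), "CE_sd": vals[:, 2].std(),
        })
    df = pd.DataFrame(rows)
    if normalize:
        for col in ("E", "C", "CE"):
            lo, hi = df[col].min(), df[col].max()
            df[col + "_norm"] = (df[col] - lo) / (hi - lo) if hi > lo else 0.0
    return df


def laplacian(network: SCNNetwork, weighted: bool = True) -> np.ndarray:
    """Local-mean-field Laplacian ``L_ij = delta_ij - W_ij / k_i``.

    ``k_i`` is the neighbor count, so L is generally non-symmetric.  Rows of
    isolated cells reduce to the identity row (their W-row is zero); they
    are pruned before spectral analysis, not here.
    """
    W = network.adjacency(weighted=weighted)
    deg = network.degrees.astype(float)
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return np.eye(network.n) - inv[:, None] * W


def singular_spectrum(network: SCNNetwork, threshold: float = NEAR_ZERO_THRESHOLD) -> SpectralSummary:
    """Singular values (ascending) of the Laplacian after removing all
    completely disconnected cells, each of which would contribute only a
    trivial zero to the spectrum."""
    keep = network.degrees > 0
    n_pruned = int((~keep).sum())
    if not keep.any():
        import warnings

        warnings.warn("network has no connected cells; empty spectrum")
        return SpectralSummary(np.array([]), 0, n_pruned, threshold)
    W = network.adjacency(weighted=True)[np.ix_(keep, keep)]
    deg = network.degrees[keep].astype(float)
    L = np.eye(int(keep.sum())) - W / deg[:, None]
    sv = np.sort(np.linalg.svd(L, compute_uv=False))
    return SpectralSummary(sv, int((sv < threshold).sum()), n_pruned, threshold)


def near_zero_singular_count(
    network: SCNNetwork, threshold: float = NEAR_ZERO_THRESHOLD
) -> tuple[int, int]:
    """(number of singular values below ``threshold``, pruned-cell count)."""
    s = singular_spectrum(network, threshold)
    return s.near_zero_count, s.n_pruned


def spectral_scan(
    config: NetworkConfig,
    deltas,
    replicates: int = 25,
    threshold: float = NEAR_ZERO_THRESHOLD,
) -> pd.DataFrame:
    """Mean and SD of the near-zero singular-value count across a delta grid."""
    rows = []
    for delta in deltas:
        counts = []
        for rep in range(replicates):
            cfg = replace(config, delta=float(delta), seed=config.seed + 1000 * rep)
            counts.append(near_zero_singular_count(build_network(cfg), threshold)[0])
        counts = np.asarray(counts, dtype=float)
        rows.append({"delta": float(delta), "near_zero_mean": counts.mean(), "near_zero_sd": counts.std()})
    return pd.DataFrame(rows)
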