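"""Shared fixtures: reference networks, populations, entrained runs, and
brute-force graph oracles used to cross-check the library implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from scnsim.core_models import PoincareParams, sample_poincare_population
from scnsim.network import CellTable, NetworkConfig, SCNNetwork, build_network
from scnsim.simulate import LightSchedule, SimConfig, Trajectory, free_run, simulate_network

SEED = 1

WINTER_DELTA = 0.01
SUMMER_DELTA = 0.005


def make_network(pos, regions, edge_list):
    """Hand-built SCNNetwork from explicit positions/regions/edges."""
    edges = pd.DataFrame(
        {
            "i": [min(i, j) for i, j, *_ in edge_list],
            "j": [max(i, j) for i, j, *_ in edge_list],
            "weight": [e[2] if len(e) > 2 else 1.0 for e in edge_list],
            "class": [e[3] if len(e) > 3 else "short" for e in edge_list],
        }
    )
    cells = CellTable(pos=np.asarray(pos, dtype=float), region=np.asarray(regions))
    return SCNNetwork(cells=cells, edges=edges)


def single_cell_network():
    return make_network([[0.5, 0.7]], ["DM"], [])


def make_trajectory(times, activity, schedule=None, transient_until=0.0):
    """Wrap a (N, T) activity array as a Trajectory for the measures module."""
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    return Trajectory(
        times=np.asarray(times, dtype=float),
        states=activity[None, :, :],
        var_names=("x",),
        transient_until=transient_until,
        model_kind="poincare",
        schedule=schedule,
    )


# ---------------------------------------------------------------------------
# Brute-force graph oracles (independent of networkx and scnsim.graphstats)
# ---------------------------------------------------------------------------


def bf_shortest_paths(n, edges):
    """All-pairs unweighted shortest path lengths by BFS; inf if disconnected."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[s, v] == np.inf:
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def bf_efficiency(n, edges):
    dist = bf_shortest_paths(n, edges)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bf_clustering(n, edges):
    nbrs = [set() for _ in range(n)]
    for i, j in edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    cs = []
    for i in range(n):
        k = len(nbrs[i])
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(1 for a in nbrs[i] for b in nbrs[i] if a < b and b in nbrs[a])
        cs.append(links / (k * (k - 1) / 2))
    return float(np.mean(cs))


def bf_laplacian(n, weighted_edges):
    """Row-normalized Laplacian built by explicit loops."""
    W = np.zeros((n, n))
    for i, j, w in weighted_edges:
        W[i, j] = w
        W[j, i] = w
    deg = (W > 0).sum(axis=1).astype(float)
    L = np.eye(n)
    for i in range(n):
        if deg[i] > 0:
            L[i, :] -= W[i, :] / deg[i]
    return L


# ---------------------------------------------------------------------------
# Session-scoped reference simulations (the seasonal comparison pair)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def population600():
    return sample_poincare_population(600, 1.0 / 3.0, SEED)


@pytest.fixture(scope="session")
def winter_network():
    return build_network(NetworkConfig(N=600, delta=WINTER_DELTA, seed=SEED))


@pytest.fixture(scope="session")
def summer_network():
    return build_network(NetworkConfig(N=600, delta=SUMMER_DELTA, seed=SEED))


@pytest.fixture(scope="session")
def winter_entrained(winter_network, population600):
    sim = SimConfig(seed=SEED)
    return simulate_network(winter_network, population600, LightSchedule(sigma_L=8.0), sim)


@pytest.fixture(scope="session")
def summer_entrained(summer_network, population600):
    sim = SimConfig(seed=SEED)
    return simulate_network(summer_network, population600, LightSchedule(sigma_L=16.0), sim)


@pytest.fixture(scope="session")
def winter_uncoupled(winter_network, population600):
    sim = SimConfig(g=0.0, seed=SEED)
    return free_run(winter_network, population600, sim)
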