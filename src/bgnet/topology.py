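"""Directed connectivity of the basal ganglia-thalamus network.

Population sizes are 500 STN, 500 GPe, 500 GPi and 200 thalamic neurons
(1700 in total).  Projections:

* intra-GPe and intra-GPi: Watts-Strogatz small-world rings (k=20,
  p=0.005), every undirected edge instantiated in both directions;
* intra-STN: sparse -- only 20% of neurons ("hubs") are interconnected,
  each with ~25 partners drawn from ring-distance bands, matching tracing
  data in which most subthalamic neurons lack local collaterals; a dense
  small-world variant (k=20) is available for robustness studies;
* GPe<->STN and STN->GPi: index-matched one-to-one wiring;
* GPe->GPi: each GPe neuron inhibits its 18 ring-nearest GPi counterparts
  plus 2 random remote ones (mean out-degree 20);
* GPi->THA: each thalamic neuron receives exactly 3 afferents from a pool
  of 200 uniformly chosen GPi neurons.

Adjacency matrices are boolean CSR matrices with A[i, j] = 1 iff
presynaptic neuron j projects to postsynaptic neuron i.  All randomness is
driven by a single integer seed, so identical seeds give bit-identical
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

N_STN, N_GPE, N_GPI, N_THA = 500, 500, 500, 200

#: synaptic conductances (nS/um^2) per projection, shared by all conditions
CONDUCTANCES = {
    "STN->STN": 0.5,     # g_STST, glutamatergic
    "GPe->STN": 4.5,     # g_GPST, GABAergic
    "GPe->GPe": 0.07,    # g_GPeGPe
    "STN->GPe": 0.56,    # g_STGPe
    "GPi->GPi": 0.07,    # g_GPiGPi
    "GPe->GPi": 0.01,    # g_GPeGPi
    "STN->GPi": 0.2,     # g_STGPi
    "GPi->THA": 0.1,     # g_GPiTha
}

E_GLU = -10.0   # mV, glutamatergic reversal
E_GABA = -70.0  # mV, GABAergic reversal

#: excitatory projections (all others are GABAergic)
EXCITATORY = {"STN->STN", "STN->GPe", "STN->GPi"}

PROJECTIONS = tuple(CONDUCTANCES)

_POP_SIZES = {"STN": N_STN, "GPe": N_GPE, "GPi": N_GPI, "THA": N_THA}

#: ring-distance bands (lo, hi, weight) for sparse intra-STN wiring:
#: 30% of contacts local (|d| <= 10), 45% intermediate (10 < |d| <= 20),
#: 25% remote (|d| > 25); distances between 20 and 25 are unused.
DEFAULT_STN_BANDS = ((0, 10, 0.30), (10, 20, 0.45), (25, None, 0.25))


def _ring_distance(i, j, n):
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n - d)


def build_ws_ring(n: int, k: int, p: float, seed: int) -> sp.csr_matrix:
    """Watts-Strogatz small-world ring as a symmetric directed adjacency.

    Each node starts coupled to its k/2 nearest neighbours on either side;
    every lattice edge is rewired with probability p to a uniformly chosen
    non-duplicate target.  The undirected edge count n*k/2 is conserved,
    and both directions of every edge are present in the returned matrix.
    """
    if k % 2 or k >= n:
        raise ValueError("k must be even and smaller than n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    g = nx.watts_strogatz_graph(n, k, p, seed=int(seed))
    rows, cols = np.array(g.edges()).T
    data = np.ones(rows.size, dtype=np.int8)
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    a = (a + a.T).tolil()  # both directions
    a.setdiag(0)
    a = a.tocsr()
    a.eliminate_zeros()
    return a.astype(np.int8)


def build_sparse_stn(n: int = N_STN, hub_fraction: float = 0.2,
                     mean_degree: float = 25.0,
                     distance_bands=DEFAULT_STN_BANDS,
                     seed: int = 0) -> sp.csr_matrix:
    """Sparse intra-STN wiring: isolated majority, interconnected hub minority.

    ``hub_fraction`` of the neurons are selected as hubs; undirected edges
    between hubs are drawn until the mean total hub degree reaches
    ``mean_degree``, with partner choice weighted by ring-distance band.
    All other neurons stay unconnected.
    """
    n_hubs = hub_fraction * n
    if abs(n_hubs - round(n_hubs)) > 1e-9:
        raise ValueError("hub_fraction * n must be an integer")
    n_hubs = int(round(n_hubs))
    if n_hubs < mean_degree + 1:
        raise ValueError("need more hubs than the requested mean degree")
    rng = np.random.default_rng(seed)
    hubs = np.sort(rng.choice(n, size=n_hubs, replace=False))

    n_edges = int(round(n_hubs * mean_degree / 2.0))
    edges: set[tuple[int, int]] = set()
    while len(edges) < n_edges:
        i = hubs[rng.integers(n_hubs)]
        others = hubs[hubs != i]
        dist = _ring_distance(i, others, n)
        w = np.zeros(others.size)
        for lo, hi, weight in distance_bands:
            mask = dist > lo if hi is None else (dist > lo) & (dist <= hi)
            if mask.any():
                w[mask] += weight / mask.sum()
        if w.sum() == 0:
            continue
        j = rng.choice(others, p=w / w.sum())
        edge = (min(i, j), max(i, j))
        if edge[0] != edge[1]:
            edges.add(edge)

    if edges:
        rows, cols = np.array(sorted(edges)).T
    else:
        rows = cols = np.empty(0, dtype=int)
    data = np.ones(rows.size, dtype=np.int8)
    a = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    a = a + a.T
    return a.tocsr().astype(np.int8)


def _identity_projection(n: int) -> sp.csr_matrix:
    return sp.identity(n, dtype=np.int8, format="csr")


def _gpe_to_gpi(n: int, n_local: int, n_remote: int, seed: int) -> sp.csr_matrix:
    """Each GPe neuron contacts its ring-local GPi counterparts plus a few
    uniformly chosen remote GPi targets (small-world-like divergence)."""
    rng = np.random.default_rng(seed)
    half = n_local // 2
    rows, cols = [], []
    offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    for j in range(n):  # presynaptic GPe index j
        local = (j + offsets) % n
        candidates = np.setdiff1d(np.arange(n), np.append(local, j))
        remote = rng.choice(candidates, size=n_remote, replace=False)
        targets = np.concatenate([local, remote])
        rows.extend(targets)
        cols.extend([j] * targets.size)
    data = np.ones(len(rows), dtype=np.int8)
    return sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def _gpi_to_tha(n_gpi: int, n_tha: int, pool_size: int, afferents: int,
                seed: int) -> sp.csr_matrix:
    rng = np.random.default_rng(seed)
    pool = rng.choice(n_gpi, size=pool_size, replace=False)
    rows, cols = [], []
    for i in range(n_tha):
        pre = rng.choice(pool, size=afferents, replace=False)
        rows.extend([i] * afferents)
        cols.extend(pre)
    data = np.ones(len(rows), dtype=np.int8)
    return sp.coo_matrix((data, (rows, cols)), shape=(n_tha, n_gpi)).tocsr()


@dataclass
class NetworkTopology:
    """All projection adjacencies plus conductances and reversal potentials."""

    adjacency: dict[str, sp.csr_matrix]
    conductances: dict[str, float] = field(default_factory=lambda: dict(CONDUCTANCES))
    e_glu: float = E_GLU
    e_gaba: float = E_GABA
    seed: int = 0
    stn_variant: str = "sparse"

    @property
    def sizes(self) -> dict[str, int]:
        return dict(_POP_SIZES)

    @property
    def n_neurons(self) -> int:
        return sum(_POP_SIZES.values())

    def reversal(self, projection: str) -> float:
        return self.e_glu if projection in EXCITATORY else self.e_gaba

    def to_edge_list(self) -> pd.DataFrame:
        """Sparse edge list (projection, pre_index, post_index), 0-based."""
        frames = []
        for proj in PROJECTIONS:
            coo = self.adjacency[proj].tocoo()
            frames.append(pd.DataFrame({
                "projection": proj,
                "pre_index": coo.col,
                "post_index": coo.row,
            }))
        df = pd.concat(frames, ignore_index=True)
        return df.sort_values(["projection", "pre_index", "post_index"],
                              ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_edge_list().to_csv(path, index=False)

    @classmethod
    def from_edge_list(cls, df: pd.DataFrame, seed: int = 0,
                       stn_variant: str = "sparse") -> "NetworkTopology":
        adj = {}
        for proj in PROJECTIONS:
            pre_pop, post_pop = proj.split("->")
            shape = (_POP_SIZES[post_pop], _POP_SIZES[pre_pop])
            sub = df[df["projection"] == proj]
            data = np.ones(len(sub), dtype=np.int8)
            adj[proj] = sp.coo_matrix(
                (data, (sub["post_index"].to_numpy(), sub["pre_index"].to_numpy())),
                shape=shape).tocsr()
        return cls(adjacency=adj, seed=seed, stn_variant=stn_variant)

    @classmethod
    def load_csv(cls, path, **kwargs) -> "NetworkTopology":
        return cls.from_edge_list(pd.read_csv(path), **kwargs)


def build_full_network(seed: int = 0, stn_variant: str = "sparse",
                       conductances: dict | None = None) -> NetworkTopology:
    """Assemble all seven projections of the 1700-neuron network.

    ``stn_variant`` selects sparse (hub-based, default) or dense
    (small-world, k=20) intra-STN wiring.
    """
    if stn_variant not in ("sparse", "dense"):
        raise ValueError("stn_variant must be 'sparse' or 'dense'")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(5)]

    if stn_variant == "sparse":
        intra_stn = build_sparse_stn(N_STN, seed=seeds[0])
    else:
        intra_stn = build_ws_ring(N_STN, 20, 0.005, seed=seeds[0])

    adj = {
        "STN->STN": intra_stn,
        "GPe->GPe": build_ws_ring(N_GPE, 20, 0.005, seed=seeds[1]),
        "GPi->GPi": build_ws_ring(N_GPI, 20, 0.005, seed=seeds[2]),
        "GPe->STN": _identity_projection(N_STN),
        "STN->GPe": _identity_projection(N_STN),
        "STN->GPi": _identity_projection(N_STN),
        "GPe->GPi": _gpe_to_gpi(N_GPI, n_local=18, n_remote=2, seed=seeds[3]),
        "GPi->THA": _gpi_to_tha(N_GPI, N_THA, pool_size=200, afferents=3,
                                seed=seeds[4]),
    }
    cond = dict(CONDUCTANCES)
    if conductances:
        cond.update(conductances)
    return NetworkTopology(adjacency=adj, conductances=cond, seed=seed,
                           stn_variant=stn_variant)


def connection_census(topology: NetworkTopology) -> pd.DataFrame:
    """Per-projection synapse counts and degree summaries."""
    rows = []
    for proj in PROJECTIONS:
        a = topology.adjacency[proj]
        in_deg = np.asarray(a.sum(axis=1)).ravel()   # afferents per post neuron
        out_deg = np.asarray(a.sum(axis=0)).ravel()  # efferents per pre neuron
        rows.append({
            "projection": proj,
            "n_synapses": int(a.nnz),
            "mean_in_degree": float(in_deg.mean()),
            "mean_out_degree": float(out_deg.mean()),
            "max_in_degree": int(in_deg.max(initial=0)),
            "isolated_pre": int((out_deg == 0).sum()),
        })
    df = pd.DataFrame(rows).set_index("projection")
    df.loc["TOTAL"] = [int(df["n_synapses"].sum()), np.nan, np.nan, np.nan, np.nan]
    return df
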