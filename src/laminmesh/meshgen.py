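"""Scale-free lamin meshwork generation.

Pipeline (mirroring how cryo-ET-matched meshwork models are built):

1. grow a preferential-attachment (Barabasi-Albert) seed graph;
2. reshape its degree distribution toward a truncated power law
   P(k) ~ k^-lambda on [k_min, k_max] by a long Monte-Carlo rewiring run
   (random edge additions/deletions, Metropolis acceptance on the
   Kullback-Leibler divergence to the target distribution);
3. scatter the nodes uniformly in a 2D box (the membrane plane) and run a
   second Monte Carlo over node coordinates until filament (edge) lengths
   average 12 +- 3 nm;
4. discretize every filament into beads at 1 nm spacing for the bead-spring
   simulator.

Graphs stay simple (no self loops, no parallel edges) and connected at every
accepted rewiring move; node degrees are confined to [1, k_max] during
rewiring and raised to >= k_min by a final repair pass.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from numba import njit

logger = logging.getLogger("laminmesh")

__all__ = [
    "MeshGraph",
    "MeshGeometry",
    "BeadModel",
    "build_seed_network",
    "rewire_to_power_law",
    "place_nodes",
    "relax_edge_lengths",
    "discretize",
    "default_box",
    "truncated_power_law_pmf",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class MeshGraph:
    """Undirected junction graph of a lamin meshwork.

    Nodes are 0..n_nodes-1; ``edges`` is an (E, 2) int array of unordered
    pairs (each stored once, i < j).  Edges are the filaments.
    """

    n_nodes: int
    edges: np.ndarray
    lambda_target: float | None = None
    seed: int | None = None
    rewire_divergence: np.ndarray | None = None  # KL at checkpoints

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        e = np.sort(e, axis=1)
        if e.size and (e[:, 0] == e[:, 1]).any():
            raise ValueError("self-loop in edge list")
        if e.size:
            uniq = np.unique(e, axis=0)
            if len(uniq) != len(e):
                raise ValueError("duplicate edge in edge list")
            e = uniq
        self.edges = e

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(d, self.edges.ravel(), 1)
        return d

    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n_nodes

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def is_connected(self) -> bool:
        return self.n_nodes <= 1 or nx.is_connected(self.to_networkx())

    # ---- IO ----
    def write_edgelist_tsv(self, path) -> None:
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t",
                   header="i\tj", comments="")

    def write_graphml(self, path, coords: np.ndarray | None = None) -> None:
        g = self.to_networkx()
        if coords is not None:
            for i in range(self.n_nodes):
                g.nodes[i]["x_nm"] = float(coords[i, 0])
                g.nodes[i]["y_nm"] = float(coords[i, 1])
        nx.write_graphml(g, path)


@dataclass
class MeshGeometry:
    """A MeshGraph with per-node 2D coordinates (nm) in a rectangular box."""

    graph: MeshGraph
    coords: np.ndarray          # (n_nodes, 2) nm
    box: tuple[float, float]    # (Lx, Ly) nm

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.coords.shape[0] != self.graph.n_nodes:
            raise ValueError("coordinate count != node count")
        if np.any(self.coords < 0) or np.any(self.coords > np.asarray(self.box)):
            raise ValueError("coordinates outside box")

    def edge_lengths(self) -> np.ndarray:
        e = self.graph.edges
        if len(e) == 0:
            return np.zeros(0)
        d = self.coords[e[:, 0]] - self.coords[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def write_coords_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "id": np.arange(self.graph.n_nodes),
            "x_nm": self.coords[:, 0],
            "y_nm": self.coords[:, 1],
        }).to_csv(path, sep="\t", index=False)


@dataclass
class BeadModel:
    """Bead-spring discretization of a meshwork geometry.

    positions are nm (3D; z constant until simulated); bonds share junction
    beads between filaments; triplets are the consecutive bead triples used
    for bending, centered on every interior bead of every edge.
    """

    positions: np.ndarray                 # (n_beads, 3) nm
    bonds: np.ndarray                     # (B, 2) int
    rest_length: float                    # nm, common to all bonds
    triplets: np.ndarray                  # (T, 3) int
    node_map: np.ndarray                  # (n_nodes,) junction bead ids
    edge_beads: list = field(default_factory=list)  # per mesh edge: bead ids along it
    broken: np.ndarray | None = None      # (B,) bool

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.triplets = np.asarray(self.triplets, dtype=np.int64).reshape(-1, 3)
        if self.broken is None:
            self.broken = np.zeros(len(self.bonds), dtype=bool)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def to_json(self, path=None) -> str:
        d = {
            "positions_nm": self.positions.tolist(),
            "bonds": self.bonds.tolist(),
            "rest_length_nm": self.rest_length,
            "triplets": self.triplets.tolist(),
            "node_map": np.asarray(self.node_map).tolist(),
            "edge_beads": [np.asarray(e).tolist() for e in self.edge_beads],
            "broken": np.asarray(self.broken).astype(int).tolist(),
        }
        s = json.dumps(d)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, src) -> "BeadModel":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(
            positions=np.asarray(d["positions_nm"], dtype=float),
            bonds=np.asarray(d["bonds"], dtype=np.int64),
            rest_length=float(d["rest_length_nm"]),
            triplets=np.asarray(d["triplets"], dtype=np.int64),
            node_map=np.asarray(d["node_map"], dtype=np.int64),
            edge_beads=[np.asarray(e, dtype=np.int64) for e in d["edge_beads"]],
            broken=np.asarray(d["broken"], dtype=bool),
        )

    def write_csv(self, prefix) -> None:
        import pandas as pd
        pd.DataFrame(self.positions, columns=["x_nm", "y_nm", "z_nm"]) \
            .rename_axis("bead_id").to_csv(f"{prefix}_beads.csv")
        pd.DataFrame({"i": self.bonds[:, 0], "j": self.bonds[:, 1],
                      "rest_length_nm": self.rest_length}) \
            .to_csv(f"{prefix}_bonds.csv", index=False)
        pd.DataFrame(self.triplets, columns=["a", "b", "c"]) \
            .to_csv(f"{prefix}_triplets.csv", index=False)


# --------------------------------------------------------------------------
# seed network
# --------------------------------------------------------------------------

def build_seed_network(n_nodes: int, m: int = 2, seed: int | None = None) -> MeshGraph:
    """Grow a preferential-attachment graph (complete seed on m+1 nodes).

    Each new node attaches to ``m`` distinct existing nodes with probability
    proportional to their current degree, giving the classic heavy-tailed
    degree distribution with exponent near 3.
    """
    if m < 1 or n_nodes <= m:
        raise ValueError("require n_nodes > m >= 1")
    rng = np.random.default_rng(seed)
    edges = [(i, j) for i in range(m + 1) for j in range(i + 1, m + 1)]
    # repeated-targets list: node id appears once per unit of degree
    targets = [v for e in edges for v in e]
    for new in range(m + 1, n_nodes):
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(targets[rng.integers(len(targets))])
        for v in chosen:
            edges.append((v, new))
            targets.extend((v, new))
    return MeshGraph(n_nodes=n_nodes, edges=np.array(edges), seed=seed)


# --------------------------------------------------------------------------
# degree rewiring Monte Carlo
# --------------------------------------------------------------------------

def truncated_power_law_pmf(lam: float, k_min: int, k_max: int) -> np.ndarray:
    """P(k) ~ k^-lam normalized on [k_min, k_max]; index 0..k_max (zeros below k_min)."""
    k = np.arange(k_max + 1, dtype=float)
    p = np.zeros(k_max + 1)
    kk = np.arange(k_min, k_max + 1, dtype=float)
    w = kk ** (-lam)
    p[k_min:] = w / w.sum()
    return p


@njit(cache=True)
def _kl_bin(count, n, logp):
    if count == 0:
        return 0.0
    q = count / n
    return q * (np.log(q) - logp)


@njit(cache=True)
def _dkl_degree_change(hist, n, logp, da, da2, db, db2):
    """KL change when node degrees move da->da2 and db->db2."""
    bins = np.empty(4, dtype=np.int64)
    bins[0], bins[1], bins[2], bins[3] = da, da2, db, db2
    delta = np.zeros(4, dtype=np.int64)
    # accumulate deltas on distinct bins
    for val, d in ((da, -1), (da2, 1), (db, -1), (db2, 1)):
        for t in range(4):
            if bins[t] == val:
                delta[t] += d
                break
    dkl = 0.0
    for t in range(4):
        b = bins[t]
        seen = False
        for s in range(t):
            if bins[s] == b:
                seen = True
                break
        if seen or delta[t] == 0:
            continue
        dkl += _kl_bin(hist[b] + delta[t], n, logp[b]) - _kl_bin(hist[b], n, logp[b])
    return dkl


@njit(cache=True)
def _connected_after_removal(adj, deg, u, w, visited, stamp, queue):
    """BFS from u looking for w, with edge (u,w) already removed."""
    visited[u] = stamp
    queue[0] = u
    head, tail = 0, 1
    while head < tail:
        x = queue[head]
        head += 1
        for ii in range(deg[x]):
            y = adj[x, ii]
            if y == w:
                return True
            if visited[y] != stamp:
                visited[y] = stamp
                queue[tail] = y
                tail += 1
    return False


@njit(cache=True)
def _rewire_kernel(adj, deg, n_iter, logp, k_cap_hist, k_max, t_start, t_end,
                   seed, checkpoints):
    """Metropolis rewiring of the degree distribution toward logp.

    adj: (N, cap) adjacency lists; deg: degrees.  Moves: pick a random node;
    with prob 1/2 add an edge to a random non-neighbor, else delete a random
    incident edge.  Moves that disconnect the graph, create degree 0, exceed
    k_max, or overflow storage are rejected.  Acceptance: always if the KL
    divergence to the target decreases, else exp(-dKL/T), with T decaying
    geometrically from t_start to t_end over the run.
    """
    np.random.seed(seed)
    t_ratio = np.log(t_end / t_start)
    n = adj.shape[0]
    cap = adj.shape[1]
    hist = np.zeros(k_cap_hist + 1, dtype=np.int64)
    for i in range(n):
        hist[deg[i]] += 1
    # current KL
    kl = 0.0
    for k in range(k_cap_hist + 1):
        kl += _kl_bin(hist[k], n, logp[k])
    visited = np.zeros(n, dtype=np.int64)
    queue = np.empty(n, dtype=np.int64)
    stamp = 0
    n_check = checkpoints.shape[0]
    check_every = max(1, n_iter // max(1, n_check))
    ci = 0
    temperature = t_start
    for it in range(n_iter):
        if (it & 1023) == 0:
            temperature = t_start * np.exp(t_ratio * it / n_iter)
        u = np.random.randint(n)
        if np.random.random() < 0.5:
            # --- add edge u-v ---
            if deg[u] >= k_max or deg[u] + 1 >= cap:
                continue
            v = np.random.randint(n)
            if v == u or deg[v] >= k_max or deg[v] + 1 >= cap:
                continue
            dup = False
            for ii in range(deg[u]):
                if adj[u, ii] == v:
                    dup = True
                    break
            if dup:
                continue
            du, dv = deg[u], deg[v]
            dkl = _dkl_degree_change(hist, n, logp, du, du + 1, dv, dv + 1)
            if dkl <= 0.0 or np.random.random() < np.exp(-dkl / temperature):
                adj[u, deg[u]] = v
                adj[v, deg[v]] = u
                hist[du] -= 1
                hist[dv] -= 1
                deg[u] += 1
                deg[v] += 1
                hist[deg[u]] += 1
                hist[deg[v]] += 1
                kl += dkl
        else:
            # --- delete a random incident edge ---
            if deg[u] <= 1:
                continue
            ii = np.random.randint(deg[u])
            w = adj[u, ii]
            if deg[w] <= 1:
                continue
            du, dw = deg[u], deg[w]
            dkl = _dkl_degree_change(hist, n, logp, du, du - 1, dw, dw - 1)
            if dkl > 0.0 and np.random.random() >= np.exp(-dkl / temperature):
                continue
            # tentatively remove
            deg[u] -= 1
            adj[u, ii] = adj[u, deg[u]]
            jj = 0
            for t in range(deg[w]):
                if adj[w, t] == u:
                    jj = t
                    break
            deg[w] -= 1
            adj[w, jj] = adj[w, deg[w]]
            stamp += 1
            if not _connected_after_removal(adj, deg, u, w, visited, stamp, queue):
                # revert
                adj[u, deg[u]] = w
                deg[u] += 1
                adj[w, deg[w]] = u
                deg[w] += 1
                continue
            hist[du] -= 1
            hist[dw] -= 1
            hist[du - 1] += 1
            hist[dw - 1] += 1
            kl += dkl
        if (it + 1) % check_every == 0 and ci < n_check:
            checkpoints[ci] = kl
            ci += 1
    # recompute exact KL (guard against drift)
    kl = 0.0
    for k in range(k_cap_hist + 1):
        kl += _kl_bin(hist[k], n, logp[k])
    while ci < n_check:
        checkpoints[ci] = kl
        ci += 1
    return kl


_EPS_LOGP = np.log(1e-8)


def _adjacency_arrays(g: MeshGraph, cap: int):
    deg = g.degrees()
    cap = max(cap, int(deg.max()) + 2)
    adj = np.full((g.n_nodes, cap), -1, dtype=np.int64)
    fill = np.zeros(g.n_nodes, dtype=np.int64)
    for i, j in g.edges:
        adj[i, fill[i]] = j
        fill[i] += 1
        adj[j, fill[j]] = i
        fill[j] += 1
    return adj, deg.astype(np.int64)


def _edges_from_adjacency(adj, deg) -> np.ndarray:
    out = []
    for i in range(adj.shape[0]):
        for t in range(deg[i]):
            j = adj[i, t]
            if i < j:
                out.append((i, j))
    return np.array(out, dtype=np.int64) if out else np.zeros((0, 2), dtype=np.int64)


def rewire_to_power_law(
    g: MeshGraph,
    lambda_target: float,
    n_iter: int = 1_000_000,
    k_min: int = 3,
    k_max: int = 17,
    temperature: float | tuple[float, float] = (1e-3, 1e-6),
    seed: int | None = None,
    n_checkpoints: int = 10,
    kl_warn: float = 0.1,
) -> MeshGraph:
    """Monte-Carlo rewiring toward P(k) ~ k^-lambda_target on [k_min, k_max].

    Repeatedly selects a random node and changes its connectivity (adds or
    deletes one edge); changes are the more likely to be retained the closer
    they bring the empirical degree distribution to the target (Metropolis on
    the KL divergence, with the fictive temperature annealed geometrically
    from ``temperature[0]`` to ``temperature[1]`` so that the sparse tail of
    the distribution can settle; a scalar gives a fixed temperature).  Moves
    that would
    disconnect the graph are rejected, never raised.  Degrees outside
    [k_min, k_max] carry a tiny target probability, so the distribution is
    driven into the band; a final repair pass lifts any remaining node with
    degree < k_min.
    """
    if lambda_target <= 0:
        raise ValueError("lambda_target must be > 0")
    if k_min < 1 or k_max <= k_min:
        raise ValueError("require 1 <= k_min < k_max")
    if n_iter == 0:
        return MeshGraph(g.n_nodes, g.edges.copy(), lambda_target=lambda_target,
                         seed=seed, rewire_divergence=None)
    rng = np.random.default_rng(seed)
    adj, deg = _adjacency_arrays(g, cap=max(k_max + 2, 2))
    k_cap_hist = adj.shape[1]
    pmf = truncated_power_law_pmf(lambda_target, k_min, k_max)
    logp = np.full(k_cap_hist + 1, _EPS_LOGP)
    nz = pmf > 0
    logp[: k_max + 1][nz] = np.log(pmf[nz])
    checkpoints = np.zeros(n_checkpoints, dtype=np.float64)
    if np.isscalar(temperature):
        t_start = t_end = float(temperature)
    else:
        t_start, t_end = map(float, temperature)
    kl = _rewire_kernel(adj, deg, int(n_iter), logp, k_cap_hist, k_max,
                        t_start, t_end, int(rng.integers(2**31 - 1)), checkpoints)
    # repair: raise nodes below k_min into the band
    low = np.flatnonzero(deg < k_min)
    guard = 0
    while len(low) and guard < 10 * g.n_nodes:
        u = int(low[0])
        order = rng.permutation(g.n_nodes)
        for v in order:
            v = int(v)
            if v == u or deg[v] >= k_max or deg[v] + 1 >= adj.shape[1]:
                continue
            if np.any(adj[u, : deg[u]] == v):
                continue
            adj[u, deg[u]] = v
            adj[v, deg[v]] = u
            deg[u] += 1
            deg[v] += 1
            break
        low = np.flatnonzero(deg < k_min)
        guard += 1
    if kl > kl_warn:
        warnings.warn(
            f"rewiring ended with KL divergence {kl:.3f} > {kl_warn} "
            f"(target lambda={lambda_target}); distribution may be off-target"
        )
    out = MeshGraph(g.n_nodes, _edges_from_adjacency(adj, deg),
                    lambda_target=lambda_target, seed=seed,
                    rewire_divergence=checkpoints)
    return out


# --------------------------------------------------------------------------
# coordinates
# --------------------------------------------------------------------------

def default_box(n_nodes: int, mean_length: float = 12.0) -> tuple[float, float]:
    """Square box whose area is n_nodes * mean_length^2 (nm)."""
    side = float(np.sqrt(n_nodes) * mean_length)
    return (side, side)


def place_nodes(g: MeshGraph, box: tuple[float, float] | None = None,
                seed: int | None = None) -> MeshGeometry:
    """Assign uniform-random 2D coordinates in the box; topology unchanged."""
    if box is None:
        box = default_box(g.n_nodes)
    if box[0] <= 0 or box[1] <= 0:
        raise ValueError("box dimensions must be positive")
    rng = np.random.default_rng(seed)
    coords = rng.random((g.n_nodes, 2)) * np.asarray(box)
    return MeshGeometry(graph=g, coords=coords, box=tuple(box))


@njit(cache=True)
def _coord_mc_kernel(coords, edges, eptr, eidx, box_x, box_y,
                     L_mean, L_sd, w_sd, step_sd, n_iter, seed):
    """Greedy node-move Monte Carlo on cost (mean_L - Lm)^2 + w*(sd_L - Ls)^2.

    eptr/eidx: CSR of incident edge ids per node.  Maintains running sum and
    sum of squares of edge lengths for O(deg) cost updates.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    ne = edges.shape[0]
    if ne == 0 or n_iter == 0:
        return 0.0
    lengths = np.empty(ne)
    sumL = 0.0
    sumL2 = 0.0
    for e in range(ne):
        dx = coords[edges[e, 0], 0] - coords[edges[e, 1], 0]
        dy = coords[edges[e, 0], 1] - coords[edges[e, 1], 1]
        L = np.sqrt(dx * dx + dy * dy)
        lengths[e] = L
        sumL += L
        sumL2 += L * L

    def cost(sL, sL2):
        m = sL / ne
        var = sL2 / ne - m * m
        if var < 0.0:
            var = 0.0
        sd = np.sqrt(var)
        return (m - L_mean) ** 2 + w_sd * (sd - L_sd) ** 2

    c = cost(sumL, sumL2)
    newlen = np.empty(64)
    for _ in range(n_iter):
        u = np.random.randint(n)
        ndeg = eptr[u + 1] - eptr[u]
        if ndeg == 0:
            continue
        nx_ = coords[u, 0] + np.random.normal() * step_sd
        ny_ = coords[u, 1] + np.random.normal() * step_sd
        if nx_ < 0.0 or nx_ > box_x or ny_ < 0.0 or ny_ > box_y:
            continue
        if ndeg > newlen.shape[0]:
            newlen = np.empty(ndeg)
        sL, sL2 = sumL, sumL2
        for t in range(ndeg):
            e = eidx[eptr[u] + t]
            v = edges[e, 0] if edges[e, 1] == u else edges[e, 1]
            dx = nx_ - coords[v, 0]
            dy = ny_ - coords[v, 1]
            L = np.sqrt(dx * dx + dy * dy)
            newlen[t] = L
            sL += L - lengths[e]
            sL2 += L * L - lengths[e] * lengths[e]
        cn = cost(sL, sL2)
        if cn < c:
            coords[u, 0] = nx_
            coords[u, 1] = ny_
            for t in range(ndeg):
                e = eidx[eptr[u] + t]
                lengths[e] = newlen[t]
            sumL, sumL2 = sL, sL2
            c = cn
    return c


def relax_edge_lengths(
    geom: MeshGeometry,
    L_mean: float = 12.0,
    L_sd: float = 3.0,
    n_iter: int = 600_000,
    w_sd: float = 1.0,
    step_sd: float = 1.0,
    seed: int | None = None,
) -> MeshGeometry:
    """Coordinate Monte Carlo driving edge lengths to mean 12 +- 3 nm.

    Single-node Gaussian moves (1 nm), accepted greedily when they lower the
    cost (mean_L - L_mean)^2 + w_sd*(sd_L - L_sd)^2.  Best-effort: warns (does
    not raise) if the mean is still off target after the budget.
    """
    g = geom.graph
    coords = geom.coords.copy()
    edges = g.edges
    # CSR of incident edges
    deg = np.zeros(g.n_nodes, dtype=np.int64)
    if len(edges):
        np.add.at(deg, edges.ravel(), 1)
    eptr = np.zeros(g.n_nodes + 1, dtype=np.int64)
    np.cumsum(deg, out=eptr[1:])
    eidx = np.zeros(max(1, int(eptr[-1])), dtype=np.int64)
    fill = eptr[:-1].copy()
    for e, (i, j) in enumerate(edges):
        eidx[fill[i]] = e
        fill[i] += 1
        eidx[fill[j]] = e
        fill[j] += 1
    rng = np.random.default_rng(seed)
    if n_iter > 0 and len(edges):
        _coord_mc_kernel(coords, edges, eptr, eidx,
                         float(geom.box[0]), float(geom.box[1]),
                         float(L_mean), float(L_sd), float(w_sd),
                         float(step_sd), int(n_iter),
                         int(rng.integers(2**31 - 1)))
    out = MeshGeometry(graph=g, coords=coords, box=geom.box)
    if len(edges):
        m = float(out.edge_lengths().mean())
        sd = float(out.edge_lengths().std())
        logger.info("coordinate MC: mean edge length %.2f nm (sd %.2f nm)", m, sd)
        if abs(m - L_mean) > L_sd:
            warnings.warn(
                f"coordinate MC did not reach target: mean edge length "
                f"{m:.2f} nm vs {L_mean} +- {L_sd} nm"
            )
    return out


# --------------------------------------------------------------------------
# bead discretization
# --------------------------------------------------------------------------

def discretize(geom: MeshGeometry, spacing: float = 1.0,
               z0: float = 1.5) -> BeadModel:
    """Bead-spring discretization at ~1 nm spacing.

    Each edge of length L carries round(L/spacing)+1 beads including the two
    shared junction beads; bond rest length is ``spacing`` (1 nm) regardless
    of the initial geometric spacing, per the mesoscopic model definition.
    Beads start at constant height ``z0`` (nm) above the substrate plane.
    Edges shorter than the spacing get a single bond with a warning.
    """
    g = geom.graph
    n = g.n_nodes
    pos = [np.column_stack([geom.coords, np.full(n, float(z0))])] if n else []
    node_map = np.arange(n, dtype=np.int64)
    bonds: list[tuple[int, int]] = []
    triplets: list[tuple[int, int, int]] = []
    edge_beads: list[np.ndarray] = []
    next_id = n
    short = 0
    lengths = geom.edge_lengths()
    for e, (i, j) in enumerate(g.edges):
        L = lengths[e]
        nseg = int(round(L / spacing))
        if nseg < 1:
            nseg = 1
            short += 1
        chain = [int(node_map[i])]
        if nseg > 1:
            t = np.arange(1, nseg)[:, None] / nseg
            inter = (1 - t) * geom.coords[i] + t * geom.coords[j]
            inter3 = np.column_stack([inter, np.full(len(inter), float(z0))])
            pos.append(inter3)
            ids = list(range(next_id, next_id + nseg - 1))
            next_id += nseg - 1
            chain.extend(ids)
        chain.append(int(node_map[j]))
        for a, b in zip(chain[:-1], chain[1:]):
            bonds.append((a, b))
        for a, b, c in zip(chain[:-2], chain[1:-1], chain[2:]):
            triplets.append((a, b, c))
        edge_beads.append(np.array(chain, dtype=np.int64))
    if short:
        warnings.warn(f"{short} edge(s) shorter than bead spacing; "
                      "represented by a single bond")
    positions = np.vstack(pos) if pos else np.zeros((0, 3))
    return BeadModel(
        positions=positions,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        rest_length=float(spacing),
        triplets=np.array(triplets, dtype=np.int64).reshape(-1, 3),
        node_map=node_map,
        edge_beads=edge_beads,
    )
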