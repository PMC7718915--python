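"""Graph-theoretic analysis of lamin meshworks.

Converts rendered filament skeletons (3D polylines) into an undirected graph
whose vertices are filament crossovers (points of different filaments closer
than a merge distance, 1.3 nm by default) and whose edges are the filament
stretches between them, then computes the topology observables used to
characterize the lamina: mean degree 2|E|/|N|, the degree histogram, the
power-law exponent of P(k) ~ k^-lambda (discrete maximum likelihood on a
truncated support, with a log-log least-squares fit reported alongside), the
hub census, and the small-world scaling of mean shortest-path length with
meshwork size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .meshgen import MeshGraph

logger = logging.getLogger("laminmesh")

__all__ = [
    "FilamentSegmentSet",
    "TopologyMetrics",
    "PowerLawFit",
    "segments_to_graph",
    "degree_stats",
    "fit_power_law",
    "path_length_scaling",
]


@dataclass
class FilamentSegmentSet:
    """A set of 3D filament polylines (ordered points, nm)."""

    polylines: list  # list of (m_i, 3) float arrays
    label: str | None = None

    def __post_init__(self):
        pls = []
        for p in self.polylines:
            p = np.asarray(p, dtype=float).reshape(-1, 3)
            if len(p) < 2:
                raise ValueError("each polyline needs >= 2 points")
            if not np.isfinite(p).all():
                raise ValueError("non-finite coordinates in polyline")
            pls.append(p)
        self.polylines = pls

    def __len__(self):
        return len(self.polylines)

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = []
        for sid, p in enumerate(self.polylines):
            for k, (x, y, z) in enumerate(p):
                rows.append((sid, k, x, y, z))
        pd.DataFrame(rows, columns=["segment_id", "point_index",
                                    "x_nm", "y_nm", "z_nm"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FilamentSegmentSet":
        import pandas as pd
        df = pd.read_csv(path)
        pls = [g.sort_values("point_index")[["x_nm", "y_nm", "z_nm"]].to_numpy()
               for _, g in df.groupby("segment_id")]
        return cls(polylines=pls)


@dataclass
class PowerLawFit:
    exponent: float            # discrete MLE
    exponent_ls: float         # log-log least squares, for comparison
    k_min: int
    k_max: int
    n_tail: int
    ks_distance: float
    degenerate: bool = False


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    mean_degree: float
    degree_histogram: dict
    hub_count: int
    power_law: PowerLawFit | None = None
    path_scaling: list = field(default_factory=list)  # (N, mean shortest path)

    def to_json(self, path=None) -> str:
        import json
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "mean_degree": self.mean_degree,
            "degree_histogram": {int(k): int(v) for k, v in self.degree_histogram.items()},
            "hub_count": self.hub_count,
            "power_law": None if self.power_law is None else vars(self.power_law),
            "path_scaling": [[int(n), float(l)] for n, l in self.path_scaling],
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


# --------------------------------------------------------------------------
# skeleton -> graph
# --------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        while self.p[a] != a:
            self.p[a] = self.p[self.p[a]]
            a = self.p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.p[rb] = ra


def segments_to_graph(segs: FilamentSegmentSet, merge_dist: float = 1.3,
                      contract_passthrough: bool = True,
                      min_edge_len: float | None = None) -> tuple[MeshGraph, np.ndarray]:
    """Convert filament polylines into a junction graph.

    Crossover vertices are placed where points of *different* polylines come
    closer than ``merge_dist`` (one candidate per close-approach run of each
    polyline pair, candidates clustered by single linkage), plus free
    polyline endpoints; edges are the filament stretches between consecutive
    vertices along each polyline.  The automatic analogues of the manual
    tomogram cleanup are then applied: links shorter than ``min_edge_len``
    (default 3x merge_dist; far below the filament scale) are contracted,
    pass-through vertices of degree 2 removed, self-loops and duplicate
    edges dropped.

    Returns (graph, node_coords) with node coordinates at cluster centroids.
    """
    if min_edge_len is None:
        min_edge_len = 3.0 * merge_dist
    if len(segs) == 0:
        raise ValueError("empty segment set")
    pts = np.vstack(segs.polylines)
    owner = np.concatenate([np.full(len(p), i) for i, p in enumerate(segs.polylines)])
    offsets = np.cumsum([0] + [len(p) for p in segs.polylines])

    # 1. close-approach runs between polyline pairs -> crossover candidates
    tree = cKDTree(pts)
    close = tree.query_pairs(merge_dist, output_type="ndarray")
    by_pair: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in close:
        sa, sb = int(owner[a]), int(owner[b])
        if sa == sb:
            continue
        ia, ib = int(a - offsets[sa]), int(b - offsets[sb])
        if sa > sb:
            sa, sb, ia, ib = sb, sa, ib, ia
        by_pair.setdefault((sa, sb), []).append((ia, ib))
    # each contiguous run of close indices is one crossover of the pair
    cand_xyz: list[np.ndarray] = []
    cand_hits: list[list[tuple[int, int]]] = []  # (polyline, index) per candidate
    for (sa, sb), idx_pairs in by_pair.items():
        idx_pairs.sort()
        runs: list[list[tuple[int, int]]] = [[idx_pairs[0]]]
        for prev, cur in zip(idx_pairs[:-1], idx_pairs[1:]):
            if cur[0] - prev[0] <= 3:
                runs[-1].append(cur)
            else:
                runs.append([cur])
        for run in runs:
            pa = segs.polylines[sa]
            pb = segs.polylines[sb]
            ii = np.array([i for i, _ in run])
            jj = np.array([j for _, j in run])
            dists = np.linalg.norm(pa[ii] - pb[jj], axis=1)
            # locate the crossover at the minimum of the smoothed distance
            # profile: identical to the raw minimum for clean data, robust
            # to jitter when the profile is flat (small-angle junctions)
            if len(dists) >= 5:
                from scipy.ndimage import uniform_filter1d
                prof = uniform_filter1d(dists, size=min(5, len(dists)),
                                        mode="nearest")
            else:
                prof = dists
            k = int(np.argmin(prof))
            i, j = int(ii[k]), int(jj[k])
            cand_xyz.append(0.5 * (pa[i] + pb[j]))
            cand_hits.append([(sa, i), (sb, j)])

    # 2. single-linkage clustering of crossover candidates -> junction nodes
    coords: list[np.ndarray] = []
    g = nx.MultiGraph()
    hit_marks: dict[int, list[tuple[int, int]]] = {}  # polyline -> (index, node)
    if cand_xyz:
        cxyz = np.asarray(cand_xyz)
        # candidates are noisy estimates of the same crossover; link them a
        # little more generously than the raw point-proximity threshold
        uf = _UnionFind(len(cxyz))
        ctree = cKDTree(cxyz)
        for a, b in ctree.query_pairs(3.0 * merge_dist, output_type="ndarray"):
            uf.union(int(a), int(b))
        root = np.array([uf.find(i) for i in range(len(cxyz))])
        node_of_root: dict[int, int] = {}
        for c, r in enumerate(root):
            if r not in node_of_root:
                nid = len(coords)
                members = np.flatnonzero(root == r)
                coords.append(cxyz[members].mean(axis=0))
                node_of_root[r] = nid
                g.add_node(nid)
            nid = node_of_root[r]
            for sid, idx in cand_hits[c]:
                hit_marks.setdefault(sid, []).append((idx, nid))

    # 3. walk each polyline through its ordered vertices
    for sid, p in enumerate(segs.polylines):
        marks = sorted(set(hit_marks.get(sid, [])))
        chain: list[int] = []
        # free start endpoint unless the first junction sits at/near it
        if not marks or not (marks[0][0] <= 1
                             or np.linalg.norm(p[0] - coords[marks[0][1]]) < merge_dist):
            nid = len(coords)
            coords.append(p[0])
            g.add_node(nid)
            chain.append(nid)
        for _, nid in marks:
            if not chain or chain[-1] != nid:
                chain.append(nid)
        if not marks or not (marks[-1][0] >= len(p) - 2
                             or np.linalg.norm(p[-1] - coords[marks[-1][1]]) < merge_dist):
            nid = len(coords)
            coords.append(p[-1])
            g.add_node(nid)
            chain.append(nid)
        for a, b in zip(chain[:-1], chain[1:]):
            g.add_edge(a, b)

    # contract sub-resolution links (split-junction artifacts)
    coords_arr = {i: np.asarray(c) for i, c in enumerate(coords)}
    changed = True
    while changed:
        changed = False
        for a, b in list(g.edges()):
            if a == b or not g.has_edge(a, b):
                continue
            if np.linalg.norm(coords_arr[a] - coords_arr[b]) < min_edge_len:
                coords_arr[a] = 0.5 * (coords_arr[a] + coords_arr[b])
                g = nx.contracted_nodes(g, a, b, self_loops=False)
                del coords_arr[b]
                changed = True
                break
    coords = coords_arr

    sg = nx.Graph(g)  # drop parallel edges
    sg.remove_edges_from(nx.selfloop_edges(sg))

    if contract_passthrough:
        # a degree-2 vertex is a pass-through point, not a crossover
        changed = True
        while changed:
            changed = False
            for v in list(sg.nodes):
                if sg.degree(v) == 2:
                    a, b = list(sg.neighbors(v))
                    if a != b and not sg.has_edge(a, b):
                        sg.remove_node(v)
                        sg.add_edge(a, b)
                        changed = True

    nodes = sorted(sg.nodes)
    relabel = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(relabel[a], relabel[b]) for a, b in sg.edges],
                     dtype=np.int64).reshape(-1, 2)
    out_coords = np.array([coords[v] for v in nodes]).reshape(-1, 3)
    return MeshGraph(n_nodes=len(nodes), edges=edges), out_coords


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def degree_stats(g: MeshGraph, hub_degree: int = 5) -> TopologyMetrics:
    """Exact degree statistics: mean 2|E|/|N|, histogram, hub census."""
    if g.n_nodes < 1:
        raise ValueError("graph has no nodes")
    deg = g.degrees()
    vals, counts = np.unique(deg, return_counts=True)
    return TopologyMetrics(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        mean_degree=g.mean_degree(),
        degree_histogram=dict(zip(vals.tolist(), counts.tolist())),
        hub_count=int((deg >= hub_degree).sum()),
    )


def fit_power_law(degrees, k_min: int = 3, k_max: int | None = None,
                  min_tail: int = 20) -> PowerLawFit:
    """Discrete power-law exponent of a degree sample.

    Maximum likelihood for P(k) ~ k^-lambda normalized on [k_min, k_max]
    (k_max defaults to the sample maximum); a log-log least-squares slope on
    the binned histogram is reported alongside, since network-analysis GUIs
    typically fit that way.  Raises on fewer than ``min_tail`` tail samples;
    flags degenerate fits (boundary solutions / single support point).
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    tail = degrees[degrees >= k_min]
    if k_max is None:
        k_max = int(tail.max()) if len(tail) else k_min + 1
    tail = tail[tail <= k_max]
    if len(tail) < min_tail:
        raise ValueError(f"need >= {min_tail} samples with degree >= {k_min}")
    ks = np.arange(k_min, k_max + 1, dtype=float)
    slk = float(np.log(tail).sum())
    n = len(tail)

    def nll(lam):
        return lam * slk + n * np.log(np.sum(ks ** (-lam)))

    res = minimize_scalar(nll, bounds=(0.01, 50.0), method="bounded")
    lam = float(res.x)
    degenerate = lam > 49.0 or lam < 0.02 or len(np.unique(tail)) < 2

    # LS on log-log histogram
    vals, counts = np.unique(tail, return_counts=True)
    if len(vals) >= 2:
        slope, _ = np.polyfit(np.log(vals.astype(float)), np.log(counts.astype(float)), 1)
        lam_ls = float(-slope)
    else:
        lam_ls = float("nan")

    # KS distance between empirical and fitted CDF on the support
    p = ks ** (-lam)
    p /= p.sum()
    cdf_fit = np.cumsum(p)
    emp = np.array([(tail <= k).mean() for k in ks])
    ks_d = float(np.abs(emp - cdf_fit).max())

    if degenerate:
        warnings.warn("degenerate power-law fit (boundary exponent or "
                      "single-valued sample)")
    return PowerLawFit(exponent=lam, exponent_ls=lam_ls, k_min=k_min,
                       k_max=int(k_max), n_tail=n, ks_distance=ks_d,
                       degenerate=degenerate)


def sample_truncated_power_law(lam: float, k_min: int, k_max: int, size: int,
                               seed=None) -> np.ndarray:
    """Exact draws from P(k) ~ k^-lam on [k_min, k_max] (testing oracle)."""
    rng = np.random.default_rng(seed)
    ks = np.arange(k_min, k_max + 1)
    p = ks.astype(float) ** (-lam)
    p /= p.sum()
    return rng.choice(ks, size=size, p=p)


def path_length_scaling(g: MeshGraph, sizes, reps: int = 20,
                        seed=None) -> list[tuple[int, float]]:
    """Mean shortest-path length of breadth-first-grown subgraphs.

    For each requested size N, grows a connected subgraph by breadth-first
    search from a random start node, truncated at N nodes, and averages the
    subgraph's mean shortest-path length over ``reps`` repetitions.  The
    resulting (N, path length) pairs grow with N for small-world meshworks.
    """
    G = g.to_networkx()
    if g.n_nodes > 1 and not nx.is_connected(G):
        warnings.warn("graph is disconnected; using largest connected component")
        G = G.subgraph(max(nx.connected_components(G), key=len)).copy()
    rng = np.random.default_rng(seed)
    nodes = list(G.nodes)
    out = []
    for N in sizes:
        if N > len(nodes):
            raise ValueError(f"subgraph size {N} exceeds graph size {len(nodes)}")
        if N < 2:
            out.append((int(N), 0.0))
            continue
        acc = 0.0
        for _ in range(reps):
            start = nodes[rng.integers(len(nodes))]
            sub = []
            for v in nx.bfs_tree(G, start):
                sub.append(v)
                if len(sub) >= N:
                    break
            H = G.subgraph(sub)
            acc += nx.average_shortest_path_length(H)
        out.append((int(N), acc / reps))
    return out
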