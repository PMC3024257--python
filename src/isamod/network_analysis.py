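"""Interaction-network analysis of recurring module genes.

Subnetwork extraction from an evidence-weighted gene network, random
subnetwork nulls for the total edge evidence, degree / PageRank comparisons
against the rest of the network, hierarchical-random-graph (HRG) fitting via
MCMC over dendrograms, and degree-preserving rewiring nulls for the HRG
likelihood.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


class GeneNetwork:
    """Undirected graph over gene symbols with an ``evidence`` score in
    (0, 1] on every edge; no self-loops or parallel edges."""

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges):
            raise NetworkError("self-loops are not allowed")
        for u, v, data in graph.edges(data=True):
            ev = data.get("evidence", 1.0)
            if not (0 < ev <= 1):
                raise NetworkError(f"evidence score out of (0,1] on edge {u}-{v}")
            data.setdefault("evidence", 1.0)
        self.graph = graph

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple], vertices: Iterable | None = None
    ) -> "GeneNetwork":
        g = nx.Graph()
        if vertices is not None:
            g.add_nodes_from(vertices)
        for edge in edges:
            u, v, *rest = edge
            g.add_edge(u, v, evidence=float(rest[0]) if rest else 1.0)
        return cls(g)

    @property
    def vertices(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, vertex) -> int:
        return self.graph.degree[vertex]

    def largest_component(self) -> "GeneNetwork":
        if self.n_vertices == 0:
            return self
        comp = max(nx.connected_components(self.graph), key=lambda c: (len(c), sorted(c)))
        return GeneNetwork(self.graph.subgraph(comp).copy())


def extract_subnetwork(
    net: GeneNetwork, genes: Iterable, min_evidence: float = 0.0
) -> GeneNetwork:
    """Induced subgraph on ``genes`` keeping edges with evidence strictly
    above ``min_evidence``."""
    if not (0 <= min_evidence <= 1):
        raise NetworkError("min_evidence must be in [0, 1]")
    keep = set(genes) & set(net.graph.nodes)
    if not keep:
        log.warning("extract_subnetwork: no requested gene is in the network")
    sub = net.graph.subgraph(keep).copy()
    drop = [
        (u, v) for u, v, d in sub.edges(data=True) if d["evidence"] <= min_evidence
    ]
    sub.remove_edges_from(drop)
    return GeneNetwork(sub)


def total_evidence(net: GeneNetwork) -> float:
    """Sum of the evidence over all edges."""
    return float(sum(d["evidence"] for *_, d in net.graph.edges(data=True)))


def random_subnetwork_null(
    net: GeneNetwork,
    k: int,
    n_draws: int,
    observed: float,
    rng_seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical p-value of an observed total evidence against ``n_draws``
    uniform k-vertex induced subgraphs: ``(1 + #{null >= observed}) /
    (n_draws + 1)``."""
    if k > net.n_vertices:
        raise NetworkError("k exceeds the number of vertices")
    if n_draws < 1:
        raise NetworkError("n_draws must be >= 1")
    rng = np.random.default_rng(rng_seed)
    vertices = np.array(net.vertices, dtype=object)
    nulls = np.empty(n_draws)
    for i in range(n_draws):
        pick = set(rng.choice(len(vertices), size=k, replace=False))
        chosen = {vertices[j] for j in pick}
        nulls[i] = sum(
            d["evidence"]
            for u, v, d in net.graph.edges(chosen, data=True)
            if u in chosen and v in chosen
        )
    p = (1 + int((nulls >= observed).sum())) / (n_draws + 1)
    return p, nulls


def pagerank(
    net: GeneNetwork, damping: float = 0.85, tol: float = 1e-10, max_iter: int = 10000
) -> dict:
    """PageRank by power iteration on the unweighted adjacency with uniform
    teleportation; isolated vertices receive teleportation mass only.
    Scores sum to 1."""
    if not (0 < damping < 1):
        raise NetworkError("damping must be in (0, 1)")
    nodes = net.vertices
    n = len(nodes)
    if n == 0:
        raise NetworkError("network is empty")
    pos = {v: i for i, v in enumerate(nodes)}
    deg = np.array([net.graph.degree[v] for v in nodes], dtype=float)
    neighbors = [np.array([pos[u] for u in net.graph.neighbors(v)]) for v in nodes]
    x = np.full(n, 1.0 / n)
    dangling = deg == 0
    for _ in range(max_iter):
        spread = np.where(dangling, 0.0, x / np.maximum(deg, 1.0))
        new = np.full(n, (1.0 - damping) / n)
        new += damping * x[dangling].sum() / n
        for i, nbrs in enumerate(neighbors):
            if nbrs.size:
                new[i] += damping * spread[nbrs].sum()
        if np.abs(new - x).sum() < tol:
            x = new
            break
        x = new
    return dict(zip(nodes, x))


def degree_centrality_compare(
    sub: GeneNetwork, full: GeneNetwork, measure: str = "degree"
) -> tuple[float, dict]:
    """Two-sided Wilcoxon rank-sum test comparing the ``measure`` values
    (computed in the FULL network) of the subnetwork vertices against all
    remaining vertices. Exact enumeration is used for small tie-free groups,
    otherwise the tie-corrected normal approximation."""
    sub_vertices = set(sub.graph.nodes)
    if not sub_vertices <= set(full.graph.nodes):
        raise NetworkError("subnetwork vertices must be a subset of the full network")
    rest = [v for v in full.graph.nodes if v not in sub_vertices]
    if not sub_vertices or not rest:
        raise NetworkError("both groups must be non-empty")
    if measure == "degree":
        values = {v: float(full.graph.degree[v]) for v in full.graph.nodes}
    elif measure == "pagerank":
        values = pagerank(full)
    else:
        raise NetworkError(f"unknown measure {measure!r}")
    a = np.array([values[v] for v in sub_vertices])
    b = np.array([values[v] for v in rest])
    if math.comb(len(a) + len(b), len(a)) <= 200_000:
        p = _exact_ranksum_p(a, b)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return p, {"sub": a, "rest": b}


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments
    (tie-safe): 2 * min tail probability of the rank sum, capped at 1."""
    import itertools

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    observed = ranks[:n1].sum()
    lo = hi = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        s = ranks[list(combo)].sum()
        total += 1
        if s <= observed + 1e-9:
            lo += 1
        if s >= observed - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


# ---------------------------------------------------------------------------
# hierarchical random graphs
# ---------------------------------------------------------------------------


def _h(e: int, t: int) -> float:
    # per-node log-likelihood at the MLE p = e/t, with 0 log 0 = 0
    if t == 0 or e == 0 or e == t:
        return 0.0
    p = e / t
    return e * math.log(p) + (t - e) * math.log(1.0 - p)


def _popcount(x: int) -> int:
    return x.bit_count()


class DendrogramModel:
    """Binary dendrogram over the vertices of a graph with per-internal-node
    cross-edge counts. Leaves are indexed by position in ``leaves``; children
    are encoded as ``-(leaf+1)`` for leaves and the node id for internals."""

    def __init__(self, leaves: Sequence, left: list[int], right: list[int], root: int):
        self.leaves = list(leaves)
        self.left = list(left)
        self.right = list(right)
        self.root = root
        n = len(self.leaves)
        if len(self.left) != n - 1:
            raise NetworkError("a dendrogram over n leaves has n-1 internal nodes")
        self.parent = [-1] * (n - 1)
        for i in range(n - 1):
            for child in (self.left[i], self.right[i]):
                if child >= 0:
                    self.parent[child] = i
        self.leafmask = [0] * (n - 1)
        self._fill_masks(self.root)
        self.E = [0] * (n - 1)

    def _fill_masks(self, node: int) -> int:
        if node < 0:
            return 1 << (-node - 1)
        mask = self._fill_masks(self.left[node]) | self._fill_masks(self.right[node])
        self.leafmask[node] = mask
        return mask

    def _child_mask(self, child: int) -> int:
        return 1 << (-child - 1) if child < 0 else self.leafmask[child]

    def compute_edge_counts(self, adj: list[int]) -> None:
        for i in range(len(self.left)):
            self.E[i] = _cross_edges(
                self._child_mask(self.left[i]), self._child_mask(self.right[i]), adj
            )

    def loglik(self) -> float:
        total = 0.0
        for i in range(len(self.left)):
            lm = self._child_mask(self.left[i])
            rm = self._child_mask(self.right[i])
            total += _h(self.E[i], _popcount(lm) * _popcount(rm))
        return total

    def table(self) -> list[tuple[int, int, int, float]]:
        """Per internal node: (left leaves L_r, right leaves R_r, cross edges
        E_r, MLE probability p_r)."""
        rows = []
        for i in range(len(self.left)):
            L = _popcount(self._child_mask(self.left[i]))
            R = _popcount(self._child_mask(self.right[i]))
            t = L * R
            rows.append((L, R, self.E[i], self.E[i] / t if t else 0.0))
        return rows

    def copy(self) -> "DendrogramModel":
        model = DendrogramModel.__new__(DendrogramModel)
        model.leaves = list(self.leaves)
        model.left = list(self.left)
        model.right = list(self.right)
        model.root = self.root
        model.parent = list(self.parent)
        model.leafmask = list(self.leafmask)
        model.E = list(self.E)
        return model


def _cross_edges(mask_a: int, mask_b: int, adj: list[int]) -> int:
    # iterate the smaller side's set bits
    if _popcount(mask_a) > _popcount(mask_b):
        mask_a, mask_b = mask_b, mask_a
    count = 0
    m = mask_a
    while m:
        low = m & -m
        v = low.bit_length() - 1
        count += _popcount(adj[v] & mask_b)
        m ^= low
    return count


def _adjacency_masks(net: GeneNetwork, leaves: Sequence) -> list[int]:
    pos = {v: i for i, v in enumerate(leaves)}
    adj = [0] * len(leaves)
    for u, v in net.graph.edges:
        adj[pos[u]] |= 1 << pos[v]
        adj[pos[v]] |= 1 << pos[u]
    return adj


def random_dendrogram(vertices: Sequence, rng: np.random.Generator) -> DendrogramModel:
    """Uniformly random sequence of pairwise merges over the vertices."""
    items = [-(i + 1) for i in range(len(vertices))]
    left, right = [], []
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        node = len(left)
        left.append(items[i])
        right.append(items[j])
        items[i] = node
        items.pop(j)
    return DendrogramModel(vertices, left, right, items[0])


def hrg_loglik(net: GeneNetwork, model: DendrogramModel) -> float:
    """Log-likelihood of the network under the dendrogram at the MLE
    connection probabilities: sum_r [E_r log p_r + (L_r R_r - E_r)
    log(1 - p_r)] with 0 log 0 = 0."""
    if set(model.leaves) != set(net.graph.nodes):
        raise NetworkError("dendrogram leaf set must equal the vertex set")
    if not nx.is_connected(net.graph):
        raise NetworkError("network must be connected")
    adj = _adjacency_masks(net, model.leaves)
    model.compute_edge_counts(adj)
    return model.loglik()


def fit_hrg(
    net: GeneNetwork, n_steps: int = 50000, rng_seed: int = 0
) -> tuple[DendrogramModel, float]:
    """MCMC over dendrograms with random subtree-exchange moves and
    Metropolis acceptance on the likelihood; returns the best model seen."""
    if net.n_vertices < 3:
        raise NetworkError("need at least 3 vertices to fit a hierarchy")
    if not nx.is_connected(net.graph):
        raise NetworkError("network must be connected (extract a component first)")
    if n_steps < 1:
        raise NetworkError("n_steps must be >= 1")
    rng = np.random.default_rng(rng_seed)
    leaves = net.vertices
    adj = _adjacency_masks(net, leaves)
    model = random_dendrogram(leaves, rng)
    model.compute_edge_counts(adj)
    n_internal = len(model.left)
    h_cache = [0.0] * n_internal
    for i in range(n_internal):
        lm = model._child_mask(model.left[i])
        rm = model._child_mask(model.right[i])
        h_cache[i] = _h(model.E[i], _popcount(lm) * _popcount(rm))
    loglik = sum(h_cache)
    best = model.copy()
    best_loglik = loglik

    internals = [i for i in range(n_internal) if i != model.root]
    for _ in range(n_steps):
        if not internals:
            break
        r = internals[rng.integers(len(internals))]
        p = model.parent[r]
        # sibling of r under p
        if model.left[p] == r:
            s = model.right[p]
        else:
            s = model.left[p]
        a, b = model.left[r], model.right[r]
        swap_a = bool(rng.integers(2))
        keep = b if swap_a else a  # child of r that stays
        out = a if swap_a else b  # child of r moved up next to p
        mask_s = model._child_mask(s)
        mask_keep = model._child_mask(keep)
        mask_out = model._child_mask(out)

        new_mask_r = mask_s | mask_keep
        new_E_r = _cross_edges(mask_s, mask_keep, adj)
        new_E_p = _cross_edges(new_mask_r, mask_out, adj)
        new_h_r = _h(new_E_r, _popcount(mask_s) * _popcount(mask_keep))
        new_h_p = _h(new_E_p, _popcount(new_mask_r) * _popcount(mask_out))
        delta = (new_h_r + new_h_p) - (h_cache[r] + h_cache[p])
        if delta >= 0 or rng.random() < math.exp(delta):
            model.left[r], model.right[r] = s, keep
            # r stays a child of p; the slot that held s now holds `out`
            if model.left[p] == s:
                model.left[p] = out
            else:
                model.right[p] = out
            if s >= 0:
                model.parent[s] = r
            if out >= 0:
                model.parent[out] = p
            model.leafmask[r] = new_mask_r
            model.E[r], model.E[p] = new_E_r, new_E_p
            h_cache[r], h_cache[p] = new_h_r, new_h_p
            loglik += delta
            if loglik > best_loglik + 1e-12:
                best_loglik = loglik
                best = model.copy()
    return best, float(best_loglik)


def rewire_degree_preserving(
    net: GeneNetwork, n_swaps: int, rng_seed: int = 0
) -> GeneNetwork:
    """Degree-preserving randomization by attempted double edge swaps
    (swaps creating self-loops or multi-edges are rejected). The multiset of
    evidence scores is randomly reassigned to the rewired edges."""
    if net.n_edges < 2:
        raise NetworkError("need at least 2 edges to rewire")
    rng = np.random.default_rng(rng_seed)
    edges = [tuple(e) for e in net.graph.edges]
    evidences = [d["evidence"] for *_, d in net.graph.edges(data=True)]
    edge_set = {frozenset(e) for e in edges}
    for _ in range(n_swaps):
        i, j = rng.integers(len(edges)), rng.integers(len(edges))
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.integers(2):
            x, y = y, x
        # propose (u, x) and (v, y)
        if len({u, v, x, y}) < 4:
            continue
        e1, e2 = frozenset((u, x)), frozenset((v, y))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set -= {frozenset((u, v)), frozenset((x, y))}
        edge_set |= {e1, e2}
        edges[i] = (u, x)
        edges[j] = (v, y)
    rng.shuffle(evidences)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for (u, v), ev in zip(edges, evidences):
        g.add_edge(u, v, evidence=ev)
    return GeneNetwork(g)


def hierarchy_significance(
    net: GeneNetwork,
    n_random: int = 1000,
    n_steps: int = 50000,
    rng_seed: int = 0,
    swaps_per_edge: int = 10,
) -> tuple[float, np.ndarray, float]:
    """Compare the best HRG likelihood of the network against degree-
    preserving rewired nulls (fitted on their largest component); small
    empirical p means the network is more hierarchical than random.

    Returns (observed_loglik, null_logliks, empirical_p)."""
    work = net.largest_component()
    if work.n_vertices < 4:
        raise NetworkError("largest component must have >= 4 vertices")
    _, observed = fit_hrg(work, n_steps=n_steps, rng_seed=rng_seed)
    nulls = np.empty(n_random)
    for i in range(n_random):
        rewired = rewire_degree_preserving(
            work, n_swaps=swaps_per_edge * work.n_edges, rng_seed=rng_seed + 1 + i
        )
        comp = rewired.largest_component()
        _, nulls[i] = fit_hrg(comp, n_steps=n_steps, rng_seed=rng_seed + 1 + i)
    p = (1 + int((nulls >= observed).sum())) / (n_random + 1)
    return float(observed), nulls, p
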