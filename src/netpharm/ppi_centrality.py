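"""Interactome subnetwork expansion and the two-stage median-multiple core screen.

Six topological indices in the CytoNCA convention, computed on undirected
simple graphs:

* **DC** — degree, ``|N(v)|``.
* **BC** — betweenness, ``sum over unordered pairs s != t != v of
  sigma_st(v) / sigma_st`` (shortest-path counts, unnormalized), by Brandes
  accumulation.
* **CC** — closeness with component-size normalization,
  ``(n_c - 1) / sum_u d(v, u)`` over v's component of size ``n_c``; 0 for an
  isolated node.
* **EC** — eigenvector centrality: the nonnegative principal eigenvector of
  the adjacency matrix, computed per connected component by power iteration
  and scaled to unit Euclidean norm within each component block; 0 on
  single-node components.
* **LAC** — local average connectivity: mean degree of v's neighbors within
  the subgraph induced on those neighbors; 0 for an isolated node.
* **NC** — network centrality: ``sum over u in N(v) of ECC(u, v)`` where the
  edge clustering coefficient is ``ECC(u, v) = |common neighbors| /
  min(DC(u) - 1, DC(v) - 1)``, defined as 0 when the denominator is 0.

Core-target screening applies the indices in two stages: stage 1 keeps nodes
with DC >= multiplier x median(DC) over the input network (hub network =
induced subgraph); stage 2 recomputes all six indices on the hub network and
keeps nodes meeting multiplier x median on every index (core network).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph_io import Network
from .target_assembly import TargetSet

__all__ = [
    "CentralityTable",
    "ScreeningReport",
    "INDEX_NAMES",
    "expand_subnetwork",
    "intersect_networks",
    "compute_centralities",
    "median_multiple_threshold",
    "two_stage_screen",
]

INDEX_NAMES = ("DC", "BC", "EC", "CC", "LAC", "NC")


@dataclass
class CentralityTable:
    """Per-node values of the six indices, as a dict of dicts node -> value."""

    nodes: list[str]
    values: dict[str, dict[str, float]]  # index name -> node -> value

    def column(self, index: str) -> list[float]:
        return [self.values[index][v] for v in self.nodes]

    def row(self, node: str) -> dict[str, float]:
        return {idx: self.values[idx][node] for idx in INDEX_NAMES}

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({idx: self.values[idx] for idx in INDEX_NAMES})
        df.index.name = "node"
        return df.loc[sorted(self.nodes)]


@dataclass
class ScreeningReport:
    """Everything the two-stage screen decided and why."""

    stage1_threshold: float
    stage2_thresholds: dict[str, float]
    hub_network: Network
    core_network: Network
    stage1_table: CentralityTable  # DC on the input network; other indices NaN
    stage2_table: CentralityTable  # all six indices on the hub network
    multiplier: float = 2.0


# ---------------------------------------------------------------------------
# Network set operations


def expand_subnetwork(interactome: Network, seeds: TargetSet | set[str], depth: int = 1) -> Network:
    """Seed-plus-neighbors expansion against an interactome.

    The node set is the seeds present in the interactome plus their
    neighbors to the given depth; the edge set is every interactome edge
    induced on those nodes. Seeds absent from the interactome are recorded
    on the result as a ``missing`` list attribute and are not included.
    """
    symbols = seeds.symbols if isinstance(seeds, TargetSet) else set(seeds)
    if not symbols:
        raise ValueError("seed set is empty")
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    present = symbols & interactome.nodes
    missing = sorted(symbols - interactome.nodes)
    if not present:
        raise ValueError("no seed is present in the interactome")
    adj = interactome.adjacency()
    keep = set(present)
    frontier = set(present)
    for _ in range(depth):
        frontier = set().union(*(adj[v] for v in frontier)) - keep if frontier else set()
        keep |= frontier
    sub = interactome.induced_subgraph(keep, name="expanded")
    for v in present:
        sub.add_node(v, seed="1")
    sub.missing_seeds = missing  # type: ignore[attr-defined]
    sub.validate()
    return sub


def intersect_networks(a: Network, b: Network, name: str = "intersection") -> Network:
    """Node-and-edge intersection of two networks; isolated nodes retained."""
    out = Network(name=name)
    for v in a.nodes & b.nodes:
        attrs = {**b.node_attrs.get(v, {}), **a.node_attrs.get(v, {})}
        out.add_node(v, **attrs)
    out.edges = a.edges & b.edges
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Centrality indices


def _connected_components(adj: dict[str, set[str]]) -> list[list[str]]:
    seen: set[str] = set()
    comps: list[list[str]] = []
    for start in adj:
        if start in seen:
            continue
        comp = []
        queue = deque([start])
        seen.add(start)
        while queue:
            v = queue.popleft()
            comp.append(v)
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    queue.append(u)
        comps.append(comp)
    return comps


def _betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    """Brandes accumulation; returns unordered-pair counts (halved)."""
    bc = dict.fromkeys(adj, 0.0)
    for s in adj:
        # single-source shortest-path counting
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in adj}
        sigma = dict.fromkeys(adj, 0.0)
        dist = dict.fromkeys(adj, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = dict.fromkeys(adj, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    # each unordered pair counted from both endpoints as source
    return {v: x / 2.0 for v, x in bc.items()}


def _closeness(adj: dict[str, set[str]], components: list[list[str]]) -> dict[str, float]:
    cc = dict.fromkeys(adj, 0.0)
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(components):
        for v in comp:
            comp_of[v] = i
    for v in adj:
        n_c = len(components[comp_of[v]])
        if n_c == 1:
            cc[v] = 0.0
            continue
        total = 0
        dist = {v: 0}
        queue = deque([v])
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    total += dist[w]
                    queue.append(w)
        cc[v] = (n_c - 1) / total
    return cc


def _eigenvector(adj: dict[str, set[str]], components: list[list[str]],
                 tol: float = 1e-10, max_iter: int = 10_000) -> dict[str, float]:
    """Power iteration per component, deterministic uniform start, unit 2-norm."""
    ec = dict.fromkeys(adj, 0.0)
    for comp in components:
        if len(comp) == 1:
            continue
        order = sorted(comp)
        index = {v: i for i, v in enumerate(order)}
        n = len(order)
        rows, cols = [], []
        for v in order:
            for u in adj[v]:
                rows.append(index[v])
                cols.append(index[u])
        a = np.zeros((n, n))
        a[rows, cols] = 1.0
        x = np.full(n, 1.0 / np.sqrt(n))
        for _ in range(max_iter):
            # shifted iteration (A + I): same eigenvectors, but the Perron
            # root strictly dominates, so bipartite graphs cannot oscillate
            x_new = a @ x + x
            x_new /= np.linalg.norm(x_new)
            if np.linalg.norm(x_new - x) < tol:
                x = x_new
                break
            x = x_new
        x = np.abs(x)
        x /= np.linalg.norm(x)
        for v in order:
            ec[v] = float(x[index[v]])
    return ec


def _lac(adj: dict[str, set[str]]) -> dict[str, float]:
    lac = dict.fromkeys(adj, 0.0)
    for v, nbrs in adj.items():
        if not nbrs:
            continue
        # degree of each neighbor within the subgraph induced on N(v)
        total = sum(len(adj[u] & nbrs) for u in nbrs)
        lac[v] = total / len(nbrs)
    return lac


def _nc(adj: dict[str, set[str]]) -> dict[str, float]:
    nc = dict.fromkeys(adj, 0.0)
    for v, nbrs in adj.items():
        total = 0.0
        dv = len(nbrs)
        for u in nbrs:
            denom = min(dv - 1, len(adj[u]) - 1)
            if denom > 0:
                total += len(nbrs & adj[u]) / denom
        nc[v] = total
    return nc


def compute_centralities(net: Network) -> CentralityTable:
    """Compute all six indices (DC, BC, EC, CC, LAC, NC) on a simple graph."""
    if net.n_nodes < 1:
        raise ValueError("network has no nodes")
    net.validate()
    adj = net.adjacency()
    comps = _connected_components(adj)
    values = {
        "DC": {v: float(len(nbrs)) for v, nbrs in adj.items()},
        "BC": _betweenness(adj),
        "EC": _eigenvector(adj, comps),
        "CC": _closeness(adj, comps),
        "LAC": _lac(adj),
        "NC": _nc(adj),
    }
    return CentralityTable(nodes=sorted(net.nodes), values=values)


def median_multiple_threshold(values: list[float], multiplier: float = 2.0) -> float:
    """``multiplier x median``; even-length medians average the two central order stats."""
    if len(values) == 0:
        raise ValueError("cannot take the median of an empty list")
    return float(multiplier * np.median(values))


def two_stage_screen(net: Network, multiplier: float = 2.0) -> ScreeningReport:
    """Median-multiple hub and core screening.

    Stage 1: DC on the full network; keep nodes with DC >= multiplier x
    median(DC); hub network = induced subgraph. Stage 2: recompute all six
    indices on the hub network; keep nodes with every index >= multiplier x
    that index's hub-network median; core network = induced subgraph.
    Comparisons are inclusive (>=).
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes to screen")
    deg = net.degree()
    dc_values = [float(d) for d in deg.values()]
    stage1_threshold = median_multiple_threshold(dc_values, multiplier)
    hub_nodes = {v for v, d in deg.items() if d >= stage1_threshold}
    if not hub_nodes:
        q = np.percentile(dc_values, [0, 25, 50, 75, 100])
        raise ValueError(
            "stage-1 screen kept no nodes: "
            f"threshold {stage1_threshold} vs DC quartiles min/q1/med/q3/max = {q.tolist()}"
        )
    hub = net.induced_subgraph(hub_nodes, name="hub")
    stage1_table = CentralityTable(
        nodes=sorted(net.nodes),
        values={
            "DC": {v: float(d) for v, d in deg.items()},
            **{idx: dict.fromkeys(net.nodes, float("nan")) for idx in INDEX_NAMES if idx != "DC"},
        },
    )

    stage2_table = compute_centralities(hub)
    stage2_thresholds = {
        idx: median_multiple_threshold(stage2_table.column(idx), multiplier)
        for idx in INDEX_NAMES
    }
    core_nodes = {
        v for v in hub.nodes
        if all(stage2_table.values[idx][v] >= stage2_thresholds[idx] for idx in INDEX_NAMES)
    }
    core = hub.induced_subgraph(core_nodes, name="core")
    return ScreeningReport(
        stage1_threshold=stage1_threshold,
        stage2_thresholds=stage2_thresholds,
        hub_network=hub,
        core_network=core,
        stage1_table=stage1_table,
        stage2_table=stage2_table,
        multiplier=multiplier,
    )
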