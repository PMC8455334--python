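"""Seed interactome models and overlapping modules via influence landscapes.

The module detector is a deterministic, testable take on centrality-landscape
community detection: every node accumulates an *influence* score from its
attenuated shortest-path neighbourhood, module centres are the local maxima
of that field, and membership of a node in a module decays with its distance
from the centre.  Centres whose member sets largely coincide (tied maxima in
symmetric graphs, multiple peaks inside one dense block) are consolidated
into the highest-priority centre, so a dense planted block yields one
module.  Each module's *metanode* is its ten most central genes; the union
of metanodes over modules is the functional core of the network model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .datatypes import ValidationError

__all__ = [
    "build_seed_network",
    "influence_landscape",
    "detect_overlapping_modules",
    "module_core",
    "network_core",
    "group_clustering_coefficient",
    "ModuleLandscape",
    "Module",
    "Metanode",
]

DEFAULT_LAMBDA = 0.5
DEFAULT_DEPTH = 3
DEFAULT_TAU = 0.2
DEFAULT_METANODE_SIZE = 10


@dataclass
class Module:
    centre: str
    membership: dict[str, float]  # node -> normalized weight in [0, 1]

    @property
    def members(self) -> list[str]:
        return sorted(self.membership)


@dataclass
class ModuleLandscape:
    influence: dict[str, float]
    modules: list[Module] = field(default_factory=list)
    centrality: dict[str, dict[str, float]] = field(default_factory=dict)
    # centrality[centre][node] = normalized membership * influence(node)


@dataclass
class Metanode:
    module_id: str
    genes: list[str]  # descending centrality, ties lexicographic


def build_seed_network(seeds: Iterable[str], interactome: nx.Graph) -> nx.Graph:
    """Induced subgraph on the seeds and their first neighbours.

    Neighbour-neighbour edges are retained (induced subgraph); seeds absent
    from the interactome are kept as isolated nodes flagged ``missing=True``.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValidationError("empty seed set")
    if interactome.number_of_nodes() == 0:
        raise ValidationError("empty interactome")
    present = seeds & set(interactome.nodes)
    nodes = set(present)
    for s in present:
        nodes.update(interactome.neighbors(s))
    sub = nx.Graph()
    sub.add_nodes_from(sorted(nodes))
    sub.add_edges_from(
        sorted(tuple(sorted(e)) for e in interactome.subgraph(nodes).edges)
    )
    for s in sorted(seeds - present):
        sub.add_node(s, missing=True)
    return sub


def influence_landscape(
    graph: nx.Graph, lam: float = DEFAULT_LAMBDA, depth: int = DEFAULT_DEPTH
) -> dict[str, float]:
    """Attenuated-reachability influence: sum of lam**d over nodes within depth.

    The self term contributes lam**0 = 1, so isolated nodes have influence 1.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    if not 0 < lam < 1:
        raise ValidationError("attenuation must lie in (0, 1)")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    weights = lam ** np.arange(depth + 1)
    influence = {}
    for v in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, v, cutoff=depth)
        influence[v] = float(sum(weights[d] for d in dists.values()))
    return influence


def _priority(graph: nx.Graph, influence: Mapping[str, float]):
    """Sort key: higher influence, then higher degree, then smaller id first."""
    return lambda v: (-influence[v], -graph.degree(v), v)


def _find_centres(graph: nx.Graph, influence: Mapping[str, float]) -> list[str]:
    """Local maxima of the influence field over triangle-supported edges.

    The comparison with a neighbour only counts when the edge is embedded in
    at least one triangle: a stray unembedded edge into a foreign dense
    region must not suppress a region's own peak.  Nodes with no supported
    neighbour are vacuous local maxima; the consolidation pass absorbs them.
    """
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    centres = [
        v
        for v in graph.nodes
        if all(
            influence[v] >= influence[u]
            for u in adj[v]
            if adj[v] & adj[u]  # edge supported by a common neighbour
        )
    ]
    assert centres, "non-empty graphs always have an influence local maximum"
    return sorted(centres, key=_priority(graph, influence))


def _raw_memberships(
    graph: nx.Graph,
    centres: list[str],
    influence: Mapping[str, float],
    lam: float,
    depth: int,
) -> dict[str, dict[str, float]]:
    """Attenuated walk-count membership of every node in every centre's hill.

    raw[v][c] = influence(c) * sum over walk lengths l <= depth of
    lam**l times the number of length-l walks between v and c.  Counting
    walk multiplicity (not just shortest-path length) lets a node side with
    the centre its dense surroundings belong to even when a stray cross edge
    puts a foreign centre at the same hop distance.
    """
    import scipy.sparse  # local import keeps networkx-only callers light

    nodes = list(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csr", dtype=float)
    raw: dict[str, dict[str, float]] = {v: {} for v in nodes}
    for c in centres:
        x = np.zeros(len(nodes))
        x[index[c]] = 1.0
        acc = x.copy()
        for ell in range(1, depth + 1):
            x = adj @ x
            acc = acc + (lam**ell) * x
        for i in np.nonzero(acc)[0]:
            raw[nodes[i]][c] = float(acc[i]) * influence[c]
    # a node beyond `depth` of every centre falls back to its nearest centre
    orphans = [v for v, m in raw.items() if not m]
    if orphans:
        order = {c: i for i, c in enumerate(centres)}
        for v in orphans:
            dists = nx.single_source_shortest_path_length(graph, v)
            reach = [(dists[c], order[c], c) for c in centres if c in dists]
            if reach:
                d, _, c = min(reach)
                raw[v][c] = (lam**d) * influence[c]
            else:  # different component with no centre cannot happen; guard anyway
                raw[v][v] = influence[v]
    return raw


def _member_sets(norm: Mapping[str, Mapping[str, float]], centres: list[str], tau: float):
    members = {c: set() for c in centres}
    for v, m in norm.items():
        for c, w in m.items():
            if w >= tau:
                members[c].add(v)
    for c in centres:  # a centre always belongs to its own module
        members[c].add(c)
    return members


def _basins(
    raw: Mapping[str, Mapping[str, float]], centres: list[str]
) -> dict[str, set[str]]:
    """Hard assignment of each node to its best centre (ties by priority)."""
    order = {c: i for i, c in enumerate(centres)}
    basins: dict[str, set[str]] = {c: set() for c in centres}
    for v, m in raw.items():
        best = min(m, key=lambda c: (-m[c], order[c]))
        basins[best].add(v)
    return basins


def _local_moves(
    graph: nx.Graph,
    basins: Mapping[str, set[str]],
    centres: list[str],
    max_sweeps: int = 10,
) -> dict[str, set[str]]:
    """Deterministic modularity local moves refining the basin partition.

    Nodes (in sorted order, centres pinned) move to the adjacent basin with
    the largest positive modularity gain until a full sweep makes no move.
    """
    m = graph.number_of_edges()
    if m == 0:
        return {c: set(vs) for c, vs in basins.items()}
    order = {c: i for i, c in enumerate(centres)}
    owner = {v: c for c, vs in basins.items() for v in vs}
    parts = {c: set(vs) for c, vs in basins.items()}
    degsum = {c: float(sum(graph.degree(v) for v in vs)) for c, vs in basins.items()}
    pinned = set(centres)
    nodes = sorted(graph.nodes)
    for _ in range(max_sweeps):
        moved = False
        for v in nodes:
            if v in pinned:
                continue
            a = owner[v]
            links: dict[str, int] = {}
            for u in graph.neighbors(v):
                links[owner[u]] = links.get(owner[u], 0) + 1
            kv = graph.degree(v)
            base = links.get(a, 0) / m - kv * (degsum[a] - kv) / (2.0 * m * m)
            best_gain, best_c = 0.0, a
            for b, e_vb in sorted(links.items(), key=lambda kv_: order.get(kv_[0], 0)):
                if b == a:
                    continue
                gain = e_vb / m - kv * degsum[b] / (2.0 * m * m) - base
                if gain > best_gain + 1e-12:
                    best_gain, best_c = gain, b
            if best_c != a:
                parts[a].discard(v)
                parts[best_c].add(v)
                degsum[a] -= kv
                degsum[best_c] += kv
                owner[v] = best_c
                moved = True
        if not moved:
            break
    return parts


def _propagate_membership(
    graph: nx.Graph, partition: Mapping[str, set[str]], centres: list[str], n_iter: int = 3
) -> dict[str, dict[str, float]]:
    """Soft overlapping memberships by lazy label propagation.

    Starts from the hard partition indicator and averages each node's label
    distribution over its closed neighbourhood ``n_iter`` times; centres are
    pinned to their own module (semi-supervised anchors), interior nodes
    stay with their module, boundary nodes acquire graded membership in
    every adjacent module.  Rows sum to 1.
    """
    order = {c: i for i, c in enumerate(centres)}
    anchors = set(centres)
    current: dict[str, dict[str, float]] = {}
    for c, vs in partition.items():
        for v in vs:
            current[v] = {c: 1.0}
    for v in graph.nodes:  # guard: nodes outside every basin stay singletons
        current.setdefault(v, {v: 1.0})
    for _ in range(n_iter):
        nxt: dict[str, dict[str, float]] = {}
        for v in graph.nodes:
            if v in anchors:
                nxt[v] = current[v]
                continue
            acc: dict[str, float] = dict(current[v])
            for u in graph.neighbors(v):
                for c, w in current[u].items():
                    acc[c] = acc.get(c, 0.0) + w
            total = sum(acc.values())
            nxt[v] = {c: w / total for c, w in sorted(acc.items(), key=lambda t: order.get(t[0], 0))}
        current = nxt
    return current


def _modularity_consolidate(
    graph: nx.Graph, centres: list[str], basins: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """Greedy agglomeration of influence basins by Newman modularity.

    Adjacent basins are merged (into the higher-priority centre) while the
    merge increases modularity.  A dense block split across several peaks
    re-unites -- its internal cut is as dense as expected at random -- while
    genuinely separated regions (a sparse bridge between cliques, planted
    blocks linked by stray edges) stay apart.  Deterministic: the largest
    modularity gain is merged first, ties broken by centre priority.
    """
    m = graph.number_of_edges()
    if m == 0:
        return dict(basins)
    order = {c: i for i, c in enumerate(centres)}
    owner = {v: c for c, vs in basins.items() for v in vs}
    degsum = {c: float(sum(graph.degree(v) for v in vs)) for c, vs in basins.items()}
    between: dict[tuple[str, str], float] = {}
    for u, v in graph.edges:
        cu, cv = owner[u], owner[v]
        if cu != cv:
            key = (cu, cv) if order[cu] < order[cv] else (cv, cu)
            between[key] = between.get(key, 0.0) + 1.0
    merged = {c: set(vs) for c, vs in basins.items()}
    while between:
        def gain(pair):
            hi, lo = pair
            return between[pair] / m - degsum[hi] * degsum[lo] / (2.0 * m * m)
        best = max(between, key=lambda p: (gain(p), -order[p[0]], -order[p[1]]))
        if gain(best) <= 1e-12:
            break
        hi, lo = best
        merged[hi] |= merged.pop(lo)
        degsum[hi] += degsum.pop(lo)
        del between[best]
        for pair in list(between):
            if lo in pair:
                other = pair[0] if pair[1] == lo else pair[1]
                key = (hi, other) if order[hi] < order[other] else (other, hi)
                if key != (hi, hi):
                    between[key] = between.get(key, 0.0) + between.pop(pair)
                else:  # pragma: no cover - hi cannot pair with itself
                    del between[pair]
    return merged


def detect_overlapping_modules(
    graph: nx.Graph,
    influence: Mapping[str, float] | None = None,
    lam: float = DEFAULT_LAMBDA,
    depth: int = DEFAULT_DEPTH,
    tau: float = DEFAULT_TAU,
) -> ModuleLandscape:
    """Overlapping modules around the local maxima of the influence field.

    The pipeline is: (1) influence local maxima over triangle-supported
    edges are candidate centres; (2) every node joins the basin of the
    centre with the largest attenuated walk-count affinity
    (sum over walk lengths l <= depth of lam**l times the number of
    length-l walks, weighted by the centre's influence); (3) basins are
    refined by deterministic modularity local moves and redundant centres
    consolidated by greedy modularity agglomeration, so a dense region that
    hosts several influence peaks (ties in symmetric graphs, degree
    fluctuations inside a dense block) ends up as one module while regions
    separated by a sparse cut stay apart; (4) overlapping memberships are
    obtained by lazy label propagation from the consolidated partition,
    normalized per node, with a module's member set keeping nodes at
    membership >= ``tau``.  Centre priority everywhere is higher influence,
    then higher degree, then lexicographically smaller id.  Per-module
    centrality of a member is its normalized membership times its own
    influence.
    """
    if influence is None:
        influence = influence_landscape(graph, lam, depth)
    centres = _find_centres(graph, influence)

    # drop centres outcompeted even at home (their basin misses themselves)
    raw = _raw_memberships(graph, centres, influence, lam, depth)
    basins = _basins(raw, centres)
    survivors = [c for c in centres if c in basins[c]]
    if len(survivors) < len(centres):
        centres = survivors
        raw = _raw_memberships(graph, centres, influence, lam, depth)
        basins = _basins(raw, centres)

    basins = _local_moves(graph, basins, centres)
    merged = _modularity_consolidate(graph, centres, basins)
    centres = [c for c in centres if c in merged]

    norm = _propagate_membership(graph, merged, centres)
    members = _member_sets(norm, centres, tau)
    modules = []
    centrality: dict[str, dict[str, float]] = {}
    for c in centres:
        memb = {v: norm[v][c] for v in members[c] if c in norm[v]}
        modules.append(Module(centre=c, membership=memb))
        centrality[c] = {v: memb[v] * influence[v] for v in memb}
    return ModuleLandscape(influence=dict(influence), modules=modules, centrality=centrality)


def module_core(
    landscape: ModuleLandscape, module: Module, k: int = DEFAULT_METANODE_SIZE
) -> Metanode:
    """Top-k module members by centrality (descending, ties lexicographic)."""
    if k < 1:
        raise ValidationError("metanode size must be >= 1")
    if not module.membership:
        raise ValidationError("empty module")
    cent = landscape.centrality[module.centre]
    ranked = sorted(cent, key=lambda v: (-cent[v], v))
    return Metanode(module_id=module.centre, genes=ranked[:k])


def network_core(metanodes: Iterable[Metanode]) -> set[str]:
    """Unique genes across the metanodes: the network model's functional core."""
    metanodes = list(metanodes)
    if not metanodes:
        raise ValidationError("need at least one metanode")
    core: set[str] = set()
    for m in metanodes:
        core.update(m.genes)
    return core


def max_membership_assignment(landscape: ModuleLandscape) -> dict[str, str]:
    """Assign each node to the module where its membership is largest.

    Ties go to the centre that comes first in the landscape's module order
    (higher priority).  Used for recovery scoring against planted partitions.
    """
    best: dict[str, tuple[float, str]] = {}
    for mod in landscape.modules:
        for v, w in mod.membership.items():
            cur = best.get(v)
            if cur is None or w > cur[0] + 1e-15:
                best[v] = (w, mod.centre)
    return {v: c for v, (_, c) in best.items()}


def group_clustering_coefficient(graph: nx.Graph, genes: Iterable[str]) -> tuple[float, float]:
    """Mean and SEM of local clustering coefficients of ``genes`` in ``graph``.

    The local coefficient is triangles over possible triangles at the node
    (0 for degree < 2), computed on the full graph.
    """
    genes = sorted(set(genes))
    if not genes:
        raise ValidationError("empty gene group")
    missing = [g for g in genes if g not in graph]
    if missing:
        raise ValidationError(f"genes not in graph: {missing[:5]}")
    cc = nx.clustering(graph, genes)
    vals = np.array([cc[g] for g in genes], dtype=float)
    sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return float(vals.mean()), sem
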