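"""Minimum-spanning and median-joining haplotype networks.

A haplotype network summarises the mutational relationships among the
distinct sequences in a sample.  The minimum spanning network (MSN) is
the union of all minimum spanning trees over the Hamming distances; the
median-joining construction (Bandelt, Forster & Roehl 1999) additionally
infers unobserved intermediate haplotypes (median vectors) from triplets
of mutually close nodes, producing the classic star-like pictures around
a swept haplotype.

Columns containing gaps or ambiguity codes are dropped before network
construction; edge weights are exact Hamming counts over the retained
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .data_model import HaplotypeTable

__all__ = [
    "HaplotypeNetwork",
    "distance_matrix",
    "minimum_spanning_network",
    "median_joining",
    "from_haplotype_table",
    "write_gml",
    "write_nexus_network",
]

OBSERVED = "observed"
MEDIAN = "median"

#: Cap on quasi-median vectors generated from a single triplet (columns
#: with three distinct states multiply combinations).
MAX_MEDIANS_PER_TRIPLET = 81

_MAX_ITERATIONS = 100


@dataclass
class HaplotypeNetwork:
    """Observed + inferred haplotype nodes with mutation-weighted edges.

    ``graph`` is a networkx Graph whose nodes carry ``sequence``, ``kind``
    (``"observed"`` or ``"median"``), ``count`` and optional per-group
    count annotations; edges carry integer ``weight`` = Hamming distance.
    """

    graph: nx.Graph
    retained: list[int] = field(default_factory=list)

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == OBSERVED]

    @property
    def median_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == MEDIAN]

    @property
    def total_cost(self) -> int:
        return int(sum(w for _, _, w in self.graph.edges(data="weight")))


def distance_matrix(haplotypes: Sequence[str]) -> np.ndarray:
    """Symmetric integer Hamming-distance matrix over equal-length sequences."""
    if len({len(h) for h in haplotypes}) > 1:
        raise ValueError("ragged haplotype sequences")
    arr = np.array([list(h) for h in haplotypes])
    n = len(haplotypes)
    d = np.zeros((n, n), dtype=int)
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = int((arr[i] != arr[j]).sum())
    return d


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(seqs: list[str], epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Union-of-all-MSTs edges, with links within ``epsilon`` of each
    merging threshold also admitted (Bandelt's epsilon relaxation)."""
    n = len(seqs)
    d = distance_matrix(seqs)
    pairs = sorted(
        ((int(d[i, j]), i, j) for i, j in combinations(range(n), 2)),
        key=lambda t: t[0],
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, int]] = []
    k = 0
    while k < len(pairs):
        w = pairs[k][0]
        # snapshot connectivity before this weight class
        comp_before = [find(i) for i in range(n)]
        group = []
        while k < len(pairs) and pairs[k][0] <= w + epsilon:
            group.append(pairs[k])
            k += 1
        added_any = False
        for wg, i, j in group:
            if comp_before[i] != comp_before[j]:
                edges.append((i, j, wg))
                added_any = True
        for wg, i, j in group:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        if not added_any and len({find(i) for i in range(n)}) == 1:
            break
        if len({find(i) for i in range(n)}) == 1:
            break
    return edges


def _quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Quasi-median vectors of a sequence triplet.

    Columns with a majority state contribute that state; columns with
    three distinct states contribute each of the three (the quasi-median
    expansion), capped at ``MAX_MEDIANS_PER_TRIPLET`` combinations.
    """
    options: list[tuple[str, ...]] = []
    size = 1
    for a, b, c in zip(u, v, w):
        states = {a, b, c}
        if len(states) <= 2:
            # majority (or unanimity)
            if a == b or a == c:
                options.append((a,))
            else:
                options.append((b,))
        else:
            options.append((a, b, c))
            size *= 3
            if size > MAX_MEDIANS_PER_TRIPLET:
                return []
    return ["".join(combo) for combo in product(*options)]


def minimum_spanning_network(
    haplotypes: Sequence[str] | Mapping[str, str], epsilon: int = 0
) -> nx.Graph:
    """Minimum spanning network over haplotype sequences.

    Accepts a sequence list or an id -> sequence mapping; returns a
    networkx Graph keyed by id (positional ids when a list is given),
    deterministic for a fixed input order.
    """
    if isinstance(haplotypes, Mapping):
        ids = list(haplotypes)
        seqs = [haplotypes[i] for i in ids]
    else:
        seqs = list(haplotypes)
        ids = [f"n{i}" for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("need at least 2 haplotypes")
    if epsilon < 0:
        raise ValueError("epsilon must be a non-negative integer")
    g = nx.Graph()
    for i, sid in enumerate(ids):
        g.add_node(sid, sequence=seqs[i])
    for i, j, w in _msn_edges(seqs, epsilon):
        g.add_edge(ids[i], ids[j], weight=w)
    return g


def _network_cost(seqs: list[str]) -> int:
    """Total weight of a minimum spanning tree over the sequences."""
    d = distance_matrix(seqs)
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i, j in combinations(range(len(seqs)), 2):
        g.add_edge(i, j, weight=int(d[i, j]))
    return int(
        sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, algorithm="kruskal", data=True))
    )


def median_joining(
    haplotypes: Sequence[str] | Mapping[str, str], epsilon: int = 0
) -> HaplotypeNetwork:
    """Median-joining network of the observed haplotypes.

    Iterates: build the MSN; for every mutually connected triplet compute
    quasi-median vectors; greedily add medians whose inclusion strictly
    reduces the minimum-spanning cost of the node set; drop obsolete
    medians (degree <= 2 and on no shortest path between observed nodes);
    repeat to a fixpoint.  With ``epsilon=0`` the result contains a
    minimum spanning tree of the observed haplotypes and its total cost
    never increases across iterations.
    """
    if isinstance(haplotypes, Mapping):
        ids = list(haplotypes)
        observed = [haplotypes[i] for i in ids]
    else:
        observed = list(haplotypes)
        ids = [f"n{i}" for i in range(len(observed))]
    if len(observed) < 2:
        raise ValueError("need at least 2 haplotypes")
    if len(set(observed)) != len(observed):
        raise ValueError("haplotype sequences must be distinct (collapse first)")

    seqs = list(observed)  # observed prefix + appended medians
    observed_set = set(observed)
    retired: set[str] = set()  # deleted medians are never re-proposed

    for _ in range(_MAX_ITERATIONS):
        changed = False
        # 1. candidate medians from mutually connected MSN triplets
        edge_list = _msn_edges(seqs, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j, _w in edge_list:
            adj[i].add(j)
            adj[j].add(i)
        candidates: list[str] = []
        seen: set[str] = set(seqs) | retired
        for i, j in combinations(range(len(seqs)), 2):
            if j not in adj[i]:
                continue
            for k in adj[i] & adj[j]:
                if k <= j:
                    continue
                for med in _quasi_medians(seqs[i], seqs[j], seqs[k]):
                    if med not in seen:
                        seen.add(med)
                        candidates.append(med)
        # greedy cost-reduction filter
        cost = _network_cost(seqs)
        scored = []
        for med in candidates:
            c = _network_cost(seqs + [med])
            if c < cost:
                scored.append((c, med))
        scored.sort(key=lambda t: t[0])
        for _c, med in scored:
            c_with = _network_cost(seqs + [med])
            if c_with < cost:
                seqs.append(med)
                cost = c_with
                changed = True
        # 2. delete obsolete medians
        g = _build_graph(seqs, observed, ids, epsilon)
        removable = _obsolete_medians(g)
        if removable:
            keep = [s for s in seqs if s in observed_set or s not in removable]
            if len(keep) != len(seqs):
                retired |= {s for s in seqs if s not in keep}
                seqs = keep
                changed = True
        if not changed:
            break
    else:
        raise RuntimeError("median-joining failed to converge within 100 iterations")

    g = _build_graph(seqs, observed, ids, epsilon)
    return HaplotypeNetwork(graph=g)


def _build_graph(
    seqs: list[str], observed: list[str], ids: list[str], epsilon: int
) -> nx.Graph:
    observed_index = {s: ids[i] for i, s in enumerate(observed)}
    g = nx.Graph()
    med_counter = 0
    node_ids = []
    for s in seqs:
        if s in observed_index:
            nid = observed_index[s]
            g.add_node(nid, sequence=s, kind=OBSERVED, count=1)
        else:
            med_counter += 1
            nid = f"mv{med_counter}"
            g.add_node(nid, sequence=s, kind=MEDIAN, count=0)
        node_ids.append(nid)
    for i, j, w in _msn_edges(seqs, epsilon):
        g.add_edge(node_ids[i], node_ids[j], weight=w)
    return g


def _obsolete_medians(g: nx.Graph) -> set[str]:
    """Sequences of median nodes with degree <= 2 lying on no weighted
    shortest path between a pair of observed nodes."""
    obs = [n for n, d in g.nodes(data=True) if d["kind"] == OBSERVED]
    needed: set[str] = set()
    # a median m is on a shortest u-v path iff dist(u,m)+dist(m,v) == dist(u,v)
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    for m, d in g.nodes(data=True):
        if d["kind"] != MEDIAN or g.degree(m) > 2:
            continue
        on_path = any(
            abs(dist[u][m] + dist[m][v] - dist[u][v]) < 1e-9
            for u, v in combinations(obs, 2)
        )
        if not on_path:
            needed.add(d["sequence"])
    return needed


def from_haplotype_table(
    table: HaplotypeTable,
    group_of: Mapping[str, str] | None = None,
    epsilon: int = 0,
) -> HaplotypeNetwork:
    """Median-joining network from a collapsed haplotype table.

    Node counts are the haplotype sample counts; when ``group_of`` maps
    sample ids to groups (population, infection status, ...) each node
    also carries ``count_<group>`` annotations for pie-chart style
    rendering downstream.
    """
    net = median_joining(dict(table.haplotypes), epsilon=epsilon)
    counts = table.counts
    for hid, total in counts.items():
        net.graph.nodes[hid]["count"] = total
    if group_of is not None:
        for (hid, group), c in table.counts_by(group_of).items():
            net.graph.nodes[hid][f"count_{group}"] = c
    net.retained = list(table.retained)
    return net


def write_gml(network: HaplotypeNetwork, path: str | Path) -> None:
    nx.write_gml(network.graph, str(path))


def write_nexus_network(network: HaplotypeNetwork, path: str | Path) -> None:
    """Write a PopART-compatible NEXUS file (Taxa + Network blocks)."""
    g = network.graph
    obs = network.observed_nodes
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={len(obs)};", "TAXLABELS"]
    lines += [f"  {n}" for n in obs]
    lines += [";", "END;", "", "BEGIN NETWORK;"]
    lines.append(f"DIMENSIONS NVERTICES={g.number_of_nodes()} NEDGES={g.number_of_edges()};")
    lines.append("VERTICES")
    index = {}
    for i, (n, d) in enumerate(g.nodes(data=True), start=1):
        index[n] = i
        lines.append(f"  {i} {n} [kind={d['kind']},count={d.get('count', 0)}]")
    lines.append(";")
    lines.append("EDGES")
    for k, (u, v, w) in enumerate(g.edges(data="weight"), start=1):
        lines.append(f"  {k} {index[u]} {index[v]} [weight={w}]")
    lines.append(";")
    lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")
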