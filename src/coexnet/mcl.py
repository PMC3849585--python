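"""Markov Cluster algorithm (MCL) for undirected weighted graphs.

MCL simulates flow on a graph: the column-stochastic transition matrix is
alternately *expanded* (matrix power, letting flow spread) and *inflated*
(element-wise power followed by column renormalization, strengthening
already-strong flow), with small entries pruned each round for sparsity.
Flow converges to a set of attractor nodes; the nodes draining into the
same attractor system form a cluster.  The inflation exponent controls
granularity: larger values give more, smaller clusters.

Implementation notes
--------------------
* Self-loops are added before normalization (weight = the node's maximum
  incident edge weight by default), which damps oscillation and stabilizes
  attractors without dominating flow.
* Edge weights (correlation ``r``) are used as similarities by default;
  ``use_edge_weights=False`` reproduces unweighted clustering.
* Pruning drops matrix entries below ``prune_threshold`` and renormalizes
  columns; it is the main source of divergence between MCL implementations.
* Clustering is deterministic for a fixed graph and parameters: nodes are
  ordered by id, and the documented tie-breaks are all lexicographic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Sentinel cluster value for nodes in clusters too small to be numbered.
UNASSIGNED = None


@dataclass
class MclParams:
    """Tunable parameters of the Markov Cluster algorithm.

    ``inflation`` must exceed 1 (2.2 is a widely used default granularity
    for coexpression graphs); ``expansion_power`` is almost always 2.
    """

    inflation: float = 2.2
    expansion_power: int = 2
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    use_edge_weights: bool = True
    self_loop_weight: str = "max_weight"  # or "unit"

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError(f"inflation must exceed 1, got {self.inflation}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.expansion_power < 2:
            raise ValueError("expansion_power must be >= 2")
        if self.self_loop_weight not in ("max_weight", "unit"):
            raise ValueError(f"unknown self_loop_weight {self.self_loop_weight!r}")


@dataclass
class ClusterAssignment:
    """Node-to-cluster map with size-ordered cluster numbering.

    Clusters are numbered 1..K in non-increasing size order (ties broken by
    the lexicographically smallest member).  Only clusters with strictly
    more than ``min_numbered_size`` members receive numbers; nodes in
    smaller clusters map to :data:`UNASSIGNED`.  ``raw_clusters`` keeps the
    full partition, including unnumbered clusters, in numbering order.
    """

    cluster_of: dict
    cluster_sizes: dict[int, int]
    min_numbered_size: int
    raw_clusters: list[set] = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0

    @property
    def n_numbered(self) -> int:
        return len(self.cluster_sizes)

    def members(self, cluster_number: int) -> set:
        return {n for n, c in self.cluster_of.items() if c == cluster_number}

    def numbered_nodes(self) -> set:
        return {n for n, c in self.cluster_of.items() if c is not UNASSIGNED}


def _column_normalize(m: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0  # empty columns stay empty
    return m.multiply(1.0 / sums).tocsc()


def _prune(m: sp.csc_matrix, threshold: float) -> sp.csc_matrix:
    if threshold <= 0:
        return m
    m = m.copy()
    m.data[m.data < threshold] = 0.0
    m.eliminate_zeros()
    return m


def run_mcl(graph: nx.Graph, params: MclParams | None = None) -> ClusterAssignment:
    """Cluster an undirected graph with the Markov Cluster algorithm.

    Returns a :class:`ClusterAssignment` whose raw partition covers every
    graph node; numbering applies the default strictly-greater-than-6 size
    rule (use :func:`number_clusters` on ``raw_clusters`` to renumber with a
    different cutoff).  Deterministic for fixed input and parameters.  If
    the iteration has not converged after ``max_iterations`` the current
    flow matrix is interpreted anyway, with ``converged=False`` and a
    logged warning.
    """
    params = params or MclParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    rows, cols, data = [], [], []
    max_incident = np.zeros(n)
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0)) if params.use_edge_weights else 1.0
        if w < 0:
            raise ValueError(f"negative edge weight on ({u!r}, {v!r})")
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
        max_incident[i] = max(max_incident[i], w)
        max_incident[j] = max(max_incident[j], w)
    loops = max_incident if params.self_loop_weight == "max_weight" else np.ones(n)
    loops = np.where(loops > 0, loops, 1.0)  # isolated nodes get a unit loop
    rows += list(range(n))
    cols += list(range(n))
    data += list(loops)

    m = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
    m = _column_normalize(m)

    converged = False
    iteration = 0
    for iteration in range(1, params.max_iterations + 1):
        prev = m
        m = m ** params.expansion_power          # expansion
        m = m.power(params.inflation)            # inflation
        m = _prune(m, params.prune_threshold)
        m = _column_normalize(m)
        change = abs(m - prev)
        delta = change.data.max() if change.nnz else 0.0
        if delta < params.convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations; interpreting current matrix",
            params.max_iterations,
        )

    raw = _interpret(m.tocsr(), nodes)
    assignment = number_clusters(raw, min_numbered_size=6)
    assignment.converged = converged
    assignment.n_iterations = iteration
    return assignment


def _interpret(m: sp.csr_matrix, nodes: list) -> list[set]:
    """Read clusters from the converged flow matrix.

    Rows with positive diagonal are attractors; attractors sharing flow form
    an attractor system; every node joins the system receiving the largest
    share of its column mass (ties resolved toward the system containing the
    lexicographically smallest attractor).
    """
    n = len(nodes)
    diag = m.diagonal()
    attractors = np.flatnonzero(diag > 0)
    if attractors.size == 0:
        # pathological (e.g. hard pruning); fall back to singletons
        return [{node} for node in nodes]

    # union attractors that appear in each other's rows
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    attractor_set = set(attractors.tolist())
    for i in attractors:
        row = m.getrow(i)
        for j in row.indices[row.data > 0]:
            if j in attractor_set:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(int(i)), []).append(int(i))
    system_roots = sorted(systems, key=lambda r: nodes[min(systems[r], key=lambda i: nodes[i])])

    mc = m.tocsc()
    clusters: dict[int, set] = {r: set() for r in systems}
    for j in range(n):
        col = mc.getcol(j)
        mass: dict[int, float] = {}
        for i, v in zip(col.indices, col.data):
            if int(i) in attractor_set:
                r = find(int(i))
                mass[r] = mass.get(r, 0.0) + float(v)
        if mass:
            best = max(mass.values())
            tied = [r for r, v in mass.items() if v >= best - 1e-12]
            choice = min(tied, key=lambda r: nodes[min(systems[r], key=lambda i: nodes[i])])
            clusters[choice].add(nodes[j])
        else:
            clusters.setdefault(-j - 1, set()).add(nodes[j])  # orphan: singleton
    return [c for r in sorted(clusters) for c in [clusters[r]] if c] if clusters else []


def number_clusters(raw_partition, min_numbered_size: int = 6) -> ClusterAssignment:
    """Number clusters by size, leaving small clusters unassigned.

    Clusters are ordered by size descending, ties broken by the
    lexicographically smallest member id; clusters with size strictly
    greater than ``min_numbered_size`` receive numbers 1, 2, ...; every node
    of a smaller cluster maps to :data:`UNASSIGNED`.
    """
    clusters = [set(c) for c in raw_partition if c]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    cluster_of: dict = {}
    cluster_sizes: dict[int, int] = {}
    number = 0
    for c in clusters:
        if len(c) > min_numbered_size:
            number += 1
            cluster_sizes[number] = len(c)
            for node in c:
                cluster_of[node] = number
        else:
            for node in c:
                cluster_of[node] = UNASSIGNED
    return ClusterAssignment(
        cluster_of=cluster_of,
        cluster_sizes=cluster_sizes,
        min_numbered_size=min_numbered_size,
        raw_clusters=clusters,
    )


def write_cluster_table(assignment: ClusterAssignment, path, gene_symbol_of=None) -> None:
    """Write the cluster table TSV: probeset_id, gene_symbol, cluster_number.

    ``cluster_number`` is empty for unassigned nodes.  ``gene_symbol_of``
    optionally maps node ids to symbols.
    """
    gene_symbol_of = gene_symbol_of or {}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probeset_id\tgene_symbol\tcluster_number\n")
        def sort_key(item):
            node, c = item
            return (c is UNASSIGNED, c if c is not UNASSIGNED else 0, node)
        for node, c in sorted(assignment.cluster_of.items(), key=sort_key):
            num = "" if c is UNASSIGNED else str(c)
            fh.write(f"{node}\t{gene_symbol_of.get(node, '')}\t{num}\n")
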