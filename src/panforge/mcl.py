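"""Markov clustering (MCL) of protein similarity graphs into ortholog families.

The algorithm simulates random walks on the similarity graph by alternating
*expansion* (matrix power, letting flow spread) and *inflation* (entrywise
power followed by column renormalization, strengthening strong currents and
weakening weak ones) on a column-stochastic matrix, until the flow matrix
converges.  Regions where flow concentrates — the attractor structure of the
limit matrix — are the clusters.

This is a dense-matrix implementation intended for the graph sizes a
single-species pan-genome produces (thousands of proteins); it is not tuned
for metagenome-scale graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix
from .similarity import SimilarityGraph

__all__ = [
    "MCLParams",
    "OrthologClusterSet",
    "mcl_cluster",
    "clusters_to_matrix",
    "write_cluster_tsv",
    "read_cluster_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MCLParams:
    """MCL iteration parameters.

    Defaults follow common ortholog-clustering practice: expansion 2,
    inflation 2.0 (midpoint of the customary 1.5-4 range), light pruning, and
    a tight convergence tolerance.
    """

    expansion: int = 2
    inflation: float = 2.0
    prune_threshold: float = 1e-5
    max_iterations: int = 100
    convergence_tol: float = 1e-6
    #: add self-loops with the max incident edge weight before iterating
    #: (standard regularization; without it bipartite-ish flow oscillates)
    self_loops: bool = True

    def __post_init__(self):
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol < 0:
            raise ValueError("convergence_tol must be >= 0")


@dataclass
class OrthologClusterSet:
    """Disjoint partition of protein ids into gene families.

    ``clusters`` covers every input protein (singletons included) and
    ``genome_map`` tags each protein with its genome of origin.  ``converged``
    is False when MCL hit the iteration cap; the best partition is still
    returned.
    """

    clusters: list[frozenset[str]]
    genome_map: dict[str, str] = field(default_factory=dict)
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters must be disjoint")
            seen |= c
        # canonical deterministic order: by smallest member id
        self.clusters = sorted(self.clusters, key=lambda c: min(c))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def protein_ids(self) -> set[str]:
        return set().union(*self.clusters) if self.clusters else set()


def _column_normalize(M: np.ndarray) -> np.ndarray:
    colsum = M.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return M / colsum


def mcl_cluster(
    graph: SimilarityGraph,
    params: MCLParams = MCLParams(),
    genome_map: dict[str, str] | None = None,
) -> OrthologClusterSet:
    """Partition a similarity graph into ortholog clusters with MCL.

    Nodes are processed in sorted order, so the partition is invariant to the
    order in which records or hits were supplied.  Isolated nodes come out as
    singleton clusters.  Clusters are read from the converged flow matrix as
    the connected components of its supra-threshold support, which cannot
    merge nodes across disconnected components of the input graph.
    """
    nodes = sorted(graph.graph.nodes)
    if not nodes:
        raise ValueError("graph is empty")
    n = len(nodes)
    idx = {node: i for i, node in enumerate(nodes)}

    A = np.zeros((n, n))
    for u, v, data in graph.graph.edges(data=True):
        w = float(data["weight"])
        A[idx[u], idx[v]] = w
        A[idx[v], idx[u]] = w

    if params.self_loops:
        incident_max = A.max(axis=0)
        incident_max[incident_max == 0] = 1.0  # isolated nodes
        np.fill_diagonal(A, incident_max)
    else:
        np.fill_diagonal(A, np.maximum(A.diagonal(), 1e-12))

    M = _column_normalize(A)
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        prev = M
        M = np.linalg.matrix_power(M, params.expansion)
        M = _column_normalize(np.power(M, params.inflation))
        if params.prune_threshold > 0:
            M[M < params.prune_threshold] = 0.0
            M = _column_normalize(M)
        if np.abs(M - prev).max() < params.convergence_tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "MCL did not converge in %d iterations; returning best partition",
            params.max_iterations,
        )

    # clusters = connected components of the limit matrix's support
    tau = max(params.prune_threshold, 1e-8)
    support = (M > tau) | (M.T > tau)
    np.fill_diagonal(support, True)
    labels = _components(support)

    groups: dict[int, set[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(nodes[i])
    clusters = [frozenset(g) for g in groups.values()]
    return OrthologClusterSet(
        clusters=clusters,
        genome_map=dict(genome_map or {}),
        converged=converged,
        n_iterations=iterations,
    )


def _components(adj: np.ndarray) -> np.ndarray:
    """Connected-component labels of a boolean adjacency matrix (BFS)."""
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=int)
    current = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            node = stack.pop()
            for nb in np.nonzero(adj[node])[0]:
                if labels[nb] == -1:
                    labels[nb] = current
                    stack.append(nb)
        current += 1
    return labels


def clusters_to_matrix(
    cluster_set: OrthologClusterSet,
    genome_order: list[str],
    family_prefix: str = "OG",
) -> PresenceAbsenceMatrix:
    """Collapse clusters to a gene-family presence/absence matrix.

    One row per cluster; a cell is true iff the cluster contains at least one
    protein from that genome (paralogs within a genome collapse to a single
    presence).  Family ids are assigned in the cluster set's canonical order.

    Raises
    ------
    ValueError
        If a protein's genome is missing from ``genome_order`` or a protein
        has no genome mapping at all.
    """
    gidx = {g: i for i, g in enumerate(genome_order)}
    if len(gidx) != len(genome_order):
        raise ValueError("genome_order contains duplicates")
    rows = []
    ids = []
    width = max(7, len(str(len(cluster_set.clusters))))
    for c_i, cluster in enumerate(cluster_set.clusters):
        row = np.zeros(len(genome_order), dtype=bool)
        for pid in sorted(cluster):
            genome = cluster_set.genome_map.get(pid)
            if genome is None:
                raise ValueError(f"protein {pid!r} has no genome mapping")
            if genome not in gidx:
                raise ValueError(
                    f"genome {genome!r} of protein {pid!r} missing from genome order"
                )
            row[gidx[genome]] = True
        rows.append(row)
        ids.append(f"{family_prefix}{str(c_i).zfill(width)}")
    if rows:
        data = pd.DataFrame(np.vstack(rows), index=ids, columns=list(genome_order))
    else:
        data = pd.DataFrame(
            np.zeros((0, len(genome_order)), dtype=bool), columns=list(genome_order)
        )
    return PresenceAbsenceMatrix(data)


def write_cluster_tsv(
    cluster_set: OrthologClusterSet, genome_order: list[str], path
) -> None:
    """Write clusters in the orthogroups-TSV dialect.

    Header: ``Orthogroup`` then one column per genome; each cell is a
    comma-separated list of that genome's member proteins.
    """
    width = max(7, len(str(len(cluster_set.clusters))))
    with open(path, "w") as out:
        out.write("Orthogroup\t" + "\t".join(genome_order) + "\n")
        for c_i, cluster in enumerate(cluster_set.clusters):
            by_genome: dict[str, list[str]] = {g: [] for g in genome_order}
            for pid in sorted(cluster):
                genome = cluster_set.genome_map.get(pid)
                if genome not in by_genome:
                    raise ValueError(f"genome {genome!r} missing from genome order")
                by_genome[genome].append(pid)
            cells = [", ".join(by_genome[g]) for g in genome_order]
            out.write(f"OG{str(c_i).zfill(width)}\t" + "\t".join(cells) + "\n")


def read_cluster_tsv(path) -> OrthologClusterSet:
    """Read an orthogroups-style TSV back into an OrthologClusterSet."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genome_cols = list(df.columns[1:])
    clusters = []
    genome_map: dict[str, str] = {}
    for _, row in df.iterrows():
        members = set()
        for g in genome_cols:
            cell = row[g].strip()
            if not cell:
                continue
            for pid in cell.split(","):
                pid = pid.strip()
                if pid:
                    members.add(pid)
                    genome_map[pid] = g
        if members:
            clusters.append(frozenset(members))
    return OrthologClusterSet(clusters=clusters, genome_map=genome_map)
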