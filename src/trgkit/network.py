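"""Protein-interaction network analysis: degrees, Markov Clustering,
and hypergeometric enrichment of clusters and annotation sets.

MCL alternates expansion (matrix power) and inflation (entrywise power
with column renormalization) of a column-stochastic matrix built from the
adjacency plus self-loops, until the matrix stops changing.  Clusters are
read off the attractor structure of the limit matrix.  Only genes with at
least one interaction enter degree comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .stats import TestResult, bonferroni, hypergeom_tail, wilcoxon_rank_sum

DEFAULT_INFLATION = 1.5
DEFAULT_EXPANSION = 2
DEFAULT_PRUNE = 1e-5
DEFAULT_MAX_ITER = 200
MCL_CONV_TOL = 1e-8
#: paper rule "clusters with >30 members" read as >= 31
DEFAULT_MIN_CLUSTER_SIZE = 31

DEGREE_CONTRASTS = (("TRG-E", "TRG-NE"), ("TRG-E", "Shared-E"))


@dataclass
class ClusterAssignment:
    """A partition of network nodes, cluster ids dense from 1 by size."""

    labels: dict[str, int]
    clusters: list[set] = field(repr=False)
    inflation: float = DEFAULT_INFLATION
    expansion: int = DEFAULT_EXPANSION
    prune_below: float = DEFAULT_PRUNE
    iterations: int = 0
    converged: bool = True
    #: worst column-sum deviation from 1 seen after any renormalization
    max_column_error: float = 0.0

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


def degree_compare(graph: nx.Graph, classes: pd.DataFrame,
                   contrasts=DEGREE_CONTRASTS
                   ) -> tuple[dict[str, np.ndarray], dict[str, TestResult]]:
    """Per-class degree distributions and Wilcoxon contrasts.

    Degree counts distinct neighbors; only nodes with degree >= 1 that
    appear in the class table are considered.
    """
    cls = classes.set_index("gene")["four_class"]
    deg = {n: d for n, d in graph.degree() if d >= 1 and n in cls.index}
    if not deg:
        raise ValueError("no network node matches the class table")
    per_class: dict[str, list] = {}
    for n, d in deg.items():
        per_class.setdefault(cls[n], []).append(d)
    arrays = {c: np.array(v, dtype=float) for c, v in per_class.items()}
    tests = {}
    for a, b in contrasts:
        for name in (a, b):
            if name not in arrays:
                raise ValueError(f"class {name} has no nodes in the network")
        tests[f"{a}_vs_{b}"] = wilcoxon_rank_sum(arrays[a], arrays[b])
    return arrays, tests


def _extract_clusters(m: np.ndarray, nodes: list[str]) -> list[set]:
    """Read clusters from a converged MCL matrix.

    Attractors are rows with positive diagonal mass; attractors whose rows
    overlap (they attract each other) are merged, then every node joins the
    attractor group holding the largest share of its column (ties to the
    lowest attractor index).  Nodes with no attractor mass become
    singletons.
    """
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > 0]
    parent = {i: i for i in attractors}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > 0 or m[j, i] > 0):
                union(i, j)
    groups: dict[int, set] = {}
    if attractors:
        arows = np.array(attractors)
        mass = m[arows, :]
        for col in range(n):
            cmass = mass[:, col]
            if cmass.max() > 0:
                root = find(int(arows[int(np.argmax(cmass))]))
            else:
                root = -col - 1  # orphan -> singleton
            groups.setdefault(root, set()).add(nodes[col])
    else:
        groups = {-c - 1: {nodes[c]} for c in range(n)}
    return sorted(groups.values(), key=lambda s: (-len(s), sorted(s)[0]))


def mcl_cluster(graph: nx.Graph, inflation: float = DEFAULT_INFLATION,
                expansion: int = DEFAULT_EXPANSION,
                prune_below: float = DEFAULT_PRUNE,
                max_iter: int = DEFAULT_MAX_ITER) -> ClusterAssignment:
    """Markov Clustering of an undirected graph.

    Self-loops of weight 1 are added, columns are normalized to stochastic,
    then expand (power ``expansion``) / inflate (entrywise power
    ``inflation``) / prune (zero entries < ``prune_below``) cycles run
    until the matrix changes by less than 1e-8 or ``max_iter`` is hit
    (non-convergence warns and returns the current state flagged).
    """
    if inflation <= 1:
        raise ValueError(f"inflation must exceed 1, got {inflation}")
    nodes = sorted(graph.nodes())
    if not nodes:
        raise ValueError("empty graph")
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(a, np.diag(a) + 1.0)

    def normalize(mat):
        mat /= mat.sum(axis=0, keepdims=True)
        return mat

    m = normalize(a)
    max_col_err = float(np.max(np.abs(m.sum(axis=0) - 1.0)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = normalize(np.power(m, inflation))
        if prune_below > 0:
            m[m < prune_below] = 0.0
            m = normalize(m)
        max_col_err = max(max_col_err,
                          float(np.max(np.abs(m.sum(axis=0) - 1.0))))
        if float(np.max(np.abs(m - prev))) < MCL_CONV_TOL:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge in {max_iter} iterations",
                      RuntimeWarning)
    clusters = _extract_clusters(m, nodes)
    labels = {g: cid for cid, members in enumerate(clusters, start=1)
              for g in members}
    return ClusterAssignment(labels=labels, clusters=clusters,
                             inflation=inflation, expansion=expansion,
                             prune_below=prune_below, iterations=it,
                             converged=converged,
                             max_column_error=max_col_err)


def enrich_clusters(assign: ClusterAssignment, annotated: set,
                    universe: set | None = None,
                    min_size: int = DEFAULT_MIN_CLUSTER_SIZE) -> pd.DataFrame:
    """Hypergeometric enrichment of the annotated set in each large cluster.

    Clusters of at least ``min_size`` members are tested; the Bonferroni
    factor is the number tested.  Universe defaults to all clustered nodes.
    """
    if universe is None:
        universe = set(assign.labels)
    annotated = set(annotated) & universe
    rows = []
    for cid, members in enumerate(assign.clusters, start=1):
        members = members & universe
        if len(members) < min_size:
            continue
        rows.append({
            "cluster_id": cid,
            "n": len(members),
            "k": len(members & annotated),
            "K": len(annotated),
            "N": len(universe),
        })
    if not rows:
        warnings.warn("no cluster reaches the minimum size", RuntimeWarning)
        return pd.DataFrame(columns=["cluster_id", "k", "n", "K", "N",
                                     "p_raw", "p_bonferroni", "m_tests"])
    df = pd.DataFrame(rows)
    df["p_raw"] = [hypergeom_tail(r.N, r.K, r.n, r.k)
                   for r in df.itertuples()]
    df["m_tests"] = len(df)
    df["p_bonferroni"] = bonferroni(df["p_raw"].to_numpy(), m=len(df))
    return df.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def enrich_sets(member_genes: set, annotations: dict[str, set],
                universe: set) -> pd.DataFrame:
    """Hypergeometric enrichment of annotation sets within a gene set.

    Tests each annotation's overlap with ``member_genes`` against draws
    from ``universe``; Bonferroni over the number of annotations tested.
    Annotations disjoint from the universe are skipped with a note.
    """
    member_genes = set(member_genes) & universe
    rows, skipped = [], []
    for sid in sorted(annotations):
        ann = set(annotations[sid]) & universe
        if not ann:
            skipped.append(sid)
            continue
        rows.append({"set_id": sid, "n": len(member_genes),
                     "k": len(member_genes & ann), "K": len(ann),
                     "N": len(universe)})
    if skipped:
        warnings.warn(f"annotations disjoint from universe skipped: "
                      f"{skipped[:5]}", RuntimeWarning)
    df = pd.DataFrame(rows)
    df["p_raw"] = [hypergeom_tail(r.N, r.K, r.n, r.k)
                   for r in df.itertuples()]
    df["m_tests"] = len(df)
    df["p_bonferroni"] = bonferroni(df["p_raw"].to_numpy(), m=len(df))
    return df.sort_values("p_raw", kind="mergesort").reset_index(drop=True)


def largest_essential_trg_component(graph: nx.Graph,
                                    classes: pd.DataFrame) -> nx.Graph:
    """Subgraph export: largest connected component among essential TRGs.

    A plain dump (TSV/GraphML-ready) of the neighborhood the paper-style
    figures draw; no layout is computed.
    """
    cls = classes.set_index("gene")["four_class"]
    trg_e = [n for n in graph.nodes if cls.get(n) == "TRG-E"]
    sub = graph.subgraph(trg_e)
    if sub.number_of_nodes() == 0:
        return nx.Graph()
    comp = max(nx.connected_components(sub), key=len)
    neighbors = set(comp)
    for n in comp:
        neighbors |= set(graph.neighbors(n))
    return graph.subgraph(neighbors).copy()
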