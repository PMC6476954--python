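"""Correlation networks over CGI methylation profiles and MCL clustering.

A node per CGI; an edge where the Pearson correlation of two methylation
profiles exceeds a threshold (default r > 0.85), weighted by r.  Clusters
come from the Markov Cluster algorithm: flow simulation on the
column-stochastic adjacency matrix alternating expansion (matrix power)
and inflation (entry-wise power with column renormalisation) until the
flow stabilises; clusters are read off the attractor rows.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd


def build_correlation_graph(
    meth_values: pd.DataFrame,
    r_min: float = 0.85,
    min_pairwise: int = 3,
) -> nx.Graph:
    """Graph of CGI methylation profiles with edges where r > ``r_min``.

    Correlations use pairwise-complete tissues; pairs with fewer than
    ``min_pairwise`` shared observations get no edge.  Isolated nodes are
    dropped.
    """
    if len(meth_values) < 2:
        raise ValueError("need at least 2 profiles")
    # rows are profiles: correlate across columns, pairwise-complete
    corr = meth_values.T.corr(min_periods=min_pairwise)
    arr = corr.to_numpy(dtype=float)
    np.fill_diagonal(arr, np.nan)
    ii, jj = np.where(np.triu(arr > r_min, k=1))
    graph = nx.Graph()
    ids = corr.index.to_numpy()
    for i, j in zip(ii, jj):
        graph.add_edge(ids[i], ids[j], weight=float(arr[i, j]))
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.3,
    expansion: int = 2,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[dict[Hashable, int], bool]:
    """Markov Cluster algorithm on a weighted undirected graph.

    Self-loops are added with weight equal to the node's maximum incident
    edge weight; the adjacency matrix is made column-stochastic and the
    expansion/inflation cycle iterates until the largest column change
    falls below ``tol`` or ``max_iter`` is hit (the latter returns the
    current interpretation with ``converged=False`` and a warning).
    Deterministic and invariant to node order; a node attracted to several
    clusters goes to the one with the larger flow mass, ties broken by
    smallest node id.

    Returns (labels, converged); labels number clusters 1..k in order of
    their smallest member node.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if u == v:
            continue
        m[index[u], index[v]] = w
        m[index[v], index[u]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0  # isolated node: unit self-loop
    m[np.diag_indices(n)] = loop

    m = m / m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        change = np.abs(inflated - m).max()
        m = inflated
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    # attractors: rows with positive diagonal flow; attractors connected
    # through residual flow belong to one attractor system
    attractors = np.flatnonzero(np.diag(m) > prune)
    if attractors.size == 0:
        # degenerate limit (periodic flow, no self-attraction): fall back to
        # connected components of the residual flow support
        support = nx.from_numpy_array((m + m.T) > prune)
        labels = {}
        comps = sorted(nx.connected_components(support), key=min)
        for lab, comp in enumerate(comps, start=1):
            for j in comp:
                labels[nodes[j]] = lab
        return labels, converged
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    attractor_set = set(int(a) for a in attractors)
    for a in attractors:
        for b in np.flatnonzero(m[a] > prune):
            if int(b) in attractor_set:
                ra, rb = find(int(a)), find(int(b))
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(int(a)), []).append(int(a))

    # assign every node to the attractor system with the largest flow mass;
    # ties resolve to the system containing the smallest attractor id because
    # argmax takes the first maximum and systems are ordered by root id
    roots = sorted(systems)
    mass = np.zeros((len(roots), n))
    for k_idx, root in enumerate(roots):
        mass[k_idx] = m[systems[root], :].sum(axis=0)
    assignment = mass.argmax(axis=0)
    labels_by_index = {j: int(assignment[j]) for j in range(n)}

    # renumber clusters 1..k by smallest member node
    by_system: dict[int, list[int]] = {}
    for j, s in labels_by_index.items():
        by_system.setdefault(s, []).append(j)
    ordered = sorted(by_system.values(), key=lambda js: min(js))
    labels: dict[Hashable, int] = {}
    for lab, js in enumerate(ordered, start=1):
        for j in js:
            labels[nodes[j]] = lab
    return labels, converged


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(
        (u, v, data.get("weight", 1.0)) if u <= v else (v, u, data.get("weight", 1.0))
        for u, v, data in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for _, row in df.iterrows():
        graph.add_edge(row["source"], row["target"], weight=float(row["weight"]))
    return graph


def write_clusters(labels: Mapping[Hashable, int], path: str | Path) -> None:
    rows = sorted(labels.items(), key=lambda kv: (kv[1], kv[0]))
    pd.DataFrame(rows, columns=["node", "cluster"]).to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path)
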