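"""Decomposable Gaussian graphical model learning.

The network over features (metabolites, genes, flux activities) is learned
in two sequential steps, with pairwise correlation as the associative
criterion throughout:

1. the maximum-likelihood spanning tree (Chow-Liu): for Gaussian data the
   likelihood gain of joining u and v is the mutual information
   ``-(n/2) ln(1 - r_uv^2)``, so the ML tree is the maximum-weight spanning
   tree under these weights;
2. greedy forward selection of additional edges, restricted to moves that
   preserve decomposability (chordality) and accepted only while they
   strictly reduce the Bayesian Information Criterion.

For a decomposable model the log-likelihood factorizes over maximal cliques
and separators, so the gain of adding edge (u, v) is local:
``-(n/2) ln(1 - rho^2)`` with rho the partial correlation of u and v given
the separator of the clique the new edge creates.  BIC counts 2p + |E|
parameters (means, variances, one free covariance per edge).

All tie-breaks are lexicographic on feature ids, making runs
bit-reproducible.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np

from .omics import OmicsMatrix

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)


class GgmError(ValueError):
    pass


# ----------------------------------------------------------------------
# Chordality via maximum cardinality search
# ----------------------------------------------------------------------

def mcs_order(graph: nx.Graph) -> list:
    """Maximum-cardinality-search vertex ordering (lexicographic tie-break)."""
    order: list = []
    weight = {v: 0 for v in graph.nodes}
    remaining = set(graph.nodes)
    while remaining:
        v = min(remaining, key=lambda u: (-weight[u], str(u)))
        order.append(v)
        remaining.discard(v)
        for w in graph.neighbors(v):
            if w in remaining:
                weight[w] += 1
    return order


def is_chordal_mcs(graph: nx.Graph) -> bool:
    """Chordality test: the reverse MCS order must be a perfect elimination order.

    Uses the Tarjan-Yannakakis check: for each vertex v, with S(v) its
    neighbours numbered before v and u the latest-numbered member of S(v),
    the graph is chordal iff S(v) \\ {u} is contained in the neighbourhood
    of u for every v.
    """
    order = mcs_order(graph)
    pos = {v: i for i, v in enumerate(order)}
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    for v in order:
        earlier = {w for w in adj[v] if pos[w] < pos[v]}
        if not earlier:
            continue
        u = max(earlier, key=lambda w: pos[w])
        if not (earlier - {u}) <= adj[u]:
            return False
    return True


# ----------------------------------------------------------------------
# Decomposable graph with clique / separator bookkeeping
# ----------------------------------------------------------------------

@dataclass
class DecomposableGraph:
    """Chordal graph over features with junction-tree bookkeeping.

    Cliques, separators and the junction tree are recomputed from the edge
    set on demand, so they are consistent by construction; chordality is
    enforced at creation and after every mutation.
    """

    graph: nx.Graph

    def __post_init__(self):
        if not is_chordal_mcs(self.graph):
            raise GgmError("graph is not chordal")

    # -- construction --------------------------------------------------
    @classmethod
    def from_edges(cls, vertices: Iterable, edges: Iterable[tuple]) -> "DecomposableGraph":
        g = nx.Graph()
        g.add_nodes_from(vertices)
        g.add_edges_from(edges)
        return cls(g)

    # -- basic queries --------------------------------------------------
    @property
    def vertices(self) -> list:
        return sorted(self.graph.nodes, key=str)

    @property
    def edges(self) -> list[tuple]:
        return sorted((tuple(sorted(e, key=str)) for e in self.graph.edges), key=lambda e: (str(e[0]), str(e[1])))

    def cliques(self) -> list[frozenset]:
        """Maximal cliques of the chordal graph."""
        if self.graph.number_of_nodes() == 0:
            return []
        out = set()
        for comp in nx.connected_components(self.graph):
            sub = self.graph.subgraph(comp)
            if sub.number_of_nodes() == 1:
                out.add(frozenset(comp))
            else:
                out |= {frozenset(c) for c in nx.chordal_graph_cliques(sub)}
        return sorted(out, key=lambda c: sorted(map(str, c)))

    def junction_tree(self) -> nx.Graph:
        """Maximum-weight spanning tree over cliques, weight = |intersection|.

        Satisfies the running-intersection property for chordal graphs.
        """
        cliques = self.cliques()
        jt = nx.Graph()
        jt.add_nodes_from(cliques)
        candidate_edges = []
        for i, ci in enumerate(cliques):
            for cj in cliques[i + 1:]:
                inter = ci & cj
                if inter:
                    candidate_edges.append((len(inter), ci, cj))
        # Kruskal on -|intersection| with deterministic order
        candidate_edges.sort(key=lambda t: (-t[0], sorted(map(str, t[1])), sorted(map(str, t[2]))))
        uf = {c: c for c in cliques}

        def find(x):
            while uf[x] != x:
                uf[x] = uf[uf[x]]
                x = uf[x]
            return x

        for w, ci, cj in candidate_edges:
            ri, rj = find(ci), find(cj)
            if ri != rj:
                uf[ri] = rj
                jt.add_edge(ci, cj, separator=ci & cj, weight=w)
        return jt

    def separators(self) -> list[frozenset]:
        """Separator multiset (one per junction-tree edge, with multiplicity)."""
        jt = self.junction_tree()
        seps = [frozenset(d["separator"]) for _, _, d in jt.edges(data=True)]
        return sorted(seps, key=lambda s: (len(s), sorted(map(str, s))))

    def check_running_intersection(self) -> bool:
        jt = self.junction_tree()
        for v in self.graph.nodes:
            containing = [c for c in jt.nodes if v in c]
            if len(containing) <= 1:
                continue
            if not nx.is_connected(jt.subgraph(containing)):
                return False
        return True

    # -- mutation -------------------------------------------------------
    def with_edge(self, u, v) -> "DecomposableGraph":
        g = self.graph.copy()
        g.add_edge(u, v)
        return DecomposableGraph(g)


# ----------------------------------------------------------------------
# Edge scores
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeScore:
    """Pairwise association of two features.

    ``weight`` is the Gaussian mutual-information log-likelihood gain
    ``-(n/2) ln(1 - r^2)`` in nats; it is nonnegative and zero iff r = 0.
    """

    u: str
    v: str
    pearson_r: float
    weight: float


def edge_weights(matrix: OmicsMatrix) -> list[EdgeScore]:
    """All-pairs Pearson correlations and tree weights.

    Requires a fully observed matrix with at least 3 samples; raises for
    zero-variance features (correlation undefined).
    """
    if not matrix.fully_observed:
        raise GgmError("edge weights require a fully observed matrix")
    n = matrix.n_samples
    if n < 3:
        raise GgmError("need at least 3 samples")
    X = matrix.values
    sds = X.std(axis=1)
    for f, sd in zip(matrix.feature_ids, sds):
        if sd == 0.0:
            raise GgmError(f"zero-variance feature {f!r}")
    R = np.corrcoef(X)
    scores = []
    ids = matrix.feature_ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(np.clip(R[i, j], -1.0, 1.0))
            r2 = min(r * r, 1.0 - 1e-15)
            w = -(n / 2.0) * math.log1p(-r2)
            scores.append(EdgeScore(ids[i], ids[j], r, w))
    return scores


def max_likelihood_tree(scores: Sequence[EdgeScore], vertices: Sequence[str] | None = None) -> DecomposableGraph:
    """Maximum-weight spanning tree (Kruskal), the Gaussian Chow-Liu tree.

    Ties are broken lexicographically on the (sorted) edge ids.  If the
    candidate set does not connect all vertices a forest is returned with a
    warning.
    """
    if vertices is None:
        vs = sorted({s.u for s in scores} | {s.v for s in scores})
    else:
        vs = list(vertices)
    ordered = sorted(scores, key=lambda s: (-s.weight, *sorted((str(s.u), str(s.v)))))
    parent = {v: v for v in vs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    g = nx.Graph()
    g.add_nodes_from(vs)
    for s in ordered:
        ru, rv = find(s.u), find(s.v)
        if ru != rv:
            parent[ru] = rv
            g.add_edge(s.u, s.v, weight=s.weight, pearson_r=s.pearson_r)
    if nx.number_connected_components(g) > 1:
        warnings.warn("candidate edge set is disconnected; returning a spanning forest")
    return DecomposableGraph(g)


# ----------------------------------------------------------------------
# Likelihood machinery
# ----------------------------------------------------------------------

def _marginal_loglik(cov: np.ndarray, idx: list[int], n: int) -> float:
    """Profile Gaussian log-likelihood of the saturated model on variables idx."""
    k = len(idx)
    if k == 0:
        return 0.0
    sub = cov[np.ix_(idx, idx)]
    sign, logdet = np.linalg.slogdet(sub)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular marginal covariance")
    return -(n / 2.0) * (k * LOG_2PI + logdet + k)


def decomposable_loglik(graph: DecomposableGraph, cov: np.ndarray,
                        feature_index: dict, n: int) -> float:
    """Exact Gaussian log-likelihood of a decomposable model.

    Factorizes over maximal cliques and separators:
    ``ll = sum_C ll(C) - sum_S ll(S)`` with saturated MLE marginals.
    """
    ll = 0.0
    for c in graph.cliques():
        ll += _marginal_loglik(cov, [feature_index[v] for v in c], n)
    for s in graph.separators():
        ll -= _marginal_loglik(cov, [feature_index[v] for v in s], n)
    return ll


def partial_correlation(cov: np.ndarray, i: int, j: int, given: list[int]) -> float:
    """Partial correlation of variables i, j given a conditioning set."""
    idx = [i, j] + list(given)
    sub = cov[np.ix_(idx, idx)]
    prec = np.linalg.inv(sub)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


@dataclass
class ModelScore:
    """One step of the stepwise trace: full-model likelihood and BIC."""

    loglik: float
    n_params: int  # 2p + |E|
    bic: float
    edge_added: tuple | None = None
    delta_bic: float = 0.0


def n_params(p: int, n_edges: int) -> int:
    return 2 * p + n_edges


def bic(loglik: float, p: int, n_edges: int, n: int) -> float:
    return -2.0 * loglik + n_params(p, n_edges) * math.log(n)


# ----------------------------------------------------------------------
# Candidate generation and stepwise selection
# ----------------------------------------------------------------------

def _bit_neighbors(adj: list[int], mask: int) -> Iterable[int]:
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def _separates(adj: list[int], u: int, v: int, blocked: int) -> bool:
    """True when ``blocked`` cuts every u-v path (bitmask BFS in G - blocked)."""
    target = 1 << v
    visited = 1 << u
    frontier = visited
    forbid = blocked | visited
    while frontier:
        reach = 0
        for w in _bit_neighbors(adj, frontier):
            reach |= adj[w]
        reach &= ~forbid
        if reach & target:
            return False
        visited |= reach
        forbid |= reach
        frontier = reach
    return True


def addable_edge_separator(adj: list[int], u: int, v: int) -> int | None:
    """Separator of the chordality-preserving addition (u, v), or None.

    For a chordal graph, adding the non-edge (u, v) keeps it chordal
    exactly when the common neighborhood T = N(u) & N(v) separates u from
    v; T is then complete (any two non-adjacent common neighbors would
    close a chordless 4-cycle through u and v) and is the separator of the
    new clique {u, v} | T.  Returns T as a bitmask, or None when the
    addition would break chordality.
    """
    T = adj[u] & adj[v]
    return T if _separates(adj, u, v, T) else None


def decomposability_preserving_candidates(graph: DecomposableGraph) -> set[tuple]:
    """Exactly the non-edges whose addition leaves the graph chordal."""
    vs = graph.vertices
    index = {x: i for i, x in enumerate(vs)}
    adj = [0] * len(vs)
    for a, b in graph.graph.edges:
        adj[index[a]] |= 1 << index[b]
        adj[index[b]] |= 1 << index[a]
    out = set()
    for i, u in enumerate(vs):
        for j in range(i + 1, len(vs)):
            if adj[i] >> j & 1:
                continue
            if addable_edge_separator(adj, i, j) is not None:
                out.add((u, vs[j]))
    return out


def stepwise_bic(
    tree: DecomposableGraph,
    matrix: OmicsMatrix,
    audit: Callable[[DecomposableGraph], None] | None = None,
) -> tuple[DecomposableGraph, list[ModelScore]]:
    """Greedy BIC forward selection over decomposability-preserving edges.

    Starting from the ML spanning tree, repeatedly add the candidate edge
    with the largest (strict) BIC reduction, where the likelihood gain is
    the local term ``-(n/2) ln(1 - rho^2)`` with rho the partial
    correlation of the endpoints given the new clique's separator; stop
    when no candidate reduces BIC.  Returns the final graph and the full
    score trace.  ``audit``, when given, is called with the graph after
    every accepted edge (used by validation harnesses).
    """
    if not matrix.fully_observed:
        raise GgmError("stepwise selection requires a fully observed matrix")
    ids = matrix.feature_ids
    feature_index = {f: i for i, f in enumerate(ids)}
    n = matrix.n_samples
    p = len(ids)
    X = matrix.values
    cov = np.atleast_2d(np.cov(X, bias=True))  # MLE covariance
    log_n = math.log(n)

    # internal vertex order: lexicographic on ids (deterministic tie-breaks)
    vs = sorted(ids)
    vindex = {f: i for i, f in enumerate(vs)}
    covx = cov[np.ix_([feature_index[f] for f in vs], [feature_index[f] for f in vs])]
    adj = [0] * p
    for a, b in tree.graph.edges:
        adj[vindex[a]] |= 1 << vindex[b]
        adj[vindex[b]] |= 1 << vindex[a]

    current = tree
    try:
        ll = decomposable_loglik(current, cov, feature_index, n)
    except np.linalg.LinAlgError:
        # exactly collinear features (e.g. duplicated layers) make the model
        # covariance singular; edge selection still works from the local
        # partial-correlation terms, the absolute likelihood trace does not
        logger.warning("singular model covariance: likelihood trace reported as nan")
        ll = math.nan
    trace = [ModelScore(ll, n_params(p, current.graph.number_of_edges()),
                        bic(ll, p, current.graph.number_of_edges(), n))]
    while True:
        best = None  # (delta_bic, i, j, delta_ll)
        for i in range(p):
            for j in range(i + 1, p):
                if adj[i] >> j & 1:
                    continue
                T = addable_edge_separator(adj, i, j)
                if T is None:
                    continue
                idx = [i, j] + list(_bit_neighbors(adj, T))
                sub = covx[np.ix_(idx, idx)]
                try:
                    prec = np.linalg.inv(sub)
                except np.linalg.LinAlgError:
                    logger.warning("singular separator covariance for (%s, %s); skipped",
                                   vs[i], vs[j])
                    continue
                rho = -prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1])
                rho2 = min(rho * rho, 1.0 - 1e-15)
                delta_ll = -(n / 2.0) * math.log1p(-rho2)
                delta_bic = -2.0 * delta_ll + log_n
                if delta_bic < 0 and (best is None or delta_bic < best[0] - 1e-12):
                    best = (delta_bic, i, j, delta_ll)
        if best is None:
            break
        delta_bic, i, j, delta_ll = best
        adj[i] |= 1 << j
        adj[j] |= 1 << i
        current = current.with_edge(vs[i], vs[j])
        if audit is not None:
            audit(current)
        ll += delta_ll
        trace.append(ModelScore(ll, n_params(p, current.graph.number_of_edges()),
                                bic(ll, p, current.graph.number_of_edges(), n),
                                edge_added=(vs[i], vs[j]), delta_bic=delta_bic))
    return current, trace


def learn_network(matrix: OmicsMatrix) -> tuple[DecomposableGraph, list[ModelScore]]:
    """Convenience: edge weights -> ML spanning tree -> stepwise BIC."""
    scores = edge_weights(matrix)
    tree = max_likelihood_tree(scores, vertices=matrix.feature_ids)
    return stepwise_bic(tree, matrix)


# ----------------------------------------------------------------------
# GraphML export
# ----------------------------------------------------------------------

def export_graphml(graph: DecomposableGraph, path,
                   node_attributes: dict | None = None) -> None:
    """Write GraphML with optional per-node attributes (branch id, function label)."""
    g = nx.Graph()
    g.add_nodes_from(graph.graph.nodes)
    g.add_edges_from(graph.graph.edges)
    if node_attributes:
        for attr, mapping in node_attributes.items():
            nx.set_node_attributes(g, {k: v for k, v in mapping.items() if k in g.nodes}, attr)
    nx.write_graphml(g, str(path))


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(str(path))


def export_edge_list(graph: DecomposableGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")
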