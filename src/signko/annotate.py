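"""Sign-consistency of physical networks and activation/suppression annotation.

A fully signed physical network is *sign-consistent* (balanced) when its
undirected form is defined (no antiparallel edge pair with contradicting
signs) and contains no cycle whose edge-sign product is negative.  Balance
is equivalent to the existence of a node 2-coloring sigma with every edge
sign equal to sigma(u)*sigma(v); the checker returns that coloring as a
certificate, or a negative cycle as a counterexample witness.

Two structural facts connect physical and functional networks: a
sign-consistent physical network can only generate sign-linear functional
networks (path signs telescope to products of endpoint labels), and
conversely any sign-linear functional network can be explained by signing
any connected covering topology with sigma(u)*sigma(v)
(:func:`construct_explaining_annotation`).

Annotation infers edge signs from knockout data alone: fit Boolean
assignments (or multi-group partitions) on the functional network many
times and let each run vote sigma(u)*sigma(v) — same group = activating,
different groups = suppressing — for every physical edge whose endpoints
carry data.  Votes use products of node labels, so the global +/- ambiguity
of each run cancels without aligning assignments across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

from .netio import (
    AnnotatedPhysicalNetwork,
    BooleanAssignment,
    FunctionalNetwork,
    GenePair,
    PhysicalEdge,
)
from .signcluster import (
    GenePartition,
    group_pair_sign_counts,
    predict_pair_cluster,
    run_partitions,
)
from .signlinear import _run_seeds, greedy_local_search, satisfied_fraction

__all__ = [
    "ConsistencyCertificate",
    "check_sign_consistency",
    "construct_explaining_annotation",
    "AnnotationResult",
    "annotate_edges",
    "annotate_edges_multigroup",
]


@dataclass(frozen=True)
class ConsistencyCertificate:
    """Outcome of a balance check, with a verifiable witness.

    If consistent, ``coloring`` maps every node to +/-1 such that each
    annotated edge satisfies sign = coloring(u)*coloring(v).  Otherwise
    ``witness_cycle`` lists the nodes of an undirected cycle (closed walk,
    first node repeated last) whose aggregate sign is -1.
    """

    consistent: bool
    coloring: Optional[dict] = None
    witness_cycle: Optional[tuple] = None


def _cycle_sign(cycle: Sequence[str], usigns: dict) -> int:
    prod = 1
    for a, b in zip(cycle, cycle[1:]):
        prod *= usigns[frozenset((a, b))]
    return prod


def check_sign_consistency(
    phys: AnnotatedPhysicalNetwork,
) -> ConsistencyCertificate:
    """Decide balance by parity propagation over the undirected form.

    Requires every edge to carry a sign; raises ValueError for unassigned
    signs or contradicting antiparallel signs (undirected form undefined).
    """
    usigns = phys.undirected_sign_map()
    for key, s in usigns.items():
        if s is None:
            raise ValueError(f"edge {set(key)} has no sign; annotate first")
    adj: dict[str, list] = {n: [] for n in phys.nodes}
    for key, s in usigns.items():
        a, b = tuple(key)
        adj[a].append((b, s))
        adj[b].append((a, s))
    color: dict[str, int] = {}
    parent: dict[str, Optional[str]] = {}
    for root in sorted(phys.nodes):
        if root in color:
            continue
        color[root] = 1
        parent[root] = None
        stack = [root]
        while stack:
            u = stack.pop()
            for v, s in adj[u]:
                want = color[u] * s
                if v not in color:
                    color[v] = want
                    parent[v] = u
                    stack.append(v)
                elif color[v] != want:
                    # negative cycle: u -> ... -> lca -> ... -> v -> u
                    cyc = _witness(u, v, parent)
                    assert _cycle_sign(cyc, usigns) == -1
                    return ConsistencyCertificate(False, witness_cycle=tuple(cyc))
    return ConsistencyCertificate(True, coloring=color)


def _witness(u: str, v: str, parent: dict) -> list:
    path_u = [u]
    while parent[path_u[-1]] is not None:
        path_u.append(parent[path_u[-1]])
    anc_u = {n: i for i, n in enumerate(path_u)}
    path_v = [v]
    while path_v[-1] not in anc_u:
        path_v.append(parent[path_v[-1]])
    lca = path_v[-1]
    cycle = path_u[: anc_u[lca] + 1] + list(reversed(path_v[:-1]))
    cycle.append(u)
    return cycle


def construct_explaining_annotation(
    func: FunctionalNetwork,
    sigma: BooleanAssignment,
    topology: Union[AnnotatedPhysicalNetwork, Sequence],
) -> AnnotatedPhysicalNetwork:
    """Sign a covering topology so it is balanced and explains ``func``.

    Requires ``sigma`` to explain the functional network exactly
    (satisfied fraction 1) and the topology to be connected over a node
    superset of the functional genes.  Every edge (u, v) receives
    sigma(u)*sigma(v) (auxiliary nodes get label +1), so every undirected
    path from a to b has aggregate sign sigma(a)*sigma(b) = s(a,b).
    """
    if not isinstance(topology, AnnotatedPhysicalNetwork):
        topology = AnnotatedPhysicalNetwork(topology)
    if satisfied_fraction(func, sigma) < 1.0:
        raise ValueError("assignment does not fully explain the functional network")
    missing = func.genes - topology.nodes
    if missing:
        raise ValueError(f"topology does not cover genes {sorted(missing)[:5]}")
    if not nx.is_connected(topology.undirected_graph()):
        raise ValueError("topology must be connected")
    full = {n: sigma.get(n, 1) for n in topology.nodes}
    return AnnotatedPhysicalNetwork(
        e.with_sign(full[e.source] * full[e.target]) for e in topology.edges
    )


@dataclass(frozen=True)
class AnnotationResult:
    """Annotated network plus per-edge consensus vote fractions."""

    network: AnnotatedPhysicalNetwork
    frac_activating: dict
    frac_suppressing: dict
    n_runs: int


def _consensus_annotation(
    phys: AnnotatedPhysicalNetwork,
    votes_per_run,
    n_runs: int,
    cutoff: float,
) -> AnnotationResult:
    if not 0.5 <= cutoff < 1:
        raise ValueError("cutoff must be in [0.5, 1)")
    frac_act: dict[GenePair, float] = {}
    frac_sup: dict[GenePair, float] = {}
    edges = []
    for e in phys.edges:
        key = (e.source, e.target)
        n_act = n_sup = 0
        for votes in votes_per_run:
            v = votes.get(key)
            if v == 1:
                n_act += 1
            elif v == -1:
                n_sup += 1
        fa, fs = n_act / n_runs, n_sup / n_runs
        frac_act[key] = fa
        frac_sup[key] = fs
        if fa > cutoff:
            sign = 1
        elif fs > cutoff:
            sign = -1
        else:
            sign = None
        edges.append(e.with_sign(sign))
    return AnnotationResult(
        AnnotatedPhysicalNetwork(edges), frac_act, frac_sup, n_runs
    )


def annotate_edges(
    phys: AnnotatedPhysicalNetwork,
    net: FunctionalNetwork,
    n_runs: int = 100,
    cutoff: float = 0.5,
    seed: int = 0,
) -> AnnotationResult:
    """Two-group annotation: per run, edge (u, v) votes sigma(u)*sigma(v).

    Edges whose endpoints are absent from the functional network, or lie in
    different undirected components of it (so their product is not pinned
    down by the data), abstain and come out unassigned unless the vote
    clears the cutoff.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results = [greedy_local_search(net, s) for s in _run_seeds(seed, n_runs)]
    votes_per_run = []
    for res in results:
        votes = {}
        for e in phys.edges:
            u, v = e.source, e.target
            if u in net.genes and v in net.genes and net.same_component(u, v):
                votes[(u, v)] = res.assignment[u] * res.assignment[v]
        votes_per_run.append(votes)
    return _consensus_annotation(phys, votes_per_run, n_runs, cutoff)


def annotate_edges_multigroup(
    phys: AnnotatedPhysicalNetwork,
    net: FunctionalNetwork,
    n_runs: int = 100,
    cutoff: float = 0.5,
    p0: float = 0.05,
    seed: int = 0,
    p_fail: Optional[float] = None,
) -> AnnotationResult:
    """Multi-group annotation via sign-clustering partitions.

    Per run, edge (u, v) votes the majority functional sign observed
    between the groups of u and v (both directions pooled); no evidence or
    a tie abstains.  On sign-linear data with a two-group partition this
    coincides with :func:`annotate_edges` since all between-group signs
    equal the product of the group labels.
    """
    parts = run_partitions(net, n_runs, p0, seed, p_fail)
    votes_per_run = []
    for part in parts:
        counts = group_pair_sign_counts(net, part)
        votes = {}
        for e in phys.edges:
            u, v = e.source, e.target
            gu = part.group_of.get(u)
            gv = part.group_of.get(v)
            if gu is None or gv is None:
                continue
            # pool both directions between the two groups
            p1, n1 = counts.get((gu, gv), (0, 0))
            if gu != gv:
                p2, n2 = counts.get((gv, gu), (0, 0))
            else:
                p2 = n2 = 0
            pos, neg = p1 + p2, n1 + n2
            if pos > neg:
                votes[(u, v)] = 1
            elif neg > pos:
                votes[(u, v)] = -1
        votes_per_run.append(votes)
    return _consensus_annotation(phys, votes_per_run, n_runs, cutoff)
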