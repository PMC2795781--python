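"""Sign-clustering: multi-group partitions from binomial functional similarity.

The sign-linear model's two groups are sometimes too coarse — signaling
pathways whose members up-regulate each other upon knockout cannot be
captured by any Boolean assignment.  Sign-clustering generalizes to an
arbitrary number of groups: genes are clustered by how similarly they act
in the knockout data, and a hidden effect of u on v is predicted by a
majority vote over the observed effects of u's group on v's group.

Similarity of a gene pair (u, v) pools two evidence sets: common upstream
knockouts (genes whose deletion affected both u and v) and common
downstream targets (genes affected by deleting u and by deleting v).  Each
common neighbor is a Bernoulli trial; a *failure* is a trial where the two
genes behaved differently (unequal signs).  The score is the binomial CDF
P(X <= k_failures | n_trials, p_fail): small scores mean fewer failures
than chance.  The chance failure probability defaults to 2q(1-q), the
probability that two independent edges with P(+)=q carry different signs,
where q is the network's '+' frequency.

Groups come from complete-linkage agglomeration: merge the cluster pair
with the smallest complete-linkage score (the maximum pairwise score
between the clusters) while that score stays below the a-priori similarity
probability p0; pairs with no shared evidence score 1 and thus never drive
a merge.  Ties in merge selection are broken by a gene ordering, which is
the only stochastic element — consensus runs redraw the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import binom

from .netio import (
    ConsensusPrediction,
    FunctionalNetwork,
    GenePair,
    resolve_call,
)

__all__ = [
    "SimilarityScore",
    "GenePartition",
    "pairwise_similarity",
    "default_p_fail",
    "similarity_matrix",
    "complete_linkage",
    "predict_pair_cluster",
    "consensus_cluster_predict",
    "consensus_partition",
]


@dataclass(frozen=True)
class SimilarityScore:
    gene_u: str
    gene_v: str
    n_trials: int
    k_failures: int
    score: float


@dataclass(frozen=True)
class GenePartition:
    """A partition of (a subset of) the genes into disjoint groups."""

    group_of: Mapping[str, int]
    groups: tuple[frozenset, ...]

    @classmethod
    def from_groups(cls, groups: Sequence[frozenset]) -> "GenePartition":
        mapping: dict[str, int] = {}
        for i, grp in enumerate(groups):
            for g in grp:
                if g in mapping:
                    raise ValueError(f"gene {g!r} in more than one group")
                mapping[g] = i
        return cls(mapping, tuple(frozenset(g) for g in groups))

    @classmethod
    def from_labels(cls, labels: Mapping[str, int]) -> "GenePartition":
        by_label: dict[int, set] = {}
        for g, lab in labels.items():
            by_label.setdefault(lab, set()).add(g)
        groups = [frozenset(by_label[k]) for k in sorted(by_label)]
        return cls.from_groups(groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def default_p_fail(net: FunctionalNetwork) -> float:
    """Chance failure probability 2q(1-q), q = '+' frequency in the network."""
    q = net.positive_fraction()
    if q in (0.0, 1.0):
        raise ValueError("degenerate sign distribution (all edges same sign)")
    return 2.0 * q * (1.0 - q)


def pairwise_similarity(
    net: FunctionalNetwork, u: str, v: str, p_fail: float
) -> SimilarityScore:
    """Binomial-CDF functional similarity of two genes.

    Trials are common upstream knockouts plus common downstream targets; a
    gene in both evidence sets contributes two trials.  No shared evidence
    gives score 1 (no support for similarity).
    """
    if u == v:
        raise ValueError("similarity is defined for distinct genes")
    if not 0 < p_fail < 1:
        raise ValueError("p_fail must be in (0, 1)")
    signs = net.edge_signs
    n_trials = 0
    agreements = 0
    for g in net.ko_genes:
        su, sv = signs.get((g, u)), signs.get((g, v))
        if su is not None and sv is not None:
            n_trials += 1
            agreements += su == sv
    targets_u = {t: s for (a, t), s in signs.items() if a == u}
    for (a, t), sv in signs.items():
        if a == v and t in targets_u:
            n_trials += 1
            agreements += targets_u[t] == sv
    k_failures = n_trials - agreements
    if n_trials == 0:
        score = 1.0
    else:
        score = float(binom.cdf(k_failures, n_trials, p_fail))
    return SimilarityScore(u, v, n_trials, k_failures, score)


def similarity_matrix(
    net: FunctionalNetwork,
    genes: Sequence[str],
    p_fail: Optional[float] = None,
) -> np.ndarray:
    """All-pairs similarity scores, aligned to ``genes``; diagonal is 0.

    Vectorized equivalent of :func:`pairwise_similarity` over every pair.
    """
    if p_fail is None:
        p_fail = default_p_fail(net)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    m = np.zeros((n, n), dtype=np.int8)  # signed adjacency, 0 = no edge
    for (u, v), s in net.edge_signs.items():
        if u in idx and v in idx:
            m[idx[u], idx[v]] = s
    a = np.abs(m).astype(np.int32)
    ms = m.astype(np.int32)
    # downstream: common targets of u and v  -> rows;  upstream: columns
    trials = a @ a.T + a.T @ a
    agree = (trials + ms @ ms.T + ms.T @ ms) // 2
    fails = trials - agree
    scores = np.where(trials > 0, binom.cdf(fails, np.maximum(trials, 1), p_fail), 1.0)
    np.fill_diagonal(scores, 0.0)
    return scores


def _scores_as_matrix(
    scores: Union[np.ndarray, Mapping],
    gene_order: Sequence[str],
) -> np.ndarray:
    n = len(gene_order)
    if isinstance(scores, np.ndarray):
        if scores.shape != (n, n):
            raise ValueError("score matrix shape does not match gene_order")
        return scores
    idx = {g: i for i, g in enumerate(gene_order)}
    mat = np.ones((n, n), dtype=float)
    for key, val in scores.items():
        if isinstance(val, SimilarityScore):
            u, v, sc = val.gene_u, val.gene_v, val.score
        else:
            (u, v), sc = key, float(val)
        if u in idx and v in idx:
            mat[idx[u], idx[v]] = sc
            mat[idx[v], idx[u]] = sc
    np.fill_diagonal(mat, 0.0)
    return mat


def complete_linkage(
    scores: Union[np.ndarray, Mapping],
    gene_order: Sequence[str],
    p0: float,
) -> GenePartition:
    """Agglomerative complete-linkage clustering cut at merge score p0.

    ``scores`` is either an (n, n) array aligned to ``gene_order`` (as from
    :func:`similarity_matrix` with a permuted gene list) or a mapping of
    pairs / SimilarityScore records; missing pairs score 1.  At each step
    the cluster pair with the minimal complete-linkage score (maximum
    pairwise score across the two clusters) is merged, provided that score
    is below ``p0``; merging stops when no pair qualifies, which yields the
    maximal dendrogram subtrees below the p0 cut.  Ties in merge selection
    are broken toward clusters earlier in ``gene_order``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    n = len(gene_order)
    if n == 0:
        return GenePartition({}, ())
    if isinstance(scores, np.ndarray) and scores.shape == (n, n):
        # re-permute is the caller's job: matrix must be aligned to gene_order
        d = scores.astype(float).copy()
    else:
        d = _scores_as_matrix(scores, gene_order)
    members: dict[int, set] = {i: {gene_order[i]} for i in range(n)}
    active = np.ones(n, dtype=bool)
    big = 2.0  # > any score
    d = d.copy()
    np.fill_diagonal(d, big)
    while True:
        alive = np.flatnonzero(active)
        if len(alive) < 2:
            break
        sub = d[np.ix_(alive, alive)]
        best = sub.min()
        if best >= p0:
            break
        # tie-break: smallest (i, j) in gene_order position among minima
        ii, jj = np.nonzero(sub == best)
        pairs = sorted(
            (int(alive[a]), int(alive[b])) for a, b in zip(ii, jj) if a < b
        )
        i, j = pairs[0]
        # complete linkage: merged cluster's score to others = elementwise max
        merged = np.maximum(d[i], d[j])
        d[i, :] = merged
        d[:, i] = merged
        d[i, i] = big
        active[j] = False
        d[j, :] = big
        d[:, j] = big
        members[i] |= members.pop(j)
    groups = [frozenset(members[i]) for i in sorted(members) if active[i]]
    return GenePartition.from_groups(groups)


def predict_pair_cluster(
    net: FunctionalNetwork,
    part: GenePartition,
    u: str,
    v: str,
    exclude: Optional[GenePair] = None,
) -> str:
    """Group-majority prediction of the knockout effect of u on v.

    Evidence is every observed edge from u's group to v's group (minus the
    held-out ``exclude`` pair).  A strict majority of +1 signs predicts
    'down', of -1 signs 'up'; empty or tied evidence is 'undecided', as is
    a gene not assigned to any group.
    """
    gu = part.group_of.get(u)
    gv = part.group_of.get(v)
    if gu is None or gv is None:
        return "undecided"
    group_u = part.groups[gu]
    group_v = part.groups[gv]
    pos = neg = 0
    for (a, b), s in net.edge_signs.items():
        if (a, b) == exclude:
            continue
        if a in group_u and b in group_v:
            if s == 1:
                pos += 1
            else:
                neg += 1
    if pos > neg:
        return "down"
    if neg > pos:
        return "up"
    return "undecided"


def group_pair_sign_counts(
    net: FunctionalNetwork, part: GenePartition
) -> dict[tuple[int, int], tuple[int, int]]:
    """(#+1, #-1) observed edge signs per ordered group pair (one edge scan)."""
    counts: dict[tuple[int, int], list[int]] = {}
    gof = part.group_of
    for (a, b), s in net.edge_signs.items():
        ga = gof.get(a)
        gb = gof.get(b)
        if ga is None or gb is None:
            continue
        c = counts.setdefault((ga, gb), [0, 0])
        c[0 if s == 1 else 1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def _order_seeds(seed: int, n_runs: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n_runs)]


def run_partitions(
    net: FunctionalNetwork,
    n_runs: int,
    p0: float,
    seed: int,
    p_fail: Optional[float] = None,
) -> list[GenePartition]:
    """One complete-linkage partition per random gene ordering."""
    genes = sorted(net.genes)
    scores = similarity_matrix(net, genes, p_fail)
    parts = []
    for rng in _order_seeds(seed, n_runs):
        perm = rng.permutation(len(genes))
        order = [genes[i] for i in perm]
        mat = scores[np.ix_(perm, perm)]
        parts.append(complete_linkage(mat, order, p0))
    return parts


def consensus_cluster_predict(
    net: FunctionalNetwork,
    pairs: Sequence[GenePair],
    n_runs: int = 100,
    cutoff: float = 0.5,
    p0: float = 0.05,
    seed: int = 0,
    p_fail: Optional[float] = None,
    exclude_self: bool = False,
) -> list[ConsensusPrediction]:
    """Consensus over random-ordering clustering runs.

    Each run re-clusters under a fresh gene ordering (scores themselves are
    order-independent; only merge tie-breaks vary) and casts a group-majority
    vote per pair; undecided votes abstain but stay in the denominator.
    With ``exclude_self`` the queried pair's own edge, if present, is
    removed from its evidence.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    parts = run_partitions(net, n_runs, p0, seed, p_fail)
    counts = [group_pair_sign_counts(net, part) for part in parts]
    preds = []
    for (u, v) in pairs:
        n_down = n_up = 0
        excl_sign = net.edge_signs.get((u, v)) if exclude_self else None
        for part, cnt in zip(parts, counts):
            gu = part.group_of.get(u)
            gv = part.group_of.get(v)
            if gu is None or gv is None:
                continue
            pos, neg = cnt.get((gu, gv), (0, 0))
            if excl_sign == 1:
                pos -= 1
            elif excl_sign == -1:
                neg -= 1
            if pos > neg:
                n_down += 1
            elif neg > pos:
                n_up += 1
        frac_down = n_down / n_runs
        frac_up = n_up / n_runs
        preds.append(
            ConsensusPrediction(
                u, v, frac_down, frac_up, n_runs,
                resolve_call(frac_down, frac_up, cutoff),
            )
        )
    return preds


def consensus_partition(
    net: FunctionalNetwork,
    n_runs: int = 100,
    p0: float = 0.05,
    seed: int = 0,
    p_fail: Optional[float] = None,
    co_cluster_cutoff: float = 0.5,
) -> GenePartition:
    """Majority co-membership partition across clustering runs.

    Two genes end up in the same consensus group when they co-cluster in
    more than ``co_cluster_cutoff`` of the runs (connected components of
    the majority co-clustering graph).
    """
    genes = sorted(net.genes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    counts = np.zeros((n, n), dtype=np.int32)
    for part in run_partitions(net, n_runs, p0, seed, p_fail):
        for grp in part.groups:
            ids = [idx[g] for g in grp]
            counts[np.ix_(ids, ids)] += 1
    majority = counts > co_cluster_cutoff * n_runs
    np.fill_diagonal(majority, True)
    # connected components of the majority graph
    label = {}
    next_label = 0
    for i in range(n):
        if genes[i] in label:
            continue
        stack = [i]
        label[genes[i]] = next_label
        while stack:
            a = stack.pop()
            for b in np.flatnonzero(majority[a]):
                if genes[b] not in label:
                    label[genes[b]] = next_label
                    stack.append(int(b))
        next_label += 1
    return GenePartition.from_labels(label)
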