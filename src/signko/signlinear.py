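"""Sign-linear model fitting by greedy local search (MAX-E2-LIN2).

A functional network is *sign-linear* if there is a Boolean assignment
sigma: genes -> {+1, -1} such that every edge sign equals the product
sigma(u) * sigma(v).  Equivalently, the genes split into two groups with
down-regulation (+1) edges within groups and up-regulation (-1) edges
between them.  In general no perfect assignment exists; fitting maximizes
the number of satisfied edges, the MAX-E2-LIN2 problem, which is NP-hard.

The solver here is a randomized greedy local search: start from a uniform
random assignment, repeatedly sweep the genes in random order and flip any
gene whose flip strictly increases the satisfied-edge count, and stop after
a full sweep with no accepted flip.  The satisfied count strictly increases
at every accepted flip and is bounded by the edge count, so termination is
guaranteed and the result is a strict local maximum.  Because the global
sign flip sigma -> -sigma leaves all products invariant, predictions are
made from products sigma(u)*sigma(v), which are negation-free.

Consensus prediction repeats the search from independent seeds and votes;
individual runs can stall in non-global local maxima (e.g. on balanced
cycles), which the vote fraction exposes and the decision cutoff filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .netio import (
    BooleanAssignment,
    ConsensusPrediction,
    FunctionalNetwork,
    GenePair,
    SIGN_TO_EFFECT,
    resolve_call,
)

__all__ = [
    "LocalSearchResult",
    "satisfied_fraction",
    "greedy_local_search",
    "is_local_maximum",
    "brute_force_optimum",
    "predict_pair",
    "consensus_predict",
]


@dataclass(frozen=True)
class LocalSearchResult:
    """A local maximum of the sign-linear objective."""

    assignment: dict
    satisfied_fraction: float
    n_flips: int
    seed: int


def _edge_arrays(net: FunctionalNetwork, genes: Sequence[str]):
    idx = {g: i for i, g in enumerate(genes)}
    iu = np.empty(net.n_edges, dtype=np.int64)
    iv = np.empty(net.n_edges, dtype=np.int64)
    s = np.empty(net.n_edges, dtype=np.int8)
    for k, ((u, v), sign) in enumerate(sorted(net.edge_signs.items())):
        iu[k], iv[k], s[k] = idx[u], idx[v], sign
    return iu, iv, s


def satisfied_fraction(net: FunctionalNetwork, sigma: BooleanAssignment) -> float:
    """Fraction of edges (u,v) with s(u,v) = sigma(u)*sigma(v)."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    missing = net.genes - set(sigma)
    if missing:
        raise ValueError(f"assignment is partial; missing {sorted(missing)[:5]}")
    sat = sum(
        1
        for (u, v), s in net.edge_signs.items()
        if sigma[u] * sigma[v] == s
    )
    return sat / net.n_edges


def greedy_local_search(net: FunctionalNetwork, seed: int) -> LocalSearchResult:
    """Randomized greedy ascent to a strict local maximum.

    Deterministic given ``seed``: the seed drives both the initial
    assignment (i.i.d. uniform on +/-1) and the per-sweep gene order.
    """
    if net.n_edges == 0:
        raise ValueError("cannot fit an empty network")
    genes = sorted(net.genes)
    n = len(genes)
    iu, iv, s = _edge_arrays(net, genes)
    # incident edge ids per gene
    incident: list[list[int]] = [[] for _ in range(n)]
    for k in range(net.n_edges):
        incident[iu[k]].append(k)
        incident[iv[k]].append(k)

    rng = np.random.default_rng(seed)
    sigma = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
    sat = (sigma[iu] * sigma[iv] == s)
    n_flips = 0
    improved = True
    while improved:
        improved = False
        for g in rng.permutation(n):
            inc = incident[g]
            # flipping g toggles satisfaction of every incident edge
            delta = sum(1 if not sat[k] else -1 for k in inc)
            if delta > 0:
                sigma[g] = -sigma[g]
                for k in inc:
                    sat[k] = not sat[k]
                n_flips += 1
                improved = True
    frac = float(np.count_nonzero(sat)) / net.n_edges
    assignment = {g: int(sigma[i]) for i, g in enumerate(genes)}
    return LocalSearchResult(assignment, frac, n_flips, int(seed))


def is_local_maximum(net: FunctionalNetwork, sigma: BooleanAssignment) -> bool:
    """Certificate check: no single gene flip strictly increases the score."""
    genes = sorted(net.genes)
    iu, iv, s = _edge_arrays(net, genes)
    vec = np.array([sigma[g] for g in genes], dtype=np.int8)
    sat = (vec[iu] * vec[iv] == s)
    for g in range(len(genes)):
        mask = (iu == g) | (iv == g)
        delta = int(np.count_nonzero(~sat[mask])) - int(np.count_nonzero(sat[mask]))
        if delta > 0:
            return False
    return True


def brute_force_optimum(
    net: FunctionalNetwork, max_genes: int = 20
) -> tuple[dict, float]:
    """Exhaustive maximum of satisfied_fraction over all assignments.

    Fixes the first gene to +1 (global negation symmetry) and enumerates
    the remaining 2^(n-1) assignments.  Test oracle for the heuristic;
    refuses networks with more than ``max_genes`` genes.
    """
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    genes = sorted(net.genes)
    n = len(genes)
    if n > max_genes:
        raise ValueError(f"too many genes for brute force ({n} > {max_genes})")
    iu, iv, s = _edge_arrays(net, genes)
    best_sat = -1
    best_code = 0
    total = 1 << (n - 1)
    chunk = 1 << 16
    shifts = np.arange(n - 1, dtype=np.uint32)
    for start in range(0, total, chunk):
        codes = np.arange(start, min(start + chunk, total), dtype=np.uint32)
        bits = (codes[:, None] >> shifts) & 1
        sigma = np.empty((len(codes), n), dtype=np.int8)
        sigma[:, 0] = 1
        sigma[:, 1:] = 1 - 2 * bits.astype(np.int8)
        sat = (sigma[:, iu] * sigma[:, iv] == s).sum(axis=1)
        k = int(np.argmax(sat))
        if int(sat[k]) > best_sat:
            best_sat = int(sat[k])
            best_code = start + k
    sigma = {genes[0]: 1}
    for i in range(1, n):
        sigma[genes[i]] = 1 - 2 * ((best_code >> (i - 1)) & 1)
    return sigma, best_sat / net.n_edges


def predict_pair(sigma: BooleanAssignment, u: str, v: str) -> str:
    """Predicted knockout effect for the hidden pair (u, v).

    The predicted functional sign is sigma(u)*sigma(v); the effect call is
    its complement ('down' for +1, 'up' for -1).  Raises KeyError if either
    gene is unassigned; callers abstain for cross-component pairs.
    """
    return SIGN_TO_EFFECT[sigma[u] * sigma[v]]


def _run_seeds(seed: int, n_runs: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]


def consensus_predict(
    net: FunctionalNetwork,
    pairs: Sequence[GenePair],
    n_runs: int = 100,
    cutoff: float = 0.5,
    seed: int = 0,
    return_results: bool = False,
):
    """Multi-restart consensus prediction of knockout effects.

    Runs ``n_runs`` independent local searches (seeds derived from the
    master seed) and, per queried pair, reports the fraction of runs voting
    down/up.  Pairs whose genes are absent from the network or lie in
    different undirected components abstain in every run; abstentions keep
    ``n_runs`` as the denominator.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0.5 <= cutoff < 1:
        raise ValueError("cutoff must be in [0.5, 1)")
    results = [greedy_local_search(net, s) for s in _run_seeds(seed, n_runs)]
    preds = []
    for (u, v) in pairs:
        votable = (
            u in net.genes and v in net.genes and net.same_component(u, v)
        )
        n_down = 0
        n_up = 0
        if votable:
            for res in results:
                if res.assignment[u] * res.assignment[v] == 1:
                    n_down += 1
                else:
                    n_up += 1
        frac_down = n_down / n_runs
        frac_up = n_up / n_runs
        preds.append(
            ConsensusPrediction(
                u, v, frac_down, frac_up, n_runs,
                resolve_call(frac_down, frac_up, cutoff),
            )
        )
    if return_results:
        return preds, results
    return preds
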