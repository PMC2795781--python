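"""Cross-validation, accuracy/coverage metrics and robustness protocols.

Two quality measures are used throughout: *accuracy*, the fraction of
correct predictions among predictions made, and *coverage*, the fraction
of all evaluated knockout pairs that were predicted correctly; by
construction coverage = accuracy x (predicted / evaluated).

Cross-validation hides disjoint folds of knockout pairs, refits on the
remainder and scores consensus predictions of the hidden pairs against
their observed signs.  Genes appearing only in hidden edges drop out of
the training network and their pairs become abstentions.  The noise
protocol flips a fixed fraction of input signs and measures call
consistency between the clean and perturbed analyses over pairs decided
in both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .netio import (
    ConsensusPrediction,
    FunctionalNetwork,
    GenePair,
    SIGN_TO_EFFECT,
    resolve_call,
)
from .signcluster import GenePartition, consensus_cluster_predict
from .signlinear import consensus_predict

__all__ = [
    "EvalResult",
    "score_predictions",
    "cross_validate",
    "accuracy_coverage_curve",
    "noise_robustness",
    "prediction_stability",
    "partition_agreement",
]


@dataclass(frozen=True)
class EvalResult:
    """Accuracy/coverage of one batch of scored predictions.

    ``accuracy`` is NaN when no prediction was made.
    """

    n_pairs: int
    n_predicted: int
    n_correct: int
    cutoff: float

    @property
    def accuracy(self) -> float:
        if self.n_predicted == 0:
            return math.nan
        return self.n_correct / self.n_predicted

    @property
    def coverage(self) -> float:
        if self.n_pairs == 0:
            return math.nan
        return self.n_correct / self.n_pairs

    @property
    def prediction_rate(self) -> float:
        if self.n_pairs == 0:
            return math.nan
        return self.n_predicted / self.n_pairs


ScoredPrediction = tuple[ConsensusPrediction, str]  # (prediction, true effect)


def score_predictions(
    scored: Sequence[ScoredPrediction], cutoff: Optional[float] = None
) -> EvalResult:
    """EvalResult from (prediction, true effect) pairs.

    With ``cutoff`` given, calls are re-resolved from the stored vote
    fractions at that cutoff (used for accuracy/coverage curves);
    otherwise each prediction's own call is scored.
    """
    n_pred = n_corr = 0
    used_cutoff = cutoff
    for pred, truth in scored:
        if cutoff is None:
            call = pred.call
        else:
            call = resolve_call(pred.frac_down, pred.frac_up, cutoff)
        if call != "undecided":
            n_pred += 1
            n_corr += call == truth
    if used_cutoff is None:
        used_cutoff = 0.5
    return EvalResult(len(scored), n_pred, n_corr, used_cutoff)


def _predict(
    net: FunctionalNetwork,
    pairs: Sequence[GenePair],
    algorithm: str,
    n_runs: int,
    cutoff: float,
    seed: int,
    p0: float,
    p_fail: Optional[float],
) -> list[ConsensusPrediction]:
    if net.n_edges == 0:
        return [
            ConsensusPrediction(u, v, 0.0, 0.0, n_runs, "undecided")
            for (u, v) in pairs
        ]
    if algorithm == "linear":
        return consensus_predict(net, pairs, n_runs=n_runs, cutoff=cutoff, seed=seed)
    if algorithm == "cluster":
        return consensus_cluster_predict(
            net, pairs, n_runs=n_runs, cutoff=cutoff, p0=p0, seed=seed, p_fail=p_fail
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def cross_validate(
    net: FunctionalNetwork,
    algorithm: str = "linear",
    holdout_size: int = 1,
    n_folds: Optional[int] = None,
    n_runs: int = 100,
    cutoff: float = 0.5,
    seed: int = 0,
    p0: float = 0.05,
    p_fail: Optional[float] = None,
) -> tuple[list[EvalResult], EvalResult, list[ScoredPrediction]]:
    """Hidden-fold cross-validation of either prediction algorithm.

    Edges are shuffled once and partitioned into disjoint folds of
    ``holdout_size`` (a final smaller fold covers the remainder);
    ``n_folds`` caps how many folds are evaluated.  Truth for a hidden
    pair is its observed sign in ``net``.  Returns per-fold results, the
    pooled result, and the scored predictions for curve analysis.
    """
    m = net.n_edges
    if holdout_size >= m:
        raise ValueError("holdout_size must be smaller than the edge count")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(17,))
    rng = np.random.default_rng(ss)
    pairs = sorted(net.edge_signs)
    order = [pairs[int(i)] for i in rng.permutation(m)]
    folds = [order[i : i + holdout_size] for i in range(0, m, holdout_size)]
    if n_folds is not None:
        folds = folds[:n_folds]
    fold_results = []
    scored_all: list[ScoredPrediction] = []
    for k, hidden in enumerate(folds):
        train = net.without_edges(hidden)
        fold_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(18, k))
            .generate_state(1)[0] % (2**31)
        )
        preds = _predict(
            train, hidden, algorithm, n_runs, cutoff, fold_seed, p0, p_fail
        )
        scored = [
            (pred, SIGN_TO_EFFECT[net.sign(u, v)])
            for pred, (u, v) in zip(preds, hidden)
        ]
        fold_results.append(score_predictions(scored, cutoff))
        scored_all.extend(scored)
    pooled = score_predictions(scored_all, cutoff)
    return fold_results, pooled, scored_all


def accuracy_coverage_curve(
    scored: Sequence[ScoredPrediction], cutoffs: Sequence[float]
) -> list[EvalResult]:
    """Re-threshold stored vote fractions along an ascending cutoff grid."""
    if list(cutoffs) != sorted(cutoffs):
        raise ValueError("cutoff grid must be ascending")
    return [score_predictions(scored, c) for c in cutoffs]


def noise_robustness(
    net: FunctionalNetwork,
    algorithm: str = "linear",
    flip_rates: Sequence[float] = (0.05, 0.10, 0.15),
    n_runs: int = 100,
    cutoff: float = 0.5,
    seed: int = 0,
    p0: float = 0.05,
    p_fail: Optional[float] = None,
) -> dict:
    """Call consistency between clean and sign-perturbed analyses.

    For each rate, round(rate * n_edges) edge signs are flipped and all
    observed pairs re-predicted; consistency is the fraction of pairs
    decided in both analyses that keep the same call.
    """
    for r in flip_rates:
        if not 0 <= r < 1:
            raise ValueError("flip rates must be in [0, 1)")
    pairs = sorted(net.edge_signs)
    base_seed = int(
        np.random.SeedSequence(entropy=seed, spawn_key=(19,))
        .generate_state(1)[0] % (2**31)
    )
    clean = _predict(net, pairs, algorithm, n_runs, cutoff, base_seed, p0, p_fail)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(20,))
    )
    out = {}
    for rate in flip_rates:
        n_flip = int(round(rate * net.n_edges))
        flip_ids = set(
            int(i) for i in rng.choice(net.n_edges, size=n_flip, replace=False)
        )
        signs = {
            p: (-net.edge_signs[p] if i in flip_ids else net.edge_signs[p])
            for i, p in enumerate(pairs)
        }
        perturbed = net.with_signs(signs)
        pert = _predict(
            perturbed, pairs, algorithm, n_runs, cutoff, base_seed, p0, p_fail
        )
        both = [
            (a.call, b.call)
            for a, b in zip(clean, pert)
            if a.call != "undecided" and b.call != "undecided"
        ]
        out[rate] = (
            math.nan
            if not both
            else sum(1 for a, b in both if a == b) / len(both)
        )
    return out


def prediction_stability(
    preds: Sequence[ConsensusPrediction], threshold: float = 0.9
) -> float:
    """Fraction of pairs whose leading vote reaches ``threshold``."""
    if not preds:
        raise ValueError("no predictions")
    return sum(1 for p in preds if p.max_fraction >= threshold) / len(preds)


def partition_agreement(a: GenePartition, b: GenePartition) -> float:
    """Adjusted (chance-corrected) agreement between two partitions.

    Computed over the genes present in both partitions.
    """
    common = sorted(set(a.group_of) & set(b.group_of))
    if not common:
        raise ValueError("partitions share no genes")
    return float(
        adjusted_rand_score(
            [a.group_of[g] for g in common], [b.group_of[g] for g in common]
        )
    )
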