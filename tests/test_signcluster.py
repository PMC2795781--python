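"""Binomial similarity, complete-linkage partitioning, group-majority votes."""

import numpy as np
import pytest

from signko import (
    FunctionalNetwork,
    brute_force_optimum,
    complete_linkage,
    consensus_cluster_predict,
    default_p_fail,
    pairwise_similarity,
    predict_pair_cluster,
    similarity_matrix,
)
from signko.signcluster import GenePartition
from signko.synthgen import GeneratorConfig, generate_planted_partition, product_matrix


def _four_trial_net():
    # u and v share two upstream knockouts and two downstream targets
    return FunctionalNetwork(
        [
            ("k1", "u", 1), ("k1", "v", 1),
            ("k2", "u", -1), ("k2", "v", -1),
            ("u", "t1", 1), ("v", "t1", 1),
            ("u", "t2", -1), ("v", "t2", -1),
        ]
    )


def test_similarity_four_trials_all_agree():
    s = pairwise_similarity(_four_trial_net(), "u", "v", 0.5)
    assert (s.n_trials, s.k_failures) == (4, 0)
    assert s.score == pytest.approx(0.0625)  # P(X<=0 | 4, 0.5) = 1/16


def test_similarity_four_trials_one_failure():
    net = FunctionalNetwork(
        [
            ("k1", "u", 1), ("k1", "v", -1),  # the single disagreement
            ("k2", "u", -1), ("k2", "v", -1),
            ("u", "t1", 1), ("v", "t1", 1),
            ("u", "t2", -1), ("v", "t2", -1),
        ]
    )
    s = pairwise_similarity(net, "u", "v", 0.5)
    assert (s.n_trials, s.k_failures) == (4, 1)
    assert s.score == pytest.approx(5 / 16)  # P(X<=1 | 4, 0.5)


def test_similarity_no_evidence_scores_one():
    net = FunctionalNetwork([("a", "b", 1), ("c", "d", -1)])
    s = pairwise_similarity(net, "a", "c", 0.5)
    assert s.n_trials == 0 and s.score == 1.0


def test_similarity_symmetry_and_errors():
    net = _four_trial_net()
    su = pairwise_similarity(net, "u", "v", 0.3)
    sv = pairwise_similarity(net, "v", "u", 0.3)
    assert su.score == pytest.approx(sv.score)
    with pytest.raises(ValueError):
        pairwise_similarity(net, "u", "u", 0.5)


def test_similarity_monotone_in_failures():
    # at fixed n_trials the score is non-decreasing in k_failures
    from scipy.stats import binom

    scores = [binom.cdf(k, 6, 0.4) for k in range(7)]
    assert scores == sorted(scores)
    assert scores[-1] == pytest.approx(1.0)  # CDF(n; n, p) = 1


def test_similarity_matrix_matches_pairwise():
    net = _four_trial_net()
    genes = sorted(net.genes)
    mat = similarity_matrix(net, genes, 0.5)
    for i, a in enumerate(genes):
        for j, b in enumerate(genes):
            if i < j:
                assert mat[i, j] == pytest.approx(
                    pairwise_similarity(net, a, b, 0.5).score
                )
    assert np.allclose(mat, mat.T)


def test_default_p_fail():
    half = FunctionalNetwork([("a", "b", 1), ("b", "c", -1)])
    assert default_p_fail(half) == pytest.approx(0.5)  # q = 0.5
    skew = FunctionalNetwork(
        [(f"a{i}", f"b{i}", 1) for i in range(9)] + [("x", "y", -1)]
    )
    assert default_p_fail(skew) == pytest.approx(0.18)  # 2 * 0.9 * 0.1
    allpos = FunctionalNetwork([("a", "b", 1)])
    with pytest.raises(ValueError, match="degenerate"):
        default_p_fail(allpos)


def test_complete_linkage_all_similar_one_group():
    genes = ["a", "b", "c"]
    mat = np.full((3, 3), 0.01)
    np.fill_diagonal(mat, 0.0)
    part = complete_linkage(mat, genes, 0.05)
    assert part.groups == (frozenset("abc"),)


def test_complete_linkage_no_similarity_all_singletons():
    genes = ["a", "b", "c"]
    mat = np.ones((3, 3))
    np.fill_diagonal(mat, 0.0)
    part = complete_linkage(mat, genes, 0.05)
    assert part.n_groups == 3
    assert all(len(g) == 1 for g in part.groups)


def test_complete_linkage_planted_two_blocks():
    genes = ["a", "b", "c", "d", "e", "f"]
    mat = np.full((6, 6), 0.9)
    mat[:3, :3] = 0.001
    mat[3:, 3:] = 0.001
    np.fill_diagonal(mat, 0.0)
    part = complete_linkage(mat, genes, 0.05)
    assert set(part.groups) == {frozenset("abc"), frozenset("def")}


def test_complete_linkage_p0_refinement():
    # a lower p0 cut of the same dendrogram refines a higher one
    rng = np.random.default_rng(0)
    n = 12
    mat = rng.random((n, n))
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0.0)
    genes = [f"g{i}" for i in range(n)]
    coarse = complete_linkage(mat, genes, 0.7)
    fine = complete_linkage(mat, genes, 0.2)
    for grp in fine.groups:
        assert any(grp <= big for big in coarse.groups)


def test_complete_linkage_p0_validation():
    with pytest.raises(ValueError):
        complete_linkage(np.zeros((2, 2)), ["a", "b"], 1.5)


def test_predict_pair_cluster_majority_and_ties():
    net = FunctionalNetwork(
        [("a1", "b1", 1), ("a2", "b1", 1), ("a1", "b2", -1), ("x", "y", 1)]
    )
    part = GenePartition.from_groups(
        [frozenset({"a1", "a2"}), frozenset({"b1", "b2"}), frozenset({"x", "y"})]
    )
    # evidence {+1, +1, -1} -> down
    assert predict_pair_cluster(net, part, "a1", "b1") == "down"
    # excluding one +1 edge leaves {+1, -1}: a tie -> undecided
    assert (
        predict_pair_cluster(net, part, "a1", "b1", exclude=("a2", "b1"))
        == "undecided"
    )
    # no evidence between the groups -> undecided
    assert predict_pair_cluster(net, part, "a1", "y") == "undecided"
    # unassigned gene -> undecided
    assert predict_pair_cluster(net, part, "zz", "b1") == "undecided"


def test_consensus_cluster_no_ties_is_deterministic():
    cfg = GeneratorConfig(
        n_genes=24, n_phys_edges=30, n_ko_genes=24, targets_per_ko=12,
        noise_rate=0.0, k_groups=3,
        group_sign_matrix=np.array([[1, -1, 1], [-1, 1, 1], [1, 1, 1]]),
        seed=7,
    )
    net, planted, truth = generate_planted_partition(cfg)
    pairs = sorted(net.edge_signs)[:10]
    preds = consensus_cluster_predict(net, pairs, n_runs=8, p0=0.05, seed=1)
    for p in preds:
        assert {p.frac_down, p.frac_up} <= {0.0, 1.0}


def test_consensus_cluster_recovers_planted_signs():
    # noiseless 3-group instance: held-out pairs with evidence recover the
    # planted matrix sign in every run
    m = np.array([[1, -1, 1], [-1, 1, -1], [1, -1, 1]])
    cfg = GeneratorConfig(
        n_genes=30, n_phys_edges=40, n_ko_genes=30, targets_per_ko=15,
        noise_rate=0.0, k_groups=3, group_sign_matrix=m, seed=3,
    )
    net, planted, truth = generate_planted_partition(cfg)
    rng = np.random.default_rng(0)
    pairs = sorted(net.edge_signs)
    held_out = [pairs[i] for i in rng.choice(len(pairs), size=20, replace=False)]
    train = net.without_edges(held_out)
    preds = consensus_cluster_predict(train, held_out, n_runs=10, p0=0.05, seed=2)
    for pred in preds:
        true_effect = "down" if truth[(pred.ko_gene, pred.target_gene)] == 1 else "up"
        if pred.call != "undecided":
            assert pred.call == true_effect
            assert pred.max_fraction == 1.0
    assert sum(p.call != "undecided" for p in preds) >= 15


def test_beyond_sign_linearity_mutually_up_triple():
    # three genes that up-regulate each other upon knockout: no Boolean
    # assignment satisfies all three -1 products, but the planted partition
    # predicts 'up' for every within-group pair
    edges = [
        ("a", "b", -1), ("b", "a", -1), ("a", "c", -1),
        ("c", "a", -1), ("b", "c", -1), ("c", "b", -1),
    ]
    net = FunctionalNetwork(edges)
    _, opt = brute_force_optimum(net)
    assert opt < 1.0
    part = GenePartition.from_groups([frozenset("abc")])
    held = ("a", "b")
    assert predict_pair_cluster(net, part, *held, exclude=held) == "up"
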