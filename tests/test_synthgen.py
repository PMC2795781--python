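"""Generators: determinism, planted structure, noise model."""

import networkx as nx
import numpy as np
import pytest

from signko import (
    FunctionalNetwork,
    brute_force_optimum,
    check_sign_consistency,
    satisfied_fraction,
)
from signko.synthgen import (
    GeneratorConfig,
    generate_functional_from_physical,
    generate_physical,
    generate_planted_partition,
    pathway_motif_matrix,
    product_matrix,
)


def test_config_validation():
    with pytest.raises(ValueError, match="n_ko_genes"):
        GeneratorConfig(n_genes=5, n_ko_genes=9, targets_per_ko=2)
    with pytest.raises(ValueError, match="targets_per_ko"):
        GeneratorConfig(n_genes=5, n_ko_genes=2, targets_per_ko=5)
    with pytest.raises(ValueError, match="group_sign_matrix required"):
        GeneratorConfig(n_genes=6, n_ko_genes=2, targets_per_ko=2, k_groups=2)
    with pytest.raises(ValueError, match="shape"):
        GeneratorConfig(
            n_genes=6, n_ko_genes=2, targets_per_ko=2, k_groups=3,
            group_sign_matrix=np.ones((2, 2), dtype=int),
        )


def test_generate_physical_connected_and_consistent():
    for seed in range(5):
        cfg = GeneratorConfig(n_genes=12, n_phys_edges=20, n_ko_genes=6,
                              targets_per_ko=4, seed=seed)
        phys, coloring = generate_physical(cfg)
        assert phys.n_edges == 20
        assert nx.is_connected(phys.undirected_graph())
        assert check_sign_consistency(phys).consistent
        for e in phys.edges:
            assert e.sign == coloring[e.source] * coloring[e.target]


def test_generate_physical_inconsistent_has_negative_cycle():
    cfg = GeneratorConfig(
        n_genes=12, n_phys_edges=20, consistent=False, n_ko_genes=6,
        targets_per_ko=4, seed=3,
    )
    phys, coloring = generate_physical(cfg)
    assert coloring is None
    cert = check_sign_consistency(phys)
    assert not cert.consistent


def test_generate_physical_two_nodes_acyclic_always_consistent():
    cfg = GeneratorConfig(
        n_genes=2, n_phys_edges=1, n_ko_genes=1, targets_per_ko=1, seed=0
    )
    phys, _ = generate_physical(cfg)
    assert check_sign_consistency(phys).consistent


def test_generate_physical_edge_count_guards():
    with pytest.raises(ValueError, match="connectivity"):
        generate_physical(
            GeneratorConfig(n_genes=10, n_phys_edges=5,
                            n_ko_genes=2, targets_per_ko=2)
        )


def test_determinism_byte_for_byte(tmp_path):
    cfg = GeneratorConfig(
        n_genes=15, n_phys_edges=24, n_ko_genes=8, targets_per_ko=5,
        noise_rate=0.1, seed=99,
    )
    outputs = []
    for rep in range(2):
        phys, _ = generate_physical(cfg)
        net, truth = generate_functional_from_physical(phys, cfg)
        from signko import write_functional_network, write_physical_network

        fp = tmp_path / f"f{rep}.tsv"
        pp = tmp_path / f"p{rep}.tsv"
        write_functional_network(net, fp)
        write_physical_network(phys, pp)
        outputs.append((fp.read_bytes(), pp.read_bytes(), truth))
    assert outputs[0] == outputs[1]


def test_functional_from_consistent_physical_is_sign_linear():
    # balance of the physical layer implies a perfectly satisfiable
    # functional network (verified by exhaustive optimum on small nets)
    cfg = GeneratorConfig(
        n_genes=10, n_phys_edges=16, n_ko_genes=6, targets_per_ko=4, seed=31
    )
    phys, coloring = generate_physical(cfg)
    net, truth = generate_functional_from_physical(phys, cfg)
    assert satisfied_fraction(net, coloring) == 1.0
    _, opt = brute_force_optimum(net)
    assert opt == 1.0


def test_path_signs_well_defined_in_consistent_network():
    # in a balanced network every simple path between two nodes has the
    # same aggregate sign, so the generator's walk sampling is immaterial
    cfg = GeneratorConfig(n_genes=8, n_phys_edges=14, n_ko_genes=4,
                          targets_per_ko=3, seed=2)
    phys, _ = generate_physical(cfg)
    usigns = phys.undirected_sign_map()
    g = phys.undirected_graph()
    nodes = sorted(phys.nodes)
    for a, b in [(nodes[0], nodes[-1]), (nodes[1], nodes[3])]:
        prods = set()
        for path in nx.all_simple_paths(g, a, b, cutoff=7):
            prod = 1
            for x, y in zip(path, path[1:]):
                prod *= usigns[frozenset((x, y))]
            prods.add(prod)
        assert len(prods) <= 1


def test_functional_truth_matches_path_aggregate_and_noise_flips():
    cfg = GeneratorConfig(
        n_genes=12, n_phys_edges=20, n_ko_genes=8, targets_per_ko=5,
        noise_rate=0.3, seed=77,
    )
    phys, coloring = generate_physical(cfg)
    net, truth = generate_functional_from_physical(phys, cfg)
    # pre-noise truth follows the hidden coloring exactly
    for (u, v), s in truth.items():
        assert s == coloring[u] * coloring[v]
    flips = sum(net.edge_signs[p] != truth[p] for p in truth)
    assert 0 < flips < len(truth)  # noise applied, but not to everything


def test_planted_partition_noise_zero_matches_matrix():
    m = pathway_motif_matrix(3)
    cfg = GeneratorConfig(
        n_genes=18, n_phys_edges=20, n_ko_genes=12, targets_per_ko=6,
        noise_rate=0.0, k_groups=3, group_sign_matrix=m, seed=41,
    )
    net, planted, truth = generate_planted_partition(cfg)
    for (u, v), s in net.edge_signs.items():
        assert s == m[planted.group_of[u], planted.group_of[v]]
        assert truth[(u, v)] == s


def test_planted_two_group_product_matrix_is_sign_linear():
    cfg = GeneratorConfig(
        n_genes=10, n_phys_edges=12, n_ko_genes=8, targets_per_ko=4,
        noise_rate=0.0, k_groups=2, group_sign_matrix=product_matrix([1, -1]),
        seed=5,
    )
    net, planted, _ = generate_planted_partition(cfg)
    _, opt = brute_force_optimum(net)
    assert opt == 1.0


def test_pathway_motif_contains_unsatisfiable_triple():
    m = pathway_motif_matrix(3)
    cfg = GeneratorConfig(
        n_genes=9, n_phys_edges=10, n_ko_genes=9, targets_per_ko=8,
        noise_rate=0.0, k_groups=3, group_sign_matrix=m, seed=1,
    )
    net, planted, _ = generate_planted_partition(cfg)
    # dense sampling guarantees a mutually up-regulating within-group triple
    _, opt = brute_force_optimum(net)
    assert opt < 1.0
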