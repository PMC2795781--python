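"""Synthetic benchmark generation with planted ground truth.

Three generators mirror the modeling assumptions of the inference methods:

* :func:`generate_physical` — a connected random directed interaction
  topology (random spanning tree plus uniform extra edges).  When
  ``consistent`` a hidden node coloring sigma* is drawn and every edge is
  signed sigma*(u)*sigma*(v), which is balanced by construction; otherwise
  a stated number of non-tree edge signs are flipped, each closing a
  negative undirected cycle.
* :func:`generate_functional_from_physical` — knockout effects explained
  by directed physical paths: sources are sampled, targets reached by
  random simple walks, and each functional sign is the walk's aggregate
  edge-sign product (in a balanced network this is path-independent).
* :func:`generate_planted_partition` — genes split round-robin into k
  groups with a fixed k x k group sign matrix; sampled knockout pairs get
  the matrix sign of their groups.  The *pathway motif* matrix (diagonal
  -1, off-diagonal +1) emulates negative-feedback pathways whose members
  up-regulate each other upon knockout — such instances contain mutually
  up-regulating triples and are therefore not sign-linear.

All generators apply i.i.d. sign-flip noise at ``noise_rate`` after the
ground truth is recorded, and are byte-for-byte deterministic given the
config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .netio import (
    AnnotatedPhysicalNetwork,
    FunctionalNetwork,
    GenePair,
    PDI,
    PPI,
    PhysicalEdge,
)
from .signcluster import GenePartition

__all__ = [
    "GeneratorConfig",
    "generate_physical",
    "generate_functional_from_physical",
    "generate_planted_partition",
    "pathway_motif_matrix",
    "product_matrix",
]


def pathway_motif_matrix(k: int) -> np.ndarray:
    """Group sign matrix of the negative-feedback pathway pattern.

    Within-group knockout effects are all up-regulation (sign -1, members
    increase each other upon knockout), between-group effects are
    down-regulation (+1).  Any group with >= 3 sampled members yields a
    mutually up-regulating triple, which no Boolean assignment satisfies.
    """
    m = np.ones((k, k), dtype=int)
    np.fill_diagonal(m, -1)
    return m


def product_matrix(labels: Sequence[int]) -> np.ndarray:
    """Sign-linear group matrix M[g][h] = tau_g * tau_h for group labels tau."""
    t = np.asarray(labels, dtype=int)
    return np.outer(t, t)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults describe a mid-sized, densely sampled benchmark: a connected
    30-gene physical layer with 50% extra (cycle-closing) edges, full
    knockout coverage of the planted-partition instances, and 5% sign-flip
    noise.
    """

    n_genes: int = 30
    n_phys_edges: int = 45
    pdi_fraction: float = 0.3
    consistent: bool = True
    n_inconsistent_flips: int = 1
    n_ko_genes: int = 20
    targets_per_ko: int = 8
    noise_rate: float = 0.0
    k_groups: int = 0
    group_sign_matrix: Optional[np.ndarray] = None
    seed: int = 0
    max_path_len: int = 12

    def __post_init__(self) -> None:
        if self.n_ko_genes > self.n_genes:
            raise ValueError("n_ko_genes cannot exceed n_genes")
        if self.targets_per_ko > self.n_genes - 1:
            raise ValueError("targets_per_ko cannot exceed n_genes - 1")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.k_groups >= 2:
            m = self.group_sign_matrix
            if m is None:
                raise ValueError("group_sign_matrix required when k_groups >= 2")
            m = np.asarray(m)
            if m.shape != (self.k_groups, self.k_groups):
                raise ValueError("group_sign_matrix shape mismatch")
            if not np.all(np.isin(m, (-1, 1))):
                raise ValueError("group_sign_matrix entries must be +/-1")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,))
    )


def _gene_names(n: int) -> list:
    return [f"g{i:03d}" for i in range(n)]


def generate_physical(
    config: GeneratorConfig,
) -> tuple[AnnotatedPhysicalNetwork, Optional[dict]]:
    """Connected random signed topology; returns (network, hidden coloring).

    The topology is a random spanning tree directed away from its root
    (so the root reaches every node) plus uniform extra directed edges.
    The hidden coloring is returned for consistent networks as a test
    oracle; inconsistent networks return None.
    """
    n = config.n_genes
    if config.n_phys_edges < n - 1:
        raise ValueError("need at least n_genes - 1 edges for connectivity")
    max_edges = n * (n - 1)
    if config.n_phys_edges > max_edges:
        raise ValueError("more edges than ordered pairs")
    if not config.consistent:
        if config.n_phys_edges < n:
            raise ValueError("inconsistent networks need at least one non-tree edge")
        if config.n_inconsistent_flips < 1:
            raise ValueError("n_inconsistent_flips must be >= 1 when inconsistent")
    rng = _rng(config, 0)
    genes = _gene_names(n)
    order = [genes[i] for i in rng.permutation(n)]
    pairs: list[GenePair] = []
    seen = set()
    for i in range(1, n):
        parent = order[int(rng.integers(0, i))]
        pairs.append((parent, order[i]))
        seen.add((parent, order[i]))
    n_tree = len(pairs)
    while len(pairs) < config.n_phys_edges:
        u, v = (genes[int(i)] for i in rng.choice(n, size=2, replace=False))
        if (u, v) not in seen:
            seen.add((u, v))
            pairs.append((u, v))
    coloring = {g: int(s) for g, s in zip(genes, rng.choice((-1, 1), size=n))}
    signs = [coloring[u] * coloring[v] for (u, v) in pairs]
    if not config.consistent:
        extra_ids = list(rng.permutation(np.arange(n_tree, len(pairs))))
        flipped: set[frozenset] = set()
        for i in extra_ids:
            if len(flipped) == config.n_inconsistent_flips:
                break
            u, v = pairs[int(i)]
            key = frozenset((u, v))
            if key in flipped:
                continue
            flipped.add(key)
            # flip the whole undirected edge so antiparallel records stay in
            # agreement and the tree path u..v closes a negative cycle
            for j, (a, b) in enumerate(pairs):
                if {a, b} == {u, v}:
                    signs[j] = -signs[j]
    etypes = [
        PDI if rng.random() < config.pdi_fraction else PPI for _ in pairs
    ]
    net = AnnotatedPhysicalNetwork(
        PhysicalEdge(u, v, et, s)
        for (u, v), et, s in zip(pairs, etypes, signs)
    )
    return net, (coloring if config.consistent else None)


def _sample_walk(
    successors: dict, source: str, max_len: int, rng: np.random.Generator
) -> list:
    """Random directed walk without node repetition; returns visited path."""
    path = [source]
    on_path = {source}
    while len(path) <= max_len:
        nxt = [w for w in successors.get(path[-1], ()) if w not in on_path]
        if not nxt:
            break
        w = nxt[int(rng.integers(0, len(nxt)))]
        path.append(w)
        on_path.add(w)
    return path


def generate_functional_from_physical(
    phys: AnnotatedPhysicalNetwork,
    config: GeneratorConfig,
    max_attempts: int = 200,
) -> tuple[FunctionalNetwork, dict]:
    """Knockout effects sampled along directed physical paths.

    Per sampled source, random simple walks collect up to
    ``targets_per_ko`` distinct reachable targets; the functional sign of
    (source, target) is the aggregate sign of the sampled walk prefix.
    Returns the noisy network and the pre-noise ground-truth signs.
    Sources with no reachable target are resampled; running out of
    candidate sources is fatal.
    """
    rng = _rng(config, 1)
    succ: dict[str, list] = {}
    esign: dict[GenePair, int] = {}
    for e in phys.edges:
        if e.sign is None:
            raise ValueError("physical network must be fully signed")
        succ.setdefault(e.source, []).append(e.target)
        esign[(e.source, e.target)] = e.sign
    for v in succ.values():
        v.sort()
    candidates = [g for g in sorted(phys.nodes) if succ.get(g)]
    if not candidates:
        raise RuntimeError("physical network has no source with outgoing edges")
    rng.shuffle(candidates)
    truth: dict[GenePair, int] = {}
    n_sources = 0
    for source in candidates:
        if n_sources == config.n_ko_genes:
            break
        found: dict[str, int] = {}
        for _ in range(max_attempts):
            if len(found) >= config.targets_per_ko:
                break
            path = _sample_walk(succ, source, config.max_path_len, rng)
            sign = 1
            for a, b in zip(path, path[1:]):
                sign *= esign[(a, b)]
                if b not in found:
                    found[b] = sign
        if not found:
            continue  # unreachable source: resample another candidate
        n_sources += 1
        for t, s in list(found.items())[: config.targets_per_ko]:
            truth[(source, t)] = s
    if n_sources < config.n_ko_genes:
        raise RuntimeError(
            f"only {n_sources} of {config.n_ko_genes} sources have reachable targets"
        )
    noisy = {
        pair: (-s if rng.random() < config.noise_rate else s)
        for pair, s in truth.items()
    }
    return FunctionalNetwork((u, v, s) for (u, v), s in noisy.items()), truth


def generate_planted_partition(
    config: GeneratorConfig,
) -> tuple[FunctionalNetwork, GenePartition, dict]:
    """Functional network from a planted k-group sign structure.

    Genes are assigned to groups round-robin; each of ``n_ko_genes``
    sampled knockout genes gets ``targets_per_ko`` sampled targets with
    sign matrix[group(u)][group(v)], then i.i.d. noise flips.  Returns the
    noisy network, the planted partition and the pre-noise signs.
    """
    if config.k_groups < 2:
        raise ValueError("k_groups must be >= 2")
    m = np.asarray(config.group_sign_matrix)
    rng = _rng(config, 2)
    genes = _gene_names(config.n_genes)
    group = {g: i % config.k_groups for i, g in enumerate(genes)}
    kos = [genes[int(i)] for i in rng.choice(
        config.n_genes, size=config.n_ko_genes, replace=False
    )]
    truth: dict[GenePair, int] = {}
    for u in kos:
        others = [g for g in genes if g != u]
        targets = [others[int(i)] for i in rng.choice(
            len(others), size=config.targets_per_ko, replace=False
        )]
        for v in targets:
            truth[(u, v)] = int(m[group[u], group[v]])
    noisy = {
        pair: (-s if rng.random() < config.noise_rate else s)
        for pair, s in truth.items()
    }
    net = FunctionalNetwork((u, v, s) for (u, v), s in noisy.items())
    planted = GenePartition.from_labels({g: group[g] for g in net.genes})
    return net, planted, truth
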