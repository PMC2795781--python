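"""Core data types and tab-separated I/O for knockout-effect networks.

A *functional network* is a directed signed graph summarizing single-gene
knockout experiments: an edge (u, v) means that deleting gene ``u``
significantly changed the expression of gene ``v``.  The edge sign is the
complement of the observed effect, i.e. the wild-type influence:

* ``+1`` — knocking out ``u`` DOWN-regulates ``v`` (u normally activates v);
* ``-1`` — knocking out ``u`` UP-regulates ``v`` (u normally represses v).

A *physical network* is a directed graph of protein-protein (PPI) and
protein-DNA (PDI) interactions whose edges may carry activation (``+1``) /
suppression (``-1``) signs or be unassigned (``None``).

Gene identifiers are opaque, case-sensitive strings.  Expression magnitudes
are deliberately not represented: the model is sign-only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd

__all__ = [
    "EFFECT_TO_SIGN",
    "SIGN_TO_EFFECT",
    "PPI",
    "PDI",
    "FunctionalEdge",
    "FunctionalNetwork",
    "PhysicalEdge",
    "AnnotatedPhysicalNetwork",
    "ConsensusPrediction",
    "read_functional_network",
    "write_functional_network",
    "read_physical_network",
    "write_physical_network",
    "write_predictions",
]

#: Observed knockout effect -> functional edge sign (the complement rule).
EFFECT_TO_SIGN: Mapping[str, int] = {"down": 1, "up": -1}
#: Functional edge sign -> predicted knockout effect (inverse of the above).
SIGN_TO_EFFECT: Mapping[int, str] = {1: "down", -1: "up"}

PPI = "ppi"
PDI = "pdi"

_SIGN_TOKENS = {"+": 1, "-": -1, "−": -1, ".": None}
_TOKEN_OF_SIGN = {1: "+", -1: "-", None: "."}

GenePair = tuple[str, str]
#: gene -> {+1, -1}; the sign-linear model's parameter vector.
BooleanAssignment = Mapping[str, int]


def _check_sign(sign: int) -> int:
    if sign not in (1, -1):
        raise ValueError(f"sign must be +1 or -1, got {sign!r}")
    return int(sign)


@dataclass(frozen=True)
class FunctionalEdge:
    """One signed knockout relation: ko_gene affects target_gene."""

    ko_gene: str
    target_gene: str
    sign: int

    def __post_init__(self) -> None:
        if self.ko_gene == self.target_gene:
            raise ValueError(f"self-loop functional edge on {self.ko_gene!r}")
        _check_sign(self.sign)

    @property
    def effect(self) -> str:
        """The observed knockout effect ('down' or 'up')."""
        return SIGN_TO_EFFECT[self.sign]


class FunctionalNetwork:
    """Directed signed graph of knockout relations.

    The gene set is exactly the set of genes appearing in at least one
    edge; isolated genes are not representable (the model is restricted to
    genes implicated in at least one experiment).  At most one edge exists
    per ordered pair; antiparallel edges (u,v) and (v,u) are independent.
    """

    def __init__(self, edges: Iterable[Union[FunctionalEdge, tuple]]) -> None:
        signs: dict[GenePair, int] = {}
        for e in edges:
            if not isinstance(e, FunctionalEdge):
                e = FunctionalEdge(*e)
            key = (e.ko_gene, e.target_gene)
            prev = signs.get(key)
            if prev is None:
                signs[key] = e.sign
            elif prev != e.sign:
                raise ValueError(
                    f"conflicting sign for ({e.ko_gene}, {e.target_gene})"
                )
        self._signs = signs
        genes: set[str] = set()
        kos: set[str] = set()
        for (u, v) in signs:
            genes.add(u)
            genes.add(v)
            kos.add(u)
        self._genes = frozenset(genes)
        self._ko_genes = frozenset(kos)
        self._components: Optional[dict[str, int]] = None

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        return self._genes

    @property
    def ko_genes(self) -> frozenset[str]:
        return self._ko_genes

    @property
    def edges(self) -> tuple[FunctionalEdge, ...]:
        return tuple(
            FunctionalEdge(u, v, s) for (u, v), s in sorted(self._signs.items())
        )

    @property
    def edge_signs(self) -> dict[GenePair, int]:
        """Mapping (ko_gene, target_gene) -> sign.  Do not mutate."""
        return self._signs

    @property
    def n_edges(self) -> int:
        return len(self._signs)

    def __len__(self) -> int:
        return len(self._genes)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._signs

    def sign(self, u: str, v: str) -> int:
        return self._signs[(u, v)]

    def positive_fraction(self) -> float:
        """Fraction q of '+' (activation) edges."""
        if not self._signs:
            raise ValueError("empty network has no sign frequency")
        pos = sum(1 for s in self._signs.values() if s == 1)
        return pos / len(self._signs)

    # -- connectivity ------------------------------------------------------
    def component_of(self) -> dict[str, int]:
        """Undirected connected component index per gene."""
        if self._components is None:
            g = nx.Graph()
            g.add_nodes_from(self._genes)
            g.add_edges_from(self._signs)
            comp = {}
            for i, nodes in enumerate(nx.connected_components(g)):
                for n in nodes:
                    comp[n] = i
            self._components = comp
        return self._components

    def same_component(self, u: str, v: str) -> bool:
        comp = self.component_of()
        return u in comp and v in comp and comp[u] == comp[v]

    # -- derived networks --------------------------------------------------
    def without_edges(self, pairs: Iterable[GenePair]) -> "FunctionalNetwork":
        """Network with the given ordered pairs removed (CV training set)."""
        drop = set(pairs)
        return FunctionalNetwork(
            (u, v, s) for (u, v), s in self._signs.items() if (u, v) not in drop
        )

    def with_signs(self, signs: Mapping[GenePair, int]) -> "FunctionalNetwork":
        """Same topology with signs replaced by ``signs`` (total over edges)."""
        return FunctionalNetwork((u, v, signs[(u, v)]) for (u, v) in self._signs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FunctionalNetwork):
            return NotImplemented
        return self._signs == other._signs

    def __repr__(self) -> str:
        return (
            f"FunctionalNetwork(n_genes={len(self._genes)}, "
            f"n_edges={len(self._signs)})"
        )


@dataclass(frozen=True)
class PhysicalEdge:
    """One directed physical interaction, optionally signed.

    ``sign`` is +1 (activating), -1 (suppressing) or None (unassigned).
    """

    source: str
    target: str
    etype: str
    sign: Optional[int] = None

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop physical edge on {self.source!r}")
        if self.etype not in (PPI, PDI):
            raise ValueError(f"unknown interaction type {self.etype!r}")
        if self.sign is not None:
            _check_sign(self.sign)

    def with_sign(self, sign: Optional[int]) -> "PhysicalEdge":
        return replace(self, sign=sign)


class AnnotatedPhysicalNetwork:
    """Directed physical interaction graph with optional edge signs."""

    def __init__(self, edges: Iterable[Union[PhysicalEdge, tuple]]) -> None:
        by_pair: dict[GenePair, PhysicalEdge] = {}
        for e in edges:
            if not isinstance(e, PhysicalEdge):
                e = PhysicalEdge(*e)
            key = (e.source, e.target)
            prev = by_pair.get(key)
            if prev is not None and prev != e:
                raise ValueError(f"conflicting records for physical edge {key}")
            by_pair[key] = e
        self._edges = by_pair
        nodes: set[str] = set()
        for (u, v) in by_pair:
            nodes.add(u)
            nodes.add(v)
        self._nodes = frozenset(nodes)

    @property
    def nodes(self) -> frozenset[str]:
        return self._nodes

    @property
    def edges(self) -> tuple[PhysicalEdge, ...]:
        return tuple(self._edges[k] for k in sorted(self._edges))

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edge(self, source: str, target: str) -> PhysicalEdge:
        return self._edges[(source, target)]

    def undirected_sign_map(self) -> dict[frozenset, Optional[int]]:
        """Signs of the undirected form, one entry per undirected edge.

        Raises ValueError if antiparallel edges carry contradicting signs
        (the undirected form is then not defined).
        """
        out: dict[frozenset, Optional[int]] = {}
        for (u, v), e in self._edges.items():
            key = frozenset((u, v))
            if key in out:
                prev = out[key]
                if prev is None:
                    out[key] = e.sign
                elif e.sign is not None and e.sign != prev:
                    raise ValueError(
                        f"undirected form not defined: contradicting signs on "
                        f"{{{u}, {v}}}"
                    )
            else:
                out[key] = e.sign
        return out

    def undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from((u, v) for (u, v) in self._edges)
        return g

    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for (u, v), e in self._edges.items():
            g.add_edge(u, v, sign=e.sign, etype=e.etype)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedPhysicalNetwork):
            return NotImplemented
        return self._edges == other._edges

    def __repr__(self) -> str:
        return (
            f"AnnotatedPhysicalNetwork(n_nodes={len(self._nodes)}, "
            f"n_edges={len(self._edges)})"
        )


@dataclass(frozen=True)
class ConsensusPrediction:
    """Vote fractions over consensus runs for one knockout pair.

    ``frac_down`` / ``frac_up`` are the fractions of runs voting for a
    down- / up-regulation knockout effect; runs may abstain, so the two
    fractions need not sum to one.  ``call`` is the label whose fraction
    strictly exceeds the decision cutoff, else 'undecided'.
    """

    ko_gene: str
    target_gene: str
    frac_down: float
    frac_up: float
    n_runs: int
    call: str

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if self.frac_down < 0 or self.frac_up < 0 or (
            self.frac_down + self.frac_up > 1 + 1e-9
        ):
            raise ValueError("vote fractions must be nonnegative and sum <= 1")
        if self.call not in ("down", "up", "undecided"):
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def max_fraction(self) -> float:
        return max(self.frac_down, self.frac_up)


def resolve_call(frac_down: float, frac_up: float, cutoff: float) -> str:
    """Decision rule: the label whose vote fraction strictly exceeds cutoff."""
    if not 0.5 <= cutoff < 1:
        raise ValueError("cutoff must be in [0.5, 1)")
    if frac_down > cutoff:
        return "down"
    if frac_up > cutoff:
        return "up"
    return "undecided"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_functional_network(
    path: Union[str, Path], sep: str = "\t"
) -> FunctionalNetwork:
    """Read a functional network from a TSV of knockout pairs.

    Expected header columns: ``ko_gene``, ``target_gene``, ``effect`` with
    effect in {up, down}.  'down' maps to sign +1, 'up' to -1 (complement
    rule).  Duplicate identical rows are deduplicated; duplicates with
    conflicting effects raise ValueError.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ["ko_gene", "target_gene", "effect"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    edges = []
    for row in df.itertuples(index=False):
        effect = str(row.effect)
        if effect not in EFFECT_TO_SIGN:
            raise ValueError(f"unknown effect token {effect!r}")
        edges.append((str(row.ko_gene), str(row.target_gene), EFFECT_TO_SIGN[effect]))
    return FunctionalNetwork(edges)


def write_functional_network(
    net: FunctionalNetwork, path: Union[str, Path]
) -> None:
    df = pd.DataFrame(
        [(e.ko_gene, e.target_gene, e.effect) for e in net.edges],
        columns=["ko_gene", "target_gene", "effect"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_physical_network(path: Union[str, Path]) -> AnnotatedPhysicalNetwork:
    """Read a physical network from a SIF-like TSV.

    Expected header columns: ``source``, ``target``, ``type``, ``sign``
    with type in {ppi, pdi} (case-insensitive) and sign in {+, -, .}
    ('.' = unassigned).  Self-loop rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["source", "target", "type", "sign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    edges = []
    for row in df.itertuples(index=False):
        etype = str(row.type).lower()
        if etype not in (PPI, PDI):
            raise ValueError(f"unknown type token {row.type!r}")
        token = str(row.sign)
        if token not in _SIGN_TOKENS:
            raise ValueError(f"unknown sign token {row.sign!r}")
        if str(row.source) == str(row.target):
            raise ValueError(f"self-loop on {row.source!r}")
        edges.append(
            PhysicalEdge(str(row.source), str(row.target), etype, _SIGN_TOKENS[token])
        )
    return AnnotatedPhysicalNetwork(edges)


def write_physical_network(
    phys: AnnotatedPhysicalNetwork,
    path: Union[str, Path],
    extra_columns: Optional[Mapping[str, Mapping[GenePair, object]]] = None,
) -> None:
    """Write a physical network as TSV; optional per-edge extra columns."""
    rows = []
    for e in phys.edges:
        row = {
            "source": e.source,
            "target": e.target,
            "type": e.etype,
            "sign": _TOKEN_OF_SIGN[e.sign],
        }
        if extra_columns:
            for col, values in extra_columns.items():
                row[col] = values.get((e.source, e.target), "")
        rows.append(row)
    cols = ["source", "target", "type", "sign"]
    if extra_columns:
        cols += list(extra_columns)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_predictions(
    preds: Sequence[ConsensusPrediction], path: Union[str, Path]
) -> None:
    """Write consensus predictions as TSV, preserving input order."""
    df = pd.DataFrame(
        [
            (
                p.ko_gene,
                p.target_gene,
                p.call,
                f"{p.frac_down:.4f}",
                f"{p.frac_up:.4f}",
                p.n_runs,
            )
            for p in preds
        ],
        columns=["ko_gene", "target_gene", "call", "frac_down", "frac_up", "n_runs"],
    )
    df.to_csv(path, sep="\t", index=False)
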