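"""Causal diagrams, d-separation, and basis sets of conditional-independence
constraints.

A causal diagram here is a directed acyclic graph over named variables,
optionally augmented with *bidirected* arrows ``a <-> b`` that stand for a
latent common cause of ``a`` and ``b``.  Arrows encode direct-cause claims;
*missing* arrows encode independence claims, which d-separation turns into
testable conditional-independence statements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CausalDiagram",
    "DSepStatement",
    "BasisSet",
    "CycleError",
    "build_diagram",
    "to_adjacency",
    "from_adjacency",
    "d_separated",
    "basis_set",
    "basis_count",
    "read_diagram",
    "write_diagram",
    "diagram_diff",
]


class CycleError(ValueError):
    """The directed part of a diagram contains a cycle."""


@dataclass(frozen=True)
class DSepStatement:
    """A claim ``x`` is d-separated from ``y`` given the set ``given``.

    Written ``X des Y | Z`` in the output tables.
    """

    x: str
    y: str
    given: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.x == self.y:
            raise ValueError("a d-separation statement needs two distinct variables")
        object.__setattr__(self, "given", frozenset(self.given))
        if self.x in self.given or self.y in self.given:
            raise ValueError("conditioning set may not contain the tested variables")

    def __str__(self) -> str:
        z = ", ".join(sorted(self.given)) if self.given else "{}"
        return f"{self.x} des {self.y} | {z}"


@dataclass(frozen=True)
class BasisSet:
    """An ordered list of d-separation statements, one per missing arrow."""

    statements: tuple[DSepStatement, ...]

    def __len__(self) -> int:
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    def __getitem__(self, i):
        return self.statements[i]


class CausalDiagram:
    """A validated causal diagram.

    Parameters
    ----------
    nodes :
        Ordered variable names.  The declared order is preserved in every
        serialisation (adjacency matrices, basis-set enumeration).
    directed_arrows :
        ``(parent, child)`` pairs.  The directed part must be acyclic.
    bidirected_arrows :
        Unordered pairs standing for a latent common cause.  For
        d-separation each pair ``{a, b}`` behaves exactly like a fresh
        latent node ``L -> a``, ``L -> b``.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        directed_arrows: Iterable[tuple[str, str]] = (),
        bidirected_arrows: Iterable[Iterable[str]] = (),
    ) -> None:
        nodes = list(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        node_set = set(nodes)

        directed = []
        seen_dir = set()
        for a, b in directed_arrows:
            if a not in node_set or b not in node_set:
                raise KeyError(f"unknown node in arrow {a!r} -> {b!r}")
            if a == b:
                raise ValueError(f"self-arrow on {a!r}")
            if (a, b) in seen_dir:
                raise ValueError(f"duplicate arrow {a!r} -> {b!r}")
            seen_dir.add((a, b))
            directed.append((a, b))

        bidirected = []
        seen_bi = set()
        for pair in bidirected_arrows:
            a, b = tuple(pair)
            if a not in node_set or b not in node_set:
                raise KeyError(f"unknown node in bidirected arrow {a!r} <-> {b!r}")
            if a == b:
                raise ValueError(f"self-arrow on {a!r}")
            key = frozenset((a, b))
            if key in seen_bi:
                raise ValueError(f"duplicate bidirected arrow {a!r} <-> {b!r}")
            seen_bi.add(key)
            bidirected.append(key)

        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(directed)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise CycleError(f"directed arrows contain a cycle: {cyc}")

        self.nodes: tuple[str, ...] = tuple(nodes)
        self.directed_arrows: tuple[tuple[str, str], ...] = tuple(directed)
        self.bidirected_arrows: tuple[frozenset[str], ...] = tuple(bidirected)

        self._parents: dict[str, frozenset[str]] = {
            n: frozenset(p for p, c in directed if c == n) for n in nodes
        }
        # latent expansion: one fresh parent per bidirected pair
        expanded: dict[str, set[str]] = {n: set(self._parents[n]) for n in nodes}
        for i, pair in enumerate(bidirected):
            latent = f"~latent{i}"
            expanded[latent] = set()
            for v in pair:
                expanded[v].add(latent)
        self._expanded_parents: dict[str, frozenset[str]] = {
            k: frozenset(v) for k, v in expanded.items()
        }
        order_index = {n: i for i, n in enumerate(nodes)}
        self._topo_order: tuple[str, ...] = tuple(
            nx.lexicographical_topological_sort(g, key=lambda n: order_index[n])
        )

    # -- convenience -----------------------------------------------------
    def parents(self, node: str) -> frozenset[str]:
        return self._parents[node]

    @property
    def topological_order(self) -> tuple[str, ...]:
        """A deterministic topological order (declared order as tie-break)."""
        return self._topo_order

    def is_adjacent(self, a: str, b: str) -> bool:
        """True when any arrow (directed either way, or bidirected) joins a, b."""
        return (
            (a, b) in set(self.directed_arrows)
            or (b, a) in set(self.directed_arrows)
            or frozenset((a, b)) in set(self.bidirected_arrows)
        )

    def latent_expansion(self) -> "CausalDiagram":
        """The diagram with every bidirected arrow replaced by an explicit
        latent common cause ``~latentK -> a``, ``~latentK -> b``."""
        latents = [f"~latent{i}" for i in range(len(self.bidirected_arrows))]
        arrows = list(self.directed_arrows)
        for lat, pair in zip(latents, self.bidirected_arrows):
            for v in sorted(pair, key=self.nodes.index):
                arrows.append((lat, v))
        return CausalDiagram(list(self.nodes) + latents, arrows)

    def __repr__(self) -> str:
        return (
            f"CausalDiagram({len(self.nodes)} nodes, "
            f"{len(self.directed_arrows)} arrows, "
            f"{len(self.bidirected_arrows)} bidirected)"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CausalDiagram):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and set(self.directed_arrows) == set(other.directed_arrows)
            and set(self.bidirected_arrows) == set(other.bidirected_arrows)
        )


def build_diagram(
    nodes: Sequence[str],
    directed_arrows: Iterable[tuple[str, str]] = (),
    bidirected_arrows: Iterable[Iterable[str]] = (),
) -> CausalDiagram:
    """Validate and construct a :class:`CausalDiagram`.

    Raises :class:`CycleError` if the directed arrows contain a cycle,
    ``KeyError`` for arrows referencing undeclared nodes, and ``ValueError``
    for duplicate or self arrows.
    """
    return CausalDiagram(nodes, directed_arrows, bidirected_arrows)


def to_adjacency(diagram: CausalDiagram) -> pd.DataFrame:
    """The square (1,0) adjacency matrix of the directed part.

    Cell ``(i, j)`` is 1 iff there is an arrow ``i -> j``; the diagonal is
    zero.  Rows/columns follow the declared node order.
    """
    n = len(diagram.nodes)
    idx = {v: i for i, v in enumerate(diagram.nodes)}
    mat = np.zeros((n, n), dtype=int)
    for a, b in diagram.directed_arrows:
        mat[idx[a], idx[b]] = 1
    return pd.DataFrame(mat, index=diagram.nodes, columns=diagram.nodes)


def from_adjacency(adjacency: pd.DataFrame) -> CausalDiagram:
    """Rebuild a diagram (directed arrows only) from its adjacency matrix."""
    nodes = list(adjacency.index)
    if list(adjacency.columns) != nodes:
        raise ValueError("adjacency matrix rows and columns must match")
    arrows = [
        (a, b)
        for a in nodes
        for b in nodes
        if adjacency.loc[a, b]
    ]
    return CausalDiagram(nodes, arrows)


def d_separated(
    diagram: CausalDiagram,
    x: str,
    y: str,
    given: Iterable[str] = (),
) -> bool:
    """Decide whether ``x`` is d-separated from ``y`` given ``given``.

    Uses moralized-ancestral-graph reachability: restrict to the ancestors
    of ``{x, y} ∪ given``, marry co-parents, drop arrow directions, delete
    the conditioning nodes, and test whether ``x`` and ``y`` are
    disconnected.  Bidirected arrows participate through their latent
    expansion.  Under the Markov condition a ``True`` verdict implies the
    conditional independence ``x ⊥ y | given``.
    """
    given = frozenset(given)
    node_set = set(diagram.nodes)
    for v in (x, y, *given):
        if v not in node_set:
            raise KeyError(f"unknown node {v!r}")
    if x == y:
        raise ValueError("x and y must be distinct")
    if x in given or y in given:
        raise ValueError("conditioning set may not contain x or y")

    parents = diagram._expanded_parents

    # ancestral closure of {x, y} ∪ given
    anc: set[str] = set()
    stack = [x, y, *given]
    while stack:
        v = stack.pop()
        if v not in anc:
            anc.add(v)
            stack.extend(parents[v])

    # moral graph on the ancestral set
    adj: dict[str, set[str]] = {v: set() for v in anc}
    for v in anc:
        ps = parents[v]  # ancestors of v, hence all in anc
        for p in ps:
            adj[p].add(v)
            adj[v].add(p)
        for p, q in combinations(ps, 2):
            adj[p].add(q)
            adj[q].add(p)

    # connectivity avoiding the conditioning set
    seen = {x}
    stack = [x]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w == y:
                return False
            if w not in seen and w not in given:
                seen.add(w)
                stack.append(w)
    return True


def basis_set(diagram: CausalDiagram) -> BasisSet:
    """The basis set of conditional-independence constraints.

    One statement per non-adjacent node pair ``{i, j}``, conditioning on the
    union of both variables' parents (minus the pair itself).  Pairs joined
    only by a bidirected arrow carry no independence claim (their latent
    common cause is exactly what exempts them) and get no statement.
    Statements are enumerated lexicographically in declared node order and
    each emitted statement satisfies :func:`d_separated` by construction.
    """
    directed = set(diagram.directed_arrows)
    bidirected = set(diagram.bidirected_arrows)
    statements = []
    for i, a in enumerate(diagram.nodes):
        for b in diagram.nodes[i + 1 :]:
            if (a, b) in directed or (b, a) in directed:
                continue
            if frozenset((a, b)) in bidirected:
                continue
            cond = (diagram.parents(a) | diagram.parents(b)) - {a, b}
            statements.append(DSepStatement(a, b, cond))
    return BasisSet(tuple(statements))


def basis_count(V: int, A: int) -> int:
    """Expected basis-set size ``V(V-1)/2 - A``.

    ``V`` is the number of variables and ``A`` the number of arrows
    (adjacent pairs) in the diagram.  For diagrams with bidirected arrows,
    count each bidirected pair in ``A`` as well: no statement is generated
    for it.
    """
    if V < 2:
        raise ValueError("need at least two variables")
    max_arrows = V * (V - 1) // 2
    if not 0 <= A <= max_arrows:
        raise ValueError(f"A must be in [0, {max_arrows}] for V={V}")
    return max_arrows - A


def diagram_diff(old: CausalDiagram, new: CausalDiagram) -> dict[str, list]:
    """What changed between two diagram versions (model-revision aid).

    Returns added/removed nodes, directed arrows and bidirected arrows, for
    the user-driven iterate-and-retest loop.
    """
    return {
        "nodes_added": sorted(set(new.nodes) - set(old.nodes)),
        "nodes_removed": sorted(set(old.nodes) - set(new.nodes)),
        "arrows_added": sorted(set(new.directed_arrows) - set(old.directed_arrows)),
        "arrows_removed": sorted(set(old.directed_arrows) - set(new.directed_arrows)),
        "bidirected_added": sorted(
            tuple(sorted(p)) for p in set(new.bidirected_arrows) - set(old.bidirected_arrows)
        ),
        "bidirected_removed": sorted(
            tuple(sorted(p)) for p in set(old.bidirected_arrows) - set(new.bidirected_arrows)
        ),
    }


# -- plain-text diagram files -------------------------------------------------

def read_diagram(path) -> CausalDiagram:
    """Parse a plain-text edge list.

    One item per line: ``A -> B`` (directed arrow), ``A <-> B`` (bidirected
    arrow), or ``node C`` (isolated node).  ``#`` starts a comment.  Node
    order is first-appearance order.
    """
    nodes: list[str] = []
    seen: set[str] = set()

    def note(v: str) -> None:
        if v not in seen:
            seen.add(v)
            nodes.append(v)

    directed: list[tuple[str, str]] = []
    bidirected: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("node "):
                note(line[5:].strip())
                continue
            if "<->" in line:
                a, b = (s.strip() for s in line.split("<->", 1))
                note(a), note(b)
                bidirected.append((a, b))
            elif "->" in line:
                a, b = (s.strip() for s in line.split("->", 1))
                note(a), note(b)
                directed.append((a, b))
            else:
                raise ValueError(f"line {lineno}: cannot parse {raw.rstrip()!r}")
    return CausalDiagram(nodes, directed, bidirected)


def write_diagram(diagram: CausalDiagram, path) -> None:
    """Write the same edge-list dialect :func:`read_diagram` parses.

    Every node is declared up front so the declared order (which fixes the
    adjacency-matrix and basis-set enumeration order) survives the
    round-trip.
    """
    with open(path, "w") as fh:
        for v in diagram.nodes:
            fh.write(f"node {v}\n")
        for a, b in diagram.directed_arrows:
            fh.write(f"{a} -> {b}\n")
        for pair in diagram.bidirected_arrows:
            a, b = sorted(pair, key=diagram.nodes.index)
            fh.write(f"{a} <-> {b}\n")
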