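"""Mixed-mark graph data model and equivalence-class utilities.

A single :class:`MixedGraph` type represents DAGs, CPDAGs and PAGs
uniformly.  Each edge carries one mark per endpoint drawn from
{TAIL, ARROW, CIRCLE}, composing the usual edge kinds:

====================  =========================
notation              marks (at a, at b)
====================  =========================
``a --> b``           TAIL, ARROW
``a --- b``           TAIL, TAIL
``a o-> b``           CIRCLE, ARROW
``a o-o b``           CIRCLE, CIRCLE
``a <-> b``           ARROW, ARROW
====================  =========================

The module also provides the pattern machinery shared by the searches:
Meek-rule closure, DAG <-> CPDAG conversion, consistent PDAG extension
(Dor & Tarsi) and brute-force DAG enumeration for small node sets.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Endpoint",
    "Edge",
    "MixedGraph",
    "GraphError",
    "dag_to_cpdag",
    "meek_closure",
    "pdag_to_dag",
    "enumerate_dags",
    "markov_equivalent",
    "read_graph",
    "write_graph",
    "graph_from_text",
    "graph_to_text",
]


class GraphError(ValueError):
    """Raised for structurally invalid graphs or malformed graph text."""


class Endpoint(Enum):
    """Edge-end mark."""

    TAIL = "-"
    ARROW = ">"
    CIRCLE = "o"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Endpoint.{self.name}"


_LEFT_CHAR = {Endpoint.TAIL: "-", Endpoint.ARROW: "<", Endpoint.CIRCLE: "o"}
_RIGHT_CHAR = {Endpoint.TAIL: "-", Endpoint.ARROW: ">", Endpoint.CIRCLE: "o"}
_LEFT_MARK = {"-": Endpoint.TAIL, "<": Endpoint.ARROW, "o": Endpoint.CIRCLE}
_RIGHT_MARK = {"-": Endpoint.TAIL, ">": Endpoint.ARROW, "o": Endpoint.CIRCLE}


@dataclass(frozen=True)
class Edge:
    """Undirected pair of nodes with one mark per end.

    Canonical order: ``a < b`` lexicographically, so ``Edge('B','A',...)``
    normalises itself and ``(a, b)`` / ``(b, a)`` denote the same edge.
    """

    a: str
    b: str
    mark_at_a: Endpoint
    mark_at_b: Endpoint

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise GraphError(f"self-loop on {self.a!r}")
        if self.a > self.b:
            a, b = self.a, self.b
            ma, mb = self.mark_at_a, self.mark_at_b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)
            object.__setattr__(self, "mark_at_a", mb)
            object.__setattr__(self, "mark_at_b", ma)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))

    def mark_at(self, node: str) -> Endpoint:
        if node == self.a:
            return self.mark_at_a
        if node == self.b:
            return self.mark_at_b
        raise KeyError(node)

    def other(self, node: str) -> str:
        if node == self.a:
            return self.b
        if node == self.b:
            return self.a
        raise KeyError(node)

    def with_mark(self, node: str, mark: Endpoint) -> "Edge":
        if node == self.a:
            return Edge(self.a, self.b, mark, self.mark_at_b)
        if node == self.b:
            return Edge(self.a, self.b, self.mark_at_a, mark)
        raise KeyError(node)

    @property
    def is_directed(self) -> bool:
        """True for tail -> arrow edges (either canonical direction)."""
        m = {self.mark_at_a, self.mark_at_b}
        return m == {Endpoint.TAIL, Endpoint.ARROW}

    @property
    def is_undirected(self) -> bool:
        return self.mark_at_a == Endpoint.TAIL and self.mark_at_b == Endpoint.TAIL

    @property
    def source(self) -> str:
        """Tail end of a directed edge."""
        if not self.is_directed:
            raise GraphError(f"{self} is not directed")
        return self.a if self.mark_at_a == Endpoint.TAIL else self.b

    @property
    def target(self) -> str:
        if not self.is_directed:
            raise GraphError(f"{self} is not directed")
        return self.b if self.mark_at_b == Endpoint.ARROW else self.a

    def __str__(self) -> str:
        return f"{self.a} {_LEFT_CHAR[self.mark_at_a]}-{_RIGHT_CHAR[self.mark_at_b]} {self.b}"


def directed_edge(source: str, target: str) -> Edge:
    return Edge(source, target, Endpoint.TAIL, Endpoint.ARROW)


def undirected_edge(a: str, b: str) -> Edge:
    return Edge(a, b, Endpoint.TAIL, Endpoint.TAIL)


@dataclass
class MixedGraph:
    """Node set plus at most one marked edge per unordered pair."""

    nodes: list[str]
    kind_hint: str | None = None
    _edges: dict[frozenset, Edge] = field(default_factory=dict, repr=False)

    def __init__(self, nodes: Iterable[str], edges: Iterable[Edge] = (),
                 kind_hint: str | None = None) -> None:
        self.nodes = list(dict.fromkeys(nodes))
        self.kind_hint = kind_hint
        self._edges = {}
        node_set = set(self.nodes)
        for e in edges:
            if e.a not in node_set or e.b not in node_set:
                raise GraphError(f"edge {e} references undeclared node")
            self._edges[e.pair] = e

    # -- basic queries -------------------------------------------------
    @property
    def edges(self) -> list[Edge]:
        return sorted(self._edges.values(), key=lambda e: (e.a, e.b))

    def __len__(self) -> int:
        return len(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._edges

    def edge(self, a: str, b: str) -> Edge | None:
        return self._edges.get(frozenset((a, b)))

    def adjacent(self, node: str) -> set[str]:
        return {e.other(node) for e in self._edges.values() if node in e.pair}

    def mark_at(self, node: str, other: str) -> Endpoint:
        e = self._edges[frozenset((node, other))]
        return e.mark_at(node)

    def is_directed_edge(self, source: str, target: str) -> bool:
        e = self.edge(source, target)
        return e is not None and e.is_directed and e.source == source

    def is_undirected_edge(self, a: str, b: str) -> bool:
        e = self.edge(a, b)
        return e is not None and e.is_undirected

    def parents(self, node: str) -> set[str]:
        """Nodes x with a fully directed edge x --> node."""
        return {e.other(node) for e in self._edges.values()
                if node in e.pair and e.is_directed and e.target == node}

    def children(self, node: str) -> set[str]:
        return {e.other(node) for e in self._edges.values()
                if node in e.pair and e.is_directed and e.source == node}

    def undirected_neighbors(self, node: str) -> set[str]:
        return {e.other(node) for e in self._edges.values()
                if node in e.pair and e.is_undirected}

    def directed_edges(self) -> list[tuple[str, str]]:
        return sorted((e.source, e.target) for e in self._edges.values() if e.is_directed)

    # -- mutation ------------------------------------------------------
    def add_edge(self, edge: Edge) -> None:
        if edge.a not in self.nodes or edge.b not in self.nodes:
            raise GraphError(f"edge {edge} references undeclared node")
        self._edges[edge.pair] = edge

    def add_directed(self, source: str, target: str) -> None:
        self.add_edge(directed_edge(source, target))

    def add_undirected(self, a: str, b: str) -> None:
        self.add_edge(undirected_edge(a, b))

    def remove_edge(self, a: str, b: str) -> None:
        del self._edges[frozenset((a, b))]

    def set_mark(self, node: str, other: str, mark: Endpoint) -> None:
        """Set the mark at ``node``'s end of the (node, other) edge."""
        key = frozenset((node, other))
        self._edges[key] = self._edges[key].with_mark(node, mark)

    def orient(self, source: str, target: str) -> None:
        """Force the (source, target) edge to source --> target."""
        self._edges[frozenset((source, target))] = directed_edge(source, target)

    # -- structure checks ----------------------------------------------
    def is_acyclic(self) -> bool:
        """Acyclicity of the fully-directed sub-relation (iterative DFS)."""
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for s, t in self.directed_edges():
            children[s].append(t)
        WHITE, GREY, BLACK = 0, 1, 2
        color = dict.fromkeys(self.nodes, WHITE)
        for root in self.nodes:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, Iterator[str]]] = [(root, iter(children[root]))]
            color[root] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for v in it:
                    if color[v] == GREY:
                        return False
                    if color[v] == WHITE:
                        color[v] = GREY
                        stack.append((v, iter(children[v])))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()
        return True

    def is_dag(self) -> bool:
        return all(e.is_directed for e in self._edges.values()) and self.is_acyclic()

    def has_directed_path(self, source: str, target: str) -> bool:
        """Reachability through fully-directed edges only."""
        stack, seen = [source], {source}
        while stack:
            u = stack.pop()
            for v in self.children(u):
                if v == target:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def has_semi_directed_path(self, source: str, target: str,
                               blocked: set[str] = frozenset()) -> bool:
        """Path from source to target along edges never pointing back
        (undirected or away-directed steps), avoiding ``blocked``."""
        stack, seen = [source], {source}
        while stack:
            u = stack.pop()
            step = self.children(u) | self.undirected_neighbors(u)
            for v in step:
                if v in blocked:
                    continue
                if v == target:
                    return True
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return False

    def copy(self) -> "MixedGraph":
        return MixedGraph(self.nodes, self._edges.values(), self.kind_hint)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MixedGraph):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self._edges == other._edges

    def __repr__(self) -> str:
        es = "; ".join(str(e) for e in self.edges)
        return f"MixedGraph({len(self.nodes)} nodes: {es})"

    def skeleton(self) -> set[frozenset]:
        return set(self._edges)

    def v_structures(self) -> set[tuple[str, str, str]]:
        """Unshielded colliders x -> z <- y of the fully-directed relation,
        returned as (min(x,y), z, max(x,y))."""
        out = set()
        for z in self.nodes:
            pa = sorted(self.parents(z))
            for x, y in itertools.combinations(pa, 2):
                if not self.has_edge(x, y):
                    out.add((x, z, y))
        return out


# ---------------------------------------------------------------------------
# Pattern machinery
# ---------------------------------------------------------------------------

def meek_closure(graph: MixedGraph, knowledge=None) -> MixedGraph:
    """Orient undirected edges compelled by Meek's rules (in place semantics:
    operates on and returns a copy).

    Rules applied until fixpoint, for each undirected edge a --- b:

    * R1: some c --> a with c, b nonadjacent  =>  a --> b
    * R2: a has a directed path to b          =>  a --> b (generalised R2)
    * R3: c --> b, d --> b with c, d nonadjacent and a --- c, a --- d
                                              =>  a --> b
    * R4: a --- c, c --> d, d --> b with c, b nonadjacent  =>  a --> b
      (orienting b --> a would force either the cycle a->c->d->b->a or the
      new collider c -> a <- b)

    If ``knowledge`` is given, undirected edges whose one direction is
    forbidden are oriented the allowed way before each sweep.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        if knowledge is not None:
            for e in g.edges:
                if not e.is_undirected:
                    continue
                fab = knowledge.is_forbidden(e.a, e.b)
                fba = knowledge.is_forbidden(e.b, e.a)
                if fab and not fba:
                    g.orient(e.b, e.a)
                    changed = True
                elif fba and not fab:
                    g.orient(e.a, e.b)
                    changed = True
        for e in list(g.edges):
            if not e.is_undirected:
                continue
            for a, b in ((e.a, e.b), (e.b, e.a)):
                if _meek_applies(g, a, b):
                    if knowledge is not None and knowledge.is_forbidden(a, b):
                        continue
                    g.orient(a, b)
                    changed = True
                    break
    return g


def _meek_applies(g: MixedGraph, a: str, b: str) -> bool:
    adj_b = g.adjacent(b)
    # R1
    for c in g.parents(a):
        if c != b and c not in adj_b:
            return True
    # R2 (generalised: any directed path a ~> b)
    if g.has_directed_path(a, b):
        return True
    # R3
    nbrs = g.undirected_neighbors(a)
    into_b = [c for c in g.parents(b) if c in nbrs]
    for c, d in itertools.combinations(into_b, 2):
        if not g.has_edge(c, d):
            return True
    # R4 (needs c nonadjacent to b)
    for c in nbrs:
        if c == b or c in adj_b:
            continue
        for d in g.children(c):
            if d != a and d != b and g.is_directed_edge(d, b):
                return True
    return False


def dag_to_cpdag(dag: MixedGraph) -> MixedGraph:
    """Completed pattern of a DAG: v-structure arrows plus Meek closure."""
    if not dag.is_dag():
        raise GraphError("input must be a DAG")
    g = MixedGraph(dag.nodes, kind_hint="CPDAG")
    for e in dag.edges:
        g.add_undirected(e.a, e.b)
    for x, z, y in dag.v_structures():
        g.orient(x, z)
        g.orient(y, z)
    out = meek_closure(g)
    out.kind_hint = "CPDAG"
    return out


def pdag_to_dag(pdag: MixedGraph) -> MixedGraph:
    """Consistent DAG extension of a PDAG (Dor & Tarsi 1992).

    Keeps every directed edge, orients every undirected edge, creates no
    new v-structure and no cycle.  Raises GraphError when no extension
    exists.
    """
    g = pdag.copy()
    result = pdag.copy()
    remaining = set(g.nodes)
    while remaining:
        for x in sorted(remaining):
            if g.children(x) & remaining:
                continue
            nbrs = {n for n in g.undirected_neighbors(x) if n in remaining}
            adj = {n for n in g.adjacent(x) if n in remaining}
            ok = all(adj - {y} <= g.adjacent(y) for y in nbrs)
            if not ok:
                continue
            for y in nbrs:
                result.orient(y, x)
                g.orient(y, x)
            remaining.discard(x)
            break
        else:
            raise GraphError("PDAG admits no consistent extension")
    result.kind_hint = "DAG"
    return result


def enumerate_dags(nodes: list[str],
                   skeleton: set[frozenset] | None = None) -> Iterator[MixedGraph]:
    """All DAGs over ``nodes`` (optionally restricted to a fixed skeleton).

    3^(n choose 2) candidate orientations are generated and filtered for
    acyclicity; intended for n <= 5.
    """
    nodes = sorted(nodes)
    if len(nodes) > 5:
        raise GraphError("enumeration limited to 5 nodes")
    pairs = [p for p in itertools.combinations(nodes, 2)
             if skeleton is None or frozenset(p) in skeleton]
    states = (0, 1, 2) if skeleton is None else (1, 2)
    for assignment in itertools.product(states, repeat=len(pairs)):
        g = MixedGraph(nodes, kind_hint="DAG")
        for (a, b), s in zip(pairs, assignment):
            if s == 1:
                g.add_directed(a, b)
            elif s == 2:
                g.add_directed(b, a)
        if g.is_acyclic():
            yield g


def markov_equivalent(d1: MixedGraph, d2: MixedGraph) -> bool:
    """Verma-Pearl criterion: same skeleton and same v-structures."""
    return d1.skeleton() == d2.skeleton() and d1.v_structures() == d2.v_structures()


# ---------------------------------------------------------------------------
# Text I/O (Tetrad-style edge notation)
# ---------------------------------------------------------------------------

_EDGE_RE = re.compile(r"^(?:\d+\.\s*)?(\S+)\s+([<o-])-([>o-])\s+(\S+)$")


def graph_to_text(graph: MixedGraph) -> str:
    lines = ["Graph Nodes:", ";".join(graph.nodes), "", "Graph Edges:"]
    for i, e in enumerate(graph.edges, start=1):
        lines.append(f"{i}. {e}")
    return "\n".join(lines) + "\n"


def graph_from_text(text: str) -> MixedGraph:
    lines = [ln.strip() for ln in text.splitlines()]
    nodes: list[str] | None = None
    edges: list[Edge] = []
    section = None
    for ln in lines:
        if not ln:
            continue
        low = ln.lower()
        if low.startswith("graph nodes"):
            section = "nodes"
            continue
        if low.startswith("graph edges"):
            section = "edges"
            continue
        if section == "nodes" and nodes is None:
            nodes = [n.strip() for n in re.split(r"[;,]", ln) if n.strip()]
            continue
        m = _EDGE_RE.match(ln)
        if not m:
            raise GraphError(f"malformed graph line: {ln!r}")
        a, left, right, b = m.groups()
        edges.append(Edge(a, b, _LEFT_MARK[left], _RIGHT_MARK[right])
                     if a < b else
                     Edge(b, a, _RIGHT_MARK[right], _LEFT_MARK[left]))
    if nodes is None:
        raise GraphError("missing node-list header")
    declared = set(nodes)
    for e in edges:
        if e.a not in declared or e.b not in declared:
            raise GraphError(f"edge {e} references undeclared node")
    return MixedGraph(nodes, edges)


def write_graph(graph: MixedGraph, path: str | Path) -> None:
    Path(path).write_text(graph_to_text(graph))


def read_graph(path: str | Path) -> MixedGraph:
    return graph_from_text(Path(path).read_text())
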