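"""Constraint-based search producing a partial ancestral graph.

Three stages: PC-style adjacency search with conditioning sets drawn
from current adjacencies, a possible-d-sep re-pruning pass, then
endpoint orientation -- unshielded colliders followed by the closure of
the augmented orientation rules (R1-R4 and the tail-completion rules
R8-R10; the selection-bias rules R5-R7 are deliberately not applied
because no selection variables are modelled).

The conditional-independence decision is pluggable: any callable
``test(x, y, S) -> bool`` (True = independent) can replace the default
Fisher-z test, which is how the d-separation oracle variant is run.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable

from .graphs import Edge, Endpoint, MixedGraph
from .knowledge import BackgroundKnowledge
from .stats import CovarianceModel, StatError, fisher_z_test

log = logging.getLogger(__name__)

__all__ = ["SepsetMap", "learn_skeleton", "orient_pag", "fci_search",
           "dsep_oracle"]

CITest = Callable[[str, str, tuple], bool]


@dataclass
class SepsetMap:
    """Separating set recorded for each removed pair."""

    _sets: dict[frozenset, tuple[str, ...]] = field(default_factory=dict)

    def record(self, x: str, y: str, s: tuple[str, ...]) -> None:
        self._sets[frozenset((x, y))] = tuple(sorted(s))

    def get(self, x: str, y: str) -> tuple[str, ...] | None:
        return self._sets.get(frozenset((x, y)))

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self._sets


def _fisher_test(cov: CovarianceModel, alpha: float) -> CITest:
    def test(x: str, y: str, s: tuple) -> bool:
        try:
            return fisher_z_test(cov, x, y, s, alpha=alpha).independent
        except StatError:
            return False
    return test


def dsep_oracle(dag: MixedGraph) -> CITest:
    """CI oracle answering by d-separation on a generating DAG."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.directed_edges())

    def test(x: str, y: str, s: tuple) -> bool:
        return nx.is_d_separator(g, {x}, {y}, set(s))
    return test


def _prune(g: MixedGraph, sepsets: SepsetMap, test: CITest,
           pool_of, max_depth: int | None) -> None:
    """Remove edges x *-* y whenever some subset of ``pool_of(x, y)`` (or of
    ``pool_of(y, x)``) of increasing size separates the pair."""
    depth = 0
    while True:
        if max_depth is not None and depth > max_depth:
            break
        any_candidate = False
        for e in list(g.edges):
            for x, y in ((e.a, e.b), (e.b, e.a)):
                if not g.has_edge(x, y):
                    continue
                pool = sorted(pool_of(x, y))
                if len(pool) < depth:
                    continue
                any_candidate = any_candidate or len(pool) > depth
                for s in itertools.combinations(pool, depth):
                    if test(x, y, s):
                        g.remove_edge(x, y)
                        sepsets.record(x, y, s)
                        break
                if not g.has_edge(x, y):
                    break
        if not any_candidate and depth > 0:
            break
        depth += 1


def learn_skeleton(cov: CovarianceModel, alpha: float = 0.05,
                   knowledge: BackgroundKnowledge | None = None,
                   max_depth: int | None = None,
                   ci_test: CITest | None = None,
                   nodes: list[str] | None = None
                   ) -> tuple[MixedGraph, SepsetMap]:
    """Adjacency phase: start complete (minus pairs forbidden in both
    directions), remove separable pairs, leave circle-circle edges."""
    nodes = list(nodes if nodes is not None else cov.names)
    knowledge = knowledge or BackgroundKnowledge()
    test = ci_test or _fisher_test(cov, alpha)
    g = MixedGraph(nodes, kind_hint="PAG")
    for a, b in itertools.combinations(nodes, 2):
        if knowledge.is_forbidden(a, b) and knowledge.is_forbidden(b, a):
            continue
        g.add_edge(Edge(a, b, Endpoint.CIRCLE, Endpoint.CIRCLE))
    sepsets = SepsetMap()
    _prune(g, sepsets, test,
           lambda x, y: g.adjacent(x) - {y}, max_depth)
    return g, sepsets


def _orient_unshielded_colliders(g: MixedGraph, sepsets: SepsetMap) -> None:
    """x *-> z <-* y for unshielded triples with z outside sepset(x, y).

    Triples are visited in a deterministic order; a triple that would
    overwrite a tail mark set earlier (e.g. by background knowledge) is
    logged and its arrowhead still placed, favouring the collider.
    """
    for z in sorted(g.nodes):
        for x, y in itertools.combinations(sorted(g.adjacent(z)), 2):
            if g.has_edge(x, y):
                continue
            s = sepsets.get(x, y)
            if s is None or z in s:
                continue
            for w in (x, y):
                if g.mark_at(z, w) == Endpoint.TAIL:
                    log.warning("collider conflict at %s on triple (%s,%s,%s)",
                                z, x, z, y)
                g.set_mark(z, w, Endpoint.ARROW)


def _possible_d_sep(g: MixedGraph, x: str) -> set[str]:
    """Nodes reachable from x along paths whose every interior triple is a
    collider or part of a triangle."""
    out: set[str] = set()
    frontier = [(x, v) for v in g.adjacent(x)]
    seen = set(frontier)
    while frontier:
        u, v = frontier.pop()
        out.add(v)
        for w in g.adjacent(v):
            if w in (u, x):
                continue
            collider = (g.mark_at(v, u) == Endpoint.ARROW
                        and g.mark_at(v, w) == Endpoint.ARROW)
            triangle = g.has_edge(u, w)
            if (collider or triangle) and (v, w) not in seen:
                seen.add((v, w))
                frontier.append((v, w))
    return out - {x}


def _apply_knowledge_marks(g: MixedGraph, knowledge: BackgroundKnowledge) -> None:
    """Forbidden (a, b): a cannot be a direct cause of b, so put an
    arrowhead at a's end of the edge.  Required (a, b): orient a --> b."""
    for e in list(g.edges):
        for a, b in ((e.a, e.b), (e.b, e.a)):
            if knowledge.is_required(a, b):
                g.set_mark(a, b, Endpoint.TAIL)
                g.set_mark(b, a, Endpoint.ARROW)
            elif knowledge.is_forbidden(a, b):
                if g.mark_at(a, b) == Endpoint.TAIL:
                    log.warning("knowledge conflict: tail at %s on %s-%s is "
                                "forbidden direction", a, a, b)
                g.set_mark(a, b, Endpoint.ARROW)


# -- orientation rule closure ------------------------------------------------

def _rule_sweep(g: MixedGraph, sepsets: SepsetMap,
                knowledge: BackgroundKnowledge) -> bool:
    changed = False
    changed |= _r1(g)
    changed |= _r2(g)
    changed |= _r3(g)
    changed |= _r4(g, sepsets)
    changed |= _r8(g)
    changed |= _r9(g)
    changed |= _r10(g)
    return changed


def _arrow_into(g: MixedGraph, a: str, b: str) -> bool:
    return g.mark_at(b, a) == Endpoint.ARROW


def _r1(g: MixedGraph) -> bool:
    """a *-> b o-* c, a and c nonadjacent  =>  b --> c."""
    changed = False
    for b in sorted(g.nodes):
        adj = sorted(g.adjacent(b))
        for a, c in itertools.permutations(adj, 2):
            if g.has_edge(a, c):
                continue
            if _arrow_into(g, a, b) and g.mark_at(b, c) == Endpoint.CIRCLE:
                g.set_mark(b, c, Endpoint.TAIL)
                g.set_mark(c, b, Endpoint.ARROW)
                changed = True
    return changed


def _r2(g: MixedGraph) -> bool:
    """chain a -> b *-> c (or a *-> b -> c) with a *-o c  =>  a *-> c."""
    changed = False
    for a, c in itertools.permutations(sorted(g.nodes), 2):
        e = g.edge(a, c)
        if e is None or e.mark_at(c) != Endpoint.CIRCLE:
            continue
        for b in sorted(g.adjacent(a) & g.adjacent(c)):
            ab_dir = (g.mark_at(a, b) == Endpoint.TAIL and _arrow_into(g, a, b))
            bc_dir = (g.mark_at(b, c) == Endpoint.TAIL and _arrow_into(g, b, c))
            if (ab_dir and _arrow_into(g, b, c)) or (_arrow_into(g, a, b) and bc_dir):
                g.set_mark(c, a, Endpoint.ARROW)
                changed = True
                break
    return changed


def _r3(g: MixedGraph) -> bool:
    """a *-> b <-* c, a *-o d o-* c, a,c nonadjacent, d *-o b  =>  d *-> b."""
    changed = False
    for b in sorted(g.nodes):
        for d in sorted(g.adjacent(b)):
            if g.mark_at(b, d) != Endpoint.CIRCLE:
                continue
            cands = sorted(g.adjacent(b) & g.adjacent(d) - {b, d})
            for a, c in itertools.combinations(cands, 2):
                if g.has_edge(a, c):
                    continue
                if (_arrow_into(g, a, b) and _arrow_into(g, c, b)
                        and g.mark_at(d, a) == Endpoint.CIRCLE
                        and g.mark_at(d, c) == Endpoint.CIRCLE):
                    g.set_mark(b, d, Endpoint.ARROW)
                    changed = True
                    break
    return changed


def _discriminating_paths(g: MixedGraph, b: str, c: str):
    """Paths <d, ..., a, b, c> discriminating b for the (b, c) edge: every
    interior node is a collider on the path and a parent of c; d, c
    nonadjacent.  Found by walking backwards from b."""
    # walk backwards from b over collider-parent-of-c interior nodes
    starts = [a for a in g.adjacent(b)
              if a != c and g.mark_at(a, b) == Endpoint.ARROW
              and g.is_directed_edge(a, c)]
    for a in starts:
        stack = [(a, (a, b))]
        while stack:
            u, path = stack.pop()
            for d in sorted(g.adjacent(u)):
                if d in path or d == c:
                    continue
                if g.mark_at(u, d) != Endpoint.ARROW:
                    continue  # collider condition at u, far side
                if not g.has_edge(d, c):
                    yield (d, *path, c)
                    continue
                # d adjacent to c: extend only if d is itself a
                # collider-on-path parent of c
                if g.mark_at(d, u) == Endpoint.ARROW and g.is_directed_edge(d, c):
                    stack.append((d, (d, *path)))


def _r4(g: MixedGraph, sepsets: SepsetMap) -> bool:
    """Discriminating-path rule."""
    changed = False
    for b in sorted(g.nodes):
        for c in sorted(g.adjacent(b)):
            if g.mark_at(b, c) != Endpoint.CIRCLE and \
               g.mark_at(c, b) != Endpoint.CIRCLE:
                continue
            for path in _discriminating_paths(g, b, c):
                d = path[0]
                s = sepsets.get(d, c)
                if s is not None and b in s:
                    g.set_mark(b, c, Endpoint.TAIL)
                    g.set_mark(c, b, Endpoint.ARROW)
                else:
                    a = path[-3]
                    g.set_mark(b, a, Endpoint.ARROW)
                    g.set_mark(a, b, Endpoint.ARROW)
                    g.set_mark(b, c, Endpoint.ARROW)
                    g.set_mark(c, b, Endpoint.ARROW)
                changed = True
                break
    return changed


def _r8(g: MixedGraph) -> bool:
    """a o-> c with a -> b -> c or a -o b -> c  =>  tail at a (a --> c)."""
    changed = False
    for a, c in itertools.permutations(sorted(g.nodes), 2):
        e = g.edge(a, c)
        if e is None or not (e.mark_at(a) == Endpoint.CIRCLE
                             and e.mark_at(c) == Endpoint.ARROW):
            continue
        for b in sorted(g.adjacent(a) & g.adjacent(c)):
            ab = g.edge(a, b)
            a_side = (ab.mark_at(a) == Endpoint.TAIL
                      and ab.mark_at(b) in (Endpoint.ARROW, Endpoint.CIRCLE))
            if a_side and g.is_directed_edge(b, c):
                g.set_mark(a, c, Endpoint.TAIL)
                changed = True
                break
    return changed


def _uncovered_pd_paths(g: MixedGraph, a: str, c: str):
    """Uncovered possibly-directed paths from a to c (no arrowhead facing
    a anywhere; consecutive triple endpoints nonadjacent)."""
    stack = [(a,)]
    while stack:
        path = stack.pop()
        u = path[-1]
        for v in sorted(g.adjacent(u)):
            if v in path:
                continue
            if g.mark_at(u, v) == Endpoint.ARROW:
                continue  # arrow back toward a: not possibly directed
            if g.mark_at(v, u) == Endpoint.TAIL:
                continue
            if len(path) >= 2 and g.has_edge(path[-2], v):
                continue  # covered triple
            if v == c:
                yield (*path, c)
            else:
                stack.append((*path, v))


def _r9(g: MixedGraph) -> bool:
    """a o-> c with an uncovered pd path <a, b, ..., c>, b nonadjacent to c
    =>  tail at a."""
    changed = False
    for a, c in itertools.permutations(sorted(g.nodes), 2):
        e = g.edge(a, c)
        if e is None or not (e.mark_at(a) == Endpoint.CIRCLE
                             and e.mark_at(c) == Endpoint.ARROW):
            continue
        for path in _uncovered_pd_paths(g, a, c):
            if len(path) < 3:
                continue
            b = path[1]
            if not g.has_edge(b, c):
                g.set_mark(a, c, Endpoint.TAIL)
                changed = True
                break
    return changed


def _r10(g: MixedGraph) -> bool:
    """a o-> c, b --> c <-- d, uncovered pd paths a..b and a..d whose first
    steps are distinct and nonadjacent  =>  tail at a."""
    changed = False
    for a, c in itertools.permutations(sorted(g.nodes), 2):
        e = g.edge(a, c)
        if e is None or not (e.mark_at(a) == Endpoint.CIRCLE
                             and e.mark_at(c) == Endpoint.ARROW):
            continue
        into_c = [b for b in g.adjacent(c) if g.is_directed_edge(b, c) and b != a]
        done = False
        for b, d in itertools.combinations(sorted(into_c), 2):
            p1s = [p[1] for p in _uncovered_pd_paths(g, a, b)]
            p2s = [p[1] for p in _uncovered_pd_paths(g, a, d)]
            for m in p1s:
                for w in p2s:
                    if m != w and not g.has_edge(m, w):
                        g.set_mark(a, c, Endpoint.TAIL)
                        changed = done = True
                        break
                if done:
                    break
            if done:
                break
    return changed


def orient_pag(skeleton: MixedGraph, sepsets: SepsetMap,
               knowledge: BackgroundKnowledge | None = None) -> MixedGraph:
    """Endpoint orientation on a learned skeleton."""
    g = skeleton.copy()
    knowledge = knowledge or BackgroundKnowledge()
    if not knowledge.is_empty():
        _apply_knowledge_marks(g, knowledge)
    _orient_unshielded_colliders(g, sepsets)
    if not knowledge.is_empty():
        _apply_knowledge_marks(g, knowledge)
    while _rule_sweep(g, sepsets, knowledge):
        pass
    if not knowledge.is_empty():
        # rules may have placed tails on forbidden directions; report and fix
        _apply_knowledge_marks(g, knowledge)
    g.kind_hint = "PAG"
    return g


def fci_search(cov: CovarianceModel, alpha: float = 0.05,
               knowledge: BackgroundKnowledge | None = None,
               max_depth: int | None = None,
               skip_pdsep: bool = False,
               ci_test: CITest | None = None,
               nodes: list[str] | None = None) -> MixedGraph:
    """Full FCI: skeleton, possible-d-sep re-pruning, orientation."""
    knowledge = knowledge or BackgroundKnowledge()
    test = ci_test or _fisher_test(cov, alpha)
    g, sepsets = learn_skeleton(cov, alpha, knowledge, max_depth,
                                ci_test=test, nodes=nodes)
    if not skip_pdsep:
        _orient_unshielded_colliders(g, sepsets)
        pds = {x: _possible_d_sep(g, x) for x in g.nodes}
        _prune(g, sepsets, test, lambda x, y: pds[x] - {y}, max_depth)
        # wipe orientation and start over on the reduced skeleton
        for e in list(g.edges):
            g.add_edge(Edge(e.a, e.b, Endpoint.CIRCLE, Endpoint.CIRCLE))
    return orient_pag(g, sepsets, knowledge)
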