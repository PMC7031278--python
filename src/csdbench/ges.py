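"""Score-based equivalence-class search (serial GES) plus an exhaustive
oracle for small variable sets.

The search follows the classic two-phase scheme: a forward phase that
repeatedly applies the best admissible Insert operator while the total
BIC improves, then a backward phase applying the best admissible Delete.
Operator validity uses the published clique / semi-directed-path
conditions; after every accepted move the state is reverted to a
completed pattern (consistent DAG extension -> CPDAG -> knowledge-forced
orientation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .graphs import (GraphError, MixedGraph, dag_to_cpdag, enumerate_dags,
                     meek_closure, pdag_to_dag)
from .knowledge import BackgroundKnowledge
from .stats import CovarianceModel, ScoreConfig, StatError, graph_bic_score, local_bic_score

log = logging.getLogger(__name__)

__all__ = ["fges_search", "exhaustive_best_cpdag", "SearchState"]

_EPS = 1e-10


@dataclass
class SearchState:
    graph: MixedGraph
    score: float
    moves: list[str] = field(default_factory=list)


def _neighbors_adjacent_to(g: MixedGraph, y: str, x: str) -> set[str]:
    """NA(y, x): undirected neighbors of y that are adjacent to x."""
    return {n for n in g.undirected_neighbors(y) if g.has_edge(n, x)}


def _is_clique(g: MixedGraph, nodes: set[str]) -> bool:
    return all(g.has_edge(a, b) for a, b in itertools.combinations(sorted(nodes), 2))


def _subsets(items: set[str]):
    items = sorted(items)
    for r in range(len(items) + 1):
        yield from (set(c) for c in itertools.combinations(items, r))


def _local_delta(cov: CovarianceModel, child: str, base: set[str],
                 extra: str, config: ScoreConfig) -> float:
    return (local_bic_score(cov, child, base | {extra}, config)
            - local_bic_score(cov, child, base, config))


def _forward_moves(g: MixedGraph, cov: CovarianceModel,
                   knowledge: BackgroundKnowledge, config: ScoreConfig):
    """Yield (delta, x, y, T) for all valid Insert(x, y, T)."""
    for x, y in itertools.permutations(g.nodes, 2):
        if g.has_edge(x, y) or knowledge.is_forbidden(x, y):
            continue
        na = _neighbors_adjacent_to(g, y, x)
        t_pool = g.undirected_neighbors(y) - na - {x} - g.adjacent(x)
        pa_y = g.parents(y)
        for t_set in _subsets(t_pool):
            if any(knowledge.is_forbidden(t, y) for t in t_set):
                continue
            union = na | t_set
            if not _is_clique(g, union):
                continue
            if g.has_semi_directed_path(y, x, blocked=union):
                continue
            try:
                delta = _local_delta(cov, y, pa_y | union, x, config)
            except StatError:
                continue
            if delta > _EPS:
                yield delta, x, y, tuple(sorted(t_set))


def _backward_moves(g: MixedGraph, cov: CovarianceModel,
                    knowledge: BackgroundKnowledge, config: ScoreConfig):
    """Yield (delta, x, y, H) for all valid Delete(x, y, H)."""
    for e in g.edges:
        pairs = []
        if e.is_undirected:
            pairs = [(e.a, e.b), (e.b, e.a)]
        elif e.is_directed:
            pairs = [(e.source, e.target)]
        for x, y in pairs:
            if knowledge.is_required(x, y) or knowledge.is_required(y, x):
                continue
            na = _neighbors_adjacent_to(g, y, x)
            pa_y = g.parents(y)
            for h_set in _subsets(na):
                if not _is_clique(g, na - h_set):
                    continue
                # Delete orients x -> h and y -> h for h in H
                if any(knowledge.is_forbidden(x, h) or knowledge.is_forbidden(y, h)
                       for h in h_set):
                    continue
                keep = (pa_y | (na - h_set)) - {x}
                try:
                    delta = -_local_delta(cov, y, keep, x, config)
                except StatError:
                    continue
                if delta > _EPS:
                    yield delta, x, y, tuple(sorted(h_set))


def _rebuild_pattern(g: MixedGraph, knowledge: BackgroundKnowledge) -> MixedGraph:
    """PDAG -> consistent DAG -> CPDAG, then knowledge-forced orientation."""
    dag = pdag_to_dag(g)
    cpdag = dag_to_cpdag(dag)
    if not knowledge.is_empty():
        cpdag = meek_closure(cpdag, knowledge)
        for s, t in cpdag.directed_edges():
            if knowledge.is_forbidden(s, t):
                log.warning("knowledge conflict: compelled edge %s -> %s is "
                            "forbidden; reversing", s, t)
                cpdag.orient(t, s)
        cpdag = meek_closure(cpdag, knowledge)
    cpdag.kind_hint = "CPDAG"
    return cpdag


def _sorted_moves(moves) -> list[tuple]:
    return sorted(((-delta, x, y, extra) for delta, x, y, extra in moves))


def fges_search(cov: CovarianceModel,
                knowledge: BackgroundKnowledge | None = None,
                config: ScoreConfig = ScoreConfig(),
                return_state: bool = False):
    """Greedy equivalence search over the variables of ``cov``.

    Returns the CPDAG (no circle marks); with ``return_state`` the
    :class:`SearchState` including the move log and final score.
    """
    knowledge = knowledge or BackgroundKnowledge()
    g = MixedGraph(list(cov.names), kind_hint="CPDAG")
    for s, t in sorted(knowledge.required):
        if (t, s) in knowledge.required:
            raise GraphError(f"required edges {s}->{t} and {t}->{s} form a cycle")
        g.add_directed(s, t)
    if not g.is_acyclic():
        raise GraphError("required edges form a cycle")
    state = SearchState(g, graph_bic_score(cov, pdag_to_dag(g), config))

    for phase, mover in (("insert", _forward_moves), ("delete", _backward_moves)):
        while True:
            applied = False
            for neg_delta, x, y, extra in _sorted_moves(
                    mover(state.graph, cov, knowledge, config)):
                g = state.graph.copy()
                if phase == "insert":
                    g.add_directed(x, y)
                    for t in extra:
                        g.orient(t, y)
                else:
                    g.remove_edge(x, y)
                    for h in extra:
                        if g.is_undirected_edge(x, h):
                            g.orient(x, h)
                        if g.is_undirected_edge(y, h):
                            g.orient(y, h)
                try:
                    pattern = _rebuild_pattern(g, knowledge)
                    new_score = graph_bic_score(cov, pdag_to_dag(pattern), config)
                except GraphError:
                    continue  # move inconsistent with knowledge-forced pattern
                state.graph = pattern
                state.score = new_score
                state.moves.append(
                    f"{phase}({x},{y},{extra}) delta={-neg_delta:.4f}")
                applied = True
                break
            if not applied:
                break
    return state if return_state else state.graph


def _pattern_with_knowledge(dag: MixedGraph,
                            knowledge: BackgroundKnowledge) -> MixedGraph:
    cp = dag_to_cpdag(dag)
    if not knowledge.is_empty():
        cp = meek_closure(cp, knowledge)
        cp.kind_hint = "CPDAG"
    return cp


def exhaustive_best_cpdag(cov: CovarianceModel,
                          knowledge: BackgroundKnowledge | None = None,
                          config: ScoreConfig = ScoreConfig(),
                          return_all: bool = False):
    """Score every knowledge-admissible DAG over the variables (<= 5) and
    return the CPDAG of the argmax.

    Ties across distinct equivalence classes (score difference below
    1e-9) are resolved to the lexicographically smallest edge list; with
    ``return_all`` every tied CPDAG is returned.
    """
    names = list(cov.names)
    if len(names) > 5:
        raise GraphError("exhaustive search limited to 5 variables")
    knowledge = knowledge or BackgroundKnowledge()
    best_score = -float("inf")
    best: list[MixedGraph] = []
    for dag in enumerate_dags(names):
        if any(knowledge.is_forbidden(s, t) for s, t in dag.directed_edges()):
            continue
        if any(not dag.is_directed_edge(s, t) for s, t in knowledge.required):
            continue
        try:
            score = graph_bic_score(cov, dag, config)
        except StatError:
            continue
        if score > best_score + 1e-9:
            best_score = score
            best = [_pattern_with_knowledge(dag, knowledge)]
        elif abs(score - best_score) <= 1e-9:
            cp = _pattern_with_knowledge(dag, knowledge)
            if all(cp != b for b in best):
                best.append(cp)
    if not best:
        raise GraphError("no admissible DAG")
    best.sort(key=lambda g: [str(e) for e in g.edges])
    return best if return_all else best[0]
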