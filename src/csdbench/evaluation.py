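"""Edge-level scoring against the gold standard.

An edge between a pair that is adjacent in the gold DAG (true direction
X -> Y) is *correct* when it is exactly X --> Y, *incorrect* when it
carries an arrowhead at X (asserting X is not a cause of Y: covers <--,
<->, <-o), and *semi-correct* otherwise (---, o-o, o->: orientation does
not contradict the truth).  Any edge on a pair absent from the gold
graph is incorrect.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .graphs import Edge, Endpoint, MixedGraph

__all__ = ["EdgeClassification", "EvaluationReport", "classify_edge",
           "score_graph", "adjacency_scores", "occurrence_rates",
           "consensus_graph"]

CORRECT = "correct"
SEMI = "semi_correct"
INCORRECT = "incorrect"


@dataclass(frozen=True)
class EdgeClassification:
    edge: Edge
    label: str


@dataclass(frozen=True)
class EvaluationReport:
    correct: int
    semi_correct: int
    incorrect: int
    precision: float | None   # None when the graph reported no edges
    recall: float

    @property
    def total(self) -> int:
        return self.correct + self.semi_correct + self.incorrect


def classify_edge(edge: Edge, gold: MixedGraph) -> EdgeClassification:
    """Label one discovered edge against the gold DAG."""
    for node in (edge.a, edge.b):
        if node not in gold.nodes:
            raise ValueError(f"edge references node {node!r} absent from gold")
    gold_edge = gold.edge(edge.a, edge.b)
    if gold_edge is None:
        return EdgeClassification(edge, INCORRECT)
    cause = gold_edge.source
    effect = gold_edge.target
    if edge.mark_at(cause) == Endpoint.ARROW:
        return EdgeClassification(edge, INCORRECT)
    if edge.mark_at(cause) == Endpoint.TAIL and edge.mark_at(effect) == Endpoint.ARROW:
        return EdgeClassification(edge, CORRECT)
    return EdgeClassification(edge, SEMI)


def score_graph(graph: MixedGraph, gold: MixedGraph) -> EvaluationReport:
    """Counts, precision and recall per the edge-label definitions.

    precision = (correct + semi) / edges reported (None when no edges);
    recall    = (correct + semi) / gold edge count.
    """
    labels = Counter(classify_edge(e, gold).label for e in graph.edges)
    correct, semi = labels[CORRECT], labels[SEMI]
    total = len(graph.edges)
    gold_total = len(gold.edges)
    precision = (correct + semi) / total if total else None
    recall = (correct + semi) / gold_total if gold_total else 0.0
    return EvaluationReport(correct, semi, labels[INCORRECT], precision, recall)


def adjacency_scores(graph: MixedGraph, gold: MixedGraph
                     ) -> tuple[float | None, float]:
    """Orientation-blind (precision, recall) of the discovered adjacencies."""
    found = graph.skeleton()
    truth = gold.skeleton()
    precision = len(found & truth) / len(found) if found else None
    recall = len(found & truth) / len(truth) if truth else 0.0
    return precision, recall


def _common_nodes(graphs: list[MixedGraph]) -> list[str]:
    if not graphs:
        raise ValueError("at least one graph required")
    nodes = set(graphs[0].nodes)
    for g in graphs[1:]:
        if set(g.nodes) != nodes:
            raise ValueError("graphs have inconsistent node sets")
    return graphs[0].nodes


def occurrence_rates(graphs: list[MixedGraph]) -> dict[frozenset, float]:
    """Adjacency occurrence percentage per unordered pair (orientation
    ignored), over the list of graphs."""
    _common_nodes(graphs)
    counts: Counter = Counter()
    for g in graphs:
        counts.update(g.skeleton())
    return {pair: 100.0 * c / len(graphs) for pair, c in counts.items()}


def consensus_graph(graphs: list[MixedGraph],
                    threshold_pct: float = 80.0) -> MixedGraph:
    """Pairs with occurrence >= threshold, endpoint marks by the majority
    configuration among graphs containing the pair (tie -> circles)."""
    nodes = _common_nodes(graphs)
    rates = occurrence_rates(graphs)
    out = MixedGraph(nodes)
    for pair, rate in sorted(rates.items(), key=lambda kv: sorted(kv[0])):
        if rate < threshold_pct:
            continue
        a, b = sorted(pair)
        configs = Counter()
        for g in graphs:
            e = g.edge(a, b)
            if e is not None:
                configs[(e.mark_at_a, e.mark_at_b)] += 1
        ranked = configs.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            marks = (Endpoint.CIRCLE, Endpoint.CIRCLE)
        else:
            marks = ranked[0][0]
        out.add_edge(Edge(a, b, marks[0], marks[1]))
    return out
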