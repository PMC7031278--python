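import itertools

import numpy as np
import pytest

from csdbench.graphs import (Edge, Endpoint, GraphError, MixedGraph,
                             dag_to_cpdag, enumerate_dags, graph_from_text,
                             graph_to_text, markov_equivalent, pdag_to_dag,
                             read_graph, write_graph)

from conftest import dsep_statements, equivalence_class, random_dag


class TestEdge:
    def test_canonical_order(self):
        e1 = Edge("B", "A", Endpoint.ARROW, Endpoint.TAIL)
        e2 = Edge("A", "B", Endpoint.TAIL, Endpoint.ARROW)
        assert e1 == e2
        assert e1.a == "A" and e1.mark_at_a == Endpoint.TAIL

    def test_self_loop_rejected(self):
        with pytest.raises(GraphError):
            Edge("A", "A", Endpoint.TAIL, Endpoint.ARROW)

    def test_directed_accessors(self):
        # arrow at 'B', tail at 'A': the edge is A --> B however it is built
        e = Edge("B", "A", Endpoint.ARROW, Endpoint.TAIL)
        assert e.is_directed and e.source == "A" and e.target == "B"

    def test_mark_lookup(self):
        e = Edge("X", "Y", Endpoint.CIRCLE, Endpoint.ARROW)
        assert e.mark_at("X") == Endpoint.CIRCLE
        assert e.mark_at("Y") == Endpoint.ARROW
        with pytest.raises(KeyError):
            e.mark_at("Z")


class TestMixedGraph:
    def test_one_edge_per_pair(self):
        g = MixedGraph(["A", "B"])
        g.add_directed("A", "B")
        g.add_undirected("A", "B")
        assert len(g) == 1 and g.is_undirected_edge("A", "B")

    def test_undeclared_node_rejected(self):
        g = MixedGraph(["A", "B"])
        with pytest.raises(GraphError):
            g.add_directed("A", "C")

    def test_acyclicity(self):
        g = MixedGraph(["A", "B", "C"])
        g.add_directed("A", "B")
        g.add_directed("B", "C")
        assert g.is_acyclic()
        g.add_directed("C", "A")
        assert not g.is_acyclic()

    def test_parents_children(self):
        g = MixedGraph(["A", "B", "C"])
        g.add_directed("A", "B")
        g.add_undirected("B", "C")
        assert g.parents("B") == {"A"}
        assert g.children("A") == {"B"}
        assert g.undirected_neighbors("B") == {"C"}


class TestTextIO:
    def test_directed_notation(self):
        g = graph_from_text("Graph Nodes:\nABETA;FDG\nGraph Edges:\n1. ABETA --> FDG\n")
        e = g.edge("ABETA", "FDG")
        assert e.mark_at("ABETA") == Endpoint.TAIL
        assert e.mark_at("FDG") == Endpoint.ARROW

    def test_circle_arrow_notation(self):
        g = graph_from_text("Graph Nodes:\nPTAU;DX\nGraph Edges:\nPTAU o-> DX\n")
        e = g.edge("PTAU", "DX")
        assert e.mark_at("PTAU") == Endpoint.CIRCLE
        assert e.mark_at("DX") == Endpoint.ARROW

    @pytest.mark.parametrize("notation,ma,mb", [
        ("A --> B", Endpoint.TAIL, Endpoint.ARROW),
        ("A --- B", Endpoint.TAIL, Endpoint.TAIL),
        ("A o-> B", Endpoint.CIRCLE, Endpoint.ARROW),
        ("A o-o B", Endpoint.CIRCLE, Endpoint.CIRCLE),
        ("A <-> B", Endpoint.ARROW, Endpoint.ARROW),
        ("A <-o B", Endpoint.ARROW, Endpoint.CIRCLE),
    ])
    def test_all_edge_kinds(self, notation, ma, mb):
        g = graph_from_text(f"Graph Nodes:\nA;B\nGraph Edges:\n{notation}\n")
        e = g.edge("A", "B")
        assert (e.mark_at("A"), e.mark_at("B")) == (ma, mb)

    def test_round_trip_gold(self, gold, tmp_path):
        path = tmp_path / "gold.txt"
        write_graph(gold, path)
        back = read_graph(path)
        assert back == gold

    def test_malformed_line(self):
        with pytest.raises(GraphError):
            graph_from_text("Graph Nodes:\nA;B\nGraph Edges:\nA ==> B\n")

    def test_undeclared_node(self):
        with pytest.raises(GraphError):
            graph_from_text("Graph Nodes:\nA;B\nGraph Edges:\nA --> C\n")

    def test_missing_header(self):
        with pytest.raises(GraphError):
            graph_from_text("A --> B\n")


class TestTextRoundTripProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    marks = st.sampled_from([Endpoint.TAIL, Endpoint.ARROW, Endpoint.CIRCLE])
    pairs = st.lists(
        st.tuples(st.integers(0, 7), st.integers(0, 7), marks, marks)
        .filter(lambda t: t[0] != t[1]),
        max_size=12)

    @given(pairs)
    @settings(max_examples=60, deadline=None)
    def test_write_read_identity(self, raw):
        nodes = [f"N{i}" for i in range(8)]
        g = MixedGraph(nodes)
        for i, j, ma, mb in raw:
            g.add_edge(Edge(nodes[i], nodes[j], ma, mb))
        assert graph_from_text(graph_to_text(g)) == MixedGraph(nodes, g.edges)


class TestDagToCpdag:
    def test_chain_fully_undirected(self):
        g = MixedGraph(["A", "B", "C"])
        g.add_directed("A", "B")
        g.add_directed("B", "C")
        cp = dag_to_cpdag(g)
        assert cp.is_undirected_edge("A", "B") and cp.is_undirected_edge("B", "C")

    def test_collider_preserved(self):
        g = MixedGraph(["A", "B", "C"])
        g.add_directed("A", "C")
        g.add_directed("B", "C")
        cp = dag_to_cpdag(g)
        assert cp.is_directed_edge("A", "C") and cp.is_directed_edge("B", "C")

    def test_cyclic_rejected(self):
        g = MixedGraph(["A", "B"])
        g.add_directed("A", "B")
        g._edges[frozenset(("A", "B"))] = Edge("A", "B", Endpoint.ARROW,
                                               Endpoint.ARROW)
        with pytest.raises(GraphError):
            dag_to_cpdag(g)

    def test_idempotent_on_member_dags(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            dag = random_dag(rng, 4)
            cp = dag_to_cpdag(dag)
            member = pdag_to_dag(cp)
            assert dag_to_cpdag(member) == cp

    @pytest.mark.parametrize("seed", range(20))
    def test_compelled_edges_match_bruteforce(self, seed):
        """An edge is directed in the CPDAG iff every Markov-equivalent DAG
        (equivalence judged by full d-separation enumeration) agrees."""
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, 4)
        cp = dag_to_cpdag(dag)
        cls = equivalence_class(dag)
        assert cp.skeleton() == dag.skeleton()
        for e in dag.edges:
            orientations = {d.is_directed_edge(e.source, e.target) for d in cls}
            compelled = len(orientations) == 1
            assert cp.is_directed_edge(e.source, e.target) == compelled

    def test_gold_standard_split_matches_enumeration(self, gold):
        """Enumerate every acyclic orientation of the gold skeleton, keep
        those with identical d-separations (independent networkx oracle),
        and require the CPDAG to direct exactly the unanimous edges.

        Conditioning sets are capped at size 3, which distinguishes any
        two same-skeleton orientations of a graph this sparse (maximum
        in-degree 3)."""
        cp = dag_to_cpdag(gold)
        assert cp.skeleton() == gold.skeleton()
        target = _restricted_dsep(gold)
        equivalents = [
            cand for cand in _orientations(gold)
            if _restricted_dsep(cand) == target]
        assert gold in equivalents
        for e in gold.edges:
            unanimous = all(d.is_directed_edge(e.source, e.target)
                            for d in equivalents)
            assert cp.is_directed_edge(e.source, e.target) == unanimous


def _orientations(dag):
    import networkx as nx

    pairs = [tuple(sorted(p)) for p in dag.skeleton()]
    for flips in itertools.product((False, True), repeat=len(pairs)):
        g = MixedGraph(dag.nodes, kind_hint="DAG")
        for (a, b), flip in zip(pairs, flips):
            g.add_directed(b, a) if flip else g.add_directed(a, b)
        if g.is_acyclic():
            yield g


def _restricted_dsep(dag, max_size=3):
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.directed_edges())
    nodes = sorted(dag.nodes)
    out = set()
    for x, y in itertools.combinations(nodes, 2):
        rest = [v for v in nodes if v not in (x, y)]
        for r in range(min(max_size, len(rest)) + 1):
            for s in itertools.combinations(rest, r):
                if nx.is_d_separator(g, {x}, {y}, set(s)):
                    out.add((x, y, s))
    return frozenset(out)


class TestPdagToDag:
    def test_extension_is_equivalent_member(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            dag = random_dag(rng, 4)
            ext = pdag_to_dag(dag_to_cpdag(dag))
            assert ext.is_dag()
            assert markov_equivalent(ext, dag)

    def test_no_extension(self):
        # square of undirected edges with two opposing colliders is fine,
        # but a 'kite' needing a new collider is not extendable
        g = MixedGraph(["A", "B", "C"])
        g.add_directed("A", "B")
        g.add_directed("C", "B")
        g.add_undirected("A", "C")
        # A-C must orient without creating a cycle or new collider: fine
        assert pdag_to_dag(g).is_dag()
        # chordless undirected 4-cycle: every acyclic orientation creates
        # a new unshielded collider, so no consistent extension exists
        g2 = MixedGraph(["A", "B", "C", "D"])
        g2.add_undirected("A", "B")
        g2.add_undirected("B", "C")
        g2.add_undirected("C", "D")
        g2.add_undirected("A", "D")
        with pytest.raises(GraphError):
            pdag_to_dag(g2)
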