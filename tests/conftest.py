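"""Shared fixtures and independent oracles for the test suite.

The oracles here (d-separation via networkx, closed-form Fisher-z,
brute-force equivalence classes) are deliberately implemented apart from
the package code paths they check.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from csdbench.cohort import default_parameters
from csdbench.gold import build_gold_standard
from csdbench.graphs import MixedGraph
from csdbench.stats import CovarianceModel


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def gold():
    return build_gold_standard("cross_sectional")


@pytest.fixture(scope="session")
def gold_longitudinal():
    return build_gold_standard("longitudinal")


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def to_networkx(dag: MixedGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.directed_edges())
    return g


def dsep_statements(dag: MixedGraph) -> frozenset:
    """Every d-separation statement (x, y, S) of a small DAG."""
    g = to_networkx(dag)
    nodes = sorted(dag.nodes)
    out = set()
    for x, y in itertools.combinations(nodes, 2):
        rest = [v for v in nodes if v not in (x, y)]
        for r in range(len(rest) + 1):
            for s in itertools.combinations(rest, r):
                if nx.is_d_separator(g, {x}, {y}, set(s)):
                    out.add((x, y, s))
    return frozenset(out)


def equivalence_class(dag: MixedGraph) -> list[MixedGraph]:
    """All DAGs with identical d-separation statements (brute force)."""
    from csdbench.graphs import enumerate_dags

    target = dsep_statements(dag)
    return [d for d in enumerate_dags(sorted(dag.nodes))
            if dsep_statements(d) == target]


def random_dag(rng: np.random.Generator, n_nodes: int,
               edge_prob: float = 0.5) -> MixedGraph:
    names = [f"V{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    g = MixedGraph(names, kind_hint="DAG")
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < edge_prob:
            g.add_directed(names[order[i]], names[order[j]])
    return g


def simulate_linear_dag(dag: MixedGraph, n: int, rng: np.random.Generator,
                        low: float = 0.3, high: float = 0.8) -> pd.DataFrame:
    """Linear-Gaussian sample from a DAG with random +/- coefficients
    bounded away from zero."""
    order = list(nx.topological_sort(to_networkx(dag)))
    data: dict[str, np.ndarray] = {}
    for v in order:
        x = rng.standard_normal(n)
        for p in dag.parents(v):
            coef = rng.uniform(low, high) * rng.choice([-1.0, 1.0])
            x = x + coef * data[p]
        data[v] = x
    return pd.DataFrame({v: data[v] for v in sorted(dag.nodes)})


def covariance_of(df: pd.DataFrame) -> CovarianceModel:
    return CovarianceModel.from_dataframe(df)
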