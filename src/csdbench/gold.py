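"""The literature-derived gold-standard causal graph.

Cross-sectional design: eight variables measured at baseline, eight
directed edges (SEX is kept as an isolated node; its weaker influences
are deliberately not part of the standard).  Longitudinal design:
biomarkers and diagnosis are duplicated at visits 0 and 24 months, the
within-visit structure is repeated at both visits, each duplicated
variable gets an autoregressive edge, and demographics point at visit-0
targets only.
"""

from __future__ import annotations

from typing import Mapping

from .graphs import MixedGraph, directed_edge

VARIABLES = ("AGE", "SEX", "EDU", "APOE4", "ABETA", "PTAU", "FDG", "DX")

#: Default edge list; overridable by passing ``edges=`` to the builder.
GOLD_EDGES: tuple[tuple[str, str], ...] = (
    ("AGE", "ABETA"),
    ("APOE4", "ABETA"),
    ("ABETA", "PTAU"),
    ("ABETA", "FDG"),
    ("PTAU", "FDG"),
    ("PTAU", "DX"),
    ("FDG", "DX"),
    ("EDU", "DX"),
)

TIME_VARYING = ("ABETA", "PTAU", "FDG", "DX")
VISITS = (0, 24)


def time_suffix_map(design: str) -> dict[str, int]:
    """Visit index per duplicated node (used by level-3 knowledge)."""
    if design == "cross_sectional":
        return {}
    return {f"{v}.{t}": t for v in TIME_VARYING for t in VISITS}


def build_gold_standard(
    design: str = "cross_sectional",
    edges: tuple[tuple[str, str], ...] = GOLD_EDGES,
) -> MixedGraph:
    """Build the gold-standard DAG for either study design."""
    if design == "cross_sectional":
        g = MixedGraph(VARIABLES, kind_hint="DAG")
        for s, t in edges:
            g.add_directed(s, t)
        return g
    if design != "longitudinal":
        raise ValueError(f"unknown design {design!r}")

    demo = [v for v in VARIABLES if v not in TIME_VARYING]
    nodes = demo + [f"{v}.{t}" for t in VISITS for v in TIME_VARYING]
    g = MixedGraph(nodes, kind_hint="DAG")
    for s, t in edges:
        s_tv, t_tv = s in TIME_VARYING, t in TIME_VARYING
        if s_tv and t_tv:
            for visit in VISITS:
                g.add_directed(f"{s}.{visit}", f"{t}.{visit}")
        elif t_tv:  # demographics feed visit-0 targets only
            g.add_directed(s, f"{t}.0")
        else:  # pragma: no cover - no such edge in the default standard
            g.add_directed(s, t)
    for v in TIME_VARYING:  # autoregressive edges
        g.add_directed(f"{v}.0", f"{v}.24")
    return g
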