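"""Background knowledge: forbidden/required edge pairs and temporal tiers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

DEMOGRAPHICS = ("AGE", "SEX", "EDU", "APOE4")


class KnowledgeError(ValueError):
    pass


@dataclass
class BackgroundKnowledge:
    """Ordered-pair constraints on directed edges.

    ``forbidden`` / ``required`` hold explicit (from, to) pairs; ``tiers``
    maps a node to an integer tier, and any pair pointing from a higher
    tier to a strictly lower tier is treated as forbidden.  Within-tier
    edges are unconstrained by the tiers.
    """

    forbidden: set[tuple[str, str]] = field(default_factory=set)
    required: set[tuple[str, str]] = field(default_factory=set)
    tiers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = self.forbidden & self.required
        if clash:
            raise KnowledgeError(f"pairs both forbidden and required: {sorted(clash)}")

    def is_forbidden(self, source: str, target: str) -> bool:
        if (source, target) in self.forbidden:
            return True
        ts, tt = self.tiers.get(source), self.tiers.get(target)
        return ts is not None and tt is not None and ts > tt

    def is_required(self, source: str, target: str) -> bool:
        return (source, target) in self.required

    def expanded_forbidden(self, nodes: Iterable[str]) -> set[tuple[str, str]]:
        """Explicit pairs plus all tier-implied pairs over ``nodes``."""
        nodes = list(nodes)
        out = set(self.forbidden)
        for s in nodes:
            for t in nodes:
                if s != t and self.is_forbidden(s, t):
                    out.add((s, t))
        return out

    def is_empty(self) -> bool:
        return not (self.forbidden or self.required or self.tiers)

    # -- YAML round-trip -----------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "forbidden": [list(p) for p in sorted(self.forbidden)],
            "required": [list(p) for p in sorted(self.required)],
            "tiers": dict(sorted(self.tiers.items())),
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "BackgroundKnowledge":
        doc = yaml.safe_load(text) or {}
        return cls(
            forbidden={tuple(p) for p in doc.get("forbidden", [])},
            required={tuple(p) for p in doc.get("required", [])},
            tiers=dict(doc.get("tiers", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundKnowledge":
        return cls.from_yaml(Path(path).read_text())


def build_background_knowledge(
    level: int,
    nodes: Iterable[str],
    time_suffix_map: Mapping[str, int] | None = None,
) -> BackgroundKnowledge:
    """Construct one of the three knowledge levels.

    Level 1: no constraints.
    Level 2: every ordered pair whose target is a demographic variable
        (AGE, SEX, EDU, APOE4) is forbidden, regardless of source.
    Level 3: level 2 plus temporal tiers -- demographics at tier 0, each
        remaining node at 1 + the rank of its visit index in
        ``time_suffix_map`` -- so edges from a later visit to an earlier
        one are forbidden.
    """
    nodes = list(nodes)
    if level not in (1, 2, 3):
        raise KnowledgeError(f"knowledge level must be 1, 2 or 3, got {level!r}")
    if level == 1:
        return BackgroundKnowledge()

    demo = [n for n in nodes if n in DEMOGRAPHICS]
    forbidden = {(s, t) for t in demo for s in nodes if s != t}
    if level == 2:
        return BackgroundKnowledge(forbidden=forbidden)

    if time_suffix_map is None:
        raise KnowledgeError("level 3 requires a time_suffix_map with visit indices")
    missing = [n for n in nodes if n not in demo and n not in time_suffix_map]
    if missing:
        raise KnowledgeError(f"level 3: no visit index for nodes {missing}")
    visit_order = sorted({time_suffix_map[n] for n in nodes if n in time_suffix_map})
    rank = {v: i + 1 for i, v in enumerate(visit_order)}
    tiers = {n: 0 for n in demo}
    tiers.update({n: rank[time_suffix_map[n]] for n in nodes if n in time_suffix_map})
    return BackgroundKnowledge(forbidden=forbidden, tiers=tiers)
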