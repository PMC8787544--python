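"""Matching dominant archetypes against expert defect classifications.

Each archetype of a fitted model is assigned, as editable YAML data rather
than code, a set of descriptive defect labels that constitute a *full* match
and a set that constitutes a *partial* match (shares features with the
archetype's pattern).  A baseline field with a dominant AT (>= 50% weight)
is compared against its expert classification through this table.  Because
historic expert classifications often did not record whether a defect was
superior or inferior (or nasal or temporal), a label without a position is a
wildcard; when both sides carry a position it must agree.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import yaml

__all__ = [
    "DefectLabel",
    "MatchOutcome",
    "MatchTable",
    "parse_label",
    "classify_match",
    "matching_summary",
    "load_match_table",
    "default_match_table",
]


class MatchOutcome(str, enum.Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"
    NO_DOMINANT_AT = "no_dominant_at"


# base class -> (admits vertical, admits horizontal)
_BASES: Dict[str, Tuple[bool, bool]] = {
    "within-normal-limits": (False, False),
    "total-loss": (False, False),
    "depression": (True, False),
    "altitudinal": (True, False),
    "arcuate": (True, False),
    "partial-arcuate": (True, False),
    "double-arcuate": (False, False),
    "nasal-step": (True, False),
    "hemianopia": (False, True),
    "temporal-wedge": (False, False),
    "quadrantanopia": (True, True),
    "central": (False, False),
    "centrocecal": (False, False),
    "paracentral": (False, False),
    "enlarged-blind-spot": (False, False),
    "peripheral-rim": (False, False),
    "cloverleaf": (False, False),
    "three-quadrant": (False, False),
    "multifocal": (False, False),
}

# normalized phrase -> base class (positions extracted separately)
_PHRASES: Dict[str, str] = {
    "within normal limits": "within-normal-limits",
    "normal": "within-normal-limits",
    "total loss": "total-loss",
    "diffuse loss": "total-loss",
    "depression": "depression",
    "altitudinal": "altitudinal",
    "partial arcuate": "partial-arcuate",
    "double arcuate": "double-arcuate",
    "arcuate": "arcuate",
    "nasal step": "nasal-step",
    "hemianopia": "hemianopia",
    "temporal wedge": "temporal-wedge",
    "quadrantanopia": "quadrantanopia",
    "quadrant": "quadrantanopia",
    "central": "central",
    "centrocecal": "centrocecal",
    "paracentral": "paracentral",
    "enlarged blind spot": "enlarged-blind-spot",
    "peripheral rim": "peripheral-rim",
    "cloverleaf": "cloverleaf",
    "three-quadrant": "three-quadrant",
    "three quadrant": "three-quadrant",
    "multifocal": "multifocal",
}


@dataclass(frozen=True)
class DefectLabel:
    """One descriptive defect class with optional position qualifiers."""

    base: str
    vertical: Optional[str] = None  # "superior" | "inferior"
    horizontal: Optional[str] = None  # "nasal" | "temporal"

    def __post_init__(self):
        if self.base not in _BASES:
            raise ValueError(f"unknown defect base class {self.base!r}")
        admits_v, admits_h = _BASES[self.base]
        if self.vertical is not None and not admits_v:
            raise ValueError(f"{self.base!r} does not admit a vertical position")
        if self.horizontal is not None and not admits_h:
            raise ValueError(f"{self.base!r} does not admit a horizontal position")
        if self.vertical not in (None, "superior", "inferior"):
            raise ValueError(f"bad vertical position {self.vertical!r}")
        if self.horizontal not in (None, "nasal", "temporal"):
            raise ValueError(f"bad horizontal position {self.horizontal!r}")

    def __str__(self):
        parts = [p for p in (self.vertical, self.horizontal) if p]
        parts.append(self.base)
        return " ".join(parts)


def _parse_single(text: str) -> DefectLabel:
    s = " ".join(text.lower().replace("_", " ").split())
    for suffix in (" vf defect", " defect"):
        if s.endswith(suffix):
            s = s[: -len(suffix)]
    vertical = None
    for v in ("superior", "inferior"):
        if s.startswith(v + " "):
            vertical = v
            s = s[len(v) + 1 :]
            break
    if s in _PHRASES:  # fixed phrases keep their own nasal/temporal words
        base = _PHRASES[s]
        horizontal = None
    else:
        horizontal = None
        for h in ("nasal", "temporal"):
            if s.startswith(h + " "):
                rest = s[len(h) + 1 :]
                if rest in _PHRASES:
                    horizontal = h
                    s = rest
                break
        if s not in _PHRASES:
            raise ValueError(f"unrecognized defect label {text!r}")
        base = _PHRASES[s]
    admits_v, admits_h = _BASES[base]
    return DefectLabel(
        base=base,
        vertical=vertical if admits_v else None,
        horizontal=horizontal if admits_h else None,
    )


def parse_label(text: Union[str, DefectLabel, Sequence]) -> Tuple[DefectLabel, ...]:
    """Parse a free-text classification into one or more defect labels.

    Expert classifications may list several components ("nasal step,
    enlarged blind spot"); each component is parsed separately and matching
    takes the best outcome over components.
    """
    if isinstance(text, DefectLabel):
        return (text,)
    if not isinstance(text, str):
        return tuple(lab for item in text for lab in parse_label(item))
    pieces: List[str] = []
    for chunk in text.split(","):
        pieces.extend(chunk.split(" or "))
    labels = [_parse_single(p) for p in pieces if p.strip()]
    if not labels:
        raise ValueError(f"empty defect label {text!r}")
    return tuple(labels)


def _labels_compatible(expert: DefectLabel, entry: DefectLabel) -> bool:
    if expert.base != entry.base:
        return False
    for a, b in ((expert.vertical, entry.vertical), (expert.horizontal, entry.horizontal)):
        if a is not None and b is not None and a != b:
            return False
    return True


@dataclass
class MatchTable:
    """Per-AT full-match and partial-match label sets (AT numbers 1-based)."""

    full: Dict[int, Tuple[DefectLabel, ...]]
    partial: Dict[int, Tuple[DefectLabel, ...]]

    def __post_init__(self):
        for at in self.full:
            overlap = set(self.full[at]) & set(self.partial.get(at, ()))
            if overlap:
                raise ValueError(
                    f"AT{at}: labels {sorted(map(str, overlap))} appear in both "
                    "full and partial sets"
                )

    @property
    def ats(self) -> Tuple[int, ...]:
        return tuple(sorted(self.full))


def load_match_table(source) -> MatchTable:
    """Load a match table from a YAML path or file-like object."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    full, partial = {}, {}
    for at, entry in doc["ats"].items():
        at = int(at)
        full[at] = tuple(lab for s in entry.get("full", []) for lab in parse_label(s))
        partial[at] = tuple(
            lab for s in entry.get("partial", []) for lab in parse_label(s)
        )
    return MatchTable(full=full, partial=partial)


def default_match_table() -> MatchTable:
    """The packaged table for the 16-AT optic-neuritis model."""
    with resources.files("vfarch.data").joinpath("match_table.yaml").open(
        encoding="utf-8"
    ) as fh:
        return load_match_table(fh)


def classify_match(
    dominant: Optional[int],
    expert,
    table: MatchTable,
) -> MatchOutcome:
    """Compare a dominant AT (1-based number, or None) with an expert label.

    Multi-component expert labels are matched component-wise and the best
    outcome (full > partial > none) is returned.
    """
    if dominant is None:
        return MatchOutcome.NO_DOMINANT_AT
    if dominant not in table.full:
        raise ValueError(f"match table has no entry for AT{dominant}")
    labels = parse_label(expert)
    best = MatchOutcome.NONE
    for lab in labels:
        if any(_labels_compatible(lab, e) for e in table.full[dominant]):
            return MatchOutcome.FULL
        if any(_labels_compatible(lab, e) for e in table.partial.get(dominant, ())):
            best = MatchOutcome.PARTIAL
    return best


def matching_summary(outcomes: Iterable[MatchOutcome]) -> dict:
    """Counts of each outcome plus match fractions among dominant-AT fields."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    counts = {o: 0 for o in MatchOutcome}
    for o in outcomes:
        counts[MatchOutcome(o)] += 1
    n_dominant = sum(
        counts[o] for o in (MatchOutcome.FULL, MatchOutcome.PARTIAL, MatchOutcome.NONE)
    )
    if n_dominant:
        full_fraction = counts[MatchOutcome.FULL] / n_dominant
        full_or_partial_fraction = (
            counts[MatchOutcome.FULL] + counts[MatchOutcome.PARTIAL]
        ) / n_dominant
    else:
        full_fraction = full_or_partial_fraction = None
    return {
        "n": len(outcomes),
        "n_dominant": n_dominant,
        "counts": {o.value: c for o, c in counts.items()},
        "full_fraction": full_fraction,
        "full_or_partial_fraction": full_or_partial_fraction,
    }
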