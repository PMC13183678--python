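"""Topology naming, glycosidic patterns, groove-width signatures and
handedness of an assembled stem."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import rise_and_twist

__all__ = [
    "TOPOLOGY_BY_PATTERN",
    "PATTERN_BY_TOPOLOGY",
    "TABLE_SIGNATURES",
    "GrooveSignature",
    "TopologyAnnotation",
    "UndefinedPatternError",
    "strand_direction_pattern",
    "topology_from_pattern",
    "gc_pattern",
    "groove_signature",
    "handedness",
    "match_by_signatures",
]

TOPOLOGY_BY_PATTERN: Dict[str, str] = {
    "dddd": "parallel",
    "dudu": "antiparallel-chair",
    "duud": "antiparallel-basket",
    "dduu": "antiparallel-basket2",
    "ddud": "hybrid1",
    "dddu": "hybrid2",
    "dudd": "hybrid3",
    "duuu": "hybrid4",
}
PATTERN_BY_TOPOLOGY = {v: k for k, v in TOPOLOGY_BY_PATTERN.items()}

# Per-topology groove-width signatures and main gc patterns (a pattern and
# its s<->a complement alternate tetrad by tetrad).
TABLE_SIGNATURES: Dict[str, Dict[str, object]] = {
    "parallel": {"groove": "iiii", "gc": ("aaaa", "ssss")},
    "antiparallel-chair": {"groove": "wnwn", "gc": ("sasa", "asas")},
    "antiparallel-basket": {"groove": "wini", "gc": ("saas", "assa")},
    "antiparallel-basket2": {"groove": "iwin", "gc": ("ssaa", "aass")},
    "hybrid1": {"groove": "iwni", "gc": ("ssas", "aasa")},
    "hybrid2": {"groove": "iiwn", "gc": ("sssa", "aaas")},
    "hybrid3": {"groove": "wnii", "gc": ("sass", "asaa")},
    "hybrid4": {"groove": "wiin", "gc": ("saaa", "asss")},
}


class UndefinedPatternError(ValueError):
    """Strand directions cannot be read off the stem."""


def strand_direction_pattern(stem) -> str:
    """Four letters of {d, u}; letter k is the direction of clockwise
    strand k. The first letter is 'd' by the orientation convention."""
    if stem.degenerate or len(stem.strands) != 4 or stem.n_tetrads < 2:
        raise UndefinedPatternError("degenerate stem has no direction pattern")
    letters = []
    for strand in stem.strands:
        if strand.direction is None:
            raise UndefinedPatternError(
                f"strand {strand.number} direction undeterminable (broken column)"
            )
        letters.append(strand.direction)
    return "".join(letters)


def topology_from_pattern(pattern: str) -> str:
    if len(pattern) != 4 or any(c not in "du" for c in pattern):
        raise ValueError(f"pattern must be 4 letters over {{d,u}}, got {pattern!r}")
    if pattern[0] != "d":
        raise ValueError("strand 1 is 'd' by convention; pattern cannot start with 'u'")
    return TOPOLOGY_BY_PATTERN[pattern]


def gc_pattern(stem) -> Tuple[List[str], List[str]]:
    """One 4-letter s/a string per tetrad (strand order 1..4); '?' marks an
    undefined glycosidic state. Returns (patterns, warnings)."""
    warnings: List[str] = []
    patterns: List[str] = []
    for t in range(stem.n_tetrads):
        letters = []
        for strand in stem.strands:
            g = strand.guanines[t] if t < len(strand.guanines) else None
            if g is None or g.gc == "undefined":
                letters.append("?")
                warnings.append(
                    f"tetrad {t + 1}, strand {strand.number}: glycosidic state undefined"
                )
            else:
                letters.append("s" if g.gc == "syn" else "a")
        patterns.append("".join(letters))
    return patterns, warnings


@dataclass
class GrooveSignature:
    widths: List[Optional[float]]  # groove k between strands k and k+1
    letters: str  # 4 of {w, n, i} ('?' when width undefined)
    min_widths: List[Optional[float]] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        return {
            "widths": [None if w is None else round(w, 2) for w in self.widths],
            "letters": self.letters,
            "min_widths": [None if w is None else round(w, 2) for w in self.min_widths],
        }


def groove_signature(stem, wide: float = 16.0, narrow: float = 11.5) -> GrooveSignature:
    """Groove k = mean over tetrads of the C5'-C5' distance between
    clockwise-adjacent strands k and k+1; letters via fixed thresholds
    (w >= wide, n <= narrow, otherwise i)."""
    widths: List[Optional[float]] = []
    min_widths: List[Optional[float]] = []
    letters = []
    for k in range(4):
        s_a = stem.strands[k]
        s_b = stem.strands[(k + 1) % 4]
        dists = []
        for t in range(stem.n_tetrads):
            a = s_a.guanines[t] if t < len(s_a.guanines) else None
            b = s_b.guanines[t] if t < len(s_b.guanines) else None
            if a is None or b is None:
                continue
            if "C5'" not in a.atoms or "C5'" not in b.atoms:
                continue
            dists.append(float(np.linalg.norm(a.atoms["C5'"] - b.atoms["C5'"])))
        if not dists:
            widths.append(None)
            min_widths.append(None)
            letters.append("?")
            continue
        w = float(np.mean(dists))
        widths.append(w)
        min_widths.append(min(dists))
        letters.append("w" if w >= wide else ("n" if w <= narrow else "i"))
    return GrooveSignature(widths=widths, letters="".join(letters), min_widths=min_widths)


def handedness(stem, blocks: Optional[List[Tuple[int, int]]] = None) -> Dict[str, object]:
    """Per-block handedness from the mean signed inter-tetrad twist (RH iff
    positive) plus the relative handedness across the block junction.
    Single-tetrad blocks are undefined ('-')."""
    blocks = blocks or stem.blocks
    _, twists = rise_and_twist(stem)
    per_block: List[str] = []
    for lo, hi in blocks:
        steps = [twists[t] for t in range(lo - 1, hi - 1) if not math.isnan(twists[t])]
        if not steps:
            per_block.append("-")
        else:
            per_block.append("RH" if float(np.mean(steps)) > 0 else "LH")
    relative = "-"
    if len(blocks) == 2:
        junction = blocks[0][1] - 1  # step index between the blocks
        if 0 <= junction < len(twists) and not math.isnan(twists[junction]):
            relative = "RH" if twists[junction] > 0 else "LH"
    return {"blocks": per_block, "relative": relative, "twists": [round(t, 2) for t in twists]}


def match_by_signatures(gc_patterns: List[str], groove_letters: str) -> Tuple[List[str], str]:
    """Fallback topology assignment from gc pattern + groove signature when
    strand directions cannot be determined (snapback-broken strands).

    Returns (candidate topologies, confidence) with confidence one of
    'both', 'signature', 'pattern', 'none'.
    """
    by_groove = {t for t, sig in TABLE_SIGNATURES.items() if sig["groove"] == groove_letters}
    by_gc = set()
    for topo, sig in TABLE_SIGNATURES.items():
        base, comp = sig["gc"]
        if all(p in (base, comp) for p in gc_patterns if "?" not in p):
            by_gc.add(topo)
    both = by_groove & by_gc
    if both:
        return sorted(both), "both"
    if by_groove:
        return sorted(by_groove), "signature"
    if by_gc:
        return sorted(by_gc), "pattern"
    return [], "none"


_ANNOTATION_FIELDS = [
    "source_id",
    "topology",
    "confidence",
    "strand_pattern",
    "n_tetrads",
    "n_blocks",
    "blocks",
    "gc_pattern",
    "groove",
    "handedness",
    "loop_combination",
    "loops",
    "discontinuities",
    "v_shaped_strands",
    "extremity_sides",
    "chain_nature",
    "sequence",
    "fn5_length",
    "fn3_length",
    "flags",
    "geometry",
    "warnings",
]


@dataclass
class TopologyAnnotation:
    """Full per-structure report (see the JSON/TSV writers)."""

    source_id: str = ""
    topology: str = "undetermined"
    confidence: str = "pattern"  # pattern | signature | both
    strand_pattern: Optional[str] = None
    n_tetrads: int = 0
    n_blocks: int = 1
    blocks: List[List[int]] = field(default_factory=list)
    gc_pattern: List[str] = field(default_factory=list)
    groove: Dict[str, object] = field(default_factory=dict)
    handedness: Dict[str, object] = field(default_factory=dict)
    loop_combination: str = ""
    loops: List[Dict[str, object]] = field(default_factory=list)
    discontinuities: List[Dict[str, object]] = field(default_factory=list)
    v_shaped_strands: List[int] = field(default_factory=list)
    extremity_sides: str = "undefined"
    chain_nature: str = "DNA"
    sequence: str = ""
    fn5_length: int = 0
    fn3_length: int = 0
    flags: List[str] = field(default_factory=list)
    geometry: Dict[str, object] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, object]:
        return {name: getattr(self, name) for name in _ANNOTATION_FIELDS}

    @classmethod
    def from_dict(cls, data: Dict[str, object]) -> "TopologyAnnotation":
        kwargs = {name: data[name] for name in _ANNOTATION_FIELDS if name in data}
        return cls(**kwargs)
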