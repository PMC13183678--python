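"""Loop taxonomy: classify the connectors between stem guanines, render
the loop-combination string, detect 0-nt loops and V-shaped strands, and
locate the 5'/3' stem extremities.

Loop kinds (length- and direction-independent definitions):
  propeller (p)  adjacent strands, different tetrads
  lateral   (l)  adjacent strands, same tetrad
  diagonal  (d)  opposite strands
  internal  (i)  same strand bottom->top, or a connector crossing blocks
                 (the linker of two-block structures)

Progression is read looking at the stem from bottom to top: '+' is
clockwise in that view (which is strand k -> k-1 in the top-view
clockwise numbering), '-' anticlockwise. Diagonal and internal loops are
rendered unsigned. Snapback loops are bracketed ("[-l]") because italics
do not survive plain text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

__all__ = [
    "Loop",
    "classify_loops",
    "render_combination",
    "parse_combination",
    "zero_nt_loops",
    "v_shaped_strands",
    "extremity_sides",
]


@dataclass
class Loop:
    kind: str  # p | l | d | i
    length_nt: int
    progression: str  # '+', '-', or 'none'
    from_strand: int
    to_strand: int
    from_tetrad: int
    to_tetrad: int
    is_snapback_loop: bool = False

    def to_dict(self) -> Dict[str, object]:
        return {
            "kind": self.kind,
            "length_nt": self.length_nt,
            "progression": self.progression,
            "from_strand": self.from_strand,
            "to_strand": self.to_strand,
            "from_tetrad": self.from_tetrad,
            "to_tetrad": self.to_tetrad,
            "is_snapback_loop": self.is_snapback_loop,
        }


def _loop_kind(from_strand: int, to_strand: int, from_tet: int, to_tet: int,
               crosses_blocks: bool) -> str:
    if crosses_blocks:
        return "i"
    if from_strand == to_strand:
        return "i"
    diff = (to_strand - from_strand) % 4
    if diff == 2:
        return "d"
    return "l" if from_tet == to_tet else "p"


def _progression(kind: str, from_strand: int, to_strand: int) -> str:
    if kind in ("d", "i"):
        return "none"
    # top-view numbering is clockwise; viewed from the bottom the apparent
    # sense flips, so k -> k-1 is '+' (clockwise from below), k -> k+1 '-'
    return "+" if (from_strand - to_strand) % 4 == 1 else "-"


def classify_loops(stem, model) -> Tuple[List[Loop], str]:
    """One Loop per connector between consecutive stem guanines in chain
    order (intra-column steps - plain stacking or bulges - are not loops).
    Returns the loops plus the rendered combination string."""
    if stem.degenerate:
        return [], ""
    seq = stem.stem_guanines_chain_order()
    chain_pos = stem._chain_pos
    blocks = stem.blocks

    def block_of(t: int) -> int:
        for bi, (lo, hi) in enumerate(blocks):
            if lo <= t <= hi:
                return bi
        return 0

    snapback_cols = {
        (d.snapback_type.split("-")[0], d.strand_number)
        for d in stem.discontinuities
        if d.kind == "snapback"
    }
    five_prime_snap_col = next((c for e, c in snapback_cols if e == "5'"), None)
    three_prime_snap_col = next((c for e, c in snapback_cols if e == "3'"), None)

    loops: List[Loop] = []
    for a, b in zip(seq, seq[1:]):
        sa, sb = stem.strand_of(a), stem.strand_of(b)
        ta, tb = stem.tetrad_of(a), stem.tetrad_of(b)
        if sa == sb and abs(ta - tb) == 1:
            continue  # column step (or bulge) within a strand
        crosses = block_of(ta) != block_of(tb)
        kind = _loop_kind(sa, sb, ta, tb, crosses)
        length = chain_pos[id(b)] - chain_pos[id(a)] - 1
        loops.append(
            Loop(
                kind=kind,
                length_nt=length,
                progression=_progression(kind, sa, sb),
                from_strand=sa,
                to_strand=sb,
                from_tetrad=ta,
                to_tetrad=tb,
            )
        )

    # a snapback loop is the connector that leaves the 5' snapback tract or
    # enters the 3' snapback tract
    if loops and five_prime_snap_col is not None and loops[0].from_strand == five_prime_snap_col:
        loops[0].is_snapback_loop = True
    if loops and three_prime_snap_col is not None and loops[-1].to_strand == three_prime_snap_col:
        loops[-1].is_snapback_loop = True

    return loops, render_combination(loops)


def render_combination(loops: List[Loop]) -> str:
    parts = []
    for lp in loops:
        sign = "" if lp.progression == "none" else lp.progression
        token = f"{sign}{lp.kind}"
        if lp.is_snapback_loop:
            token = f"[{token}]"
        parts.append(token)
    return "".join(parts)


def parse_combination(text: str) -> List[Tuple[str, str, bool]]:
    """Inverse of :func:`render_combination` at the token level:
    [(sign, kind, is_snapback), ...] where sign is '+', '-' or ''."""
    tokens: List[Tuple[str, str, bool]] = []
    i = 0
    while i < len(text):
        snap = False
        if text[i] == "[":
            snap = True
            i += 1
        sign = ""
        if text[i] in "+-":
            sign = text[i]
            i += 1
        kind = text[i]
        if kind not in "pldi":
            raise ValueError(f"bad loop kind {kind!r} in {text!r}")
        i += 1
        if snap:
            if i >= len(text) or text[i] != "]":
                raise ValueError(f"unbalanced bracket in {text!r}")
            i += 1
        tokens.append((sign, kind, snap))
    return tokens


def zero_nt_loops(loops: List[Loop], stem) -> Tuple[List[Loop], List[str]]:
    """0-nt loops (a single phosphate) with their licensing evidence.

    Every 0-nt loop should be propeller and requires a discontinuity before
    one of the two guanosines it connects; a 0-nt loop with no adjacent
    discontinuity yields a consistency warning instead of evidence.
    """
    warnings: List[str] = []
    found: List[Loop] = []
    disc_strands = {d.strand_number for d in stem.discontinuities}
    for lp in loops:
        if lp.length_nt != 0:
            continue
        found.append(lp)
        if lp.kind != "p":
            warnings.append(
                f"0-nt loop between strands {lp.from_strand} and {lp.to_strand} "
                f"classified {lp.kind!r}, expected propeller"
            )
        if not ({lp.from_strand, lp.to_strand} & disc_strands):
            warnings.append(
                f"0-nt loop between strands {lp.from_strand} and {lp.to_strand} "
                "has no licensing discontinuity on either strand"
            )
    return found, warnings


def _bend_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def v_shaped_strands(stem, loops: List[Loop], model=None, max_angle: float = 150.0) -> List[int]:
    """Strands whose backbone phosphorus path turns through the stem right
    after a 0-nt loop (three successive P positions forming the V)."""
    flagged: List[int] = []
    for lp in loops:
        if lp.length_nt != 0:
            continue
        strand = stem.strands[lp.to_strand - 1]
        ps = []
        gs = sorted(
            (g for g in strand.guanines if g is not None),
            key=lambda g: stem._chain_pos[id(g)],
        )
        for g in gs:
            if "P" in g.atoms:
                ps.append(g.atoms["P"])
        if len(ps) < 3:
            continue
        angle = min(
            _bend_angle(ps[k], ps[k + 1], ps[k + 2]) for k in range(len(ps) - 2)
        )
        if angle <= max_angle:
            flagged.append(strand.number)
    return sorted(set(flagged))


def extremity_sides(stem) -> str:
    """same / opposite / middle position of the first and last stem
    guanines; 'undefined' for a degenerate stem."""
    if stem.degenerate or stem.n_tetrads < 2:
        return "undefined"
    seq = stem.stem_guanines_chain_order()
    t_first = stem.tetrad_of(seq[0])
    t_last = stem.tetrad_of(seq[-1])
    extremes = {1, stem.n_tetrads}
    if t_first not in extremes or t_last not in extremes:
        return "middle"
    return "same" if t_first == t_last else "opposite"
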