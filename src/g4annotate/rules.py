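"""Rule engine for loop-length -> topology constraints.

Encodes the observed relationships between the three basic loop lengths
(L1, L2, L3) and the eight one-block topologies as a queryable constraint
set with per-rule provenance. Percentages attached to the allowed
topologies are dataset frequencies carried as ordinal labels, not
probabilities. The engine never returns an empty allowed set: queries
matched by no rule yield all eight topologies with a "no rule" caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = [
    "ALL_TOPOLOGIES",
    "RuleQuery",
    "RulePrediction",
    "allowed_topologies",
    "diagonal_compatible",
    "diagonal_min_length_rule",
    "predict_extremity_sides",
    "tetrad_count_tendency",
    "duplex_capable",
    "four_tetrad_loop_check",
]

ALL_TOPOLOGIES = (
    "parallel",
    "antiparallel-chair",
    "antiparallel-basket",
    "antiparallel-basket2",
    "hybrid1",
    "hybrid2",
    "hybrid3",
    "hybrid4",
)

DIAGONAL_TOPOLOGIES = frozenset(
    {"antiparallel-basket", "antiparallel-basket2", "hybrid2"}
)

DIAGONAL_MIN_NT = 4
DUPLEX_MIN_NT = 10  # 3 WC base pairs + 4 nts for the hairpin turn


@dataclass(frozen=True)
class RuleQuery:
    L1: int
    L2: int
    L3: int
    has_modified_guanines: bool = False
    has_ligand: bool = False
    chain_nature: str = "DNA"
    n_tetrads_hint: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "L3"):
            if getattr(self, name) < 0:
                raise ValueError(f"loop length {name} must be >= 0")


@dataclass
class RulePrediction:
    allowed: List[Tuple[str, str]]  # (topology, weight label)
    excluded: List[Tuple[str, str]]  # (topology, reason)
    matched_rules: List[str]
    caveats: List[str] = field(default_factory=list)

    def allowed_topologies(self) -> List[str]:
        return [t for t, _ in self.allowed]

    def to_dict(self) -> Dict[str, object]:
        return {
            "allowed": [list(x) for x in self.allowed],
            "excluded": [list(x) for x in self.excluded],
            "matched_rules": self.matched_rules,
            "caveats": self.caveats,
        }


def duplex_capable(loop_length_nt: int) -> bool:
    """Can a loop of this length fold into a stabilizing duplex?"""
    if loop_length_nt < 0:
        raise ValueError("loop length must be >= 0")
    return loop_length_nt >= DUPLEX_MIN_NT


def _rule_two_1nt(q: RuleQuery):
    ones = sum(1 for L in (q.L1, q.L2, q.L3) if L == 1)
    if ones >= 2:
        return [("parallel", "100%")], "R1:two-1nt-loops"
    return None


def _rule_l1l3_1(q: RuleQuery):
    if q.L1 == 1 and q.L3 == 1 and 1 <= q.L2 <= 15:
        return [("parallel", "100%")], "R2:L1=L3=1"
    return None


def _rule_l1l3_2(q: RuleQuery):
    if not (q.L1 == 2 and q.L3 == 2):
        return None
    if q.L2 == 1:
        return [("parallel", "100%")], "R3:L1=L3=2,L2=1"
    if q.L2 == 2:
        return (
            [("parallel", "major 73%"), ("antiparallel-chair", "minor 27%")],
            "R3:L1=L3=2,L2=2",
        )
    if q.L2 == 3:
        return [("antiparallel-chair", "100%")], "R3:L1=L3=2,L2=3"
    if q.L2 in (4, 5):
        return [("antiparallel-basket", "100%")], "R3:L1=L3=2,L2=4-5"
    if duplex_capable(q.L2):
        return [("antiparallel-chair", "duplex-stabilized")], "R3:L1=L3=2,L2-duplex"
    return None


def _rule_l1l3_3(q: RuleQuery):
    if not (q.L1 == 3 and q.L3 == 3):
        return None
    if q.L2 == 1:
        return [("parallel", "100%")], "R4:L1=L3=3,L2=1"
    if q.L2 == 2:
        return [("hybrid3", "100%")], "R4:L1=L3=3,L2=2"
    if q.L2 == 3:
        return (
            [
                ("hybrid1", "50%"),
                ("hybrid3", "27%"),
                ("antiparallel-chair", "19%"),
                ("antiparallel-basket2", "4%"),
            ],
            "R4:L1=L3=3,L2=3",
        )
    if q.L2 in (4, 5):
        return (
            [("antiparallel-basket", "75%"), ("antiparallel-basket2", "25%")],
            "R4:L1=L3=3,L2=4-5",
        )
    return None


_LENGTH_RULES = (_rule_two_1nt, _rule_l1l3_1, _rule_l1l3_2, _rule_l1l3_3)


def allowed_topologies(q: RuleQuery) -> RulePrediction:
    """Allowed/excluded topologies for a loop-length query.

    Length rules fire in priority order (the most specific, two-1-nt-loop
    rule first); when modified guanines or a ligand are flagged, no
    exclusion is forced and a caveat is emitted instead, because both can
    override the length constraints.
    """
    caveats: List[str] = []
    flagged = q.has_modified_guanines or q.has_ligand
    matched: List[str] = []
    allowed: List[Tuple[str, str]] = []

    for rule in _LENGTH_RULES:
        hit = rule(q)
        if hit is not None:
            allowed, rule_id = hit
            matched.append(rule_id)
            break

    if not allowed:
        caveats.append("no rule matches these loop lengths; all topologies allowed")
        return RulePrediction(
            allowed=[(t, "unconstrained") for t in ALL_TOPOLOGIES],
            excluded=[],
            matched_rules=["R0:fallback"],
            caveats=caveats,
        )

    if flagged:
        reasons = []
        if q.has_modified_guanines:
            reasons.append(
                "modified guanines (e.g. BrG inducing syn) can override loop-length rules"
            )
        if q.has_ligand:
            reasons.append("a bound ligand can switch the topology")
        caveats.extend(reasons)
        matched.append("R5:flags-no-exclusion")
        allowed_names = {t for t, _ in allowed}
        extra = [(t, "not excluded (flagged query)") for t in ALL_TOPOLOGIES if t not in allowed_names]
        return RulePrediction(
            allowed=allowed + extra,
            excluded=[],
            matched_rules=matched,
            caveats=caveats,
        )

    allowed_names = {t for t, _ in allowed}
    excluded = [
        (t, f"excluded by {matched[0]}") for t in ALL_TOPOLOGIES if t not in allowed_names
    ]
    return RulePrediction(
        allowed=allowed, excluded=excluded, matched_rules=matched, caveats=caveats
    )


def diagonal_compatible(topology: str) -> bool:
    """Only antiparallel-basket, antiparallel-basket2 and hybrid2 can
    accommodate a diagonal loop."""
    if topology not in ALL_TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    return topology in DIAGONAL_TOPOLOGIES


@dataclass(frozen=True)
class DiagonalLengthCheck:
    ok: bool
    message: str


def diagonal_min_length_rule(n_nts: int) -> DiagonalLengthCheck:
    """Diagonal loops, even snapback loops, should be >= 4 nts."""
    if n_nts < 0:
        raise ValueError("loop length must be >= 0")
    if n_nts >= DIAGONAL_MIN_NT:
        return DiagonalLengthCheck(True, "pass")
    return DiagonalLengthCheck(
        False,
        f"violation: {n_nts}-nt diagonal loop is below the {DIAGONAL_MIN_NT}-nt "
        "minimum (the only known 3-nt diagonal loops belong to structures with "
        "multiple anomalies, e.g. a non-planar first tetrad)",
    )


_EXTREMITY_MAP = {
    "parallel": "opposite",
    "antiparallel-chair": "same",
    "antiparallel-basket": "same",
    "antiparallel-basket2": "same",
    "hybrid1": "opposite",
}


def predict_extremity_sides(
    topology: str, chain_nature: str = "DNA", has_5p_bottom_snapback: bool = False
) -> str:
    """Expected relative position of the 5'/3' stem extremities."""
    if topology in _EXTREMITY_MAP:
        return _EXTREMITY_MAP[topology]
    if topology in ("hybrid2", "hybrid3"):
        if chain_nature not in ("DNA", "RNA"):
            raise ValueError(f"unknown chain nature {chain_nature!r}")
        return "same" if chain_nature == "RNA" else "opposite"
    if topology == "hybrid4":
        return "middle" if has_5p_bottom_snapback else "same"
    raise ValueError(f"unknown topology {topology!r}")


def tetrad_count_tendency(topology: str, chain_nature: str = "DNA") -> Tuple[int, str]:
    """Preferred tetrad count: 3 for parallel and DNA hybrids, 2 for
    antiparallel topologies and non-parallel RNA."""
    if topology not in ALL_TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    if topology.startswith("antiparallel"):
        return 2, (
            "antiparallel structures are mostly 2-tetrad: facing bottom loops "
            "H-bond into a proxy third layer, and a 3-tetrad heteropolar stack "
            "would end strands in the unfavorable syn configuration"
        )
    if topology != "parallel" and chain_nature == "RNA":
        return 2, "non-parallel G4-RNAs are 2-tetrad, stabilized by WC duplexes"
    return 3, (
        "parallel and hybrid G4s are mostly 3-tetrad; propeller loops alone "
        "do not stabilize a 2-tetrad parallel stem"
    )


def four_tetrad_loop_check(n_tetrads: int, loop_lengths, loop_kinds=None) -> List[str]:
    """A 4-tetrad parallel-type stem needs at least 2-nt propeller loops;
    warn for each propeller loop shorter than that."""
    warnings: List[str] = []
    if n_tetrads != 4:
        return warnings
    kinds = list(loop_kinds) if loop_kinds is not None else ["p"] * len(loop_lengths)
    for i, (L, kind) in enumerate(zip(loop_lengths, kinds), start=1):
        if kind == "p" and L < 2:
            warnings.append(
                f"loop {i}: a {L}-nt propeller loop cannot span the ~18 A height "
                "of a 4-tetrad stem (needs >= 2 nts)"
            )
    return warnings
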