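"""End-to-end annotation: structure model -> TopologyAnnotation."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from . import loops as loops_mod
from . import rules
from .geometry import GeometryConstants, rise_and_twist, stem_height, tetrad_planarity
from .tetrads import StemAssemblyError, assemble_stem, detect_discontinuities, detect_tetrads
from .topology import (
    TopologyAnnotation,
    UndefinedPatternError,
    gc_pattern,
    groove_signature,
    handedness,
    match_by_signatures,
    strand_direction_pattern,
    topology_from_pattern,
)

__all__ = ["AnnotationConfig", "annotate_structure"]


@dataclass(frozen=True)
class AnnotationConfig:
    """Detection tolerances and geometry constants (defaults reproduce the
    published values)."""

    hbond_cutoff: float = 3.5
    planarity_tol: float = 0.75
    groove_wide: float = 16.0
    groove_narrow: float = 11.5
    constants: GeometryConstants = field(default_factory=GeometryConstants)


DEFAULT_CONFIG = AnnotationConfig()


def _sequence_string(model) -> str:
    parts = []
    for chain in model.chains:
        parts.append(
            "".join(
                nt.parent_base.lower() if nt.is_modified else nt.parent_base
                for nt in chain
            )
        )
    return "&".join(parts)


def _fn_lengths(model, stem) -> tuple:
    """Counts of flanking nucleotides before the first / after the last
    stem guanine, within their respective chains."""
    positions = set(stem.stem_sequence_positions)
    residues = model.residues()
    if not positions:
        return 0, 0
    first, last = min(positions), max(positions)
    # chain-local offsets
    offset = 0
    fn5 = fn3 = 0
    for chain in model.chains:
        lo, hi = offset, offset + len(chain) - 1
        if lo <= first <= hi:
            fn5 = first - lo
        if lo <= last <= hi:
            fn3 = hi - last
        offset += len(chain)
    return fn5, fn3


def _block_pattern(stem, block) -> Optional[str]:
    """Strand-direction pattern of one block, from chain progression of the
    in-block column segments."""
    lo, hi = block
    if hi - lo < 1:
        return None
    letters = []
    for strand in stem.strands:
        votes = []
        seg = [(t, strand.guanines[t - 1]) for t in range(lo, hi + 1)]
        for (ta, a), (tb, b) in zip(seg, seg[1:]):
            pa, pb = stem.chain_position(a), stem.chain_position(b)
            if abs(stem.stem_guanines_chain_order().index(a) - stem.stem_guanines_chain_order().index(b)) == 1:
                votes.append(1 if pb > pa else -1)
        if not votes:
            return None
        letters.append("d" if sum(votes) > 0 else "u")
    return "".join(letters)


def _two_block_name(stem) -> tuple:
    names = []
    patterns = []
    for block in stem.blocks:
        lo, hi = block
        if hi == lo:
            names.append("-")
            patterns.append("-")
            continue
        pat = _block_pattern(stem, block)
        patterns.append(pat or "?")
        if pat is None:
            names.append("?")
        elif pat[0] == "u":
            # a block entered from below reads as the reverse pattern; all
            # resolved two-block blocks are parallel, keep the simple map
            names.append("parallel" if set(pat) == {"u"} else "?")
        else:
            try:
                names.append(topology_from_pattern(pat))
            except (KeyError, ValueError):
                names.append("?")
    return "two-block:" + "/".join(names), "/".join(patterns)


def annotate_structure(model, config: AnnotationConfig = DEFAULT_CONFIG) -> TopologyAnnotation:
    """Annotate one structure model. Never raises on classification
    failures; problems are reported in ``warnings`` and the topology
    becomes 'undetermined'."""
    ann = TopologyAnnotation(source_id=model.source_id)
    ann.chain_nature = model.chain_nature()
    ann.sequence = _sequence_string(model)
    warnings: List[str] = []

    tetrads = detect_tetrads(
        model, hbond_cutoff=config.hbond_cutoff, planarity_tol=config.planarity_tol
    )
    ann.n_tetrads = len(tetrads)
    if not tetrads:
        ann.topology = "undetermined"
        ann.warnings = ["no G-tetrad detected"]
        return ann

    if any(nt.is_modified and nt.is_guanine for nt in model.residues()):
        ann.flags.append("modified_guanines")
    if model.metadata.get("n_hetero", 0):
        ann.flags.append("ligand_present")

    try:
        stem = assemble_stem(tetrads, model)
    except StemAssemblyError as exc:
        ann.topology = "undetermined"
        ann.warnings = [f"stem assembly failed: {exc}"]
        return ann

    detect_discontinuities(stem, model)
    ann.n_blocks = len(stem.blocks)
    ann.blocks = [list(b) for b in stem.blocks]
    ann.discontinuities = [
        {
            "kind": d.kind,
            "strand": d.strand_number,
            "between_tetrads": list(d.between_tetrads),
            "inserted_nts": d.inserted_nts,
            "snapback_type": d.snapback_type,
        }
        for d in stem.discontinuities
    ]

    if stem.degenerate:
        ann.topology = "undetermined"
        ann.warnings = ["single tetrad: degenerate stem, no topology"]
        ann.extremity_sides = "undefined"
        ann.loop_combination = ""
        return ann

    gc_patterns, gc_warn = gc_pattern(stem)
    warnings.extend(gc_warn)
    ann.gc_pattern = gc_patterns
    groove = groove_signature(stem, wide=config.groove_wide, narrow=config.groove_narrow)
    ann.groove = groove.to_dict()
    ann.handedness = handedness(stem)
    if "LH" in ann.handedness["blocks"] or (
        len(set(b for b in ann.handedness["blocks"] if b != "-")) > 1
    ):
        ann.flags.append("platypus_suspect")

    loop_list, combination = loops_mod.classify_loops(stem, model)
    ann.loops = [lp.to_dict() for lp in loop_list]
    ann.loop_combination = combination
    _, zwarn = loops_mod.zero_nt_loops(loop_list, stem)
    warnings.extend(zwarn)
    ann.v_shaped_strands = loops_mod.v_shaped_strands(stem, loop_list, model)
    ann.extremity_sides = loops_mod.extremity_sides(stem)
    ann.fn5_length, ann.fn3_length = _fn_lengths(model, stem)

    if ann.n_blocks == 2:
        ann.topology, ann.strand_pattern = _two_block_name(stem)
        ann.confidence = "pattern"
    else:
        try:
            pattern = strand_direction_pattern(stem)
            ann.strand_pattern = pattern
            ann.topology = topology_from_pattern(pattern)
            ann.confidence = "pattern"
        except (UndefinedPatternError, ValueError, KeyError) as exc:
            candidates, conf = match_by_signatures(gc_patterns, groove.letters)
            if len(candidates) == 1:
                ann.topology = candidates[0]
                ann.confidence = conf
                warnings.append(
                    f"strand directions unreadable ({exc}); topology from "
                    f"gc pattern / groove signature"
                )
            else:
                ann.topology = "undetermined"
                warnings.append(
                    f"strand directions unreadable ({exc}); signature match "
                    f"ambiguous: {candidates}"
                )

    height, hwarn = stem_height(stem)
    warnings.extend(hwarn)
    rises, twists = rise_and_twist(stem)
    ann.geometry = {
        "stem_height": round(height, 2),
        "rises": [round(r, 3) for r in rises],
        "twists": [round(t, 2) for t in twists],
        "tetrad_planarity": [round(tetrad_planarity(t), 3) for t in stem.tetrads],
    }

    basic = [lp for lp in loop_list if not lp.is_snapback_loop]
    warnings.extend(
        rules.four_tetrad_loop_check(
            ann.n_tetrads,
            [lp.length_nt for lp in basic],
            [lp.kind for lp in basic],
        )
    )
    for lp in loop_list:
        if lp.kind == "d":
            check = rules.diagonal_min_length_rule(lp.length_nt)
            if not check.ok:
                warnings.append(check.message)
    ann.warnings = warnings
    return ann
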