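"""Quantitative geometric model of the G4 stem and its loops.

Implements the C5'-spacing statistics, the loop-span model
``span(n) = (n + 1) * mean_c5_step``, the diagonal-loop feasibility
threshold ``diagonal_c5 + 2 * mean_rise``, stem heights, per-step
rise/twist, and tetrad planarity. All constants default to the published
averages and are overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GeometryConstants",
    "DEFAULT_CONSTANTS",
    "DiagonalFeasibility",
    "successive_c5_distances",
    "loop_span_model",
    "diagonal_feasibility",
    "stem_height",
    "rise_and_twist",
    "tetrad_planarity",
    "fit_plane",
]


@dataclass(frozen=True)
class GeometryConstants:
    """Average distances (Å) that parameterize the geometric model.

    mean_c5_step     mean distance between C5' atoms of successive nts
    mean_rise        mean rise of guanines in the stem
    diagonal_c5      mean distance between diagonal C5' atoms of a tetrad
    height_3tetrad   typical C5'-C5' stem height, 3 tetrads
    height_4tetrad   typical C5'-C5' stem height, 4 tetrads
    """

    mean_c5_step: float = 6.25
    mean_rise: float = 3.42
    diagonal_c5: float = 21.0
    height_3tetrad: float = 12.0
    height_4tetrad: float = 18.0

    def __post_init__(self) -> None:
        for name in (
            "mean_c5_step",
            "mean_rise",
            "diagonal_c5",
            "height_3tetrad",
            "height_4tetrad",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONSTANTS = GeometryConstants()


def successive_c5_distances(model) -> Tuple[List[float], Optional[float], int]:
    """Distances between C5' atoms of consecutive intra-chain residues.

    Returns ``(distances, mean, n_skipped)`` where pairs missing a C5' atom
    are skipped (and counted). The mean is ``None`` when no pair exists.
    """
    dists: List[float] = []
    skipped = 0
    for chain in model.chains:
        for a, b in zip(chain, chain[1:]):
            if "C5'" in a.atoms and "C5'" in b.atoms:
                dists.append(float(np.linalg.norm(a.atoms["C5'"] - b.atoms["C5'"])))
            else:
                skipped += 1
    mean = float(np.mean(dists)) if dists else None
    return dists, mean, skipped


def loop_span_model(n_nts: int, constants: GeometryConstants = DEFAULT_CONSTANTS) -> float:
    """Modeled end-to-end span of an n-nt loop: (n + 1) C5' steps."""
    if n_nts < 0:
        raise ValueError("loop length must be >= 0")
    return (n_nts + 1) * constants.mean_c5_step


@dataclass(frozen=True)
class DiagonalFeasibility:
    feasible: bool
    modeled_length: float
    threshold: float


def diagonal_feasibility(
    n_nts: int, constants: GeometryConstants = DEFAULT_CONSTANTS
) -> DiagonalFeasibility:
    """Can an n-nt diagonal loop bridge the tetrad diagonal?

    The threshold is the diagonal C5'-C5' distance plus one rise of
    clearance at each loop end (27.84 Å under defaults, ~28 Å as printed).
    """
    threshold = constants.diagonal_c5 + 2.0 * constants.mean_rise
    length = loop_span_model(n_nts, constants)
    return DiagonalFeasibility(feasible=length >= threshold, modeled_length=length, threshold=threshold)


def stem_height(stem) -> Tuple[float, List[str]]:
    """Mean per-strand C5'-C5' distance between the two extreme tetrads.

    Returns ``(height, warnings)``; 0 for a single-tetrad stem. Strands
    missing a C5' on either extreme guanine are skipped with a warning.
    """
    warnings: List[str] = []
    if len(stem.tetrads) < 2:
        return 0.0, warnings
    dists = []
    for strand in stem.strands:
        gs = strand.guanines
        top, bottom = gs[0], gs[-1]
        if top is None or bottom is None:
            warnings.append(f"strand {strand.number}: incomplete column, skipped")
            continue
        if "C5'" not in top.atoms or "C5'" not in bottom.atoms:
            warnings.append(f"strand {strand.number}: missing C5', skipped")
            continue
        dists.append(float(np.linalg.norm(top.atoms["C5'"] - bottom.atoms["C5'"])))
    if not dists:
        warnings.append("no strand had usable C5' atoms")
        return float("nan"), warnings
    return float(np.mean(dists)), warnings


def _tetrad_guanine_base_centroid(nt) -> np.ndarray:
    ring = [n for n in ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4") if n in nt.atoms]
    return np.mean([nt.atoms[n] for n in ring], axis=0)


def rise_and_twist(stem) -> Tuple[List[float], List[float]]:
    """Per-step rise (Å) and signed twist (degrees) between consecutive
    tetrads, measured about the stem axis in the top-view frame.

    The sign convention is the one under which the canonical right-handed
    synthetic stem measures +30 degrees per step. Empty lists for a
    single-tetrad stem.
    """
    if len(stem.tetrads) < 2:
        return [], []
    ez, ex, ey = stem.frame()
    rises: List[float] = []
    twists: List[float] = []
    for t in range(len(stem.tetrads) - 1):
        upper, lower = stem.tetrads[t], stem.tetrads[t + 1]
        rises.append(abs(float(np.dot(upper.centroid - lower.centroid, ez))))
        step_angles = []
        for strand in stem.strands:
            a, b = strand.guanines[t], strand.guanines[t + 1]
            if a is None or b is None:
                continue
            # C1' anchors are invariant under tetrad polarity flips, so the
            # measured twist is the backbone twist, not base-ring motion
            pa = a.atoms.get("C1'", _tetrad_guanine_base_centroid(a)) - upper.centroid
            pb = b.atoms.get("C1'", _tetrad_guanine_base_centroid(b)) - lower.centroid
            tha = math.atan2(np.dot(pa, ey), np.dot(pa, ex))
            thb = math.atan2(np.dot(pb, ey), np.dot(pb, ex))
            d = math.degrees(tha - thb)
            while d > 180.0:
                d -= 360.0
            while d <= -180.0:
                d += 360.0
            step_angles.append(d)
        twists.append(float(np.mean(step_angles)) if step_angles else float("nan"))
    return rises, twists


def fit_plane(points: Sequence[np.ndarray]) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through points: (centroid, unit normal, RMS)."""
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    rms = float(np.sqrt(np.mean(np.square(centered @ normal))))
    return centroid, normal, rms


def tetrad_planarity(tetrad) -> float:
    """RMS deviation (Å) of the tetrad's base ring atoms from their
    best-fit plane."""
    points = []
    for nt in tetrad.guanines:
        for name in ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"):
            if name in nt.atoms:
                points.append(nt.atoms[name])
    if len(points) < 4:
        points = [_tetrad_guanine_base_centroid(nt) for nt in tetrad.guanines]
    _, _, rms = fit_plane(points)
    return rms
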