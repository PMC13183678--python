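"""Idealized G-quadruplex coordinate generator with known ground truth.

Builds planar Hoogsteen-closed G-tetrads stacked with configurable
rise/twist, threads a single nucleotide chain through them according to
the requested topology (strand directions per the eight canonical
patterns, clockwise strand numbering), places loop nucleotides on
interpolated backbone paths, and optionally adds snapbacks, bulges,
flanking nucleotides and Gaussian noise.

Geometry model
--------------
The guanine base + sugar template derives from ideal deoxyguanosine
coordinates (PDB chemical component dictionary), fitted once into a
C4-symmetric planar tetrad (N1->O6 2.90 A, N2->N7 2.85 A) and frozen
below. Nucleotides are rigid: a tetrad "polarity" flip of the base about
the radial axis through C1' models heteropolar steps, a flip of the
sugar about the same axis models strand direction. The glycosidic state
then *emerges* (anti ~ -153 deg for face-up/down-strand and
face-down/up-strand, syn ~ +33 deg otherwise), reproducing the canonical
per-topology gc patterns and groove asymmetry (the wide groove falls
between clockwise-adjacent down->up strands).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure_io import Nucleotide, StructureModel, assign_glycosidic, compute_chi
from .topology import PATTERN_BY_TOPOLOGY

__all__ = [
    "SyntheticSpec",
    "BuildError",
    "build_g4",
    "perturb",
    "write_pdb",
    "to_pdb_string",
    "DEFAULT_LOOPS",
]


class BuildError(ValueError):
    """The requested specification is not geometrically realizable."""


# --- frozen template (see module docstring) --------------------------------

GUANINE_BASE = {
    "N9": (6.6138, 0.3509, 0.0003),
    "C8": (6.0948, 1.6122, -0.0000),
    "N7": (4.7945, 1.5549, 0.0005),
    "C5": (4.4031, 0.2573, 0.0012),
    "C6": (3.1468, -0.3929, 0.0020),
    "O6": (2.1113, 0.2500, 0.0022),
    "N1": (3.1241, -1.7434, -0.0048),
    "C2": (4.2874, -2.4519, 0.0011),
    "N2": (4.2330, -3.8226, 0.0019),
    "N3": (5.4605, -1.8597, 0.0017),
    "C4": (5.5635, -0.5259, -0.0001),
}
SUGAR_D = {
    "P": (10.9878, 4.6500, 1.7142),
    "O5'": (10.5632, 3.1051, 1.5576),
    "C5'": (10.2591, 2.8989, 0.1775),
    "C4'": (9.8456, 1.4426, -0.0418),
    "O4'": (8.6038, 1.1536, 0.6401),
    "C3'": (9.5088, 1.1886, -1.5333),
    "O3'": (10.6878, 0.8665, -2.2750),
    "C2'": (8.5592, -0.0299, -1.4483),
    "C1'": (8.0351, 0.0000, 0.0000),
}

_FLIP = np.diag([1.0, -1.0, -1.0])  # 180 deg about the radial (x) axis


def _rz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# chain plans: tract visiting order as (clockwise column, direction) plus
# the implied kind of each of the three connecting loops
_PLANS: Dict[str, Tuple[List[Tuple[int, str]], str]] = {
    "parallel": ([(1, "d"), (2, "d"), (3, "d"), (4, "d")], "ppp"),
    "antiparallel-chair": ([(1, "d"), (4, "u"), (3, "d"), (2, "u")], "lll"),
    "antiparallel-basket": ([(1, "d"), (2, "u"), (4, "d"), (3, "u")], "ldl"),
    "antiparallel-basket2": ([(1, "d"), (4, "u"), (2, "d"), (3, "u")], "ldl"),
    "hybrid1": ([(1, "d"), (2, "d"), (3, "u"), (4, "d")], "pll"),
    "hybrid2": ([(1, "d"), (2, "d"), (4, "u"), (3, "d")], "pdl"),
    "hybrid3": ([(1, "d"), (2, "u"), (3, "d"), (4, "d")], "llp"),
    "hybrid4": ([(1, "d"), (4, "u"), (3, "u"), (2, "u")], "lpp"),
}

DEFAULT_LOOPS: Dict[str, Tuple[int, int, int]] = {
    "parallel": (1, 2, 1),
    "antiparallel-chair": (2, 3, 2),
    "antiparallel-basket": (2, 4, 2),
    "antiparallel-basket2": (3, 4, 3),
    "hybrid1": (2, 3, 3),
    "hybrid2": (1, 4, 2),
    "hybrid3": (3, 3, 2),
    "hybrid4": (3, 1, 2),
}

TWO_BLOCK_TOPOLOGY = "two-block:parallel/parallel"


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth specification of an idealized G4 model."""

    topology: str = "parallel"
    n_tetrads: int = 3
    loop_lengths: Optional[Tuple[int, int, int]] = None
    gc_pattern: Optional[Tuple[str, ...]] = None
    rise: float = 3.42
    twist: float = 30.0  # degrees per step; negative = left-handed
    chain_nature: str = "DNA"
    snapback: Optional[str] = None  # "5p-bottom" (hybrid4 layout)
    snapback_loop_length: int = 4
    bulges: Tuple[Tuple[int, int, int], ...] = ()  # (tract 1-4, after tetrad, n nts)
    block2_up: bool = False  # two-block only: block2 strands run up
    fn5: int = 0
    fn3: int = 0
    noise_sigma: float = 0.0
    seed: int = 0
    force: bool = False


def _default_faces(pattern: str, n_tetrads: int) -> List[str]:
    if pattern == "dddd":
        return ["up"] * n_tetrads
    return ["down" if t % 2 == 0 else "up" for t in range(n_tetrads)]


def _gc_from_faces(pattern: str, faces: Sequence[str]) -> List[str]:
    out = []
    for face in faces:
        letters = [
            "s" if (face == "down") == (d == "d") else "a" for d in pattern
        ]
        out.append("".join(letters))
    return out


def _faces_from_gc(pattern: str, gc: Sequence[str]) -> List[str]:
    faces = []
    for t, row in enumerate(gc):
        wanted = set()
        for d, letter in zip(pattern, row):
            if letter == "s":
                wanted.add("down" if d == "d" else "up")
            else:
                wanted.add("up" if d == "d" else "down")
        if len(wanted) != 1:
            raise BuildError(
                f"gc pattern {row!r} for tetrad {t + 1} mixes tetrad polarities; "
                "not realizable with strand directions " + pattern
            )
        faces.append(wanted.pop())
    return faces


def _stem_guanine_atoms(column: int, tetrad: int, face: str, direction: str,
                        rise: float, twist: float) -> Dict[str, np.ndarray]:
    """Atom dict for the stem guanine at (clockwise column 1-4, tetrad
    1-based from the top)."""
    slot_az = -90.0 * (column - 1)
    tet_rot = -twist * (tetrad - 1)  # positive twist = right-handed stack
    R = _rz(slot_az + tet_rot)
    atoms: Dict[str, np.ndarray] = {}
    for name, xyz in GUANINE_BASE.items():
        p = np.asarray(xyz, dtype=float)
        if face == "down":
            p = _FLIP @ p
        atoms[name] = R @ p
    for name, xyz in SUGAR_D.items():
        p = np.asarray(xyz, dtype=float)
        if direction == "u":
            p = _FLIP @ p
        atoms[name] = R @ p
    z = -(tetrad - 1) * rise
    for name in atoms:
        atoms[name] = atoms[name] + np.array([0.0, 0.0, z])
    return atoms


def _loop_residue_atoms(point: np.ndarray, nxt: np.ndarray) -> Dict[str, np.ndarray]:
    """Minimal nucleotide around a backbone path point; C5' sits on the
    path, the rest at small fixed offsets (enough for the annotator)."""
    out_dir = point[:2]
    nrm = np.linalg.norm(out_dir)
    radial = np.array([*(out_dir / nrm if nrm > 1e-6 else (1.0, 0.0)), 0.0])
    ahead = nxt - point
    ahead = ahead / max(np.linalg.norm(ahead), 1e-6)
    atoms = {
        "C5'": point.copy(),
        "C4'": point + 0.9 * ahead + 0.6 * radial,
        "C3'": point + 1.8 * ahead + 0.4 * radial,
        "O3'": point + 2.6 * ahead + 0.3 * radial,
        "O4'": point + 1.0 * ahead + 1.6 * radial,
        "C1'": point + 1.6 * ahead + 2.2 * radial,
        "N1": point + 1.9 * ahead + 3.5 * radial,
        "C2": point + 2.9 * ahead + 4.1 * radial,
        "C4": point + 1.2 * ahead + 5.0 * radial,
    }
    return atoms


class _ChainBuilder:
    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        self.records: List[Tuple[str, Dict[str, np.ndarray], bool]] = []
        # (parent base, atoms, is_stem_guanine)

    def add_guanine(self, atoms: Dict[str, np.ndarray]) -> None:
        self.records.append(("G", atoms, True))

    def add_filler(self, point: np.ndarray, nxt: np.ndarray, base: Optional[str] = None) -> None:
        base = base or ("T" if self.spec.chain_nature == "DNA" else "U")
        self.records.append((base, _loop_residue_atoms(point, nxt), False))

    def add_path(self, start: np.ndarray, end: np.ndarray, n: int,
                 push_radius: float = 12.0, z_bump: float = 0.0,
                 step: float = 6.25) -> None:
        """n filler residues on a smooth arc between two backbone anchors.

        The arc bulges radially outward (clearing the stem) with an
        amplitude chosen so its length is ~ (n + 1) * step, then the
        residues are placed at equal arc length; successive C5' spacings
        therefore sit near the mean step.
        """
        if n <= 0:
            return
        chord = end - start
        xy = np.array([chord[1], -chord[0], 0.0])
        fallback = xy / np.linalg.norm(xy) if np.linalg.norm(xy) > 1e-6 else np.array([1.0, 0.0, 0.0])

        def dense_path(amplitude: float) -> np.ndarray:
            steps = max(32, 16 * (n + 1))
            pts = [start]
            for j in range(1, steps):
                f = j / steps
                p = start + f * chord
                radial = np.array([p[0], p[1], 0.0])
                rn = np.linalg.norm(radial)
                radial = radial / rn if rn > 1e-6 else fallback
                bump = math.sin(math.pi * f)
                p = p + amplitude * bump * radial + z_bump * bump * np.array([0.0, 0.0, 1.0])
                pts.append(p)
            pts.append(end)
            return np.asarray(pts)

        def arc_length(dense: np.ndarray) -> float:
            return float(np.linalg.norm(np.diff(dense, axis=0), axis=1).sum())

        target = (n + 1) * step
        lo, hi = 0.0, 30.0
        if arc_length(dense_path(0.0)) >= target:
            amp = 0.0
        else:
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if arc_length(dense_path(mid)) < target:
                    lo = mid
                else:
                    hi = mid
            amp = hi
        dense = dense_path(amp)
        seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        pts = [
            np.array([np.interp(total * j / (n + 1), arc, dense[:, k]) for k in range(3)])
            for j in range(1, n + 1)
        ]
        for j, p in enumerate(pts):
            nxt = pts[j + 1] if j + 1 < len(pts) else end
            self.add_filler(p, nxt)

    def add_overhang(self, anchor: np.ndarray, n: int, upward: bool, prepend: bool) -> None:
        """n flanking residues on a straight ray off the stem end, spaced
        at the mean successive-C5' step (6.25 A)."""
        radial = anchor.copy()
        radial[2] = 0.0
        radial /= max(np.linalg.norm(radial), 1e-6)
        direction = radial * 0.7 + np.array([0.0, 0.0, 0.7 if upward else -0.7])
        direction /= np.linalg.norm(direction)
        pts = [anchor + direction * 6.25 * j for j in range(n, 0, -1)]
        if not prepend:
            pts = pts[::-1]
        for j, p in enumerate(pts):
            nxt = pts[j + 1] if j + 1 < len(pts) else (anchor if prepend else p + direction * 6.25)
            self.add_filler(p, nxt)

    def finish(self) -> StructureModel:
        spec = self.spec
        dna = spec.chain_nature == "DNA"
        nts: List[Nucleotide] = []
        for i, (base, atoms, is_stem) in enumerate(self.records):
            # thread phosphates between consecutive sugar anchors so the
            # backbone trace (P atoms) follows the chain
            if i > 0:
                prev_atoms = self.records[i - 1][1]
                anchor_prev = prev_atoms.get("O3'", prev_atoms["C5'"])
                atoms = dict(atoms)
                gap = atoms["C5'"] - anchor_prev
                dist = float(np.linalg.norm(gap))
                # the phosphate bonds to the previous O3'; over a long jump
                # (0-nt loop) it stays near it, which is what makes the
                # following strand's P trace V-shaped
                step = min(1.6, 0.5 * dist)
                atoms["P"] = anchor_prev + step * gap / max(dist, 1e-6)
                atoms["O5'"] = 0.5 * (atoms["P"] + atoms["C5'"])
            resname = ("D" + base) if dna else base
            if resname == "DU":
                resname = "DT"
            nt = Nucleotide(
                chain_id="A",
                residue_number=i + 1,
                base=base,
                is_modified=False,
                parent_base=base,
                atoms={k: np.asarray(v, dtype=float) for k, v in atoms.items()},
                resname=resname,
            )
            nt.chi = compute_chi(nt)
            nt.gc = assign_glycosidic(nt.chi)
            nts.append(nt)
        model = StructureModel(chains=[nts], model_index=1, source_id=self._source_id())
        if spec.noise_sigma > 0:
            model = perturb(model, spec.noise_sigma, spec.seed)
        return model

    def _source_id(self) -> str:
        return f"SYN-{self.spec.topology.upper().replace(':', '-').replace('/', '-')}"


def _validate_loops(kinds: str, lengths: Sequence[int], force: bool) -> None:
    for i, (kind, n) in enumerate(zip(kinds, lengths), start=1):
        if n < 0:
            raise BuildError(f"loop {i}: negative length")
        if kind == "d" and n < 4 and not force:
            raise BuildError(
                f"loop {i}: a {n}-nt diagonal loop is not geometrically "
                "realizable (diagonal loops require at least 4 nts); "
                "pass force=True to build it anyway"
            )
        if n == 0 and not force:
            raise BuildError(
                f"loop {i}: 0-nt loops require a licensing discontinuity "
                "(use the snapback layout or force=True)"
            )


def _tract_tetrads(direction: str, n_tetrads: int) -> List[int]:
    seq = list(range(1, n_tetrads + 1))
    return seq if direction == "d" else seq[::-1]


def build_g4(spec: SyntheticSpec) -> StructureModel:
    """Build an idealized G4 for the given spec; byte-stable given a seed.

    The model's ``metadata['ground_truth']`` records everything the
    annotator should recover.
    """
    if spec.topology.startswith("two-block"):
        return _build_two_block(spec)
    if spec.snapback is not None:
        return _build_snapback_hybrid4(spec)
    if spec.topology not in _PLANS:
        raise BuildError(f"unknown topology {spec.topology!r}")
    if not 2 <= spec.n_tetrads <= 4:
        raise BuildError("n_tetrads must be 2..4")

    pattern = PATTERN_BY_TOPOLOGY[spec.topology]
    plan, kinds = _PLANS[spec.topology]
    lengths = tuple(spec.loop_lengths or DEFAULT_LOOPS[spec.topology])
    if len(lengths) != 3:
        raise BuildError("loop_lengths must have exactly 3 entries")
    _validate_loops(kinds, lengths, spec.force)

    faces = (
        _faces_from_gc(pattern, spec.gc_pattern)
        if spec.gc_pattern
        else _default_faces(pattern, spec.n_tetrads)
    )
    if len(faces) != spec.n_tetrads:
        raise BuildError("gc_pattern must have one row per tetrad")

    stem_atoms: Dict[Tuple[int, int], Dict[str, np.ndarray]] = {}
    for col in range(1, 5):
        direction = pattern[col - 1]
        for t in range(1, spec.n_tetrads + 1):
            stem_atoms[(col, t)] = _stem_guanine_atoms(
                col, t, faces[t - 1], direction, spec.rise, spec.twist
            )

    bulge_map: Dict[Tuple[int, int], int] = {}
    for tract_idx, after_tet, n in spec.bulges:
        if not (1 <= tract_idx <= 4 and n >= 1):
            raise BuildError(f"bad bulge descriptor {(tract_idx, after_tet, n)}")
        bulge_map[(tract_idx, after_tet)] = n

    builder = _ChainBuilder(spec)
    first_anchor = stem_atoms[(plan[0][0], 1 if plan[0][1] == "d" else spec.n_tetrads)]["C5'"]
    if spec.fn5:
        builder.add_overhang(first_anchor, spec.fn5, upward=True, prepend=True)

    prev_g_atoms = None
    for ti, (col, direction) in enumerate(plan):
        tet_seq = _tract_tetrads(direction, spec.n_tetrads)
        if ti > 0:
            n = lengths[ti - 1]
            end_atoms = stem_atoms[(col, tet_seq[0])]
            z_bump = 2.0 if kinds[ti - 1] in "ld" else 0.0
            top_side = prev_g_atoms["C5'"][2] > -(spec.n_tetrads - 1) * spec.rise / 2
            builder.add_path(
                prev_g_atoms["C5'"],
                end_atoms["C5'"],
                n,
                z_bump=z_bump if top_side else -z_bump,
            )
        for k, t in enumerate(tet_seq):
            builder.add_guanine(stem_atoms[(col, t)])
            prev_g_atoms = stem_atoms[(col, t)]
            key = (ti + 1, t)
            if key in bulge_map and k < len(tet_seq) - 1:
                nxt = stem_atoms[(col, tet_seq[k + 1])]
                builder.add_path(
                    prev_g_atoms["C5'"], nxt["C5'"], bulge_map[key], push_radius=14.0
                )

    if spec.fn3:
        upward = prev_g_atoms["C5'"][2] > -(spec.n_tetrads - 1) * spec.rise / 2
        builder.add_overhang(prev_g_atoms["C5'"], spec.fn3, upward=upward, prepend=False)

    model = builder.finish()
    model.metadata["ground_truth"] = {
        "topology": spec.topology,
        "strand_pattern": pattern,
        "n_tetrads": spec.n_tetrads,
        "loop_lengths": list(lengths),
        "loop_kinds": list(kinds),
        "gc_pattern": _gc_from_faces(pattern, faces),
        "rise": spec.rise,
        "twist": spec.twist,
        "n_blocks": 1,
    }
    return model


def _build_snapback_hybrid4(spec: SyntheticSpec) -> StructureModel:
    """hybrid4 with a 2-G 5'-bottom snapback, a snapback (diagonal) loop,
    and a 0-nt loop into the V-shaped strand 4 (the 6RS3-like layout)."""
    if spec.snapback != "5p-bottom":
        raise BuildError(f"unsupported snapback layout {spec.snapback!r}")
    if spec.topology != "hybrid4":
        raise BuildError("the 5'-bottom snapback layout applies to hybrid4")
    n_tet = 3
    pattern = PATTERN_BY_TOPOLOGY["hybrid4"]  # duuu
    faces = _default_faces(pattern, n_tet)
    if spec.snapback_loop_length < 4 and not spec.force:
        raise BuildError("the snapback (diagonal) loop requires at least 4 nts")

    atoms = {
        (col, t): _stem_guanine_atoms(col, t, faces[t - 1], pattern[col - 1], spec.rise, spec.twist)
        for col in range(1, 5)
        for t in range(1, n_tet + 1)
    }
    b = _ChainBuilder(spec)
    # strand 1 bottom part (tetrads 2, 3) -- the snapback guanines
    b.add_guanine(atoms[(1, 2)])
    b.add_guanine(atoms[(1, 3)])
    # snapback loop (diagonal) to strand 3 bottom
    b.add_path(atoms[(1, 3)]["C5'"], atoms[(3, 3)]["C5'"], spec.snapback_loop_length, z_bump=-2.0)
    for t in (3, 2, 1):
        b.add_guanine(atoms[(3, t)])
    # +p to strand 2 (up)
    b.add_path(atoms[(3, 1)]["C5'"], atoms[(2, 3)]["C5'"], 1)
    for t in (3, 2, 1):
        b.add_guanine(atoms[(2, t)])
    # +l to the strand-1 top guanine
    b.add_path(atoms[(2, 1)]["C5'"], atoms[(1, 1)]["C5'"], 1, z_bump=2.0)
    b.add_guanine(atoms[(1, 1)])
    # 0-nt loop (single phosphate) into strand 4, which becomes V-shaped
    for t in (3, 2, 1):
        b.add_guanine(atoms[(4, t)])
    model = b.finish()
    model.metadata["ground_truth"] = {
        "topology": "hybrid4",
        "strand_pattern": pattern,
        "n_tetrads": n_tet,
        "loop_lengths": [spec.snapback_loop_length, 1, 1, 0],
        "loop_kinds": ["d", "p", "l", "p"],
        "gc_pattern": _gc_from_faces(pattern, faces),
        "snapback": "5'-bottom",
        "v_shaped_strand": 4,
        "n_blocks": 1,
    }
    return model


def _build_two_block(spec: SyntheticSpec) -> StructureModel:
    """Two stacked 2-tetrad parallel blocks joined by an internal-loop
    linker; >= 3 strand columns break between tetrads 2 and 3."""
    if spec.topology != TWO_BLOCK_TOPOLOGY:
        raise BuildError(f"unsupported two-block layout {spec.topology!r}")
    rise, twist = spec.rise, spec.twist
    n_tet = 4
    block2_dirs = "uuuu" if spec.block2_up else "dddd"

    def face_for(t: int, col_dir: str) -> str:
        # all-anti everywhere: anti needs (up, d) or (down, u)
        return "up" if col_dir == "d" else "down"

    atoms = {}
    for col in range(1, 5):
        for t in (1, 2):
            atoms[(col, t)] = _stem_guanine_atoms(col, t, face_for(t, "d"), "d", rise, twist)
        d2 = block2_dirs[col - 1]
        for t in (3, 4):
            atoms[(col, t)] = _stem_guanine_atoms(col, t, face_for(t, d2), d2, rise, twist)

    b = _ChainBuilder(spec)
    # block 1: parallel, tetrads 1-2
    for i, col in enumerate((1, 2, 3, 4)):
        if i > 0:
            b.add_path(atoms[(plan_prev, 2)]["C5'"], atoms[(col, 1)]["C5'"], 1)
        b.add_guanine(atoms[(col, 1)])
        b.add_guanine(atoms[(col, 2)])
        plan_prev = col
    # linker (internal loop) down to block 2
    if spec.block2_up:
        order2, t_first, t_second = (1, 4, 3, 2), 4, 3
    else:
        order2, t_first, t_second = (1, 2, 3, 4), 3, 4
    b.add_path(atoms[(4, 2)]["C5'"], atoms[(order2[0], t_first)]["C5'"], 2, push_radius=13.0)
    for i, col in enumerate(order2):
        if i > 0:
            b.add_path(atoms[(prev_col, prev_t)]["C5'"], atoms[(col, t_first)]["C5'"], 1)
        b.add_guanine(atoms[(col, t_first)])
        b.add_guanine(atoms[(col, t_second)])
        prev_col, prev_t = col, t_second
    model = b.finish()
    model.metadata["ground_truth"] = {
        "topology": TWO_BLOCK_TOPOLOGY,
        "strand_pattern": "dddd/" + block2_dirs,
        "n_tetrads": 4,
        "blocks": [[1, 2], [3, 4]],
        "n_blocks": 2,
        "rise": rise,
        "twist": twist,
    }
    return model


def perturb(model: StructureModel, sigma: float, seed: int = 0) -> StructureModel:
    """Isotropic Gaussian displacement (std ``sigma`` per coordinate) of
    every atom; deterministic given the seed; sigma = 0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = copy.deepcopy(model)
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for nt in out.residues():
        for name in list(nt.atoms):
            nt.atoms[name] = nt.atoms[name] + rng.normal(0.0, sigma, size=3)
        nt.chi = compute_chi(nt)
        nt.gc = assign_glycosidic(nt.chi)
    return out


_ELEMENT = {"P": "P", "O": "O", "N": "N", "C": "C"}


def to_pdb_string(model: StructureModel) -> str:
    """Render standard single-model PDB ATOM records."""
    lines: List[str] = []
    serial = 1
    for chain in model.chains:
        for nt in chain:
            for name, pos in nt.atoms.items():
                elem = _ELEMENT.get(name[0], name[0])
                pdb_name = name if len(name) == 4 else f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name}{nt.resname:>4s} "
                    f"{nt.chain_id}{nt.residue_number:4d}    "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                    f"  1.00  0.00          {elem:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb(model: StructureModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_pdb_string(model))
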