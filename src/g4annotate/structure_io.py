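"""Coordinate-file parsing into a uniform nucleic-acid model, glycosidic
annotation, and (de)serialization of annotation reports.

The parser is backed by :mod:`Bio.PDB` and normalizes both PDB and mmCIF
input into :class:`StructureModel`: ordered chains of :class:`Nucleotide`
records carrying the atoms needed downstream (C1', C5', base ring atoms,
Hoogsteen donors/acceptors). Modified residues are mapped to their parent
base through a bundled chemical-component table and flagged.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "Nucleotide",
    "StructureModel",
    "StructureParseError",
    "EmptyModelError",
    "ModelIndexError",
    "read_structure",
    "compute_chi",
    "assign_glycosidic",
    "write_annotation",
    "read_annotation",
    "dihedral",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T", "U"}

# Ions commonly coordinated in the central channel; recorded as metadata only.
_ION_CODES = {"K", "NA", "MG", "CA", "SR", "TL", "NH4", "CS", "LI", "ZN", "MN"}


def _load_components() -> Dict[str, Dict[str, str]]:
    with resources.files("g4annotate.data").joinpath("components.json").open() as fh:
        data = json.load(fh)
    return {"standard": data["standard"], "modified": data["modified"]}


_COMPONENTS = _load_components()


class StructureParseError(ValueError):
    """The file could not be parsed as a structure."""


class EmptyModelError(StructureParseError):
    """The selected model contains no nucleic residues."""


class ModelIndexError(StructureParseError):
    """The requested model index is outside the file's model count."""


@dataclass
class Nucleotide:
    """One nucleic residue with the coordinates the annotator needs.

    ``residue_number`` is kept as in the source file (1-based in practice);
    any list index into a chain is 0-based.
    """

    chain_id: str
    residue_number: int
    base: str
    is_modified: bool
    parent_base: str
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)
    chi: Optional[float] = None
    gc: str = "undefined"
    resname: str = ""
    insertion_code: str = ""

    @property
    def is_purine(self) -> bool:
        return self.parent_base in PURINES

    @property
    def is_guanine(self) -> bool:
        return self.parent_base == "G"

    def atom(self, name: str) -> np.ndarray:
        return self.atoms[name]

    def has_atoms(self, *names: str) -> bool:
        return all(n in self.atoms for n in names)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Nucleotide({self.chain_id}:{self.resname}{self.residue_number} "
            f"{self.parent_base} gc={self.gc})"
        )


@dataclass
class StructureModel:
    """Chains of nucleotides (each 5'->3') from one model of one entry."""

    chains: List[List[Nucleotide]]
    model_index: int = 1
    source_id: str = ""
    metadata: Dict[str, object] = field(default_factory=dict)

    def residues(self) -> List[Nucleotide]:
        return [nt for chain in self.chains for nt in chain]

    def guanines(self) -> List[Nucleotide]:
        return [nt for nt in self.residues() if nt.is_guanine]

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def chain_nature(self) -> str:
        """DNA / RNA / mixed, inferred from residue codes (T vs U, D-prefix)."""
        natures = set()
        for nt in self.residues():
            name = nt.resname.strip()
            if name.startswith("D") or nt.parent_base == "T":
                natures.add("DNA")
            elif name in {"A", "C", "G", "U"} or nt.parent_base == "U" or "O2'" in nt.atoms:
                natures.add("RNA")
        if natures == {"DNA"}:
            return "DNA"
        if natures == {"RNA"}:
            return "RNA"
        return "mixed" if natures else "DNA"


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    ang = math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def compute_chi(nt: Nucleotide) -> Optional[float]:
    """Glycosidic torsion: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for
    pyrimidines. ``None`` when any of the four atoms is missing."""
    if nt.is_purine:
        names = ("O4'", "C1'", "N9", "C4")
    else:
        names = ("O4'", "C1'", "N1", "C2")
    if not nt.has_atoms(*names):
        return None
    return dihedral(*(nt.atoms[n] for n in names))


def assign_glycosidic(chi: Optional[float]) -> str:
    """syn iff chi in (-90, 90]; anti otherwise; undefined for missing chi.

    The syn window follows standard nucleic-acid convention (the underlying
    classification only names the two states).
    """
    if chi is None:
        return "undefined"
    if not -180.0 < chi <= 180.0:
        raise ValueError(f"chi must lie in (-180, 180], got {chi}")
    return "syn" if -90.0 < chi <= 90.0 else "anti"


def _classify_residue(resname: str) -> Optional[tuple]:
    """Return (parent_base, is_modified) for nucleic residues, else None."""
    name = resname.strip().upper()
    if name in _COMPONENTS["standard"]:
        return _COMPONENTS["standard"][name], False
    if name in _COMPONENTS["modified"]:
        return _COMPONENTS["modified"][name], True
    return None


def _residue_to_nucleotide(res, chain_id: str) -> Optional[Nucleotide]:
    classified = _classify_residue(res.get_resname())
    if classified is None:
        return None
    parent, modified = classified
    atoms: Dict[str, np.ndarray] = {}
    for atom in res.get_atoms():
        name = atom.get_name().replace("*", "'")
        if name.startswith("H") or name in {"D1", "D2"}:
            continue
        atoms[name] = np.asarray(atom.get_coord(), dtype=float)
    if "C1'" not in atoms:
        return None
    hetflag, resseq, icode = res.get_id()
    nt = Nucleotide(
        chain_id=chain_id,
        residue_number=int(resseq),
        base=parent,
        is_modified=modified,
        parent_base=parent,
        atoms=atoms,
        resname=res.get_resname().strip(),
        insertion_code=icode.strip(),
    )
    nt.chi = compute_chi(nt)
    nt.gc = assign_glycosidic(nt.chi)
    return nt


def read_structure(path, format: str = "auto", model_index: int = 1) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        Coordinate file. ``format='auto'`` decides from the extension
        (.cif/.mmcif -> mmCIF, otherwise PDB).
    model_index:
        1-based model selector (NMR ensembles); defaults to the first model.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if fmt not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")

    parser = MMCIFParser(QUIET=True) if fmt == "mmcif" else PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises a zoo of exception types
        raise StructureParseError(f"could not parse {path}: {exc}") from exc

    models = list(structure.get_models())
    if not models:
        raise StructureParseError(f"{path} contains no models")
    if not 1 <= model_index <= len(models):
        raise ModelIndexError(
            f"model_index {model_index} outside 1..{len(models)} for {path}"
        )
    model = models[model_index - 1]

    chains: List[List[Nucleotide]] = []
    ions: List[str] = []
    hetero: List[str] = []
    for chain in model.get_chains():
        nts: List[Nucleotide] = []
        for res in chain.get_residues():
            resname = res.get_resname().strip().upper()
            if resname in _ION_CODES:
                ions.append(resname)
                continue
            if resname in {"HOH", "WAT", "DOD"}:
                continue
            nt = _residue_to_nucleotide(res, chain.get_id())
            if nt is not None:
                nts.append(nt)
            elif res.get_id()[0].startswith("H_"):
                hetero.append(resname)  # bound ligand, recorded only
        if nts:
            chains.append(nts)
    if not chains:
        raise EmptyModelError(f"{path} (model {model_index}) has no nucleic residues")
    return StructureModel(
        chains=chains,
        model_index=model_index,
        source_id=path.stem.upper(),
        metadata={
            "ions": sorted(set(ions)),
            "hetero": sorted(set(hetero)),
            "n_hetero": len(hetero),
            "path": str(path),
        },
    )


# ---------------------------------------------------------------------------
# annotation report serialization


def write_annotation(report, format: str = "json") -> str:
    """Serialize a TopologyAnnotation to JSON or TSV text (lossless)."""
    data = report.to_dict()
    if format == "json":
        return json.dumps(data, indent=2, sort_keys=False) + "\n"
    if format == "tsv":
        # flat key\tvalue table; nested values encoded as compact JSON so the
        # reader can reconstruct them exactly
        lines = []
        for key, value in data.items():
            lines.append(f"{key}\t{json.dumps(value, sort_keys=False)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown annotation format {format!r}")


def read_annotation(text: str, format: str = "json"):
    """Inverse of :func:`write_annotation`."""
    from .topology import TopologyAnnotation

    if format == "json":
        data = json.loads(text)
    elif format == "tsv":
        data = {}
        for line in text.splitlines():
            if not line.strip():
                continue
            key, _, raw = line.partition("\t")
            data[key] = json.loads(raw)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return TopologyAnnotation.from_dict(data)
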