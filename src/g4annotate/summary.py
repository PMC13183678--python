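"""Dataset-level aggregation: non-redundant sequence accounting and
per-topology summary tables over many annotations.

The loader accepts the characteristics spreadsheet (XLSX) or any TSV/CSV
of annotations with one row per structure. Expected canonical columns
(case-insensitive; a ``column_map`` argument renames non-canonical
inputs): ``pdb_id, sequence, topology, n_tetrads, n_blocks,
chain_nature`` plus optional ``loop_lengths`` (comma-separated) and
``loop_combination``. The loader fails loudly on a schema mismatch
rather than guessing.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "DatasetSummary",
    "nonredundant_sequences",
    "load_characteristics",
    "aggregate",
    "aggregate_frame",
    "loop_length_subset_percent",
]

REQUIRED_COLUMNS = (
    "pdb_id",
    "sequence",
    "topology",
    "n_tetrads",
    "n_blocks",
    "chain_nature",
)
OPTIONAL_COLUMNS = ("loop_lengths", "loop_combination")


def nonredundant_sequences(seqs: Iterable[str]) -> int:
    """Count distinct sequences by case-insensitive exact string identity
    (one modified residue code suffices to remove redundancy)."""
    return len({str(s).strip().upper() for s in seqs if str(s).strip()})


def load_characteristics(
    path,
    column_map: Optional[Dict[str, str]] = None,
    expected_rows: Optional[int] = None,
) -> pd.DataFrame:
    """Load a characteristics table (XLSX/TSV/CSV), validate the schema.

    Raises ``ValueError`` listing the missing columns on mismatch, and on a
    row-count mismatch when ``expected_rows`` is given.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    elif path.suffix.lower() in {".tsv", ".txt"}:
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if column_map:
        df = df.rename(columns={k.strip().lower(): v for k, v in column_map.items()})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required columns {missing}; "
            f"found {list(df.columns)}. Provide a column_map."
        )
    if expected_rows is not None and len(df) != expected_rows:
        raise ValueError(f"{path.name}: expected {expected_rows} rows, found {len(df)}")
    return df


@dataclass
class DatasetSummary:
    n_structures: int
    n_nonredundant_sequences: int
    structures_by_topology: Dict[str, int]
    sequences_by_topology: Dict[str, int]
    n_sequence_topology_pairs: int
    tetrad_histogram: Dict[str, Dict[int, int]]
    loop_combinations: Dict[str, List[Tuple[str, int]]]
    chain_nature_counts: Dict[str, int]
    discontinuity_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_structures": self.n_structures,
            "n_nonredundant_sequences": self.n_nonredundant_sequences,
            "structures_by_topology": self.structures_by_topology,
            "sequences_by_topology": self.sequences_by_topology,
            "n_sequence_topology_pairs": self.n_sequence_topology_pairs,
            "tetrad_histogram": self.tetrad_histogram,
            "loop_combinations": {
                k: [list(x) for x in v] for k, v in self.loop_combinations.items()
            },
            "chain_nature_counts": self.chain_nature_counts,
            "discontinuity_counts": self.discontinuity_counts,
        }

    def to_markdown(self) -> str:
        lines = [
            "| topology | structures | non-redundant sequences | tetrads (2/3/4) | top combinations |",
            "|---|---|---|---|---|",
        ]
        for topo in sorted(self.structures_by_topology, key=lambda t: -self.structures_by_topology[t]):
            hist = self.tetrad_histogram.get(topo, {})
            tet = "/".join(str(hist.get(k, 0)) for k in (2, 3, 4))
            combos = ", ".join(
                f"{c}({n})" for c, n in self.loop_combinations.get(topo, [])[:3]
            )
            lines.append(
                f"| {topo} | {self.structures_by_topology[topo]} | "
                f"{self.sequences_by_topology.get(topo, 0)} | {tet} | {combos} |"
            )
        lines.append(
            f"\nTotal: {self.n_structures} structures, "
            f"{self.n_nonredundant_sequences} non-redundant sequences, "
            f"{self.n_sequence_topology_pairs} sequence-topology pairs."
        )
        return "\n".join(lines)


def _norm_seq(seq: str) -> str:
    return str(seq).strip().upper()


def aggregate(annotations: Sequence) -> DatasetSummary:
    """Aggregate TopologyAnnotation objects (or dicts) into a summary."""
    rows = []
    for ann in annotations:
        data = ann.to_dict() if hasattr(ann, "to_dict") else dict(ann)
        rows.append(
            {
                "pdb_id": data.get("source_id", ""),
                "sequence": data.get("sequence", ""),
                "topology": data.get("topology", "undetermined"),
                "n_tetrads": data.get("n_tetrads", 0),
                "n_blocks": data.get("n_blocks", 1),
                "chain_nature": data.get("chain_nature", "DNA"),
                "loop_combination": data.get("loop_combination", ""),
                "n_discontinuities": len(data.get("discontinuities", [])),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "pdb_id",
            "sequence",
            "topology",
            "n_tetrads",
            "n_blocks",
            "chain_nature",
            "loop_combination",
            "n_discontinuities",
        ],
    )
    return aggregate_frame(df)


def aggregate_frame(df: pd.DataFrame) -> DatasetSummary:
    """Aggregate a characteristics DataFrame into a DatasetSummary.

    Sequence-topology pairs count a sequence once per distinct topology it
    adopts (one sequence may appear under several topologies).
    """
    if df.empty:
        return DatasetSummary(0, 0, {}, {}, 0, {}, {}, {})
    topo = df["topology"].fillna("undetermined").astype(str).str.strip()
    seqs = df["sequence"].map(_norm_seq)

    structures_by_topology = topo.value_counts().to_dict()
    sequences_by_topology = {
        t: seqs[topo == t].nunique() for t in structures_by_topology
    }
    pairs = {(s, t) for s, t in zip(seqs, topo) if s}

    tetrad_histogram: Dict[str, Dict[int, int]] = defaultdict(dict)
    if "n_tetrads" in df.columns:
        for t in structures_by_topology:
            counts = Counter(int(x) for x in df.loc[topo == t, "n_tetrads"].dropna())
            tetrad_histogram[t] = dict(sorted(counts.items()))

    loop_combinations: Dict[str, List[Tuple[str, int]]] = {}
    if "loop_combination" in df.columns:
        for t in structures_by_topology:
            combos = Counter(
                str(c) for c in df.loc[topo == t, "loop_combination"].dropna() if str(c)
            )
            loop_combinations[t] = sorted(
                combos.items(), key=lambda kv: (-kv[1], kv[0])
            )

    chain_nature_counts = (
        df["chain_nature"].astype(str).str.strip().value_counts().to_dict()
        if "chain_nature" in df.columns
        else {}
    )
    discontinuity_counts: Dict[str, int] = {}
    if "n_discontinuities" in df.columns:
        discontinuity_counts = {
            "structures_with_discontinuities": int((df["n_discontinuities"] > 0).sum()),
            "total_discontinuities": int(df["n_discontinuities"].sum()),
        }

    return DatasetSummary(
        n_structures=len(df),
        n_nonredundant_sequences=nonredundant_sequences(seqs),
        structures_by_topology=structures_by_topology,
        sequences_by_topology=sequences_by_topology,
        n_sequence_topology_pairs=len(pairs),
        tetrad_histogram=dict(tetrad_histogram),
        loop_combinations=loop_combinations,
        chain_nature_counts=chain_nature_counts,
        discontinuity_counts=discontinuity_counts,
    )


def loop_length_subset_percent(
    df: pd.DataFrame, lengths: Tuple[int, int, int], topology: str
) -> Optional[float]:
    """Percentage of one-block structures whose three basic loop lengths
    equal ``lengths`` and that are annotated with ``topology``; None when
    the subset is empty. Requires a ``loop_lengths`` column."""
    if "loop_lengths" not in df.columns:
        raise ValueError("table has no loop_lengths column")
    one_block = df[df["n_blocks"].astype(int) == 1]

    def parse(val) -> Optional[Tuple[int, ...]]:
        try:
            return tuple(int(x) for x in str(val).replace(";", ",").split(","))
        except ValueError:
            return None

    mask = one_block["loop_lengths"].map(lambda v: parse(v) == tuple(lengths))
    subset = one_block[mask.fillna(False)]
    if subset.empty:
        return None
    frac = (subset["topology"].astype(str).str.strip() == topology).mean()
    return 100.0 * float(frac)
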