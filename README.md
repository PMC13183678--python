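# g4annotate

Annotation of intramolecular G-quadruplex (G4) 3D structures, and the
topological rules that govern their folding.

Given a PDB or mmCIF coordinate file, the package

- detects **G-tetrads** from Hoogsteen-pairing geometry (closed donor→acceptor
  4-cycles over N1→O6 / N2→N7 contacts),
- assembles the **stem**: tetrad stacking order (tetrad 1 = 5′-tetrad), four
  strand columns, clockwise strand numbering with strand 1 holding the 5′-most
  stem guanine, d/u strand directions,
- names the **topology** — parallel (`dddd`), antiparallel-chair (`dudu`),
  antiparallel-basket (`duud`), antiparallel-basket2 (`dduu`), hybrid1–4
  (`ddud`, `dddu`, `dudd`, `duuu`) — plus `two-block:<block1>/<block2>`
  layouts,
- classifies every **loop** (propeller / lateral / diagonal / internal) with
  its progression sign and renders the combination string (e.g. `-p-p-p`,
  `+l+l+l`, `-ld+l`; snapback loops bracketed `[..]`),
- annotates **glycosidic patterns** (syn/anti per tetrad), **groove-width
  signatures** (w/n/i from mean adjacent-strand C5′–C5′ distances),
  **handedness** (per block + relative), **discontinuities** (bulges,
  snapbacks typed 5′/3′ × top/bottom, block breaks), **V-shaped strands**,
  stem-extremity sides and flanking-nucleotide lengths,
- implements the **quantitative geometry model**: loop span
  `(n+1) × 6.25 Å`, diagonal-loop feasibility threshold
  `21.0 + 2 × 3.42 ≈ 28 Å`, stem heights, per-step rise/twist, planarity,
- answers **rule queries**: which topologies are allowed/excluded for loop
  lengths (L1, L2, L3), diagonal-loop compatibility and minimum length,
  expected extremity sides, tetrad-count tendencies, duplex-capable loops.

A built-in **synthetic generator** produces idealized G4 models (any of the
eight topologies × 2–4 tetrads, configurable rise/twist/gc patterns, loops,
bulges, snapbacks, two-block layouts, Gaussian noise) with full ground truth,
so the entire annotation stack is testable without network access.

## CLI

```bash
# annotate structures (JSON or TSV reports)
g4annotate annotate structure.pdb
g4annotate annotate inputs_dir/ -o reports/ --format tsv

# which topologies do loop lengths allow?
g4annotate predict --loops 2,3,2          # -> antiparallel-chair
g4annotate predict --loops 1,2,1          # -> parallel
g4annotate predict --loops 1,1,9 --modified-g   # caveat, no exclusion

# generate an idealized structure
g4annotate simulate --topology antiparallel-chair --tetrads 2 --loops 2,3,2 \
    --seed 7 -o chair.pdb

# dataset-level summaries from a characteristics table
g4annotate summarize annotations.tsv --format markdown
```

Exit codes: 0 success (warnings on stderr), 1 usage error, 2 data error.

## Python API

```python
from g4annotate import (
    SyntheticSpec, build_g4, read_structure, annotate_structure,
    RuleQuery, allowed_topologies,
)

model = read_structure("6rs3.pdb")            # or build_g4(SyntheticSpec(...))
report = annotate_structure(model)
print(report.topology, report.loop_combination, report.groove["letters"])

print(allowed_topologies(RuleQuery(2, 4, 2)).allowed_topologies())
# ['antiparallel-basket']
```

## Layout

```
src/g4annotate/
  structure_io.py   PDB/mmCIF parsing, glycosidic assignment, report I/O
  tetrads.py        tetrad detection, stem assembly, discontinuities
  topology.py       d/u patterns, topology names, gc patterns, grooves
  loops.py          loop taxonomy, combination strings, V-shaped strands
  geometry.py       loop-span model, heights, rise/twist, planarity
  rules.py          loop-length -> topology constraint engine
  summary.py        dataset aggregation, non-redundant sequence accounting
  synthetic.py      idealized G4 generator with ground truth
  pipeline.py       end-to-end annotation
  cli.py            command-line interface
```
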