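# External inputs (not redistributed)

Optional inputs that unlock the network-dependent acceptance tests and
report targets. Place here:

- `Sequences_and_characteristics.xlsx` (or `.tsv`/`.csv`) — the published
  supplementary characteristics table, one row per analyzed structure, with
  columns (case-insensitive; see `g4annotate.summary.REQUIRED_COLUMNS`):
  `pdb_id, sequence, topology, n_tetrads, n_blocks, chain_nature` and
  optionally `loop_lengths` (comma-separated) and `loop_combination`.
  Use the `column_map` argument of `load_characteristics` if the deposited
  file uses different column names.
- `6RS3.pdb` — the deposited coordinates of PDB entry 6RS3.
- `pdb/` — the full set of analyzed deposited entries (`*.pdb` / `*.cif`).
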