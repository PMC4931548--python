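# dasi

Database-assisted structure identification for HPLC-MS unknowns.

When a measured metabolite is absent from every structure database, near-miss
database candidates still carry usable structural information. `dasi`
implements that idea as a four-stage pipeline:

1. **Filter** a candidate bin against the unknown's predicted
   physicochemical properties (retention index, Ecom50, drift time; closed
   windows ±40 RI / ±0.5 eV / ±0.35 ms by default), a biological-likelihood
   gate, and formula/redundancy cleanup.
2. **Seed** — derive a consensus substructure from the surviving candidates'
   in-silico CID fragments. Eight algorithms are provided: the top shared
   fragment over all candidates (`A1`), the top fragment of the best
   Tanimoto cluster (`A2`), and six variants of trimming the top cluster's
   maximum common substructure by per-atom fragment-match counts
   (`A3-1` … `A3-6`). Trimming never disconnects the seed or breaks a ring.
3. **Generate** — exhaustively enumerate all constitutional isomers of the
   unknown's formula that contain the seed and contain no forbidden
   (badlist) SMARTS pattern, under a fixed valence model (N valence 3), with
   a structure cap and a cooperative timeout.
4. **Refilter & rank** the generated structures with pluggable property
   predictors, spectral fragment matching, and an optional MMFF94
   energy-window filter (mean ± 3·sd of a reference cluster).

Module map: `chemgraph` (graph core: canonical keys, substructure/MCS
search, fingerprints, formulas) · `bin_io` (bin schema + initial filters) ·
`fragment_match` (surrogate fragmenter, peak matching, scoring) ·
`seed_algorithms` · `structgen` (constrained isomer enumerator) ·
`rank_filter` · `fixtures` (deterministic toy bins) · `pipeline` / `cli`.

## CLI

```bash
# build a deterministic toy bin around a hidden target
dasi fixtures make-bin --target "CCOC(C)=O" --n 8 --seed 42 --out toy_bin.json
dasi fixtures badlist --out bad.smarts

# the four stages, individually
dasi filter-bin --bin toy_bin.json --ri-window 40 --ecom50-window 0.5 \
    --drift-window 0.35 --out filtered.json
dasi make-seed --bin filtered.json --algorithm A3-6 --out seed.sdf
dasi generate --formula C4H8O2 --seed seed.sdf --badlist bad.smarts \
    --max 100000 --timeout 3600 --out gen.sdf
dasi refilter --structures gen.sdf --bin toy_bin.json --out ranked.csv

# or everything at once from a YAML config
dasi run --config run.yaml
```

`run.yaml` keys mirror `dasi.pipeline.PipelineConfig` (`bin_path`, `out_dir`,
`algorithm` — one of `A1`, `A2`, `A3-1`…`A3-6` or `all` — window widths,
`max_structures`, `timeout`, `badlist_path`, `energy_filter`, `target_id`,
`rng_seed`). Every run writes its resolved config and a JSON report with
per-stage counts beside the outputs.

## Notes

- Structures are hydrogen-suppressed graphs with explicit per-atom H
  counts; matching is by element, charge and bond order (aromatic matches
  only aromatic). Fragments inherit their parent's hydrogen counts.
- The generator is exhaustive whenever the result is not flagged as
  truncated by the cap or timeout, and refuses formulas above 14 heavy
  atoms unless forced (combinatorial explosion).
- Tanimoto similarity uses Morgan fingerprints (radius 2, 2048 bits),
  pinned in `dasi.config` so clustering thresholds are reproducible.
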