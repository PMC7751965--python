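# promreg

Quantifies how transcription-factor (TF) binding in defined promoter windows
explains transcription start site (TSS) activity. The pipeline:

1. **Meta-processing** (`promreg.meta_processing`) — overlaps the peak sets of
   several callers per ChIP-Seq experiment into support-annotated clusters,
   removes single-caller orphans when the experiment's injected quality metric
   (FPCM) exceeds its threshold (default 3.0), and unions the refined
   experiments into one final binding-region set per TF.
2. **Feature construction** (`promreg.feature_builder`) — for each TSS, eight
   promoter windows ([-5000,-1001] … [501,1000], closed offsets, 0 = the TSS
   base in [-100,0]) yield eight *abundance* features (fraction of TFs bound
   per window) plus eight binary presence/absence features per TF:
   8·(m+1) columns for m TFs.
3. **Activity transforms** (`promreg.expression_profiles`) — log-transformed
   expression (0 if EL < 2, else log10 EL), mean profiles, the
   sum-transformation of TSSs closer than 100 bp, and profile-correlation
   summaries.
4. **Model fitting** (`promreg.stepwise_regression`) — OLS with greedy forward
   selection maximizing the correlation between fitted and observed activity
   (r_op), 50/50 cross-validation, the predicted-mean-profile commonality
   feature, and attendant-feature extension under a p-value stop rule.
5. **Classification** (`promreg.tf_classification`) — activator/repressor
   calls by coefficient sign, per-TF eight-window classification at p < 1e-5,
   co-binding ratios, and feature-correlation neighborhoods.
6. **Synthetic data** (`promreg.synthetic_data`) — seeded generators for TSS
   landscapes, binding sets, caller replicates and activities with known
   ground truth, so every stage is testable offline.

Coordinates are BED-style internally (0-based, half-open); TSS positions are
1-based. Chromosome names are compared as exact strings — no "chr"
normalization.

## CLI

```sh
promreg simulate --seed 1 --n-tss 1000 --m-tfs 10 --out-dir sim/
promreg meta --manifest manifest.tsv --fpcm-table fpcm.tsv --out-dir final/
promreg features --bed-dir sim/final_beds --tss-table sim/tss_activity.tsv \
    --out fm.tsv --out-meta fm.meta.tsv
promreg fit --matrix fm.tsv --matrix-meta fm.meta.tsv \
    --tss-table sim/tss_activity.tsv --cell-line SIM --steps 20 --out model.tsv
promreg classify --matrix fm.tsv --matrix-meta fm.meta.tsv \
    --tss-table sim/tss_activity.tsv --cell-line SIM --out calls.tsv
promreg sumtransform --tss-table sim/tss_activity.tsv --out st.tsv
promreg cobinding --matrix fm.tsv --matrix-meta fm.meta.tsv "A[-100, 0]" "A[1, 100]"
promreg neighbors --matrix fm.tsv --matrix-meta fm.meta.tsv -k 5 "A[1, 100]"
promreg compare-profiles --profiles profiles.tsv --types types.tsv --seed 0
promreg run --config pipeline.yaml
```

`promreg run` orchestrates the stages from a YAML config with keys `mode`
(`primary`, `advanced`, `sum_transformed`, `attendant`), `bed_dir`,
`tss_table`, `cell_line`, `cell_lines` (advanced mode), `out_dir`, `steps`,
`p_stop`, `seed`; it writes `model.tsv`, `trace.tsv`, `classification.tsv`
and `provenance.json`. Exit code 2 signals a validation error.

Model reports are TSVs with columns Feature, R_o-p, increment, coefficient,
p_value in selection order; p-values below 1e-300 render as `<1.0e-300`.

## File formats

- **TFBRs**: 3+ column BED (extra columns ignored; `track`/`browser`/`#`
  lines skipped).
- **TSS activities**: TSV with header `tss_id, chrom, position, strand`
  followed by one raw-expression column per cell line.
- **Feature matrix**: TSV (rows = tss_id) plus a column-metadata sidecar TSV.
- **Manifest** (for `meta`): TSV with columns
  `experiment_id, tf, caller, bed_path`.
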