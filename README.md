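# qccmap

Identification and spatial analysis of a rare three-marker cell phenotype
(AKT low / H3K9me2 low / HES1 high — "QCCs") in per-cell quantitative
immunofluorescence tables exported from tissue/cell segmentation software.

The package implements the full analysis chain:

1. **`qccmap.cell_table`** — validated ingestion of per-cell CSVs plus
   per-FOV QC metadata; tile-level exclusion (tumor fraction < 1% or
   artifact fraction > 70%, strict inequalities); tumor-cell selection.
2. **`qccmap.qcc_calling`** — percentile-rank gating of the marker panel
   within each section. At fraction *t* exactly `ceil(t*N)` cells qualify
   per marker (ties broken by (intensity, cell_id)); a cell is a QCC when
   it qualifies on all three markers simultaneously. Relative calls are
   invariant under per-marker monotone intensity transforms, which is why
   they are reproducible across staining batches while absolute cutoffs
   are not. A threshold sweep (default 25%/33%/50%) is included.
3. **`qccmap.tumor_map`** — stitches tile-local coordinates into a single
   whole-section Cartesian map, stacks ordered section maps into a 3D
   arrangement, renders deterministic SVG scatter maps (QCC red, other
   cells blue, excluded tiles gray), and round-trips maps through CSV.
4. **`qccmap.spatial_stats`** — the QCC cluster index: for each focal QCC,
   the fraction of QCCs among its k (default 100) Euclidean-nearest tumor
   cells, restricted to a ±window (default 500 coordinate units) box per
   axis; focals with fewer than k in-window candidates are discarded. The
   section index averages retained focals. Significance comes from B
   (default 1000) label permutations over the same geometry and an
   add-one one-sided empirical p-value. Brute-force and exhaustive-
   enumeration oracles are part of the public API.
5. **`qccmap.cohort_stats`** — per-section QCC percentage and per-FOV
   density, unpaired t-tests (pooled or Welch), Pearson correlation, and a
   normal-approximation post-hoc power computation.
6. **`qccmap.synthetic`** — generates full synthetic sections/cohorts:
   CSR or Thomas-clustered QCC placement, class-conditional log-normal
   intensities, per-section batch scaling, FOV grids with QC fractions.

## CLI

```bash
qccmap simulate --config synth.yaml --outdir sim/       # synthetic cohort
qccmap ingest   --cells cells.csv --fovs fovs.csv --out clean
qccmap call     --cells clean.cells.csv --fovs clean.fovs.csv --t 0.25 --out labels.csv
qccmap map      --cells clean.cells.csv --fovs clean.fovs.csv \
                --labels labels.csv --out map.csv --render map.svg
qccmap ci       --map map.csv --k 100 --window 500 --B 1000 --seed 17 --out ci.json
qccmap cohort   --summaries dir/ --out cohort.csv
qccmap power    --diff 0.567 --se 0.25 --n1 10 --n2 16 --alpha 0.05 --sided one
```

`synth.yaml` holds a `sections:` list of generator overrides, e.g.

```yaml
sections:
  - {section_id: s1, n_cells: 1000, qcc_fraction: 0.05, seed: 1}
  - {section_id: s2, n_cells: 1000, qcc_fraction: 0.05, seed: 2,
     spatial_model: thomas, cluster_sigma: 50.0}
```

## Conventions

- Coordinates are 0-based pixels, y increasing downward; tile origins are
  `(grid_col*(w-overlap), grid_row*(h-overlap))` with configurable tile
  size (default 1392x1040) and overlap (default 0). The cluster-index
  window is interpreted in these same units.
- Percentile gating is rank-based (`ceil(t*N)` per marker) rather than a
  quantile-estimator cutoff: it is scale-invariant, nested across t, and
  deterministic under ties. Absolute mode with cutoffs set to the realized
  relative thresholds reproduces the relative call exactly (given unique
  boundary values).
- Percentiles are computed per section over tumor cells only
  (configurable via `ThresholdConfig.tumor_only`).
- Permutation replicates in which every pseudo-focal is discarded are
  excluded from the p-value denominator and their count is reported.
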