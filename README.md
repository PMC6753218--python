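# epipanel

Analysis toolkit for **deep targeted epilepsy gene-panel sequencing** in
infantile-onset epilepsy. It implements the bespoke computations that sit
between standard upstream processing (alignment, variant calling,
annotation — whose outputs are this package's inputs) and a clinical result:

* **Read-depth CNV calling.** Per-exon read counts (mapping quality > 15)
  are converted to RPKM and standardized twice — within each sample across
  its exons, then across samples at each exon. With q25/q75 the quartiles of
  a sample's dual z-scores and IQR = q75 − q25, exon-level calls use the
  per-sample fences

  ```
  deletion    : z < q25 − 2.5 · IQR
  duplication : z > q75 + 2.5 · IQR
  ```

  Samples with globally disturbed score profiles are removed as outliers,
  and a gene is called when more than half of its designed exons are called
  in the same direction.
* **Variant filtering.** Population-frequency rules by gene inheritance
  model (dominant/X-linked: zero frequency only; recessive: < 0.01%), and a
  mosaic candidate window of VAF ∈ [0.05, 0.25] with more than 30 variant
  reads, exploiting the ~1,300× depth of panel data.
* **ACMG classification.** The 2015 ACMG/AMP evidence-combining rules
  (PVS/PS/PM/PP and the benign-side codes) mapped to the five-tier scale,
  with asserted-vs-recomputed discrepancies reported, never overwritten.
* **Amplicon validation.** Demultiplexing of pooled amplicon reads by exact
  6-nt barcode + `AGAT` adaptor match, per-sample ref/variant allele
  counting, VAF% arithmetic, and a one-sided binomial test (Bonferroni
  across parents, plus a 5× over background requirement) for parental
  mosaicism.
* **Diagnostic yield.** Onset-group assignment (neonatal ≤ 1 month, early
  infantile 1–6 months, late infantile 6–12 months), stratified yield
  tables, and gene/CNV finding frequencies.
* **Synthetic data.** Ground-truthed generators for panel designs, coverage
  matrices with spiked CNVs, variant tables with planted mosaics, barcoded
  amplicon read pools, and cohort tables — every stage is testable without
  patient data.

A transcription of the pathogenic-findings tables of a published 112-patient
infantile-onset epilepsy panel cohort ships under `src/epipanel/data/` and
drives the worked examples below.

## Worked example

```python
>>> import epipanel as ep

# diagnostic yield of the packaged reference cohort
>>> cases = ep.reference_cohort()
>>> ep.compute_diagnostic_yield(cases)
  stratum  diagnosed  total  percent
0     all         53    112     47.3

# top genes among diagnosed cases
>>> ep.tabulate_gene_frequencies(cases).head(4)
    gene variant_class  count
0  PRRT2      sequence     10
1  SCN1A      sequence      6
2  KCNQ2      sequence      5
3  SCN2A      sequence      4

# ACMG evidence combination
>>> ep.combine_acmg_evidence("PVS1, PM2")
'Likely Pathogenic'
>>> ep.combine_acmg_evidence("PVS1, PS4, PM1")
'Pathogenic'

# VAF arithmetic for an amplicon-validated mosaic site
>>> from epipanel.amplicon import SampleAlleleCounts
>>> ep.compute_vaf(SampleAlleleCounts("case42", 2427, 167)).vaf_percent
6.4
```

47.3 is the percentage of the 112 reference cases with a Pathogenic or
Likely Pathogenic finding (53 cases, 48 sequence variants + 5 CNVs); 6.4 is
the percent of variant-supporting reads at a mosaic *SCN8A* site covered
2,594×, squarely inside the 5–25% mosaic window.

A CNV round trip on synthetic data:

```python
>>> from epipanel.synthetic import SimulationConfig, CNVSpike, \
...     simulate_panel_design, simulate_coverage_matrix
>>> cfg = SimulationConfig(seed=1, n_samples=31, mean_depth=1000,
...     cnv_spikes=[CNVSpike("S001", "GENE021", "deletion", 0.5)])
>>> design = simulate_panel_design(cfg)
>>> depth, truth = simulate_coverage_matrix(design, cfg)
>>> result = ep.detect_cnvs(ep.compute_rpkm(depth, design), design)
>>> [(c.sample, c.gene, c.call, c.n_exons_called, c.n_exons_total)
...  for c in result.gene_calls]
[('S001', 'GENE021', 'deletion', 10, 10)]
```

Each step is also available from the shell via the `epipanel` command
(`epipanel simulate …`, `rpkm`, `normalize`, `call-cnv`, `filter-variants`,
`classify`, `demux`, `vaf`, `yield`); run `epipanel --help`.

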