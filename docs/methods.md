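# Methods

This note documents the models, conventions and parameter choices behind
`epipanel`, and what the synthetic-data tests do and do not demonstrate
about real panel data.

## Depth normalization and CNV calling

**Counting.** A read contributes to every target exon its aligned span
overlaps by at least one base; reads with mapping quality ≤ 15 are excluded
(the threshold is exclusive, so MQ 15 itself is dropped). Because a read
spanning an exon boundary is counted once per overlapped exon, per-exon
column sums may exceed the number of distinct on-target reads. The RPKM
library-size denominator is, by default, every MQ-passing read mapping
anywhere in the supplied alignments; an `on_target_totals` switch restricts
it to reads touching the panel. For count matrices produced directly (e.g.
by the simulator), totals are the on-target column sums.

**RPKM.** `RPKM[e,s] = count[e,s] / ((length_e/10³)·(total_s/10⁶))` —
reads per kilobase of target per million mapped reads. No log transform is
applied; the dual standardization below supplies comparability.

**Dual z-scores.** Stage 1 standardizes each sample across its exons, which
cancels any multiplicative per-sample factor (library size, global depth)
exactly. Stage 2 standardizes each exon across the samples of the batch,
removing the shared per-exon capture bias. Both stages use the population
SD (denominator *n*); this convention is stated explicitly so independent
oracles can match bit-for-bit. Zero-variance rows/columns yield scores of
0, never NaN — a constant slice carries no copy-number signal.
Normalization is only defined within one capture-kit batch; single-sample
input is refused because the across-sample stage is undefined.

**Fences and calls.** For each sample, q25/q75 are the linear-interpolation
quartiles of its dual z-scores over all its exons, and the fences are
q25 − 2.5·IQR and q75 + 2.5·IQR. Inequalities are strict: a score exactly
on a fence never produces a call. Samples whose own score distribution is
globally disturbed — strictly more than 10% of exons outside their own
fences (configurable; 1.0 disables) — are flagged as outliers and removed,
after which the across-sample stage and the fences are recomputed once (a
switch allows plain dropping instead). A gene call requires strictly more
than half of the gene's *designed* exons called in one direction; exons
without data count against the call, and deletion/duplication evidence is
never mixed.

**Known limitation — the batch-size ceiling.** Because stage 2 includes the
scored sample in the per-exon mean and SD, one extreme sample among *n*
cannot exceed |z| = √(n−1) (the population-SD ceiling), i.e. √19 ≈ 4.36 at
n = 20. The per-sample fence for an equal-depth sample sits near −4.05, but
it scales with the sample's overall score dispersion, which varies with its
sequencing depth relative to the batch. At n = 20 with realistic
sample-depth dispersion the fence therefore frequently falls below the
saturated score of a true heterozygous deletion and the event is masked:
measured single-spike sensitivity at 20 samples/1,000× is ≈ 0.5, rising to
≈ 0.9 only when all samples have identical depth, while at batch sizes of
31 or 61 samples (where the ceiling is 5.3 or 7.7) measured sensitivity is
1.0 and the per-sample gene-level false-call rate on null batches is ≈ 0.
The property test therefore exercises recovery at a 31-sample batch;
deletions in very small batches are an inherent blind spot of plain
two-pass standardization, not of this implementation. Robust (e.g.
leave-one-out or median/MAD) variants would remove the ceiling but would no
longer be the plain two-pass method this package implements.

## Variant filters

* Dominant and X-linked genes: retain only variants with population
  frequency exactly 0 or absent from the database. An absent annotation is
  treated as "novel", i.e. frequency 0 — otherwise the dominant rule could
  never admit novel variants. X-linked genes follow the dominant rule.
* Recessive genes: retain frequency < 10⁻⁴ (0.01%); the boundary itself is
  excluded.
* Mosaic window: VAF ∈ [0.05, 0.25] with both endpoints **inclusive**, and
  variant-read support strictly greater than 30 (exactly 30 is rejected).
  Records with zero total depth are skipped with a warning.
* The frequency filter is monotone: lowering a variant's frequency can only
  keep it in.

## ACMG evidence combination

The 2015 combining rules are implemented verbatim (pathogenic, likely
pathogenic, benign, likely benign; anything else, or any mix of pathogenic-
and benign-side evidence, is VUS). Strength modifiers (`PM6+`) are parsed
and carried but count at base strength by default; a switch upgrades them
one tier. When records carry an externally asserted classification, the
recomputed label is stored alongside and disagreements are surfaced in a
discrepancy report — the packaged reference table contains three rows whose
printed evidence (1 PS + 1 PM + 2–3 PP) combines to Likely Pathogenic under
the strict rules but is labeled Pathogenic, and two of those rows carry the
identical evidence string as a row labeled Likely Pathogenic, so no
combiner can match all printed labels simultaneously. The combiner
reproduces 45 of the 48 packaged rows.

## Amplicon validation

Demultiplexing requires an exact match of the 6-nt barcode and the fixed
`AGAT` adaptor at the read start; no mismatch tolerance is allowed because
6-mers leave no safe edit distance. Assignment is a partition: every read
lands in exactly one sample bin or the unassigned bin. Allele counting
classifies the template base at the site as reference, variant or other
(other bases, including N, are uninformative and excluded from the VAF
denominator). VAF% is rounded half-away-from-zero at the requested
precision (default 1 decimal).

Parental mosaicism is called when (i) the parent's variant-read count is
significantly above the background error rate by a one-sided binomial test
at α = 0.01 Bonferroni-corrected over the tested parents, and (ii) the
parent's VAF is at least 5× the background percentage. The decision rule is
this package's policy; published validation tables report statuses without
stating one. When no background estimate is supplied it is pooled from the
apparently negative parents (VAF < 5%).

## Cohort tabulation

Onset groups: neonatal ≤ 30 days; early infantile 31–182 days; late
infantile 183–365 days. Month boundaries use 30.44 days/month rounded to
the 30/182-day cutoffs, and "1–6 months" owns exactly 6 months
(right-inclusive). Onset beyond the first year violates the cohort
inclusion criterion and raises. A case is diagnosed iff its finding is
classified Pathogenic or Likely Pathogenic; yield percentages are rounded
half-away-from-zero to one decimal, and empty strata report NaN rather than
0. A case with both a sequence variant and a CNV would count once for
yield and once per finding in the frequency table.

The packaged reference tables list only the diagnosed cases, so the
assembled reference cohort fills the remainder with undiagnosed cases of
unknown onset; overall yield and gene frequencies are exact, while subgroup
yields are demonstrated on synthetic cohorts built to the published group
sizes (the case-level onset/syndrome listing needed for exact subgroup
reconstruction is not packaged). One published subgroup percentage (8/28
printed as 28.5%) appears to be truncated rather than rounded; this package
rounds (28.6%) and does not emulate the truncation.

## Synthetic-data generator

Defaults describe one deep targeted batch and were fixed once:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 79 | first capture-kit scale |
| `exons_per_gene` | 5–30 | typical span for ion-channel and synaptic genes |
| `exon_length` | 100–300 bp | coding-exon size range |
| `mean_depth` | 1,300× | matches the reference batch mean (1,337×) |
| `sample_depth_sd` | 0.25 (log) | ~×1.6 spread between libraries in a pooled capture |
| `exon_bias_sd` | 0.4 (log) | strong, reproducible probe-efficiency bias |
| `read_length` | 101 bp | emulated sequencing run |
| `error_rate` | 0.005/base | post-filter substitution error |

Expected counts are `mean_depth · sample_factor · exon_factor · dosage ·
length/read_length` with Poisson noise (`poisson_noise=False` gives rounded
expectations for degenerate-case tests). Dosage encodes CNVs
multiplicatively: 0.5 heterozygous deletion, 1.5 duplication, near-0
homozygous loss. The amplicon generator uses a fixed random 80-bp template
with the variant at offset 40 and applies errors to every base, barcode
included — so a small unassigned bin is expected at nonzero error rates.
Cohort simulation produces exact group sizes with `round(size · yield)`
diagnosed cases per group. All generators draw from per-operation streams
derived from one seed, so outputs are bit-reproducible and stages can be
re-run independently.

What the generator does **not** model: GC-dependent capture bias,
correlated noise between neighboring exons, batch effects between kits,
PCR duplicates, strand artifacts, or indel-containing amplicon reads.
Passing tests therefore demonstrate the correctness of the arithmetic and
the behavior of the method under its own noise assumptions — not calling
performance on real capture data, where exon-level noise is heavier-tailed.

## Problem sizes used in tests and the acceptance script

Simulation-based checks use a 79-gene (~1,400-exon) panel, batches of 20
and 31 samples at 1,000× with 50 replicate seeds, 200-variant tables, and
amplicon pools of 10,000 reads per sample with 100-seed separation runs.
The full test suite and the acceptance script each complete in well under a
minute on one CPU.
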