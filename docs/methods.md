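# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic benchmark does and does not show.

## Study design and statistical model

The design is fully paired: each of 4 patients contributes one control,
one TNF-α-stimulated and one TGF-β-stimulated sample on each platform.
All inference reduces to one-sample *t*-tests on within-patient
differences of log-scale values (log₁₀ for MS intensities, log₂ for
array expression and qPCR ratios), two-sided, df = n−1. Significance is
raw p < 0.05 everywhere; **no multiple-testing correction is applied at
any stage**. This is a deliberate fidelity choice — the analysis this
package reimplements used the raw threshold — and gene-level hit lists
should be read accordingly (at ~340 detected genes, ~17 false positives
per contrast are expected under the null).

Degenerate cases are flagged, never silently imputed: pairs with a
missing member are dropped; fewer than two complete pairs makes a
feature untestable (p = NaN); zero-variance differences leave p
undefined. Flagged features classify as "not significant" in volcano
partitions, and a zero fold change is never counted as regulated.

## Proteomics conventions

* **Digestion** — Keil rule (cleave after K/R, suppressed before P),
  zero missed cleavages, implemented as an ordered lossless partition of
  the sequence. The strict rule is used, without the ExPASy WKP/MRP
  exceptions; tests cross-check against pyteomics outside those motifs.
* **Theoretical peptide bounds** — 6–30 residues (configurable), the
  convention of the original iBAQ definition; the same bounds apply to
  the shared-peptide set.
* **Shared-peptide exclusion** — any tryptic peptide occurring in both
  the cell-species and serum-species databases is excluded outright
  before quantification; serum contamination is thereby structurally
  impossible rather than estimated.
* **Unique-peptide quantification** — peptides matching more than one
  cell-species protein are excluded (no razor assignment); a protein's
  raw intensity is the sum of its surviving peptides. Replicate
  injections of a peptide are averaged before summing.
* **Median normalization** — each sample's detected log₁₀ intensities
  are shifted so its median equals the median of per-sample medians.
  The target convention matters only as a global offset; paired
  differences are invariant to it.
* **Extracellular proteome** — nonzero control intensity in *every*
  patient; treated samples do not count toward detection (the secretome
  is defined on quiescent cells). A flag on the operation exposes the
  alternative.
* Protein log₂ fold changes are mean paired log₁₀ differences divided
  by log₁₀ 2, keeping effect sizes comparable across platforms.

## Transcriptomics conventions

* **Quantile normalization** — the sorted-column-mean dialect: every
  column is mapped by rank onto the row-wise mean of column-sorted
  values; ties within a column receive the mean of the reference values
  over the tied block.
* **Detection** — a probe/gene is detectable at log₂ ≥ 5 (inclusive) in
  ≥ 2 of 12 samples; the filter runs at probe level before collapsing,
  and genes whose probes all fail simply drop out.
* **Probe collapsing** — one representative probe per gene, the one
  with the highest mean over control samples; exact ties break to the
  lexicographically smallest probe id.
* **qPCR** — relative expression `2^−ΔCt` against the housekeeping
  gene; the ratio paired *t*-test is computed as a paired *t*-test on
  log₂ expression, with the geometric-mean ratio as the reported effect.

## Categorization

Localization precedence for multi-keyword entries is
secreted > membrane > endoplasmic reticulum. Name-based tags use
case-insensitive anchored patterns (`COL\d+A\d+`, `MMP\d+`, `TIMP\d+`,
`FN1`) and imply ECM membership. A feature with both cytokine and ECM
evidence keeps only the cytokine tag by default (configurable), so the
compositional slices stay disjoint and fractions sum to 1. Transcript
composition is computed on the linear scale (2^log₂) — log-scale values
are not additive abundances; a switch exposes the log-scale variant for
sensitivity analysis.

## The synthetic-data generator

The generator *is* the study conditions. Defaults: 4 patients,
conditions (control, TNFA, TGFB); planted effects TNF-α → cytokines
log₂FC 1.5, TGF-β → collagens log₂FC 1.0; patient random effect SD 0.3
and residual SD 0.3 (log₂ scale, shared by both platforms; converted to
log₁₀ internally for MS); ~70 cell proteins across eight categories;
serum near-homologs for 30% of cell proteins, built by mutating every
tryptic peptide except one, so the cross-species shared-peptide set is
known exactly; abundance-dependent MS dropout, logistic in log₁₀
intensity (midpoint 5.0, scale 0.5) — the mechanism by which array
detection exceeds MS detection; 1–5 probes per gene with fixed affinity
offsets; 300 null background genes spanning log₂ ≈ 3–14 emulating the
non-secreted transcriptome; 10 genes planted below the detection
threshold; a qPCR panel of the cytokine and collagen genes against a
null housekeeping gene. Gene base expression is an affine map of the
protein's base log₁₀ abundance plus scatter, planting the positive
protein–transcript correlation characteristic of secretome data. All
randomness derives from one master seed through `SeedSequence` spawning
(stream per stage), so identical (config, seed) pairs are byte-identical
on disk.

Background-transcriptome size matters scientifically: quantile
normalization assumes regulated features are a small minority of all
probes. With only the secreted panel on the "array" the planted effects
would occupy the distribution's upper tail and be visibly shrunk by
normalization; with the 300-gene background spanning the full dynamic
range the residual shrinkage is ≤ ~0.15 log₂ units at the default
conditions, comparable to real-array behaviour.

What the generator does **not** emulate: raw spectra and peptide
identification error, probe-sequence effects and array background
(inputs are background-free intensities), the 6 h/24 h/72 h time
course (conditions are categorical), batch structure, and
protein-specific translation efficiency beyond the planted monotone
protein–transcript coupling. Passing tests therefore demonstrate the
correctness and calibration of the computational pipeline under the
stated generative model, not robustness to those real-data artifacts.

## Verification studies and problem sizes

* **Worked examples** recompute internally consistent percentages from
  the published summary counts used as inputs (112/166 secreted = 67%;
  fibronectin 17% of secretome with ECM at 58% → 29% of ECM;
  collagens+MMPs/TIMPs 11% → 19% of ECM; volcano totals 73+37 = 110 and
  80+94 = 174).
* **Null calibration** — 200 simulations at a reduced size (38 proteins,
  60 background genes, 1–3 probes per gene) with no planted effects;
  the pooled fraction of p < 0.05 calls is checked against [0.03, 0.07]
  for protein-level, gene-level and category-sum tests. The reduced
  size keeps each simulated study ~0.2 s while pooling thousands of
  tests per family.
* **Effect recovery** — 100 simulations at the default conditions;
  power of the planted category-sum effects and mean estimated log₂FC
  on both platforms.
* **Zero-noise exactness** — with all SDs zero and dropout off, the
  recovered secretome composition equals fractions derived
  independently from the planted abundances, surviving unique-peptide
  counts and theoretical-peptide counts, to 1e-9; protein fold changes
  from the log₁₀ layer equal planted values exactly. Gene-level
  exactness through quantile normalization holds for the null design
  (identical samples → normalization is the identity); with planted
  effects and no noise, equal-distribution normalization is *by
  construction* mis-specified, so gene-level exactness is not asserted
  through that path — see the background-transcriptome discussion above.

## Numerical choices

Spearman correlation uses an exact two-sided permutation p-value for
n ≤ 7 (exhaustive n! enumeration) and scipy's asymptotic p beyond.
Quantile-normalization agreement across columns is exact to 1e-12 by
construction. Median normalization raises on a sample with no detected
proteins rather than guessing. Composition denominators of zero raise;
empty categories report fraction 0 where a complete table is needed and
are skipped with a warning in category-sum testing. Percentages in
reports are rounded to the nearest integer, matching the field's
presentation convention.

## Known limitations

Synthetic gene symbols are unique per gene, so gene-level assignment
collisions (real annotation's many-to-one accession→symbol maps) are
exercised only in dedicated unit tests, not end to end. The
secretome-definition flag (controls only vs any condition) and the
cytokine-vs-ECM precedence are exposed but only their defaults are
exercised by the acceptance studies. The pipeline starts from a peptide
intensity table and a probe intensity matrix; identification FDR,
protein grouping beyond the unique-peptide rule, array background
correction and batch effects are out of scope.
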