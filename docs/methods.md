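# Methods

## Overview

`cpglights` implements a single-CpG methylation–expression analysis in
seven stages: (1) synthetic input generation, (2) profile preparation
(class averaging, RLE normalization, filters, promoter windows),
(3) Spearman correlation and traffic-light calling, (4) motif model
construction and threshold calibration, (5) promoter scanning,
(6) per-TF and per-position enrichment statistics, (7) genomic-feature
co-localization.  This note records the model assumptions, the defaults
and why, the numerical choices, and what the synthetic data does and
does not establish.

## Profiles and filters

Expression and methylation are analyzed at the level of *cell-type
classes*: per-sample values are averaged (arithmetic mean over
non-missing samples) within each class, and methylation read coverage is
summed.  CAGE-like counts are normalized by relative log expression
(median-of-ratios) before averaging; the reference set for the size
factors is restricted to clusters with positive counts in every sample.
Filters, all exposed as parameters with these defaults:

* per-class coverage ≥ 10 reads, otherwise the class value is missing
  (applied after summing sample coverage within the class — coverage is
  a property of the pooled class observation, and the per-sample
  alternative is available by filtering before averaging);
* a cytosine needs data in ≥ 50% of classes (ceil: 25 of 50, 18 of 36);
* a TSS needs at least one class with normalized expression ≥ 1
  (the boundary value 1.0 is retained);
* "differentially methylated" means profile amplitude (max − min)
  strictly greater than 50 percentage points.

Promoter windows extend 1500 bp upstream and 500 bp downstream of the
TSS cluster, strand-aware, clipped at zero, never merged: a cytosine
inside several overlapping promoters is correlated against each TSS
independently.  Coordinates are 0-based half-open everywhere; BED is the
native convention.  Minus-strand CpG measurements are collapsed onto the
forward-strand C of the dyad with a coverage-weighted average, since the
CpG (and CCGG) context is strand-symmetric.

## Correlation and traffic lights

Spearman correlation uses average ranks for ties and pairwise-complete
classes; pairs with fewer than 5 complete classes, or a constant vector,
yield no result.  The minimum of 5 is our choice (the t transform needs
n > 2; very small n gives degenerate rank statistics) and is
configurable.  Significance is the two-sided Student-t tail of
t = SCC·√(n−2)/√(1−SCC²) with n−2 df; the effect sign is read from the
SCC.  |SCC| = 1 is flagged (t infinite, P reported as 0).

A cytosine is *negative-significant* (a traffic light) when it is
differentially methylated and at least one of its promoters gives
SCC < 0 with P ≤ 0.01; *positive-significant* is defined analogously and
is only assigned when no negative call applies — cytosines significant
in both directions through different promoters keep the negative label
and are counted in an `ambiguous` column (zero on noise-free synthetic
data).  No multiple-testing correction is applied at this stage; the
correction enters in the enrichment stage.

## Motif models

* **PWM**: log-odds with a background-proportional pseudocount,
  w[a,j] = ln((x[a,j] + pc·q_a) / ((N + pc)·q_a)), pc = ln N by default;
  the pseudocount convention keeps rare-letter penalties stable in N.
* **Threshold calibration**: the exact distribution of the score of an
  i.i.d. background word is computed by dynamic programming over column
  score distributions discretized at 10⁻⁴; the threshold is the smallest
  attainable score whose tail probability is ≤ 5·10⁻⁴.  The
  discretization makes the DP exact on the grid (score-axis error at
  most L·5·10⁻⁵); tests verify the DP tail equals full 4^L enumeration.
  Note that motifs shorter than 6 columns cannot attain a 5·10⁻⁴ tail
  under a uniform background (every word has probability ≥ 4⁻⁵ ≈ 10⁻³);
  such models raise a degenerate-model error.
* **Alignment filtering**: sites scoring below the calibrated PWM
  threshold are removed; alignments left with fewer than 15 sites are
  discarded.
* **RDM**: dinucleotide frequencies f[a,i,j] over all ordered position
  pairs i < j, normalized by Σ_{i<j} max_a f — an exact identity
  Σ_{i<j} max_a r = 1 holds by construction.  A word scores the sum of
  its pairwise weights (the additive analog of PWM scoring; the
  normalization makes the consensus of a degenerate alignment score
  exactly 1).  Thresholds are calibrated by full enumeration for L ≤ 10
  and by Monte Carlo with 2·10⁶ background words (with a reported
  standard error) for longer motifs.  Whether f enters as counts or
  frequencies is immaterial — the normalization cancels the factor N.
* **DIC**: computed with natural logarithms through log-Γ, so fractional
  counts (class thresholds at N/3 or N/6) are well defined.  The
  parenthesization (1/N)(Σ ln x! − ln N!) makes DIC ≤ 0 with maximum 0
  at a single-nucleotide column, so "greater than Th" denotes higher
  information content.  The classification of a C·G column pair is
  core (both DICs > Th), medium (both in [th, Th]), low (both < th), or
  mixed otherwise; mixed pairs are reported separately rather than
  folded into a stratum.  "Major nucleotide" is tie-permissive: C counts
  as major when its count equals the column maximum.

## Scanning

Both strands of every promoter are scanned; reverse-strand windows are
scored on the reverse complement and reported in forward coordinates.
Windows containing a non-ACGT base are skipped (conservative and
deterministic).  Overlapping hits of one TF are all kept — downstream
counting deduplicates per CpG per TF per model kind.  Optional
ChIP-seq-style peak restriction keeps hits *fully contained* in a peak
(a binding site must lie within the bound region; an any-overlap variant
would only differ for hits straddling peak edges); when the peak table
carries a `tf` column the restriction is per factor.

## Enrichment

The expected traffic-light count inside a TF's sites is
global-fraction × (analyzed CpGs inside the sites), where the global
fraction is taken over all analyzed CpGs.  The test is the one-sample
chi-square with 1 df and no continuity correction — the natural test
against a fixed expected fraction when in-TFBS CpGs are a small minority
of all CpGs (a 2×2 inside/outside variant is asymptotically equivalent
in that regime).  Bonferroni's m is the number of TFs entering the test
for that model kind (default: those with at least one observed
significant CpG in their sites, mirroring the per-TF-table inclusion
rule; configurable).  Because the chi-square approximation degrades at
small expected counts, an exact binomial tail (distance-from-expectation
ordering, identical to ordering by the chi-square statistic) is always
reported alongside.  TF-function classes are compared with Welch's
unequal-variance t-test on per-TF observed/expected ratios, with an
explicit degenerate path for zero-variance inputs.  Positional analysis
attributes each CpG-in-hit to the motif column it occupies (strand-aware
for minus-strand hits, where the motif C corresponds to the forward G of
the dyad), tests each stratum separately, and emits a paired cross-TF
core-vs-flanking comparison.

## Synthetic data

The generator emulates the study's shape on one synthetic chromosome:

* 50 cell-type classes, 36 flagged normal; 1–4 samples per class (or a
  fixed count), sample library sizes uniform in [0.5, 2] so RLE
  normalization is non-trivial;
* per-cluster expression with log-normal class effects and Poisson
  sampling; a 5% housekeeping subset with high mean and low class
  variance guarantees RLE reference clusters;
* planted-negative cytosines: class-level methylation decreasing
  linearly in the class expression *rank* from 95% down to 5%
  (amplitude 90 > 50 by construction), plus truncated Gaussian noise
  (default 5 points) clipped to [0, 100] — the simplest model producing
  the observed bimodal-with-intermediates profile shape;
  planted-positive: increasing; nulls: a low/high mixture (defaults
  U(5,20) / U(80,95) with weight ½, both exposed as parameters since
  only the bimodal tendency of real data is known) independent of
  expression;
* the planted fractions default to 0.166 negative and 0.008 positive
  among background cytosines, matching the analyzed-fraction scale of
  the real data;
* per-class coverage: 15% of class values missing, 5% drawn at mean 5
  reads (below the coverage filter), the rest at mean 30, distributed
  over the class's samples; missing values are absent records, which
  forces the pairwise-complete logic to be exercised;
* motif occurrences are drawn column-independently from each TF's PCM
  and placed without overlap; a *CpG slot* (an occurrence's classified
  C·G column pair) hosts a measured cytosine with probability
  `occupancy`, in which case the two columns are fixed to C·G (the
  conditional draw given the pair is present); background cytosines are
  planted CG dyads outside all occurrences, so every measured position
  is a real CpG;
* depletion is planted at label assignment: a hosted cytosine is
  planted-negative with probability depletion_factor × the background
  rate (optionally per stratum), which makes the inside/outside rate
  ratio equal the depletion factor exactly in expectation;
* `n_cpg_per_promoter` is the mean count of *background* cytosines per
  promoter; hosted cytosines add on top of it;
* a peak track (occurrence ± 50 bp, per TF) emulates ChIP-seq
  restriction — on synthetic data it removes background-word hits away
  from planted sites, which would otherwise dilute depletion estimates
  exactly as false predictions do on real data;
* a CpG-island-like track covers planted negatives with probability 0.8
  and other cytosines with probability 0.5;
* the default motif set contains five TFs (two activators, two
  repressors, one bifunctional) with core CpG pairs, one medium pair,
  and one TF carrying both, so every positional stratum is populated.

All randomness derives from a single seed through per-stage
`numpy.random.Generator` streams; identical configurations give
bit-identical outputs, which the run manifest verifies by SHA-256
digests.

What the synthetic data does **not** emulate: chromatin-domain
autocorrelation of methylation along the genome, read-level bisulfite
noise, sequence evolution, and real motif redundancy.  Passing the
suite therefore demonstrates the correctness and calibration of the
*method* — not that real data meets its assumptions.

## Problem sizes used in validation

The validation suite calibrates on: ≥ 10,000 planted-null cytosines
(600 promoters × 18 CpGs, one sample per class) for the null rejection
rate; 700 promoters × 60 background CpGs with full slot occupancy for
depletion recovery (several hundred in-TFBS CpGs per TF); 100
counting-level replicates of 250 promoters for the core-vs-flanking
separation; 200 label permutations for the enrichment calibration; and
a 5-TF, 200-promoter end-to-end run for determinism.  These sizes give
every check a comfortable statistical margin while keeping a full run
in the minutes range on one CPU.

## Known limitations

* The recovered depletion ratio slightly exceeds the planted factor
  (≈ 0.55 for a planted 0.5) for two structural reasons shared with the
  real analysis: the global traffic-light fraction in the denominator is
  itself diluted by the depleted in-TFBS CpGs, and false-positive calls
  among nulls add equally inside and outside.  Both effects are small
  when in-TFBS CpGs are a minority.
* The traffic-light P-value uses the t approximation of the Spearman
  null distribution, adequate for the ~25–50 classes of this design but
  not for very small n.
* PWM thresholds are calibrated against an i.i.d. background;
  dinucleotide backgrounds are out of scope.
* The scanner holds one promoter's windows in memory at a time and is
  intended for promoter-scale scans, not whole-genome scans.
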