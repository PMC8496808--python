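# Methods

## Problem and model

Two related species differ by segmental duplications: some gene families
are present at different copy numbers in each genome. Three measurement
platforms observe these differences imperfectly:

* **aCGH** — competitive two-channel hybridization. Per probe, the
  expected log2 ratio is log2(cA/cB) where cA, cB are the true copy
  numbers of the probe's target in the two species, plus a smooth
  GC-dependent distortion and Gaussian array noise.
* **Long-read-style assembly** — assumed complete: exact-match probe
  counts equal true copy numbers.
* **Short-read-style assembly** — prone to collapsing near-identical
  copies: a collapsed family contributes a single exact-match count
  regardless of its true copy number.

The analysis asks how well the aCGH ratio tracks each assembly-derived
hit ratio, which probes each platform flags as species-biased, how the
platform-exclusive probe sets differ in nucleotide composition, and
whether gene-level calls are functionally biased.

## The synthetic study generator

The generator is the package's instrument: it produces data whose
latent parameters are recorded, so recovery can be scored exactly.

**Genomes.** A single-copy backbone of `genome_length` bases hosts
`n_genes` genes of `gene_length` bp separated by equal random spacers.
`n_cnv_regions` genes become CNV families with copy numbers drawn
independently per species from `copy_range_a` / `copy_range_b`
(redrawn until at least one species has ≥ 2 copies, so every planted
region is genuinely multi-copy somewhere). Copies are placed in tandem
separated by short random linkers, so each copy contributes exactly one
exact-match occurrence per probe. Inter-species divergence
(`divergence_rate`, i.i.d. substitutions) is applied to intergenic
spacers only, with intergenic-probe windows protected; gene bodies are
conserved between species. This is a deliberate superset of
"no divergence at probe target sites": it keeps per-probe truth exact
while still making the two genomes distinguishable outside probes.

**Assemblies.** The long-read-like assembly is the genome verbatim. The
short-read-like assembly drops, with probability
`collapse_probability` per multi-copy family, every copy after the
first — whole-copy collapse, the simplest model of assembly collapse;
partial collapses are out of scope. Collapse events are recorded in the
truth table.

**Probes.** Three non-overlapping 60-mers (configurable; 60 nt is a
typical long-oligo array length) are sampled uniformly from each gene
body of the species-A reference — mirroring a single-reference array
design bias — plus intergenic probes at 6 kb spacing (one per full
interval per spacer, matching floor(span/spacing)). Real array vendors
apply Tm/uniqueness screening; uniform sampling is used instead since
probe thermodynamics are not modelled.

**Arrays.** Four arrays: Bio1, Bio2 and a technical pair Bio3-TechA/B
sharing one biological sample. Per probe and array the simulated ratio
is log2(cA/cB) + `gc_bias_coeff`·(GC − mean GC) + N(0, `noise_sd`);
biological samples can perturb species-A copy numbers at
`intra_species_cnv_rate` per region (default 0 — within-species
variation exists in real data and the knob exists to emulate it, but
the default study conditions leave it off). Channel intensities are
reconstructed as brightness·2^(±ratio/2) with per-probe lognormal
brightness, so log2(test/ref) returns the simulated ratio to machine
precision. Dye-swap is not modelled (reference design).

**GO annotation.** A flat map of `n_terms` synthetic terms; each gene
draws 1–4 terms. A 10% subset of terms is sampled with weight multiplied
by `enrichment_factor` for CNV-region genes, making enrichment recovery
testable. No GO graph / true-path propagation — the map is flat, and
pre-propagated maps can be supplied as-is.

**What the generator does not emulate:** read-level sequencing error,
assembler behaviour beyond whole-copy collapse, spatial array
artifacts, probe cross-hybridization, segmental duplications of
intergenic sequence, and real genomic base composition (the backbone is
uniform i.i.d. ACGT, so GC varies only binomially around 0.5). Passing
tests therefore demonstrate correctness of the analysis machinery and
qualitative robustness of the platform-concordance effect, not
quantitative agreement with any real-data values.

## Hit counting

"Perfect alignment" is implemented as exact full-length string matching
on either strand — mathematically the 100%-identity full-length filter,
without heuristic seed losses. Semantics: distinct start positions per
FASTA record; overlapping matches all count; a position matching in
both orientations (palindromic probe) counts once; matches never span
record boundaries; `N` matches nothing on either side. Sub-100%
identity is a Hamming mismatch budget (no gaps), implemented by
pigeonhole seeding (one of k+1 probe chunks must match exactly) with
full verification; gapped matching is out of scope. The identity sweep
fixes the probe universe at the perfect-match level (≥ 1 perfect hit in
all four assemblies) before loosening the budget, so counts are
non-decreasing in the budget by construction. A brute-force
position-enumeration scanner, kept independent in the test suite,
validates the matcher exhaustively.

## Array processing

* **Raw ratios** log2(test/ref), with non-positive intensities rejected.
* **Between-channel normalization** defaults to median-centering of
  each array's log ratios. A quantile-matching variant (both channels
  mapped to their common quantile distribution, then median-centered)
  is available for data with channel-wide monotone intensity
  distortion. Median-centering is the default because quantile matching
  forces the two channels onto a common distribution and therefore
  attenuates genuine copy-number signal under a reference design; with
  a majority of copy-neutral probes the per-array median is exactly 0
  and centering is an exact identity, which preserves the noiseless
  truth-recovery contract.
* **GC-loess** subtracts a lowess fit of ratio on probe GC (span 0.3,
  tricube weights, 2 robustness iterations; statsmodels). It is off by
  default in the pipeline and enabled where GC bias is simulated or
  suspected.
* **Aggregation** is literal mean-then-median: the technical pair is
  averaged and enters a three-way median with the two other biological
  arrays, unweighted (no per-probe quality weights are modelled).
* **Calls** use strict exceedance of ±0.8 (a ratio of exactly 0.8 is
  neutral); 0.8 in log2 units sits between 1.5:1 and 2:1, a
  conservative single-copy-change threshold.

## Concordance

All inter-species ratios are oriented species-A over species-B;
positive = A-biased. Hit-platform neutrality is ratio exactly 0 (the
only neutral value for integer counts); aCGH neutrality is |ratio| ≤
0.8. Correlations are Pearson r with t = r·√(df/(1−r²)), df = n−2;
the "non-neutral pair" mode drops probes neutral in *both* platforms of
a pair before correlating. Call-set intersections are reported as the
seven regions of the three-set Venn per bias direction, for all probes,
genic probes only, and genes. A gene is called for a platform iff at
least one of its probes is (genes carry three probes, so gene counts
are bounded by probe counts). Group tests: Kruskal–Wallis (tie-
corrected, χ² on k−1 df; degenerate all-equal data returns H = 0,
p = 1) across the four assemblies' hit counts, and one-way ANOVA with
Tukey HSD (Tukey–Kramer for unequal n) comparing aCGH ratios of
platform-biased subsets against the full multicopy set — the full set
enters as its own group, overlap with the subsets accepted by design.

## Composition statistics

22 features per probe: 4 mononucleotide frequencies, 16 overlapping
dinucleotide frequencies (L−1 windows), overall G/C and A/T. The
PERMANOVA distance is Euclidean on z-scored features (the conventional
default for continuous morphometric-style data; both the metric and
standardization are exposed). pseudo-F = [(SSₜ−SS_w)/(k−1)] /
[SS_w/(N−k)] from sums of squared distances; p = (1 + #{F* ≥ F}) /
(1 + n_permutations) with seeded label permutations (999 by default;
the pipeline uses 199 to keep run times short). Pairwise p-values are
BH-FDR adjusted. PCA operates on the correlation (z-scored) matrix
because the features mix bounded frequencies of different variances;
zero-variance features are dropped with a warning, and component signs
are fixed by making each component's largest-magnitude loading
positive. Post-hoc per-feature ANOVAs use a Bonferroni factor equal to
the number of features tested (22).

## Enrichment

One-sided Fisher exact test (hypergeometric upper tail) on the 2×2
table (carries term / does not) × (test set / background − test);
enrichment of gains only — depletion is out of scope. Unannotated genes
remain in the denominators by default (`annotated_only` switches to an
annotated-only universe; conventions vary between tools, so both are
exposed). A two-sided variant is likewise available. Contrasts
enumerate, per species-bias direction, the seven Venn regions of the
three platform gene sets against the union of that direction's gains,
plus the union of all gains against all annotated genes; empty test
sets are skipped with a log notice. BH FDR across terms, significance
at FDR < 0.05. Reported percentages are shares of the test set and of
the background minus the test set.

## Numerical and design notes

* **Seeding.** One global seed fans out to named per-stage streams via
  (seed, crc32(stage)) seed sequences, so adding a stage never perturbs
  earlier streams and all outputs are bit-reproducible.
* **"Exact" recovery** in the noiseless regime means exact up to
  float64 round-trip error (< 1e-9): intensities are reconstructed as
  brightness·2^(±r/2), so log2(test/ref) reproduces r to machine
  precision; hit ratios of integer counts are exactly log2 of rational
  numbers. Truth calls for sensitivity/specificity are the planted
  ratios thresholded at the same ±0.8 as the observed calls — a planted
  3:2 family (|log2| ≈ 0.585) is *correctly* neutral at this threshold.
* **Degenerate inputs.** Zero-variance correlation inputs raise a data
  error rather than returning NaN; all-identical ANOVA/KW inputs return
  the null statistic; a fully-collapsed study yields constant (all-zero)
  short-read ratios whose correlations are deliberately undefined.
* **Problem sizes.** Default test and acceptance studies use a
  ~100–120 kb backbone with 24–40 genes and 12–20 planted families,
  and 100 replicate seeds for the platform-ordering experiment; these
  sizes give stable statistics while keeping full runs in seconds.
* **Known limitations.** Uniform base composition makes probe GC spread
  narrow compared to real genomes; the collapse model is all-or-none;
  BLAST-style gapped or partial matches are not modelled; the GO map is
  flat. Conclusions about real data should rest on the machinery being
  correct (which the oracle and calibration tests establish), not on
  the generator being a faithful genome model.
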