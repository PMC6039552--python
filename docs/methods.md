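# Methods

## Statistical model

### Non-conversion and site calling

Bisulfite converts unmethylated cytosine to uracil (sequenced as T) but
leaves 5-methylcytosine intact; N4-methylcytosine is only partially
resistant, which depresses its apparent level but does not change the error
model. Conversion fails at a non-conversion rate R, estimated by pooling
methylated-looking reads over all cytosines of an unmethylated spike-in
control: R = k_control / n_control. R is a single genome-wide scalar; no
per-position or per-context conversion variation is modelled.

At a cytosine with n reads, k of them methylated-looking, the no-methylation
null is k ~ Binomial(n, R). We use the exact one-sided upper tail
P(X ≥ k) — one-sided because the alternative of interest is an excess of
unconverted reads over the noise rate. P-values are corrected by
Benjamini–Hochberg step-up over the testing universe. By default the
universe is the set of sites already passing the coverage filter
(n ≥ min_coverage); this "filter before FDR" choice is conservative and
reproducible, and a `fdr_universe="covered"` option widens the universe to
every covered site for sensitivity analysis. An mC site is a site with
n ≥ 5 and q ≤ 0.05 (both configurable).

### Methylation level

ML_uncorrected = k/n. The generative model for observed methylation is
p_obs = m + (1 − m)·R (methylated reads fully protected, unmethylated
converted with failure rate R), so the level corrected for background is
its exact inverse, ML = (ML_uncorrected − R)/(1 − R). At finite coverage the
formula can leave [0, 1]; values are clamped because levels are
proportions. The simulator and the estimator deliberately share this model,
so parameter-recovery tests are exact up to binomial noise.

### Context and strand conventions

A site is a strand-specific cytosine; CG sites are not collapsed across
strands, since the underlying methyltransferase motifs are
strand-asymmetric and per-site bookkeeping must be unambiguous across
conditions. Context is CG / CHG / CHH by the two downstream bases on the
cytosine's own strand; cytosines within 2 bp of a replicon end or whose
downstream dinucleotide touches an N have undefined context and are
excluded from the universe (a negligible count). Coordinates are 0-based
half-open internally; cytosine-report TSVs are 1-based (Bismark
convention) and BED output 0-based half-open.

### DMR detection

Windows of 200 bp, stepped 40 bp, tiled from position 0 with no trailing
partial window. Per window and sample, methylated and unmethylated read
counts are pooled over cytosines covered ≥ min_coverage in *both* samples;
windows with fewer than min_sites (default 5) such cytosines are not
tested. The 2×2 table (sample × read class) is tested by the two-sided
Fisher exact test; windows are BH-corrected genome-wide at q ≤ 0.05, and a
significant window must also show a pooled-level difference ≥ min_diff
(default 0.1) to guard against coverage artifacts at large read counts.
Overlapping or book-ended significant windows of the same direction merge;
directions never merge. Direction is defined for the second sample relative
to the first (hyper = more methylated under treatment). Pooling *reads*
rather than averaging site levels weights deep sites more; this is the
standard sliding-window Fisher formulation and keeps the test exact.

### Multi-condition statistics

Site identity across conditions is the (replicon, position, strand) triple;
context always comes from the shared reference genome. The three
per-condition mC-site sets decompose into the exclusive 7-cell Venn
partition, from which all totals, pairwise overlaps, and the retention
statistics derive: lost = A-only + AC, gained = B-only + BC, preserved =
BC/gained, regained = AC/lost (fractions undefined when the denominator is
zero, reported as NaN). Gene-level Venn analysis reuses the same partition
with "gene has ≥ 1 mC site in its body" as membership.

Per-context methylated proportions divide by cytosines covered
≥ min_coverage in that sample by default ("covered" mode), which is robust
to coverage differences between samples; a "genomic" mode dividing by all
context-defined cytosines is available. Level summaries are five-number
summaries (min, Q1, median, Q3, max) of corrected levels over mC sites,
with quantiles by linear interpolation between order statistics — a fixed
convention so tests can assert exact values. TE-type mC sites must overlap
a transposable-element interval and no gene body ("exclusively within
TEs"). Region assignment uses the precedence gene_body > upstream >
downstream > intergenic with 100 bp default flank lengths; ties between
genes resolve to the lexicographically smallest gene id.

### Enrichment, growth and expression utilities

Pathway over-representation is the upper-tail hypergeometric test on a
user-supplied gene→pathway mapping, BH-corrected across pathways. The
universe defaults to all mapped genes (override available); pathways with
fewer than 2 genes or zero overlap are skipped before correction, since
uninformative tests only inflate the correction burden. The growth-rate
helper implements μ = (ln OD₂ − ln OD₁)/(T₂ − T₁) from endpoint optical
densities (no curve fitting) and compares groups with Welch's
unequal-variance t-test — the safe default when the variance structure is
unknown; with identical zero-variance groups the p-value is NaN. Relative
expression is 2^−ΔΔCT with no amplification-efficiency correction.

## Synthetic data generator

The generator emulates the three-condition nitrogen experiment:

- **Genome**: i.i.d. bases at a target GC fraction (default 0.475, a
  cyanobacterial value), split over replicons to mimic chromosome +
  plasmid structure. No repeats, motifs or compositional heterogeneity.
- **Baseline methylome**: each cytosine independently methylated with its
  context prevalence — defaults 3.05 % CG, 0.90 % CHG, 1.03 % CHH, the
  baseline-condition values of the study design. True levels are Beta
  draws: CG ~ Beta(8, 2) (high, tight — 5mC reads out near-completely) and
  CHG/CHH ~ Beta(2.5, 5) (low — these contexts are dominated by partially
  bisulfite-resistant 4mC, which presents as a reduced apparent level).
  An optional protection factor for designated non-CG sites defaults to 1;
  the lower Beta means already encode the reduced apparent level.
- **Condition shift** (`ShiftSpec`): under stress, round(loss_frac ×
  n_methylated) sites drop to zero (default 0.41), survivors gain
  level_delta = 0.1 (clipped at 1), and round(gain_frac × n_unmethylated)
  new sites appear (default gain_frac = 0.0017, chosen so gained sites
  ≈ 12 % of the baseline methylome at default prevalences). After
  recovery, survivors keep stressed levels, preserve_frac = 0.45 of gained
  sites persist, regain_frac = 0.01 of lost sites return at baseline
  levels. Every assignment is recorded in an exact, disjoint truth ledger.
  The shift is spatially uniform: it reproduces the site-set arithmetic of
  the experiment but not regional clustering, so stressed-vs-baseline runs
  legitimately yield ~0 DMRs; DMR detection is validated on planted
  differential blocks instead.
- **Counts**: per-site depth from a Poisson (default mean 50; the
  median-163× depth of the real study is reachable by raising the mean, at
  proportional cost) or negative-binomial model; methylated-read counts
  k ~ Binomial(n, m + (1 − m)·R) with R = 0.003. The spike-in control is a
  separate 20 kb genome with m = 0 everywhere.
- **Annotation**: genes tiled at fixed length/gap on alternating strands
  (bacterial gene density), TEs dropped into a fraction of intergenic
  gaps; random pathway maps and differential-expression tables for the
  enrichment and cross-tab stages.

All randomness derives per-stage streams from one master seed; outputs are
byte-identical for a fixed seed.

What passing tests on this generator show: correctness of the calling
mathematics, FDR control, power, level-correction accuracy, exact
set/retention bookkeeping, and DMR behaviour on localized signals. What
they do not show: robustness to alignment artifacts, coverage biases,
strand biases, context-dependent conversion failure, repeat regions, or
population heterogeneity — none of which the generator emulates.

## Numerical choices and problem sizes

- Exact tail probabilities come from scipy (binom.sf, hypergeom.sf,
  fisher_exact); the test suite verifies each against brute-force
  enumeration oracles (all binomial (k, n ≤ 50); every 2×2 table with
  N ≤ 40; every hypergeometric configuration with N ≤ 30).
- BH q-values via statsmodels, verified against a hand step-up
  implementation and hand-computed vectors.
- Ties in p-values need no special handling under BH; Fisher two-sided
  ties (tables with exactly the observed probability) are included in the
  tail, matching the integer-weight enumeration.
- Degenerate inputs: empty control tables, zero-coverage sites, all-zero
  Fisher margins, empty gene universes and single-replicate growth series
  all raise informative errors or return the documented conventions
  (p = 1 for empty margins, NaN for undefined fractions).
- Default simulation scales are desk-sized by design: 200 kb demo genome
  at 50× coverage (~95,000 cytosine sites per condition, ~5,000 DMR
  windows), 10,000-site null-FDR simulations, 5,000-site power and
  recovery checks. All results in the README were produced at these sizes.

## Known limitations

- No beta-binomial overdispersion in calling; biological replicate
  variation is not modelled (the study design pools one library per
  condition).
- Strand-specific accounting throughout; no CpG-pair collapsing.
- The DMR merger is window-based; no HMM/smoothing segmentation, no
  CpG-island logic.
- 6mA and read-level simulation (FASTQ, sequencing error, PCR duplicates)
  are out of scope: the pipeline begins at per-cytosine counts.
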