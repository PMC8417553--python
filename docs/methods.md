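# Methods

This note documents the models and procedures the toolkit implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Codon-usage tables

A table holds, for each of the 64 codons of the standard genetic code, the
organism's usage per 1000 codons (`usage_per_1000`, the convention of
published usage tables) and the codon's share of its synonymous family
(`rel_fraction`, summing to 1 within each family). The two senses of
"usage frequency" are deliberately kept separate because they serve
different consumers:

- **harmonization matches on `rel_fraction`** — per-family shares are
  comparable across organisms with different amino-acid compositions;
- **%MinMax profiles use `usage_per_1000`** — matching the per-thousand
  convention of sliding-window codon profiling.

Validation enforces: all 64 codons present exactly once, codon/amino-acid
pairs consistent with the standard genetic code, non-negative usage
summing to 1000 ± 1, and (if supplied) `rel_fraction` proportional to
usage within each family to 1e-6. RNA input (U) is transliterated to DNA
(T) on read. Tables given as raw counts or percentages can be loaded with
`rescale=True`. Two bundled tables (`example_table("human")`,
`example_table("ecoli")`) carry representative genome-wide values so every
analysis runs offline; they are fixtures, not curated references for
construct design.

## Harmonization (DUMB optimization)

Codon harmonization aims to reproduce, in the expression host, the
position-by-position codon *rarity profile* of the native gene, on the
premise that programmed slow-translation stretches support cotranslational
folding of membrane proteins. At each codon position the harmonizer picks
the host codon (synonymous with the native one) whose host family share is
closest to the native codon's native family share, subject to a rare-codon
threshold τ (default 0.05):

- `relative_to_native` (default): eligible host codons have
  host share ≥ τ × (native codon's native share) — the literal reading of
  the 5%-of-native-usage rule;
- `absolute_floor`: host share ≥ τ — the common rare-codon-avoidance
  reading.

Both modes are implemented because the published phrasing of the rule is
ambiguous; the mode is recorded with the audit trail. If no synonymous
codon clears the floor, the constraint is relaxed at that position (the
best match is taken) and the position is flagged `constrained` — a total
recoding function is more useful for construct design than a failure. The
flag is also set when the threshold excluded the otherwise-best codon.

Ties in match error resolve by higher host share, then the native codon
itself, then alphabetical order. The native-preference step only
discriminates between codons whose host shares are exactly equal; it
exists so that harmonizing a gene against its own organism's table is the
identity, which equal-frequency codon pairs (present in real tables) would
otherwise break via the alphabetical step.

In `relative_to_native` mode the total match error is nondecreasing in τ:
eligible sets are nested top-k-by-share subsets that always contain the
family's most-used codon while nonempty, and on relaxation the chosen
codon is that same codon. The same monotonicity is *not* guaranteed in
`absolute_floor` mode, where a sub-floor codon can be the global best
match and is recovered when the set empties.

The fully optimized (FO) baseline recodes every position to the host's
most frequent synonymous codon; the random control draws uniformly from
each family under a mandatory seed. All modes copy a terminal stop codon
verbatim, reject internal stops with the offending position, and preserve
the encoded protein exactly (checked by `verify_synonymy`). Engineered
linkers or tags present in the input are recoded like any other sequence;
the tool never adds or strips them.

## %MinMax profiling

For each fully contained window of W codons (default 21, odd) four window
means over per-thousand usage are computed: `Actual` (codons used), `Max`
(each amino acid's most-used codon), `Min` (least-used) and `Avg` (family
mean). The value is

    100 · (Actual − Avg) / (Max − Avg)   if Actual ≥ Avg
    100 · (Actual − Avg) / (Avg − Min)   otherwise

so +100 ⇔ all-most-common and −100 ⇔ all-least-common codons. Numerical
choices: the ratio is computed before scaling by 100 so the analytic
endpoints are attained exactly in floating point; windows whose
denominator vanishes because every family in them is a singleton (Met/Trp
runs) are defined as 0 and flagged degenerate; windows containing
uniform-frequency families also evaluate to 0 but are not flagged, since
synonymous freedom exists. A terminal stop codon is excluded from window
statistics. No edge padding is applied: a sequence of L codons yields
L − W + 1 values at window centers (W−1)/2 … L−1−(W−1)/2. Profiles of two
sequences are compared by mean absolute difference on identical centers
(`profile_distance`).

## Fluorescence-polarization binding

Polarization P = (I∥ − I⊥)/(I∥ + I⊥) of a fluorophore-labeled ligand
rises on receptor binding. Curves are normalized by subtracting the
lowest zero-point (no-receptor) read — the stated normalization and the
only one applied. The titration model fit is

    P(R) = P0 + ΔP · FB(f·R, L, Kd)

with nominal receptor concentration R, orientation factor f (1.0 for
SMALPs/open polymer discs where both membrane faces are exposed, 0.5 for
proteoliposomes where on average half the receptors face inward), fixed
labeled-ligand concentration L (100 nM in the targeted assay), and bound
fraction FB. The default FB is the exact one-site solution with ligand
depletion,

    FB = ((R + L + Kd) − sqrt((R + L + Kd)² − 4RL)) / (2L),

evaluated in the cancellation-free form 2R / (b + sqrt((R − L + Kd)² +
4LKd)), b = R + L + Kd. The depletion form is the default because L is
comparable to the Kd values of interest (tens of nM), where the hyperbolic
approximation FB = R/(R + Kd) is biased toward larger apparent Kd; the
hyperbolic model is offered for the L ≪ Kd regime, and the two agree
within 0.5% at L = Kd/1000. The orientation factor multiplies
concentration *before* fitting and is data, not a hard-coded constant;
note that the "factor 1.0 Kd = 2 × factor 0.5 Kd" identity is exact only
under the hyperbolic model, where f and Kd rescale interchangeably.

Fitting is nonlinear least squares (all replicate reads as individual
points, preserving the error structure; mean ± SEM is a reporting view
only), with Kd bounded positive, initialization Kd₀ = effective
concentration at the half-maximal mean read, ΔP₀ = maximum read, P0₀ = 0.
Reported uncertainty: asymptotic standard errors, t-based 95% intervals
(dof = n − 3), and optionally a seeded bootstrap that resamples replicates
within each concentration (SD and percentile CI). All three are reported
under explicit names because a published ± band may be any of them. A
zero-span (flat) curve raises a fit-failure with diagnostics rather than
returning a silent Kd; fewer than four points is a data-insufficiency
error; fewer than four distinct concentrations warns.

## GTPase luminescence analysis

The luminescence signal reports GTP *remaining* after the reaction
window. The pipeline order is fixed: blank-correct first (subtract the
mean of the buffer-only blanks from every condition and standard
replicate; sub-blank values are flagged, never clamped), then

    % GTP hydrolysis = 100 · (RLU_std − RLU_replicate) / RLU_std

with RLU_std the mean corrected signal of the no-hydrolysis standard
wells. Percentages outside [0, 100] are reported and flagged — they
indicate failed wells. Blank correction makes the statistic invariant to
adding any constant to all raw readings.

Pairwise condition comparisons use the two-sample two-tailed
pooled-variance Student t-test (the classic reading of "Student's
t-test"), with Welch available as an option; significance tiers are
* p < 0.05, ** p < 0.01, *** p < 0.001, ns otherwise. No multiple-testing
correction is applied by default, matching per-pair star reporting; a
Bonferroni option exists. Replicates are treated as exchangeable (the
technical/biological distinction is not modeled).

## Synthetic-data generators

All generators are bit-reproducible functions of (spec, seed) using
`numpy.random.default_rng`.

- **Genes**: codons drawn per residue with probabilities equal to the
  sampling table's family shares; with a bare length, residues are drawn
  proportional to each family's total usage so amino-acid composition
  also matches the table; a terminal stop is drawn from the stop-family
  shares. The human-like and E. coli-like fixture tables are skewed
  differently (e.g. Leu: CTG-dominance differs, Arg: AGA/AGG common in
  one, rare in the other), so harmonized-vs-fully-optimized profile
  separation is genuinely exercised.
- **Binding curves**: reads = P_free + (P_bound − P_free)·FB(f·R, L, Kd)
  + N(0, σ), replicated per concentration, zero point always included.
  Defaults emulate the targeted assay: L = 100 nM, an 11-point receptor
  grid from 0 to 2 µM bracketing Kd in the tens-of-nM range, 3
  replicates, polarization span 0.20.
- **GTPase plates**: RLU = blank + standard_level·(1 − h) + N(0, σ);
  standard wells use h = 0; blanks carry only background. Defaults follow
  assay convention: 3 replicates, 3 blanks, 3 standards; background at 5%
  of the standard level.

Noise is additive Gaussian in both assays — the simplest model consistent
with mean ± SEM/SD error reporting. What the generators do **not**
emulate: concentration-dependent nonspecific binding beyond the zero
point, instrument G-factor effects, plate drift or edge effects,
heteroscedastic luminescence noise, and any coupling between wells.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to those real-data
artifacts.

## Problem sizes used in checks

The recovery and control studies run at: 1,000 random genes (50–500
codons) for translation preservation; 1,000 codon positions per threshold
mode for oracle agreement; 100 genes of 60 codons for profile
recomputation; 20 genes of 300 codons for the harmonized-vs-optimized
profile comparison; 100 binding curves (Kd log-uniform 5–500 nM, 3
replicates, noise 5% of span) for Kd recovery and CI coverage; 1,000
same-distribution plate pairs for type-I control. These sizes give
stable rates (binomial/Monte-Carlo error well inside the asserted bands)
at interactive runtimes.

## Known limitations

- Harmonization optimizes frequency matching only: no restriction-site
  scrubbing, GC balancing, or mRNA-structure optimization.
- The binding module fits one-site, single-ligand saturation; no Hill
  cooperativity, competition formats, or anisotropy-vs-polarization
  distinction.
- The GTPase module quantifies endpoint hydrolysis, not Michaelis–Menten
  kinetics.
- CI coverage for Kd relies on the asymptotic normal approximation; at
  very low replicate counts or poorly spanning grids the bootstrap CI is
  the more trustworthy interval.
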