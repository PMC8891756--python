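# Methods

## Problem and model

Autozygosity — stretches of the genome inherited identical-by-descent from
both parents — is the molecular footprint of inbreeding.  On SNP-array data
it is measured as runs of homozygosity (ROH), and the inbreeding coefficient
F_ROH of an individual is the fraction of the genome covered by its ROH.
Inbreeding depression on a quantitative trait appears as (i) a negative
association between F_ROH and the trait across the cohort, and (ii) specific
regions (ROH islands) where excess homozygosity concentrates in the
low-trait group.  The trait here is a fertility pseudophenotype: a
deregressed estimated breeding value for reproductive efficiency (Re_dEBV),
a percent-deviation scale centred near zero.  Deregression itself (and the
REML animal model that produces the EBVs) is upstream of this package; the
pipeline consumes pseudophenotypes as given.

## ROH calling

Sliding-window scan per individual and chromosome:

* window of `window_size` = 50 consecutive SNPs, sliding one marker at a
  time; a window is *homozygous* when it contains ≤ `max_opp_window` = 1
  heterozygous and ≤ `max_miss_window` = 1 missing calls;
* marker support = homozygous windows covering the marker / windows covering
  it.  The denominator is the *actual* number of covering windows, which
  shrinks near chromosome ends so edge markers remain callable.  A marker is
  in-run when support ≥ `threshold` = 0.05 (inclusive; a `strict_threshold`
  switch gives strict inequality — the convention is not standardised across
  tools);
* maximal stretches of in-run markers are split at inter-marker gaps
  \> `max_gap_bp` = 100 kb and kept when they hold ≥ `min_snp` = 100 markers
  and span ≥ `min_length_bp` = 1 Mb.

Run length is `end − start` over the outermost in-run markers.  This
convention (not `end − start + 1`) is fixed by the region-size arithmetic of
published island tables this package's report format mirrors.  Hets and
missing calls *inside* a called run are permitted — they are controlled at
window level only, which is what makes the window paradigm robust to
genotyping error.

Boundary behaviour worth knowing: against heterozygous flanks the support
criterion trims the call by about one marker per side; against
Hardy–Weinberg background the window tolerance lets a run extend a few
chance-homozygous markers past the true segment.  Both are intrinsic to the
window method, not defects; tests bound them explicitly.

## F_ROH

Per chromosome, F_ROH = covered bp / denominator.  The default denominator
is the SNP-covered span (last − first marker position), the common choice
for array data because it needs no external genome table; a per-chromosome
length table (e.g. assembly lengths) may be supplied instead, which lowers
all values proportionally.  The genome value is the
denominator-weighted mean of chromosome values.

## Association

* **Rank correlation**: Spearman's ρ with the usual t-approximation p-value.
  Reported genome-wide and per chromosome, on the id-intersection of the
  F_ROH and phenotype tables.
* **Divergent tails**: top and bottom `round(q·N)` individuals by phenotype
  (default q = 0.10), ties broken by lexical id so selection is
  deterministic.  Tail analysis concentrates carriers of depressive alleles
  and boosts mapping power at fixed genotyping cost.
* **Segmented correlation**: the x-axis (F_ROH) is split into k
  equal-frequency segments, k = 1..`max_segments`; each k is scored by the
  weighted mean of |within-segment Pearson r| (weights n_w/N); k + 1 must
  beat the incumbent score by `margin` = 0.05 to be adopted, which penalises
  spurious segmentation.  The estimate's magnitude is the winning score and
  its sign is the sign of the weighted *signed* r sum, so k = 1 returns
  Pearson's r exactly.  Significance by permutation of y (default 500,
  seeded).  This estimator is this package's own explicit definition of a
  "non-linear correlation"; published tools of that name do not document a
  reproducible algorithm, so we define one and report rank correlation
  alongside as the robust default.
* **Group comparison**: Welch (unequal-variance) two-sample t-test of F_ROH
  between the tails, per chromosome and genome-wide, two-sided, unadjusted
  by default (Benjamini–Hochberg available) — unadjusted mirrors common
  practice in this literature; the BH column is there for good practice.

## ROH-island mapping

Observed incidence: for each marker, the number of cohort individuals with a
ROH spanning it.  Null: per permutation, every individual's per-chromosome
in-run mask is circularly rotated by an independent uniform offset.  This
preserves each individual's number of runs and their length spectrum exactly
while randomising location — precisely the "random occurrence" a genome scan
for positional excess needs.  A uniform independent re-placement null (each
run rotated separately) is available behind `null="replace"`.

Marker p-value with the add-one correction:
p = (1 + #{null ≥ observed}) / (1 + n_perm), so min p = 1/(n_perm + 1) and
−log10 p is always finite.  `n_perm` defaults to 10,000 (2,000 in the test
scenarios); α = 0.01 stays resolvable at both since the floor is well below
it.  The α = 0.01 cut is identical to demanding a 100-fold enrichment on the
−log10 scale (−log10 p > 2).

Islands: significant markers grouped while consecutive significant markers
are ≤ 100 kb apart; kept when the span (end − start, outermost significant
markers) exceeds 100 kb.  Islands are monotone in α by construction.  An
optional fold filter (`fold_filter`) additionally requires the peak observed
incidence to exceed the rotation-null expectation — which is analytically
constant per chromosome, Σ_i coverage_i/m — by a configurable factor.

Validation: carriers (individuals whose merged ROH cover ≥ 50% of the
island) versus non-carriers, Welch t-test on the pseudophenotype in the
*full* cohort — detection may use the tails, validation never does, which is
the cross-validation step that kills tail-selection artefacts.  Confirmed
when |t| ≥ 2 and both groups have ≥ 5 members.  Two-sided |t| is used
because a bare "t ≥ 2" rule is direction-ambiguous; the sign of the
carrier−non-carrier mean difference is always reported so directional
readings remain possible.  Published tables of this kind sometimes carry a
"T-value" column far below 2 alongside a t ≥ 2 rule; we implement the rule
and report the t-test p-value as well so either reading can be audited.

## Synthetic cohorts

The generator emulates the data *structure* of a large genotyped mare cohort
(≈862 individuals × ≈540 k SNPs on 31 autosomes) at desk scale — defaults:
300 individuals, 3 chromosomes × 2,000 markers at ~5 kb mean spacing
(uniform [0.5, 1.5]× spacing), MAF ~ U(0.05, 0.5), expected background
autozygosity 0.13 (matching typical closed-studbook cohort means), segment
lengths exponential with 2 Mb mean floored at 1 Mb (aligned to the caller's
minimum so recovery is well defined), genotyping error 0.002 (hom→het flips
only — the mode that disrupts ROH), missingness 0.02 (call rate ≈ 98%).

Genotypes are composed directly from the autozygosity process (homozygous
with allele by site frequency inside segments, Hardy–Weinberg outside)
rather than by pedigree gene-dropping: the analysis consumes genotypes only,
and direct composition yields exact truth labels.  A latent low-fertility
stratum (default 25% of the cohort) carries planted islands at elevated
penetrance (`penetrance_low_fert` vs `penetrance_other`) and can be given an
autozygosity multiplier; this stratum is what makes island enrichment in the
phenotypic tails possible before phenotypes exist.  Phenotypes are

    re_debv = intercept + β_FROH · true_autozygosity + Σ effect_k · carrier_k + N(0, σ²)

with defaults β = −30, σ = 3, intercept 5, island effect −5 — chosen so the
cohort-level rank correlation and tail separation are of realistic magnitude
for a moderately heritable fertility trait.

What the generator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra, pedigree structure and relatedness,
segment-length mixtures from different inbreeding ages, array intensity
artefacts, or EBV estimation/deregression noise.  Passing tests therefore
demonstrate that the pipeline's logic is correct and calibrated under its
own model assumptions — not that real-data effect sizes will match.

## Numerical and design choices

* Genotype codes are int8 with −1 for missing; the reference allele is the
  file's major allele, which cannot affect results because all downstream
  logic distinguishes only het / non-het / missing (tested).
* Coordinates are 1-based inclusive internally (MAP/VCF convention); BED
  conversion happens only at the I/O boundary.
* Call-rate filtering is strictly greater-than (CR > 0.95 keeps).
* Permutations are batched (2,000 per batch) to bound memory at
  O(batch × markers); per-chromosome masks that are empty or full are
  handled analytically (rotation-invariant).
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; map, cohort and phenotype draws use separate spawned streams so
  changing one stage's parameters does not scramble another's draws.
* Tail selection, island grouping and gene-list ordering all have
  deterministic tie-breaks (lexical id, map order, position).
* Degenerate inputs: chromosomes shorter than one window yield no windows;
  chromosomes with < 2 markers are excluded from the F_ROH denominator with
  a warning; zero-variance correlation inputs are flagged undefined rather
  than raising; islands with no carriers are reported unconfirmed with a
  reason.

## Test-scenario sizes

The simulation studies in the test suite use 300 individuals × 6,000 markers
with 2,000 permutations per marker and 20 replicates for recovery power, and
a 50 × 500 single-chromosome cohort for null calibration — sizes at which
every distributional check has adequate resolution while the whole suite
stays interactive.  The null-calibration fixture uses many short runs (~15
per individual, mean ~3 markers) so marker-level p-values are close to
independent and the binomial envelope is the correct reference; with long
runs, adjacent markers share p-values and the envelope would need an
effective-sample-size correction.

## Known limitations

* The sliding-window caller's boundaries are accurate to a few markers, not
  base pairs; F_ROH from called runs is accordingly biased slightly downward
  relative to truth when many segments sit near the length minimum.
* The permutation null conditions on each individual's observed run
  spectrum; it does not model cohort-level relatedness, so closely related
  cohorts can share islands for pedigree rather than selection reasons.
* Island carrier status is a hard threshold (≥ 50% coverage); dosage-style
  validation is not implemented.
* Gene annotation reproducibility depends entirely on the annotation release
  supplied by the user.
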