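# Methods

## The construct and its measurement

The object of study is a short core motif flanked by a perfect inverted
repeat: `L + core + revcomp(L)` with `|L| = k`. Such DNA can extrude a
hairpin whose loop contains the core, exposing cytosines to
single-strand-specific deaminases (APOBEC3 family). The scanner
measures, at every occurrence of the core or its reverse complement on
the forward strand, the *maximal* arm length: the largest `k` such that
the `k` bases left of the core equal the reverse complement of the `k`
bases to its right. "Maximal" is part of the definition — every
reported locus is checked by tests to be non-extendable.

Design choices made where the construct definition was genuinely open:

* **Arms exclude the core.** `TGAACA` is not self-complementary; the
  palindrome is the flanking pair, with the core in the loop. Arm
  length is therefore measured strictly outside the core.
* **Perfect arms only.** No bulges, mismatches, or thermodynamic
  scoring: the arm is an exact string property, which keeps the scan
  deterministic and lets a brute-force oracle verify it exactly.
  Folding-energy models are out of scope.
* **N policy.** An `N` anywhere in the core kills the match; an `N` in
  the flank stops arm extension. Unknown sequence is never declared
  palindromic.
* **Arm-length bounds.** Genome-wide defaults are `min_arm = 9`,
  `max_arm = 11` (both configurable); the variant-window discovery mode
  uses `min_arm = 8` ("longer than 7 bp") and no upper bound. Whether
  arms ≥ 12 should be excluded in genome-wide mode is not decidable
  from the published description; making both bounds explicit
  parameters is the honest reading.
* **Homopolymer filter.** A mononucleotide run satisfies the
  inverted-repeat definition trivially (`A^k` pairs with `T^k`) but is
  a replication-slippage substrate, not a hairpin arm; such loci are
  dropped. The filter always applies in variant-window mode and is an
  on-by-default flag in genome-wide mode.
* **Repeat filter.** Loci are filtered on the soft-masked (lowercase)
  fraction of their arm+core span, threshold 0 by default. This uses
  the masking already present in reference FASTA files instead of
  shipping repeat-annotation tracks.
* **Coordinates.** 0-based half-open internally and in BED output;
  1-based in user-facing tables. Overlapping core occurrences are each
  reported; only identical intervals (a self-complementary core
  matching in both orientations) are de-duplicated.

## Cohort model

The mutation matrix is binary per (sample, locus): every published
statistic for these loci treats a locus as mutated/wild-type, so allele
detail is carried in a side table only (used by context
classification). The two mutable positions of a 6-bp core are offsets
1 and 4 (the G and the C), 3 bp apart; a sample hit at both still
scores 1. Burden over the TGAACA loci defines signature groups
G1/G2/G3 = 0 / 1–2 / ≥3 mutated loci. Samples with a missing covariate
are excluded per test (pairwise deletion), matching how cohort tables
with per-parameter "data available for n patients" footnotes are built.

## Test inventory and selection

Two qualitative variables: plain Pearson χ², Yates-corrected χ²
(statistic `Σ (max(|O−E|−0.5, 0))² / E`, the floor preventing
overshoot), or two-sided Fisher exact. The Fisher two-sided p-value is
the sum of hypergeometric point probabilities not exceeding the
observed table's (point-probability method, not tail doubling); tests
verify it against exhaustive enumeration over all tables with the
observed margins. Which test runs is decided by the minimum expected
count: ≥ 5 plain, ≥ 3 Yates, otherwise Fisher. This rule is the unique
simple threshold rule consistent with every published pairwise
p-value we could verify (ten of ten cross-tables, significant and
non-significant alike); both thresholds are configurable. Quantitative
by qualitative: Kruskal–Wallis (3 groups, tie-corrected χ²
approximation) or Mann–Whitney (2 groups, two-sided, normal
approximation with continuity correction). Raw p-values are reported
at 4 decimals with significance at 0.05 two-sided; a Bonferroni column
is emitted in pairwise reports for reference but never used for calls.

Degenerate inputs: a zero row/column margin is untestable (Fisher
returns p = 1 flagged degenerate); a constant locus in the pairwise
scan is flagged untestable with p = NaN; all-tied rank data gives the
degenerate p = 1.

## Context classification

Substitutions are reported on the strand where the mutated base is a
pyrimidine; normalization is an involution and strand-invariant (both
properties tested). Classes: `TCA_optimal` (C-centered `TCA`),
`TCN_canonical` (other `TC·`), `other`. For a `TGAACA` core this
yields the characteristic split: offset-1 G>A normalizes to C>T at
`TCA` (optimal APOBEC substrate), offset-4 C>T sits in `ACA` (not TpC
at all). SBS2 membership is approximated by these context classes
rather than by COSMIC signature fitting — the claim being made is
qualitative, and signature deconvolution is out of scope. Contexts at
sequence edges are reported as `NNN` and excluded from summaries.

## Expression quantification

Replicate Ct values are arithmetically averaged per (sample, gene);
`N = 2^(Ct_ref − Ct_target)` assumes 100% amplification efficiency (no
standard-curve calibration, single reference gene). Values are then
divided by the median over the designated normal-tissue set, making
that median exactly 1 (midpoint convention for even cardinality; the
normal-set size is an input, not a constant). Undetermined wells are
missing, not zero; input values already floored to 0 are accepted.
Normalization is scale-equivariant and rank-preserving (tested).

## Synthetic-data generators

**Genomes.** Implants are exact `L + core + revcomp(L)` constructs at
non-overlapping positions in i.i.d. background (GC 0.41, the human
genome-wide value); the single base on each side of a construct is set
to the same letter, which can never pair with itself, so the planted
arm is exactly the measured arm. Decoy classes: bare cores (arm 0),
homopolymer-armed cores, and soft-masked (lowercase) implants, each
labelled in the truth table. What this does *not* emulate: real
base-composition heterogeneity, repeat families, or the density of
near-miss palindromes in a real genome — so recovery tests show the
scanner is exact, not that real-genome locus counts are reproduced
(that requires scanning an actual soft-masked reference, for which the
streaming scan-genome entry point exists).

**Cohorts.** Defaults are the study conditions: n = 103 samples and
the observed per-locus marginals (GPR126 0.456, PLEKHS1 0.291, Intron
ADM 0.117, Chr7:11 0.097, Chr15:96 0.078, GABRG3 0.068, CLVS2 0.01,
Chr3:82 0.01, RAD51B 0.049). Dependence is a single latent per-sample
factor `z = exp(σX)`, `X ~ N(0,1)`, multiplying every locus' baseline
odds: `P(mutated | z) = bz/(1+bz)`. One shared factor is the simplest
structure producing all-positive pairwise association, matching the
hypothesized common instability mechanism; an explicit copula would add
parameters the data cannot pin down. Calibration is deterministic
(Gauss–Hermite quadrature, 80 nodes): `σ` is root-found so the
Intron ADM × PLEKHS1 population odds ratio equals 10 — the value
implied by the published cross-table (70·9)/(21·3) — and each locus'
`b` is then root-found to preserve its marginal. The AGATCA-core
RAD51B locus is drawn conditionally on TGAACA-signature positivity
(marginal preserved), honoring the observed nesting; toggleable.
Covariates are drawn conditionally on the signature group with
per-group probabilities taken from the published cohort tables (e.g.
female fraction 0.077/0.130/0.444 in G1/G2/G3). Not emulated:
within-chromosome linkage, subclonal structure, measurement error in
mutation calling.

**Expression.** Log-normal expression with within-group SD of 1.0 on
the log2 scale — a typical combined biological-plus-technical
dispersion for qPCR on clinical tissue; published cohort ranges mix
between-group spread and extreme tails and therefore overstate the
within-group value. Tumors center at 10× normal (the observed order of
magnitude for *APOBEC3B*), with the high-burden group shifted by a
configurable fold (default 2). Ct pairs are constructed as
`Ct_target = Ct_ref − log2(expression)` so the quantification ladder
inverts the generator exactly when replicate noise is 0 (the default;
replicate SD is configurable).

## Problem sizes and numerics

Simulation-based checks use sizes chosen to put Monte-Carlo error well
below the effects being measured while keeping the default suite fast:
parameter recovery at n = 10⁴ samples (3-binomial-SE marginal check,
95% CI for the odds ratio); calibration at 2,000 replicates for
type-I-error rates (3 SE of 0.05 ≈ ±0.015) and p-value uniformity
(KS at α = 0.01, cohorts of n = 1,000 where the χ² approximation is
comfortably valid); power at 300 replicates with the study's group
sizes 39/46/18. The Yates type-I check runs at large expected counts
(n = 5,000 tables), where the continuity correction is asymptotically
negligible — at small counts Yates is intentionally conservative, which
is a property, not a defect. Scanner–oracle agreement covers 200
random sequences up to 5 kb including N's, plus implant recovery with
60 planted loci (arms 8–12) among decoys.

Root finding uses Brent's method on log-odds (bracket 10^±12) and on σ
in (10⁻⁶, 8); quadrature error at 80 Hermite nodes is far below the
calibration tolerance. Published p-values are compared at one unit in
the last printed digit: exact enumeration shows one published Fisher
value (printed 0.045, exact 0.0445) was itself rounded one ulp off, so
half-ulp equality is stricter than the printed values support.

## Known limitations

* Perfect-arm scanning cannot find bulged or mismatched hairpins.
* The soft-masking repeat filter inherits whatever masking the input
  FASTA carries; an unmasked reference disables it silently.
* The latent-factor cohort model produces exchangeable positive
  dependence only; it cannot represent negative or cluster-specific
  association.
* Survival analysis, signature deconvolution, variant calling, TMB and
  MSI assays are intentionally absent.
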