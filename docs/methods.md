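# Methods

## Problem setting

Most missense variants in cancer-predisposition genes such as *CHEK2* are
variants of uncertain significance (VUS). Two data sources can move them:
computational pathogenicity predictors, whose per-gene accuracy is unknown
a priori, and allele frequencies in an affected cohort versus reference
populations. This package implements both analyses as a reusable pipeline
and keeps the final reclassification step explicit and auditable.

## Predictor selection and meta-scores

**Ranking.** Every predictor column is direction-aligned (scores are negated
for predictors where *lower* means more deleterious, e.g. SIFT, FATHMM,
PROVEAN, LRT) and converted to normalised average ranks
rank / n_nonmissing in (0, 1], matching dbNSFP rankscore semantics. Columns
already supplied as rankscores pass through unchanged. Because all later
stages consume only ranks, any strictly increasing transform of a
predictor's raw scale leaves the output bit-identical; this is asserted in
the test suite.

**Group comparison.** For each predictor the non-missing ranks are split by
clinical group (Pathogenic, Benign, Unknown) and compared with the
tie-corrected Kruskal–Wallis test. A predictor is testable when every group
has at least `min_group_n = 2` non-missing values; the p-values of the
testable predictors are Bonferroni-corrected with the multiplier computed
from the data (number of testable predictors, at most the 44 analysed
columns), and predictors with adjusted p < `alpha_ssip = 0.05` become the
gene's SSIPs.

With group sizes as small as 7/5/514 the chi-square reference distribution
is the practical choice and is what the package uses at analysis scale.
At very small pooled sizes, however, the chi-square tail is a poor
approximation — we measured absolute deviations from the exhaustive
permutation p of up to 0.15 for patterns such as (2,2,2) — so
`kruskal_wallis` enumerates the exact permutation null whenever pooled
N ≤ 10 (`method="auto"`; the asymptotic and exact paths can be forced).
The enumeration treats ties correctly by permuting the pooled average
ranks.

**Meta-scores.** The combined score of a variant is the unweighted mean of
its non-missing normalised SSIP ranks; it is reported only when at least
`min_fraction = 0.5` of the SSIPs cover the variant (the coverage floor is
an implementation choice; per-variant predictor coverage is often
incomplete in dbNSFP extractions). A switch (`combine_all_predictors` /
`--all-predictors`) widens the average from the SSIP subset to every
analysed predictor. The weighted score averages *all tested* predictors
with weights w = max(0, 1 − adjusted p), normalises per variant by the
weights of the predictors actually present, and min–max rescales the
resulting vector to [0, 1] across the scored variant set. Min–max
rescaling (rather than relying on the rank convention alone) is the
default because it guarantees the documented [0, 1] endpoints for any
weighting; both conventions are rank-derived, so the caveat about monotone
invariance applies to each.

## Allele-frequency enrichment

Each variant contributes a 2×2 table — rows {cohort, reference}, columns
{altered alleles, total − altered}. Homozygote counts are carried through
for reporting but never enter the test, which operates on allele counts.
The two-sided Fisher p sums the hypergeometric point probabilities of all
tables with the observed margins that do not exceed the observed table's
probability; probabilities within a relative factor 1 + 1e-7 of the
observed one count as ties, the convention shared by mainstream
implementations. Point masses are evaluated with log-gamma and combined
with log-sum-exp, so totals of order 10⁶ are handled without underflow;
the test suite proves equality with exact-integer enumeration (relative
tolerance 1e-10) over all tables with margins ≤ 30 and cross-checks
against an independent implementation on population-scale tables. A
degenerate margin (empty row or column) carries no information and yields
p = 1 with a warning.

Rows with missing reference counts stay missing ("NA") and are excluded
from the Bonferroni family; the family size m is always computed from the
data rather than assumed, and is reported alongside every adjusted
p-value, so a discrepancy with an externally stated family size is visible
rather than silently absorbed. Significance requires raw p < 0.05 *and*
adjusted p < 0.1. The odds ratio (ad)/(bc) is reported when all cells are
positive, for information only. Bonferroni is used as a family-wise error
control; no false-discovery-rate procedure is applied.

## Evidence attribution and reclassification

Evidence tags are computed from the statistics plus passthrough
annotations:

| tag | condition | default threshold |
|---|---|---|
| PS4 | significant and cohort-enriched vs the designated reference | alpha_raw 0.05 / alpha_adj 0.1 |
| PP3_score | combined meta-score ≥ threshold | 0.75 |
| PP3_splice | supplied splice donor-loss probability ≥ threshold | 0.8 |
| BS_pop | reference AF ≥ threshold and no nominal enrichment | 0.002 |

When several references were tested, PS4 and BS_pop use the designated
population-matched reference (`ps4_reference`); a large mixed-population
database establishes rarity but not case-control enrichment within the
study population. "No nominal enrichment" means the variant is not both
raw-significant and cohort-enriched. The PP3_score cutoff of 0.75 and the
BS_pop allele-frequency cutoff of 0.2% (a conservative BS1-style frequency
for a moderate-penetrance gene) are implementation defaults, are recorded
in the output metadata, and are expected to be tuned per gene. The splice
threshold 0.8 treats high-confidence donor-loss predictions as supporting
evidence; splice prediction itself is out of scope and only precomputed
probabilities are consumed.

Reclassification is a rule table, not a full ACMG combining engine: each
rule maps an exact evidence-tag set (optionally restricted to prior
classes) to a proposed class and/or note. Exact-set matching keeps
application order-independent; conflicting rules are rejected at load
time, and a class-agnostic rule may never silently demote P/LP to a benign
class. The packaged defaults encode: PS4 (+PP3) upgrades a VUS to LP;
BS_pop downgrades a low-risk-LP to VUS/LB; PP3_score alone leaves a VUS
unchanged but flags it as meriting further investigation — supporting
evidence alone never reclassifies.

## Synthetic data generator

The generator emulates the statistical shape of the real inputs at study
scale: 7 pathogenic / 5 benign / 514 VUS variants, 17 informative + 27
noise predictors, a cohort of 3414 alleles and references of 1.6 × 10⁶
(gnomAD-like) and 7958 (population-database-like) alleles. Scores are Beta
distributed (predictor scores live in [0, 1]); informative predictors
separate Pathogenic and Benign means by `effect = 0.6` (0.8 and 0.2 at
concentration 30), noise predictors are identically distributed across
groups, every fifth predictor is emitted on a flipped scale with direction
−1, and cells are masked missing completely at random at rate 0.05.

The Unknown group is a 20/80 pathogenic-like/benign-like mixture whose
membership is shared across predictors (a deleterious VUS is deleterious
for every informative predictor at once). The mixture components sit at
*half* the confirmed groups' shift (`vus_attenuation = 0.5`). This is
deliberate: if the pathogenic-like VUS subpopulation were drawn from
exactly the Pathogenic distribution, ~100 such variants would interleave
with the 7 confirmed pathogenic variants in rank space and cap the
three-group Kruskal–Wallis statistic near H ≈ 14.5 regardless of effect
size, making full recovery of the informative predictors impossible at any
separation — whereas confirmed P/LP variants are, by construction of the
labels, the extreme cases. With the defaults, all 17 informative
predictors are recovered with zero noise selections across seeds, and
under `effect = 0` the selection rate stays within the nominal alpha.

Allele counts are binomial: reference alt ~ Bin(ref_total, AF), cohort alt
~ Bin(3414, AF · enrichment), with per-variant base AF log-uniform on
[1e-5, 1e-3] and configurable per-variant enrichment and missing-reference
rows. Homozygote counts are drawn independently as Bin(total/2, AF²) and
clipped to the sampled allele count. A single global seed feeds a
splittable generator per table, so requesting one table never perturbs
another.

What the generator does *not* emulate: linkage and haplotype structure,
population stratification within the cohort, correlated predictors
(real meta-predictors share training data, so 44 tests are far from
independent), informative missingness, and ClinVar label noise. Passing
tests on synthetic data therefore validate the statistical machinery, not
the biological calibration of any particular gene.

## Validation problem sizes

The suite verifies Fisher exactness by full enumeration over all 2×2
tables with margins ≤ 30, Kruskal–Wallis exactness against brute-force
permutation for all three-group patterns with pooled N ≤ 9 (group sizes
≥ 2), null calibration of predictor selection over 200 replicates at
7/5/80, type-I control of the enrichment test over 100 replicate tables,
and detection power at a rare strongly enriched variant (base AF 2e-4,
enrichment 25, reference 1.6 × 10⁶ alleles) over 200 seeds — a regime in
which detection succeeds in ≥ 90% of seeds. These sizes were chosen to
make the checks exhaustive where enumeration is feasible and tightly
concentrated where they are Monte Carlo.

## Known limitations

* The Kruskal–Wallis group sizes in real single-gene applications are tiny
  (here 7 and 5); the asymptotic p-values at analysis scale are
  approximations, and the Bonferroni correction over correlated predictors
  is conservative.
* The exact Fisher test is conservative for rare discrete counts, so the
  realised type-I error is below the nominal 0.05 — the calibration test
  asserts control, not equality.
* Evidence attribution encodes narrative curation decisions as explicit
  thresholds; the defaults reproduce sensible behaviour on the shipped
  cohort but are not a substitute for gene-specific calibration or a full
  Richards-style combining engine.
* ClinVar parsing handles the standard significance strings and a
  review-star filter (default ≥ 2 stars, with an
  include-regardless-of-stars source flag); free-text or conflicting
  submissions are skipped with a warning, not adjudicated.
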