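# ssipscore

Tools for reinterpreting germline missense variants in a single gene by
combining two independent lines of evidence:

1. **Gene-specific predictor benchmarking.** Dozens of in-silico
   pathogenicity predictors (ISPPs: CADD, REVEL, ClinPred, SIFT, ...) give
   conflicting calls, and their accuracy varies by gene. Given a
   dbNSFP-style score matrix and ClinVar-style clinical labels, the package
   ranks every predictor's scores across the variant set, tests each
   predictor for distributional differences between the Pathogenic (P/LP),
   Benign (B/LB) and Unknown (VUS) groups with a Kruskal–Wallis test, and
   keeps the *statistically significant in-silico predictors* (SSIPs) —
   those with Bonferroni-adjusted p < 0.05. Per-variant meta-scores follow:
   a **combined score** (mean of the variant's normalised SSIP ranks) and a
   **weighted score** (all tested predictors averaged with weights
   1 − adjusted p, min–max rescaled to [0, 1]).
2. **Population allele-frequency enrichment.** For each variant a 2×2
   Fisher's exact test compares altered/total allele counts in a study
   cohort against one or more reference populations (e.g. gnomAD or a
   population-matched database), with Bonferroni adjustment over the
   computable tests. Raw p < 0.05 together with adjusted p < 0.1 counts as
   significant.

The two statistics then drive ACMG/AMP-style evidence attribution — PS4 for
significant cohort enrichment, PP3 for computational or (supplied) splice
support, BS_pop for common non-enriched variants — and an explicit,
user-editable rule table proposes VUS reclassifications. The intended users
are clinical-genetics and variant-curation teams working on genes where
population-specific frequency data change interpretations.

## Model

For predictor $j$ with direction-aligned scores, variant $i$ receives the
normalised rank $r_{ij} = \mathrm{rank}(s_{ij}) / n_j \in (0,1]$ (average
ranks on ties, $n_j$ = non-missing count). The Kruskal–Wallis statistic
over groups $g = 1..k$,

$$H_j = \Big[\frac{12}{N(N+1)} \sum_g \frac{R_g^2}{n_g} - 3(N+1)\Big] \Big/ \Big(1 - \tfrac{\sum_t (t^3-t)}{N^3-N}\Big),$$

is referred to $\chi^2_{k-1}$ (an exact enumeration of group relabelings
replaces the asymptotic tail at very small pooled $N$). With SSIP set $S$
(adjusted $p_j < 0.05$), the meta-scores are

$$\text{combined}_i = \frac{1}{|S_i|}\sum_{j \in S_i} r_{ij}, \qquad
\text{weighted}_i = \mathrm{minmax}\Big(\frac{\sum_j w_j r_{ij}}{\sum_j w_j}\Big),\; w_j = \max(0, 1 - p_j^{\mathrm{adj}}).$$

Enrichment of variant $v$ uses the table rows {cohort, reference} and
columns {altered, total − altered}; the two-sided p sums hypergeometric
point masses not exceeding the observed one, evaluated through log-gamma so
reference totals in the millions are exact to machine precision.

## Worked example

The package ships the tables of a CHEK2 screen of 1707 individuals from
Türkiye (45 variants, 3414 cohort alleles) with allele counts from gnomAD
and the Turkish Variome, a splice donor-loss annotation, and prior ACMG
classes:

```python
import ssipscore as ss
from ssipscore import datasets

counts = datasets.load_cohort_allele_counts()
af = ss.compare_allele_frequencies(counts, "TurkishVariome")
print(af[af["significant"]][["variant", "raw_p", "adj_p", "m", "enriched_in_cohort"]])

bundles = ss.attribute_evidence(
    af,
    annotations=datasets.load_cohort_annotations(),
    prior_classes=datasets.load_prior_classes(),
    config=ss.EvidenceConfig(ps4_reference="TurkishVariome"))
report = ss.classify(bundles, datasets.default_rules())
print(report[report["proposed_class"] != report["prior_class"]])
```

prints

```
variant    raw_p   adj_p  m enriched_in_cohort
    V32 0.003653 0.08766 24               True

variant prior_class           tags proposed_class                  rule_id
     V2 low-risk-LP         BS_pop         VUS/LB bs_pop_lowrisk_downgrade
    V32         VUS PS4;PP3_splice             LP  ps4_pp3splice_vus_to_lp
```

Of the 24 variants testable against the Turkish Variome, only the splice
variant V32 (c.592+3A>T) is significantly enriched in the cohort
(raw p 0.0037 < 0.05, Bonferroni-adjusted 0.0877 < 0.1); PS4 plus the 0.90
donor-loss probability upgrade it from VUS to LP. The common "low-risk"
variant V2 (p.Ile157Thr) shows no enrichment despite a reference allele
frequency above 0.2%, so it is proposed for downgrade to VUS/LB.

The same stages are available from the shell:

```sh
ssipscore simulate --seed 1 --out sim/          # synthetic inputs
ssipscore af-test --counts sim/allele_counts.tsv --out sim/af/
ssipscore score --scores sim/scores.tsv --predictors sim/predictors.yaml \
    --labels sim/labels.tsv --out sim/meta_scores.tsv
ssipscore run --config run.yaml                 # full pipeline
```

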