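"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the shape of the real study inputs: three clinical
groups of configurable sizes (defaults 7 pathogenic / 5 benign / 514 VUS),
a subset of informative predictors whose Beta-distributed scores separate
the groups, identically distributed noise predictors, missing-completely-
at-random cells, and binomially sampled allele counts for a cohort of 3414
alleles against large reference populations, with per-variant enrichment
multipliers for designated risk variants.

Informative predictors draw Pathogenic scores from a Beta distribution
whose mean is shifted up by ``effect`` relative to Benign (means
0.5 +/- effect/2 at concentration ``concentration``).  Unknown-group
variants come from a pathogenic/benign mixture (default 20/80) whose
components are attenuated toward the centre (default half the confirmed
groups' shift): confirmed pathogenic variants are the extreme cases by
construction, and an unattenuated pathogenic-like VUS subpopulation would
interleave with the tiny Pathogenic group in rank space and bound the
Kruskal-Wallis statistic no matter how large the effect.

``effect = 0`` defines the null.  A single global seed feeds a splittable
generator per table, so generating one table never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables_io import AlleleCountTable, ClinGroupLabels, ScoreMatrix

_SCORES_STREAM, _COUNTS_STREAM = 0, 1


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study-scale defaults for the synthetic cohort.

    Group sizes, predictor counts, the cohort allele total and the
    reference totals mirror the full-scale analysis; ``effect`` is the
    mean-shift between Pathogenic and Benign score distributions on the
    [0, 1] scale.
    """

    n_pathogenic: int = 7
    n_benign: int = 5
    n_vus: int = 514
    n_informative: int = 17
    n_noise: int = 27
    effect: float = 0.6
    concentration: float = 30.0
    vus_pathogenic_fraction: float = 0.2
    vus_attenuation: float = 0.5
    missing_rate: float = 0.05
    neg_direction_every: int = 5  # every k-th predictor gets direction -1
    cohort_total: int = 3414
    ref_totals: dict[str, int] = field(
        default_factory=lambda: {"gnomAD": 1_600_000, "TurkishVariome": 7958})
    n_af_variants: int = 45
    af_range: tuple[float, float] = (1e-5, 1e-3)
    enrichment: dict[str, float] = field(default_factory=dict)
    missing_reference: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pathogenic", "n_benign", "n_vus", "n_informative", "n_noise",
                     "cohort_total", "n_af_variants"):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be non-negative")
        if self.effect < 0:
            raise SynthConfigError("effect must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise SynthConfigError("missing_rate must lie in [0, 1)")
        if self.effect >= 1.0:
            raise SynthConfigError(
                f"effect {self.effect} pushes group means outside (0, 1)")
        lo, hi = self.af_range
        if not (0 < lo <= hi < 1):
            raise SynthConfigError("af_range must satisfy 0 < low <= high < 1")

    def _rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(children[stream])


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    return mean * concentration, (1.0 - mean) * concentration


def generate_score_matrix(config: SynthConfig) -> tuple[ScoreMatrix, ClinGroupLabels]:
    """Draw a predictor-score matrix plus matching clinical group labels.

    Predictors are named ``infNN`` / ``noiseNN`` so ground truth is
    recoverable in tests; every ``neg_direction_every``-th predictor is
    emitted on a flipped scale (score = 1 - deleteriousness) with
    direction metadata -1, exercising direction alignment downstream.
    """
    rng = config._rng(_SCORES_STREAM)
    k = config.concentration
    mu_p, mu_b = 0.5 + config.effect / 2, 0.5 - config.effect / 2
    att = config.vus_attenuation
    mu_pu, mu_bu = 0.5 + config.effect * att / 2, 0.5 - config.effect * att / 2

    n_p, n_b, n_u = config.n_pathogenic, config.n_benign, config.n_vus
    labels = ([f"P{i+1:03d}" for i in range(n_p)]
              + [f"B{i+1:03d}" for i in range(n_b)]
              + [f"U{i+1:03d}" for i in range(n_u)])
    groups = ["Pathogenic"] * n_p + ["Benign"] * n_b + ["Unknown"] * n_u

    predictors = ([f"inf{i+1:02d}" for i in range(config.n_informative)]
                  + [f"noise{i+1:02d}" for i in range(config.n_noise)])
    direction = {
        p: -1 if config.neg_direction_every and (i + 1) % config.neg_direction_every == 0 else 1
        for i, p in enumerate(predictors)
    }

    # mixture membership of the Unknown group is shared across predictors:
    # a VUS is "pathogenic-like" for every informative predictor at once,
    # mimicking a truly deleterious but unclassified variant.
    vus_is_path = rng.random(n_u) < config.vus_pathogenic_fraction

    cols = {}
    for i, p in enumerate(predictors):
        informative = p.startswith("inf")
        mp, mb = (mu_p, mu_b) if informative else (0.5, 0.5)
        mpu, mbu = (mu_pu, mu_bu) if informative else (0.5, 0.5)
        path = rng.beta(*_beta_params(mp, k), n_p)
        ben = rng.beta(*_beta_params(mb, k), n_b)
        vus = np.where(vus_is_path,
                       rng.beta(*_beta_params(mpu, k), n_u),
                       rng.beta(*_beta_params(mbu, k), n_u))
        col = np.concatenate([path, ben, vus])
        if direction[p] == -1:
            col = 1.0 - col
        if config.missing_rate:
            col = np.where(rng.random(len(col)) < config.missing_rate, np.nan, col)
        cols[p] = col

    scores = pd.DataFrame(cols, index=pd.Index(labels, name="variant"))
    matrix = ScoreMatrix(scores=scores, direction=direction,
                         is_rankscore={p: False for p in predictors})
    prov = pd.DataFrame({"stars": 2, "flags": "", "retained_by": "stars"},
                        index=pd.Index(labels, name="variant"))
    clin = ClinGroupLabels(groups=pd.Series(groups, index=labels, name="group"),
                           provenance=prov)
    return matrix, clin


def generate_allele_counts(config: SynthConfig) -> AlleleCountTable:
    """Binomially sample cohort and reference allele counts.

    Per variant v with base allele frequency AF_v (log-uniform on
    ``af_range``): reference alt ~ Binomial(ref_total, AF_v) and cohort alt
    ~ Binomial(cohort_total, AF_v * enrichment_v).  Rows listed in
    ``missing_reference`` are emitted with explicit missing reference
    counts to exercise the NA paths downstream.
    """
    rng = config._rng(_COUNTS_STREAM)
    n = config.n_af_variants
    labels = [f"V{i+1}" for i in range(n)]
    lo, hi = config.af_range
    af = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    enrich = np.ones(n)
    for lab, mult in config.enrichment.items():
        if lab not in labels:
            raise SynthConfigError(f"enrichment names unknown variant {lab!r}")
        enrich[labels.index(lab)] = mult
    cohort_af = af * enrich
    if (cohort_af > 1).any():
        bad = [labels[i] for i in np.nonzero(cohort_af > 1)[0]]
        raise SynthConfigError(f"enrichment * AF exceeds 1 for {bad}")

    out = {"variant": labels,
           "cohort_alt": rng.binomial(config.cohort_total, cohort_af),
           "cohort_total": np.full(n, config.cohort_total),
           "cohort_hom": rng.binomial(config.cohort_total // 2, cohort_af**2)}
    for ref, total in config.ref_totals.items():
        alt = pd.array(rng.binomial(total, af), dtype="Int64")
        tot = pd.array(np.full(n, total), dtype="Int64")
        hom = pd.array(rng.binomial(total // 2, af**2), dtype="Int64")
        for lab in config.missing_reference.get(ref, []):
            i = labels.index(lab)
            alt[i] = pd.NA
            tot[i] = pd.NA
            hom[i] = pd.NA
        out[f"{ref}_alt"], out[f"{ref}_total"], out[f"{ref}_hom"] = alt, tot, hom

    df = pd.DataFrame(out)
    for c in ("cohort_alt", "cohort_total", "cohort_hom"):
        df[c] = pd.array(df[c], dtype="Int64")
    # homozygote draws are independent of the allele draws; clip the rare
    # case where 2*hom would exceed the sampled allele count
    df["cohort_hom"] = np.minimum(df["cohort_hom"], df["cohort_alt"] // 2)
    for ref in config.ref_totals:
        both = df[f"{ref}_hom"].notna()
        df.loc[both, f"{ref}_hom"] = np.minimum(
            df.loc[both, f"{ref}_hom"], df.loc[both, f"{ref}_alt"] // 2)
    return AlleleCountTable(df=df, references=list(config.ref_totals))


def write_synthetic_inputs(config: SynthConfig, outdir) -> dict[str, str]:
    """Emit score-matrix, label and allele-count TSVs readable by tables_io."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, labels = generate_score_matrix(config)
    counts = generate_allele_counts(config)

    scores_path = outdir / "scores.tsv"
    sm = matrix.scores.reset_index()
    sm.to_csv(scores_path, sep="\t", index=False, na_rep=".")

    labels_path = outdir / "labels.tsv"
    lab = pd.DataFrame({
        "variant": labels.groups.index,
        "significance": labels.groups.map({
            "Pathogenic": "Pathogenic", "Benign": "Benign",
            "Unknown": "Uncertain significance"}),
        "review_stars": 2,
        "source_flags": "",
    })
    lab.to_csv(labels_path, sep="\t", index=False)

    counts_path = outdir / "allele_counts.tsv"
    counts.df.to_csv(counts_path, sep="\t", index=False, na_rep="NA")

    meta_path = outdir / "predictors.yaml"
    import yaml

    with open(meta_path, "w") as fh:
        yaml.safe_dump(
            {"predictors": {p: {"direction": d} for p, d in matrix.direction.items()}},
            fh, sort_keys=True)
    return {"scores": str(scores_path), "labels": str(labels_path),
            "allele_counts": str(counts_path), "predictors": str(meta_path)}
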