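"""Packaged study-cohort tables and default configuration files.

The shipped data describe 45 germline CHEK2 variants observed in a Turkish
hereditary-cancer cohort (1707 individuals; 3414 alleles): variant
identities with prior ACMG classes, per-variant allele counts against two
reference populations (gnomAD and the Turkish Variome), and passthrough
annotations (a splice donor-loss probability and protein-stability
predictions for selected variants).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .evidence import Rule, load_rules
from .tables_io import AlleleCountTable, PredictorConfig, read_allele_counts

#: cohort size facts used for the headline positivity rate
COHORT_N_INDIVIDUALS = 1707
COHORT_N_POSITIVE = 131


def _data_path(name: str) -> Path:
    return Path(resources.files("ssipscore").joinpath("data", name))


def load_cohort_variants() -> pd.DataFrame:
    """Variant identities and prior ACMG classes for the 45 cohort variants."""
    df = pd.read_csv(_data_path("chek2_cohort_variants.tsv"), sep="\t",
                     dtype=str, keep_default_na=False)
    df["pos"] = df["pos"].astype(int)
    return df


def load_cohort_allele_counts() -> AlleleCountTable:
    """Cohort vs gnomAD / Turkish Variome allele counts for the 45 variants."""
    return read_allele_counts(_data_path("chek2_allele_counts.tsv"))


def load_cohort_annotations() -> pd.DataFrame:
    """Passthrough annotations: splice donor-loss probability, ddG stability."""
    return pd.read_csv(_data_path("chek2_annotations.tsv"), sep="\t",
                       na_values=["NA"])


def load_prior_classes() -> pd.Series:
    """variant label -> prior ACMG class, from the cohort variant table."""
    df = load_cohort_variants()
    return pd.Series(df["acmg_class"].to_numpy(), index=df["variant"])


def default_predictor_config() -> PredictorConfig:
    """Direction metadata for the 44 analysed dbNSFP-style predictors."""
    return PredictorConfig.from_yaml(_data_path("predictors_dbnsfp44.yaml"))


def default_rules() -> list[Rule]:
    """The packaged reclassification rule table."""
    return load_rules(_data_path("default_rules.yaml"))


def default_rules_path() -> Path:
    return _data_path("default_rules.yaml")


def cohort_summary() -> dict:
    return {"n_individuals": COHORT_N_INDIVIDUALS,
            "n_positive": COHORT_N_POSITIVE,
            "n_variants": 45}
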