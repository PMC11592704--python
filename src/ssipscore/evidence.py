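"""ACMG-style evidence attribution and rule-based reclassification.

Statistical outputs become evidence tags:

* ``PS4``   — significant allele-frequency enrichment in the cohort versus
  the designated (population-matched) reference,
* ``PP3_score``  — combined rank meta-score at or above a threshold,
* ``PP3_splice`` — supplied splice donor-loss probability at or above a
  threshold (the splice prediction itself is consumed, never computed),
* ``BS_pop`` — reference allele frequency at or above a benign threshold
  with no nominal cohort enrichment.

Tags are then mapped to proposed class transitions by an explicit,
user-editable rule table; the engine never combines evidence implicitly,
so every proposed reclassification names the rule that fired.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

CLASSES = ("B", "LB", "VUS", "LP", "P", "low-risk-LP", "VUS/LB")

_CLASS_ALIASES = {
    "b": "B", "benign": "B", "lb": "LB", "likely benign": "LB",
    "vus": "VUS", "uncertain significance": "VUS",
    "lp": "LP", "likely pathogenic": "LP", "p": "P", "pathogenic": "P",
    "low risk-lp": "low-risk-LP", "low-risk-lp": "low-risk-LP",
    "low risk lp": "low-risk-LP", "vus/lb": "VUS/LB",
}

BENIGN_CLASSES = {"B", "LB", "VUS/LB"}
PATHOGENIC_CLASSES = {"P", "LP"}


class RulesConfigError(ValueError):
    """Conflicting or malformed reclassification rules."""


def normalize_class(label: str) -> str:
    key = str(label).strip().lower()
    if key not in _CLASS_ALIASES:
        raise ValueError(f"unknown classification label {label!r}")
    return _CLASS_ALIASES[key]


@dataclass
class EvidenceConfig:
    """Thresholds driving evidence attribution.

    score_threshold : combined meta-score cutoff for PP3_score (0-1 scale).
    splice_threshold : donor-loss probability cutoff for PP3_splice.
    af_benign_threshold : reference allele frequency at or above which a
        non-enriched variant receives BS_pop.
    ps4_reference : reference population whose enrichment test drives PS4
        and BS_pop; may stay None when only one reference was tested.
    alpha_raw : nominal raw-p threshold used for the "no enrichment" side
        of BS_pop.
    """

    score_threshold: float = 0.75
    splice_threshold: float = 0.8
    af_benign_threshold: float = 0.002
    ps4_reference: str | None = None
    alpha_raw: float = 0.05


@dataclass
class Rule:
    id: str
    tags: frozenset[str]
    from_classes: frozenset[str] | None  # None = any prior class
    to_class: str | None  # None = no class change
    note: str = ""


def load_rules(path: str | Path) -> list[Rule]:
    """Load a reclassification rule table from YAML.

    Each rule maps an exact evidence-tag set (and optionally a set of prior
    classes) to a proposed class and/or note.  Two rules with the same tag
    set and overlapping prior classes but different outcomes are rejected
    at load time.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = []
    for i, r in enumerate(raw.get("rules", [])):
        frm = r.get("from")
        rules.append(Rule(
            id=str(r.get("id", f"rule{i}")),
            tags=frozenset(r["tags"]),
            from_classes=None if frm in (None, "any") else frozenset(normalize_class(c) for c in frm),
            to_class=None if r.get("to") is None else normalize_class(r["to"]),
            note=str(r.get("note", "")),
        ))
    validate_rules(rules)
    return rules


def validate_rules(rules: Sequence[Rule]) -> None:
    for i, a in enumerate(rules):
        for b in rules[i + 1:]:
            if a.tags != b.tags:
                continue
            overlap = (a.from_classes is None or b.from_classes is None
                       or a.from_classes & b.from_classes)
            if overlap and (a.to_class != b.to_class or a.note != b.note):
                raise RulesConfigError(
                    f"rules {a.id!r} and {b.id!r} conflict on tag set {sorted(a.tags)}")


def attribute_evidence(af_results: pd.DataFrame,
                       meta_scores: pd.DataFrame | None = None,
                       annotations: pd.DataFrame | None = None,
                       prior_classes: Mapping[str, str] | pd.Series | None = None,
                       config: EvidenceConfig | None = None) -> pd.DataFrame:
    """Attach evidence tags to every variant appearing in the inputs.

    ``af_results`` may stack several reference comparisons; the PS4 / BS_pop
    decisions use the configured ``ps4_reference`` (mandatory when more than
    one reference is present).  Variants missing from an input get empty
    tags for that evidence type plus a coverage warning.

    Returns one row per variant with boolean tag columns (PS4, PP3_score,
    PP3_splice, BS_pop), a ``tags`` summary string, and the supporting
    values (raw/adjusted p, meta-score, splice probability, reference AF).
    """
    config = config or EvidenceConfig()
    refs = sorted(af_results["reference"].unique())
    ps4_ref = config.ps4_reference
    if ps4_ref is None:
        if len(refs) > 1:
            raise ValueError(
                f"several references tested ({refs}); set EvidenceConfig.ps4_reference")
        ps4_ref = refs[0]
    elif ps4_ref not in refs:
        raise ValueError(f"ps4_reference {ps4_ref!r} not among tested references {refs}")

    af = af_results[af_results["reference"] == ps4_ref].set_index("variant")

    variants = list(dict.fromkeys(
        list(af.index)
        + (list(meta_scores["variant"]) if meta_scores is not None else [])
        + (list(annotations["variant"]) if annotations is not None else [])
    ))
    scores = meta_scores.set_index("variant") if meta_scores is not None else None
    annot = annotations.set_index("variant") if annotations is not None else None

    rows = []
    for v in variants:
        rec = {"variant": v, "PS4": False, "PP3_score": False,
               "PP3_splice": False, "BS_pop": False,
               "raw_p": np.nan, "adj_p": np.nan, "combined": np.nan,
               "splice_donor_loss": np.nan, "ref_af": np.nan}
        covered = False
        if v in af.index:
            r = af.loc[v]
            covered = True
            rec["raw_p"], rec["adj_p"] = r["raw_p"], r["adj_p"]
            enriched = bool(r["enriched_in_cohort"]) if pd.notna(r["enriched_in_cohort"]) else False
            significant = bool(r["significant"])
            if pd.notna(r["ref_total"]) and r["ref_total"]:
                rec["ref_af"] = float(r["ref_alt"]) / float(r["ref_total"])
            rec["PS4"] = significant and enriched
            nominal_enrichment = (pd.notna(r["raw_p"]) and r["raw_p"] < config.alpha_raw
                                  and enriched)
            rec["BS_pop"] = (pd.notna(rec["ref_af"])
                             and rec["ref_af"] >= config.af_benign_threshold
                             and not nominal_enrichment)
        if scores is not None and v in scores.index:
            rec["combined"] = scores.loc[v, "combined"]
            if pd.notna(rec["combined"]):
                covered = True
                rec["PP3_score"] = rec["combined"] >= config.score_threshold
        if annot is not None and v in annot.index and "splice_donor_loss" in annot.columns:
            sp = annot.loc[v, "splice_donor_loss"]
            if pd.notna(sp):
                covered = True
                rec["splice_donor_loss"] = float(sp)
                rec["PP3_splice"] = float(sp) >= config.splice_threshold
        if not covered:
            warnings.warn(f"variant {v!r} has no usable evidence inputs", stacklevel=2)

        if prior_classes is not None and v in prior_classes:
            rec["prior_class"] = normalize_class(prior_classes[v])
        else:
            rec["prior_class"] = "VUS"
        rec["tags"] = ";".join(t for t in ("PS4", "PP3_score", "PP3_splice", "BS_pop") if rec[t])
        rows.append(rec)
    return pd.DataFrame(rows)


def classify(bundles: pd.DataFrame, rules: Sequence[Rule]) -> pd.DataFrame:
    """Apply the rule table to evidence bundles.

    A rule fires when its tag set equals the bundle's tag set exactly and
    the prior class is among the rule's ``from`` classes (or the rule is
    class-agnostic).  With no matching rule the class is unchanged.  A rule
    silently demoting P/LP to a benign class without listing those classes
    explicitly is refused.

    Returns the reclassification report: variant, prior_class, tags,
    proposed_class, rule_id, note.
    """
    validate_rules(list(rules))
    rows = []
    for _, b in bundles.iterrows():
        tagset = frozenset(t for t in b["tags"].split(";") if t)
        prior = b["prior_class"]
        fired = None
        for rule in rules:
            if rule.tags != tagset:
                continue
            if rule.from_classes is not None and prior not in rule.from_classes:
                continue
            if (rule.from_classes is None and prior in PATHOGENIC_CLASSES
                    and rule.to_class in BENIGN_CLASSES):
                raise RulesConfigError(
                    f"rule {rule.id!r} would demote {prior} to {rule.to_class} "
                    "without naming pathogenic prior classes explicitly")
            fired = rule
            break
        rows.append({
            "variant": b["variant"],
            "prior_class": prior,
            "tags": b["tags"],
            "proposed_class": (fired.to_class if fired and fired.to_class else prior),
            "rule_id": fired.id if fired else "",
            "note": fired.note if fired else "",
        })
    return pd.DataFrame(rows)
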