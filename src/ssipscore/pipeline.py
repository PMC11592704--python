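"""End-to-end run orchestration: config, logging, result tables, summary.

``run_pipeline`` wires the stages together — allele-frequency enrichment per
reference population, predictor selection + meta-scoring, evidence
attribution and rule-based reclassification — and writes every result table
plus a JSON run summary and a manifest into the output directory.  All
randomness lives in the synthetic-data generator; a pipeline run on fixed
inputs is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import af_compare, evidence, ssip_core, tables_io

log = logging.getLogger(__name__)


def positivity_rate(n_positive: int, n_individuals: int) -> tuple[float, int]:
    """Fraction of individuals carrying a reportable variant, and the
    percentage rounded to the nearest integer."""
    if n_individuals <= 0 or n_positive < 0 or n_positive > n_individuals:
        raise ValueError(f"invalid counts {n_positive}/{n_individuals}")
    frac = n_positive / n_individuals
    return frac, round(frac * 100)


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults: raw Fisher p 0.05, Bonferroni-adjusted 0.1, SSIP
    selection alpha 0.05, splice donor-loss 0.8, meta-score 0.75, minimum
    predictor coverage per variant 0.5.
    """

    scores: str | None = None
    predictors: str | None = None
    labels: str | None = None
    allele_counts: str | None = None
    annotations: str | None = None
    variants: str | None = None  # optional table carrying prior ACMG classes
    rules: str | None = None
    outdir: str = "ssipscore_run"
    alpha_raw: float = 0.05
    alpha_adj: float = 0.1
    alpha_ssip: float = 0.05
    splice_threshold: float = 0.8
    score_threshold: float = 0.75
    af_benign_threshold: float = 0.002
    min_fraction: float = 0.5
    min_group_n: int = 2
    combine_all_predictors: bool = False
    ps4_reference: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> dict:
        return {k: getattr(self, k) for k in (
            "alpha_raw", "alpha_adj", "alpha_ssip", "splice_threshold",
            "score_threshold", "af_benign_threshold", "min_fraction",
            "min_group_n")}


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("ssipscore")
    for h in [h for h in root.handlers if isinstance(h, logging.FileHandler)]:
        root.removeHandler(h)
        h.close()
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write results under ``outdir``.

    Stages with missing inputs are skipped and noted in the summary; any
    hard error in a stage aborts with a stage-tagged message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    summary: dict = {"thresholds": config.thresholds(), "seed": config.seed, "stages": {}}
    manifest: list[str] = []
    t0 = time.time()

    def _stage(name):
        log.info("stage %s starting", name)
        return time.time()

    def _done(name, t):
        dt = time.time() - t
        summary["stages"][name] = round(dt, 3)
        log.info("stage %s finished in %.2fs", name, dt)

    def _write(df: pd.DataFrame, name: str) -> None:
        tables_io.write_results(df, outdir / name)
        manifest.append(name)

    af_frames = []
    if config.allele_counts:
        t = _stage("af_compare")
        try:
            counts = tables_io.read_allele_counts(config.allele_counts)
            for ref in counts.references:
                res = af_compare.compare_allele_frequencies(
                    counts, ref, alpha_raw=config.alpha_raw, alpha_adj=config.alpha_adj)
                af_frames.append(res)
                _write(res, f"af_results_{ref}.tsv")
                summary.setdefault("af_families", {})[ref] = {
                    "m": int(res["m"].iloc[0]),
                    "n_significant": int(res["significant"].sum()),
                }
        except Exception as exc:
            raise RuntimeError(f"[af_compare] {exc}") from exc
        _done("af_compare", t)

    ssip_result = None
    if config.scores and config.predictors and config.labels:
        t = _stage("ssip_core")
        try:
            pred_cfg = tables_io.PredictorConfig.from_yaml(config.predictors)
            matrix = tables_io.read_score_matrix(config.scores, pred_cfg)
            clin = tables_io.read_clin_labels(config.labels)
            ssip_result = ssip_core.score_all_variants(
                matrix, clin,
                alpha_ssip=config.alpha_ssip,
                min_group_n=config.min_group_n,
                min_fraction=config.min_fraction,
                combine_all_predictors=config.combine_all_predictors)
            _write(ssip_result.tests, "predictor_tests.tsv")
            _write(ssip_result.scores, "meta_scores.tsv")
            summary["ssip"] = ssip_result.summary
        except Exception as exc:
            raise RuntimeError(f"[ssip_core] {exc}") from exc
        _done("ssip_core", t)

    if af_frames:
        t = _stage("evidence")
        try:
            annotations = None
            if config.annotations:
                annotations = pd.read_csv(config.annotations, sep="\t", na_values=["NA"])
            prior = None
            if config.variants:
                vt = pd.read_csv(config.variants, sep="\t", dtype=str, keep_default_na=False)
                if "acmg_class" in vt.columns:
                    prior = pd.Series(vt["acmg_class"].to_numpy(), index=vt["variant"])
            ev_cfg = evidence.EvidenceConfig(
                score_threshold=config.score_threshold,
                splice_threshold=config.splice_threshold,
                af_benign_threshold=config.af_benign_threshold,
                ps4_reference=config.ps4_reference,
                alpha_raw=config.alpha_raw)
            bundles = evidence.attribute_evidence(
                pd.concat(af_frames, ignore_index=True),
                meta_scores=ssip_result.scores if ssip_result else None,
                annotations=annotations,
                prior_classes=prior,
                config=ev_cfg)
            if config.rules:
                rules = evidence.load_rules(config.rules)
            else:
                from .datasets import default_rules
                rules = default_rules()
            report = evidence.classify(bundles, rules)
            _write(bundles, "evidence_bundles.tsv")
            _write(report, "reclassification_report.tsv")
            summary["evidence"] = {
                "n_ps4": int(bundles["PS4"].sum()),
                "ps4_variants": bundles.loc[bundles["PS4"], "variant"].tolist(),
                "n_reclassified": int((report["proposed_class"] != report["prior_class"]).sum()),
            }
        except Exception as exc:
            raise RuntimeError(f"[evidence] {exc}") from exc
        _done("evidence", t)

    summary["runtime_s"] = round(time.time() - t0, 3)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    manifest.append("summary.json")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"files": manifest}, fh, indent=2)
    return summary
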