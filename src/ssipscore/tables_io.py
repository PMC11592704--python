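"""Readers, writers and validated containers for the pipeline's tabular data.

All inputs are plain tab-separated text: a dbNSFP-style predictor-score
matrix (``.`` or empty cell = missing, semicolon-separated multi-transcript
values), a ClinVar-style clinical-significance table, and allele-count
tables whose columns pair a study cohort against one or more reference
populations.  Coordinates are 1-based and fully closed.  Thousands
separators ("," ) are accepted on input and never emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

#: clinical-significance strings -> analysis group
SIGNIFICANCE_GROUPS = {
    "pathogenic": "Pathogenic",
    "likely pathogenic": "Pathogenic",
    "pathogenic/likely pathogenic": "Pathogenic",
    "benign": "Benign",
    "likely benign": "Benign",
    "benign/likely benign": "Benign",
    "uncertain significance": "Unknown",
}

GROUPS = ("Pathogenic", "Benign", "Unknown")

#: columns of a score-matrix file that carry variant identity, not scores
KEY_COLUMNS = ("variant", "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p", "dbsnp")


class TableFormatError(ValueError):
    """Malformed input table (bad header, cell, or inconsistent counts)."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant; ``label`` is the unique serial key (V1...)."""

    label: str
    chrom: str | None = None
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    dbsnp_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos is not None and self.pos < 1:
            raise TableFormatError(f"{self.label}: position must be >= 1, got {self.pos}")
        if self.ref is not None and self.alt is not None and self.ref == self.alt:
            raise TableFormatError(f"{self.label}: ref and alt alleles are identical ({self.ref})")


@dataclass
class PredictorConfig:
    """Direction / rankscore metadata for every recognised predictor.

    ``direction[p]`` is +1 when a higher score is more deleterious, -1 when a
    lower score is (SIFT-style).  ``exclude`` names columns that are dropped
    with a notice when encountered (predictors known but deliberately out of
    the analysis).
    """

    direction: dict[str, int]
    is_rankscore: dict[str, bool] = field(default_factory=dict)
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, d in self.direction.items():
            if d not in (1, -1):
                raise TableFormatError(f"predictor {name!r}: direction must be +1 or -1, got {d}")
        self.is_rankscore = {p: bool(self.is_rankscore.get(p, False)) for p in self.direction}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PredictorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        preds = raw.get("predictors", {})
        direction = {name: int(meta.get("direction", 1)) for name, meta in preds.items()}
        is_rankscore = {name: bool(meta.get("rankscore", False)) for name, meta in preds.items()}
        return cls(direction=direction, is_rankscore=is_rankscore,
                   exclude=tuple(raw.get("exclude", [])))


@dataclass
class ScoreMatrix:
    """Variants x predictors grid of optional real scores plus metadata.

    ``scores`` is indexed by variant label; missing values are NaN.
    """

    scores: pd.DataFrame
    direction: dict[str, int]
    is_rankscore: dict[str, bool]
    variants: list[VariantKey] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].tolist()
            raise TableFormatError(f"duplicate variant labels: {dups}")
        missing_meta = [c for c in self.scores.columns if c not in self.direction]
        if missing_meta:
            raise TableFormatError(f"predictors without direction metadata: {missing_meta}")
        for p, d in self.direction.items():
            if d not in (1, -1):
                raise TableFormatError(f"predictor {p!r}: direction must be +1 or -1")
        for p in self.scores.columns:
            if self.is_rankscore.get(p, False):
                col = self.scores[p].dropna()
                if len(col) and ((col < 0).any() or (col > 1).any()):
                    raise TableFormatError(f"rankscore predictor {p!r} has values outside [0, 1]")

    @property
    def predictors(self) -> list[str]:
        return list(self.scores.columns)


@dataclass
class ClinGroupLabels:
    """Pathogenic / Benign / Unknown assignment per variant with provenance."""

    groups: pd.Series  # variant label -> group
    provenance: pd.DataFrame  # columns: stars, flags, retained_by
    n_skipped: int = 0

    def __post_init__(self) -> None:
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise TableFormatError(f"unknown clinical groups: {sorted(bad)}")

    def orphans(self, matrix: ScoreMatrix) -> list[str]:
        """Labelled variants absent from the score matrix."""
        return [v for v in self.groups.index if v not in matrix.scores.index]


@dataclass
class AlleleCountTable:
    """Per-variant allele counts for a study cohort and >=1 reference population.

    ``df`` columns: ``variant``, ``cohort_alt``, ``cohort_total``,
    ``cohort_hom`` and, per reference R, ``{R}_alt``, ``{R}_total``,
    ``{R}_hom`` (nullable integers; missing reference entries are explicit
    NA, never zero).
    """

    df: pd.DataFrame
    references: list[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        for col in ("variant", "cohort_alt", "cohort_total"):
            if col not in df.columns:
                raise TableFormatError(f"allele-count table lacks required column {col!r}")
        if df["variant"].duplicated().any():
            raise TableFormatError("duplicate variant labels in allele-count table")
        groups = [("cohort_alt", "cohort_total", "cohort_hom")]
        groups += [(f"{r}_alt", f"{r}_total", f"{r}_hom") for r in self.references]
        for alt_c, tot_c, hom_c in groups:
            alt, tot = df[alt_c], df[tot_c]
            for name, col in ((alt_c, alt), (tot_c, tot)):
                if (col.dropna() < 0).any():
                    raise TableFormatError(f"negative count in column {name!r}")
            both = alt.notna() & tot.notna()
            if (alt[both] > tot[both]).any():
                rows = df.loc[both & (alt > tot), "variant"].tolist()
                raise TableFormatError(f"altered allele count exceeds total in {alt_c}: {rows}")
            if hom_c in df.columns:
                hom = df[hom_c]
                ok = hom.notna() & alt.notna()
                if (2 * hom[ok] > alt[ok]).any():
                    rows = df.loc[ok & (2 * hom > alt), "variant"].tolist()
                    raise TableFormatError(f"2 x homozygote count exceeds allele count in {hom_c}: {rows}")


def _collapse_cell(cell: str, direction: int, row: str, col: str) -> float:
    """Collapse a possibly multi-valued (semicolon) cell to one float.

    Multi-transcript values collapse to the most deleterious after
    direction alignment: max for direction +1, min for -1.
    """
    parts = [p for p in cell.split(";") if p not in (".", "", "NA")]
    if not parts:
        return np.nan
    try:
        vals = [float(p) for p in parts]
    except ValueError:
        raise TableFormatError(f"non-numeric score cell {cell!r} at row {row!r}, column {col!r}") from None
    return max(vals) if direction == 1 else min(vals)


def read_score_matrix(path: str | Path,
                      predictor_config: PredictorConfig,
                      on_unknown: str = "error") -> ScoreMatrix:
    """Read a dbNSFP-style TSV of predictor scores.

    The header names predictors; ``.``/empty cells are missing; semicolon
    lists collapse to the most deleterious value per the predictor's
    direction.  Columns on the config's ``exclude`` list are dropped with a
    logged notice; columns unknown to the config are a hard error unless
    ``on_unknown="drop"``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant" not in raw.columns:
        raise TableFormatError(f"{path}: score matrix header lacks a 'variant' column")
    if raw.columns.duplicated().any():
        raise TableFormatError(f"{path}: duplicate column names in header")

    score_cols: list[str] = []
    for col in raw.columns:
        if col in KEY_COLUMNS:
            continue
        if col in predictor_config.exclude:
            log.info("dropping excluded predictor column %r from %s", col, path)
            continue
        if col not in predictor_config.direction:
            if on_unknown == "drop":
                log.warning("dropping unknown predictor column %r from %s", col, path)
                continue
            raise TableFormatError(f"{path}: unknown predictor column {col!r}")
        score_cols.append(col)

    labels = raw["variant"].tolist()
    data = {}
    for col in score_cols:
        d = predictor_config.direction[col]
        data[col] = [
            _collapse_cell(cell, d, label, col)
            for cell, label in zip(raw[col], labels)
        ]
    scores = pd.DataFrame(data, index=pd.Index(labels, name="variant"), dtype=float)

    variants = None
    if {"chrom", "pos"} <= set(raw.columns):
        variants = [
            VariantKey(
                label=r["variant"],
                chrom=r.get("chrom") or None,
                pos=int(r["pos"]) if r.get("pos") else None,
                ref=r.get("ref") or None,
                alt=r.get("alt") or None,
                hgvs_c=r.get("hgvs_c") or None,
                hgvs_p=r.get("hgvs_p") or None,
                dbsnp_id=r.get("dbsnp") or None,
            )
            for _, r in raw.iterrows()
        ]

    return ScoreMatrix(
        scores=scores,
        direction={c: predictor_config.direction[c] for c in score_cols},
        is_rankscore={c: predictor_config.is_rankscore.get(c, False) for c in score_cols},
        variants=variants,
    )


def read_clin_labels(path: str | Path,
                     min_stars: int = 2,
                     include_regardless: Iterable[str] = ("SimpleClinVar",)) -> ClinGroupLabels:
    """Read a ClinVar-style significance table and assign analysis groups.

    Rows failing the review-star filter are dropped unless they carry one of
    the ``include_regardless`` source flags; unmappable significance strings
    are skipped with a warning and counted in ``n_skipped``.
    """
    include_regardless = set(include_regardless)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("variant", "significance", "review_stars"):
        if col not in raw.columns:
            raise TableFormatError(f"{path}: clinical-label table lacks column {col!r}")

    groups, prov_rows, n_skipped = {}, [], 0
    for _, r in raw.iterrows():
        label = r["variant"]
        sig = r["significance"].strip().lower()
        group = SIGNIFICANCE_GROUPS.get(sig)
        if group is None:
            log.warning("unmappable significance %r for %s; row skipped", r["significance"], label)
            n_skipped += 1
            continue
        stars = int(r["review_stars"])
        flags = {f for f in r.get("source_flags", "").split(";") if f}
        by_flag = bool(flags & include_regardless)
        if stars < min_stars and not by_flag:
            continue
        groups[label] = group
        prov_rows.append({"variant": label, "stars": stars,
                          "flags": ";".join(sorted(flags)),
                          "retained_by": "flag" if (by_flag and stars < min_stars) else "stars"})

    provenance = pd.DataFrame(prov_rows, columns=["variant", "stars", "flags", "retained_by"])
    if len(provenance):
        provenance = provenance.set_index("variant")
    return ClinGroupLabels(groups=pd.Series(groups, dtype=object, name="group"),
                           provenance=provenance, n_skipped=n_skipped)


def _parse_count(cell: str, row: str, col: str):
    cell = cell.strip().replace(",", "")
    if cell in ("", "NA", "."):
        return pd.NA
    try:
        v = int(cell)
    except ValueError:
        raise TableFormatError(f"non-integer count {cell!r} at row {row!r}, column {col!r}") from None
    if v < 0:
        raise TableFormatError(f"negative count {v} at row {row!r}, column {col!r}")
    return v


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    """Read a cohort-vs-references allele-count TSV.

    Reference populations are detected from ``{name}_total`` columns;
    thousands separators are accepted; ``NA``/blank cells stay missing.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "variant" not in raw.columns:
        raise TableFormatError(f"{path}: allele-count table lacks a 'variant' column")
    references = [c[: -len("_total")] for c in raw.columns
                  if c.endswith("_total") and c != "cohort_total"]
    if not references:
        raise TableFormatError(f"{path}: no reference population columns (*_total) found")

    out = {"variant": raw["variant"]}
    count_cols = [c for c in raw.columns if c != "variant"]
    for col in count_cols:
        out[col] = pd.array(
            [_parse_count(cell, label, col) for cell, label in zip(raw[col], raw["variant"])],
            dtype="Int64",
        )
    return AlleleCountTable(df=pd.DataFrame(out), references=references)


def write_results(results: pd.DataFrame, path: str | Path, float_precision: int = 9) -> None:
    """Write a result table as TSV with fixed-precision floats.

    Column order is preserved deterministically; floats are serialised with
    ``float_precision`` significant digits so printed p-values round-trip
    through :func:`read_results`.
    """
    path = Path(path)
    results.to_csv(path, sep="\t", index=False, float_format=f"%.{float_precision}g", na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
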