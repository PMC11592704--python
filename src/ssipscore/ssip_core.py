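"""Gene-specific predictor selection and rank meta-scores.

The pipeline ranks each in-silico predictor's scores across the variant set
(direction-aligned, ties averaged, normalised to (0, 1]), tests every
predictor for distributional differences across the Pathogenic / Benign /
Unknown groups with a Kruskal-Wallis test, Bonferroni-adjusts over the
testable predictors, and calls those passing adjusted p < alpha_ssip the
gene's statistically significant in-silico predictors (SSIPs).  Two
per-variant meta-scores follow: the *combined* score (unweighted mean of the
variant's normalised SSIP ranks) and the *weighted* score (all tested
predictors averaged with weights 1 - adjusted p, then min-max rescaled to
[0, 1] across the variant set).

Because every stage is rank-based, any strictly increasing transform of a
predictor's raw scores leaves the entire output unchanged.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.stats import rankdata

from .tables_io import GROUPS, ClinGroupLabels, ScoreMatrix

log = logging.getLogger(__name__)

#: total sample size at or below which kruskal_wallis(method="auto")
#: enumerates the exact permutation null instead of using the chi-square
#: approximation (which can err by ~0.15 at such sizes).
EXACT_N_LIMIT = 10


@dataclass
class RankedMatrix:
    """Per-predictor normalised ranks in (0, 1], same axes as the ScoreMatrix."""

    ranks: pd.DataFrame
    direction: dict[str, int]
    is_rankscore: dict[str, bool]

    @property
    def predictors(self) -> list[str]:
        return list(self.ranks.columns)


class KruskalResult(NamedTuple):
    H: float
    df: int
    p: float
    method: str  # "asymptotic" | "exact" | "untestable"
    degenerate: bool  # all observations tied


def rank_scores(matrix: ScoreMatrix) -> RankedMatrix:
    """Direction-align and rank every predictor column.

    Scores are negated for direction -1 predictors, average ranks break
    ties, and ranks are normalised as rank / n_nonmissing so every
    non-missing entry lies in (0, 1] with higher = more deleterious.
    Columns flagged as rankscores pass through unchanged; columns with
    fewer than two non-missing values are left entirely missing.
    """
    out = {}
    for p in matrix.scores.columns:
        col = matrix.scores[p].to_numpy(dtype=float)
        if matrix.is_rankscore.get(p, False):
            out[p] = col
            continue
        mask = ~np.isnan(col)
        if mask.sum() < 2:
            warnings.warn(f"predictor {p!r} has < 2 non-missing values; column left missing",
                          stacklevel=2)
            out[p] = np.full_like(col, np.nan)
            continue
        vals = col[mask] * matrix.direction[p]
        ranks = rankdata(vals, method="average") / mask.sum()
        full = np.full_like(col, np.nan)
        full[mask] = ranks
        out[p] = full
    ranks = pd.DataFrame(out, index=matrix.scores.index)
    return RankedMatrix(ranks=ranks, direction=dict(matrix.direction),
                        is_rankscore=dict(matrix.is_rankscore))


def _kw_statistic(ranks: np.ndarray, group_slices: Sequence[np.ndarray], tie_term: float) -> float:
    """Tie-corrected Kruskal-Wallis H for pre-computed pooled ranks."""
    n = len(ranks)
    s = sum(r.sum() ** 2 / len(r) for r in (ranks[g] for g in group_slices))
    h = 12.0 / (n * (n + 1)) * s - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _exact_kw_p(values: Sequence[np.ndarray]) -> tuple[float, float]:
    """Exact permutation p: enumerate all assignments of the pooled ranks.

    Returns (H_observed, p) with p = P(H >= H_obs) over the uniform
    distribution of group relabelings.  Feasible for small pooled N only.
    """
    pooled = np.concatenate(values)
    n = len(pooled)
    ranks = rankdata(pooled, method="average")
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (np.sum(counts**3 - counts) / (n**3 - n))
    if tie_term <= 0:  # everything tied
        return 0.0, 1.0

    sizes = [len(v) for v in values]
    bounds = np.cumsum([0] + sizes)
    obs_slices = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    h_obs = _kw_statistic(ranks, obs_slices, tie_term)

    idx_all = frozenset(range(n))
    hits = total = 0

    def recurse(remaining: frozenset, gi: int, chosen: list[np.ndarray]) -> None:
        nonlocal hits, total
        if gi == len(sizes) - 1:
            final = chosen + [np.fromiter(remaining, int)]
            h = _kw_statistic(ranks, final, tie_term)
            total += 1
            if h >= h_obs - 1e-12:
                hits += 1
            return
        for combo in combinations(sorted(remaining), sizes[gi]):
            recurse(remaining - frozenset(combo), gi + 1, chosen + [np.asarray(combo)])

    recurse(idx_all, 0, [])
    return h_obs, hits / total


def kruskal_wallis(values_by_group: Sequence[Sequence[float]],
                   method: str = "auto") -> KruskalResult:
    """Tie-corrected Kruskal-Wallis test across the given groups.

    Empty groups are dropped; df = (non-empty groups) - 1.  ``method`` is
    ``"asymptotic"`` (chi-square upper tail), ``"exact"`` (enumeration of
    all group relabelings), or ``"auto"`` (exact when pooled N <= 10, where
    the chi-square approximation is unreliable; asymptotic otherwise).
    All-tied data returns H = 0, p = 1 with the degenerate flag set.
    Fewer than two non-empty groups yields an untestable marker (NaN p).
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    groups = [g[~np.isnan(g)] for g in groups]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        return KruskalResult(math.nan, 0, math.nan, "untestable", False)
    n = sum(len(g) for g in groups)
    df = len(groups) - 1

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, df, 1.0, method, True)

    if method == "auto":
        method = "exact" if n <= EXACT_N_LIMIT else "asymptotic"
    if method == "exact":
        h, p = _exact_kw_p(groups)
        return KruskalResult(float(h), df, float(p), "exact", False)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    h, p = scipy.stats.kruskal(*groups)
    return KruskalResult(float(h), df, float(p), "asymptotic", False)


def select_ssips(ranked: RankedMatrix,
                 labels: ClinGroupLabels,
                 alpha_ssip: float = 0.05,
                 min_group_n: int = 2,
                 method: str = "auto") -> pd.DataFrame:
    """Test every predictor across the three clinical groups and flag SSIPs.

    A predictor is testable when all three groups hold at least
    ``min_group_n`` non-missing values; the Bonferroni multiplier is the
    number of testable predictors and a predictor is an SSIP when its
    adjusted p < ``alpha_ssip``.

    Returns one row per predictor: predictor, H, df, raw_p, adj_p, is_ssip,
    tested, n_pathogenic, n_benign, n_unknown.
    """
    shared = [v for v in ranked.ranks.index if v in labels.groups.index]
    if not shared:
        raise ValueError("no variant of the ranked matrix carries a clinical group label")
    sub = ranked.ranks.loc[shared]
    grp = labels.groups.loc[shared]

    rows = []
    for p in sub.columns:
        col = sub[p]
        by_group = {g: col[grp == g].dropna().to_numpy() for g in GROUPS}
        ns = {g: len(by_group[g]) for g in GROUPS}
        testable = all(ns[g] >= min_group_n for g in GROUPS)
        rec = {"predictor": p, "H": np.nan, "df": np.nan, "raw_p": np.nan,
               "tested": testable,
               "n_pathogenic": ns["Pathogenic"], "n_benign": ns["Benign"],
               "n_unknown": ns["Unknown"]}
        if testable:
            res = kruskal_wallis([by_group[g] for g in GROUPS], method=method)
            rec.update(H=res.H, df=res.df, raw_p=res.p)
        rows.append(rec)
    out = pd.DataFrame(rows)

    if not out["tested"].any():
        log.error("zero testable predictors (min_group_n = %d)", min_group_n)
        out["adj_p"] = np.nan
        out["is_ssip"] = False
        return out

    from .af_compare import bonferroni_adjust

    raw = [p if t else None for p, t in zip(out["raw_p"], out["tested"])]
    adj, m = bonferroni_adjust(raw)
    out["adj_p"] = [np.nan if p is None else p for p in adj]
    out["is_ssip"] = out["adj_p"].notna() & (out["adj_p"] < alpha_ssip)
    log.info("%d of %d predictors testable; %d selected as SSIPs (alpha = %g)",
             m, len(out), int(out["is_ssip"].sum()), alpha_ssip)
    cols = ["predictor", "H", "df", "raw_p", "adj_p", "is_ssip", "tested",
            "n_pathogenic", "n_benign", "n_unknown"]
    return out[cols]


def combined_score(ranked: RankedMatrix,
                   ssips: Iterable[str],
                   min_fraction: float = 0.5) -> pd.DataFrame:
    """Unweighted mean of each variant's non-missing normalised SSIP ranks.

    The score is missing when fewer than ``min_fraction`` of the SSIPs have
    a value for the variant.  Returns columns: variant, combined, n_used.
    """
    ssips = list(ssips)
    if not ssips:
        raise ValueError("SSIP set is empty; no combined score can be formed")
    sub = ranked.ranks[ssips]
    n_used = sub.notna().sum(axis=1)
    combined = sub.mean(axis=1)
    combined[n_used / len(ssips) < min_fraction] = np.nan
    return pd.DataFrame({"variant": sub.index, "combined": combined.to_numpy(),
                         "n_used": n_used.to_numpy()})


def weighted_score(ranked: RankedMatrix,
                   tests: pd.DataFrame,
                   min_fraction: float = 0.5) -> pd.DataFrame:
    """Significance-weighted rank meta-score over all tested predictors.

    Each tested predictor gets weight w = max(0, 1 - adjusted p); a
    variant's score is the weighted mean of its non-missing ranks
    (sum w_i r_i / sum w_i over present predictors), and the resulting
    vector is min-max rescaled to [0, 1] across the scored variants.
    Returns columns: variant, weighted, n_used.
    """
    tested = tests[tests["tested"]].set_index("predictor")
    preds = [p for p in tested.index if p in ranked.ranks.columns]
    if not preds:
        raise ValueError("no tested predictor overlaps the ranked matrix")
    w = np.maximum(0.0, 1.0 - tested.loc[preds, "adj_p"].to_numpy(dtype=float))
    if np.all(w == 0):
        warnings.warn("all predictor weights are zero; weighted scores are missing",
                      stacklevel=2)
        return pd.DataFrame({"variant": ranked.ranks.index,
                             "weighted": np.nan, "n_used": 0})

    sub = ranked.ranks[preds].to_numpy(dtype=float)
    present = ~np.isnan(sub)
    wsum = present @ w
    n_used = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        raw = np.nansum(sub * w, axis=1) / wsum
    raw[wsum == 0] = np.nan
    raw[n_used / len(preds) < min_fraction] = np.nan

    finite = ~np.isnan(raw)
    scaled = np.full_like(raw, np.nan)
    if finite.any():
        lo, hi = raw[finite].min(), raw[finite].max()
        scaled[finite] = 0.0 if hi == lo else (raw[finite] - lo) / (hi - lo)
    return pd.DataFrame({"variant": ranked.ranks.index, "weighted": scaled,
                         "n_used": n_used})


@dataclass
class SsipRunResult:
    """Output of the full selection + scoring composition."""

    tests: pd.DataFrame
    scores: pd.DataFrame
    summary: dict = field(default_factory=dict)


def score_all_variants(matrix: ScoreMatrix,
                       labels: ClinGroupLabels,
                       alpha_ssip: float = 0.05,
                       min_group_n: int = 2,
                       min_fraction: float = 0.5,
                       combine_all_predictors: bool = False,
                       method: str = "auto") -> SsipRunResult:
    """Rank, select SSIPs, and compute combined + weighted meta-scores.

    ``combine_all_predictors`` switches the combined score from the SSIP
    subset (default) to every analysed predictor.  The run summary records
    group sizes, the Bonferroni family size, SSIP count and thresholds.
    """
    ranked = rank_scores(matrix)
    tests = select_ssips(ranked, labels, alpha_ssip=alpha_ssip,
                         min_group_n=min_group_n, method=method)
    ssips = tests.loc[tests["is_ssip"], "predictor"].tolist()
    pool = list(tests.loc[tests["tested"], "predictor"]) if combine_all_predictors else ssips

    if pool:
        comb = combined_score(ranked, pool, min_fraction=min_fraction)
    else:
        log.warning("no SSIPs selected; combined scores are missing")
        comb = pd.DataFrame({"variant": ranked.ranks.index, "combined": np.nan, "n_used": 0})

    if tests["tested"].any():
        wtd = weighted_score(ranked, tests, min_fraction=min_fraction)
    else:
        wtd = pd.DataFrame({"variant": ranked.ranks.index, "weighted": np.nan, "n_used": 0})

    scores = comb.rename(columns={"n_used": "n_ssips_used"}).merge(
        wtd.rename(columns={"n_used": "n_tested_used"}), on="variant", how="left")

    group_sizes = labels.groups.value_counts().to_dict()
    summary = {
        "group_sizes": {g: int(group_sizes.get(g, 0)) for g in GROUPS},
        "n_predictors": len(matrix.predictors),
        "n_testable": int(tests["tested"].sum()),
        "n_ssips": len(ssips),
        "ssips": ssips,
        "alpha_ssip": alpha_ssip,
        "min_group_n": min_group_n,
        "min_fraction": min_fraction,
        "combine_all_predictors": combine_all_predictors,
    }
    return SsipRunResult(tests=tests, scores=scores, summary=summary)
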