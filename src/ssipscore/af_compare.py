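"""Per-variant allele-frequency enrichment tests: cohort vs reference.

Each variant contributes one 2x2 table — rows {cohort, reference}, columns
{altered alleles, total - altered} — tested with a two-sided Fisher's exact
test under the point-probability rule, then Bonferroni-adjusted within the
family of computable tests for that reference.  Homozygote counts are
carried through but never enter the test.  The raw significance threshold
is 0.05 and the adjusted threshold 0.1.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .tables_io import AlleleCountTable

log = logging.getLogger(__name__)

#: relative slack for "as or less probable" table inclusion; point
#: probabilities within a factor (1 + _REL_TOL) of the observed one count as
#: ties, matching the convention of standard two-sided Fisher implementations.
_REL_TOL = 1e-7


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    p is the sum of hypergeometric point probabilities, over all tables with
    the observed margins, that do not exceed the observed table's probability
    (within relative tolerance 1 + 1e-7).  Point masses are evaluated through
    log-gamma so totals in the millions are handled stably.

    A degenerate margin (an empty row or column) carries no information and
    returns p = 1 with a warning.
    """
    counts = (a, b, c, d)
    if any(int(x) != x for x in counts):
        raise ValueError(f"counts must be integers, got {counts}")
    a, b, c, d = (int(x) for x in counts)
    if min(a, b, c, d) < 0:
        raise ValueError(f"counts must be non-negative, got {counts}")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1", stacklevel=2)
        return 1.0

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log hypergeometric pmf over the whole support, normalised for stability
    logp = (
        -gammaln(support + 1)
        - gammaln(r1 - support + 1)
        - gammaln(c1 - support + 1)
        - gammaln(n - r1 - c1 + support + 1)
    )
    logp -= logsumexp(logp)
    log_obs = logp[a - lo]
    mask = logp <= log_obs + np.log1p(_REL_TOL)
    if mask.all():
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def bonferroni_adjust(p_values: Sequence[float | None]) -> tuple[list[float | None], int]:
    """Bonferroni adjustment over the present (non-missing) p-values.

    Returns the adjusted sequence (missing entries stay missing) and the
    family size m = number of present p-values; each present p maps to
    min(1, m * p).
    """
    present = [p for p in p_values if p is not None and not (isinstance(p, float) and np.isnan(p))]
    for p in present:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {p}")
    m = len(present)
    out: list[float | None] = []
    for p in p_values:
        if p is None or (isinstance(p, float) and np.isnan(p)):
            out.append(None)
        else:
            out.append(min(1.0, m * p))
    return out, m


def compare_allele_frequencies(table: AlleleCountTable,
                               reference_name: str,
                               alpha_raw: float = 0.05,
                               alpha_adj: float = 0.1) -> pd.DataFrame:
    """Fisher-test every variant's cohort counts against one reference.

    Rows with missing reference counts yield missing p-values and do not
    count toward the Bonferroni family size m.  A variant is ``significant``
    when raw p < ``alpha_raw`` and adjusted p < ``alpha_adj``.

    Returns a frame with columns: variant, reference, cohort_alt,
    cohort_total, ref_alt, ref_total, raw_p, adj_p, m, odds_ratio,
    enriched_in_cohort, significant.
    """
    if reference_name not in table.references:
        raise ValueError(f"unknown reference {reference_name!r}; table has {table.references}")
    df = table.df
    alt_c, tot_c = f"{reference_name}_alt", f"{reference_name}_total"

    rows = []
    for _, r in df.iterrows():
        ca, ct = r["cohort_alt"], r["cohort_total"]
        ra, rt = r[alt_c], r[tot_c]
        rec = {
            "variant": r["variant"], "reference": reference_name,
            "cohort_alt": int(ca), "cohort_total": int(ct),
            "ref_alt": ra if pd.notna(ra) else None,
            "ref_total": rt if pd.notna(rt) else None,
            "raw_p": np.nan, "odds_ratio": np.nan,
            "enriched_in_cohort": pd.NA,
        }
        if pd.notna(ra) and pd.notna(rt):
            a, b = int(ca), int(ct) - int(ca)
            c, d = int(ra), int(rt) - int(ra)
            rec["raw_p"] = fisher_exact_2x2(a, b, c, d)
            rec["enriched_in_cohort"] = (a / (a + b)) > (c / (c + d)) if (c + d) else pd.NA
            if min(a, b, c, d) > 0:
                rec["odds_ratio"] = (a * d) / (b * c)
        rows.append(rec)

    out = pd.DataFrame(rows)
    raw = [None if np.isnan(p) else p for p in out["raw_p"]]
    adj, m = bonferroni_adjust(raw)
    out["adj_p"] = [np.nan if p is None else p for p in adj]
    out["m"] = m
    out["significant"] = (
        out["raw_p"].notna()
        & (out["raw_p"] < alpha_raw)
        & (out["adj_p"] < alpha_adj)
    )
    log.info("reference %s: m = %d computable tests of %d variants, %d significant",
             reference_name, m, len(out), int(out["significant"].sum()))
    cols = ["variant", "reference", "cohort_alt", "cohort_total", "ref_alt", "ref_total",
            "raw_p", "adj_p", "m", "odds_ratio", "enriched_in_cohort", "significant"]
    return out[cols]
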