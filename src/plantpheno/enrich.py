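"""Fisher's-exact GO-slim enrichment of up- vs down-regulated gene counts.

For each (tissue, GO-slim term) the 2x2 table

    [[up_in_term,           down_in_term],
     [up_total - up_in,     down_total - down_in]]

is tested with the two-sided exact test (point-probability rule, the
convention of R's ``fisher.test``).  Significance is a plain per-term alpha
cut — no cross-term correction — mirroring how such tables are usually
screened; an optional Benjamini-Hochberg flag is provided as an extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["EnrichmentRow", "fisher_term", "enrich_table"]


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    tissue: str
    up_in_term: int
    down_in_term: int
    up_total: int
    down_total: int
    odds_ratio: float
    p_value: float
    significant: bool
    direction: str  # "up", "down" or "none"

    def __post_init__(self):
        if self.up_in_term > self.up_total or self.down_in_term > self.down_total:
            raise ValueError("in-term counts exceed totals")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def fisher_term(
    up_in: int, down_in: int, up_total: int, down_total: int
) -> tuple[float, float]:
    """Two-sided exact test of one term's 2x2 table -> (odds ratio, p).

    The sample odds ratio (up_in*down_out)/(down_in*up_out) is reported,
    with 0/0 conventions: inf when only the numerator is positive, nan when
    both vanish.  A zero margin carries no information: p = 1 with a
    warning.
    """
    for v in (up_in, down_in, up_total, down_total):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    if up_in > up_total or down_in > down_total:
        raise ValueError("in-term counts exceed totals")
    a, b = int(up_in), int(down_in)
    c, d = int(up_total - up_in), int(down_total - down_in)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("a margin of the 2x2 table is zero; the test is uninformative")
        num, den = a * d, b * c
        orat = np.nan if num == den == 0 else (np.inf if den == 0 else num / den)
        return float(orat), 1.0
    orat, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(orat), float(p)


def enrich_table(counts: pd.DataFrame, alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Exact enrichment test for every (tissue, term) row.

    ``counts`` needs columns tissue, term, up_in_term, down_in_term,
    up_total, down_total.  Adds odds_ratio, p_value, significant and a
    direction label (up-enriched when OR > 1).  ``bh=True`` additionally
    applies Benjamini-Hochberg across rows (extension; off by default).
    """
    required = {"tissue", "term", "up_in_term", "down_in_term", "up_total", "down_total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if counts.duplicated(["tissue", "term"]).any():
        raise ValueError("duplicate (tissue, term) keys in counts table")
    out = counts.copy()
    if out.empty:
        for col in ("odds_ratio", "p_value"):
            out[col] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        out["direction"] = pd.Series(dtype=object)
        return out
    ors, ps = zip(
        *(
            fisher_term(r.up_in_term, r.down_in_term, r.up_total, r.down_total)
            for r in out.itertuples()
        )
    )
    out["odds_ratio"] = ors
    out["p_value"] = ps
    if bh:
        from statsmodels.stats.multitest import multipletests

        out["p_value_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["p_value_bh"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    out["direction"] = np.select(
        [out["odds_ratio"] > 1, out["odds_ratio"] < 1], ["up", "down"], default="none"
    )
    return out
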