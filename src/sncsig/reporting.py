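"""Small descriptive-statistics helpers for cohort summary tables."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``decimals``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    frac = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def conversion_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """AD-conversion counts and percentages by biomarker group."""
    rows = []
    for grp, sub in pheno.groupby("atn_case"):
        n = len(sub)
        k = int(sub["ad_event"].sum())
        rows.append(
            {
                "group": "A+(T|N)+" if grp == 1 else "A-T-N-",
                "n": n,
                "converters": k,
                "percent": percentage(k, n),
            }
        )
    return pd.DataFrame(rows)
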