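"""Summary reporting and printed-figure consistency checks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from silencescan.windows import percent_silent

__all__ = ["fraction_check", "silent_summary"]


def fraction_check(
    numerator: int, denominator: int, printed_percent: float, ndigits: int = 2
) -> bool:
    """Verify that a printed percentage matches its printed counts.

    Recomputes ``100 * numerator / denominator`` rounded to ``ndigits``
    decimals and compares it to the printed value.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    recomputed = round(100.0 * numerator / denominator, ndigits)
    return bool(np.isclose(recomputed, printed_percent, rtol=0, atol=10 ** -(ndigits + 6)))


def silent_summary(rs_tab: pd.DataFrame, silent: pd.Series) -> pd.DataFrame:
    """Per-chromosome silent-gene counts and percentages.

    ``silent`` is a boolean series aligned to the rs table.  Percentages
    are computed with :func:`percent_silent` (nearest integer) with the
    raw value retained.
    """
    aligned = silent.reindex(rs_tab.index, fill_value=False)
    rows = []
    for chrom, group in rs_tab.groupby("chrom", sort=True):
        n_total = len(group)
        n_silent = int(aligned.loc[group.index].sum())
        rows.append(
            {
                "chrom": chrom,
                "n_total": n_total,
                "n_silent": n_silent,
                "percent_silent": percent_silent(n_silent, n_total),
                "percent_silent_raw": 100.0 * n_silent / n_total,
            }
        )
    return pd.DataFrame(rows)
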