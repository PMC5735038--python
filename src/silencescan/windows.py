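"""Sequential genomic-window summaries of repression scores.

Chromosomes are tiled with fixed-width half-open windows ([0, w),
[w, 2w), ...); each gene belongs to the window containing its start
coordinate.  The maximum-silencing region is the window with the highest
median rs among windows holding enough genes, refined by re-scanning at
narrower widths (10 / 5 / 3 Mb by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "bin_genes",
    "window_stats",
    "max_silencing_region",
    "categorize_rs",
    "percent_silent",
    "DEFAULT_WIDTHS",
    "DEFAULT_RS_BINS",
]

DEFAULT_WIDTHS = (10_000_000, 5_000_000, 3_000_000)

#: RS category edges: [0,0.1), [0.1,0.4), [0.4,0.7), [0.7,1]
DEFAULT_RS_BINS = (0.0, 0.1, 0.4, 0.7, 1.0)


def bin_genes(
    annotation: pd.DataFrame,
    chromosome: str,
    width: int,
    chrom_length: int | None = None,
) -> pd.DataFrame:
    """Tile a chromosome with half-open windows and assign genes.

    Assignment uses the gene start coordinate (0-based), so a gene
    starting exactly on a boundary belongs to the right-hand window.
    Returns one row per window with ``start``, ``end``, ``n_genes`` and
    the member ``gene_ids`` list; windows together partition the genes.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    on = annotation[annotation["chrom"] == chromosome]
    if on.empty:
        raise ValueError(f"no genes on chromosome {chromosome!r}")
    if chrom_length is None:
        chrom_length = int(on["end"].max())
    n_windows = int(np.ceil(chrom_length / width))
    starts = np.arange(n_windows, dtype=np.int64) * width
    ends = np.minimum(starts + width, chrom_length)
    assignment = (on["start"].to_numpy() // width).astype(int)
    members: list[list] = [[] for _ in range(n_windows)]
    for gene, w in zip(on.index, assignment):
        members[w].append(gene)
    windows = pd.DataFrame(
        {
            "chrom": chromosome,
            "start": starts,
            "end": ends,
            "n_genes": [len(m) for m in members],
            "gene_ids": members,
        }
    )
    return windows


def window_stats(windows: pd.DataFrame, rs: pd.Series) -> pd.DataFrame:
    """Attach median/mean rs per window (NaN for empty windows)."""
    medians = []
    means = []
    counts = []
    for member in windows["gene_ids"]:
        values = rs.reindex(member).dropna()
        counts.append(len(values))
        medians.append(float(values.median()) if len(values) else np.nan)
        means.append(float(values.mean()) if len(values) else np.nan)
    out = windows.copy()
    out["n_genes_scored"] = counts
    out["median_rs"] = medians
    out["mean_rs"] = means
    return out


def max_silencing_region(
    windows: pd.DataFrame, rs: pd.Series, min_genes: int = 5
) -> pd.Series | None:
    """Window with the maximum median rs among qualifying windows.

    A window qualifies with at least ``min_genes`` scored genes.  Ties
    break toward the window with more genes, then the leftmost.  Returns
    the winning row (with ``median_rs``) or None when nothing qualifies.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    stats = window_stats(windows, rs)
    qualified = stats[stats["n_genes_scored"] >= min_genes]
    if qualified.empty:
        return None
    order = qualified.sort_values(
        ["median_rs", "n_genes_scored", "start"],
        ascending=[False, False, True],
    )
    return order.iloc[0]


def categorize_rs(
    rs_values, bins=DEFAULT_RS_BINS
) -> pd.DataFrame:
    """Fractions of genes per RS category bin.

    ``bins`` are edges partitioning [0, 1]; every bin is half-open
    except the last, which includes 1.  Also reports the fraction of
    genes with rs in [0.1, 1].  Fractions sum to 1.
    """
    values = np.asarray(rs_values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("cannot categorize an empty rs set")
    edges = np.asarray(bins, dtype=float)
    if edges[0] != 0.0 or edges[-1] != 1.0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be increasing edges from 0 to 1")
    hist, _ = np.histogram(values, bins=edges)
    fractions = hist / values.size
    labels = [
        f"[{edges[i]:g},{edges[i + 1]:g})" if i < len(edges) - 2 else
        f"[{edges[i]:g},{edges[i + 1]:g}]"
        for i in range(len(edges) - 1)
    ]
    out = pd.DataFrame({"bin": labels, "fraction": fractions, "n_genes": hist})
    out.attrs["fraction_rs_0.1_to_1"] = float(np.mean(values >= 0.1))
    return out


def percent_silent(n_silent: int, n_total: int, ndigits: int = 0) -> float:
    """Percentage of silent genes, rounded to ``ndigits`` decimals.

    With ``ndigits=0`` the nearest integer is returned (as a float),
    matching the convention of reporting e.g. 630/659 as ~96%.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_silent <= n_total:
        raise ValueError("n_silent must lie in [0, n_total]")
    raw = 100.0 * n_silent / n_total
    return float(round(raw, ndigits if ndigits else None))
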