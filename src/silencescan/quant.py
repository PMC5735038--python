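"""Library-size normalization, allelic splitting, and expression filters.

Counts are read pairs per gene per sample; each sample is one
(condition, replicate) library.  Allele 1 is Cast/G1 and allele 2 is
129S1/G2 by convention.  CPM is computed per sample against its own
library size; allelic expression is the CPM split by the allele-assignable
read ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AllelicCounts",
    "AllelicExpression",
    "normalize_cpm",
    "split_allelic",
    "filter_genes",
    "build_expression",
    "FILTER_POLICIES",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand"]
SAMPLE_COLUMNS = ["condition", "replicate"]


@dataclass
class AllelicCounts:
    """Gene x sample matrix of total and allele-split read-pair counts.

    Parameters
    ----------
    genes
        Gene annotation indexed by gene id, with at least ``chrom``,
        ``start``, ``end`` columns (0-based half-open) and optionally
        ``strand``.
    samples
        Sample table indexed by sample id with ``condition`` (``NoDox`` /
        ``Dox``) and ``replicate`` columns.
    total, a1, a2
        Integer arrays of shape (n_genes, n_samples).  ``a1`` is the
        Cast/G1 count, ``a2`` the 129S1/G2 count; ``a1 + a2 <= total``.
    """

    genes: pd.DataFrame
    samples: pd.DataFrame
    total: np.ndarray
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.genes), len(self.samples))
        for name in ("total", "a1", "a2"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"negative values in {name}")
            setattr(self, name, arr.astype(np.int64, copy=False))
        if np.any(self.a1 + self.a2 > self.total):
            raise ValueError("allelic counts exceed total counts")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def library_sizes(self) -> pd.Series:
        """Total mapped read pairs per sample (sum over genes)."""
        return pd.Series(
            self.total.sum(axis=0), index=self.samples.index, name="library_size"
        )

    def sample_ids(self, condition: str | None = None) -> list:
        sel = self.samples
        if condition is not None:
            sel = sel[sel["condition"] == condition]
        return list(sel.index)


@dataclass
class AllelicExpression:
    """CPM and per-allele expression with the gene filter mask.

    ``expr_a1 + expr_a2 == cpm`` wherever allele-assignable reads exist;
    both allelic values are NaN (missing, not zero) where ``a1 + a2 == 0``.
    """

    cpm: pd.DataFrame
    expr_a1: pd.DataFrame
    expr_a2: pd.DataFrame
    mask: pd.Series
    genes: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    @property
    def filtered_genes(self) -> pd.Index:
        return self.mask.index[self.mask]


def normalize_cpm(counts: AllelicCounts) -> pd.DataFrame:
    """Counts per million mapped read pairs, per sample.

    Raises
    ------
    ValueError
        If any sample has a zero library size.
    """
    lib = counts.library_sizes.to_numpy(dtype=float)
    if np.any(lib <= 0):
        bad = counts.samples.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    cpm = counts.total / lib[None, :] * 1e6
    return pd.DataFrame(cpm, index=counts.genes.index, columns=counts.samples.index)


def split_allelic(
    cpm: pd.DataFrame | np.ndarray,
    a1: np.ndarray,
    a2: np.ndarray,
) -> tuple[pd.DataFrame | np.ndarray, pd.DataFrame | np.ndarray]:
    """Split CPM into per-allele expression by the assignable-read ratio.

    ``expr_a1 = cpm * a1 / (a1 + a2)`` and symmetrically for allele 2.
    Where ``a1 + a2 == 0`` both outputs are NaN.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError("allelic counts must be non-negative")
    assignable = a1 + a2
    cpm_values = np.asarray(cpm, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(assignable > 0, a1 / assignable, np.nan)
    expr1 = cpm_values * frac1
    expr2 = cpm_values * (1.0 - frac1)
    if isinstance(cpm, pd.DataFrame):
        expr1 = pd.DataFrame(expr1, index=cpm.index, columns=cpm.columns)
        expr2 = pd.DataFrame(expr2, index=cpm.index, columns=cpm.columns)
    return expr1, expr2


#: policy name -> requires threshold
FILTER_POLICIES = {
    "mean_gt1": False,
    "per_sample_gt1": False,
    "allelic_sum_gt": True,
}


def filter_genes(
    cpm: pd.DataFrame,
    expr_a1: pd.DataFrame,
    expr_a2: pd.DataFrame,
    policy: str = "mean_gt1",
    threshold: float | None = None,
) -> pd.Series:
    """Boolean keep-mask per gene under an expression filter policy.

    Policies (threshold comparisons are strict ``>``):

    ``mean_gt1``
        mean CPM across all samples > 1 (default reading of the
        average-expression rule).
    ``per_sample_gt1``
        CPM > 1 in every sample (the stricter per-sample reading).
    ``allelic_sum_gt``
        sum of allelic expression over all samples and both alleles
        > ``threshold`` (e.g. 8 for a time course, 6 for truncated
        constructs).
    """
    if policy not in FILTER_POLICIES:
        raise ValueError(
            f"unknown filter policy {policy!r}; choose from {sorted(FILTER_POLICIES)}"
        )
    if policy == "mean_gt1":
        keep = cpm.mean(axis=1) > 1.0
    elif policy == "per_sample_gt1":
        keep = (cpm > 1.0).all(axis=1)
    else:
        if threshold is None:
            raise ValueError("allelic_sum_gt policy requires a threshold")
        total = expr_a1.fillna(0.0).sum(axis=1) + expr_a2.fillna(0.0).sum(axis=1)
        keep = total > float(threshold)
    keep.name = "keep"
    return keep


def build_expression(
    counts: AllelicCounts,
    policy: str = "mean_gt1",
    threshold: float | None = None,
) -> AllelicExpression:
    """Normalize, split by allele, and apply the gene filter in one pass."""
    cpm = normalize_cpm(counts)
    expr_a1, expr_a2 = split_allelic(cpm, counts.a1, counts.a2)
    mask = filter_genes(cpm, expr_a1, expr_a2, policy=policy, threshold=threshold)
    return AllelicExpression(
        cpm=cpm,
        expr_a1=expr_a1,
        expr_a2=expr_a2,
        mask=mask,
        genes=counts.genes,
        samples=counts.samples,
    )
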