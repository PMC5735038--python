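"""Permutation significance for repression scores.

The null hypothesis is that a gene's allele-assignable reads split
between the alleles with a condition-independent probability.  Holding
every sample's total (and therefore CPM) fixed, the assignable reads are
re-assigned binomially ``n_perm`` times, the repression score is
recomputed through the identical path (including clipping), and the
p-value is the fraction of null scores at least as large as the observed
one.  Per-replicate p-values are combined with Fisher's method and
adjusted with Benjamini-Hochberg; a gene is called silent when both the
q-value and the calibrated score pass their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "permute_gene",
    "permutation_pvalues",
    "combine_replicates",
    "fisher_combine",
    "bh_adjust",
    "call_silent",
]

DEFAULT_N_PERM = 10_000


@dataclass
class PermutationResult:
    """Per-replicate permutation outcome for one gene.

    ``p[r] = n_ge[r] / n_perm`` where ``n_ge`` counts null scores no less
    than the observed score of replicate ``r``.  ``p = 1`` whenever the
    observed score is 0, because the clipped null score is never
    negative.
    """

    gene_id: str
    rs_obs: np.ndarray
    n_perm: int
    n_ge: np.ndarray
    p: np.ndarray


def _null_rs(
    cpm_0: np.ndarray,
    s_0: np.ndarray,
    n_0: np.ndarray,
    cpm_i: np.ndarray,
    s_i: np.ndarray,
    n_i: np.ndarray,
    baseline: str,
) -> np.ndarray:
    """Clipped repression scores from silenced-count splits.

    ``s_*``/``n_*`` have shape (..., n_reps); cpm vectors broadcast.
    Returns scores of shape (..., n_treated_reps); NaN where a baseline
    allele has no signal.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_0 = np.where(n_0 > 0, s_0 / np.maximum(n_0, 1), np.nan)
        frac_i = np.where(n_i > 0, s_i / np.maximum(n_i, 1), np.nan)
    sil_0 = cpm_0 * frac_0
    act_0 = cpm_0 * (1.0 - frac_0)
    sil_i = cpm_i * frac_i
    act_i = cpm_i * (1.0 - frac_i)
    if baseline == "pooled":
        sil_base = np.nanmean(sil_0, axis=-1, keepdims=True)
        act_base = np.nanmean(act_0, axis=-1, keepdims=True)
    else:  # matched: replicate r of baseline pairs with replicate r treated
        sil_base = sil_0
        act_base = act_0
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (act_i - act_base) / act_base - (sil_i - sil_base) / sil_base
    raw = np.where((act_base > 0) & (sil_base > 0), raw, np.nan)
    return np.clip(raw, 0.0, 1.0)


def permute_gene(
    counts_nodox: np.ndarray,
    counts_dox: np.ndarray,
    n_perm: int,
    allelic_p: float,
    rng: np.random.Generator,
    lib_nodox: np.ndarray,
    lib_dox: np.ndarray,
    silenced_allele: str = "a1",
    baseline: str = "pooled",
    gene_id: str = "",
) -> PermutationResult:
    """Permutation p-values for a single gene.

    ``counts_nodox``/``counts_dox`` are arrays of shape (n_reps, 3) with
    columns (total, a1, a2); ``lib_*`` are per-replicate library sizes.
    Totals stay fixed (CPM is permutation-invariant); only the allelic
    assignment of the ``a1 + a2`` assignable reads is redrawn with
    probability ``allelic_p`` for the silenced allele.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < allelic_p < 1.0:
        raise ValueError("allelic_p must lie in (0, 1)")
    counts_nodox = np.asarray(counts_nodox, dtype=np.int64)
    counts_dox = np.asarray(counts_dox, dtype=np.int64)
    sil_col = 1 if silenced_allele == "a1" else 2

    cpm_0 = counts_nodox[:, 0] / np.asarray(lib_nodox, dtype=float) * 1e6
    cpm_i = counts_dox[:, 0] / np.asarray(lib_dox, dtype=float) * 1e6
    n_0 = counts_nodox[:, 1] + counts_nodox[:, 2]
    n_i = counts_dox[:, 1] + counts_dox[:, 2]
    s_obs_0 = counts_nodox[:, sil_col]
    s_obs_i = counts_dox[:, sil_col]

    rs_obs = _null_rs(cpm_0, s_obs_0, n_0, cpm_i, s_obs_i, n_i, baseline)

    s_null_0 = rng.binomial(n_0[None, :], allelic_p, size=(n_perm, n_0.size))
    s_null_i = rng.binomial(n_i[None, :], allelic_p, size=(n_perm, n_i.size))
    rs_null = _null_rs(
        cpm_0[None, :], s_null_0, n_0[None, :], cpm_i[None, :], s_null_i, n_i[None, :],
        baseline,
    )
    with np.errstate(invalid="ignore"):
        n_ge = np.nansum(rs_null >= rs_obs[None, :], axis=0)
    p = np.where(np.isnan(rs_obs), np.nan, n_ge / n_perm)
    return PermutationResult(
        gene_id=gene_id, rs_obs=rs_obs, n_perm=n_perm,
        n_ge=n_ge.astype(np.int64), p=p,
    )


def permutation_pvalues(
    counts,
    rs_tab: pd.DataFrame,
    orientation,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    allelic_p: str | float = "pooled_nodox",
    baseline: str = "pooled",
    baseline_condition: str = "NoDox",
    treated_condition: str = "Dox",
) -> pd.DataFrame:
    """Per-gene per-replicate permutation p-values for an rs table.

    ``allelic_p='pooled_nodox'`` (default) re-splits with each gene's
    pooled baseline allelic fraction, preserving constitutive skew while
    destroying condition-specific skew; a float fixes the probability
    (e.g. 0.5).  One counted random stream is spawned per gene from
    ``seed``, so results are independent of gene subset and order.
    """
    from silencescan.score import _as_orientation

    silenced = _as_orientation(orientation).silenced_allele
    sil_arr = counts.a1 if silenced == "a1" else counts.a2
    lib = counts.library_sizes.to_numpy(dtype=float)
    samples = counts.samples
    idx_0 = [samples.index.get_loc(s) for s in counts.sample_ids(baseline_condition)]
    idx_i = [samples.index.get_loc(s) for s in counts.sample_ids(treated_condition)]
    if not idx_0 or not idx_i:
        raise ValueError("both baseline and treated samples are required")
    reps_i = samples.iloc[idx_i]["replicate"].tolist()

    gene_pos = pd.Series(np.arange(len(counts.genes)), index=counts.genes.index)
    assignable = counts.a1 + counts.a2

    rows = {}
    for gene in rs_tab.index:
        g = int(gene_pos[gene])
        n_0 = assignable[g, idx_0]
        n_i = assignable[g, idx_i]
        s_0 = sil_arr[g, idx_0]
        s_i = sil_arr[g, idx_i]
        if allelic_p == "pooled_nodox":
            pooled_n = n_0.sum()
            if pooled_n == 0:
                rows[gene] = [np.nan] * (2 * len(idx_i))
                continue
            p_split = s_0.sum() / pooled_n
            # degenerate splits cannot be permuted meaningfully
            p_split = min(max(p_split, 1.0 / (pooled_n + 1)), 1 - 1.0 / (pooled_n + 1))
        else:
            p_split = float(allelic_p)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(g,)))
        nodox = np.column_stack(
            [counts.total[g, idx_0], s_0, n_0 - s_0]
        )
        dox = np.column_stack([counts.total[g, idx_i], s_i, n_i - s_i])
        res = permute_gene(
            nodox, dox, n_perm, p_split, rng,
            lib_nodox=lib[idx_0], lib_dox=lib[idx_i],
            silenced_allele="a1",  # columns already ordered (silenced, active)
            baseline=baseline, gene_id=str(gene),
        )
        rows[gene] = list(res.p) + list(res.rs_obs)

    columns = [f"p_rep{r}" for r in reps_i] + [f"rs_obs_rep{r}" for r in reps_i]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    out.index.name = rs_tab.index.name
    return out


def combine_replicates(pvals: pd.DataFrame, n_perm: int = DEFAULT_N_PERM) -> pd.DataFrame:
    """Fisher-combine the per-replicate p-value columns of a gene table."""
    p_cols = [c for c in pvals.columns if c.startswith("p_rep")]
    if not p_cols:
        raise ValueError("no per-replicate p-value columns found")
    floor = 1.0 / (n_perm + 1)
    combined = np.full(len(pvals), np.nan)
    values = pvals[p_cols].to_numpy(dtype=float)
    for i in range(len(pvals)):
        row = values[i]
        row = row[~np.isnan(row)]
        if row.size == 0:
            continue
        combined[i] = fisher_combine(row, floor=floor)
    return pd.DataFrame({"p_combined": combined}, index=pvals.index)


def fisher_combine(p_values, floor: float | None = None) -> float:
    """Combine p-values with Fisher's method.

    The statistic ``-2 * sum(ln p)`` is referred to a chi-square
    distribution with ``2k`` degrees of freedom.  Zeros must be floored
    (e.g. at ``1 / (n_perm + 1)``) before taking logs; a single p-value
    is returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("cannot combine an empty set of p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if floor is not None:
        p = np.maximum(p, floor)
    elif np.any(p == 0):
        raise ValueError("p = 0 requires a floor (e.g. 1 / (n_perm + 1))")
    statistic = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(statistic, df=2 * p.size))


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up q-values, capped at 1.

    NaN entries propagate as NaN and are excluded from the adjustment.
    """
    arr = np.asarray(p_values, dtype=float)
    q = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        q[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(q, index=p_values.index, name="q")
    return q


def call_silent(crs, q, crs_min: float = 0.1, q_max: float = 0.05):
    """Silent iff ``q < q_max`` and ``crs > crs_min`` (both strict)."""
    crs_arr = np.asarray(crs, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    with np.errstate(invalid="ignore"):
        silent = (q_arr < q_max) & (crs_arr > crs_min)
    if isinstance(crs, pd.Series):
        return pd.Series(silent, index=crs.index, name="silent")
    if silent.ndim == 0:
        return bool(silent)
    return silent
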