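"""Per-gene repression scores and transgene chromosome/allele inference.

The repression score of a gene contrasts the relative expression change
of its two alleles between the untreated baseline ('0', NoDox) and a
treated condition ('i', Dox):

    rs_raw = (active_i - active_0) / active_0
           - (silenced_i - silenced_0) / silenced_0
    rs     = clip(rs_raw, 0, 1)

where "silenced" is the allele the orientation designates as putatively
repressed and "active" the other.  Complete loss of the silenced allele
with an unchanged active allele gives rs = 1; proportional changes on
both alleles cancel to 0.  The score is defined role-wise so that both
orientations (Cast silenced / 129S1 silenced) can be scanned and the
better-supported one selected.

RS is undefined (NaN) when either allele has no baseline expression;
such genes are dropped from downstream tables rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from silencescan.quant import AllelicExpression

__all__ = [
    "Orientation",
    "repression_score",
    "repression_score_raw",
    "rs_table",
    "random_rs",
    "calibrated_rs",
    "detect_transgene",
    "TransgeneCall",
]


@dataclass(frozen=True)
class Orientation:
    """Designation of the putatively silenced allele ('a1' Cast or 'a2' 129S1)."""

    silenced_allele: str

    def __post_init__(self) -> None:
        if self.silenced_allele not in ("a1", "a2"):
            raise ValueError("silenced_allele must be 'a1' or 'a2'")

    @property
    def active_allele(self) -> str:
        return "a2" if self.silenced_allele == "a1" else "a1"

    def flipped(self) -> "Orientation":
        return Orientation(self.active_allele)


def _as_orientation(orientation) -> Orientation:
    if isinstance(orientation, Orientation):
        return orientation
    return Orientation(str(orientation))


def repression_score_raw(active_0, active_i, silenced_0, silenced_i):
    """Unclipped score; NaN wherever a baseline value is not positive."""
    active_0 = np.asarray(active_0, dtype=float)
    active_i = np.asarray(active_i, dtype=float)
    silenced_0 = np.asarray(silenced_0, dtype=float)
    silenced_i = np.asarray(silenced_i, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (active_i - active_0) / active_0 - (silenced_i - silenced_0) / silenced_0
    raw = np.where((active_0 > 0) & (silenced_0 > 0), raw, np.nan)
    if raw.ndim == 0:
        return float(raw)
    return raw


def repression_score(active_0, active_i, silenced_0, silenced_i):
    """Repression score clipped to [0, 1]; NaN where undefined."""
    raw = repression_score_raw(active_0, active_i, silenced_0, silenced_i)
    return np.clip(raw, 0.0, 1.0) if np.ndim(raw) else (
        float(np.clip(raw, 0.0, 1.0)) if not np.isnan(raw) else float("nan")
    )


def _condition_samples(samples: pd.DataFrame, condition: str) -> pd.DataFrame:
    sel = samples[samples["condition"] == condition]
    if sel.empty:
        raise ValueError(f"no samples for condition {condition!r}")
    return sel


def rs_table(
    expr: AllelicExpression,
    orientation,
    baseline_condition: str = "NoDox",
    treated_condition: str = "Dox",
    baseline: str = "pooled",
) -> pd.DataFrame:
    """Per-gene repression scores for one orientation.

    The baseline allelic expression is either the mean over all baseline
    replicates (``baseline='pooled'``, default) or the replicate-matched
    baseline sample (``baseline='matched'``).  The score is computed per
    treated replicate and averaged; genes failing the expression filter
    or with an undefined score in every replicate are excluded.

    Returns a frame indexed by gene id with gene coordinates,
    per-replicate ``rs_rep<i>`` columns, the averaged ``rs_raw`` and
    ``rs``, and the orientation recorded in ``attrs``.
    """
    orientation = _as_orientation(orientation)
    if baseline not in ("pooled", "matched"):
        raise ValueError("baseline must be 'pooled' or 'matched'")
    base_samples = _condition_samples(expr.samples, baseline_condition)
    treat_samples = _condition_samples(expr.samples, treated_condition)

    sil = expr.expr_a1 if orientation.silenced_allele == "a1" else expr.expr_a2
    act = expr.expr_a2 if orientation.silenced_allele == "a1" else expr.expr_a1

    if baseline == "pooled":
        act_0 = act[base_samples.index].mean(axis=1).to_numpy()
        sil_0 = sil[base_samples.index].mean(axis=1).to_numpy()

    rep_cols: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    raw_cols: dict[int, np.ndarray] = {}
    clipped_cols: dict[int, np.ndarray] = {}
    for rep, sid_i in zip(treat_samples["replicate"], treat_samples.index):
        if baseline == "matched":
            match = base_samples.index[base_samples["replicate"] == rep]
            if match.empty:
                raise ValueError(
                    f"no baseline replicate matching treated replicate {rep}"
                )
            act_0 = act[match[0]].to_numpy()
            sil_0 = sil[match[0]].to_numpy()
        raw = repression_score_raw(
            act_0, act[sid_i].to_numpy(), sil_0, sil[sid_i].to_numpy()
        )
        raw_cols[rep] = raw
        clipped_cols[rep] = np.clip(raw, 0.0, 1.0)

    table = expr.genes[["chrom", "start", "end"]].copy()
    for rep in sorted(clipped_cols):
        table[f"rs_rep{rep}"] = clipped_cols[rep]
    raw_stack = np.column_stack([raw_cols[rep] for rep in sorted(raw_cols)])
    clip_stack = np.column_stack([clipped_cols[rep] for rep in sorted(clipped_cols)])
    def _row_nanmean(stack: np.ndarray) -> np.ndarray:
        valid = ~np.isnan(stack)
        count = valid.sum(axis=1)
        total = np.where(valid, stack, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    table["rs_raw"] = _row_nanmean(raw_stack)
    table["rs"] = _row_nanmean(clip_stack)

    keep = expr.mask.reindex(table.index, fill_value=False) & table["rs"].notna()
    table = table[keep]
    table.attrs["orientation"] = orientation.silenced_allele
    table.attrs["baseline_condition"] = baseline_condition
    table.attrs["treated_condition"] = treated_condition
    return table


def random_rs(
    rs_tab: pd.DataFrame,
    control: pd.DataFrame | None = None,
    candidate_chrom: str | None = None,
) -> pd.Series:
    """Background ("random") repression score per gene.

    With a matched ``control`` score table (an independent control line,
    same orientation), the control line's per-gene rs is used.  Otherwise
    the scalar median rs over all genes *not* on ``candidate_chrom`` is
    broadcast to every gene.
    """
    if control is not None:
        rrs = control["rs"].reindex(rs_tab.index)
        rrs.name = "rrs"
        return rrs
    if candidate_chrom is None:
        raise ValueError("either a control table or candidate_chrom is required")
    others = rs_tab[rs_tab["chrom"] != candidate_chrom]
    if others.empty:
        raise ValueError(f"no genes outside candidate chromosome {candidate_chrom!r}")
    value = float(others["rs"].median())
    return pd.Series(value, index=rs_tab.index, name="rrs")


def calibrated_rs(rs, rrs):
    """cRS = RS - rRS.  Not re-clipped; may be negative."""
    result = np.asarray(rs, dtype=float) - np.asarray(rrs, dtype=float)
    if isinstance(rs, pd.Series):
        return pd.Series(result, index=rs.index, name="crs")
    if result.ndim == 0:
        return float(result)
    return result


@dataclass
class TransgeneCall:
    """Result of transgene chromosome/allele inference.

    ``scores`` counts significantly repressed genes per chromosome (rows)
    and orientation (columns); ``status`` is 'ok' or 'undetected'.
    """

    chrom: str | None
    silenced_allele: str | None
    scores: pd.DataFrame
    status: str = "ok"


def detect_transgene(
    expr: AllelicExpression,
    counts=None,
    n_perm: int = 1000,
    seed: int = 0,
    q_max: float = 0.05,
    crs_min: float = 0.1,
    baseline: str = "pooled",
    allelic_p: str | float = "pooled_nodox",
) -> TransgeneCall:
    """Infer the transgene-bearing chromosome and the silenced allele.

    Both orientations are scanned genome-wide; per gene a permutation
    p-value is computed per replicate, replicates are combined, and
    q-values are assigned chromosome-wide.  The chromosome/orientation
    pair with the largest number of significant silent genes wins; ties
    break toward the higher median rs on the winning chromosome, then
    lexicographic chromosome order.  When no gene is significant
    anywhere the call is ``(None, None)`` with status ``'undetected'``.
    """
    from silencescan import significance as sig

    if counts is None:
        raise ValueError("detect_transgene requires the count matrix for permutation")
    chroms = sorted(expr.genes["chrom"].unique())
    if len(chroms) < 2:
        raise ValueError("at least 2 chromosomes are required")

    n_silent = pd.DataFrame(0, index=chroms, columns=["a1", "a2"], dtype=int)
    median_rs = pd.DataFrame(np.nan, index=chroms, columns=["a1", "a2"])
    for allele in ("a1", "a2"):
        tab = rs_table(expr, allele, baseline=baseline)
        pvals = sig.permutation_pvalues(
            counts,
            tab,
            orientation=allele,
            n_perm=n_perm,
            seed=seed,
            allelic_p=allelic_p,
            baseline=baseline,
        )
        combined = sig.combine_replicates(pvals, n_perm=n_perm)
        tab = tab.join(combined, how="inner")
        for chrom in chroms:
            on = tab[tab["chrom"] == chrom]
            if on.empty:
                continue
            rrs = random_rs(tab, candidate_chrom=chrom)
            crs = calibrated_rs(on["rs"], rrs.loc[on.index])
            q = sig.bh_adjust(on["p_combined"])
            silent = sig.call_silent(crs, q, crs_min=crs_min, q_max=q_max)
            n_silent.loc[chrom, allele] = int(silent.sum())
            median_rs.loc[chrom, allele] = float(on["rs"].median())

    best = n_silent.max().max()
    if best <= 0:
        import warnings

        warnings.warn(
            "no significantly repressed genes on any chromosome; "
            "transgene-bearing chromosome undetectable",
            stacklevel=2,
        )
        return TransgeneCall(None, None, n_silent, status="undetected")

    candidates = [
        (chrom, allele)
        for chrom in chroms
        for allele in ("a1", "a2")
        if n_silent.loc[chrom, allele] == best
    ]
    # ties: higher median rs on the winning chromosome, then name order
    candidates.sort(key=lambda ca: (-median_rs.loc[ca[0], ca[1]], ca[0], ca[1]))
    chrom, allele = candidates[0]
    return TransgeneCall(chrom, allele, n_silent, status="ok")
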