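"""Allelic ATAC-seq accessibility differential (ddscore).

Per genomic element the allelic accessibility difference G1 - G2 is
computed per condition on library-size-normalized counts (per 10 million
mapped reads); the ddscore is the Dox-minus-NoDox change of that
difference.  Negative values on the transgene chromosome indicate
induction-driven accessibility loss on the G1 (Cast) allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AtacAllelicTrack",
    "normalize_atac",
    "ddscore",
    "ddscore_track",
    "aggregate_by_state",
    "rank_sum_compare",
]


@dataclass
class AtacAllelicTrack:
    """Allelic fragment counts per interval per sample.

    ``intervals`` is a sorted half-open BED-like table (``chrom``,
    ``start``, ``end``, optional ``state``); ``a1``/``a2`` are count
    arrays of shape (n_intervals, n_samples); ``mapped_totals`` holds the
    per-sample mapped-read totals used for normalization.
    """

    intervals: pd.DataFrame
    samples: pd.DataFrame
    a1: np.ndarray
    a2: np.ndarray
    mapped_totals: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.intervals), len(self.samples))
        for name in ("a1", "a2"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if np.any(arr < 0):
                raise ValueError(f"negative counts in {name}")
            setattr(self, name, arr.astype(np.int64, copy=False))
        self.mapped_totals = np.asarray(self.mapped_totals, dtype=np.int64)
        if self.mapped_totals.shape != (len(self.samples),):
            raise ValueError("mapped_totals must have one entry per sample")
        if (self.intervals["end"] <= self.intervals["start"]).any():
            raise ValueError("intervals must be half-open with end > start")

    def sample_ids(self, condition: str | None = None) -> list:
        sel = self.samples
        if condition is not None:
            sel = sel[sel["condition"] == condition]
        return list(sel.index)


def normalize_atac(
    counts: np.ndarray | float, mapped_total: np.ndarray | float
) -> np.ndarray | float:
    """Scale counts to coverage per 10 million mapped reads."""
    mapped = np.asarray(mapped_total, dtype=float)
    if np.any(mapped <= 0):
        raise ValueError("mapped_total must be positive")
    return np.asarray(counts, dtype=float) * 1e7 / mapped


def ddscore(g1_dox, g2_dox, g1_nodox, g2_nodox):
    """``[G1(Dox) - G2(Dox)] - [G1(NoDox) - G2(NoDox)]`` on normalized inputs."""
    g1_dox = np.asarray(g1_dox, dtype=float)
    g2_dox = np.asarray(g2_dox, dtype=float)
    g1_nodox = np.asarray(g1_nodox, dtype=float)
    g2_nodox = np.asarray(g2_nodox, dtype=float)
    result = (g1_dox - g2_dox) - (g1_nodox - g2_nodox)
    if result.ndim == 0:
        return float(result)
    return result


def ddscore_track(track: AtacAllelicTrack) -> pd.DataFrame:
    """Per-interval ddscore, per replicate pair and averaged.

    Replicate ``i`` of the Dox condition is paired with replicate ``i``
    of NoDox; per-replicate columns ``ddscore_rep<i>`` are retained and
    ``ddscore`` is their mean.
    """
    nodox = track.samples[track.samples["condition"] == "NoDox"]
    dox = track.samples[track.samples["condition"] == "Dox"]
    if nodox.empty or dox.empty:
        raise ValueError("both NoDox and Dox samples are required")
    reps = sorted(set(nodox["replicate"]) & set(dox["replicate"]))
    if not reps:
        raise ValueError("no matching replicates between conditions")

    pos = {sid: i for i, sid in enumerate(track.samples.index)}
    out = track.intervals.copy()
    per_rep = []
    for rep in reps:
        sid_0 = nodox.index[nodox["replicate"] == rep][0]
        sid_i = dox.index[dox["replicate"] == rep][0]
        i0, ii = pos[sid_0], pos[sid_i]
        g1_0 = normalize_atac(track.a1[:, i0], track.mapped_totals[i0])
        g2_0 = normalize_atac(track.a2[:, i0], track.mapped_totals[i0])
        g1_i = normalize_atac(track.a1[:, ii], track.mapped_totals[ii])
        g2_i = normalize_atac(track.a2[:, ii], track.mapped_totals[ii])
        col = f"ddscore_rep{rep}"
        out[col] = ddscore(g1_i, g2_i, g1_0, g2_0)
        per_rep.append(col)
    out["ddscore"] = out[per_rep].mean(axis=1)
    return out


def aggregate_by_state(dds: pd.DataFrame) -> pd.DataFrame:
    """Mean ddscore per chromatin state per chromosome.

    Expects a frame with ``chrom``, ``state`` and ``ddscore`` columns
    (the output of :func:`ddscore_track`).  States with no intervals on a
    chromosome are simply absent; an entirely empty input produces an
    empty result with a warning.
    """
    required = {"chrom", "state", "ddscore"}
    missing = required - set(dds.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if dds.empty:
        warnings.warn("no intervals to aggregate", stacklevel=2)
        return pd.DataFrame(columns=["chrom", "state", "mean_ddscore", "n_intervals"])
    grouped = (
        dds.groupby(["chrom", "state"], sort=True)["ddscore"]
        .agg(mean_ddscore="mean", n_intervals="size")
        .reset_index()
    )
    return grouped


def _exact_rank_sum(target: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney by full enumeration of group assignments."""
    pooled = np.concatenate([target, control])
    n1, n2 = len(target), len(control)
    n = n1 + n2
    # pairwise win matrix: 1 if pooled[i] > pooled[j], 0.5 on ties
    greater = (pooled[:, None] > pooled[None, :]).astype(float)
    greater += 0.5 * (pooled[:, None] == pooled[None, :])
    mu = n1 * n2 / 2.0

    def u_for(idx: tuple[int, ...]) -> float:
        rest = [j for j in range(n) if j not in idx]
        return float(greater[np.ix_(idx, rest)].sum())

    u_obs = u_for(tuple(range(n1)))
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(u_for(idx) - mu) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


def rank_sum_compare(
    target, control, exact: bool | None = None
) -> tuple[float, float]:
    """Mann-Whitney U comparison of two value sets.

    Returns ``(U, two-sided p)`` with U counted for ``target``.  Uses
    exact enumeration of all group assignments when both samples have
    at most 8 values (or when ``exact=True``); otherwise the normal
    approximation with tie and continuity correction.
    """
    target = np.asarray(target, dtype=float)
    control = np.asarray(control, dtype=float)
    if target.size == 0 or control.size == 0:
        raise ValueError("both samples must be non-empty")
    if exact is None:
        exact = target.size <= 8 and control.size <= 8
    if exact:
        return _exact_rank_sum(target, control)
    res = stats.mannwhitneyu(
        target, control, alternative="two-sided", method="asymptotic"
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
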