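"""Plain-text readers and writers (TSV, BED, bedGraph).

All files are UTF-8 with Unix newlines.  Count tables carry one sample
per file with the columns ``gene_id chrom start end strand total a1 a2``;
sample identity (condition, replicate) is encoded in the file name as
``counts_<condition>_rep<r>.tsv``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from silencescan.quant import AllelicCounts
from silencescan.atac import AtacAllelicTrack

__all__ = [
    "write_counts",
    "read_counts",
    "write_annotation_bed",
    "read_annotation_bed",
    "write_rs_table",
    "read_rs_table",
    "write_expression",
    "write_ground_truth",
    "read_ground_truth",
    "write_atac_track",
    "read_atac_track",
    "write_bedgraph",
    "write_run_metadata",
]

COUNT_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "total", "a1", "a2"]
_COUNT_FILE_RE = re.compile(r"counts_(?P<condition>[^_]+)_rep(?P<rep>\d+)\.tsv$")


def write_counts(counts: AllelicCounts, outdir) -> list[Path]:
    """One TSV per sample; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s, (sid, sample) in enumerate(counts.samples.iterrows()):
        frame = counts.genes.reset_index()[["gene_id", "chrom", "start", "end"]].copy()
        frame["strand"] = counts.genes.get(
            "strand", pd.Series("+", index=counts.genes.index)
        ).to_numpy()
        frame["total"] = counts.total[:, s]
        frame["a1"] = counts.a1[:, s]
        frame["a2"] = counts.a2[:, s]
        path = outdir / f"counts_{sample['condition']}_rep{sample['replicate']}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_counts(indir) -> AllelicCounts:
    """Load a directory of per-sample count tables."""
    indir = Path(indir)
    files = sorted(indir.glob("counts_*_rep*.tsv"))
    if not files:
        raise FileNotFoundError(f"no count tables found in {indir}")
    frames = {}
    sample_rows = []
    for path in files:
        match = _COUNT_FILE_RE.search(path.name)
        if not match:
            raise ValueError(f"unrecognized count file name: {path.name}")
        condition = match["condition"]
        replicate = int(match["rep"])
        sid = f"{condition}_rep{replicate}"
        try:
            frame = pd.read_csv(path, sep="\t")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        missing = set(COUNT_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        frames[sid] = frame.set_index("gene_id")
        sample_rows.append(
            {"sample_id": sid, "condition": condition, "replicate": replicate}
        )
    samples = (
        pd.DataFrame(sample_rows)
        .sort_values(["condition", "replicate"], ascending=[False, True])
        .set_index("sample_id")
    )
    first = frames[samples.index[0]]
    genes = first[["chrom", "start", "end", "strand"]].copy()
    total = np.zeros((len(genes), len(samples)), dtype=np.int64)
    a1 = np.zeros_like(total)
    a2 = np.zeros_like(total)
    for s, sid in enumerate(samples.index):
        frame = frames[sid].reindex(genes.index)
        if frame[["total", "a1", "a2"]].isna().any().any():
            raise ValueError(f"sample {sid}: gene set differs from other samples")
        total[:, s] = frame["total"].to_numpy()
        a1[:, s] = frame["a1"].to_numpy()
        a2[:, s] = frame["a2"].to_numpy()
    return AllelicCounts(genes=genes, samples=samples, total=total, a1=a1, a2=a2)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    """BED6: chrom, start, end, gene id, score 0, strand."""
    frame = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation.index,
            "score": 0,
            "strand": annotation.get("strand", "+"),
        }
    )
    frame.to_csv(path, sep="\t", index=False, header=False)


def read_annotation_bed(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
    )
    return frame.set_index("gene_id")[["chrom", "start", "end", "strand"]]


def write_rs_table(rs_tab: pd.DataFrame, path) -> None:
    """TSV with the orientation recorded in a header comment line."""
    path = Path(path)
    with open(path, "w") as handle:
        orientation = rs_tab.attrs.get("orientation", "unknown")
        handle.write(f"# orientation: silenced={orientation}\n")
        rs_tab.to_csv(handle, sep="\t", index_label="gene_id")


def read_rs_table(path) -> pd.DataFrame:
    path = Path(path)
    orientation = None
    with open(path) as handle:
        first = handle.readline()
        if first.startswith("#"):
            match = re.search(r"silenced=(\w+)", first)
            orientation = match.group(1) if match else None
    frame = pd.read_csv(path, sep="\t", comment="#").set_index("gene_id")
    if orientation:
        frame.attrs["orientation"] = orientation
    return frame


def write_expression(expr, path) -> None:
    """Long-format expression table with the filter mask column."""
    frames = []
    for sid in expr.samples.index:
        frame = pd.DataFrame(
            {
                "gene_id": expr.cpm.index,
                "sample_id": sid,
                "cpm": expr.cpm[sid].to_numpy(),
                "expr_a1": expr.expr_a1[sid].to_numpy(),
                "expr_a2": expr.expr_a2[sid].to_numpy(),
                "keep": expr.mask.to_numpy(),
            }
        )
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_ground_truth(truth, path) -> None:
    frame = pd.DataFrame(
        {"true_rs": truth.true_rs, "affected": truth.affected.astype(int)}
    )
    with open(path, "w") as handle:
        handle.write(
            f"# transgene_chrom={truth.transgene_chrom} "
            f"silenced_allele={truth.silenced_allele}\n"
        )
        frame.to_csv(handle, sep="\t", index_label="gene_id")


def read_ground_truth(path):
    from silencescan.simulate import GroundTruth

    with open(path) as handle:
        header = handle.readline().strip()
    match = re.search(r"transgene_chrom=(\S+) silenced_allele=(\S+)", header)
    chrom, allele = match.group(1), match.group(2)
    frame = pd.read_csv(path, sep="\t", comment="#").set_index("gene_id")
    return GroundTruth(
        true_rs=frame["true_rs"],
        transgene_chrom=None if chrom == "None" else chrom,
        silenced_allele=allele,
        affected=frame["affected"].astype(bool),
    )


def write_atac_track(track: AtacAllelicTrack, outdir) -> list[Path]:
    """BED intervals plus per-sample allelic count columns; one file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = track.intervals.copy()
    for s, sid in enumerate(track.samples.index):
        frame[f"a1_{sid}"] = track.a1[:, s]
        frame[f"a2_{sid}"] = track.a2[:, s]
    path = outdir / "atac_counts.tsv"
    frame.to_csv(path, sep="\t", index=False)
    meta = outdir / "atac_mapped_totals.tsv"
    pd.DataFrame(
        {
            "sample_id": track.samples.index,
            "condition": track.samples["condition"].to_numpy(),
            "replicate": track.samples["replicate"].to_numpy(),
            "mapped_total": track.mapped_totals,
        }
    ).to_csv(meta, sep="\t", index=False)
    return [path, meta]


def read_atac_track(indir) -> AtacAllelicTrack:
    indir = Path(indir)
    frame = pd.read_csv(indir / "atac_counts.tsv", sep="\t")
    meta = pd.read_csv(indir / "atac_mapped_totals.tsv", sep="\t")
    samples = meta.set_index("sample_id")[["condition", "replicate"]]
    interval_cols = [c for c in frame.columns if not re.match(r"a[12]_", c)]
    intervals = frame[interval_cols].copy()
    a1 = np.column_stack([frame[f"a1_{sid}"].to_numpy() for sid in samples.index])
    a2 = np.column_stack([frame[f"a2_{sid}"].to_numpy() for sid in samples.index])
    return AtacAllelicTrack(
        intervals=intervals,
        samples=samples,
        a1=a1,
        a2=a2,
        mapped_totals=meta["mapped_total"].to_numpy(),
    )


def write_bedgraph(frame: pd.DataFrame, path, value_column: str = "ddscore") -> None:
    """4-column bedGraph (chrom, start, end, value)."""
    frame[["chrom", "start", "end", value_column]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_run_metadata(path, **params) -> None:
    """JSON sidecar recording version, seed and parameters."""
    from silencescan import __version__

    payload = {"version": __version__, **params}
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")
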