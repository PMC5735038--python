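# silencescan

Allele-specific chromosome silencing analysis for hybrid-line nascent-RNA
experiments: per-gene repression scores on allele-split count tables,
permutation-based significance, window scans for the maximum-silencing
region, transgene chromosome/allele inference, and an allelic ATAC-seq
accessibility differential (ddscore). A synthetic-data generator emulates
the allelic count structure, so the whole pipeline runs end-to-end with no
external data.

## Method overview

Inputs are gene-level allelic count tables (total read pairs plus
allele-1/allele-2 assignable counts per gene, one table per sample) for an
untreated baseline (NoDox) and an induced condition (Dox), from a cross
with two distinguishable alleles (allele 1 = Cast/G1, allele 2 = 129S1/G2).

1. **Quantification** — counts are normalized to CPM per library and split
   into per-allele expression by the assignable-read ratio; genes below
   configurable expression filters are dropped.
2. **Repression score (RS)** — per gene, under an *orientation* that
   designates the putatively silenced allele:
   `rs = clip((active_i − active_0)/active_0 − (silenced_i − silenced_0)/silenced_0, 0, 1)`.
   A calibrated score `crs = rs − rrs` subtracts a background RS estimated
   from a matched control line or from all other chromosomes.
3. **Significance** — allele-assignable reads are re-split binomially
   (totals, and hence CPM, held fixed), the RS recomputed through the
   identical path 10,000 times per gene, and `p = #{RS_null ≥ RS_obs}/N`.
   Per-replicate p-values are Fisher-combined and BH-adjusted; a gene is
   *silent* when `q < 0.05` and `crs > 0.1` (both configurable).
4. **Transgene inference** — both orientations are scanned over all
   chromosomes; the chromosome with the most significant silent genes
   wins.
5. **Window scan** — chromosomes are tiled with 10/5/3 Mb half-open
   windows; the maximum-silencing region is the window with the highest
   median rs among windows with ≥ 5 genes.
6. **ATAC ddscore** — per element,
   `ddscore = [G1(Dox) − G2(Dox)] − [G1(NoDox) − G2(NoDox)]` on coverage
   normalized per 10 M mapped reads, aggregated per chromatin state and
   compared between chromosomes with a Mann-Whitney test (exact
   enumeration for small samples).

## Command line

```sh
# simulate a dataset (counts + annotation + ground truth + ATAC)
silencescan simulate --config scenario.yaml --out sim/ --atac

# score: orientation auto-detection, permutation significance, silent calls
silencescan score --counts sim/ --out scored/ --n-perm 10000 --seed 1

# window scans and maximum-silencing regions at 10/5/3 Mb
silencescan scan --rs-table scored/rs_table.tsv --out scan/ --windows 10,5,3

# allelic accessibility ddscores and per-state aggregates
silencescan atac --atac sim/ --out atac/ --target-chrom chr5

# per-chromosome silent-gene summary
silencescan report --rs-table scored/rs_table.tsv --out report.tsv

# printed-percentage consistency check
silencescan fraction-check 9471317 23005850 41.17
```

A scenario YAML holds any subset of the `SimulationScenario` fields, e.g.

```yaml
n_chromosomes: 20
genes_per_chromosome: 150
transgene_chrom: chr5
silenced_allele: a1
repressed_fraction: 0.6
repression_strength: 0.5
library_size: 4000000
seed: 1
```

All outputs are plain TSV / BED / bedGraph with a JSON run-metadata
sidecar; reruns with the same seed and config are byte-identical.

## Layout

- `src/silencescan/simulate.py` — scenario configuration and the
  negative-binomial / beta-binomial allelic count generator with ground
  truth
- `src/silencescan/quant.py` — CPM, allelic split, expression filters
- `src/silencescan/score.py` — RS/cRS/rRS, orientation handling, transgene
  inference
- `src/silencescan/significance.py` — permutation p-values, Fisher
  combination, BH, silent calls
- `src/silencescan/windows.py` — window binning, maximum-silencing region,
  RS categories, percentages
- `src/silencescan/atac.py` — normalization, ddscore, state aggregation,
  rank-sum comparison
- `src/silencescan/io.py`, `cli.py`, `report.py` — text formats, CLI,
  summaries
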