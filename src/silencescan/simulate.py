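"""Synthetic allelic count data with known cis-repression ground truth.

The generator emulates the count structure the analysis consumes: a
hybrid line with two distinguishable alleles per gene, two conditions
(NoDox baseline, Dox induction), replicate libraries, and one optional
transgene-bearing chromosome on which induction represses one allele in
cis.

Generative model per gene g and sample s:

* base expression ``b_g ~ Gamma(shape=2, mean=baseline_mean)``, scaled so
  the expected library total matches ``library_size``;
* per-gene allelic ratio ``rho_g ~ Beta(c/2, c/2)`` (allele-1 share),
  concentration ``c = allelic_balance_concentration``;
* true repression ``r_g`` = ``repression_strength`` for the affected
  subset of transgene-chromosome genes, optionally decayed with distance
  from the integration site; 0 elsewhere and in NoDox samples;
* repression removes a fraction ``r_g`` of the silenced allele's
  expression, so the gene's expected total drops to
  ``mu_g * (1 - rho_sil * r_g)`` and the silenced allele's expected share
  of what remains is ``rho_sil * (1 - r_g) / (1 - rho_sil * r_g)``;
* total ~ NegativeBinomial(mean, dispersion); allele-assignable reads ~
  Binomial(total, informative_fraction); allele split ~ Binomial on the
  assignable reads.

Random streams are split per gene and per (gene, condition, replicate)
from the scenario seed, so adding replicates or samples never perturbs
existing draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from silencescan.quant import AllelicCounts
from silencescan.atac import AtacAllelicTrack

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "simulate_genome",
    "simulate_allelic_counts",
    "simulate_atac_counts",
]

CONDITIONS = ("NoDox", "Dox")

# spawn-key namespaces for the per-scenario random tree
_KEY_GENOME = 0
_KEY_GENE = 1
_KEY_COUNTS = 2
_KEY_AFFECTED = 3
_KEY_ATAC_INTERVAL = 4
_KEY_ATAC_COUNTS = 5


@dataclass
class SimulationScenario:
    """Configuration of one synthetic dataset.

    ``transgene_chrom=None`` produces a global null (no gene carries any
    true repression).  ``repression_strength`` is the expected fractional
    loss of the silenced allele's expression, i.e. the true repression
    score of an affected gene.
    """

    n_chromosomes: int = 3
    chrom_lengths: dict[str, int] | None = None
    genes_per_chromosome: int = 100
    baseline_mean: float = 500.0
    dispersion: float = 10.0
    allelic_balance_concentration: float = 50.0
    transgene_chrom: str | None = None
    silenced_allele: str = "a1"
    repressed_fraction: float = 0.6
    repression_strength: float = 0.5
    integration_site: int = 0
    distance_decay_halflife: float | None = None
    n_replicates: int = 2
    library_size: int = 1_000_000
    informative_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_lengths is None:
            self.chrom_lengths = {
                f"chr{i + 1}": 100_000_000 for i in range(self.n_chromosomes)
            }
        else:
            self.chrom_lengths = dict(self.chrom_lengths)
            self.n_chromosomes = len(self.chrom_lengths)
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.genes_per_chromosome < 1:
            raise ValueError("genes_per_chromosome must be >= 1")
        for name in ("repressed_fraction", "repression_strength"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.informative_fraction <= 1.0:
            raise ValueError("informative_fraction must lie in (0, 1]")
        if self.silenced_allele not in ("a1", "a2"):
            raise ValueError("silenced_allele must be 'a1' or 'a2'")
        if self.transgene_chrom is not None and (
            self.transgene_chrom not in self.chrom_lengths
        ):
            raise ValueError(
                f"transgene_chrom {self.transgene_chrom!r} not in chrom_lengths"
            )
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean and dispersion must be positive")
        if self.allelic_balance_concentration <= 0:
            raise ValueError("allelic_balance_concentration must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")

    @property
    def conditions(self) -> tuple[str, str]:
        return CONDITIONS

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimulationScenario":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)


@dataclass
class GroundTruth:
    """Per-gene true repression score and the transgene configuration."""

    true_rs: pd.Series
    transgene_chrom: str | None
    silenced_allele: str
    affected: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.affected is None:
            self.affected = self.true_rs > 0
        self.affected.name = "affected"
        self.true_rs.name = "true_rs"


def _rng(scenario: SimulationScenario, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=key))


def simulate_genome(scenario: SimulationScenario) -> pd.DataFrame:
    """Place genes uniformly on each chromosome.

    Returns a BED-like annotation (``chrom``, ``start``, ``end``,
    ``strand``) indexed by gene id, sorted by chromosome then start,
    0-based half-open.  Deterministic for a given scenario seed.
    """
    records = []
    for chrom_index, (chrom, length) in enumerate(scenario.chrom_lengths.items()):
        rng = _rng(scenario, _KEY_GENOME, chrom_index)
        n = scenario.genes_per_chromosome
        starts = np.sort(rng.integers(0, length, size=n))
        max_len = max(1, min(100_000, length // max(n, 1)))
        lengths = rng.integers(1, max_len + 1, size=n)
        ends = np.minimum(starts + lengths, length)
        ends = np.maximum(ends, starts + 1)
        ends = np.minimum(ends, length)
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        for j in range(n):
            records.append(
                {
                    "gene_id": f"{chrom}_g{j:04d}",
                    "chrom": chrom,
                    "start": int(starts[j]),
                    "end": int(ends[j]),
                    "strand": strands[j],
                }
            )
    annotation = pd.DataFrame.from_records(records).set_index("gene_id")
    return annotation


def _gene_params(
    annotation: pd.DataFrame, scenario: SimulationScenario
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene base expression and allele-1 share, one stream per gene."""
    n = len(annotation)
    base = np.empty(n)
    rho = np.empty(n)
    c = scenario.allelic_balance_concentration
    for i in range(n):
        rng = _rng(scenario, _KEY_GENE, i)
        base[i] = rng.gamma(shape=2.0, scale=scenario.baseline_mean / 2.0)
        rho[i] = rng.beta(c / 2.0, c / 2.0)
    return base, rho


def _true_rs(annotation: pd.DataFrame, scenario: SimulationScenario) -> np.ndarray:
    """True repression score per gene (0 off the transgene chromosome)."""
    true_rs = np.zeros(len(annotation))
    if scenario.transgene_chrom is None or scenario.repression_strength == 0:
        return true_rs
    on_tg = (annotation["chrom"] == scenario.transgene_chrom).to_numpy()
    idx = np.flatnonzero(on_tg)
    if idx.size == 0:
        return true_rs
    rng = _rng(scenario, _KEY_AFFECTED)
    n_affected = int(round(scenario.repressed_fraction * idx.size))
    affected = rng.choice(idx, size=n_affected, replace=False)
    strength = np.full(affected.size, scenario.repression_strength)
    if scenario.distance_decay_halflife:
        mid = (
            annotation["start"].to_numpy()[affected]
            + annotation["end"].to_numpy()[affected]
        ) / 2.0
        distance = np.abs(mid - scenario.integration_site)
        strength = strength * np.exp(
            -np.log(2.0) * distance / scenario.distance_decay_halflife
        )
    true_rs[affected] = strength
    return true_rs


def simulate_allelic_counts(
    annotation: pd.DataFrame, scenario: SimulationScenario
) -> tuple[AllelicCounts, GroundTruth]:
    """Draw total and allele-split counts for every gene and sample.

    Returns the count matrix together with the per-gene ground truth.
    Conservation (``a1 + a2 <= total``) holds by construction, and
    identical scenario + seed give bit-identical output.
    """
    if not annotation["chrom"].isin(scenario.chrom_lengths).all():
        raise ValueError("annotation contains chromosomes absent from the scenario")
    n_genes = len(annotation)
    base, rho = _gene_params(annotation, scenario)
    true_rs = _true_rs(annotation, scenario)

    # deterministic scaling to the target library size (expected totals)
    scale = scenario.library_size / (n_genes * scenario.baseline_mean)
    mu = base * scale

    samples = []
    for cond_index, condition in enumerate(CONDITIONS):
        for rep in range(1, scenario.n_replicates + 1):
            samples.append(
                {
                    "sample_id": f"{condition}_rep{rep}",
                    "condition": condition,
                    "replicate": rep,
                    "_cond_index": cond_index,
                }
            )
    sample_table = pd.DataFrame(samples).set_index("sample_id")

    rho_sil = rho if scenario.silenced_allele == "a1" else 1.0 - rho
    k = scenario.dispersion

    total = np.zeros((n_genes, len(sample_table)), dtype=np.int64)
    a1 = np.zeros_like(total)
    a2 = np.zeros_like(total)
    for s, (_, sample) in enumerate(sample_table.iterrows()):
        dox = sample["condition"] == "Dox"
        r = true_rs if dox else np.zeros(n_genes)
        mean_total = mu * (1.0 - rho_sil * r)
        with np.errstate(invalid="ignore", divide="ignore"):
            share_sil = np.where(
                mean_total > 0, rho_sil * (1.0 - r) / (1.0 - rho_sil * r), 0.0
            )
        p_a1 = share_sil if scenario.silenced_allele == "a1" else 1.0 - share_sil
        for g in range(n_genes):
            rng = _rng(
                scenario,
                _KEY_COUNTS,
                g,
                int(sample["_cond_index"]),
                int(sample["replicate"]),
            )
            t = rng.negative_binomial(k, k / (k + mean_total[g]))
            assignable = rng.binomial(t, scenario.informative_fraction)
            g1 = rng.binomial(assignable, p_a1[g])
            total[g, s] = t
            a1[g, s] = g1
            a2[g, s] = assignable - g1
    sample_table = sample_table.drop(columns="_cond_index")
    counts = AllelicCounts(
        genes=annotation.copy(),
        samples=sample_table,
        total=total,
        a1=a1,
        a2=a2,
    )
    truth = GroundTruth(
        true_rs=pd.Series(true_rs, index=annotation.index),
        transgene_chrom=scenario.transgene_chrom,
        silenced_allele=scenario.silenced_allele,
    )
    return counts, truth


def _validate_elements(elements: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "start", "end"}
    missing = required - set(elements.columns)
    if missing:
        raise ValueError(f"element table missing columns: {sorted(missing)}")
    if (elements["end"] <= elements["start"]).any():
        raise ValueError("malformed intervals: end must exceed start")
    elements = elements.sort_values(["chrom", "start"]).reset_index(drop=True)
    for chrom, group in elements.groupby("chrom", sort=False):
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping intervals on {chrom}")
    return elements


def simulate_atac_counts(
    elements: pd.DataFrame,
    scenario: SimulationScenario,
    reduction: float | None = None,
) -> AtacAllelicTrack:
    """Draw allelic ATAC fragment counts per interval.

    ``elements`` is a BED-like table with ``chrom``, ``start``, ``end``
    and optionally ``state``.  On the transgene chromosome under Dox the
    silenced allele's accessibility mean is multiplied by
    ``1 - reduction`` (default: ``scenario.repression_strength``).
    Mapped-read totals are fixed at ``scenario.library_size`` per sample
    so normalized expectations are exact.
    """
    elements = _validate_elements(elements)
    if "state" not in elements.columns:
        elements = elements.assign(state="element")
    if reduction is None:
        reduction = scenario.repression_strength
    if not 0.0 <= reduction <= 1.0:
        raise ValueError("reduction must lie in [0, 1]")
    n = len(elements)

    c = scenario.allelic_balance_concentration
    mu = np.empty(n)
    rho = np.empty(n)
    for i in range(n):
        rng = _rng(scenario, _KEY_ATAC_INTERVAL, i)
        mu[i] = rng.gamma(shape=2.0, scale=scenario.baseline_mean / 2.0)
        rho[i] = rng.beta(c / 2.0, c / 2.0)

    on_tg = (
        (elements["chrom"] == scenario.transgene_chrom).to_numpy()
        if scenario.transgene_chrom is not None
        else np.zeros(n, dtype=bool)
    )

    samples = []
    for cond_index, condition in enumerate(CONDITIONS):
        for rep in range(1, scenario.n_replicates + 1):
            samples.append(
                {
                    "sample_id": f"{condition}_rep{rep}",
                    "condition": condition,
                    "replicate": rep,
                    "_cond_index": cond_index,
                }
            )
    sample_table = pd.DataFrame(samples).set_index("sample_id")

    k = scenario.dispersion
    a1 = np.zeros((n, len(sample_table)), dtype=np.int64)
    a2 = np.zeros_like(a1)
    for s, (_, sample) in enumerate(sample_table.iterrows()):
        dox = sample["condition"] == "Dox"
        factor = np.ones(n)
        if dox and reduction > 0:
            factor = np.where(on_tg, 1.0 - reduction, 1.0)
        mean_a1 = mu * rho
        mean_a2 = mu * (1.0 - rho)
        if scenario.silenced_allele == "a1":
            mean_a1 = mean_a1 * factor
        else:
            mean_a2 = mean_a2 * factor
        for i in range(n):
            rng = _rng(
                scenario,
                _KEY_ATAC_COUNTS,
                i,
                int(sample["_cond_index"]),
                int(sample["replicate"]),
            )
            a1[i, s] = (
                rng.negative_binomial(k, k / (k + mean_a1[i])) if mean_a1[i] > 0 else 0
            )
            a2[i, s] = (
                rng.negative_binomial(k, k / (k + mean_a2[i])) if mean_a2[i] > 0 else 0
            )
    sample_table = sample_table.drop(columns="_cond_index")
    mapped = np.full(len(sample_table), scenario.library_size, dtype=np.int64)
    return AtacAllelicTrack(
        intervals=elements,
        samples=sample_table,
        a1=a1,
        a2=a2,
        mapped_totals=mapped,
    )
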