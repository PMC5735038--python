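import numpy as np
import pandas as pd
import pytest

import silencescan as ss


@pytest.fixture(scope="session")
def tg_scenario():
    """Small transgene scenario: chr2 carries a1-silencing at strength 0.6."""
    return ss.SimulationScenario(
        n_chromosomes=3,
        genes_per_chromosome=40,
        transgene_chrom="chr2",
        silenced_allele="a1",
        repressed_fraction=0.6,
        repression_strength=0.6,
        n_replicates=2,
        library_size=300_000,
        baseline_mean=500.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tg_dataset(tg_scenario):
    annotation = ss.simulate_genome(tg_scenario)
    counts, truth = ss.simulate_allelic_counts(annotation, tg_scenario)
    expr = ss.build_expression(counts)
    return annotation, counts, truth, expr


@pytest.fixture(scope="session")
def null_scenario():
    return ss.SimulationScenario(
        n_chromosomes=3,
        genes_per_chromosome=40,
        transgene_chrom=None,
        n_replicates=2,
        library_size=300_000,
        seed=23,
    )


@pytest.fixture(scope="session")
def null_dataset(null_scenario):
    annotation = ss.simulate_genome(null_scenario)
    counts, truth = ss.simulate_allelic_counts(annotation, null_scenario)
    expr = ss.build_expression(counts)
    return annotation, counts, truth, expr


@pytest.fixture()
def elements():
    rows = []
    states = ["promoter", "enhancer", "CTCF"]
    for chrom in ("chr1", "chr2", "chr3"):
        for i in range(30):
            rows.append(
                {
                    "chrom": chrom,
                    "start": 1_000_000 * (i + 1),
                    "end": 1_000_000 * (i + 1) + 2000,
                    "state": states[i % 3],
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_counts():
    """Hand-built 4-gene, 4-sample count matrix."""
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "start": [100, 5000, 200, 9000],
            "end": [600, 5600, 900, 9900],
            "strand": ["+", "-", "+", "-"],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "condition": ["NoDox", "NoDox", "Dox", "Dox"],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(
            ["NoDox_rep1", "NoDox_rep2", "Dox_rep1", "Dox_rep2"], name="sample_id"
        ),
    )
    total = np.array(
        [
            [100, 110, 90, 105],
            [200, 190, 210, 200],
            [150, 160, 80, 70],
            [50, 55, 52, 48],
        ]
    )
    a1 = np.array(
        [
            [40, 45, 35, 42],
            [80, 76, 84, 80],
            [60, 64, 8, 7],
            [20, 22, 21, 19],
        ]
    )
    a2 = np.array(
        [
            [40, 44, 36, 42],
            [80, 76, 84, 80],
            [60, 64, 60, 52],
            [20, 22, 20, 19],
        ]
    )
    return ss.AllelicCounts(genes=genes, samples=samples, total=total, a1=a1, a2=a2)
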