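import numpy as np
import pandas as pd
import pytest

import silencescan as ss
from silencescan import significance as sig
from silencescan.atac import ddscore_track
from silencescan.simulate import simulate_atac_counts


class TestScenario:
    def test_defaults_valid(self):
        sc = ss.SimulationScenario()
        assert sc.n_chromosomes == len(sc.chrom_lengths)
        assert sc.conditions == ("NoDox", "Dox")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chrom_lengths": {"chr1": 0}},
            {"genes_per_chromosome": 0},
            {"repressed_fraction": 1.5},
            {"repression_strength": -0.1},
            {"informative_fraction": 0.0},
            {"silenced_allele": "b"},
            {"transgene_chrom": "chrX"},
            {"dispersion": 0.0},
            {"n_replicates": 0},
        ],
    )
    def test_invalid_configuration(self, kwargs):
        with pytest.raises(ValueError):
            ss.SimulationScenario(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        sc = ss.SimulationScenario(seed=5, transgene_chrom="chr1")
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        assert ss.SimulationScenario.from_yaml(path) == sc


class TestSimulateGenome:
    def test_bounds(self):
        sc = ss.SimulationScenario(
            chrom_lengths={"chr1": 100_000_000}, genes_per_chromosome=100
        )
        ann = ss.simulate_genome(sc)
        assert len(ann) == 100
        assert (ann["start"] >= 0).all()
        assert (ann["start"] < ann["end"]).all()
        assert (ann["end"] <= 100_000_000).all()

    def test_deterministic(self):
        sc = ss.SimulationScenario(seed=3)
        pd.testing.assert_frame_equal(ss.simulate_genome(sc), ss.simulate_genome(sc))

    def test_counts_per_chromosome(self):
        sc = ss.SimulationScenario(n_chromosomes=3, genes_per_chromosome=50)
        ann = ss.simulate_genome(sc)
        assert len(ann) == 150
        assert (ann.groupby("chrom").size() == 50).all()

    def test_sorted_within_chromosome(self):
        sc = ss.SimulationScenario(n_chromosomes=2, genes_per_chromosome=30)
        ann = ss.simulate_genome(sc)
        for _, group in ann.groupby("chrom"):
            assert group["start"].is_monotonic_increasing


class TestSimulateCounts:
    def test_conservation(self, tg_dataset):
        _, counts, _, _ = tg_dataset
        assert np.all(counts.a1 + counts.a2 <= counts.total)
        assert np.all(counts.total >= 0)

    def test_deterministic(self, tg_scenario):
        ann = ss.simulate_genome(tg_scenario)
        c1, t1 = ss.simulate_allelic_counts(ann, tg_scenario)
        c2, t2 = ss.simulate_allelic_counts(ann, tg_scenario)
        np.testing.assert_array_equal(c1.total, c2.total)
        np.testing.assert_array_equal(c1.a1, c2.a1)
        np.testing.assert_array_equal(c1.a2, c2.a2)
        pd.testing.assert_series_equal(t1.true_rs, t2.true_rs)

    def test_adding_replicates_preserves_existing_draws(self, tg_scenario):
        ann = ss.simulate_genome(tg_scenario)
        base, _ = ss.simulate_allelic_counts(ann, tg_scenario)
        wider = ss.SimulationScenario(**{**tg_scenario.to_dict(), "n_replicates": 3})
        more, _ = ss.simulate_allelic_counts(ann, wider)
        shared = [s for s in base.samples.index if s in more.samples.index]
        for sid in shared:
            i = list(base.samples.index).index(sid)
            j = list(more.samples.index).index(sid)
            np.testing.assert_array_equal(base.total[:, i], more.total[:, j])
            np.testing.assert_array_equal(base.a1[:, i], more.a1[:, j])

    def test_null_truth_all_zero(self, null_dataset):
        _, _, truth, _ = null_dataset
        assert (truth.true_rs == 0).all()
        assert truth.transgene_chrom is None

    def test_zero_strength_truth_zero(self):
        sc = ss.SimulationScenario(
            n_chromosomes=2, transgene_chrom="chr1", repression_strength=0.0, seed=1
        )
        ann = ss.simulate_genome(sc)
        _, truth = ss.simulate_allelic_counts(ann, sc)
        assert (truth.true_rs == 0).all()

    def test_true_rs_zero_off_transgene(self, tg_dataset):
        ann, _, truth, _ = tg_dataset
        off = ann["chrom"] != "chr2"
        assert (truth.true_rs[off] == 0).all()

    def test_full_silencing_limit(self):
        sc = ss.SimulationScenario(
            n_chromosomes=2,
            genes_per_chromosome=30,
            transgene_chrom="chr1",
            silenced_allele="a1",
            repressed_fraction=1.0,
            repression_strength=1.0,
            informative_fraction=1.0,
            library_size=3_000_000,
            seed=2,
        )
        ann = ss.simulate_genome(sc)
        counts, truth = ss.simulate_allelic_counts(ann, sc)
        dox = [list(counts.samples.index).index(s) for s in counts.sample_ids("Dox")]
        affected = truth.affected.to_numpy()
        assert counts.a1[np.ix_(affected, dox)].sum() == 0

    def test_silenced_expression_ratio_matches_strength(self):
        # Monte-Carlo oracle: repression removes a fraction r of the silenced
        # allele's expression, so its allelic-expression Dox/NoDox ratio -> 1-r.
        ratios = []
        for seed in (101, 102, 103):
            sc = ss.SimulationScenario(
                n_chromosomes=20,
                genes_per_chromosome=500,
                transgene_chrom="chr5",
                silenced_allele="a1",
                repressed_fraction=0.6,
                repression_strength=0.5,
                library_size=5_000_000,
                seed=seed,
            )
            ann = ss.simulate_genome(sc)
            counts, truth = ss.simulate_allelic_counts(ann, sc)
            expr = ss.build_expression(counts)
            nodox = expr.expr_a1[counts.sample_ids("NoDox")].mean(axis=1)
            dox = expr.expr_a1[counts.sample_ids("Dox")].mean(axis=1)
            affected = truth.affected[truth.affected].index
            ratios.append(float(dox[affected].mean() / nodox[affected].mean()))
        assert abs(np.mean(ratios) - 0.5) < 0.05

    def test_annotation_scenario_mismatch(self, tg_scenario):
        ann = ss.simulate_genome(tg_scenario)
        bad = ann.copy()
        bad.loc[bad.index[0], "chrom"] = "chr99"
        with pytest.raises(ValueError):
            ss.simulate_allelic_counts(bad, tg_scenario)


class TestNullExchangeability:
    def test_silent_rate_controlled(self):
        # full pipeline on >= 20 null datasets: silent rate at q<0.05 bounded
        n_perm = 200
        silent_total = 0
        gene_total = 0
        for seed in range(20):
            sc = ss.SimulationScenario(
                n_chromosomes=3,
                genes_per_chromosome=20,
                transgene_chrom=None,
                library_size=120_000,
                seed=1000 + seed,
            )
            ann = ss.simulate_genome(sc)
            counts, _ = ss.simulate_allelic_counts(ann, sc)
            expr = ss.build_expression(counts)
            tab = ss.rs_table(expr, "a1")
            pvals = sig.permutation_pvalues(
                counts, tab, "a1", n_perm=n_perm, seed=seed
            )
            combined = sig.combine_replicates(pvals, n_perm=n_perm)
            q = sig.bh_adjust(combined["p_combined"])
            rrs = ss.random_rs(tab, candidate_chrom="chr1")
            crs = ss.calibrated_rs(tab["rs"], rrs)
            silent = sig.call_silent(crs, q)
            silent_total += int(silent.sum())
            gene_total += len(tab)
        rate = silent_total / gene_total
        se = np.sqrt(0.05 * 0.95 / gene_total)
        assert rate <= 0.05 + 3 * se


class TestSimulateAtac:
    def test_deterministic(self, elements, tg_scenario):
        t1 = simulate_atac_counts(elements, tg_scenario)
        t2 = simulate_atac_counts(elements, tg_scenario)
        np.testing.assert_array_equal(t1.a1, t2.a1)
        np.testing.assert_array_equal(t1.a2, t2.a2)

    def test_no_reduction_null_ddscore(self, elements, tg_scenario):
        track = simulate_atac_counts(elements, tg_scenario, reduction=0.0)
        dds = ddscore_track(track)
        # no condition effect anywhere: mean ddscore ~ 0 at this depth
        scale = (track.a1.mean() + track.a2.mean()) * 1e7 / tg_scenario.library_size
        assert abs(dds["ddscore"].mean()) < 0.1 * scale

    def test_overlapping_intervals_rejected(self, tg_scenario):
        bad = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [100, 500],
                "end": [1000, 1500],
                "state": ["promoter", "enhancer"],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_atac_counts(bad, tg_scenario)

    def test_malformed_intervals_rejected(self, tg_scenario):
        bad = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [500]})
        with pytest.raises(ValueError):
            simulate_atac_counts(bad, tg_scenario)

    def test_reduction_only_on_transgene_chrom(self, elements, tg_scenario):
        track = simulate_atac_counts(elements, tg_scenario, reduction=0.9)
        dds = ddscore_track(track)
        on = dds[dds["chrom"] == "chr2"]["ddscore"]
        off = dds[dds["chrom"] != "chr2"]["ddscore"]
        assert on.mean() < off.mean()
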