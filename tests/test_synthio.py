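import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from compscape import compcall, growthfit, synthio


class TestEvolutionExperiment:
    def test_noise_free_compensable_line_reaches_one(self):
        params = synthio.EvolutionSimParams(
            n_genotypes=1, lines_per_genotype=1, n_controls=3,
            initial_fitness_distribution=(0.7, 0.7), control_drift=0.0,
            control_drift_sd=0.0, compensable_fraction=1.0,
            compensation_effect=(0.3, 0.0), replicate_noise_sd=0.0, seed=0,
        )
        fitness, truth = synthio.simulate_evolution_experiment(params)
        final = fitness[(fitness["role"] == "deletion") & (fitness["day"] == 104)]
        assert np.allclose(final["fitness"], 1.0)
        traj = truth.trajectories.query("genotype != 'control'")
        assert traj.loc[traj["day"] == 0, "true_fitness"].iloc[0] == pytest.approx(0.7)

    def test_trajectory_saturating_and_monotone(self):
        params = synthio.EvolutionSimParams(n_genotypes=5, seed=1)
        _, truth = synthio.simulate_evolution_experiment(params)
        for _, g in truth.trajectories.groupby("line"):
            f = g.sort_values("day")["true_fitness"].to_numpy()
            assert (np.diff(f) >= -1e-12).all()
            # gains shrink with time (exponential approach)
            gains = np.diff(f)
            if gains[0] > 1e-9:
                assert gains[-1] < gains[0]

    def test_controls_drift_on_average(self):
        params = synthio.EvolutionSimParams(n_genotypes=2, n_controls=50, seed=2)
        fitness, _ = synthio.simulate_evolution_experiment(params)
        ctrl_rfi = compcall.control_rfis(fitness)
        assert ctrl_rfi.mean() == pytest.approx(0.05, abs=0.012)

    def test_seeded_runs_byte_identical(self):
        params = synthio.EvolutionSimParams(n_genotypes=10, seed=9)
        a, _ = synthio.simulate_evolution_experiment(params)
        b, _ = synthio.simulate_evolution_experiment(params)
        assert a.to_csv() == b.to_csv()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            synthio.EvolutionSimParams(initial_fitness_distribution=(0.0, 0.9)).validate()
        with pytest.raises(ValueError):
            synthio.EvolutionSimParams(replicates=3).validate()
        with pytest.raises(ValueError):
            synthio.EvolutionSimParams(timepoints_days=(26, 52)).validate()

    def test_ground_truth_traceability(self):
        params = synthio.EvolutionSimParams(n_genotypes=4, seed=3)
        fitness, truth = synthio.simulate_evolution_experiment(params)
        assert set(fitness["line"]) == set(truth.trajectories["line"])
        assert set(truth.compensable) == set(
            fitness.loc[fitness["role"] == "deletion", "genotype"]
        )
        # noise-free recomputation matches ground truth
        params0 = synthio.EvolutionSimParams(n_genotypes=4, replicate_noise_sd=0.0,
                                             seed=3)
        f0, t0 = synthio.simulate_evolution_experiment(params0)
        merged = f0.merge(t0.trajectories, on=["genotype", "line", "day"])
        assert np.allclose(merged["fitness"], merged["true_fitness"])


class TestGrowthPlate:
    def test_well_counts(self):
        layout = synthio.interleaved_layout(
            ["s1", "s2"], empty_wells=[(0, 1), (3, 3), (15, 23), (7, 7)]
        )
        od = synthio.simulate_growth_plate(layout, {"s1": 0.3, "s2": 0.32,
                                                    "reference": 0.35})
        n_curves = od[od["role"] != "empty"].groupby(["row", "col"]).ngroups
        assert n_curves == 380
        empty = od[od["role"] == "empty"]
        assert np.allclose(empty["od"], empty["od"].iloc[0])

    def test_noise_free_pipeline_recovers_ratio(self):
        layout = synthio.interleaved_layout(["s"], n_rows=8, n_cols=8)
        od = synthio.simulate_growth_plate(layout, {"s": 0.28, "reference": 0.35},
                                           noise_sd=0.0)
        rates = growthfit.estimate_plate_rates(od, layout)
        normed = growthfit.normalize_by_neighbors(rates, radius=2)
        fitness = normed.loc[normed["role"] == "sample", "normalized_rate"]
        assert fitness.mean() == pytest.approx(0.8, abs=0.01)

    def test_negative_rate_rejected(self):
        layout = synthio.interleaved_layout(["s"], n_rows=4, n_cols=4)
        with pytest.raises(ValueError):
            synthio.simulate_growth_plate(layout, {"s": -0.1, "reference": 0.35})


class TestMutationTables:
    def test_snp_count_calibration(self):
        muts, _, _ = synthio.simulate_mutation_tables(300, orf_set_params=(120, 100),
                                                      seed=4)
        per_line = (
            muts[muts["class"] == "snp"].groupby("line").size()
            .reindex([f"line{i + 1:03d}" for i in range(300)], fill_value=0)
        )
        # Poisson(6): sample mean within 3 standard errors
        assert abs(per_line.mean() - 6.0) < 3 * np.sqrt(6.0 / 300)

    def test_coding_effect_consistent_with_orf(self):
        from compscape._codons import snp_effect

        muts, orfs, ann = synthio.simulate_mutation_tables(20, seed=5)
        starts = {}
        offset = 400
        for g in sorted(orfs):
            starts[g] = offset + 1
            offset += len(orfs[g]) + 400
        snps = muts[(muts["class"] == "snp") & (muts["coding_effect"] != "noncoding")]
        for rec in snps.itertuples(index=False):
            pos0 = rec.pos - starts[rec.gene]
            assert orfs[rec.gene][pos0] == rec.ref
            assert snp_effect(orfs[rec.gene], pos0, rec.alt) == rec.coding_effect

    def test_functional_bias_enriches_related_genes(self):
        from compscape import mutstats

        common = dict(orf_set_params=(60, 80), lines_per_genotype=3)
        ann_builder = lambda ann: mutstats.RelatednessAnnotation.from_tables(
            complexes=ann["complexes"], categories=ann["categories"]
        )

        def enrichment(bias, seed):
            muts, _, ann = synthio.simulate_mutation_tables(
                60, functional_bias=bias, seed=seed, **common
            )
            snps = muts[muts["class"] == "snp"]
            ko = ann["lines"].set_index("line")["ko_gene"].to_dict()
            genes = {l: list(g["gene"]) for l, g in snps.groupby("line")}
            ko = {l: ko[l] for l in genes}
            return mutstats.functional_relatedness_test(
                ko, genes, ann_builder(ann), "co_category", n_shuffles=200, seed=seed
            )

        biased = enrichment(0.8, seed=6)
        unbiased = enrichment(0.0, seed=7)
        assert biased.enrichment > 2
        assert biased.pvalue < 0.01
        assert 0.5 < unbiased.enrichment < 2

    def test_empty_orf_set_rejected(self):
        with pytest.raises(ValueError):
            synthio.simulate_mutation_tables(10, orf_set_params=(0, 100))

    def test_determinism(self):
        a, orfs_a, _ = synthio.simulate_mutation_tables(15, seed=8)
        b, orfs_b, _ = synthio.simulate_mutation_tables(15, seed=8)
        assert a.to_csv() == b.to_csv()
        assert orfs_a == orfs_b


class TestExpressionTriplets:
    def test_truth_labels_match_construction(self):
        mats, truth = synthio.simulate_expression_triplets(
            n_genes=400, n_de=40, restoration_fraction=0.25, replicate_sd=0.0, seed=9
        )
        assert (truth.restoration == "restored").sum() == 10
        restored = truth.restoration[truth.restoration == "restored"].index
        assert np.allclose(mats["evolved"].loc[restored], 0.0)
        assert np.allclose(mats["wt"].to_numpy(), 0.0)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            synthio.simulate_expression_triplets(restoration_fraction=1.2)

    @given(frac=st.floats(0.0, 1.0))
    @settings(max_examples=10, deadline=None)
    def test_restored_count_rounds_correctly(self, frac):
        _, truth = synthio.simulate_expression_triplets(
            n_genes=200, n_de=20, restoration_fraction=frac, seed=0
        )
        assert (truth.restoration == "restored").sum() == int(round(frac * 20))


class TestColonyPlates:
    def test_replicate_count(self):
        eff = pd.DataFrame(
            [("s", "l1", 0, "YPD", 1.0), ("s", "l1", 104, "YPD", 1.2)],
            columns=["strain", "line", "day", "environment", "effect"],
        )
        col = synthio.simulate_colony_plates(eff, seed=0, n_rows=8, n_cols=8)
        per = col[col["line"] == "l1"].groupby("day").size()
        assert (per == 4).all()

    def test_shared_plate_for_ancestor_and_evolved(self):
        eff = pd.DataFrame(
            [("s", "l1", 0, "YPD", 1.0), ("s", "l1", 104, "YPD", 1.2)],
            columns=["strain", "line", "day", "environment", "effect"],
        )
        col = synthio.simulate_colony_plates(eff, seed=0, n_rows=8, n_cols=8)
        plates_day0 = set(col[(col["line"] == "l1") & (col["day"] == 0)]["plate"])
        plates_day104 = set(col[(col["line"] == "l1") & (col["day"] == 104)]["plate"])
        assert plates_day0 == plates_day104


class TestGiMap:
    def test_implanted_flags_recoverable_exactly(self):
        from compscape import suppress_epi

        gi, truth = synthio.simulate_gi_map(n_genes=300, partners_per_gene=20, seed=10)
        flagged = suppress_epi.find_suppressors(gi)
        assert (
            flagged["suppressor"].to_numpy()
            == truth.suppression["true_suppressor"].to_numpy()
        ).all()

    def test_determinism(self):
        a, _ = synthio.simulate_gi_map(n_genes=100, partners_per_gene=10, seed=11)
        b, _ = synthio.simulate_gi_map(n_genes=100, partners_per_gene=10, seed=11)
        assert a.to_csv() == b.to_csv()
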