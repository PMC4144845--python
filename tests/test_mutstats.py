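import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from compscape import mutstats


class TestMutationStatus:
    def setup_method(self):
        self.line_to_anc = {"evo1": "anc1"}
        self.ancestors = pd.DataFrame(
            [
                ("anc1", "chrI", 100, "A", "G"),  # private to anc1
                ("anc1", "chrI", 200, "C", "T"),  # shared with anc2
                ("anc2", "chrI", 200, "C", "T"),
                ("anc2", "chrI", 300, "G", "A"),  # private to anc2
            ],
            columns=["ancestor", "chrom", "pos", "ref", "alt"],
        )

    def classify(self, evolved_rows):
        evolved = pd.DataFrame(
            evolved_rows, columns=["line", "chrom", "pos", "ref", "alt"]
        )
        return mutstats.classify_mutation_status(
            evolved, self.ancestors, self.line_to_anc
        )

    def test_variant_only_in_evolved_is_de_novo(self):
        evo, _ = self.classify([("evo1", "chrI", 500, "T", "C")])
        assert evo.loc[0, "status"] == "de_novo"

    def test_variant_in_own_ancestor_is_ancestral(self):
        evo, _ = self.classify([("evo1", "chrI", 100, "A", "G")])
        assert evo.loc[0, "status"] == "ancestral"

    def test_variant_in_foreign_ancestor_is_ambiguous(self):
        evo, _ = self.classify([("evo1", "chrI", 300, "G", "A")])
        assert evo.loc[0, "status"] == "ambiguous"

    def test_ancestor_private_vs_background(self):
        _, anc = self.classify([])
        anc = anc.set_index(["ancestor", "pos"])
        assert anc.loc[("anc1", 100), "status"] == "secondary_ancestor"
        assert anc.loc[("anc1", 200), "status"] == "background"
        assert anc.loc[("anc2", 300), "status"] == "secondary_ancestor"


class TestNsSiteProbability:
    def test_single_codon_ttt_t_to_c(self):
        # TTC (Phe) synonymous at pos 3; CTT (Leu), TCT (Ser) nonsynonymous
        assert mutstats.ns_site_probability("T", "C", {"g": "TTT"}) == pytest.approx(
            2 / 3
        )

    def test_repeated_ggg_g_to_a(self):
        # GGA synonymous (pos 3); AGG, GAG nonsynonymous
        orfs = {"g": "GGG" * 7}
        assert mutstats.ns_site_probability("G", "A", orfs) == pytest.approx(2 / 3)

    def test_matches_exhaustive_translation_oracle(self, small_orfs):
        # oracle: translate the whole protein before/after every mutation
        for ref, alt in itertools.permutations("ACGT", 2):
            ns = tot = 0
            for seq in small_orfs.values():
                protein = str(Seq(seq).translate())
                for i, base in enumerate(seq):
                    if base != ref:
                        continue
                    mutated = str(Seq(seq[:i] + alt + seq[i + 1 :]).translate())
                    tot += 1
                    ns += mutated != protein
            if tot == 0:
                continue
            assert mutstats.ns_site_probability(ref, alt, small_orfs) == pytest.approx(
                ns / tot
            )

    def test_invalid_inputs(self, small_orfs):
        with pytest.raises(ValueError):
            mutstats.ns_site_probability("A", "A", small_orfs)
        with pytest.raises(ValueError):
            mutstats.ns_site_probabilities({})
        with pytest.raises(ValueError):
            mutstats.ns_site_probabilities({"g": "ACGTA"})  # length not multiple of 3


class TestPoissonBinomial:
    def test_two_snps_both_nonsynonymous(self):
        assert mutstats.poisson_binomial_tail([0.75, 0.75], 2) == pytest.approx(0.5625)

    def test_two_snps_at_least_one(self):
        assert mutstats.poisson_binomial_tail([0.75, 0.75], 1) == pytest.approx(0.9375)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(1)
        ps = rng.random(10)
        for k in (0, 3, 7, 10):
            exact = 0.0
            for outcome in itertools.product([0, 1], repeat=10):
                if sum(outcome) >= k:
                    prob = np.prod([p if o else 1 - p for p, o in zip(ps, outcome)])
                    exact += prob
            assert mutstats.poisson_binomial_tail(ps, k) == pytest.approx(exact)

    def test_equal_probabilities_reduce_to_binomial(self):
        from hypothesis import given, settings, strategies as st
        from scipy.stats import binom

        @given(p=st.floats(0.01, 0.99), n=st.integers(1, 40),
               frac=st.floats(0.0, 1.0))
        @settings(max_examples=50, deadline=None)
        def check(p, n, frac):
            k = int(round(frac * n))
            assert mutstats.poisson_binomial_tail([p] * n, k) == pytest.approx(
                binom.sf(k - 1, n, p), abs=1e-10
            )

        check()

    def test_tail_monotone_in_k(self):
        ps = [0.2, 0.5, 0.9, 0.4]
        tails = [mutstats.poisson_binomial_tail(ps, k) for k in range(5)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))
        assert tails[0] == pytest.approx(1.0)


class TestNsExcess:
    def test_all_forced_synonymous_fraction_zero(self):
        # mutations at 4-fold degenerate third positions never change the protein
        snps = pd.DataFrame(
            {"ref": ["G", "G"], "alt": ["A", "C"],
             "coding_effect": ["synonymous", "synonymous"]}
        )
        res = mutstats.ns_excess_test(snps, {"g": "GGGCTG"})
        assert res.ns_fraction == 0.0
        assert res.tail_probability == pytest.approx(1.0)

    def test_excess_detected(self, small_orfs):
        snps = pd.DataFrame(
            {"ref": ["A"] * 20, "alt": ["G"] * 20,
             "coding_effect": ["nonsynonymous"] * 20}
        )
        res = mutstats.ns_excess_test(snps, small_orfs)
        p_site = mutstats.ns_site_probability("A", "G", small_orfs)
        assert res.tail_probability == pytest.approx(p_site**20)

    def test_no_coding_snps_errors(self, small_orfs):
        snps = pd.DataFrame({"ref": [], "alt": [], "coding_effect": []})
        with pytest.raises(ValueError):
            mutstats.ns_excess_test(snps, small_orfs)


class TestParallelism:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a"}, {"b"}, 0.0),
        ],
    )
    def test_jaccard_pairs(self, a, b, expected):
        res = mutstats.parallelism(
            {"l1": a, "l2": b}, {"l1": "g", "l2": "g"}
        )
        assert res.within_mean == pytest.approx(expected)

    def test_within_vs_between_split(self):
        sets = {"l1": {"a", "b"}, "l2": {"a", "b"}, "l3": {"x"}}
        genos = {"l1": "g1", "l2": "g1", "l3": "g2"}
        res = mutstats.parallelism(sets, genos)
        assert res.within_mean == pytest.approx(1.0)
        assert res.between_mean == pytest.approx(0.0)
        assert res.n_within_pairs == 1 and res.n_between_pairs == 2

    def test_both_empty_pair_excluded(self):
        res = mutstats.parallelism(
            {"l1": set(), "l2": set()}, {"l1": "g", "l2": "g"}
        )
        assert res.n_within_pairs == 0


class TestFunctionalRelatedness:
    def make_annotation(self, n_genes=100, complex_size=2):
        genes = [f"g{i}" for i in range(n_genes)]
        cpx = pd.DataFrame(
            {"gene": genes, "cid": [f"c{i // complex_size}" for i in range(n_genes)]}
        )
        return genes, mutstats.RelatednessAnnotation.from_tables(complexes=cpx)

    def test_constructed_enrichment(self):
        genes, ann = self.make_annotation()
        # each KO's mutated gene is always its complex partner
        ko = {f"l{i}": genes[2 * i] for i in range(20)}
        muts = {f"l{i}": [genes[2 * i + 1]] for i in range(20)}
        res = mutstats.functional_relatedness_test(
            ko, muts, ann, "co_complex", n_shuffles=500, seed=0
        )
        assert res.observed == 1.0
        assert res.enrichment > 10
        assert res.pvalue == pytest.approx(1 / 501)

    def test_random_assignment_no_enrichment(self):
        rng = np.random.default_rng(2)
        genes, ann = self.make_annotation(n_genes=40, complex_size=4)
        ko = {f"l{i}": genes[rng.integers(40)] for i in range(30)}
        muts = {f"l{i}": list(rng.choice(genes, 5)) for i in range(30)}
        res = mutstats.functional_relatedness_test(
            ko, muts, ann, "co_complex", n_shuffles=300, seed=3
        )
        assert 0.2 < res.enrichment < 5
        assert res.pvalue > 0.01

    def test_continuous_measure(self):
        genes = ["a", "b", "c"]
        sim = pd.DataFrame(
            {"x": ["a", "a", "b"], "y": ["b", "c", "c"], "r": [0.9, 0.1, 0.2]}
        )
        ann = mutstats.RelatednessAnnotation.from_tables(gi_similarity=sim)
        res = mutstats.functional_relatedness_test(
            {"l1": "a", "l2": "b"}, {"l1": ["b"], "l2": ["c"]}, ann,
            "gi_profile_similarity", n_shuffles=100, seed=0,
        )
        assert res.observed == pytest.approx((0.9 + 0.2) / 2)

    def test_single_genotype_degenerate(self):
        genes, ann = self.make_annotation()
        with pytest.warns(UserWarning):
            res = mutstats.functional_relatedness_test(
                {"l1": "g0", "l2": "g0"}, {"l1": ["g1"], "l2": ["g1"]}, ann,
                "co_complex", n_shuffles=100,
            )
        assert res.pvalue == 1.0

    def test_no_coverage_errors(self):
        ann = mutstats.RelatednessAnnotation()
        with pytest.raises(ValueError):
            mutstats.functional_relatedness_test(
                {"l1": "a", "l2": "b"}, {"l1": ["x"], "l2": ["y"]}, ann, "co_complex"
            )


class TestPromoterEnrichment:
    def make_inputs(self, positions, prom_bp=100, genome=1000):
        muts = pd.DataFrame({"chrom": "chrI", "pos": positions})
        proms = pd.DataFrame({"chrom": ["chrI"], "start": [1], "end": [prom_bp]})
        return muts, proms, genome

    def test_expected_rate_not_significant(self):
        muts, proms, genome = self.make_inputs(
            list(range(1, 11)) + list(range(101, 191)), prom_bp=100, genome=1000
        )
        res = mutstats.promoter_enrichment(muts, proms, genome)
        assert res.n_promoter == 10 and res.n_total == 100
        assert res.pvalue > 0.5

    def test_strong_depletion(self):
        muts, proms, genome = self.make_inputs(list(range(101, 201)))
        res = mutstats.promoter_enrichment(muts, proms, genome)
        assert res.n_promoter == 0
        assert res.pvalue < 1e-4

    def test_all_in_promoters_closed_form(self):
        muts, proms, genome = self.make_inputs(list(range(1, 101)), prom_bp=500,
                                               genome=1000)
        res = mutstats.promoter_enrichment(muts, proms, genome)
        assert res.expected_fraction == pytest.approx(0.5)
        assert res.pvalue == pytest.approx(min(1.0, 2 * 0.5**100), rel=0.01)

    def test_zero_mutations_undefined(self):
        with pytest.raises(ValueError):
            mutstats.promoter_enrichment(
                pd.DataFrame(columns=["chrom", "pos"]),
                pd.DataFrame({"chrom": ["chrI"], "start": [1], "end": [10]}),
                100,
            )


class TestParalogFilter:
    def make_records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_a", "gene_b", "evalue", "aln_length", "similarity",
                     "transposon_a", "transposon_b"],
        )

    def test_rules(self):
        records = self.make_records(
            [
                # the ribosomal-duplicate archetype: high identity, long alignment
                ("RPL6A", "RPL6B", 1e-9, 150, 94.0, False, False),
                ("a", "b", 1e-9, 90, 50.0, False, False),   # too short
                ("c", "d", 1e-7, 200, 50.0, False, False),  # E-value too large
                ("e", "f", 1e-9, 200, 25.0, False, False),  # similarity too low
                ("g", "h", 1e-9, 200, 50.0, True, False),   # transposon
            ]
        )
        kept = mutstats.paralog_filter(records)
        assert list(kept["gene_a"]) == ["RPL6A"]

    def test_missing_fields_rejected(self):
        records = self.make_records(
            [("a", "b", np.nan, 150, 94.0, False, False),
             ("c", "d", 1e-9, 150, 94.0, False, False)]
        )
        kept = mutstats.paralog_filter(records)
        assert list(kept["gene_a"]) == ["c"]
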