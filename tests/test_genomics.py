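"""HGT statistics, genotype/site filters, QC gates and ANI clustering."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from camii import fixtures as fx
from camii import genomics as gen


def exact_binomial_tail(k: int, n: int, p: float) -> float:
    """Arbitrary-precision P(X >= k) for X ~ Binomial(n, p)."""
    pf = Fraction(p)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


class TestParseBlastTab:
    def _write(self, tmp_path, lines):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_twelve_column_line_parsed(self, tmp_path):
        line = "g1\tg2\t99.5\t2500\t10\t0\t1\t2500\t100\t2599\t0.0\t4600"
        blocks = gen.parse_blast_tab(self._write(tmp_path, [line]))
        b = blocks[0]
        assert (b.query, b.subject, b.length) == ("g1", "g2", 2500)
        assert b.identity == pytest.approx(0.995)

    def test_self_hits_dropped(self, tmp_path):
        line = "g1\tg1\t100.0\t5000\t0\t0\t1\t5000\t1\t5000\t0.0\t9000"
        assert gen.parse_blast_tab(self._write(tmp_path, [line])) == []

    def test_short_line_cites_line_number(self, tmp_path):
        lines = [
            "g1\tg2\t99.5\t2500\t10\t0\t1\t2500\t100\t2599\t0.0\t4600",
            "g1\tg2\t99.5\t2500",
        ]
        with pytest.raises(ValueError, match="line 2"):
            gen.parse_blast_tab(self._write(tmp_path, lines))


class TestHgtPvalue:
    def test_clonal_background_gives_p_one(self):
        assert gen.hgt_pvalue(2000, 0.99, 1.0) == 1.0
        assert gen.hgt_pvalue(500, 1.0, 1.0) == 1.0

    def test_identity_at_ani_sits_at_binomial_median(self):
        p = gen.hgt_pvalue(10_000, 0.90, 0.90)
        assert 0.4 <= p <= 0.6

    def test_matches_arbitrary_precision_oracle(self):
        for L, ident, a in [
            (2000, 0.99, 0.90),
            (3000, 1.0, 0.95),
            (500, 0.98, 0.80),
            (2500, 0.995, 0.97),
            (100, 0.9, 0.5),
        ]:
            k = int(round(ident * L))
            oracle = exact_binomial_tail(k, L, a)
            mine = gen.hgt_pvalue(L, ident, a)
            assert mine == pytest.approx(oracle, rel=1e-12)
        assert gen.hgt_pvalue(2000, 0.99, 0.90) < 1e-5

    def test_monotone_in_length_and_identity(self):
        ps_len = [gen.hgt_pvalue(L, 0.99, 0.9) for L in (500, 1000, 2000, 4000)]
        assert all(a >= b for a, b in zip(ps_len, ps_len[1:]))
        ps_id = [gen.hgt_pvalue(2000, i, 0.9) for i in (0.92, 0.95, 0.98, 1.0)]
        assert all(a >= b for a, b in zip(ps_id, ps_id[1:]))

    def test_invalid_ani_rejected(self):
        with pytest.raises(ValueError, match="ani"):
            gen.hgt_pvalue(100, 0.9, 0.0)


class TestCallHgt:
    @staticmethod
    def _blocks(rows):
        return pd.DataFrame(rows, columns=["query", "subject", "length", "identity"])

    def test_bh_step_up_hand_example(self):
        from camii.stats import bh_adjust

        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_length_2000_exactly_fails_strict_rule(self):
        blocks = self._blocks(
            [("a", "b", 2000, 1.0), ("a", "b", 2001, 1.0)]
        )
        calls = gen.call_hgt(blocks, {frozenset(("a", "b")): 0.90})
        assert [c.passed for c in calls] == [False, True]
        assert all(c.p_adjusted < 1e-5 for c in calls)

    def test_missing_ani_names_pair(self):
        blocks = self._blocks([("a", "b", 2500, 1.0)])
        with pytest.raises(KeyError, match="a.*b|b.*a"):
            gen.call_hgt(blocks, {frozenset(("a", "c")): 0.9})

    def test_planted_block_called_background_not(self):
        sc = fx.HgtScenario(
            genome_length_bp=30_000,
            background_ani=0.90,
            planted_blocks=[("S1", "S2", 3000, 1.0)],
            seed=17,
        )
        gs = fx.generate_hgt_genomes(sc)
        blocks = fx.candidate_blocks_from_genomes(gs, seed=17)
        calls = gen.call_hgt(blocks, gs.ani)
        planted_pair = {"S1_g0", "S2_g0"}
        planted_call = next(
            c
            for c in calls
            if {c.block.query, c.block.subject} == planted_pair
            and c.block.length == 3000
        )
        assert planted_call.passed

    def test_block_free_scenarios_produce_zero_calls(self):
        for seed in range(10):
            sc = fx.HgtScenario(
                genome_length_bp=20_000, background_ani=0.92, seed=seed
            )
            gs = fx.generate_hgt_genomes(sc)
            blocks = fx.candidate_blocks_from_genomes(gs, seed=seed)
            calls = gen.call_hgt(blocks, gs.ani)
            assert sum(c.passed for c in calls) == 0


class TestMergeBlocks:
    def test_overlapping_blocks_collapse_to_one_event(self):
        blocks = [
            gen.AlignmentBlock("a", "b", 2500, 1.0, qstart=1, qend=2500),
            gen.AlignmentBlock("a", "b", 2500, 1.0, qstart=2000, qend=4500),
            gen.AlignmentBlock("a", "b", 2200, 1.0, qstart=9000, qend=11199),
        ]
        calls = [
            gen.HgtCall(block=b, ani=0.9, p_raw=0.0, p_adjusted=0.0, passed=True)
            for b in blocks
        ]
        merged = gen.merge_blocks(calls)
        assert merged[frozenset(("a", "b"))] == [(1, 4500), (9000, 11199)]

    def test_failing_blocks_excluded(self):
        call = gen.HgtCall(
            block=gen.AlignmentBlock("a", "b", 2500, 1.0, qstart=1, qend=2500),
            ani=0.9, p_raw=0.5, p_adjusted=0.5, passed=False,
        )
        assert gen.merge_blocks([call]) == {}


class TestFrequencyNetwork:
    @staticmethod
    def _calls(pairs, species_map):
        blocks = [
            gen.AlignmentBlock(a, b, 2500, 1.0, qstart=1, qend=2500) for a, b in pairs
        ]
        return [
            gen.HgtCall(block=b, ani=0.9, p_raw=0.0, p_adjusted=0.0, passed=True)
            for b in blocks
        ]

    def test_three_of_six_pairs_share(self):
        species_map = {
            "a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B",
        }
        calls = self._calls([("a1", "b1"), ("a1", "b2"), ("a2", "b3")], species_map)
        net = gen.hgt_frequency_network(calls, species_map)
        edge = net.edges[0]
        assert (edge.n_pairs_sharing, edge.n_pairs_total) == (3, 6)
        assert edge.frequency == pytest.approx(0.5)

    def test_matches_pair_enumeration_oracle_on_fixture(self):
        sc = fx.HgtScenario(
            genome_length_bp=20_000,
            n_species=3,
            genomes_per_species=2,
            background_ani=0.90,
            planted_blocks=[("S1", "S2", 3000, 1.0)],
            seed=23,
        )
        gs = fx.generate_hgt_genomes(sc)
        calls = gen.call_hgt(fx.candidate_blocks_from_genomes(gs, seed=23), gs.ani)
        net = gen.hgt_frequency_network(calls, gs.species_map)
        # oracle: exhaustive enumeration of inter-species genome pairs
        passing = {
            frozenset((c.block.query, c.block.subject)) for c in calls if c.passed
        }
        for edge in net.edges:
            ga = [g for g, s in gs.species_map.items() if s == edge.species_a]
            gb = [g for g, s in gs.species_map.items() if s == edge.species_b]
            sharing = sum(frozenset((x, y)) in passing for x in ga for y in gb)
            assert edge.n_pairs_total == len(ga) * len(gb)
            assert edge.n_pairs_sharing == sharing

    def test_no_passing_calls_empty_network(self):
        net = gen.hgt_frequency_network([], {"a1": "A", "b1": "B"})
        assert net.edges == [] and np.isnan(net.high_frequency_fraction)

    def test_unmapped_genome_rejected(self):
        calls = self._calls([("a1", "zz")], {})
        with pytest.raises(ValueError, match="zz"):
            gen.hgt_frequency_network(calls, {"a1": "A"})


class TestGramEnrichment:
    def test_perfect_association_closed_form(self):
        # 10 same-Gram pairs all with HGT, 10 different-Gram pairs all without:
        # chi2 = n (ad - bc)^2 / (row/col margins) = 20
        species = {f"p{i}": "positive" for i in range(5)}
        species.update({f"n{i}": "negative" for i in range(5)})
        same_pairs = [p for p in combinations(sorted(species), 2)
                      if species[p[0]] == species[p[1]]]
        edges = [
            gen.HgtEdge(a, b, 1.0, 1, 1, "intrafamily") for a, b in same_pairs
        ]
        # restrict the universe so the table is exactly [[20, 0], [0, 25]]
        chi2, p, table, _ = gen.gram_enrichment(edges, species)
        assert table.loc["hgt", "same_gram"] == 20
        assert table.loc["no_hgt", "different_gram"] == 25
        n = table.to_numpy().sum()
        a, b_, c, d = table.to_numpy().ravel()
        oracle = n * (a * d - b_ * c) ** 2 / (
            (a + b_) * (c + d) * (a + c) * (b_ + d)
        )
        assert chi2 == pytest.approx(oracle)
        assert p < 1e-4

    def test_null_calibration_uniform_p(self):
        from scipy import stats as sps

        rng = np.random.default_rng(31)
        species = {f"s{i}": ("positive" if i % 2 else "negative") for i in range(10)}
        pairs = list(combinations(sorted(species), 2))
        ps = []
        for _ in range(300):
            edges = [
                gen.HgtEdge(a, b, 1.0, 1, 1, "x")
                for a, b in pairs
                if rng.random() < 0.4  # independent of Gram combination
            ]
            try:
                _, p, _, _ = gen.gram_enrichment(edges, species)
            except ValueError:
                continue
            ps.append(p)
        # discrete statistic: compare CDF loosely
        assert sps.kstest(ps, "uniform").statistic < 0.15

    def test_single_gram_category_rejected(self):
        species = {"a": "positive", "b": "positive", "c": "positive"}
        with pytest.raises(ValueError, match="Gram"):
            gen.gram_enrichment([], species)


class TestGenotypeFilters:
    @staticmethod
    def _matrix(depth, haploidy, alleles=None):
        depth = pd.DataFrame(depth)
        haploidy = pd.DataFrame(haploidy)
        if alleles is None:
            alleles = pd.DataFrame(
                np.full(depth.shape, "A"), index=depth.index, columns=depth.columns
            )
        return gen.GenotypeMatrix(alleles=alleles, depth=depth, haploidy=haploidy)

    def test_boundary_cell_depth5_haploidy09_is_reliable(self):
        m = self._matrix([[5]], [[0.9]])
        reliable, _ = gen.filter_genotypes(m)
        assert bool(reliable.iloc[0, 0])

    def test_site_with_exactly_90pct_reliable_dropped(self):
        depth = [[10] * 9 + [1], [10] * 10]
        hap = [[1.0] * 10, [1.0] * 10]
        m = self._matrix(depth, hap)
        _, retained = gen.filter_genotypes(m)
        assert retained == [1]  # 9/10 = 0.9 is not > 0.9

    def test_clean_matrix_fully_retained(self):
        m = self._matrix(np.full((4, 6), 100), np.ones((4, 6)))
        reliable, retained = gen.filter_genotypes(m)
        assert reliable.all().all() and retained == [0, 1, 2, 3]

    def test_leaf_snp_counting(self):
        # 8 polymorphic sites, 3 with a singleton minor allele -> 0.375
        alleles = pd.DataFrame(
            [
                list("AAAAT"),  # singleton
                list("AATTT"),  # not singleton
                list("CCCCG"),  # singleton
                list("CCGGG"),  # not
                list("GGGGA"),  # singleton
                list("GGAAA"),  # not
                list("TTAAT"),  # not
                list("ATATA"),  # not
            ]
        )
        assert gen.leaf_snp_proportion(alleles) == pytest.approx(0.375)

    def test_all_singletons_and_no_singletons(self):
        all_leaf = pd.DataFrame([list("AAAT"), list("CCCA")])
        assert gen.leaf_snp_proportion(all_leaf) == 1.0
        none_leaf = pd.DataFrame([list("AATT"), list("CCGG")])
        assert gen.leaf_snp_proportion(none_leaf) == 0.0

    def test_zero_retained_sites_flagged_nan(self):
        alleles = pd.DataFrame([list("AA")])
        assert np.isnan(gen.leaf_snp_proportion(alleles, retained_sites=[]))


class TestGenomeQc:
    def test_passing_genome(self):
        qc = pd.DataFrame(
            {"coverage": [25.0], "n50": [6000.0], "completeness": [85.0],
             "contamination": [2.0]}, index=["g1"],
        )
        assert gen.genome_qc_filter(qc).loc["g1"]

    @pytest.mark.parametrize(
        "metric,value",
        [("coverage", 20.0), ("n50", 5000.0), ("completeness", 80.0),
         ("contamination", 5.0)],
    )
    def test_boundary_values_fail_strict_inequalities(self, metric, value):
        qc = pd.DataFrame(
            {"coverage": [25.0], "n50": [6000.0], "completeness": [85.0],
             "contamination": [2.0]}, index=["g1"],
        )
        qc.loc["g1", metric] = value
        assert not gen.genome_qc_filter(qc).loc["g1"]

    def test_missing_metric_names_genome(self):
        qc = pd.DataFrame(
            {"coverage": [25.0], "n50": [np.nan], "completeness": [85.0],
             "contamination": [2.0]}, index=["gX"],
        )
        with pytest.raises(ValueError, match="gX.*n50"):
            gen.genome_qc_filter(qc)


class TestSpeciesClustering:
    @staticmethod
    def _ani(mat, names):
        return pd.DataFrame(mat, index=names, columns=names)

    def test_threshold_semantics(self):
        ani = self._ani(
            [[1.0, 0.96, 0.94], [0.96, 1.0, 0.94], [0.94, 0.94, 1.0]], list("abc")
        )
        labels = gen.species_cluster_by_ani(ani)
        assert labels["a"] == labels["b"] != labels["c"]

    def test_single_linkage_chain_transitivity(self):
        ani = self._ani(
            [[1.0, 0.96, 0.90], [0.96, 1.0, 0.96], [0.90, 0.96, 1.0]], list("abc")
        )
        labels = gen.species_cluster_by_ani(ani)
        assert labels.nunique() == 1

    def test_disconnected_genomes_singletons(self):
        ani = self._ani(np.eye(4), list("abcd"))
        assert gen.species_cluster_by_ani(ani).nunique() == 4

    def test_asymmetric_matrix_rejected(self):
        ani = self._ani([[1.0, 0.9], [0.5, 1.0]], list("ab"))
        with pytest.raises(ValueError, match="asymmetric"):
            gen.species_cluster_by_ani(ani)
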