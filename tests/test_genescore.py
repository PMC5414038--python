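import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylica.genescore import (
    GenotypeMatrix,
    build_score,
    hwe_exact_test,
    mqtl_cis_enrichment,
    mqtl_pair_tests,
    qc_snps,
    score_phenotype_test,
    stouffer_meta,
)
from methylica.preprocess import ResidualMatrix
from methylica.synthetic import (
    SyntheticDesign,
    generate_annotation,
    generate_genotypes,
    generate_methylome,
)


def toy_genotypes(counts, gene_map=None):
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    snps = [f"rs{j}" for j in range(m)]
    return GenotypeMatrix(
        counts,
        [f"s{i}" for i in range(n)],
        snps,
        gene_map=gene_map or {s: f"g{j}" for j, s in enumerate(snps)},
    )


class TestHweExact:
    def test_enumeration_oracle_small_case(self):
        # oracle: direct enumeration of all heterozygote configurations
        n_het, n_rare, n_common = 3, 1, 6
        n = n_het + n_rare + n_common
        rare = n_het + 2 * n_rare
        from math import comb, factorial

        def prob(het):
            hom_r = (rare - het) // 2
            hom_c = (n - het - hom_r - hom_r) - 0  # placeholder, recompute below
            hom_c = ((2 * n - rare) - het) // 2
            return (
                2**het
                * factorial(n)
                / (factorial(het) * factorial(hom_r) * factorial(hom_c))
                * factorial(rare)
                * factorial(2 * n - rare)
                / factorial(2 * n)
            )

        hets = range(rare % 2, min(rare, 2 * n - rare) + 1, 2)
        probs = {h: prob(h) for h in hets}
        obs = probs[n_het]
        expected = sum(p for p in probs.values() if p <= obs * (1 + 1e-12))
        assert hwe_exact_test(n_het, n_rare, n_common) == pytest.approx(expected, rel=1e-10)

    def test_no_heterozygotes_is_extreme(self):
        # 100/0/100: total depletion of heterozygotes
        assert hwe_exact_test(0, 100, 100) < 1e-4

    def test_monomorphic_is_one(self):
        assert hwe_exact_test(0, 0, 50) == 1.0


class TestQcSnps:
    def test_monomorphic_removed(self):
        counts = np.zeros((50, 2))
        counts[:, 1] = np.tile([0, 1, 1, 2, 0], 10)  # polymorphic, HWE-ish
        out = qc_snps(toy_genotypes(counts))
        assert out.snp_ids == ["rs1"]

    def test_hwe_violation_removed(self):
        rng = np.random.default_rng(0)
        good = rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        bad = np.repeat([0.0, 2.0], 100)[:, None]  # no heterozygotes
        counts = np.hstack([good, bad])
        out = qc_snps(toy_genotypes(counts))
        assert "rs1" not in out.snp_ids
        assert "rs0" in out.snp_ids

    def test_callrate_threshold_arithmetic(self):
        rng = np.random.default_rng(1)
        counts = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        counts[:8, 0] = np.nan  # call rate 0.92
        g = toy_genotypes(counts)
        assert "rs0" in qc_snps(g, callrate_min=0.90).snp_ids
        with pytest.raises(ValueError, match="no SNP"):
            qc_snps(g, callrate_min=0.95)


class TestBuildScore:
    def test_planted_mqtl_score_correlates(self):
        design = SyntheticDesign(
            n_samples=500, n_cpgs=500, n_snps=30, mqtl_effect=0.5,
            cis_fraction=0.999, genotype_missing_rate=0.02, seed=21,
        )
        _, truth = generate_methylome(design)
        cpgs, tx = generate_annotation(design)
        geno, _ = generate_genotypes(design, truth, cpgs, tx)
        comp = truth.component_weights()
        score = build_score(geno, comp, p_threshold=0.05)
        r = np.corrcoef(score.per_sample_score, comp)[0, 1]
        assert r > 0.3

    def test_all_positive_weights_equals_rowsum(self):
        rng = np.random.default_rng(2)
        n = 300
        comp = rng.standard_normal(n)
        counts = np.column_stack(
            [rng.binomial(2, 0.4, n) for _ in range(3)]
        ).astype(float)
        # make every SNP positively associated
        order = np.argsort(comp)
        for j in range(3):
            counts[:, j] = np.sort(counts[:, j])[np.argsort(order.argsort())]
            counts[order, j] = np.sort(counts[order, j])
        g = toy_genotypes(counts)
        score = build_score(g, comp, p_threshold=0.05)
        assert all(w == 1 for w in score.weights.values())
        np.testing.assert_allclose(
            score.raw_score, counts[:, [g.snp_ids.index(s) for s in score.snps]].sum(axis=1)
        )

    def test_one_snp_per_gene_smallest_p(self):
        rng = np.random.default_rng(3)
        n = 400
        comp = rng.standard_normal(n)
        strong = np.clip(np.round(comp + 1 + 0.5 * rng.standard_normal(n)), 0, 2)
        weak = np.clip(np.round(0.3 * comp + 1 + rng.standard_normal(n)), 0, 2)
        counts = np.column_stack([weak, strong])
        g = toy_genotypes(counts, gene_map={"rs0": "gA", "rs1": "gA"})
        score = build_score(g, comp, p_threshold=0.05)
        assert score.snps == ["rs1"]  # smaller p wins within the gene

    def test_tie_break_lexicographic(self):
        rng = np.random.default_rng(4)
        n = 200
        comp = rng.standard_normal(n)
        snp = np.clip(np.round(comp + 1), 0, 2)
        counts = np.column_stack([snp, snp])  # identical SNPs, identical p
        g = toy_genotypes(counts, gene_map={"rs0": "gA", "rs1": "gA"})
        score = build_score(g, comp)
        assert score.snps == ["rs0"]

    def test_shared_top_snp_prunes_weaker_gene(self):
        rng = np.random.default_rng(5)
        n = 300
        comp = rng.standard_normal(n)
        snp = np.clip(np.round(comp + 1), 0, 2)
        counts = snp[:, None]
        g = toy_genotypes(counts, gene_map={"rs0": "gA"})
        # same SNP mapped to two genes via the gene_set path: emulate by two
        # genotype columns with the same data mapped to different genes
        counts2 = np.column_stack([snp, snp])
        g2 = toy_genotypes(counts2, gene_map={"rs0": "gA", "rs1": "gB"})
        score = build_score(g2, comp)
        assert len(score.snps) == 2  # distinct SNP ids: both kept
        assert len(set(score.genes.values())) == 2

    def test_no_qualifying_snp_is_error(self):
        rng = np.random.default_rng(6)
        counts = rng.binomial(2, 0.3, size=(50, 2)).astype(float)
        comp = rng.standard_normal(50)
        with pytest.raises(ValueError, match="no SNP qualifies"):
            build_score(toy_genotypes(counts), comp, p_threshold=1e-12)

    def test_score_invariant_to_snp_order(self):
        rng = np.random.default_rng(7)
        n = 300
        comp = rng.standard_normal(n)
        counts = np.column_stack(
            [np.clip(np.round(0.8 * comp + 1 + 0.3 * rng.standard_normal(n)), 0, 2) for _ in range(4)]
        )
        g1 = toy_genotypes(counts)
        perm = [2, 0, 3, 1]
        g2 = GenotypeMatrix(
            counts[:, perm],
            g1.sample_ids,
            [g1.snp_ids[j] for j in perm],
            gene_map=g1.gene_map,
        )
        s1 = build_score(g1, comp)
        s2 = build_score(g2, comp)
        np.testing.assert_allclose(s1.per_sample_score, s2.per_sample_score, atol=1e-12)


class TestScorePhenotypeTest:
    def test_exact_zero_r_one_sided_half(self):
        x = np.array([1.0, -1.0, 2.0, -2.0, 0.0, 0.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 2.0, -2.0])
        assert abs(np.corrcoef(x, y)[0, 1]) < 1e-12
        res = score_phenotype_test(x, y, sidedness="less")
        assert res.p_nominal == pytest.approx(0.5)

    def test_negative_r_lower_tail(self):
        x = np.arange(10.0)
        y = -x + np.random.default_rng(8).normal(0, 2, 10)
        res = score_phenotype_test(x, y, sidedness="less")
        assert res.p_nominal < 0.5

    def test_one_sided_type_i_error(self):
        rng = np.random.default_rng(9)
        n, reps = 100, 10_000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = stats.t.cdf(t, n - 2)  # lower tail
        for i in range(3):
            assert score_phenotype_test(x[i], y[i], sidedness="less").p_nominal == pytest.approx(
                p[i], abs=1e-10
            )
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestStoufferMeta:
    def test_table_of_four_weighted_r(self):
        results = [
            (-0.062, 1445, 0.00912),
            (-0.02, 534, 0.32),
            (-0.073, 624, 0.0349),
            (-0.076, 743, 0.0191),
        ]
        _, weighted_r = stouffer_meta(results)
        assert round(weighted_r, 2) == -0.06

    def test_combined_p_in_printed_range(self):
        results = [
            (-0.062, 1445, 0.00912),
            (-0.02, 534, 0.32),
            (-0.073, 624, 0.0349),
            (-0.076, 743, 0.0191),
        ]
        for weighting in ("sqrt_n", "n", "none"):
            p, _ = stouffer_meta(results, weighting=weighting)
            assert 1e-4 < p < 1e-3

    def test_identical_studies_closed_form(self):
        p_single = 0.05
        z = stats.norm.isf(p_single)
        for k in (2, 4):
            results = [(0.1, 100, p_single)] * k
            p, _ = stouffer_meta(results)
            assert p == pytest.approx(stats.norm.sf(np.sqrt(k) * z), rel=1e-10)

    def test_two_studies_hand_computed(self):
        z = stats.norm.isf(0.05)
        p, _ = stouffer_meta([(0.1, 50, 0.05), (0.2, 50, 0.05)])
        assert p == pytest.approx(stats.norm.sf(2 * z / np.sqrt(2)), rel=1e-10)

    def test_single_study_identity(self):
        p, r = stouffer_meta([(0.3, 100, 0.07)])
        assert p == pytest.approx(0.07, rel=1e-10)
        assert r == pytest.approx(0.3)

    def test_degenerate_p_clipped(self):
        p, _ = stouffer_meta([(0.1, 50, 0.0), (0.1, 50, 0.5)])
        assert 0.0 < p < 1.0


class TestCisEnrichment:
    def test_snps_on_cpgs_fraction_one(self):
        cpg = pd.DataFrame({"chrom": ["1", "2"], "pos": [100, 200]})
        snp = pd.DataFrame({"chrom": ["1", "2"], "pos": [100, 200]})
        frac, _ = mqtl_cis_enrichment(snp, cpg, {"1": 1000, "2": 1000}, window=10, n_perm=50, seed=0)
        assert frac == 1.0

    def test_saturated_genome_p_near_one(self):
        cpg = pd.DataFrame({"chrom": ["1"], "pos": [500_000]})
        snp = pd.DataFrame({"chrom": ["1"], "pos": [100]})
        frac, p = mqtl_cis_enrichment(
            snp, cpg, {"1": 1_000_000}, window=1_000_000, n_perm=200, seed=1
        )
        assert frac == 1.0
        assert p > 0.9

    def test_geometric_probability_oracle(self):
        # one CpG in the middle of a 10 Mb genome, 1 Mb window: a uniform SNP
        # lands cis with probability ~0.2
        cpg = pd.DataFrame({"chrom": ["1"], "pos": [5_000_000]})
        rng = np.random.default_rng(2)
        positions = rng.integers(1, 10_000_001, size=400)
        snp = pd.DataFrame({"chrom": ["1"] * 400, "pos": positions})
        frac, _ = mqtl_cis_enrichment(
            snp, cpg, {"1": 10_000_000}, window=1_000_000, n_perm=100, seed=3
        )
        se = np.sqrt(0.2 * 0.8 / 400)
        assert abs(frac - 0.2) < 4 * se

    def test_p_floor(self):
        cpg = pd.DataFrame({"chrom": ["1"], "pos": [100]})
        snp = pd.DataFrame({"chrom": ["1"] * 20, "pos": [100] * 20})
        _, p = mqtl_cis_enrichment(snp, cpg, {"1": 100_000_000}, window=10, n_perm=99, seed=4)
        assert p == pytest.approx(1 / 100)


class TestMqtlPairTests:
    @staticmethod
    def _residuals(values):
        values = np.asarray(values, dtype=float)
        std = (values - values.mean(0)) / values.std(0, ddof=1)
        n, p = std.shape
        return ResidualMatrix(std, [f"s{i}" for i in range(n)], [f"cg{j}" for j in range(p)])

    def test_null_ks_not_significant(self):
        rng = np.random.default_rng(10)
        n, m = 300, 40
        counts = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        meth = rng.standard_normal((n, m))
        g = toy_genotypes(counts)
        res = self._residuals(meth)
        pairs = [(f"rs{j}", f"cg{j}") for j in range(m)]
        table = mqtl_pair_tests(g, res, pairs)
        assert table.attrs["ks"]["p"] > 0.01

    def test_planted_effects_left_shift(self):
        rng = np.random.default_rng(11)
        n, m = 300, 30
        counts = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        meth = 0.4 * counts + rng.standard_normal((n, m))
        table = mqtl_pair_tests(
            toy_genotypes(counts),
            self._residuals(meth),
            [(f"rs{j}", f"cg{j}") for j in range(m)],
        )
        assert table.attrs["ks"]["p"] < 0.01
        assert (table["p"] < 0.05).mean() > 0.5

    def test_perfect_relation_tiny_p(self):
        rng = np.random.default_rng(12)
        counts = rng.binomial(2, 0.5, size=(100, 1)).astype(float)
        meth = counts.copy()
        table = mqtl_pair_tests(
            toy_genotypes(counts), self._residuals(meth), [("rs0", "cg0")]
        )
        assert table["p"].iloc[0] < 1e-100

    def test_monomorphic_skipped(self):
        counts = np.column_stack([np.zeros(50), np.random.default_rng(13).binomial(2, 0.4, 50)])
        meth = np.random.default_rng(14).standard_normal((50, 2))
        table = mqtl_pair_tests(
            toy_genotypes(counts),
            self._residuals(meth),
            [("rs0", "cg0"), ("rs1", "cg1")],
        )
        assert list(table["snp"]) == ["rs1"]
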