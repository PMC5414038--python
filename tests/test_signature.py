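import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylica.decompose import ICAModel, decompose
from methylica.preprocess import BetaMatrix, residualize
from methylica.signature import (
    classify_context,
    context_chisq,
    overlap_test,
    project,
    select_cpgs,
)
from methylica.synthetic import (
    SyntheticDesign,
    generate_methylome,
)


def model_from_loadings(row: np.ndarray) -> ICAModel:
    row = np.asarray(row, dtype=float)
    return ICAModel(
        loadings=row[None, :],
        mixing=np.random.default_rng(0).standard_normal((10, 1)),
        sample_ids=[f"s{i}" for i in range(10)],
        cpg_ids=[f"cg{j}" for j in range(row.size)],
        k=1,
        n_restarts=1,
        stability=np.ones(1),
        dominance=np.full(1, 0.05),
        retained=np.ones(1, dtype=bool),
    )


class TestSelectCpgs:
    def test_gaussian_tail_count(self):
        rng = np.random.default_rng(1)
        p = 400_000
        row = rng.standard_normal(p)
        sig = select_cpgs(model_from_loadings(row), 0, n_sigma=4.0)
        expected = p * 2 * stats.norm.sf(4.0)  # ~25.3
        band = stats.poisson(expected).ppf([0.005, 0.995])
        assert band[0] <= len(sig) <= band[1]

    def test_small_n_arithmetic(self):
        # mean 2.5, sample sd 5: |10 - 2.5| = 7.5 < 4 * 5 -> empty
        sig = select_cpgs(model_from_loadings([0.0, 0.0, 0.0, 10.0]), 0, n_sigma=4.0)
        assert len(sig) == 0

    def test_planted_recall(self):
        design = SyntheticDesign(
            n_samples=300, n_cpgs=8000, n_components=4, loading_scale=6.0,
            signal_scale=0.05, seed=5,
        )
        betas, truth = generate_methylome(design)
        model = decompose(residualize(betas), k=4, n_restarts=5, seed=5)
        # match each planted component to its best estimated counterpart
        recalls = []
        for j in range(4):
            best = max(
                range(4),
                key=lambda i: abs(np.corrcoef(truth.mixing[:, j], model.mixing[:, i])[0, 1]),
            )
            sig = select_cpgs(model, best, n_sigma=4.0)
            planted = {f"cg{c + 1:07d}" for c in truth.active_sets[j]}
            recalls.append(len(planted & sig.cpg_set) / len(planted))
        assert min(recalls) >= 0.9

    def test_affine_rescale_equivariance(self):
        rng = np.random.default_rng(2)
        row = rng.standard_normal(500) * np.where(rng.random(500) < 0.01, 20, 1)
        s1 = select_cpgs(model_from_loadings(row), 0, 3.0)
        s2 = select_cpgs(model_from_loadings(5.0 * row + 2.0), 0, 3.0)
        assert s1.cpg_set == s2.cpg_set


def brute_force_context(cpgs: pd.DataFrame, transcripts: pd.DataFrame) -> list[str]:
    """Oracle: exhaustive per-transcript interval scan."""
    flags = []
    for _, cpg in cpgs.iterrows():
        flag = "Intergenic"
        genic = False
        tss = False
        for _, tr in transcripts.iterrows():
            if str(tr["chrom"]) != str(cpg["chrom"]):
                continue
            pos = int(cpg["pos"])
            t = int(tr["start"]) if tr["strand"] == "+" else int(tr["end"])
            if tr["strand"] == "+" and t - 1500 <= pos <= t - 1:
                tss = True
            if tr["strand"] == "-" and t + 1 <= pos <= t + 1500:
                tss = True
            if int(tr["start"]) <= pos <= int(tr["end"]):
                genic = True
        if tss:
            flag = "TSS"
        elif genic:
            flag = "Genic"
        flags.append(flag)
    return flags


class TestClassifyContext:
    def toy_transcripts(self):
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "2"],
                "start": [10_000, 30_000, 5_000],
                "end": [20_000, 40_000, 9_000],
                "strand": ["+", "-", "+"],
            }
        )

    def test_upstream_plus_strand_is_tss(self):
        cpgs = pd.DataFrame({"cpg_id": ["a"], "chrom": ["1"], "pos": [9_000]})
        flags = classify_context(cpgs, self.toy_transcripts())
        assert flags["a"] == "TSS"

    def test_tss_precedence_over_genic(self):
        # inside transcript 1 body and 1,200 bp upstream of a '-' TSS at 40,000?
        # position 41_200 is upstream of the '-' transcript and outside bodies
        cpgs = pd.DataFrame(
            {"cpg_id": ["a", "b"], "chrom": ["1", "1"], "pos": [15_000, 41_200]}
        )
        flags = classify_context(cpgs, self.toy_transcripts())
        assert flags["a"] == "Genic"
        assert flags["b"] == "TSS"

    def test_overlapping_body_and_upstream_precedence(self):
        transcripts = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [1_000, 6_200],
                "end": [10_000, 9_500],
                "strand": ["+", "+"],
            }
        )
        # inside first transcript body AND 1,200 bp upstream of the second TSS
        cpgs = pd.DataFrame({"cpg_id": ["a"], "chrom": ["1"], "pos": [5_000]})
        assert classify_context(cpgs, transcripts)["a"] == "TSS"

    def test_unknown_chromosome_warns_intergenic(self):
        cpgs = pd.DataFrame({"cpg_id": ["a"], "chrom": ["99"], "pos": [123]})
        with pytest.warns(UserWarning, match="unannotated"):
            flags = classify_context(cpgs, self.toy_transcripts())
        assert flags["a"] == "Intergenic"

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        transcripts = pd.DataFrame(
            {
                "chrom": rng.integers(1, 3, size=5).astype(str),
                "start": rng.integers(1, 80_000, size=5),
                "strand": rng.choice(["+", "-"], size=5),
            }
        )
        transcripts["end"] = transcripts["start"] + rng.integers(1_000, 20_000, size=5)
        cpgs = pd.DataFrame(
            {
                "cpg_id": [f"cg{i}" for i in range(50)],
                "chrom": rng.integers(1, 3, size=50).astype(str),
                "pos": rng.integers(1, 100_000, size=50),
            }
        )
        got = classify_context(cpgs, transcripts)
        expected = brute_force_context(cpgs, transcripts)
        assert list(got) == expected


class TestContextChisq:
    def test_identical_proportions_zero(self):
        bg = pd.Series(["A"] * 40 + ["B"] * 40 + ["C"] * 20)
        sig = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 10)
        chi2, df, p = context_chisq(sig, bg)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_single_category_closed_form(self):
        # uniform background over 4 categories, signature all in one: chi2 = 3n
        bg = pd.Series(["A", "B", "C", "D"] * 25)
        n = 40
        sig = pd.Series(["A"] * n)
        chi2, df, p = context_chisq(sig, bg)
        assert chi2 == pytest.approx(3 * n)
        assert df == 3

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        cats = np.array(["A", "B", "C", "D"])
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        bg = pd.Series(np.repeat(cats, (probs * 1000).astype(int)))
        pvals = []
        for _ in range(500):
            draw = pd.Series(rng.choice(cats, size=200, p=probs))
            pvals.append(context_chisq(draw, bg)[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_small_expected_warns(self):
        bg = pd.Series(["A"] * 99 + ["B"])
        sig = pd.Series(["A"] * 10)
        with pytest.warns(UserWarning, match="expected count"):
            context_chisq(sig, bg)


class TestProject:
    def test_training_round_trip(self, recovery_model):
        model = recovery_model["model"]
        design = recovery_model["design"]
        betas, _ = generate_methylome(design)
        pattern = project(model, 0, betas)
        r = abs(np.corrcoef(pattern.weights, model.mixing[:, 0])[0, 1])
        assert r > 0.999

    def test_independent_cohort_recovers_truth(self, recovery_model):
        # new samples, same loadings: regenerate with a different seed but
        # project with the trained model; compare to the new cohort's truth
        design = recovery_model["design"]
        model = recovery_model["model"]
        truth = recovery_model["truth"]
        import dataclasses

        new_design = dataclasses.replace(design, seed=design.seed + 1000)
        betas_new, truth_new = generate_methylome(new_design)
        # the new cohort has its own loadings; instead build a cohort from the
        # *training* loadings with fresh mixing weights
        rng = np.random.default_rng(17)
        A_new = rng.standard_normal((150, design.n_components))
        logits = truth.baselines[None, :] + design.signal_scale * (
            A_new @ truth.loadings + 0.3 * rng.standard_normal((150, design.n_cpgs))
        )
        betas_cohort = BetaMatrix(
            1 / (1 + np.exp(-logits)),
            [f"new{i}" for i in range(150)],
            [f"cg{j + 1:07d}" for j in range(design.n_cpgs)],
        )
        # align: trained component 0 corresponds to some planted component
        best_j = max(
            range(design.n_components),
            key=lambda j: abs(np.corrcoef(truth.mixing[:, j], model.mixing[:, 0])[0, 1]),
        )
        pattern = project(model, 0, betas_cohort)
        r = abs(np.corrcoef(pattern.weights, A_new[:, best_j])[0, 1])
        assert r > 0.9

    def test_permutation_alignment_invariance(self, recovery_model):
        model = recovery_model["model"]
        design = recovery_model["design"]
        betas, _ = generate_methylome(design)
        rng = np.random.default_rng(18)
        perm = rng.permutation(design.n_cpgs)
        shuffled = BetaMatrix(
            betas.values[:, perm],
            betas.sample_ids,
            [betas.cpg_ids[j] for j in perm],
        )
        p1 = project(model, 0, betas)
        p2 = project(model, 0, shuffled)
        np.testing.assert_allclose(p1.weights, p2.weights, atol=1e-8)

    def test_low_overlap_is_error(self, recovery_model):
        model = recovery_model["model"]
        design = recovery_model["design"]
        betas, _ = generate_methylome(design)
        half = BetaMatrix(
            betas.values[:, : design.n_cpgs // 2],
            betas.sample_ids,
            betas.cpg_ids[: design.n_cpgs // 2],
        )
        with pytest.raises(ValueError, match="90%"):
            project(model, 0, half)


class TestOverlapTest:
    def test_identical_sets_infinite_or_with_haldane(self):
        s = {f"g{i}" for i in range(20)}
        res = overlap_test(s, s, universe=1000)
        assert np.isinf(res.odds_ratio)
        assert np.isfinite(res.odds_ratio_haldane)
        assert res.odds_ratio_haldane > 100
        assert res.p < 1e-30

    def test_independent_sets_or_near_one(self):
        rng = np.random.default_rng(5)
        universe = 2000
        ors = []
        for _ in range(200):
            a = set(rng.choice(universe, size=200, replace=False))
            b = set(rng.choice(universe, size=200, replace=False))
            ors.append(overlap_test(a, b, universe).odds_ratio)
        assert 0.8 < np.median(ors) < 1.25

    def test_direct_arithmetic_and_tail_sum(self):
        # table a=10, b=5, c=5, d=980
        a_set = {f"x{i}" for i in range(15)}
        b_set = {f"x{i}" for i in range(10)} | {f"y{i}" for i in range(5)}
        universe = 1000
        res = overlap_test(a_set, b_set, universe)
        assert res.odds_ratio == pytest.approx((10 * 980) / (5 * 5))
        # oracle: exhaustive hypergeometric tail sum
        from math import comb

        expected_p = sum(
            comb(15, k) * comb(universe - 15, 15 - k) for k in range(10, 16)
        ) / comb(universe, 15)
        assert res.p == pytest.approx(expected_p, rel=1e-9)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            overlap_test(set(), {"a"}, 10)
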