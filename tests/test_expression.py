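import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from panploid import expression, simulate
from panploid.containers import CountMatrix, HomeologPairSet
from panploid.errors import ParameterError

from conftest import make_count_matrix


class TestRleSizeFactors:
    def test_identical_samples_unit_factors(self):
        cm = make_count_matrix(
            np.array([[10, 10], [20, 20]]), ["g1", "g2"], ["s1", "s2"],
            ["FB", "FB"], [1, 2],
        )
        assert np.allclose(expression.rle_size_factors(cm), [1.0, 1.0])

    def test_two_gene_worked_example(self):
        # counts (10,20) and (20,40): geometric means sqrt(200), sqrt(800);
        # both ratio columns give medians 1/sqrt(2) and sqrt(2)
        cm = make_count_matrix(
            np.array([[10, 20], [20, 40]]), ["g1", "g2"], ["s1", "s2"],
            ["FB", "FB"], [1, 2],
        )
        f = expression.rle_size_factors(cm)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert f["s2"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 100, size=(50, 3))
        cm = make_count_matrix(base, [f"g{i}" for i in range(50)],
                               ["a", "b", "c"], ["FB"] * 3, [1, 2, 3])
        scaled = base.copy()
        scaled[:, 1] *= 5
        cm2 = make_count_matrix(scaled, [f"g{i}" for i in range(50)],
                                ["a", "b", "c"], ["FB"] * 3, [1, 2, 3])
        f1 = expression.rle_size_factors(cm)
        f2 = expression.rle_size_factors(cm2)
        # factors are defined up to a common scale (the geometric-mean
        # reference moves too), so equivariance shows up in factor ratios
        assert (f2["b"] / f2["a"]) / (f1["b"] / f1["a"]) == pytest.approx(5.0, rel=1e-9)

    def test_median_ratio_to_reference_is_one(self):
        # odd gene count so the log-space median is an actual data point
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 500, size=(201, 4))
        cm = make_count_matrix(counts, [f"g{i}" for i in range(201)],
                               list("wxyz"), ["FB"] * 4, [1, 2, 3, 4])
        f = expression.rle_size_factors(cm)
        norm = cm.counts / f
        log_ref = np.log(cm.counts.to_numpy(dtype=float)).mean(axis=1)
        ratios = norm.to_numpy() / np.exp(log_ref)[:, None]
        assert np.allclose(np.median(ratios, axis=0), 1.0)

    def test_no_common_positive_gene_rejected(self):
        cm = make_count_matrix(
            np.array([[5, 0], [0, 5]]), ["g1", "g2"], ["s1", "s2"],
            ["FB", "FB"], [1, 2],
        )
        with pytest.raises(ParameterError, match="pseudo-reference"):
            expression.rle_size_factors(cm)


class TestSignPermutation:
    def test_matches_explicit_enumeration(self):
        rng = np.random.default_rng(3)
        R = rng.normal(0.3, 1.0, size=(20, 4))
        got = expression._sign_permutation_p(R)
        for row, p in zip(R, got):
            obs = abs(row.mean())
            count = sum(
                abs(np.dot(signs, row) / len(row)) >= obs - 1e-12
                for signs in itertools.product([1, -1], repeat=len(row))
            )
            assert p == pytest.approx(count / 2 ** len(row))


def pairs_for(n):
    return HomeologPairSet(
        pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "gene_A": [f"gA{i}" for i in range(n)],
                "gene_B": [f"gB{i}" for i in range(n)],
                "chrom_pair": ["chr1A|chr1B"] * n,
            }
        )
    )


class TestHebTest:
    def test_identical_homeologs_unbiased(self):
        counts = np.array([[10, 12, 11], [10, 12, 11]])
        cm = make_count_matrix(counts, ["gA0", "gB0"],
                               ["FB_1", "FB_2", "FB_3"], ["FB"] * 3, [1, 2, 3])
        res = expression.heb_test(cm, pairs_for(1), "FB")
        assert res.iloc[0]["log2fc"] == 0
        assert not res.iloc[0]["biased"]

    def test_single_replicate_reports_fc_without_p(self):
        counts = np.array([[10], [40]])
        cm = make_count_matrix(counts, ["gA0", "gB0"], ["FB_1"], ["FB"], [1])
        res = expression.heb_test(cm, pairs_for(1), "FB")
        assert res.iloc[0]["log2fc"] > 0
        assert np.isnan(res.iloc[0]["p"])
        assert not res.iloc[0]["biased"]

    def test_biased_fc_estimate_near_truth(self):
        # Monte-Carlo: with true bias 2 log2-units the estimated log2fc of
        # biased pairs averages within 0.3 of 2.0
        errs = []
        for seed in range(50):
            cm, pairs, truth = simulate.make_homeolog_counts(
                50, 1, 3, 0.2, 2.0, 0.05, seed=seed
            )
            res = expression.heb_test(cm, pairs, "FB")
            biased = res[res["pair_id"].isin(truth.biased_pairs)]
            errs.append(biased["log2fc"].mean())
        assert np.mean(errs) == pytest.approx(2.0, abs=0.3)

    def test_null_biased_fraction_below_alpha(self):
        fracs = []
        for seed in range(20):
            cm, pairs, _ = simulate.make_homeolog_counts(
                300, 1, 3, 0.0, 0.0, 0.05, seed=100 + seed
            )
            res = expression.heb_test(cm, pairs, "FB", alpha=0.05)
            fracs.append(res["biased"].mean())
        assert np.mean(fracs) <= 0.05

    def test_bh_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=200)
        q = expression._bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassifyBreadth:
    def make_results(self, biased_by_tissue):
        out = {}
        for t, flags in biased_by_tissue.items():
            n = len(flags)
            out[t] = pd.DataFrame(
                {
                    "pair_id": [f"p{i}" for i in range(n)],
                    "chrom_pair": ["c1"] * n,
                    "tissue": t,
                    "log2fc": [0.0] * n,
                    "p": [0.5] * n,
                    "q": [0.5] * n,
                    "biased": flags,
                }
            )
        return out

    def test_breadth_counting(self):
        results = self.make_results(
            {"FB": [True, True, False], "FF": [False, True, False],
             "JF": [False, True, False], "L": [False, True, False]}
        )
        table, summary = expression.classify_breadth(results)
        assert summary["biased_any_tissue"] == 2
        assert summary["biased_all_tissues"] == 1
        assert table.set_index("pair_id").at["p0", "tissues_biased"] == "FB"

    def test_na_p_excluded_from_all_only(self):
        results = self.make_results({"FB": [True], "FF": [True]})
        results["FF"].loc[0, "p"] = np.nan
        _, summary = expression.classify_breadth(results)
        assert summary["biased_any_tissue"] == 1
        assert summary["biased_all_tissues"] == 0

    def test_inconsistent_pair_sets_rejected(self):
        results = self.make_results({"FB": [True, False], "FF": [True]})
        with pytest.raises(ParameterError):
            expression.classify_breadth(results)


class TestChromosomeBias:
    def heb_frame(self, log2fc, chrom="c1"):
        n = len(log2fc)
        return pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "chrom_pair": [chrom] * n,
                "tissue": "FB",
                "mean_norm_A": np.ones(n),
                "mean_norm_B": np.exp2(log2fc),
                "log2fc": log2fc,
                "p": 0.5,
                "q": 0.5,
                "biased": False,
            }
        )

    def test_uniform_positive_fc_points_to_B(self):
        res = expression.chromosome_bias(self.heb_frame([1.0] * 8))
        row = res[res["chrom_pair"] == "c1"].iloc[0]
        assert row["direction"] == "B"
        assert row["p"] == pytest.approx(2 / 2 ** 8, rel=0.1)

    def test_symmetric_fc_has_no_direction(self):
        res = expression.chromosome_bias(self.heb_frame([1.0, -1.0, 1.0, -1.0]))
        assert res[res["chrom_pair"] == "c1"].iloc[0]["direction"] == "none"

    def test_all_zero_fc_p_one(self):
        res = expression.chromosome_bias(self.heb_frame([0.0] * 5))
        row = res[res["chrom_pair"] == "c1"].iloc[0]
        assert row["p"] == 1.0
        assert row["direction"] == "none"

    def test_exact_p_matches_sign_enumeration(self):
        values = np.array([1.0, 2.0, 3.0, -1.0])
        res = expression.chromosome_bias(self.heb_frame(values))
        got = res[res["chrom_pair"] == "c1"].iloc[0]["p"]
        # brute-force: signed-rank W over all 2^4 sign assignments
        ranks = np.argsort(np.argsort(np.abs(values))) + 1
        obs = ranks[values > 0].sum()
        n = len(values)
        total = ranks.sum()
        ws = []
        for signs in itertools.product([1, -1], repeat=n):
            w = ranks[np.array(signs) > 0].sum()
            ws.append(min(w, total - w))
        obs_stat = min(obs, total - obs)
        expected = sum(w <= obs_stat for w in ws) / 2 ** n
        assert got == pytest.approx(expected)

    def test_ranksum_mode(self):
        frame = self.heb_frame(np.linspace(0.5, 1.5, 10))
        res = expression.chromosome_bias(frame, mode="ranksum")
        assert (res["direction"] == "B").all()


class TestPavExpressionContrast:
    def make_cm(self, n_genes, seed, shift_first_half=1.0):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(20, 200, size=n_genes)
        mu[: n_genes // 2] *= shift_first_half
        counts = rng.poisson(mu[:, None], size=(n_genes, 3))
        return make_count_matrix(
            counts, [f"g{i}" for i in range(n_genes)],
            ["FB_1", "FB_2", "FB_3"], ["FB"] * 3, [1, 2, 3],
        )

    def test_same_distribution_p_uniformish(self):
        ps = [
            expression.pav_expression_contrast(
                self.make_cm(300, seed), {f"g{i}" for i in range(150)}, "FB"
            )["p"]
            for seed in range(20)
        ]
        assert 0.02 < np.mean(ps) < 0.98  # no systematic bias
        assert max(ps) > 0.2

    def test_downshifted_set_detected(self):
        res = expression.pav_expression_contrast(
            self.make_cm(1000, 5, shift_first_half=0.5),
            {f"g{i}" for i in range(500)}, "FB",
        )
        assert res["p"] < 0.05
        assert res["median_affected"] < res["median_rest"]

    def test_empty_set_rejected(self):
        with pytest.raises(ParameterError):
            expression.pav_expression_contrast(self.make_cm(10, 0), set(), "FB")


class TestDegBetweenGroups:
    def make_two_group_cm(self, n_genes, fold_first_frac, fold, seed):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(20, 500, size=n_genes)
        n_changed = int(n_genes * fold_first_frac)
        mu2 = mu.copy()
        mu2[:n_changed] *= fold
        disp = 0.05
        size = 1 / disp
        g1 = rng.negative_binomial(size, size / (size + mu[:, None]), (n_genes, 3))
        g2 = rng.negative_binomial(size, size / (size + mu2[:, None]), (n_genes, 3))
        counts = np.hstack([g1, g2])
        samples = [f"X_{i}" for i in range(3)] + [f"Y_{i}" for i in range(3)]
        return make_count_matrix(
            counts, [f"g{i}" for i in range(n_genes)], samples,
            ["FB"] * 6, [1, 2, 3, 1, 2, 3],
        ), n_changed, samples

    def test_identical_groups_no_degs(self):
        rng = np.random.default_rng(0)
        half = rng.poisson(100, size=(50, 3))
        counts = np.hstack([half, half])  # group2 duplicates group1
        samples = [f"X_{i}" for i in range(3)] + [f"Y_{i}" for i in range(3)]
        cm = make_count_matrix(counts, [f"g{i}" for i in range(50)], samples,
                               ["FB"] * 6, [1, 2, 3, 1, 2, 3])
        res = expression.deg_between_groups(cm, samples[:3], samples[3:])
        assert res["deg"].sum() == 0
        assert (res["log2fc"] == 0).all()

    def test_label_swap_flips_log2fc(self):
        cm, _, samples = self.make_two_group_cm(50, 0.2, 4.0, 1)
        a = expression.deg_between_groups(cm, samples[:3], samples[3:])
        b = expression.deg_between_groups(cm, samples[3:], samples[:3])
        assert np.allclose(a["log2fc"], -b["log2fc"])

    def test_power_at_fourfold_change(self):
        # 10% of genes at 4-fold change, NB dispersion 0.05, 3v3
        recalls = []
        for seed in range(10):
            cm, n_changed, samples = self.make_two_group_cm(400, 0.1, 4.0, 10 + seed)
            res = expression.deg_between_groups(cm, samples[:3], samples[3:])
            recalls.append(res["deg"][:n_changed].mean())
        assert np.mean(recalls) >= 0.8

    def test_permutation_method_enumerates_labels(self):
        cm, _, samples = self.make_two_group_cm(30, 0.5, 4.0, 2)
        res = expression.deg_between_groups(
            cm, samples[:3], samples[3:], method="permutation"
        )
        # with C(6,3)=20 assignments the smallest attainable p is 2/20
        assert res["p"].min() >= 0.1 - 1e-12

    def test_too_few_replicates_rejected(self):
        cm, _, samples = self.make_two_group_cm(10, 0.0, 1.0, 3)
        with pytest.raises(ParameterError):
            expression.deg_between_groups(cm, samples[:1], samples[1:])


class TestHebRecoveryRoc:
    def test_auc_high_at_strong_bias(self):
        aucs = []
        for seed in range(5):
            cm, pairs, truth = simulate.make_homeolog_counts(
                500, 1, 3, 0.1, 2.0, 0.05, seed=seed
            )
            res = expression.heb_test(cm, pairs, "FB")
            is_biased = res["pair_id"].isin(truth.biased_pairs).to_numpy()
            score = res["log2fc"].abs().to_numpy()
            u = mannwhitneyu(score[is_biased], score[~is_biased]).statistic
            aucs.append(u / (is_biased.sum() * (~is_biased).sum()))
        assert np.mean(aucs) >= 0.95
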