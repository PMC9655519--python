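import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import phosphoquant as pq
from phosphoquant.diffstats import (
    ModeratedTTest,
    _trigamma_inverse,
    bh_adjust,
    fit_variance_prior,
    moderated_t_test,
)
from phosphoquant.io import DataError


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "mean_a,mean_b,fold",
        [
            # printed condition means of a 23.2-fold protein induction
            (1.57e6, 3.64e7, 23.2),
            (2.90e6, 2.63e8, 90.6),
        ],
    )
    def test_direction_resolved_fold(self, mean_a, mean_b, fold):
        ratio, log2fc = pq.log2_fold_change(mean_a, mean_b)
        assert max(ratio, 1 / ratio) == pytest.approx(fold, rel=0.01)
        assert log2fc == pytest.approx(math.log2(ratio))

    def test_equal_means_identity(self):
        ratio, log2fc = pq.log2_fold_change(5.0, 5.0)
        assert ratio == 1.0 and log2fc == 0.0

    def test_volcano_cutoff_fold_equivalence(self):
        """The log2 cutoff 1.17 corresponds to a 2.25-fold change."""
        assert 2 ** 1.17 == pytest.approx(2.25, abs=0.005)

    def test_non_positive_mean_is_hard_error(self):
        with pytest.raises(DataError):
            pq.log2_fold_change(0.0, 1.0)


class TestVariancePrior:
    def test_recovery_from_scaled_f_model(self):
        """Variances ~ s0^2 F(d_g, d0) with d0=4, s0^2=1: moment matching
        recovers d0 within 25% and s0^2 within 10% at 5000 features."""
        rng = np.random.default_rng(7)
        d0, s0_sq, d_g, n = 4.0, 1.0, 4, 5000
        s2 = s0_sq * (rng.chisquare(d_g, n) / d_g) * (d0 / rng.chisquare(d0, n))
        prior = fit_variance_prior(s2, residual_df=d_g)
        assert prior.d0 == pytest.approx(d0, rel=0.25)
        assert prior.s0_sq == pytest.approx(s0_sq, rel=0.10)

    def test_identical_variances_give_infinite_d0(self):
        prior = fit_variance_prior(np.full(100, 0.3), residual_df=4)
        assert math.isinf(prior.d0)
        assert prior.s0_sq > 0

    def test_two_features_never_crash(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prior = fit_variance_prior(rng.chisquare(4, 2) / 4, residual_df=4)
            assert prior.s0_sq > 0 and (math.isinf(prior.d0) or prior.d0 > 0)

    def test_all_zero_variances_is_hard_error(self):
        with pytest.raises(DataError):
            fit_variance_prior(np.zeros(10), residual_df=4)

    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma

        for y in (0.01, 0.5, 1.0, 7.3, 150.0):
            x = float(polygamma(1, y))
            assert _trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def _data(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        X = rng.normal(20, 1, size=(6, n))
        y = np.array(["A"] * 3 + ["B"] * 3)
        return X, y

    def test_identical_groups_give_t0_p1(self):
        X = np.tile(np.array([[5.0, 6.0, 7.0]]).T, (2, 4))
        y = np.array(["A"] * 3 + ["B"] * 3)
        t, p, _ = moderated_t_test(X, y, ("A", "B"), pq.VariancePrior(4.0, 0.05))
        assert np.all(t == 0) and np.all(p == 1)

    def test_d0_zero_equals_classical_pooled_t(self):
        """With no moderation the statistic is the textbook pooled t."""
        X, y = self._data(seed=1)
        t, p, df = moderated_t_test(X, y, ("A", "B"), pq.VariancePrior(0.0, 1.0))
        t_ref, p_ref = stats.ttest_ind(X[3:], X[:3], equal_var=True)
        assert df == 4
        np.testing.assert_allclose(t, t_ref, atol=1e-12)
        np.testing.assert_allclose(p, p_ref, atol=1e-12)

    def test_huge_d0_approaches_known_variance_z_test(self):
        X, y = self._data(seed=2)
        s0_sq = 1.3
        t, p, _ = moderated_t_test(X, y, ("A", "B"), pq.VariancePrior(1e9, s0_sq))
        diff = X[3:].mean(axis=0) - X[:3].mean(axis=0)
        z = diff / np.sqrt(s0_sq * (1 / 3 + 1 / 3))
        p_ref = 2 * stats.norm.sf(np.abs(z))
        np.testing.assert_allclose(p, p_ref, atol=1e-6)

    def test_infinite_d0_uses_normal_reference(self):
        X, y = self._data(seed=3)
        t, p, df = moderated_t_test(
            X, y, ("A", "B"), pq.VariancePrior(math.inf, 0.5)
        )
        assert math.isinf(df)
        np.testing.assert_allclose(p, 2 * stats.norm.sf(np.abs(t)))

    def test_single_replicate_condition_is_hard_error(self):
        X = np.zeros((4, 5))
        y = np.array(["A", "A", "A", "B"])
        with pytest.raises(DataError, match=">= 2 samples"):
            moderated_t_test(X, y, ("A", "B"), pq.VariancePrior(4.0, 0.05))

    def test_null_type_one_error_calibrated(self):
        """On pure null data the moderated test rejects at ~ the nominal 5%."""
        rng = np.random.default_rng(42)
        sigma2 = 0.05 * 4 / rng.chisquare(4, 2000)
        X = rng.normal(0, np.sqrt(sigma2)[None, :], size=(6, 2000))
        y = np.array(["A"] * 3 + ["B"] * 3)
        est = ModeratedTTest(pair=("A", "B")).fit(X, y)
        frac = float(np.mean(est.p_ < 0.05))
        band = 2.576 * math.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < band


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma_ebayes(tmp_path):
    """Full moment-matching + moderated t agrees with the Bioconductor limma
    eBayes implementation on the same matrix (independent oracle)."""
    rng = np.random.default_rng(11)
    n = 300
    sigma2 = 0.05 * 4 / rng.chisquare(4, n)
    E = rng.normal(0, np.sqrt(sigma2)[:, None], size=(n, 6)) + 20
    E[:30, 3:] += 1.5
    mat = tmp_path / "mat.tsv"
    pd.DataFrame(E).to_csv(mat, sep="\t", index=False)
    out = tmp_path / "limma.csv"
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        E <- as.matrix(read.delim("{mat}"))
        design <- cbind(Intercept = 1, B = c(0, 0, 0, 1, 1, 1))
        fit <- eBayes(lmFit(E, design))
        write.csv(data.frame(d0 = fit$df.prior, s0 = fit$s2.prior,
                             t = fit$t[, 2], p = fit$p.value[, 2]),
                  "{out}", row.names = FALSE)
    """)
    res = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    if res.returncode != 0:
        pytest.skip(f"limma oracle unavailable: {res.stderr[-200:]}")
    ref = pd.read_csv(out)
    y = np.array(["A"] * 3 + ["B"] * 3)
    est = ModeratedTTest(pair=("A", "B")).fit(E.T, y)
    assert est.prior_.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
    assert est.prior_.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-5)
    np.testing.assert_allclose(est.t_, ref["t"], atol=1e-8)
    np.testing.assert_allclose(est.p_, ref["p"], atol=1e-8)


def bh_brute_force(p):
    """q_i = min over j with p_j >= p_i of n*p_j/rank_j (rank in sorted order)."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    rank_of = np.empty(n, int)
    rank_of[order] = np.arange(1, n + 1)
    q = np.empty(n)
    for i in range(n):
        cands = [n * p[j] / rank_of[j] for j in range(n) if p[j] >= p[i]]
        q[i] = min(min(cands), 1.0)
    return q


class TestBH:
    def test_closed_form_examples(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(50)
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-14)

    def test_large_vector_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.random(1000)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-14
        )

    def test_q_at_least_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(500)
        assert np.all(bh_adjust(p) >= p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.randoms())
    def test_permutation_equivariance(self, p, rnd):
        p = np.array(p)
        perm = np.arange(len(p))
        rnd.shuffle(perm)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_p_is_hard_error(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(DataError):
            bh_adjust([0.5, np.nan])


class TestZScore:
    def test_symmetric_vector(self):
        np.testing.assert_allclose(
            pq.zscore_logfc([-1.0, 0.0, 1.0]), [-1.2247448, 0.0, 1.2247448],
            atol=1e-6,
        )

    def test_value_at_mean_is_zero(self):
        z = pq.zscore_logfc([1.0, 2.0, 3.0])
        assert z[1] == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=30),
        st.floats(0.1, 5), st.floats(-3, 3),
    )
    def test_affine_invariance(self, L, a, b):
        L = np.array(L)
        if np.std(L) < 1e-6:
            return
        np.testing.assert_allclose(
            pq.zscore_logfc(L), pq.zscore_logfc(a * L + b), atol=1e-6
        )

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(8)
        z = pq.zscore_logfc(rng.normal(2, 3, 500))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1) < 1e-9

    def test_zero_spread_is_hard_error(self):
        with pytest.raises(DataError, match="zero spread"):
            pq.zscore_logfc([2.0, 2.0, 2.0])


class TestClassification:
    @pytest.mark.parametrize(
        "q,z,label",
        [
            (0.04, 2.0, "up"),
            (0.04, -2.0, "down"),
            (0.04, 1.0, "not_significant"),
            (0.06, 2.5, "not_significant"),
            (0.04, 1.96, "up"),  # boundary: |z| >= 1.96 counts
        ],
    )
    def test_variant_rule(self, q, z, label):
        assert pq.call_variants([q], [z])[0] == label

    @pytest.mark.parametrize(
        "log2fc,p,label",
        [
            (1.5, 0.01, "up"),
            (-1.5, 0.01, "down"),
            (1.5, 0.2, "not_significant"),
            (0.5, 0.01, "not_significant"),
            (1.17, 0.01, "up"),  # boundary: |log2fc| >= 1.17 counts
        ],
    )
    def test_volcano_rule(self, log2fc, p, label):
        assert pq.classify_volcano([log2fc], [p])[0] == label

    def test_volcano_labels_partition_features(self):
        rng = np.random.default_rng(9)
        L, p = rng.normal(0, 2, 300), rng.random(300)
        labels = pq.classify_volcano(L, p)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == 300

    def test_planted_effects_recovered(self):
        """8-fold effects in 50/1000 features at n=3+3: nearly all flagged by
        the dual q/z criterion with few false positives."""
        rng = np.random.default_rng(12)
        n, k = 1000, 50
        sigma2 = 0.05 * 4 / rng.chisquare(4, n)
        X = rng.normal(0, np.sqrt(sigma2)[None, :], size=(6, n))
        X[3:, :k] += 3.0  # 8-fold on log2 scale
        y = np.array(["A"] * 3 + ["B"] * 3)
        est = ModeratedTTest(pair=("A", "B")).fit(X, y)
        log2fc = X[3:].mean(axis=0) - X[:3].mean(axis=0)
        labels = pq.call_variants(est.q_, pq.zscore_logfc(log2fc))
        called = np.flatnonzero(labels != "not_significant")
        assert np.sum(labels[:k] == "up") >= 45
        assert np.sum(labels[k:] != "not_significant") <= 5
        assert len(called) > 0


class TestHeatmap:
    def _values(self):
        return pd.DataFrame(
            {"s1": [1e6, 1e7, 1e5], "s2": [1e6, 1e7, 1e5]},
            index=["F1", "F2", "F3"],
        )

    def test_log10_cells_and_ordering(self):
        hm = pq.heatmap_matrix(
            self._values(), ["F1", "F2", "F3"], {"F1": 2.0, "F2": -1.0, "F3": 0.5}
        )
        assert list(hm.index) == ["F1", "F3", "F2"]  # descending log2fc
        assert hm.loc["F1", "s1"] == pytest.approx(6.0)

    def test_shape_is_variants_by_samples(self):
        hm = pq.heatmap_matrix(self._values(), ["F2"], {"F2": 1.0})
        assert hm.shape == (1, 2)

    def test_empty_variant_set_warns_not_errors(self):
        with pytest.warns(UserWarning, match="empty variant set"):
            hm = pq.heatmap_matrix(self._values(), [], {})
        assert hm.empty
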