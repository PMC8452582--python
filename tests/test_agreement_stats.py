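"""Statistics battery against independent oracles."""

import numpy as np
import pytest

from atriakit.agreement_stats import (
    bland_altman,
    delong_test,
    fleiss_kappa,
    icc_absolute,
    kappa_band,
    ks_normality,
    mann_whitney_u,
    r_squared,
    roc_auc,
)
from atriakit.core import AtriakitError


def anova_icc_oracle(m, measure="single"):
    """Brute-force two-way ANOVA ICC via explicit sums of squares."""
    m = np.asarray(m, float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (m[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if measure == "single":
        return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
    return (msr - mse) / (msr + (msc - mse) * k / n)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)  # enumeration over C(4,2) splits

    def test_identical_groups(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0] * 10, [1.0, 2.0, 3.0] * 10)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_u_complement_identity(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=11)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(8 * 11)

    def test_degenerate_all_ties(self):
        _, p = mann_whitney_u([5.0] * 6, [5.0] * 6)
        assert p == 1.0

    def test_empty_group(self):
        with pytest.raises(AtriakitError):
            mann_whitney_u([], [1.0])


class TestICC:
    def test_identical_columns(self, rng):
        col = rng.normal(size=12)
        assert icc_absolute(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_absolute_agreement_penalises_offset(self, rng):
        col = rng.normal(size=15)
        m = np.column_stack([col, col + 10.0])
        icc = icc_absolute(m)
        assert icc < 1.0
        assert icc == pytest.approx(anova_icc_oracle(m), rel=1e-10)
        # pingouin's ICC2 (two-way random/mixed, absolute, single) cross-check
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame({
            "targets": np.repeat(np.arange(15), 2),
            "raters": np.tile([0, 1], 15),
            "scores": m.ravel(),
        })
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = pg.intraclass_corr(df, "targets", "raters", "scores")
        table = table.set_index("Type")
        assert icc == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-6)
        # the consistency form ignores the systematic offset entirely
        assert table.loc["ICC(C,1)", "ICC"] == pytest.approx(1.0)

    def test_matches_anova_oracle_on_random_matrices(self, rng):
        for _ in range(25):
            m = rng.normal(size=(rng.integers(4, 15), rng.integers(2, 5)))
            assert icc_absolute(m) == pytest.approx(
                anova_icc_oracle(m), rel=1e-10, abs=1e-12
            )
            assert icc_absolute(m, "average") == pytest.approx(
                anova_icc_oracle(m, "average"), rel=1e-10, abs=1e-12
            )

    def test_pure_noise_near_zero(self):
        m = np.random.default_rng(6).normal(size=(6, 2))
        icc = icc_absolute(m)
        assert abs(icc) < 0.6
        assert icc == pytest.approx(anova_icc_oracle(m), rel=1e-10)

    def test_missing_cells_rejected(self):
        m = np.ones((4, 2))
        m[1, 1] = np.nan
        with pytest.raises(AtriakitError):
            icc_absolute(m)


class TestBlandAltman:
    def test_constant_difference(self):
        s = bland_altman([15.0, 25.0, 35.0], [10.0, 20.0, 30.0])
        assert s.bias == 5.0 and s.sd_diff == 0.0
        assert s.loa_lower == s.loa_upper == 5.0

    def test_two_point_sd(self):
        s = bland_altman([0.0, 2.0], [1.0, 1.0])  # differences -1, +1
        assert s.bias == 0.0
        assert s.sd_diff == pytest.approx(np.sqrt(2))
        assert s.loa_upper == pytest.approx(1.96 * np.sqrt(2))
        assert s.loa_upper == pytest.approx(2.772, abs=1e-3)

    def test_orientation_antisymmetry(self, rng):
        a, b = rng.normal(50, 5, 30), rng.normal(48, 5, 30)
        s_ab, s_ba = bland_altman(a, b), bland_altman(b, a)
        assert s_ba.bias == pytest.approx(-s_ab.bias)
        assert s_ba.loa_lower == pytest.approx(-s_ab.loa_upper)
        assert s_ba.loa_upper - s_ba.loa_lower == pytest.approx(
            s_ab.loa_upper - s_ab.loa_lower
        )

    def test_loa_symmetry_about_bias(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        s = bland_altman(a, b)
        assert s.loa_upper - s.bias == pytest.approx(s.bias - s.loa_lower)

    def test_needs_two_pairs(self):
        with pytest.raises(AtriakitError):
            bland_altman([1.0], [2.0])


class TestRSquared:
    def test_exact_linear(self):
        x = np.arange(10.0)
        assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)
        assert r_squared(x, -x) == pytest.approx(1.0)  # sign-insensitive

    def test_independent_series(self, rng):
        assert r_squared(rng.normal(size=1000), rng.normal(size=1000)) < 0.02

    def test_zero_variance(self):
        with pytest.raises(AtriakitError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestFleissKappa:
    def test_perfect_agreement(self):
        ratings = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [1, 1, 1]])
        kappa, band = fleiss_kappa(ratings)
        assert kappa == pytest.approx(1.0)
        assert band == "almost excellent"

    def test_perfect_disagreement_two_by_two(self):
        # hand computation: Po = 0, Pe = 0.5 -> kappa = -1
        kappa, band = fleiss_kappa(np.array([[0, 1], [1, 0]]))
        assert kappa == pytest.approx(-1.0)
        assert band == "poor"

    def test_single_category_degenerate(self):
        with pytest.raises(AtriakitError):
            fleiss_kappa(np.ones((5, 3), dtype=int))

    def test_band_scale(self):
        assert kappa_band(0.1) == "slight"
        assert kappa_band(0.3) == "fair"
        assert kappa_band(0.5) == "moderate"
        assert kappa_band(0.7) == "substantial"
        assert kappa_band(0.85) == "almost excellent"


class TestRocAuc:
    def test_perfect_separation(self):
        v = np.array([1, 2, 3, 10, 11, 12], float)
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        s = roc_auc(v, y, +1)
        assert s.auc == 1.0
        assert s.sensitivity == 100.0 and s.specificity == 100.0

    def test_direction_flip(self):
        v = np.array([1, 2, 3, 10, 11, 12], float)
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        assert roc_auc(v, y, -1).auc == 1.0

    def test_null_distribution_near_half(self, rng):
        v = rng.normal(size=2000)
        y = rng.permutation(np.repeat([True, False], 1000))
        assert roc_auc(v, y, +1).auc == pytest.approx(0.5, abs=0.03)

    def test_complement_identity(self, rng):
        v = rng.normal(size=40)  # tie-free
        y = rng.random(40) < 0.4
        if y.all() or (~y).all():
            y[:3] = [True, False, True]
        assert roc_auc(v, y, +1).auc + roc_auc(-v, y, +1).auc == pytest.approx(1.0)

    def test_matches_trapezoidal_integration(self, rng):
        # dual route: Mann-Whitney identity vs sklearn's trapezoidal ROC
        sk = pytest.importorskip("sklearn.metrics")
        for _ in range(50):
            n = int(rng.integers(10, 40))
            v = rng.normal(size=n).round(1)  # force ties
            y = rng.random(n) < 0.5
            if y.all() or (~y).all():
                continue
            assert roc_auc(v, y, +1).auc == pytest.approx(
                sk.roc_auc_score(y, v), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(AtriakitError):
            roc_auc([1.0, 2.0], [True, True])


class TestDeLong:
    def test_identical_predictors(self, rng):
        v = rng.normal(size=30)
        y = rng.random(30) < 0.5
        y[:2] = [True, False]
        z, p, a, b = delong_test(v, v, y)
        assert z == 0.0 and p == 1.0 and a == b

    def test_antisymmetry(self, rng):
        va, vb = rng.normal(size=40), rng.normal(size=40)
        y = rng.random(40) < 0.5
        y[:2] = [True, False]
        z1, p1, *_ = delong_test(va, vb, y)
        z2, p2, *_ = delong_test(vb, va, y)
        assert z2 == pytest.approx(-z1)
        assert p2 == pytest.approx(p1)

    def test_variance_against_bootstrap(self):
        # subject-level bootstrap of Delta AUC at n=60, 2000 replicates
        rng = np.random.default_rng(17)
        n = 60
        y = np.repeat([True, False], [25, 35])
        signal = np.where(y, 1.0, 0.0)
        va = signal + rng.normal(0, 1, n)
        vb = signal + 0.6 * (va - signal) + rng.normal(0, 0.8, n)

        def auc(v, lab):
            from scipy.stats import rankdata

            r = rankdata(v)
            pos = lab.sum()
            return (r[lab].sum() - pos * (pos + 1) / 2) / (pos * (~lab).sum())

        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.all() or (~yy).all():
                continue
            boots.append(auc(va[idx], yy) - auc(vb[idx], yy))
        var_boot = np.var(boots, ddof=1)
        z, p, auc_a, auc_b = delong_test(va, vb, y)
        var_delong = ((auc_a - auc_b) / z) ** 2
        assert var_delong == pytest.approx(var_boot, rel=0.15)


class TestKSNormality:
    def test_normal_samples_pass(self):
        passed = 0
        for seed in range(100):
            v = np.random.default_rng(seed).normal(10, 2, size=1000)
            _, p = ks_normality(v)
            passed += p > 0.05
        assert passed >= 95

    def test_exponential_samples_fail(self):
        v = np.random.default_rng(0).exponential(size=1000)
        _, p = ks_normality(v)
        assert p < 0.05

    def test_statistic_is_sup_distance(self, rng):
        from scipy.stats import norm

        v = np.sort(rng.normal(size=50))
        d, _ = ks_normality(v)
        cdf = norm.cdf(v, v.mean(), v.std(ddof=1))
        n = v.size
        brute = max(
            max(abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i])) for i in range(n)
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_minimum_sample_size(self):
        with pytest.raises(AtriakitError):
            ks_normality([1.0, 2.0, 3.0, 4.0])
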