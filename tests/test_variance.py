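"""Variance partitioning: Welch test, Gibbs samplers, repeatability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichetrack.variance import (
    MCMCConfig,
    diagnostics,
    fit_binary_varcomp,
    fit_gaussian_varcomp,
    repeatability,
    standardize,
    welch_t,
)

FAST = MCMCConfig(iterations=8_000, thin=5, burn_in=1_000)


def simulate_gaussian(seed, J=40, nobs=10, vb=2.0, vw=1.0, flyway_effect=0.0):
    """Balanced unit data with the realized unit variance pinned to vb."""
    r = np.random.default_rng(seed)
    u = r.normal(0, 1, J)
    u = (u - u.mean()) / u.std(ddof=1) * np.sqrt(vb)
    units = np.repeat(np.arange(J), nobs)
    e = r.normal(0, 1, J * nobs)
    e = (e - e.mean()) / e.std(ddof=1) * np.sqrt(vw)
    fw = np.repeat(np.arange(J) % 2, nobs)
    y = u[units] + e + flyway_effect * fw
    return y, units, fw


class TestStandardize:
    def test_symmetric_triple(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_moments_and_idempotence(self, rng):
        x = rng.gamma(3, 2, 500)
        z = standardize(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12
        np.testing.assert_allclose(standardize(z), z)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestWelch:
    def test_hand_computed_example(self):
        res = welch_t([1, 2, 3], [2, 4, 6])
        assert res.t == pytest.approx(-1.5491933384829668, abs=1e-9)
        assert res.df == pytest.approx(2.9411764705882355, abs=1e-9)

    def test_matches_scipy(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 2, 20)
        res = welch_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)
        assert res.df == pytest.approx(ref.df, abs=1e-9)

    def test_identical_samples_and_antisymmetry(self, rng):
        x = rng.normal(0, 1, 10)
        same = welch_t(x, x)
        assert same.t == 0.0 and same.p == pytest.approx(1.0)
        y = rng.normal(1, 1, 15)
        ab, ba = welch_t(x, y), welch_t(y, x)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.p == pytest.approx(ba.p)

    def test_df_reduces_to_pooled_when_balanced(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + 10.0  # same variance, same n
        res = welch_t(x, y)
        assert res.df == pytest.approx(len(x) + len(y) - 2)
        assert len(x) - 1 <= res.df <= len(x) + len(y) - 2


class TestRepeatability:
    def test_analytic_ratios(self):
        d = np.ones(200)
        assert repeatability(d, d)["mean"] == pytest.approx(0.5)
        assert repeatability(3 * d, d)["mean"] == pytest.approx(0.75)
        small = np.full(200, 1e-9)
        assert repeatability(small, d)["mean"] < 1e-6

    def test_rejects_bad_draws(self):
        with pytest.raises(ValueError):
            repeatability(np.ones(10), np.ones(9))
        with pytest.raises(ValueError):
            repeatability(np.zeros(10), np.ones(10))


class TestDiagnostics:
    def test_iid_passes_ar1_and_constant_fail(self, rng):
        iid = rng.standard_normal(4500)
        ar = np.empty(2000)
        ar[0] = 0.0
        for i in range(1, 2000):
            ar[i] = 0.5 * ar[i - 1] + rng.standard_normal()
        const = np.ones(500)
        rep = diagnostics({"iid": iid, "ar": ar, "const": const})
        as_dict = rep.set_index("parameter")["ok"].to_dict()
        assert as_dict["iid"] is True or as_dict["iid"] == True  # noqa: E712
        assert not as_dict["ar"]
        assert not as_dict["const"]
        assert not rep.attrs["pass"]


class TestGaussianModel:
    def test_recovers_repeatability_two_thirds(self):
        y, units, _ = simulate_gaussian(1)
        vc = fit_gaussian_varcomp(y, units, mcmc=FAST, seed=11)
        rep = repeatability(vc.draws["V_B"], vc.draws["V_W"])
        assert rep["q2_5"] < 2 / 3 < rep["q97_5"]
        assert rep["q97_5"] - rep["q2_5"] < 0.25
        assert (vc.draws["V_B"] > 0).all() and (vc.draws["V_W"] > 0).all()
        assert len(vc.draws["V_B"]) == FAST.n_draws

    def test_null_data_gives_low_repeatability(self):
        r = np.random.default_rng(2)
        units = np.repeat(np.arange(40), 10)
        y = r.normal(0, 1, 400)  # no between-unit structure
        vc = fit_gaussian_varcomp(y, units, mcmc=FAST, seed=12)
        assert vc.R_draws.mean() < 0.15

    def test_flyway_effect_detected(self):
        y, units, fw = simulate_gaussian(3, flyway_effect=1.0)
        vc = fit_gaussian_varcomp(y, units, flyway=fw, mcmc=FAST, seed=13)
        lo, hi = np.quantile(vc.draws["beta_1"], [0.025, 0.975])
        assert lo > 0.0  # credible interval excludes zero

    def test_matches_reml_oracle_on_balanced_design(self):
        """Posterior means of V_B, V_W within 15% of REML (statsmodels)."""
        import statsmodels.api as sm

        ratios_b, ratios_w = [], []
        for seed in range(10):
            y, units, _ = simulate_gaussian(100 + seed)
            md = sm.MixedLM(y, np.ones((len(y), 1)), groups=units)
            fit = md.fit(reml=True)
            reml_vb = float(np.asarray(fit.cov_re)[0, 0])
            reml_vw = float(fit.scale)
            vc = fit_gaussian_varcomp(y, units, mcmc=FAST, seed=seed)
            ratios_b.append(vc.draws["V_B"].mean() / reml_vb)
            ratios_w.append(vc.draws["V_W"].mean() / reml_vw)
        assert abs(np.mean(ratios_b) - 1) < 0.15
        assert abs(np.mean(ratios_w) - 1) < 0.15

    def test_year_component_reported_but_not_in_R(self):
        r = np.random.default_rng(4)
        units = np.repeat(np.arange(20), 8)
        years = np.tile(np.repeat(np.arange(4), 2), 20)
        y = r.normal(0, 1, 160) + r.normal(0, 1, 20)[units]
        vc = fit_gaussian_varcomp(y, units, year_ids=years, mcmc=FAST, seed=5)
        assert "V_Y" in vc.draws
        np.testing.assert_allclose(
            vc.R_draws, vc.draws["V_B"] / (vc.draws["V_B"] + vc.draws["V_W"])
        )


class TestBinaryModel:
    @staticmethod
    def _simulate(seed, J=40, nobs=10, vb=1.0):
        r = np.random.default_rng(seed)
        u = r.normal(0, 1, J)
        u = (u - u.mean()) / u.std(ddof=1) * np.sqrt(vb)
        units = np.repeat(np.arange(J), nobs)
        latent = u[units] + r.normal(0, 1, J * nobs)
        return (latent > 0).astype(int), units

    def test_recovers_latent_repeatability_half(self):
        means = []
        for seed in range(5):
            y01, units = self._simulate(seed)
            vc = fit_binary_varcomp(y01, units, mcmc=FAST, seed=seed)
            means.append(vc.R_draws.mean())
        assert all(0.3 < m < 0.7 for m in means)

    def test_iid_labels_give_low_repeatability(self):
        r = np.random.default_rng(9)
        units = np.repeat(np.arange(40), 10)
        y01 = r.integers(0, 2, 400)
        vc = fit_binary_varcomp(y01, units, mcmc=FAST, seed=3)
        assert vc.R_draws.mean() < 0.15

    def test_label_flip_symmetry(self):
        y01, units = self._simulate(42)
        a = fit_binary_varcomp(y01, units, mcmc=FAST, seed=6)
        b = fit_binary_varcomp(1 - y01, units, mcmc=FAST, seed=6)
        # variance posteriors agree in distribution; intercept flips sign
        assert a.draws["V_B"].mean() == pytest.approx(b.draws["V_B"].mean(), rel=0.2)
        assert a.draws["beta_0"].mean() == pytest.approx(-b.draws["beta_0"].mean(), abs=0.1)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            fit_binary_varcomp(np.ones(20, int), np.repeat(np.arange(4), 5))
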