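"""Statistical estimators: Bell-Evans, exponential, Hill, mixtures,
partial correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teloforce import kinetics as kin
from teloforce import synth
from teloforce.polymer import KBT_PN_NM


class TestBellEvans:
    def test_noiseless_line_recovered_exactly(self):
        f = np.array([2.0, 4.0, 6.0, 8.0])
        tau = 1.0 / synth.bell_evans_rate(f, 0.04, 0.7)
        fit = kin.fit_bell_evans(f, tau)
        assert fit.k0 == pytest.approx(0.04, abs=1e-9)
        assert fit.x_dagger == pytest.approx(0.7, abs=1e-9)
        assert fit.zero_force_dwell == pytest.approx(25.0, rel=1e-9)

    def test_zero_force_rate_is_k0(self):
        assert synth.bell_evans_rate(0.0, 0.04, 0.7) == 0.04

    def test_single_force_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_bell_evans([4.0, 4.0, 4.0], [1.0, 1.1, 0.9])

    def test_simulated_recovery(self):
        from teloforce.replica import bell_evans_recovery
        fit = bell_evans_recovery(7)
        assert 0.04 / 1.5 < fit.k0 < 0.04 * 1.5
        assert abs(fit.x_dagger - 0.7) < 0.15

    def test_weighted_fit_accepts_ses(self):
        f = np.array([2.0, 4.0, 6.0, 8.0])
        tau = 1.0 / synth.bell_evans_rate(f, 0.04, 0.7)
        fit = kin.fit_bell_evans(f, tau, dwell_se=0.1 * tau)
        assert fit.x_dagger == pytest.approx(0.7, abs=1e-9)


class TestExponential:
    def test_constant_dwells_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = kin.fit_exponential(np.full(30, 0.5))
        assert fit.degenerate

    def test_tau_036_recovery_n1290(self):
        rng = np.random.default_rng(5)
        d = 0.02 + rng.exponential(0.36, size=1290)
        fit = kin.fit_exponential(d)
        assert fit.tau_se == pytest.approx(0.36 / np.sqrt(1290), rel=0.1)
        assert abs(fit.tau - 0.36) < 2 * fit.tau_se

    def test_tau_171_recovery_n588(self):
        rng = np.random.default_rng(6)
        d = 0.02 + rng.exponential(1.71, size=588)
        fit = kin.fit_exponential(d)
        assert abs(fit.tau - 1.71) < 2 * fit.tau_se
        assert fit.r_squared > 0.8

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        d = rng.exponential(1.0, size=500) + 0.02
        a = kin.fit_exponential(d, min_dwell=0.02)
        b = kin.fit_exponential(3.0 * d, min_dwell=0.06)
        assert b.tau == pytest.approx(3.0 * a.tau, rel=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_exponential(np.ones(10))


class TestHill:
    def test_half_saturation_at_kd(self):
        for n in (0.5, 1.0, 2.0):
            assert kin.hill_fraction(17.5, 17.5, n) == pytest.approx(0.5)

    def test_exact_recovery(self):
        c = np.array([2.0, 5.0, 10.0, 25.0, 60.0, 150.0])
        f = kin.hill_fraction(c, 17.5, 1.0)
        fit = kin.fit_hill(c, f)
        assert fit.kd == pytest.approx(17.5, abs=1e-6)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-6)

    def test_noisy_recovery_within_2nM(self):
        from teloforce.replica import hill_kd_recovery
        fit = hill_kd_recovery(8)
        assert abs(fit.kd - 17.5) < 2.0

    def test_fixed_n_option(self):
        c = np.array([2.0, 5.0, 10.0, 25.0, 60.0, 150.0])
        f = kin.hill_fraction(c, 17.5, 1.0)
        fit = kin.fit_hill(c, f, fix_n=1.0)
        assert fit.fixed_n and fit.hill_n == 1.0
        assert fit.kd == pytest.approx(17.5, abs=1e-6)

    def test_saturated_fractions_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_hill([1, 2, 3, 4], [1.0, 1.0, 1.0, 1.0])


class TestGaussianMixture:
    def test_single_tight_component(self, rng):
        x = rng.normal(250.0, 5.0, size=200)
        fit = kin.fit_gaussian_mixture(x, n_components=1)
        assert fit.means[0] == pytest.approx(np.mean(x), abs=0.5)

    def test_two_component_recovery(self):
        from teloforce.replica import loop_mixture_recovery
        fit = loop_mixture_recovery(9)
        assert abs(fit.means[0] - 258.0) < 40.0
        assert abs(fit.means[1] - 470.0) < 40.0

    def test_equal_means_collapse_to_one_by_bic(self, rng):
        x = np.concatenate([rng.normal(300, 50, 300),
                            rng.normal(300, 50, 300)])
        fit = kin.fit_gaussian_mixture(x)
        assert fit.n_components == 1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            kin.fit_gaussian_mixture(np.ones(30), n_components=2)


class TestPartialCorrelation:
    def residual_oracle(self, x, y, controls):
        """Correlation of OLS residuals after regressing out controls."""
        Z = np.column_stack([np.ones(len(x)), *controls])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        return float(np.corrcoef(rx, ry)[0, 1])

    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_residual_regression_oracle(self, order, rng):
        for _ in range(5):
            x = rng.normal(size=200)
            y = 0.4 * x + rng.normal(size=200)
            controls = [0.3 * x + rng.normal(size=200)
                        for _ in range(order)]
            res = kin.partial_correlation(x, y, controls)
            assert res.r == pytest.approx(
                self.residual_oracle(x, y, controls), abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        df = pd.DataFrame({"x": rng.normal(size=150),
                           "z1": rng.normal(size=150),
                           "z2": rng.normal(size=150)})
        df["y"] = 0.5 * df.x - 0.3 * df.z1 + rng.normal(size=150)
        res = kin.partial_correlation(df.x, df.y, [df.z1, df.z2])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.p_value == pytest.approx(float(ref[pcol].iloc[0]),
                                            abs=1e-6)

    def test_identical_variables_r_one(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        assert kin.partial_correlation(x, x).r == pytest.approx(1.0)
        assert kin.partial_correlation(x, x, [z]).r == pytest.approx(1.0)

    def test_uncorrelated_control_leaves_r(self, rng):
        x = rng.normal(size=100000)
        y = 0.5 * x + rng.normal(size=100000)
        z = rng.normal(size=100000)
        r0 = kin.partial_correlation(x, y).r
        r1 = kin.partial_correlation(x, y, [z]).r
        assert r1 == pytest.approx(r0, abs=0.01)

    def test_collinear_control_rejected(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            kin.partial_correlation(x, y, [2 * x + 1])

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10000))
    def test_r_bounded(self, seed):
        g = np.random.default_rng(seed)
        x, y, z = g.normal(size=(3, 30))
        res = kin.partial_correlation(x, y, [z])
        assert -1.0 <= res.r <= 1.0


def test_physiological_dimer_concentration():
    # 40 000 monomers in 1540 um^3 -> 21.6 nM dimers; 760 um^3 -> 43.7 nM
    assert kin.dimer_concentration_nm(40_000, 1540.0) == pytest.approx(
        21.6, abs=0.05)
    assert kin.dimer_concentration_nm(40_000, 760.0) == pytest.approx(
        43.7, abs=0.05)
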