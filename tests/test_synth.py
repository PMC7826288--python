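"""Synthetic trace generators: determinism, event statistics, bounds."""

import numpy as np
import pytest
from scipy import stats

from teloforce import synth
from teloforce.polymer import KBT_PN_NM, nm_per_bp
from teloforce.protocol import ForceProtocol, Segment


def ramp_hold(f_max=17.0, rate=4.0, hold=3.0):
    d = (f_max - 0.01) / rate
    return ForceProtocol([Segment("ramp", 0.01, d, force_end=f_max),
                          Segment("constant", f_max, hold)])


class TestForceExtension:
    def test_noiseless_plateau_matches_wlc(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=2500.0, noise_sd=0.0)
        tr = synth.simulate_force_extension(spec, ramp_hold(), seed=1)
        at17 = tr.extension[np.abs(tr.force - 17.0) < 1e-9]
        assert at17.size > 0
        np.testing.assert_allclose(at17, 2500.0 * nm_per_bp(17.0), rtol=1e-12)

    def test_same_seed_identical_traces(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=2000.0)
        a = synth.simulate_force_extension(spec, ramp_hold(), seed=9)
        b = synth.simulate_force_extension(spec, ramp_hold(), seed=9)
        np.testing.assert_array_equal(a.extension, b.extension)

    def test_seed_required(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=2000.0)
        with pytest.raises(ValueError):
            synth.simulate_force_extension(spec, ramp_hold(), seed=None)

    def test_requires_ramp(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=2000.0)
        proto = ForceProtocol([Segment("constant", 17.0, 2.0)])
        with pytest.raises(ValueError):
            synth.simulate_force_extension(spec, proto, seed=1)

    def test_single_loop_gives_one_upward_leap(self):
        spec = synth.TelomereMoleculeSpec(
            tl_bp=2500.0, noise_sd=0.0, loops=[synth.LoopEvent(640.0)])
        tr = synth.simulate_force_extension(spec, ramp_hold(), seed=4)
        jumps = np.diff(tr.extension)
        # ignore the steep entropic rise below 1 pN at the ramp start
        big = np.flatnonzero((jumps > 20.0) & (tr.force[1:] > 1.0))
        assert len(big) == 1
        f_rupture = tr.force[big[0] + 1]
        expected = 640.0 * nm_per_bp(f_rupture)
        assert jumps[big[0]] == pytest.approx(expected, rel=0.02)

    def test_rupture_times_match_inverse_cdf_oracle(self):
        """Ramp rupture-time sample vs the analytic Bell-Evans survival.

        Oracle: S(t) = exp(-H(t)) with the hazard integrated numerically
        along the ramp, independent of the generator's sampling path.
        """
        k0, xd, rate = 0.5, 0.7, 4.0
        times = []
        for s in range(400):
            spec = synth.TelomereMoleculeSpec(
                tl_bp=2500.0, noise_sd=0.0,
                loops=[synth.LoopEvent(300.0, k0=k0, x_dagger=xd)])
            tr = synth.simulate_force_extension(spec, ramp_hold(), seed=1000 + s)
            rts = tr.metadata["true_rupture_times"]
            if rts:
                times.append(rts[0])
        t_grid = np.linspace(0, ramp_hold().total_duration, 20000)
        f_grid = np.clip(0.01 + rate * t_grid, None, 17.0)
        haz = np.concatenate(
            [[0.0], np.cumsum(k0 * np.exp(f_grid * xd / KBT_PN_NM))[:-1]
             * (t_grid[1] - t_grid[0])])
        surv = np.exp(-haz)
        p_rupt = 1 - surv[-1]

        def cdf(t):
            return np.interp(t, t_grid, (1 - surv) / p_rupt)
        res = stats.kstest(times, cdf)
        assert res.pvalue > 0.01

    def test_extension_bounds(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=1000.0)
        tr = synth.simulate_force_extension(spec, ramp_hold(), seed=2)
        assert tr.extension.min() >= 0.0
        assert tr.extension.max() <= 1000.0 * 0.34 * 1.05


class TestForceJump:
    def test_mean_rupture_dwell_matches_bell_evans(self):
        rng = np.random.default_rng(0)
        d = synth.draw_rupture_dwells(0.04, 0.7, 8.0, 1000, rng)
        expected = 1.0 / (0.04 * np.exp(8.0 * 0.7 / KBT_PN_NM))  # ~6.4 s
        assert np.mean(d) == pytest.approx(expected, rel=0.10)

    def test_dwells_are_exponential(self):
        rng = np.random.default_rng(1)
        d = synth.draw_rupture_dwells(0.04, 0.7, 6.0, 1000, rng)
        res = stats.kstest(d / np.mean(d), stats.expon.cdf)
        assert res.pvalue > 0.01

    def test_dwell_mean_within_3se(self):
        rng = np.random.default_rng(2)
        k = synth.bell_evans_rate(4.0, 0.04, 0.7)
        d = synth.draw_rupture_dwells(0.04, 0.7, 4.0, 1000, rng)
        se = (1 / k) / np.sqrt(1000)
        assert abs(np.mean(d) - 1 / k) < 3 * se

    def test_low_rate_mostly_no_rupture(self):
        # k(F_test) * duration << 1: almost every cycle ends loop-bound
        spec = synth.TelomereMoleculeSpec(
            tl_bp=2500.0, loops=[synth.LoopEvent(250.0, k0=1e-5)])
        tr = synth.simulate_force_jump(spec, f_test=2.0, t_rest=0.5,
                                       t_test=2.0, n_cycles=10, seed=3)
        dwells = [e["dwell"] for e in tr.metadata["true_events"]]
        in_window = [d for d in dwells if d < 2.0]
        assert len(in_window) <= 2

    def test_binding_probability_zero_gives_no_events(self):
        spec = synth.TelomereMoleculeSpec(
            tl_bp=2500.0, loops=[synth.LoopEvent(250.0)],
            binding_probability=0.0)
        tr = synth.simulate_force_jump(spec, t_rest=0.5, t_test=2.0,
                                       n_cycles=5, seed=4)
        assert tr.metadata["true_events"] == []


class TestStrandSeparation:
    def test_no_proteins_single_cooperative_step(self, long_hairpin):
        tr = synth.simulate_strand_separation(long_hairpin, [], seed=1,
                                              noise_sd=0.0, t_test=2.0)
        w0, w1 = tr.metadata["test_window"]
        m = (tr.time >= w0 + 0.05) & (tr.time < w1)
        assert np.ptp(tr.extension[m]) < 1.0  # already fully open

    def test_dimer_on_spacer_rejected(self, long_hairpin):
        # footprint 70..81 straddles the TGG spacer at 79-81
        with pytest.raises(ValueError, match="spacer"):
            synth.simulate_strand_separation(
                long_hairpin, [synth.BoundDimer(site_end=81)], seed=1)

    def test_overlapping_dimers_rejected(self, long_hairpin):
        dimers = [synth.BoundDimer(site_end=30), synth.BoundDimer(site_end=36)]
        with pytest.raises(ValueError, match="overlap"):
            synth.simulate_strand_separation(long_hairpin, dimers, seed=1)

    def test_pause_step_sizes_follow_dimer_spacing(self, long_hairpin):
        """Dimers packed on adjacent footprints give ~12 bp transits."""
        dimers = [synth.BoundDimer(site_end=e)
                  for e in (30, 42, 54, 66)]
        tr = synth.simulate_strand_separation(long_hairpin, dimers, seed=5,
                                              noise_sd=0.0, t_test=10.0)
        pauses = tr.metadata["true_pauses"]
        starts = [p["site_start"] for p in pauses]
        assert np.all(np.diff(starts) == 12)

    def test_determinism(self, long_hairpin):
        dimers = [synth.BoundDimer(site_end=30)]
        a = synth.simulate_strand_separation(long_hairpin, dimers, seed=6)
        b = synth.simulate_strand_separation(long_hairpin, dimers, seed=6)
        np.testing.assert_array_equal(a.extension, b.extension)


class TestHopping:
    def test_open_fraction_at_half_force(self):
        spec = synth.HoppingSpec(f_half=14.7, delta_x=14.0)
        tr = synth.simulate_hopping(spec, 14.7, 200.0, seed=7)
        assert np.mean(tr.metadata["true_path"]) == pytest.approx(0.5,
                                                                  abs=0.05)

    def test_open_fraction_follows_boltzmann(self):
        spec = synth.HoppingSpec(f_half=14.7, delta_x=14.0)
        tr = synth.simulate_hopping(spec, 14.9, 400.0, seed=8)
        expected = 1.0 / (1.0 + np.exp(-0.2 * 14.0 / KBT_PN_NM))  # ~0.66
        assert np.mean(tr.metadata["true_path"]) == pytest.approx(expected,
                                                                  abs=0.05)

    def test_zero_noise_two_levels(self):
        spec = synth.HoppingSpec(f_half=14.7, delta_x=14.0, noise_sd=0.0)
        tr = synth.simulate_hopping(spec, 14.7, 30.0, seed=9)
        assert set(np.unique(tr.extension)) == {0.0, 14.0}

    def test_force_outside_band_rejected(self):
        spec = synth.HoppingSpec(f_half=14.7, delta_x=14.0)
        with pytest.raises(ValueError):
            synth.simulate_hopping(spec, 16.0, 10.0, seed=1)

    def test_short_trace_flagged(self):
        spec = synth.HoppingSpec(f_half=14.7, delta_x=14.0, attempt_rate=0.2)
        tr = synth.simulate_hopping(spec, 14.7, 20.0, seed=1)
        assert tr.metadata["short_trace_warning"]


class TestLoopPopulation:
    def test_point_mass_component(self):
        mix = synth.GaussianMixtureSpec(((1.0, 250.0, 1e-6),))
        loops = synth.sample_loop_population(2500.0, mix, seed=1)
        assert loops and all(abs(x - 250.0) < 0.01 for x in loops)

    def test_budget_respected(self):
        mix = synth.loop_mixture_preset(20, "2.5-3.5")
        for s in range(30):
            loops = synth.sample_loop_population(1200.0, mix, seed=s)
            assert sum(loops) <= 1200.0

    def test_infeasible_mixture_rejected(self):
        mix = synth.GaussianMixtureSpec(((1.0, 5000.0, 10.0),))
        with pytest.raises(ValueError):
            synth.sample_loop_population(300.0, mix, seed=1)

    def test_budget_rejection_induces_negative_correlation(self):
        from teloforce.replica import loop_correlation
        r0, r2 = loop_correlation(2)
        assert r0.r < 0 and r0.p_value < 0.05
        assert r2.r < 0
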