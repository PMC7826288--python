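"""Step fitting against exhaustive oracles; zero correction; residence maps."""

import itertools

import numpy as np
import pytest

from teloforce import steps as st
from teloforce import synth
from teloforce.polymer import ss_nm_per_nt
from teloforce.trace import Trace


def enumerate_changepoints(y, k):
    """Literal enumeration of every k-step segmentation (small inputs)."""
    n = len(y)
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k):
        b = [0, *cuts, n]
        sse = sum(np.sum((y[lo:hi] - np.mean(y[lo:hi])) ** 2)
                  for lo, hi in zip(b[:-1], b[1:]))
        if sse < best[0] - 1e-12:
            best = (sse, list(cuts))
    return best[1]


def exhaustive_changepoints(y, k):
    """Exact optimal k-step segmentation by dynamic programming.

    Equivalent to full enumeration (verified against it on small inputs
    below) but tractable for n ~ 200.
    """
    n = len(y)
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(lo, hi):
        s = c1[hi] - c1[lo]
        return c2[hi] - c2[lo] - s * s / (hi - lo)

    cost = np.full((k + 1, n + 1), np.inf)
    arg = np.zeros((k + 1, n + 1), dtype=int)
    for i in range(1, n + 1):
        cost[0][i] = sse(0, i)
    for j in range(1, k + 1):
        for i in range(j + 1, n + 1):
            cands = [(cost[j - 1][m] + sse(m, i), m) for m in range(j, i)]
            cost[j][i], arg[j][i] = min(cands)
    cuts, i = [], n
    for j in range(k, 0, -1):
        i = arg[j][i]
        cuts.append(int(i))
    return sorted(cuts)


class TestFitSteps:
    def test_noiseless_staircase_exact(self, staircase):
        y, changes = staircase([0, 10, 25, 18, 40, 55, 70],
                               [30, 25, 40, 30, 25, 35, 30])
        fit = st.fit_steps_array(y, 100.0)
        assert [p.start for p in fit.plateaus[1:]] == changes
        np.testing.assert_allclose(fit.levels,
                                   [0, 10, 25, 18, 40, 55, 70], atol=1e-12)
        assert fit.sse == pytest.approx(0.0, abs=1e-9)

    def test_noisy_staircase_positions_within_2_samples(self, staircase, rng):
        levels = [0, 10, 20, 30, 40, 50]
        y, changes = staircase(levels, [60] * 6, noise_sd=5.0, rng=rng)
        fit = st.fit_steps_array(y, 100.0)
        found = [p.start for p in fit.plateaus[1:]]
        assert len(found) == len(changes)
        for c, f in zip(changes, found):
            assert abs(c - f) <= 2

    def test_min_dwell_filters_short_plateaus(self, staircase):
        # a 1-sample (10 ms at 100 Hz) plateau is below the Nyquist floor
        y, _ = staircase([0, 50, 0], [50, 1, 50])
        fit = st.fit_steps_array(y, 100.0)
        assert all(s.dwell > 0.02 for s in fit.sub_steps)

    def test_idempotent_on_fitted_signal(self, staircase, rng):
        y, _ = staircase([0, 12, 30], [40, 50, 40], noise_sd=2.0, rng=rng)
        fit = st.fit_steps_array(y, 100.0)
        refit = st.fit_steps_array(fit.fitted(), 100.0)
        np.testing.assert_allclose(refit.levels, fit.levels, atol=1e-9)
        assert [p.start for p in refit.plateaus] == \
               [p.start for p in fit.plateaus]

    def test_substeps_sum_to_net_change(self, staircase, rng):
        y, _ = staircase([0, 15, 40, 22], [50, 60, 50, 60],
                         noise_sd=3.0, rng=rng)
        fit = st.fit_steps_array(y, 100.0)
        net = fit.plateaus[-1].level - fit.plateaus[0].level
        assert sum(s.size for s in fit.sub_steps) == pytest.approx(
            net, abs=3.0)

    def test_dp_oracle_matches_enumeration(self, rng):
        y = rng.normal(0, 1, 40) + np.repeat([0.0, 5.0], 20)
        assert exhaustive_changepoints(y, 2) == enumerate_changepoints(y, 2)

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_matches_exhaustive_oracle_noiseless(self, k, rng):
        """Greedy fit equals brute-force optimal on noiseless staircases."""
        n = 120
        cuts = sorted(rng.choice(np.arange(10, n - 10), size=k,
                                 replace=False).tolist())
        while np.any(np.diff([0, *cuts, n]) < 8):
            cuts = sorted(rng.choice(np.arange(10, n - 10), size=k,
                                     replace=False).tolist())
        levels = rng.uniform(0, 100, size=k + 1)
        y = np.concatenate([np.full(hi - lo, lv) for lv, lo, hi in
                            zip(levels, [0, *cuts], [*cuts, n])])
        fit = st.fit_steps_array(y, 100.0)
        oracle = exhaustive_changepoints(y, k)
        assert [p.start for p in fit.plateaus[1:]] == oracle

    def test_pure_constant_single_plateau(self):
        fit = st.fit_steps_array(np.full(100, 5.0), 100.0)
        assert len(fit.plateaus) == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            st.fit_steps_array(np.zeros(5), 100.0)

    def test_nonconstant_force_rejected(self):
        n = 100
        tr = Trace(np.arange(n) / 100, np.linspace(0, 10, n),
                   np.zeros(n), 100.0)
        with pytest.raises(ValueError, match="constant"):
            st.fit_steps(tr)


class TestZeroCorrect:
    def test_open_and_closed_levels(self, long_hairpin):
        dimers = [synth.BoundDimer(site_end=93, mean_dwell=1.0)]
        tr = synth.simulate_strand_separation(long_hairpin, dimers, seed=3,
                                              noise_sd=0.5, t_test=8.0)
        zc = st.zero_correct(tr)
        assert zc.metadata["units"] == "bp_remaining"
        fit = st.fit_steps_array(zc.extension, zc.sampling_rate)
        levels = sorted(fit.levels)
        assert levels[0] == pytest.approx(0.0, abs=2.0)      # fully open
        # blocked at the dimer footprint start (82): 169 - 81 = 88 remaining
        assert any(abs(lv - 88.0) < 2.0 for lv in levels)

    def test_conversion_uses_ss_wlc(self, long_hairpin):
        tr = synth.simulate_strand_separation(long_hairpin, [], seed=4,
                                              noise_sd=0.0, t_test=4.0)
        zc = st.zero_correct(tr)
        assert zc.metadata["ss_nm_per_bp"] == pytest.approx(
            2 * ss_nm_per_nt(17.0), rel=1e-9)

    def test_error_when_f_test_absent(self, long_hairpin):
        tr = synth.simulate_strand_separation(long_hairpin, [], seed=5)
        tr2 = Trace(tr.time, np.full(len(tr), 6.0), tr.extension,
                    tr.sampling_rate, dict(tr.metadata))
        with pytest.raises(ValueError):
            st.zero_correct(tr2, f_test=17.0)


class TestExtractRuptures:
    def test_recovers_loop_sizes(self):
        spec = synth.TelomereMoleculeSpec(
            tl_bp=2500.0,
            loops=[synth.LoopEvent(250.0), synth.LoopEvent(640.0)])
        tr = synth.simulate_force_jump(spec, f_test=8.0, t_rest=2.0,
                                       t_test=40.0, n_cycles=4, seed=11)
        events = st.extract_ruptures(tr)
        truth = tr.metadata["true_events"]
        in_window = [e for e in truth if e["dwell"] > 0.05]
        assert len(events) >= len(in_window) - 1
        # two ruptures closer than the 20 ms dwell floor merge into one
        # leap of the summed size; every event must match one of those
        for e in events:
            assert min(abs(e.delta_l_bp - 250), abs(e.delta_l_bp - 640),
                       abs(e.delta_l_bp - 890)) < 0.1 * 890

    def test_no_protein_trace_empty(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=2500.0)
        tr = synth.simulate_force_jump(spec, t_rest=1.0, t_test=5.0,
                                       n_cycles=2, seed=12)
        assert st.extract_ruptures(tr) == []

    def test_dwells_match_generator(self):
        spec = synth.TelomereMoleculeSpec(tl_bp=2500.0,
                                          loops=[synth.LoopEvent(640.0)])
        tr = synth.simulate_force_jump(spec, f_test=6.0, t_rest=1.0,
                                       t_test=60.0, n_cycles=10, seed=13)
        events = st.extract_ruptures(tr)
        truth = {round(e["rupture_time"], 1): e["dwell"]
                 for e in tr.metadata["true_events"]}
        matched = 0
        for ev in events:
            for t, d in truth.items():
                if abs(ev.dwell_s - d) < 0.05:
                    matched += 1
                    break
        assert matched >= len(events) - 1


class TestResidenceMap:
    def test_single_pause_occupies_one_bin(self, long_hairpin):
        # synthetic corrected trace: 1 s pause at fork position 100
        fs = 100.0
        remaining = 169 - 100 + 1  # level while blocked at bp 100
        y = np.concatenate([np.full(100, float(remaining)), np.zeros(100)])
        tr = Trace(np.arange(200) / fs, np.full(200, 17.0), y, fs,
                   {"units": "bp_remaining", "stem_length": 169,
                    "construct": "telomeric_hairpin_long"})
        rmap = st.residence_map([tr])
        assert rmap.mean_time[99] == pytest.approx(1.0, abs=0.02)
        others = np.delete(rmap.mean_time, 99)
        assert others.max() == pytest.approx(0.0, abs=1e-9)

    def test_total_time_equals_sum_of_plateau_dwells(self, long_hairpin):
        dimers = [synth.BoundDimer(site_end=e, mean_dwell=0.8)
                  for e in (30, 93, 157)]
        corrected = []
        for s in range(5):
            tr = synth.simulate_strand_separation(long_hairpin, dimers,
                                                  seed=40 + s, t_test=8.0)
            corrected.append(st.zero_correct(tr))
        rmap = st.residence_map(corrected)
        total_check = 0.0
        for tr in corrected:
            fit = st.fit_steps_array(tr.extension, tr.sampling_rate)
            for p in fit.plateaus:
                pos = round(169 - p.level + 1)
                if 1 <= pos <= 169 and p.level >= 2.0:
                    total_check += p.n / tr.sampling_rate
        assert rmap.total_time == pytest.approx(total_check, rel=1e-9)

    def test_mixed_constructs_rejected(self, long_hairpin):
        fs = 100.0
        y = np.zeros(100)
        a = Trace(np.arange(100) / fs, np.full(100, 17.0), y, fs,
                  {"units": "bp_remaining", "stem_length": 169,
                   "construct": "long"})
        b = Trace(np.arange(100) / fs, np.full(100, 17.0), y, fs,
                  {"units": "bp_remaining", "stem_length": 105,
                   "construct": "short"})
        with pytest.raises(ValueError, match="mixed"):
            st.residence_map([a, b])

    def test_spacer_windows_are_valleys(self):
        from teloforce.replica import residence_map_ensemble
        rmap, construct = residence_map_ensemble(21, n_traces=30)
        t = rmap.mean_time
        for (a, b) in construct.spacer_windows():
            window_density = t[a - 1:b].mean()
            up_peak = t[a - 13:a - 1].max()
            down_peak = t[b:b + 12].max()
            assert window_density < 0.25 * min(up_peak, down_peak)
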