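"""End-to-end synthetic replica of the headline analyses.

Each function here regenerates synthetic data under the study
conditions the package emulates (sample sizes, kinetic parameters,
mixture presets) and runs the corresponding estimator, returning the
recovered quantity.  They are shared by the ``replicate`` CLI
command, the numbered analysis scripts and the acceptance checks, so
the numbers those report are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from . import hopping as hp
from . import kinetics as kin
from . import steps as st
from . import synth
from . import tl as tlmod
from .constructs import build_hairpin
from .polymer import KBT_PN_NM, DsWlcParams, nm_per_bp
from .protocol import ForceProtocol, Segment

__all__ = [
    "wlc_conversion_factor", "physiological_concentrations",
    "hairpin_spacer_positions", "boltzmann_half_probability",
    "activation_distance_noiseless", "bell_evans_recovery",
    "exponential_dwell_recovery", "hill_kd_recovery",
    "loop_mixture_recovery", "hopping_energetics", "loop_correlation",
    "tl_ensemble", "tl_roundtrip_error", "residence_map_ensemble",
]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


def _subseeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) >> 1]


# -- desk-scale quantities --------------------------------------------------

def wlc_conversion_factor(force: float = 17.0) -> float:
    """Extension per bp (nm/bp) of dsDNA at the reference force, 2 dp."""
    return round(nm_per_bp(force, DsWlcParams()), 2)


def physiological_concentrations() -> tuple[float, float]:
    """(nominal, upper-bound) physiological TRF1 dimer concentration, nM.

    40 000 monomers per cell; nominal cell volume 1540 um^3, lower-bound
    volume 760 um^3 (which bounds the concentration from above).
    """
    nominal = kin.dimer_concentration_nm(40_000, 1540.0)
    upper = kin.dimer_concentration_nm(40_000, 760.0)
    return nominal, upper


def hairpin_spacer_positions() -> tuple[int, int]:
    """First-base stem positions of the TGG and CGTC spacers (long construct)."""
    c = build_hairpin(long=True)
    assert c.stem_length == 169
    return c.spacer_positions[0], c.spacer_positions[1]


def boltzmann_half_probability(f_half: float = 14.7,
                               delta_x: float = 17.0) -> float:
    """Open probability (%) of the two-state fork at its half force.

    Fits the Boltzmann curve to exact points and evaluates it at the
    fitted F_half; by construction of the model this is 50%.
    """
    forces = f_half + np.linspace(-0.3, 0.3, 7)
    p = hp.boltzmann_p_open(forces, f_half, delta_x)
    fit = hp.fit_boltzmann(forces, p)
    return float(100.0 * hp.boltzmann_p_open(fit.f_half, fit.f_half,
                                             fit.delta_x))


def activation_distance_noiseless(k0: float = 0.04, x_dagger: float = 0.7,
                                  forces=(2.0, 4.0, 6.0, 8.0)) -> float:
    """x† (nm) recovered by the Bell-Evans regression from exact dwells."""
    f = np.asarray(forces, dtype=float)
    tau = 1.0 / synth.bell_evans_rate(f, k0, x_dagger)
    return kin.fit_bell_evans(f, tau).x_dagger


# -- parameter-recovery replicas -------------------------------------------

def bell_evans_recovery(seed: int, k0: float = 0.04, x_dagger: float = 0.7,
                        forces=(2.0, 4.0, 6.0, 8.0),
                        n_per_force: int = 200) -> kin.BellEvansFit:
    """Recover (k0, x†) from simulated rupture dwells at each test force."""
    rngs = _spawn(seed, len(forces))
    means = [float(np.mean(synth.draw_rupture_dwells(k0, x_dagger, f,
                                                     n_per_force, rng)))
             for f, rng in zip(forces, rngs)]
    return kin.fit_bell_evans(np.asarray(forces), np.asarray(means))


def exponential_dwell_recovery(seed: int, tau: float = 0.36, n: int = 1290,
                               floor: float = 0.02) -> kin.ExponentialFit:
    """Recover tau from n pause dwells (recorded dwells exceed the floor)."""
    rng = np.random.default_rng(seed)
    dwells = floor + rng.exponential(tau, size=n)
    return kin.fit_exponential(dwells, min_dwell=floor)


def hill_kd_recovery(seed: int, kd: float = 17.5, hill_n: float = 1.0,
                     noise_sd: float = 0.05, n_replicates: int = 3):
    """Recover Kd from noisy synthetic binding isotherms (EMSA-like)."""
    rng = np.random.default_rng(seed)
    conc = np.array([2.5, 5.0, 10.0, 20.0, 50.0, 100.0, 200.0])
    cs, fs = [], []
    for _ in range(n_replicates):
        f = kin.hill_fraction(conc, kd, hill_n)
        f = np.clip(f + rng.normal(0, noise_sd, size=len(conc)), 0.0, 1.0)
        cs.append(conc)
        fs.append(f)
    return kin.fit_hill(np.concatenate(cs), np.concatenate(fs))


def loop_mixture_recovery(seed: int, concentration_nm: int = 20,
                          tl_bin: str = "2.5-3.5",
                          n: int = 500) -> kin.GaussianMixtureFit:
    """Recover the loop-size mixture centers from n synthetic ΔL draws."""
    rng = np.random.default_rng(seed)
    spec = synth.loop_mixture_preset(concentration_nm, tl_bin)
    comps = spec.components
    w = np.array([c[0] for c in comps])
    draws = []
    while len(draws) < n:
        j = rng.choice(len(w), p=w)
        x = rng.normal(comps[j][1], comps[j][2])
        if x > 0:
            draws.append(x)
    return kin.fit_gaussian_mixture(np.asarray(draws),
                                    n_components=len(comps), seed=seed % 2**31)


def hopping_energetics(seed: int, f_half: float = 14.7,
                       dg_with: float = 61.0, dg_without: float = 50.0,
                       duration: float = 1000.0, n_forces: int = 20,
                       force_span: float = 0.6,
                       sampling_rate: float = 100.0):
    """Boltzmann energetics of the telomeric fork with and without TRF1.

    Two synthetic conditions share F_half = 14.7 pN; their free-energy
    presets (61 vs 50 kBT) fix the respective unfolding distances via
    dx = dG kBT / F_half.  Hopping traces at ``n_forces`` forces
    bracketing F_half (span ±``force_span`` pN, long constant-force
    holds so each open probability rests on hundreds of dwells) are
    HMM-decoded, open probabilities fitted to the Boltzmann curve, and
    the two dG estimates differenced.

    Returns (fit_with, fit_without, hmm_results_by_condition).
    """
    forces = f_half + np.linspace(-force_span, force_span, n_forces)
    seeds = _subseeds(seed, 2 * len(forces))
    fits, all_results = [], {}
    for ci, dg in enumerate((dg_with, dg_without)):
        dx = dg * KBT_PN_NM / f_half
        spec = synth.HoppingSpec(f_half=f_half, delta_x=dx,
                                 attempt_rate=1.0, noise_sd=3.0,
                                 forces=tuple(forces))
        p, se, results = [], [], []
        for fi, f in enumerate(forces):
            tr = synth.simulate_hopping(spec, float(f), duration,
                                        seed=seeds[ci * len(forces) + fi],
                                        sampling_rate=sampling_rate)
            res = hp.fit_two_state_hmm(tr)
            po, po_se = hp.open_probability(res)
            p.append(po)
            se.append(po_se)
            results.append(res)
        fits.append(hp.fit_boltzmann(forces, np.asarray(p), np.asarray(se)))
        all_results["with_trf1" if ci == 0 else "without_trf1"] = results
    return fits[0], fits[1], all_results


def loop_correlation(seed: int, n_molecules: int = 131,
                     mean_loops: float = 8.0):
    """Per-event (N, ΔL) correlation across a synthetic molecule ensemble.

    Molecules draw a telomere length from the 1.5-4.5 kb range of the
    truncated TL distribution and a TRF1 concentration from {20, 40} nM;
    loops come from the matching mixture preset with the shared-budget
    rejection rule.  Returns (zero-order, second-order) correlation
    results for N vs ΔL, controls = (concentration, TL).
    """
    rng = np.random.default_rng(seed)
    sub = _subseeds(seed + 1, n_molecules)
    tls = synth.sample_tl(4 * n_molecules, rng)
    tls = tls[(tls >= 1500) & (tls <= 4500)][:n_molecules]
    events = {"n": [], "dl": [], "conc": [], "tl": []}
    for i in range(n_molecules):
        tl_bp = float(tls[i])
        conc = int(rng.choice([20, 40]))
        tl_bin = ("1.5-2.5" if tl_bp < 2500 else
                  "2.5-3.5" if tl_bp < 3500 else "3.5-4.5")
        mix = synth.loop_mixture_preset(conc, tl_bin)
        loops = synth.sample_loop_population(tl_bp, mix, seed=sub[i],
                                             mean_loops=mean_loops)
        for dl in loops:
            events["n"].append(len(loops))
            events["dl"].append(dl)
            events["conc"].append(conc)
            events["tl"].append(tl_bp)
    n_arr = np.asarray(events["n"], dtype=float)
    dl_arr = np.asarray(events["dl"], dtype=float)
    r0 = kin.partial_correlation(n_arr, dl_arr)
    r2 = kin.partial_correlation(
        n_arr, dl_arr,
        controls=[np.asarray(events["conc"], float),
                  np.asarray(events["tl"], float)],
        control_names=("concentration", "TL"))
    return r0, r2


def _ramp_protocol(f_max: float = 17.0, rate: float = 4.0,
                   f_min: float = 0.01) -> ForceProtocol:
    d = (f_max - f_min) / rate
    return ForceProtocol([Segment("ramp", f_min, d, force_end=f_max),
                          Segment("ramp", f_max, d, force_end=f_min)])


def tl_ensemble(seed: int, n_molecules: int = 150,
                sampling_rate: float = 200.0):
    """Simulate and measure a protein-free telomere-length ensemble.

    Returns (summary, measurements); the generator draws lengths from
    the truncated N(2.5, 0.9) kb distribution, so the measured mean
    recovers ~2.5 kb.
    """
    rng = np.random.default_rng(seed)
    sub = _subseeds(seed + 2, n_molecules)
    tls = synth.sample_tl(n_molecules, rng)
    proto = _ramp_protocol()
    measurements = []
    for i, tl_bp in enumerate(tls):
        spec = synth.TelomereMoleculeSpec(tl_bp=float(tl_bp),
                                          molecule_id=f"mol{i:04d}")
        tr = synth.simulate_force_extension(spec, proto, seed=sub[i],
                                            sampling_rate=sampling_rate)
        measurements.append(tlmod.measure_tl(tr))
    return tlmod.tl_distribution(measurements), measurements


def tl_roundtrip_error(seed: int, tl_values=(500.0, 2500.0, 7000.0)) -> float:
    """Worst relative error of simulate -> measure on noise-free telomeres."""
    proto = _ramp_protocol()
    errs = []
    for i, tl_bp in enumerate(tl_values):
        spec = synth.TelomereMoleculeSpec(tl_bp=tl_bp, noise_sd=0.0)
        tr = synth.simulate_force_extension(spec, proto, seed=seed + i)
        m = tlmod.measure_tl(tr)
        errs.append(abs(m.tl_bp - tl_bp) / tl_bp)
    return float(max(errs))


def residence_map_ensemble(seed: int, n_traces: int = 50,
                           mean_dwell: float = 0.36,
                           n_dimers: int = 3):
    """Residence map of a synthetic strand-separation ensemble.

    Each trace has ``n_dimers`` TRF1 dimers on distinct, non-overlapping
    telomeric footprints of the long hairpin; pauses are exponential
    with the given mean dwell.  Returns (map, construct).
    """
    construct = build_hairpin(long=True)
    sites = np.asarray(construct.dimer_sites())
    rng = np.random.default_rng(seed)
    sub = _subseeds(seed + 3, n_traces)
    corrected = []
    for i in range(n_traces):
        chosen: list[int] = []
        for s in rng.permutation(sites):
            if all(abs(int(s) - c) >= 12 for c in chosen):
                chosen.append(int(s))
            if len(chosen) == n_dimers:
                break
        dimers = [synth.BoundDimer(site_end=s, mean_dwell=mean_dwell)
                  for s in sorted(chosen)]
        tr = synth.simulate_strand_separation(construct, dimers, seed=sub[i],
                                              t_test=8.0)
        corrected.append(st.zero_correct(tr))
    return st.residence_map(corrected), construct
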