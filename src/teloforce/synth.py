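"""Synthetic magnetic-tweezers traces with known ground truth.

Every downstream stage (telomere-length measurement, step fitting,
rupture kinetics, residence maps, hopping HMM) is exercised against
traces generated here, whose event times, loop sizes, pause sites and
hopping rates are known exactly and recorded in the trace metadata.

The generators emulate the study conditions of the emulated experiments:

* telomere lengths drawn from N(2.5, 0.9) kb truncated to [0.3, 7.4] kb;
* TRF1-mediated loops whose rupture follows Bell-Evans kinetics,
  k(F) = k0 exp(F x† / kBT), with defaults k0 = 0.04 1/s, x† = 0.7 nm;
* loop-size Gaussian mixtures per concentration and length bin;
* hairpin strand separation with exponential pause dwells at bound-dimer
  sites and ssDNA release of 2 nt per unzipped bp;
* two-state fork hopping obeying the Boltzmann relation
  k_forward/k_backward = exp((F - F_half) dx / kBT).

Bead noise is Gaussian with a force-dependent default SD (8 nm at <= 8 pN
shrinking to 3 nm at >= 14 pN), chosen so that ~10-bp unzipping steps are
resolvable at 100 Hz.  All generators require an explicit seed and are
bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constructs import HairpinConstruct
from .polymer import (KBT_PN_NM, DsWlcParams, SsWlcParams,
                      ds_relative_extension, ss_relative_extension)
from .protocol import ForceProtocol, force_jump_cycle, strand_separation_cycle
from .trace import Trace

__all__ = [
    "LoopEvent", "TelomereMoleculeSpec", "HoppingSpec", "GaussianMixtureSpec",
    "BINDING_PROBABILITY", "LOOP_MIXTURE_PRESETS", "CRITICAL_MELTING_FORCE",
    "default_noise_sd", "sample_tl", "bell_evans_rate", "draw_rupture_dwells",
    "simulate_force_extension", "simulate_force_jump",
    "simulate_strand_separation", "simulate_hopping", "sample_loop_population",
]

#: Observed probability of a binding signal per protocol cycle vs [TRF1] (nM).
BINDING_PROBABILITY = {10: 0.38, 20: 0.50, 25: 0.76, 40: 0.60}

#: Critical melting force of the telomeric hairpin stem, pN.
CRITICAL_MELTING_FORCE = 15.1

#: Loop-size mixture presets (weight, center bp, sigma bp) by
#: ([TRF1] nM, telomere-length bin kb).
LOOP_MIXTURE_PRESETS = {
    (10, "2.5-3.5"): [(0.5, 250.0, 100.0), (0.5, 640.0, 212.0)],
    (20, "1.5-2.5"): [(0.5, 172.0, 170.0), (0.5, 415.0, 157.0)],
    (20, "2.5-3.5"): [(0.5, 258.0, 117.0), (0.5, 470.0, 120.0)],
    (20, "3.5-4.5"): [(1 / 3, 442.0, 171.0), (1 / 3, 785.0, 223.0),
                      (1 / 3, 1266.0, 164.0)],
    (40, "1.5-2.5"): [(1.0, 340.0, 207.0)],
    (40, "2.5-3.5"): [(0.5, 290.0, 134.0), (0.5, 538.0, 212.0)],
    (40, "3.5-4.5"): [(0.5, 277.0, 135.0), (0.5, 725.0, 181.0)],
}


def default_noise_sd(force) -> np.ndarray:
    """Force-dependent Gaussian bead noise SD, nm.

    8 nm at <= 8 pN, 3 nm at >= 14 pN, linear in between (bead
    fluctuations shrink as the tether is pulled taut).
    """
    f = np.asarray(force, dtype=float)
    sd = np.interp(f, [8.0, 14.0], [8.0, 3.0])
    return sd


def sample_tl(n: int, rng: np.random.Generator,
              mean: float = 2500.0, sd: float = 900.0,
              lo: float = 300.0, hi: float = 7400.0) -> np.ndarray:
    """Telomere lengths (bp) from a truncated normal, rejection-sampled."""
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, size=2 * n)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def bell_evans_rate(force, k0: float, x_dagger: float,
                    kbt: float = KBT_PN_NM):
    """Bell-Evans dissociation rate k(F) = k0 exp(F x† / kBT), 1/s."""
    return k0 * np.exp(np.asarray(force, dtype=float) * x_dagger / kbt)


def draw_rupture_dwells(k0: float, x_dagger: float, force: float, n: int,
                        rng: np.random.Generator,
                        kbt: float = KBT_PN_NM) -> np.ndarray:
    """n exponential rupture waiting times at constant ``force``, s."""
    rate = bell_evans_rate(force, k0, x_dagger, kbt)
    return rng.exponential(1.0 / rate, size=n)


@dataclass(frozen=True)
class LoopEvent:
    """One TRF1-mediated loop: released length and rupture kinetics."""

    delta_l_bp: float
    k0: float = 0.04          # zero-force dissociation rate, 1/s
    x_dagger: float = 0.7     # activation distance, nm


@dataclass
class TelomereMoleculeSpec:
    """A single telomere molecule with optional compaction loops."""

    tl_bp: float
    loops: list[LoopEvent] = field(default_factory=list)
    noise_sd: float | None = None      # None -> force-dependent default
    binding_probability: float = 1.0   # per protocol cycle, at F_rest
    molecule_id: str = "mol0"

    def __post_init__(self) -> None:
        if self.tl_bp <= 0:
            raise ValueError("tl_bp must be positive")
        if sum(l.delta_l_bp for l in self.loops) > self.tl_bp:
            raise ValueError("sum of loop sizes exceeds telomere length")
        if not 0 <= self.binding_probability <= 1:
            raise ValueError("binding_probability must be in [0, 1]")


@dataclass
class HoppingSpec:
    """Two-state fork-hopping parameters (Boltzmann-compliant telegraph)."""

    f_half: float                    # pN, open probability 1/2
    delta_x: float                   # nm, forward/backward separation
    attempt_rate: float = 1.0        # 1/s, symmetric rate at F_half
    noise_sd: float = 3.0            # nm emission noise
    forces: tuple[float, ...] = ()   # pN, forces to probe

    def __post_init__(self) -> None:
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")
        if self.attempt_rate <= 0:
            raise ValueError("attempt_rate must be positive")


@dataclass(frozen=True)
class GaussianMixtureSpec:
    """1-D Gaussian mixture: (weight, center, sigma) components."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(c[2] < 0 for c in self.components):
            raise ValueError("sigmas must be non-negative")


def _require_seed(seed) -> np.random.Generator:
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    return np.random.default_rng(seed)


def _ds_rel_clamped(force: np.ndarray, params: DsWlcParams) -> np.ndarray:
    """dsDNA relative extension, clamped to >= 0 and defined at F = 0."""
    f = np.maximum(np.asarray(force, dtype=float), 1e-9)
    rel = (1.0 - 0.5 * np.sqrt(params.thermal_energy
                               / (f * params.persistence_length))
           + f / params.stretch_modulus)
    return np.clip(rel, 0.0, None)


def _noise(rng, force, noise_sd, n):
    sd = default_noise_sd(force) if noise_sd is None else noise_sd
    return rng.normal(0.0, 1.0, size=n) * sd


def _finalize_extension(ext: np.ndarray, contour_nm: float) -> np.ndarray:
    return np.clip(ext, 0.0, contour_nm * 1.05)


def _loop_rupture_times(loops, time, force, rng,
                        kbt: float = KBT_PN_NM) -> list[float]:
    """Rupture time of each loop along an arbitrary force trajectory.

    Inverse-CDF sampling on the cumulative Bell-Evans hazard
    H(t) = int_0^t k(F(s)) ds: rupture when H reaches -log(u).
    """
    dt = np.diff(time, prepend=time[0])
    out = []
    for loop in loops:
        rates = bell_evans_rate(force, loop.k0, loop.x_dagger, kbt)
        hazard = np.cumsum(rates * dt)
        target = -np.log(rng.uniform())
        idx = np.searchsorted(hazard, target)
        out.append(time[idx] if idx < len(time) else np.inf)
    return out


def simulate_force_extension(spec: TelomereMoleculeSpec,
                             protocol: ForceProtocol,
                             seed: int,
                             sampling_rate: float = 200.0,
                             ds_params: DsWlcParams | None = None) -> Trace:
    """Force-ramp trace of a (possibly compacted) telomere.

    Extension is the WLC prediction for the currently released length,
    ``(TL - sum of still-compacted loop sizes) * rise * x_rel(F)``, plus
    Gaussian bead noise.  Loop ruptures are drawn from the Bell-Evans
    hazard integrated along the force trajectory, so ramp assays produce
    upward leaps at stochastic rupture forces.
    """
    rng = _require_seed(seed)
    p = ds_params or DsWlcParams()
    if not any(s.kind == "ramp" for s in protocol.segments):
        raise ValueError("force-extension protocol must contain ramp segments")
    n = int(round(protocol.total_duration * sampling_rate))
    time = np.arange(n) / sampling_rate
    force = protocol.force_at(time)
    rupture_t = _loop_rupture_times(spec.loops, time, force, rng, p.thermal_energy)

    compacted = np.zeros(n)
    for loop, t_r in zip(spec.loops, rupture_t):
        compacted += np.where(time < t_r, loop.delta_l_bp, 0.0)
    released_bp = spec.tl_bp - compacted
    ext = released_bp * p.rise_per_bp * _ds_rel_clamped(force, p)
    ext = ext + _noise(rng, force, spec.noise_sd, n)
    contour = spec.tl_bp * p.rise_per_bp
    trace = Trace(time, force, _finalize_extension(ext, contour),
                  sampling_rate,
                  {"assay": "force_extension", "seed": seed,
                   "molecule": spec.molecule_id, "tl_bp": spec.tl_bp,
                   "true_rupture_times": [round(t, 6) for t in rupture_t
                                          if np.isfinite(t)],
                   "true_loop_sizes": [l.delta_l_bp for l in spec.loops]})
    return trace


def simulate_force_jump(spec: TelomereMoleculeSpec,
                        f_rest: float = 0.0, f_test: float = 8.0,
                        f_high: float = 10.0, f_max: float = 20.0,
                        t_rest: float = 120.0, t_test: float = 60.0,
                        n_cycles: int = 1, seed: int | None = None,
                        sampling_rate: float = 200.0,
                        ds_params: DsWlcParams | None = None) -> Trace:
    """Force-jump trace: rest/bind at F_rest, score ruptures at F_test.

    In each cycle every loop of the molecule spec binds with the configured
    binding probability during the rest phase; at F_test the bound loops
    rupture sequentially, each after an exponential waiting time with
    rate k(F_test), producing extension leaps separated by dwells.
    Loops still bound at the end of the F_test hold are released at the
    jump to F_high (complete rupture is guaranteed by the high forces).
    """
    rng = _require_seed(seed)
    p = ds_params or DsWlcParams()
    cycle = force_jump_cycle(f_rest, f_test, f_high, f_max,
                             t_rest=t_rest, t_test=t_test)
    n_per = int(round(cycle.total_duration * sampling_rate))
    cycle_T = n_per / sampling_rate      # snap cycles to the sample grid
    test_windows = cycle.segment_windows(kind="jump", force=f_test)
    test_start, test_end = test_windows[0]
    high_start = cycle.segment_windows(kind="jump", force=f_high)[0][0]

    times, forces, compacted = [], [], []
    truth = []
    for c in range(n_cycles):
        t_local = np.arange(n_per) / sampling_rate
        f_local = cycle.force_at(t_local)
        bound = [l for l in spec.loops
                 if rng.uniform() < spec.binding_probability]
        comp = np.zeros(n_per)
        cursor = test_start
        for loop in bound:
            rate = bell_evans_rate(f_test, loop.k0, loop.x_dagger,
                                   p.thermal_energy)
            dwell = rng.exponential(1.0 / rate)
            t_r = cursor + dwell
            if t_r >= test_end:       # swept away at the jump to F_high
                t_r = high_start
            comp += np.where(t_local < t_r, loop.delta_l_bp, 0.0)
            truth.append({"cycle": c, "delta_l_bp": loop.delta_l_bp,
                          "rupture_time": round(c * cycle_T + t_r, 6),
                          "dwell": round(t_r - cursor, 6)})
            cursor = min(t_r, test_end)
        times.append(t_local + c * cycle_T)
        forces.append(f_local)
        compacted.append(comp)

    time = np.concatenate(times)
    force = np.concatenate(forces)
    comp = np.concatenate(compacted)
    released_bp = spec.tl_bp - comp
    ext = released_bp * p.rise_per_bp * _ds_rel_clamped(force, p)
    ext = ext + _noise(rng, force, spec.noise_sd, len(time))
    contour = spec.tl_bp * p.rise_per_bp
    meta = {"assay": "force_jump", "seed": seed, "molecule": spec.molecule_id,
            "tl_bp": spec.tl_bp, "f_rest": f_rest, "f_test": f_test,
            "f_high": f_high, "f_max": f_max, "cycle_duration": cycle_T,
            "t_rest": t_rest, "t_test": t_test, "n_cycles": n_cycles,
            "true_events": truth}
    return Trace(time, force, _finalize_extension(ext, contour),
                 sampling_rate, meta)


@dataclass(frozen=True)
class BoundDimer:
    """A TRF1 dimer on the hairpin stem.

    ``site_end`` is the 1-based stem position of the last base of its
    12-bp footprint (two adjacent TTAGGG); ``mean_dwell`` the exponential
    pause duration at F_test, s.
    """

    site_end: int
    mean_dwell: float = 0.36

    @property
    def site_start(self) -> int:
        return self.site_end - 11


def simulate_strand_separation(construct: HairpinConstruct,
                               bound_dimers: list[BoundDimer],
                               f_low: float = 6.0, f_test: float = 17.0,
                               f_high: float = 22.0,
                               t_low: float = 2.0, t_test: float = 20.0,
                               seed: int | None = None,
                               sampling_rate: float = 100.0,
                               noise_sd: float | None = None,
                               allow_backward: bool | None = None,
                               ds_params: DsWlcParams | None = None,
                               ss_params: SsWlcParams | None = None) -> Trace:
    """One strand-separation cycle of a hairpin with bound TRF1 dimers.

    At F_test the fork advances instantly to the first bound dimer,
    pauses there for an exponential dwell, then advances to the next,
    finally opening completely.  Each unzipped bp releases 2 nt of ssDNA
    whose extension follows the Marko-Siggia WLC at the current force.
    The fully-open hold at F_test is the zero-correction reference.

    Backward fork excursions are generated during pauses only when
    ``f_test`` is within 0.9 pN of the critical melting force
    (mimicking the observed force sensitivity); override with
    ``allow_backward``.
    """
    rng = _require_seed(seed)
    dsp = ds_params or DsWlcParams()
    ssp = ss_params or SsWlcParams()
    stem = construct.stem_length
    dimers = sorted(bound_dimers, key=lambda d: d.site_end)
    spacer_windows = construct.spacer_windows()
    occupied = []
    for d in dimers:
        if d.site_start < 1 or d.site_end > stem:
            raise ValueError(f"dimer footprint {d.site_start}-{d.site_end} "
                             "outside the stem")
        for (a, b) in spacer_windows:
            if d.site_start <= b and a <= d.site_end:
                raise ValueError("dimer footprint overlaps a spacer "
                                 "(spacers are non-binding)")
        for (a, b) in occupied:
            if d.site_start <= b and a <= d.site_end:
                raise ValueError("dimer footprints overlap")
        occupied.append((d.site_start, d.site_end))

    proto = strand_separation_cycle(f_low, f_test, f_high,
                                    t_low=t_low, t_test=t_test)
    n = int(round(proto.total_duration * sampling_rate))
    time = np.arange(n) / sampling_rate
    force = proto.force_at(time)
    test_start, test_end = proto.segment_windows(kind="jump", force=f_test)[0]

    # Fork position timeline within the F_test hold: (time, unzipped_bp).
    # While a dimer occupies sites s..e the fork is blocked with s-1 bp
    # unzipped; transits between blocks are instantaneous.
    changes: list[tuple[float, int]] = [(0.0, 0)]
    truth = []
    cursor = test_start
    for d in dimers:
        changes.append((cursor, d.site_start - 1))
        dwell = rng.exponential(d.mean_dwell)
        truth.append({"site_start": d.site_start, "site_end": d.site_end,
                      "pause_start": round(cursor, 6),
                      "dwell": round(dwell, 6)})
        cursor += dwell
    changes.append((min(cursor, test_end - 1e-9), stem))  # fully open

    unzipped = np.zeros(n)
    for t_c, pos in changes:
        unzipped = np.where(time >= t_c, float(pos), unzipped)
    # re-zip instantly when the force drops back to F_low at cycle end
    relow = proto.boundaries()[-2]
    unzipped = np.where(time >= relow + 0.39, 0.0, unzipped)

    if allow_backward is None:
        allow_backward = f_test < CRITICAL_MELTING_FORCE + 0.9
    if allow_backward and dimers:
        # brief backward excursions of ~1 repeat during pauses
        for ev in truth:
            t0, t1 = ev["pause_start"], ev["pause_start"] + ev["dwell"]
            t = t0 + rng.exponential(0.5)
            while t < t1:
                back = rng.exponential(0.1)
                m = (time >= t) & (time < min(t + back, t1))
                unzipped[m] = np.maximum(unzipped[m] - 6.0, 0.0)
                t += back + rng.exponential(0.5)

    # extension: dsDNA handles + released ssDNA (2 nt per unzipped bp)
    rel_ds = _ds_rel_clamped(force, dsp)
    handle_ext = 2 * construct.handle_bp * dsp.rise_per_bp * rel_ds
    f_round = np.round(force, 6)
    uniq, inv = np.unique(f_round, return_inverse=True)
    rel_uniq = np.array([ss_relative_extension(f, ssp) if f > 0 else 0.0
                         for f in uniq])
    rel_ss = rel_uniq[inv]
    ss_ext = 2.0 * unzipped * ssp.contour_per_nt * rel_ss
    sd = noise_sd if noise_sd is not None else float(default_noise_sd(f_test))
    ext = handle_ext + ss_ext + rng.normal(0.0, sd, size=n)
    contour = (2 * construct.handle_bp * dsp.rise_per_bp
               + 2 * stem * ssp.contour_per_nt + 50.0)
    meta = {"assay": "strand_separation", "seed": seed,
            "construct": construct.name, "stem_length": stem,
            "f_low": f_low, "f_test": f_test, "f_high": f_high,
            "handle_bp": construct.handle_bp,
            "test_window": (round(test_start, 6), round(test_end, 6)),
            "true_pauses": truth}
    return Trace(time, force, _finalize_extension(ext, contour),
                 sampling_rate, meta)


def simulate_hopping(spec: HoppingSpec, force: float, duration: float,
                     seed: int | None = None,
                     sampling_rate: float = 200.0,
                     kbt: float = KBT_PN_NM) -> Trace:
    """Constant-force two-state hopping trace (telegraph + Gaussian noise).

    Rates obey detailed balance, k_forward/k_backward =
    exp((F - F_half) dx / kBT), with geometric-mean attempt rate
    ``spec.attempt_rate``; emission levels are 0 (backward) and
    ``spec.delta_x`` nm (forward).
    """
    rng = _require_seed(seed)
    if abs(force - spec.f_half) > 1.0:
        raise ValueError("probe force must be within 1 pN of F_half")
    delta = (force - spec.f_half) * spec.delta_x / kbt
    k_fwd = spec.attempt_rate * np.exp(+delta / 2.0)   # backward -> forward
    k_back = spec.attempt_rate * np.exp(-delta / 2.0)  # forward -> backward
    if min(1.0 / k_fwd, 1.0 / k_back) < 5.0 / sampling_rate:
        raise ValueError("rates give mean dwells < 5 samples at this "
                         "sampling rate")
    n = int(round(duration * sampling_rate))
    time = np.arange(n) / sampling_rate

    state = int(rng.uniform() < k_fwd / (k_fwd + k_back))  # 1 = forward
    t, states, switch_times = 0.0, [state], [0.0]
    while t < duration:
        rate = k_back if state else k_fwd
        t += rng.exponential(1.0 / rate)
        state = 1 - state
        states.append(state)
        switch_times.append(t)
    idx = np.searchsorted(switch_times, time, side="right") - 1
    path = np.asarray(states)[idx]
    ext = path * spec.delta_x + rng.normal(0.0, spec.noise_sd, size=n)

    mean_dwell = 0.5 * (1.0 / k_fwd + 1.0 / k_back)
    meta = {"assay": "hopping", "seed": seed, "force": force,
            "f_half": spec.f_half, "delta_x": spec.delta_x,
            "attempt_rate": spec.attempt_rate,
            "k_forward": float(k_fwd), "k_backward": float(k_back),
            "true_path_changes": int(np.count_nonzero(np.diff(path))),
            "short_trace_warning": bool(duration < 20 * mean_dwell)}
    trace = Trace(time, np.full(n, float(force)), ext, sampling_rate, meta)
    trace.metadata["true_path"] = path  # in-memory ground truth only
    return trace


def sample_loop_population(tl_bp: float,
                           mixture: GaussianMixtureSpec,
                           seed: int | None = None,
                           mean_loops: float = 6.0,
                           max_retries: int = 20) -> list[float]:
    """Loop sizes for one molecule from a truncated Gaussian mixture.

    The number of binding attempts is Poisson(``mean_loops``); each draw
    comes from the mixture truncated to ΔL > 0 and is rejected when it
    would push the running total over the telomere length.  That budget
    rejection is what induces the negative correlation between the
    number of loops per molecule and the loop sizes.
    """
    rng = _require_seed(seed)
    weights = np.array([c[0] for c in mixture.components])
    if all(c[1] - 3 * c[2] > tl_bp for c in mixture.components):
        raise ValueError("mixture mass lies entirely above the telomere length")
    out: list[float] = []
    total = 0.0
    n_attempts = rng.poisson(mean_loops)
    for _ in range(n_attempts):
        for _ in range(max_retries):
            j = rng.choice(len(weights), p=weights)
            _, mu, sigma = mixture.components[j]
            dl = rng.normal(mu, sigma)
            if dl > 0 and total + dl <= tl_bp:
                out.append(float(dl))
                total += dl
                break
        else:
            break  # budget exhausted
    return out


def loop_mixture_preset(concentration_nm: float,
                        tl_bin: str) -> GaussianMixtureSpec:
    """Preset loop-size mixture for a concentration / TL-bin condition."""
    key = (int(concentration_nm), tl_bin)
    if key not in LOOP_MIXTURE_PRESETS:
        raise KeyError(f"no preset for {key}; available: "
                       f"{sorted(LOOP_MIXTURE_PRESETS)}")
    comps = LOOP_MIXTURE_PRESETS[key]
    w = sum(c[0] for c in comps)
    return GaussianMixtureSpec(tuple((c[0] / w, c[1], c[2]) for c in comps))
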