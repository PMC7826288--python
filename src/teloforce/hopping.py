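"""Two-state hidden-Markov analysis of constant-force hopping traces.

A telomeric fork held near its critical force hops between a forward
(more-unzipped, higher-extension) and a backward state.  A two-state
Gaussian HMM assigns each sample to a state; the decoded path yields
per-state dwell times and the open (forward-state) probability.  Across
forces the open probability follows the Boltzmann relation

.. math:: P_o(F) = \\frac{1}{1 + \\exp((F_{1/2} - F)\\,\\Delta x / k_BT)},

whose fitted half-force and distance give the free-energy change
``dG = F_half * dx / kBT`` (reported in kBT units at 23 C).

Note: some descriptions of this relation omit the kBT in the exponent,
which is dimensionally inconsistent; here the exponent is always
(F_half - F) * dx / kBT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .polymer import KBT_PN_NM
from .trace import Trace

__all__ = ["HmmResult", "BoltzmannFit", "fit_two_state_hmm",
           "open_probability", "fit_boltzmann", "dwell_vs_force"]

MIN_DWELL_S = 0.02


@dataclass
class HmmResult:
    """Decoded two-state HMM of a hopping trace.

    ``state_path`` is 1 in the forward (higher-extension) state and 0 in
    the backward state; dwell lists exclude dwells truncated by the
    trace boundaries and dwells <= 20 ms.
    """

    state_path: np.ndarray
    means: tuple[float, float]          # (backward, forward) level, nm
    emission_sd: float                  # common SD, nm
    rates: tuple[float, float]          # (k_fwd, k_back) 1/s
    dwell_forward: np.ndarray           # s
    dwell_backward: np.ndarray          # s
    log_likelihood: float
    sampling_rate: float
    force: float


def _runs(path: np.ndarray):
    """(state, length) run-length encoding of a 0/1 path."""
    changes = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [len(path)]])
    return [(int(path[s]), int(e - s)) for s, e in zip(starts, ends)]


def fit_two_state_hmm(trace: Trace, n_restarts: int = 5,
                      max_iter: int = 500, tol: float = 1e-6,
                      restart_seed: int = 0) -> HmmResult:
    """Fit and decode a 2-state Gaussian HMM on a constant-force trace.

    EM (Baum-Welch) with k-means initialisation plus random restarts,
    best likelihood kept; the state path is the most probable (Viterbi)
    path.  Requires >= 500 samples at constant force and a resolvable
    two-level signal.
    """
    import logging

    from hmmlearn.hmm import GaussianHMM
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

    if len(trace) < 500:
        raise ValueError("need at least 500 samples for the HMM")
    if np.ptp(trace.force) > 0.2:
        raise ValueError("HMM requires a constant-force trace")
    y = trace.extension.reshape(-1, 1)
    if np.std(y) < 1e-12:
        raise ValueError("fewer than two states resolvable (constant signal)")

    best = None
    for r in range(n_restarts):
        # hmmlearn seeds its k-means mean initialisation from random_state
        model = GaussianHMM(n_components=2, covariance_type="tied",
                            n_iter=max_iter, tol=tol, init_params="stmc",
                            random_state=restart_seed + r)
        try:
            with warnings.catch_warnings():
                # the monitor flags float-precision LL decreases (~1e-8)
                warnings.simplefilter("ignore")
                model.fit(y)
                ll = model.score(y)
        except ValueError:
            continue
        if best is None or ll > best[0]:
            best = (ll, model)
    if best is None:
        raise ValueError("HMM fit failed on all restarts")
    ll, model = best

    means = model.means_.ravel()
    if abs(means[1] - means[0]) < 1e-9:
        raise ValueError("fewer than two states resolvable")
    order = np.argsort(means)                 # backward first
    decoded = model.predict(y)
    path = np.where(decoded == order[1], 1, 0)

    fs = trace.sampling_rate
    runs = _runs(path)
    # drop boundary-truncated dwells (first and last runs)
    interior = runs[1:-1] if len(runs) > 2 else []
    dwell_f = np.array([n / fs for s, n in interior
                        if s == 1 and n / fs > MIN_DWELL_S])
    dwell_b = np.array([n / fs for s, n in interior
                        if s == 0 and n / fs > MIN_DWELL_S])
    # transition rates from the transition matrix in the sorted order
    tm = model.transmat_[np.ix_(order, order)]
    k_fwd = float(tm[0, 1] * fs)   # backward -> forward
    k_back = float(tm[1, 0] * fs)  # forward -> backward
    sd = float(np.sqrt(model.covars_.ravel()[0]))
    return HmmResult(state_path=path,
                     means=(float(means[order[0]]), float(means[order[1]])),
                     emission_sd=sd, rates=(k_fwd, k_back),
                     dwell_forward=dwell_f, dwell_backward=dwell_b,
                     log_likelihood=float(ll), sampling_rate=fs,
                     force=float(np.mean(trace.force)))


def open_probability(hmm: HmmResult) -> tuple[float, float]:
    """Time fraction in the forward state and a binomial-style SE.

    The SE uses the number of decoded dwells as the effective sample
    size (samples within a dwell are not independent).
    """
    p = float(np.mean(hmm.state_path))
    n_eff = max(len(hmm.dwell_forward) + len(hmm.dwell_backward), 1)
    se = float(np.sqrt(max(p * (1 - p), 1e-12) / n_eff))
    return p, se


@dataclass
class BoltzmannFit:
    f_half: float               # pN
    delta_x: float              # nm
    delta_g: float              # kBT units, F_half * dx / kBT
    f_half_se: float
    delta_x_se: float
    forces: np.ndarray
    p_open: np.ndarray
    p_open_se: np.ndarray


def boltzmann_p_open(force, f_half, delta_x, kbt: float = KBT_PN_NM):
    return 1.0 / (1.0 + np.exp((f_half - np.asarray(force, float))
                               * delta_x / kbt))


def fit_boltzmann(forces, p_open, p_open_se=None,
                  kbt: float = KBT_PN_NM) -> BoltzmannFit:
    """Weighted NLS fit of the Boltzmann open-probability curve.

    Requires >= 4 forces and open probabilities on both sides of 1/2
    (otherwise F_half is not identifiable).
    """
    f = np.asarray(forces, dtype=float)
    p = np.asarray(p_open, dtype=float)
    if len(f) < 4:
        raise ValueError("need at least 4 forces")
    if p.min() >= 0.5 or p.max() <= 0.5:
        raise ValueError("open probabilities all on one side of 1/2; "
                         "F_half not identifiable")
    sigma = (np.asarray(p_open_se, dtype=float)
             if p_open_se is not None else None)
    if sigma is not None:
        sigma = np.clip(sigma, 1e-3, None)
    # initial guesses: F_half from the crossing, dx from the logit slope
    f0 = float(np.interp(0.5, p[np.argsort(p)], f[np.argsort(p)]))
    popt, pcov = curve_fit(
        lambda F, fh, dx: boltzmann_p_open(F, fh, dx, kbt),
        f, p, p0=[f0, 10.0], sigma=sigma, absolute_sigma=False,
        maxfev=20000)
    f_half, dx = map(float, popt)
    if dx <= 0:
        raise ValueError("fitted delta_x non-positive")
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return BoltzmannFit(f_half=f_half, delta_x=dx,
                        delta_g=f_half * dx / kbt,
                        f_half_se=float(perr[0]), delta_x_se=float(perr[1]),
                        forces=f, p_open=p,
                        p_open_se=(sigma if sigma is not None
                                   else np.full_like(f, np.nan)))


def dwell_vs_force(results: list[HmmResult]):
    """Mean dwell per state per force, with SE, as a table (dict of arrays).

    Requires results at >= 3 distinct forces.  Use
    :func:`dwell_difference` to compare two conditions at matched force.
    """
    forces = sorted({round(r.force, 3) for r in results})
    if len(forces) < 3:
        raise ValueError("need results at >= 3 distinct forces")
    rows = {"force": [], "dwell_forward": [], "dwell_forward_se": [],
            "dwell_backward": [], "dwell_backward_se": [], "n_forward": [],
            "n_backward": []}
    for f in forces:
        df = np.concatenate([r.dwell_forward for r in results
                             if round(r.force, 3) == f] or [np.empty(0)])
        db = np.concatenate([r.dwell_backward for r in results
                             if round(r.force, 3) == f] or [np.empty(0)])
        rows["force"].append(f)
        for name, d in (("forward", df), ("backward", db)):
            mean = float(np.mean(d)) if d.size else np.nan
            se = (float(np.std(d, ddof=1) / np.sqrt(d.size))
                  if d.size > 1 else np.nan)
            rows[f"dwell_{name}"].append(mean)
            rows[f"dwell_{name}_se"].append(se)
            rows[f"n_{name}"].append(int(d.size))
    return {k: np.asarray(v) for k, v in rows.items()}


def dwell_difference(table_a: dict, table_b: dict, force: float,
                     state: str = "backward") -> float:
    """Mean-dwell difference (condition a - b) for one state at a force."""
    def pick(tab):
        i = int(np.argmin(np.abs(tab["force"] - force)))
        return tab[f"dwell_{state}"][i]
    return float(pick(table_a) - pick(table_b))
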