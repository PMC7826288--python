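"""Step detection and rupture/pause extraction from constant-force traces.

The fitter is a greedy recursive change-point search in the style used
for molecular-motor stepping records: repeatedly place the single step
that maximally reduces the residual sum of squares, stopping when the
best remaining step's SSE reduction falls below a noise-scaled
significance penalty (no genuine step left, only noise to chase), then
locally re-optimise every change point between its neighbours.

Dwells at or below 20 ms (two samples at 100 Hz) are discarded, because
below the Nyquist limit a plateau cannot be distinguished from noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polymer import DsWlcParams, nm_per_bp
from .trace import Trace

__all__ = [
    "Plateau", "SubStep", "StepFitResult", "RuptureEvent", "ResidenceMap",
    "fit_steps", "fit_steps_array", "zero_correct", "extract_ruptures",
    "residence_map",
]

MIN_DWELL_S = 0.02  # Nyquist dwell filter at 100 Hz


@dataclass(frozen=True)
class Plateau:
    start: int        # sample index, inclusive
    end: int          # sample index, exclusive
    level: float      # mean of samples, signal units

    @property
    def n(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SubStep:
    index: int        # sample index of the change point
    time: float       # s, relative to segment start
    size: float       # level change across the step, signal units
    dwell: float      # duration of the preceding plateau, s


@dataclass
class StepFitResult:
    plateaus: list[Plateau]
    sub_steps: list[SubStep]
    sse: float
    sampling_rate: float
    noise_sd: float

    @property
    def levels(self) -> np.ndarray:
        return np.array([p.level for p in self.plateaus])

    def fitted(self, n: int | None = None) -> np.ndarray:
        """Piecewise-constant fitted signal."""
        n = n if n is not None else self.plateaus[-1].end
        out = np.empty(n)
        for p in self.plateaus:
            out[p.start:p.end] = p.level
        return out


def _plateau_sse(c1: np.ndarray, c2: np.ndarray, lo: int, hi: int) -> float:
    s = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    n = hi - lo
    return s2 - s * s / n


def _best_split(c1: np.ndarray, c2: np.ndarray, lo: int, hi: int):
    """Best single change point inside [lo, hi): (index, SSE gain).

    Ties broken toward the earlier index.  Returns (None, 0) when the
    plateau cannot be split.
    """
    if hi - lo < 2:
        return None, 0.0
    j = np.arange(lo + 1, hi)
    nl = j - lo
    nr = hi - j
    sl = c1[j] - c1[lo]
    sr = c1[hi] - c1[j]
    sse0 = _plateau_sse(c1, c2, lo, hi)
    sse_split = (c2[hi] - c2[lo]) - sl * sl / nl - sr * sr / nr
    gains = sse0 - sse_split
    k = int(np.argmax(gains))      # argmax returns the first maximum
    return int(j[k]), float(gains[k])


def _piecewise_sse(c1, c2, boundaries) -> float:
    return sum(_plateau_sse(c1, c2, lo, hi)
               for lo, hi in zip(boundaries[:-1], boundaries[1:]))


def fit_steps_array(y: np.ndarray, sampling_rate: float,
                    max_steps: int = 30, min_dwell: float = MIN_DWELL_S,
                    penalty_factor: float = 3.0,
                    merge_factor: float = 1.0) -> StepFitResult:
    """Fit a staircase of plateaus to a 1-D signal.

    Steps are added greedily while the best step's SSE reduction exceeds
    a noise-scaled significance penalty, ``penalty_factor * sigma^2 *
    log(n)`` (a Schwarz-type change-point penalty; on noiseless input the
    penalty vanishes and every genuine step is taken).  Placed change
    points are then locally re-optimised, adjacent plateaus whose levels
    differ by less than ``merge_factor`` noise SDs are merged, and
    plateaus shorter than ``min_dwell`` are absorbed into the
    nearer-level neighbour.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples to fit steps")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])
    # robust noise estimate from first differences
    noise_sd = float(np.median(np.abs(np.diff(y))) / (np.sqrt(2) * 0.6745))

    tiny = max(1e-12, 1e-12 * float(c2[-1]))
    penalty = max(penalty_factor * noise_sd ** 2 * np.log(n), tiny)
    boundaries = [0, n]
    for _ in range(max_steps):
        best = (None, 0.0)
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            j, gain = _best_split(c1, c2, lo, hi)
            if j is not None and gain > best[1]:
                best = (j, gain)
        if best[0] is None or best[1] <= penalty:
            break
        boundaries = sorted(boundaries + [best[0]])
        if _piecewise_sse(c1, c2, boundaries) <= tiny:
            break
    chosen = _refine(c1, c2, boundaries) if len(boundaries) > 2 else boundaries

    plateaus = _build_plateaus(y, chosen)
    plateaus = _merge_close(y, plateaus, merge_factor * noise_sd)
    plateaus = _absorb_short(y, plateaus, min_dwell, sampling_rate)
    sub_steps = _substeps(plateaus, sampling_rate, min_dwell)
    sse = float(sum(np.sum((y[p.start:p.end] - p.level) ** 2)
                    for p in plateaus))
    return StepFitResult(plateaus, sub_steps, sse, sampling_rate, noise_sd)


def _refine(c1, c2, boundaries, max_passes: int = 20) -> list[int]:
    """Coordinate-descent refinement: re-place each change point optimally
    between its flanking neighbours until stable (escapes the greedy
    sequence's local misplacements)."""
    b = list(boundaries)
    for _ in range(max_passes):
        moved = False
        for i in range(1, len(b) - 1):
            j, _ = _best_split(c1, c2, b[i - 1], b[i + 1])
            if j is not None and j != b[i]:
                b[i] = j
                moved = True
        if not moved:
            break
    return b


def _build_plateaus(y, boundaries) -> list[Plateau]:
    return [Plateau(lo, hi, float(np.mean(y[lo:hi])))
            for lo, hi in zip(boundaries[:-1], boundaries[1:])]


def _merge_close(y, plateaus, threshold) -> list[Plateau]:
    if threshold <= 0:
        return plateaus
    out = list(plateaus)
    merged = True
    while merged and len(out) > 1:
        merged = False
        for i in range(len(out) - 1):
            if abs(out[i + 1].level - out[i].level) < threshold:
                lo, hi = out[i].start, out[i + 1].end
                out[i:i + 2] = [Plateau(lo, hi, float(np.mean(y[lo:hi])))]
                merged = True
                break
    return out


def _absorb_short(y, plateaus, min_dwell, fs) -> list[Plateau]:
    """Merge plateaus with dwell <= min_dwell into the closer neighbour."""
    min_n = min_dwell * fs
    out = list(plateaus)
    changed = True
    while changed and len(out) > 1:
        changed = False
        for i, p in enumerate(out):
            if p.n > min_n:
                continue
            left = out[i - 1] if i > 0 else None
            right = out[i + 1] if i < len(out) - 1 else None
            if left is None and right is None:
                break
            if right is None or (left is not None and
                                 abs(left.level - p.level)
                                 <= abs(right.level - p.level)):
                lo, hi = left.start, p.end
                out[i - 1:i + 1] = [Plateau(lo, hi, float(np.mean(y[lo:hi])))]
            else:
                lo, hi = p.start, right.end
                out[i:i + 2] = [Plateau(lo, hi, float(np.mean(y[lo:hi])))]
            changed = True
            break
    return out


def _substeps(plateaus, fs, min_dwell) -> list[SubStep]:
    out = []
    for prev, nxt in zip(plateaus[:-1], plateaus[1:]):
        dwell = prev.n / fs
        if dwell <= min_dwell:
            continue
        out.append(SubStep(index=nxt.start, time=nxt.start / fs,
                           size=nxt.level - prev.level, dwell=dwell))
    return out


def fit_steps(segment: Trace, max_steps: int = 30,
              min_dwell: float = MIN_DWELL_S,
              penalty_factor: float = 3.0,
              merge_factor: float = 1.0,
              force_atol: float = 0.2) -> StepFitResult:
    """Step-fit a constant-force trace segment (see :func:`fit_steps_array`)."""
    f = segment.force
    if len(f) and (np.max(f) - np.min(f)) > force_atol:
        raise ValueError("segment force is not constant")
    return fit_steps_array(segment.extension, segment.sampling_rate,
                           max_steps=max_steps, min_dwell=min_dwell,
                           penalty_factor=penalty_factor,
                           merge_factor=merge_factor)


# ---------------------------------------------------------------------------
# strand-separation zero correction and residence maps


def zero_correct(trace: Trace, f_test: float | None = None,
                 ss_nm_per_bp: float | None = None,
                 min_open_dwell: float = 0.1,
                 force_window: float = 0.25) -> Trace:
    """Re-reference a strand-separation trace to released base pairs.

    The bead height of the fully-open hairpin at ``f_test`` (the highest
    sustained plateau of the first F_test hold) defines zero.  Corrected
    values are ``(open_level - extension) / (2 nt/bp * ss nm/nt)`` — the
    number of base pairs still to unzip: a fully-open plateau maps to
    ~0 bp and the closed hairpin to the stem length.
    """
    from .polymer import ss_nm_per_nt

    f_test = f_test if f_test is not None else trace.metadata.get("f_test")
    if f_test is None:
        raise ValueError("f_test not given and absent from trace metadata")
    if ss_nm_per_bp is None:
        ss_nm_per_bp = 2.0 * ss_nm_per_nt(f_test)

    in_test = np.abs(trace.force - f_test) <= force_window
    if not np.any(in_test):
        raise ValueError("trace never reaches F_test")
    # first contiguous F_test hold
    idx = np.flatnonzero(in_test)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    stop = idx[breaks[0]] + 1 if breaks.size else idx[-1] + 1
    start = idx[0]
    seg_ext = trace.extension[start:stop]

    fit = fit_steps_array(seg_ext, trace.sampling_rate)
    candidates = [p for p in fit.plateaus
                  if p.n / trace.sampling_rate >= min_open_dwell]
    if not candidates:
        raise ValueError("no sustained plateau found; cannot locate the "
                         "fully-open level")
    open_level = max(p.level for p in candidates)
    spread = np.ptp([p.level for p in fit.plateaus])
    if spread > 0 and open_level < np.max(seg_ext) - 5 * fit.noise_sd:
        raise ValueError("fully-open plateau not detectable at F_test")

    corrected = (open_level - seg_ext) / ss_nm_per_bp
    meta = dict(trace.metadata)
    meta.update({"units": "bp_remaining", "open_level_nm": float(open_level),
                 "ss_nm_per_bp": float(ss_nm_per_bp), "f_test": f_test})
    return Trace(trace.time[start:stop], trace.force[start:stop], corrected,
                 trace.sampling_rate, meta)


@dataclass(frozen=True)
class RuptureEvent:
    """One loop-rupture event scored at F_test in a force-jump assay."""

    delta_l_bp: float
    dwell_s: float
    f_test: float
    molecule: str = ""
    cycle: int = 0

    def __post_init__(self) -> None:
        if self.delta_l_bp <= 0:
            raise ValueError("delta_l_bp must be positive")
        if self.dwell_s <= MIN_DWELL_S:
            raise ValueError("dwell must exceed the 20 ms Nyquist filter")


def extract_ruptures(trace: Trace, ds_params: DsWlcParams | None = None,
                     min_delta_l_bp: float = 20.0,
                     merge_factor: float = 3.0,
                     **fit_kwargs) -> list[RuptureEvent]:
    """Rupture events (ΔL, dwell) from a force-jump trace.

    The F_test windows are located from the trace metadata written by
    the generator/CLI (``f_test``, ``cycle_duration``, ``t_rest``,
    ``t_test``, ``n_cycles``).  Steps inside each window come from
    :func:`fit_steps`; upward extension steps are converted to base
    pairs with the force-dependent WLC factor at F_test.  The dwell of
    the first event is counted from the F_test onset, later ones from
    the previous rupture.  A trace with no steps yields an empty list.
    """
    md = trace.metadata
    try:
        f_test = md["f_test"]
        cycle_T = md["cycle_duration"]
        t_rest = md["t_rest"]
        t_test = md["t_test"]
        n_cycles = md.get("n_cycles", 1)
    except KeyError as exc:
        raise ValueError(f"trace metadata lacks protocol key {exc}") from exc
    from .protocol import JUMP_TRANSITION_TIME

    factor = nm_per_bp(f_test, ds_params)
    events: list[RuptureEvent] = []
    for c in range(n_cycles):
        w0 = c * cycle_T + t_rest + JUMP_TRANSITION_TIME
        w1 = c * cycle_T + t_rest + t_test
        seg = trace.window(w0, w1)
        if len(seg) < 10:
            continue
        # rupture leaps dwarf the bead noise, so plateaus within 3 noise
        # SDs of each other are spurious splits, not separate levels
        fit = fit_steps(seg, merge_factor=merge_factor, **fit_kwargs)
        for step in fit.sub_steps:
            if step.size <= 0:
                continue
            dl = step.size / factor
            if dl < min_delta_l_bp or step.dwell <= MIN_DWELL_S:
                continue
            events.append(RuptureEvent(delta_l_bp=float(dl),
                                       dwell_s=float(step.dwell),
                                       f_test=f_test,
                                       molecule=str(md.get("molecule", "")),
                                       cycle=c))
    return events


@dataclass
class ResidenceMap:
    """Per-bp accumulated residence time along the hairpin stem.

    Positions are 1-based from the fork end in the unzipping direction;
    bin ``s`` holds the time the fork spent blocked with base pair ``s``
    as the first still-closed position.
    """

    positions: np.ndarray       # 1..stem_length
    mean_time: np.ndarray       # s, averaged over traces
    se_time: np.ndarray         # standard error over traces
    total_time: float           # s, summed over traces and positions
    n_traces: int


def residence_map(corrected_traces: list[Trace],
                  stem_length: int | None = None,
                  open_margin_bp: float = 2.0,
                  **fit_kwargs) -> ResidenceMap:
    """Site-specific residence-time map from zero-corrected traces.

    Each trace is step-fitted; every plateau's dwell is accumulated in
    the 1-bp bin of its fork position ``stem_length - level + 1`` (level
    is in bp-still-to-unzip units from :func:`zero_correct`).  Plateaus
    mapping outside 1..stem_length, and plateaus within
    ``open_margin_bp`` of the fully-open level (whose long open-state
    dwell is not fork residence), are excluded.
    """
    if not corrected_traces:
        raise ValueError("no traces given")
    stems = {t.metadata.get("stem_length") for t in corrected_traces}
    constructs = {t.metadata.get("construct") for t in corrected_traces}
    if len(constructs) > 1:
        raise ValueError(f"mixed constructs in one map: {constructs}")
    if stem_length is None:
        (stem_length,) = stems
        if stem_length is None:
            raise ValueError("stem_length not given and absent from metadata")
    stem_length = int(stem_length)

    per_trace = np.zeros((len(corrected_traces), stem_length))
    for i, tr in enumerate(corrected_traces):
        if tr.metadata.get("units") != "bp_remaining":
            raise ValueError("traces must be zero-corrected first")
        fit = fit_steps_array(tr.extension, tr.sampling_rate, **fit_kwargs)
        for p in fit.plateaus:
            if p.level < open_margin_bp:      # fully-open state
                continue
            pos = int(round(stem_length - p.level + 1))
            if 1 <= pos <= stem_length:
                per_trace[i, pos - 1] += p.n / tr.sampling_rate
    mean = per_trace.mean(axis=0)
    se = (per_trace.std(axis=0, ddof=1) / np.sqrt(len(corrected_traces))
          if len(corrected_traces) > 1 else np.zeros(stem_length))
    return ResidenceMap(positions=np.arange(1, stem_length + 1),
                        mean_time=mean, se_time=se,
                        total_time=float(per_trace.sum()),
                        n_traces=len(corrected_traces))
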