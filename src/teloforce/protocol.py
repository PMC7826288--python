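"""Force protocols: ordered constant / ramp / jump segments.

A protocol describes the force applied by the magnets over time.  Jumps
are not instantaneous: the measured force-change time of the instrument
class emulated here is 390 +/- 30 ms, so a jump segment is rendered as a
fast linear ramp over ``transition_time`` followed by a hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "ForceProtocol", "JUMP_TRANSITION_TIME"]

#: Default force-jump transition time, s (measured 390 +/- 30 ms).
JUMP_TRANSITION_TIME = 0.39


@dataclass(frozen=True)
class Segment:
    """One protocol segment.

    kind
        ``"constant"`` holds ``force`` for ``duration``;
        ``"ramp"`` goes linearly from ``force`` to ``force_end`` over
        ``duration`` (loading rate = (force_end - force)/duration);
        ``"jump"`` ramps from the previous force to ``force`` over
        ``transition_time`` then holds, ``duration`` total.
    """

    kind: str
    force: float
    duration: float
    force_end: float | None = None
    transition_time: float = JUMP_TRANSITION_TIME

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ramp", "jump"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
        if self.force < 0 or (self.force_end is not None and self.force_end < 0):
            raise ValueError("forces must be non-negative")
        if self.kind == "ramp" and self.force_end is None:
            raise ValueError("ramp segment needs force_end")
        if self.kind == "jump" and not 0 < self.transition_time <= self.duration:
            raise ValueError("jump transition_time must be in (0, duration]")


@dataclass
class ForceProtocol:
    """Ordered list of segments defining F(t) from t = 0."""

    segments: list[Segment] = field(default_factory=list)

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    def boundaries(self) -> list[float]:
        """Segment start times plus the final end time."""
        t, out = 0.0, [0.0]
        for s in self.segments:
            t += s.duration
            out.append(t)
        return out

    def force_at(self, t):
        """Applied force at time(s) ``t`` (vectorised, piecewise linear)."""
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        bounds = self.boundaries()
        prev_force = self.segments[0].force if self.segments else 0.0
        for i, seg in enumerate(self.segments):
            t0, t1 = bounds[i], bounds[i + 1]
            m = (t >= t0) & (t < t1) if i < len(self.segments) - 1 else (t >= t0) & (t <= t1)
            local = t[m] - t0
            if seg.kind == "constant":
                out[m] = seg.force
            elif seg.kind == "ramp":
                out[m] = seg.force + (seg.force_end - seg.force) * local / seg.duration
            else:  # jump: fast ramp from prev_force, then hold
                ramp = np.minimum(local / seg.transition_time, 1.0)
                out[m] = prev_force + (seg.force - prev_force) * ramp
            prev_force = seg.force_end if seg.kind == "ramp" else seg.force
        return out if out.ndim else float(out)

    def segment_windows(self, kind: str | None = None,
                        force: float | None = None,
                        atol: float = 1e-9) -> list[tuple[float, float]]:
        """(start, end) times of segments matching ``kind`` and/or ``force``.

        For jump segments the window starts after the transition ramp so
        that it covers only the constant-force hold.
        """
        bounds = self.boundaries()
        out = []
        for i, seg in enumerate(self.segments):
            if kind is not None and seg.kind != kind:
                continue
            if force is not None and abs(seg.force - force) > atol:
                continue
            t0, t1 = bounds[i], bounds[i + 1]
            if seg.kind == "jump":
                t0 += seg.transition_time
            out.append((t0, t1))
        return out


def force_jump_cycle(f_rest: float, f_test: float, f_high: float, f_max: float,
                     t_rest: float = 120.0, t_test: float = 60.0,
                     t_high: float = 5.0, t_max: float = 5.0) -> ForceProtocol:
    """One cycle of the four-level force-jump protocol.

    Rest at ``f_rest`` (binding), jump to ``f_test`` (rupture scoring),
    then ``f_high`` and ``f_max`` to guarantee complete extension, then
    back down to ``f_test`` and ``f_rest``.
    """
    if not f_rest < f_test < f_high < f_max:
        raise ValueError("require f_rest < f_test < f_high < f_max")
    segs = [
        Segment("constant", f_rest, t_rest),
        Segment("jump", f_test, t_test),
        Segment("jump", f_high, t_high),
        Segment("jump", f_max, t_max),
        Segment("jump", f_high, t_high),
        Segment("jump", f_test, t_high),
        Segment("jump", f_rest, t_high),
    ]
    return ForceProtocol(segs)


def strand_separation_cycle(f_low: float = 6.0, f_test: float = 17.0,
                            f_high: float = 22.0, t_low: float = 60.0,
                            t_test: float = 20.0, t_high: float = 5.0,
                            t_ref: float = 5.0) -> ForceProtocol:
    """One strand-separation cycle: F_low -> F_test -> F_high -> F_test -> F_low."""
    if not f_low < f_test < f_high:
        raise ValueError("require f_low < f_test < f_high")
    segs = [
        Segment("constant", f_low, t_low),
        Segment("jump", f_test, t_test),
        Segment("jump", f_high, t_high),
        Segment("jump", f_test, t_ref),
        Segment("jump", f_low, t_ref),
    ]
    return ForceProtocol(segs)
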