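"""Trace container and delimited-text I/O.

A trace is a uniformly sampled record of (time, force, extension) from a
magnetic-tweezers assay at >= 100 Hz.  On disk it is a comma-delimited
table with a ``#``-commented header block carrying the metadata needed to
re-analyse it (assay type, sampling rate, seed, construct, ...).
"""

from __future__ import annotations

import ast
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace", "write_trace"]

MIN_SAMPLING_RATE = 100.0


@dataclass
class Trace:
    """Uniformly sampled single-molecule trace.

    Attributes
    ----------
    time, force, extension : ndarray
        Equal-length arrays; seconds, pN, nm.
    sampling_rate : float
        Hz, >= 100.
    metadata : dict
        Free-form provenance (assay, molecule id, seed, condition, ...).
    """

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        n = len(self.time)
        if len(self.force) != n or len(self.extension) != n:
            raise ValueError("time, force and extension must have equal length")
        if self.sampling_rate < MIN_SAMPLING_RATE:
            raise ValueError("sampling_rate must be >= 100 Hz")
        if n > 1:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "force": self.force, "extension": self.extension}
        )

    def window(self, t0: float, t1: float) -> "Trace":
        """Sub-trace with t0 <= time < t1 (metadata shared)."""
        m = (self.time >= t0) & (self.time < t1)
        return Trace(self.time[m], self.force[m], self.extension[m],
                     self.sampling_rate, dict(self.metadata))


def write_trace(trace: Trace, path: str | os.PathLike) -> None:
    """Write a trace as commented-header CSV, atomically (temp + rename)."""
    path = os.fspath(path)
    dirname = os.path.dirname(path) or "."
    lines = [f"# sampling_rate = {trace.sampling_rate!r}"]
    for key in sorted(trace.metadata):
        lines.append(f"# {key} = {trace.metadata[key]!r}")
    header = "\n".join(lines) + "\n"
    fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(header)
            trace.to_frame().to_csv(fh, index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_trace(path: str | os.PathLike) -> Trace:
    """Read a trace written by :func:`write_trace`.

    Raises ``ValueError`` naming the offending line on malformed input.
    """
    path = os.fspath(path)
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"{path}:{lineno}: malformed header line {line!r}")
            key, _, raw = body.partition("=")
            try:
                meta[key.strip()] = ast.literal_eval(raw.strip())
            except (ValueError, SyntaxError) as exc:
                raise ValueError(f"{path}:{lineno}: bad header value {raw!r}") from exc
    try:
        df = pd.read_csv(path, skiprows=n_header)
    except Exception as exc:
        raise ValueError(f"{path}: unparseable trace table ({exc})") from exc
    for col in ("time", "force", "extension"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    rate = meta.pop("sampling_rate", None)
    if rate is None:
        raise ValueError(f"{path}: header lacks sampling_rate")
    return Trace(df["time"].to_numpy(), df["force"].to_numpy(),
                 df["extension"].to_numpy(), float(rate), meta)
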