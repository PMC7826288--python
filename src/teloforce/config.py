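"""Run configuration: structured-text (YAML) round-trip with validation.

Every stochastic run must carry a seed; unknown keys are rejected with
an error naming them, so typos in configs fail fast instead of being
silently ignored.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "load_config", "save_config"]

KNOWN_KEYS = {
    "assay", "seed", "n_traces", "out_dir", "log_level", "params",
}

KNOWN_ASSAYS = {"force_extension", "force_jump", "strand_separation",
                "hopping"}


@dataclass
class RunConfig:
    assay: str
    seed: int
    n_traces: int = 1
    out_dir: str = "."
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in KNOWN_ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; "
                             f"expected one of {sorted(KNOWN_ASSAYS)}")
        if self.seed is None:
            raise ValueError("seed is required (reproducibility is mandatory)")
        self.seed = int(self.seed)
        if self.n_traces < 1:
            raise ValueError("n_traces must be >= 1")


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "assay" not in raw:
        raise ValueError(f"{path}: missing required key 'assay'")
    if "seed" not in raw:
        raise ValueError(f"{path}: missing required key 'seed'")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(path) or ".")
    try:
        with os.fdopen(fd, "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
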