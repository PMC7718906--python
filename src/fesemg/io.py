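"""Plain-text signal files, run configuration and session logging.

Signal files are two-column delimited text (time_s, value) with a minimal
``# key: value`` header carrying the sample rate, channel label and the
optional stimulation pulse indices, so a written trace round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signals import ArtifactParams, ConfigurationError, ParameterError, SignalTrace

__all__ = [
    "FormatError",
    "read_signal",
    "write_signal",
    "RunConfig",
    "load_config",
    "SessionLog",
    "get_logger",
]

logger = logging.getLogger("fesemg")


def get_logger() -> logging.Logger:
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    return logger


class FormatError(ValueError):
    """Malformed signal or configuration file."""


def write_signal(trace: SignalTrace, path, pulse_indices=None) -> None:
    path = Path(path)
    lines = [f"# fs: {trace.fs!r}", f"# label: {trace.label}"]
    if pulse_indices is not None:
        lines.append("# pulse_indices: " + ",".join(str(int(p)) for p in pulse_indices))
    t = np.arange(len(trace)) / trace.fs
    body = "\n".join(f"{ti:.6f}\t{float(vi)!r}" for ti, vi in zip(t, trace.samples))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def read_signal(path) -> tuple[SignalTrace, np.ndarray | None]:
    """Read a signal file; returns (trace, pulse_indices or None)."""
    path = Path(path)
    fs = None
    label = ""
    pulses = None
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: malformed header line")
            key, _, val = line[1:].partition(":")
            key, val = key.strip(), val.strip()
            if key == "fs":
                fs = float(val)
            elif key == "label":
                label = val
            elif key == "pulse_indices":
                pulses = (np.array([int(v) for v in val.split(",") if v], dtype=int)
                          if val else np.array([], dtype=int))
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            values.append(float(parts[1]))
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: {e}") from None
    if fs is None:
        raise FormatError(f"{path}: missing 'fs' header")
    if not values:
        raise FormatError(f"{path}: no samples")
    return SignalTrace(np.array(values), fs, label), pulses


@dataclass(frozen=True)
class RunConfig:
    """Defaults reproduce the study operating point (1 kHz, 25 Hz, M=6, L=40, 35 s)."""

    seed: int = 0
    fs: float = 1000.0
    f_stim: float = 25.0
    duration_s: float = 35.0
    vemg_rms: float = 1.0
    frame_length: int = 40
    history: int = 6
    use_comb: bool = True
    segment_len: int = 1024
    magnitude_ratio: float = 200.0
    clip_window: int = 0
    clip_level: float = 0.0
    kernel: str = "cmap"
    output_dir: str = "."

    def __post_init__(self):
        ratio = self.fs / self.f_stim
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError(f"fs/f_stim = {ratio} is not an integer")
        if self.duration_s <= 0 or self.frame_length < 1 or self.history < 1:
            raise ConfigurationError("invalid duration/frame_length/history")

    def artifact_params(self) -> ArtifactParams:
        return ArtifactParams(f_stim=self.f_stim, magnitude_ratio=self.magnitude_ratio,
                              clip_window=self.clip_window, clip_level=self.clip_level,
                              kernel=self.kernel, seed=self.seed)


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def load_config(path) -> RunConfig:
    """Key-value text configuration; unknown keys are rejected."""
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sep = "=" if "=" in line else ":"
        if sep not in line:
            raise ConfigurationError(f"{path}:{lineno}: expected key{sep}value")
        key, _, val = line.partition(sep)
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise ConfigurationError(f"{path}:{lineno}: unknown key {key!r}")
        default = getattr(RunConfig, key)
        try:
            if isinstance(default, bool):
                kwargs[key] = _BOOL[val.lower()]
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        except (KeyError, ValueError):
            raise ConfigurationError(f"{path}:{lineno}: bad value for {key!r}: {val!r}") from None
    return RunConfig(**kwargs)


@dataclass
class SessionLog:
    """Append-only structured record of a run."""

    records: list = field(default_factory=list)

    def add(self, stage: str, **fields) -> None:
        self.records.append({"t": time.time(), "stage": stage, **fields})
        get_logger().info("%s %s", stage, json.dumps(fields, default=str))

    def dump(self, path) -> None:
        Path(path).write_text("\n".join(json.dumps(r, default=str) for r in self.records) + "\n")
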