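"""Pipeline configuration: one flat key = value text file, lossless round-trip.

Unknown keys are rejected so that typos fail loudly. The SHA-1 of the
canonical serialization is stamped onto every output table.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # randomness / cohort
    seed: int = 0
    n_participants: int = 30
    tier4_fraction: float = 0.3
    n_scenes: int = 7
    fs: float = 40.0
    baseline_dur: float = 5.0
    guided_dur: float = 45.0
    self_dur: float = 60.0
    noise_sd: float = 0.008
    # cleaning
    iqr_k: float = 1.5
    clean_scope: str = "segment"  # per-segment fence (vs "recording")
    # fluctuation counting
    nfsc_min_amp: float = 0.02  # uS
    nfsc_max_rise_slope: float = 2.0  # uS/s
    nfsc_smooth_window: float = 0.5  # s
    nfsc_on_raw: bool = True
    # DTW similarity
    dtw_resample_hz: float = 4.0
    dtw_cost: str = "abs"
    dtw_window: int = 0  # 0 = unconstrained
    similarity_map: str = "minmax"
    display_threshold: float = 60.0
    # clustering
    k: int = 2
    n_init: int = 10
    max_iter: int = 100
    consensus_threshold: int = 10
    # stats
    sign_tol_frac: float = 0.05
    alpha: float = 0.05
    # paths
    input_csv: str = ""
    outdir: str = "sclshape_out"

    def __post_init__(self) -> None:
        if self.clean_scope not in ("segment", "recording"):
            raise ConfigError(f"clean_scope must be segment|recording, got {self.clean_scope}")
        if self.dtw_cost != "abs":
            raise ConfigError("only the absolute-difference DTW cost is implemented")
        if self.similarity_map != "minmax":
            raise ConfigError("only the minmax similarity mapping is implemented")
        if self.k < 2:
            raise ConfigError("k must be >= 2")

    def to_text(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls)}
        defaults = cls()
        values: dict = {}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ConfigError(f"line {lineno}: unknown key {key!r}")
            values[key] = _parse(val, getattr(defaults, key), key, lineno)
        return cls(**values)

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_text(Path(path).read_text())

    def hash(self) -> str:
        """Hash of the analysis-relevant values (paths excluded, so the same
        analysis run into a different directory keeps the same stamp)."""
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)
                 if f.name not in ("input_csv", "outdir")]
        return hashlib.sha1("\n".join(lines).encode()).hexdigest()[:12]

    def as_dict(self) -> dict:
        return asdict(self)


def _parse(val: str, default, key: str, lineno: int):
    if isinstance(default, bool):
        if val in ("True", "true", "1"):
            return True
        if val in ("False", "false", "0"):
            return False
        raise ConfigError(f"line {lineno}: {key} expects a boolean, got {val!r}")
    try:
        if isinstance(default, int):
            return int(val)
        if isinstance(default, float):
            return float(val)
    except ValueError as exc:
        raise ConfigError(f"line {lineno}: bad value for {key}: {val!r}") from exc
    return val
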