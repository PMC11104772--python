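"""Run configuration: every analysis knob, validated on load, fail-fast.

Config files are YAML or JSON mirroring the nested dataclasses below; unknown
keys are errors so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RoiConfig", "DetectionConfig", "LinkingConfig", "PermutationConfig", "AnalysisConfig"]


@dataclass
class RoiConfig:
    n_min: int = 16
    n_max: int = 20
    size: int = 11
    min_sep: float = 30.0
    separation_mode: str = "center"  # "center" (Euclidean center distance) is the only v1 mode

    def __post_init__(self) -> None:
        if self.n_min < 1 or self.n_min > self.n_max:
            raise ValueError(f"need 1 <= n_min <= n_max, got {self.n_min}, {self.n_max}")
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError(f"roi size must be odd and >=3, got {self.size}")
        if self.min_sep <= 0:
            raise ValueError("min_sep must be positive")
        if self.separation_mode != "center":
            raise ValueError(f"unsupported separation_mode {self.separation_mode!r}")


@dataclass
class DetectionConfig:
    sigma_px: float = 2.0
    threshold_rel: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if not (0 < self.threshold_rel < 1):
            raise ValueError(f"threshold_rel must be in (0, 1), got {self.threshold_rel}")


@dataclass
class LinkingConfig:
    max_disp_px: float = 15.0
    min_len: int = 3
    speed_mode: str = "path"  # "path" = mean frame-to-frame; "net" = end-to-end

    def __post_init__(self) -> None:
        if self.max_disp_px <= 0:
            raise ValueError("max_disp_px must be positive")
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")
        if self.speed_mode not in ("path", "net"):
            raise ValueError(f"speed_mode must be 'path' or 'net', got {self.speed_mode!r}")


@dataclass
class PermutationConfig:
    n_iterations: int = 10_000
    statistic: str = "mean_diff"
    alternative: str = "two_sided"
    exhaustive_limit: int = 200_000

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.statistic not in ("mean_diff", "median_diff"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.alternative not in ("two_sided", "greater", "less"):
            raise ValueError(f"unknown alternative {self.alternative!r}")


@dataclass
class AnalysisConfig:
    """All pipeline knobs, nested per stage. See docs/methods.md for defaults."""

    band_hz: tuple[float, float] = (5.0, 100.0)
    # peak/median of a pure-noise periodogram over ~100 in-band bins sits near
    # ln(n)/ln(2) ~ 6.6, so 20 rejects non-beating ROIs with large margin while
    # genuine tones exceed it by orders of magnitude
    snr_min: float = 20.0
    window: str = "hann"
    detrend: str = "linear"
    roi: RoiConfig = field(default_factory=RoiConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    linking: LinkingConfig = field(default_factory=LinkingConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    seed: int = 0
    output_dir: str = "ciliaflow_out"

    def __post_init__(self) -> None:
        self.band_hz = (float(self.band_hz[0]), float(self.band_hz[1]))
        if not (0 < self.band_hz[0] < self.band_hz[1]):
            raise ValueError(f"band_hz must satisfy 0 < low < high, got {self.band_hz}")
        if self.snr_min < 0:
            raise ValueError("snr_min must be >= 0")
        if self.window not in ("hann", "rect"):
            raise ValueError(f"window must be 'hann' or 'rect', got {self.window!r}")
        if self.detrend not in ("mean", "linear"):
            raise ValueError(f"detrend must be 'mean' or 'linear', got {self.detrend!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        nested = {"roi": RoiConfig, "detection": DetectionConfig,
                  "linking": LinkingConfig, "permutation": PermutationConfig}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})")
        for key, sub_cls in nested.items():
            if key in data:
                sub = data[key]
                if not isinstance(sub, dict):
                    raise ValueError(f"config key {key!r} must be a mapping")
                sub_known = {f.name for f in fields(sub_cls)}
                sub_unknown = set(sub) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                data[key] = sub_cls(**sub)
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if data is None:
            data = {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the full config, for run manifests."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def derive_seed(seed: int, stage: str) -> int:
    """Stage-keyed child seed so pipeline stages are independently reproducible."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
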