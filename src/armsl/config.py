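"""Pipeline configuration: every numeric threshold of the analysis in one place.

Defaults are the published analysis settings: arm-score deletion cutoff -2.5,
SCNA gain/loss cutoffs at +/-0.1 (log2 ratio), expression prefilter mean
log2(TPM+1) > 1, IHW FDR level 0.1, hit selection at adjusted p < 0.25 and
dCERES < -0.075 (strict tier at 0.1), pan-essential removal at mean CERES
< -0.75, BaCoN candidate filters, and the proteomics constants (70% valid
values, 1.8/0.3 SD downshifted imputation, |log2FC| >= 0.6, adjusted p < 0.05).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # arm classification
    chromosome: str = "8"
    arm: str = "p"
    cn_threshold: float = -2.5
    gain_cut: float = 0.1
    loss_cut: float = -0.1

    # differential dependency
    prefilter_min_mean: float = 1.0
    ihw_alpha: float = 0.1
    ihw_bins: int = 5
    ihw_folds: int = 5
    hit_p_cut: float = 0.25
    strict_p_cut: float = 0.1
    dceres_cut: float = -0.075
    # when True, "adjusted p < hit_p_cut" is evaluated on a second IHW run at
    # alpha = hit_p_cut instead of on the alpha = ihw_alpha adjusted values
    ihw_rerun_at_hit_level: bool = False

    # BaCoN
    pan_essential_cut: float = -0.75
    buffering_sd_min: float = 1.0
    buffering_level: float = 3.0
    buffering_min_lines: int = 100
    buffered_mean_expr_min: float = 2.0
    buffered_abs_mean_ceres_min: float = 0.3
    buffered_ceres_sd_min: float = 0.2
    bacon_variant: str = "multiplicative"  # or "subtractive"
    desk_scale: bool = False  # scale the ">=100 lines" count rule to 20% of lines
    top_k: int = 25

    # proteomics
    proteome_valid_frac: float = 0.70
    proteome_shift: float = 1.8
    proteome_width: float = 0.3
    proteome_fc_cut: float = 0.6
    proteome_alpha: float = 0.05

    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ConfigError(f"{f.name} must be finite, got {v}")
        if self.bacon_variant not in ("multiplicative", "subtractive"):
            raise ConfigError(f"bacon_variant must be multiplicative|subtractive, got {self.bacon_variant!r}")
        if self.arm not in ("p", "q"):
            raise ConfigError(f"arm must be 'p' or 'q', got {self.arm!r}")
        for name in ("ihw_bins", "ihw_folds", "buffering_min_lines", "top_k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0 < self.proteome_valid_frac <= 1:
            raise ConfigError("proteome_valid_frac must be in (0, 1]")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable 12-hex digest of the full configuration; stamped on outputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
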