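"""Pipeline configuration: YAML loading with strict validation.

Unknown keys are rejected (with a did-you-mean suggestion) rather than
silently ignored, so a typo like ``minscore`` cannot quietly fall back
to a default.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import comparison_label


@dataclass
class ComparisonSpec:
    path: str
    dose: float
    timepoint: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = comparison_label(self.dose, self.timepoint)


@dataclass
class PipelineConfig:
    """Typed, defaulted configuration for a full pipeline run.

    Defaults encode the analysis conventions: alpha = 0.05 with a strict
    q < alpha DEG rule, STRING medium confidence (min_score = 0.4),
    BP-only annotations with true-path propagation, Euclidean/complete
    clustering and a 1e-6 relative residual tolerance for the cut rule.
    """

    comparisons: list[ComparisonSpec] = field(default_factory=list)
    interactome_path: str = ""
    gaf_path: str = ""
    obo_path: str = ""
    alias_path: str | None = None
    seed_node: str = ""
    min_score: float = 0.4
    alpha: float = 0.05
    universe_mode: str = "annotated"       # or "custom"
    custom_universe_path: str | None = None
    min_term_size: int = 2
    propagate: bool = True
    fc_scale: str = "log2"                 # or "linear"
    distance: str = "euclidean"
    linkage: str = "complete"
    tol_rel: float = 1e-6
    balance_tol: float = 0.0
    size_coeff: float = 1.0
    score_scale: str = "raw_0_1000"
    rng_seed: int = 0

    def validate(self) -> None:
        if not self.comparisons:
            raise ConfigError("config lists no comparisons")
        if not self.seed_node:
            raise ConfigError("missing required key: seed_node")
        for key in ("interactome_path", "gaf_path", "obo_path"):
            if not getattr(self, key):
                raise ConfigError(f"missing required key: {key}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 <= self.min_score <= 1:
            raise ConfigError(f"min_score must be in [0,1], got {self.min_score}")
        if self.universe_mode not in ("annotated", "custom"):
            raise ConfigError(f"unknown universe_mode {self.universe_mode!r}")
        if self.universe_mode == "custom" and not self.custom_universe_path:
            raise ConfigError("universe_mode 'custom' needs custom_universe_path")
        if self.fc_scale not in ("log2", "linear"):
            raise ConfigError(f"unknown fc_scale {self.fc_scale!r}")
        labels = [c.label for c in self.comparisons]
        if len(set(labels)) != len(labels):
            raise ConfigError("comparison labels must be unique")
        missing = [
            p for p in [c.path for c in self.comparisons]
            + [self.interactome_path, self.gaf_path, self.obo_path]
            if not Path(p).exists()
        ]
        if missing:
            raise ConfigError(f"input paths do not exist: {missing}")


_KNOWN_KEYS = {f.name for f in fields(PipelineConfig)}
_CMP_KEYS = {f.name for f in fields(ComparisonSpec)}


def _reject_unknown(given, known, where: str) -> None:
    for key in given:
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            suffix = f" (did you mean {hint[0]!r}?)" if hint else ""
            raise ConfigError(f"unknown {where} key {key!r}{suffix}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    _reject_unknown(raw, _KNOWN_KEYS, "config")
    comparisons = []
    for entry in raw.get("comparisons", []):
        if not isinstance(entry, dict):
            raise ConfigError("each comparison must be a mapping")
        _reject_unknown(entry, _CMP_KEYS, "comparison")
        comparisons.append(ComparisonSpec(**entry))
    kwargs = {k: v for k, v in raw.items() if k != "comparisons"}
    base = Path(path).parent
    cfg = PipelineConfig(comparisons=comparisons, **kwargs)
    # resolve relative paths against the config file's directory
    for c in cfg.comparisons:
        c.path = str((base / c.path).resolve()) if not Path(c.path).is_absolute() else c.path
    for key in ("interactome_path", "gaf_path", "obo_path", "alias_path",
                "custom_universe_path"):
        val = getattr(cfg, key)
        if val and not Path(val).is_absolute():
            setattr(cfg, key, str((base / val).resolve()))
    cfg.validate()
    return cfg
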