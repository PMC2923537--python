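"""Pipeline thresholds: defaults, file loading and validation.

The configuration file is a flat YAML mapping (key: value).  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid configuration value or key."""


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds.

    fdr_de         BH FDR cutoff of the moderated F-test (0.01)
    fc_min         minimum parental fold change, ratio scale (1.3)
    intensity_min  minimum mean log2 intensity of a differential probe (8.0)
    alpha_step1    Step-1 significance of the two-step selection (1e-4)
    alpha_step2    Step-2 candidate-pool significance (0.01)
    r_coexpr       co-expression gate of Step 2, signed Pearson r (0.9)
    n_boot         bootstrap resamples of the BCa interval (10000)
    n_perm         Monte Carlo samples of the trait permutation test (9999)
    cv_rounds      cross-validation rounds (100)
    cv_top         size of the compared top lists (200)
    threshold_on   'raw' applies alpha cutoffs to raw p, 'fdr' to BH q
    min_lines      number of line means that must exceed the reliability
                   threshold for a probe to count as expressed (1)
    prefilter_fc   apply the fold-change prefilter before the F-test
    intensity_summary  'mean' or 'max' over line means for the 8.0 filter
    """

    fdr_de: float = 0.01
    fc_min: float = 1.3
    intensity_min: float = 8.0
    alpha_step1: float = 1e-4
    alpha_step2: float = 0.01
    r_coexpr: float = 0.9
    n_boot: int = 10000
    n_perm: int = 9999
    cv_rounds: int = 100
    cv_top: int = 200
    threshold_on: str = "raw"
    min_lines: int = 1
    prefilter_fc: bool = True
    intensity_summary: str = "mean"

    def __post_init__(self) -> None:
        def chk(cond: bool, msg: str) -> None:
            if not cond:
                raise ConfigError(msg)

        chk(0 < self.fdr_de <= 1, f"fdr_de={self.fdr_de} outside (0, 1]")
        chk(self.fc_min >= 1, f"fc_min={self.fc_min} must be a ratio >= 1")
        chk(0 < self.alpha_step1 <= 1, f"alpha_step1={self.alpha_step1} outside (0, 1]")
        chk(0 < self.alpha_step2 <= 1, f"alpha_step2={self.alpha_step2} outside (0, 1]")
        chk(
            self.alpha_step1 <= self.alpha_step2,
            f"alpha_step1={self.alpha_step1} must be <= alpha_step2={self.alpha_step2}",
        )
        chk(0 < self.r_coexpr <= 1, f"r_coexpr={self.r_coexpr} outside (0, 1]")
        for key in ("n_boot", "n_perm", "cv_rounds", "cv_top", "min_lines"):
            chk(int(getattr(self, key)) >= 1, f"{key}={getattr(self, key)} must be >= 1")
        chk(self.threshold_on in ("raw", "fdr"), f"threshold_on={self.threshold_on!r}")
        chk(
            self.intensity_summary in ("mean", "max"),
            f"intensity_summary={self.intensity_summary!r}",
        )

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a flat YAML key:value file; absent keys take defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key: value mapping")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    kw = {}
    for key, value in raw.items():
        want = _FIELD_TYPES[key]
        if want == "bool" and not isinstance(value, bool):
            raise ConfigError(f"{path}: key {key} expects a boolean, got {value!r}")
        if want == "int":
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"{path}: key {key} expects an integer, got {value!r}")
        if want == "float" and not isinstance(value, (int, float)):
            raise ConfigError(f"{path}: key {key} expects a number, got {value!r}")
        if want == "str" and not isinstance(value, str):
            raise ConfigError(f"{path}: key {key} expects a string, got {value!r}")
        kw[key] = value
    return PipelineConfig(**kw)
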