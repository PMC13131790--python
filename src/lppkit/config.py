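"""Configuration objects for analysis and simulation.

Two dataclasses mirror the two halves of the pipeline: :class:`AnalysisConfig`
holds every analysis constant (ROI, windows, priors, resampling sizes) and
:class:`GeneratorConfig` holds the generative model of the synthetic study.
Both round-trip through YAML via :func:`load_config` / :func:`dump_config`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: The ten a-priori centro-parietal sensors (1-based montage labels) over
#: which the late positive potential is scored.
DEFAULT_ROI: tuple[int, ...] = (7, 31, 37, 54, 55, 79, 80, 87, 106, 129)

#: Default Cauchy / stretched-beta prior scale for all Bayes factors.
DEFAULT_PRIOR_SCALE: float = math.sqrt(2.0) / 2.0


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class AnalysisConfig:
    """Analysis constants.

    Parameters
    ----------
    roi_channels
        1-based channel labels averaged for the LPP score.
    lpp_window
        Measurement window in seconds, half-open ``[start, end)``.
    winsor_limits
        Percentile limits ``(low, high)`` for winsorization of subject-level
        condition means.
    baseline_window
        Pre-stimulus window (seconds) used for baseline correction.  The
        published record defers this to supplementary material; ``[-0.1, 0]``
        is the package's documented stand-in.
    artifact_threshold_uv
        Absolute-voltage rejection threshold (microvolts); also a documented
        stand-in.
    prior_scale_t, prior_scale_r
        Prior scales for the t-test and correlation Bayes factors.
    n_boot, n_perm, seq_orderings
        Resampling sizes for bootstrap, decoding permutations, and sequential
        Bayes-factor subject orderings.
    seq_n_start
        First sample size of the sequential Bayes-factor grid.
    winsor_level
        ``"subject"`` (winsorize subject-level condition means, the default)
        or ``"trial"``.
    winsor_scope
        ``"condition"`` (percentiles computed within each valence x
        instruction cell) or ``"pooled"``.
    """

    roi_channels: tuple[int, ...] = DEFAULT_ROI
    lpp_window: tuple[float, float] = (0.400, 0.800)
    winsor_limits: tuple[float, float] = (1.0, 99.0)
    baseline_window: tuple[float, float] = (-0.100, 0.0)
    artifact_threshold_uv: float = 100.0
    prior_scale_t: float = DEFAULT_PRIOR_SCALE
    prior_scale_r: float = DEFAULT_PRIOR_SCALE
    n_boot: int = 10_000
    n_perm: int = 1000
    seq_orderings: int = 500
    seq_n_start: int = 20
    cv_folds: int = 5
    rng_seed: int = 0
    winsor_level: str = "subject"
    winsor_scope: str = "condition"

    def __post_init__(self) -> None:
        if self.lpp_window[0] >= self.lpp_window[1]:
            raise ConfigError("lpp_window start must precede end")
        lo, hi = self.winsor_limits
        if not (0.0 <= lo < hi <= 100.0):
            raise ConfigError(f"winsor_limits must satisfy 0 <= lo < hi <= 100, got {self.winsor_limits}")
        if self.prior_scale_t <= 0 or self.prior_scale_r <= 0:
            raise ConfigError("prior scales must be positive")
        if self.winsor_level not in ("subject", "trial"):
            raise ConfigError(f"winsor_level must be 'subject' or 'trial', got {self.winsor_level!r}")
        if self.winsor_scope not in ("condition", "pooled"):
            raise ConfigError(f"winsor_scope must be 'condition' or 'pooled', got {self.winsor_scope!r}")
        self.roi_channels = tuple(int(c) for c in self.roi_channels)


@dataclass
class GeneratorConfig:
    """Generative model of the synthetic multi-subject ERP study.

    The defaults emulate the study conditions: 107 subjects, a 129-channel
    montage sampled at 250 Hz, a centro-parietal late positivity in the
    0.3-0.9 s range whose region-of-interest window mean carries an
    emotion effect (emotional > neutral, within-subject dz 0.45) and an
    instruction effect under one of three switchable regimes, plus 1-7
    intensity ratings ordered Enhance > View > Suppress regardless of the
    neural regime (the behavioural/neural dissociation under study).

    ``trials_per_cell = 24`` is a plausible stand-in: the number of trials
    per condition cell is not part of the public record.

    ``instruction_dz`` is the population within-subject effect size of the
    active contrast of the regime, measured on the valence-pooled
    per-subject contrast score (the unit all inference runs on): for
    ``regime="load"`` the cognitive-load score ``2*View - Enhance -
    Suppress``; for ``regime="reappraisal"`` the reappraisal score
    ``Enhance - Suppress``.  ``regime="null"`` forces all neural
    instruction effects to zero while rating effects remain as configured.
    """

    n_subjects: int = 107
    trials_per_cell: int = 24
    n_channels: int = 129
    sfreq: float = 250.0
    epoch: tuple[float, float] = (-0.100, 1.000)
    emotion_dz: float = 0.45
    regime: str = "load"
    instruction_dz: float = 0.33
    rating_enhance_dz: float = 0.62
    rating_suppress_dz: float = 0.42
    trial_noise_sd: float = 5.0
    subject_sd: float = 1.0
    pink_noise_scale: float = 2.0
    roi_channels: tuple[int, ...] = DEFAULT_ROI
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if self.trials_per_cell < 1:
            raise ConfigError("trials_per_cell must be >= 1")
        if self.regime not in ("reappraisal", "load", "null"):
            raise ConfigError(f"regime must be one of reappraisal/load/null, got {self.regime!r}")
        if self.sfreq <= 0:
            raise ConfigError("sfreq must be positive")
        if self.epoch[0] > -0.05:
            raise ConfigError("epoch must start at t0 <= -0.05 s to allow a baseline")
        if self.epoch[1] < 1.0:
            raise ConfigError("epoch must extend to at least 1.0 s post-onset")
        for name in ("emotion_dz", "instruction_dz", "rating_enhance_dz", "rating_suppress_dz"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.trial_noise_sd <= 0 or self.subject_sd < 0 or self.pink_noise_scale < 0:
            raise ConfigError("noise scales must be positive (subject_sd/pink may be zero)")
        self.roi_channels = tuple(int(c) for c in self.roi_channels)
        if not set(self.roi_channels) <= set(range(1, self.n_channels + 1)):
            raise ConfigError("roi_channels must be 1-based labels within the montage")


def _from_mapping(cls, mapping: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in mapping:
            v = mapping[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path: str | Path) -> tuple[GeneratorConfig, AnalysisConfig]:
    """Load a YAML file with optional ``generator:`` and ``analysis:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen = _from_mapping(GeneratorConfig, raw.get("generator", {}) or {})
    ana = _from_mapping(AnalysisConfig, raw.get("analysis", {}) or {})
    return gen, ana


def dump_config(gen: GeneratorConfig, ana: AnalysisConfig, path: str | Path) -> None:
    doc = {"generator": dataclasses.asdict(gen), "analysis": dataclasses.asdict(ana)}

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_clean(doc), fh, sort_keys=False)
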