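"""Synthetic multi-subject ERP study generator.

Generates epoched EEG and a matching trial table with the statistical
structure the analysis pipeline assumes, under three switchable generative
regimes for the neural instruction effect:

``reappraisal``
    Enhance > View > Suppress on the ROI-window LPP, with the configured
    within-subject dz on the Enhance - Suppress score.
``load``
    View > Enhance = Suppress: both regulation instructions are reduced by
    the same amount, calibrated so the per-subject cognitive-load score
    ``2*View - Enhance - Suppress`` has the configured dz.
``null``
    No neural instruction effect at all.

Intensity ratings are generated Enhance > View > Suppress with their own
configured effect sizes in every regime — the behavioural and neural effects
are deliberately decoupled, which is the dissociation the analysis pipeline
is built to detect.

Each trial is 1/f (pink) background noise plus a condition-dependent late
positivity: a Hann (raised-cosine) bump spanning 0.3-0.9 s, spatially
weighted toward the ROI channels with a fixed smooth falloff, normalized so
that its ROI/analysis-window mean equals the trial's amplitude parameter.
Amplitudes are calibrated so subject-level condition-mean differences hit the
configured population dz; the pink-noise contribution to the measured window
mean is computed exactly from the synthesis filter and folded into the
trial-level noise budget (see :func:`pink_window_sd`), so the configured
``trial_noise_sd`` is the *total* trial-level SD of the measured score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .io import EpochSet, validate_trial_table

logger = logging.getLogger(__name__)

#: Raw spatial weight of non-ROI channels before zero-mean renormalisation.
#: A documented constant of the generator, not configurable.
NON_ROI_WEIGHT = 0.3

#: Temporal extent of the late-positivity template (seconds post-onset).
TEMPLATE_SPAN = (0.3, 0.9)

#: Analysis window whose ROI mean the amplitude parameter is calibrated to.
CALIBRATION_WINDOW = (0.4, 0.8)

#: Grand-mean ROI LPP of the neutral/view cell (microvolts); realism constant.
BASELINE_AMPLITUDE = 5.0

#: SD of the per-subject overall-amplitude intercept (cancels in contrasts).
SUBJECT_INTERCEPT_SD = 2.0

#: Rating-scale noise model: per-subject-condition SD and per-trial SD on the
#: latent continuous scale before discretisation to 1..7.
RATING_SUBJECT_SD = 0.5
RATING_TRIAL_SD = 1.2
RATING_BASE = {"neutral": 3.6, "pleasant": 4.6, "unpleasant": 5.1}

CELLS = [
    ("neutral", "view"),
    ("pleasant", "view"),
    ("pleasant", "enhance"),
    ("pleasant", "suppress"),
    ("unpleasant", "view"),
    ("unpleasant", "enhance"),
    ("unpleasant", "suppress"),
]


class CalibrationError(ValueError):
    """The requested effect sizes are infeasible under the noise model."""


def calibrate_amplitude(
    target_dz: float, trial_noise_sd: float, subject_sd: float, trials_per_cell: int
) -> float:
    """Template amplitude (uV) for a target within-subject dz on a two-condition difference.

    Subject-level condition means are modelled with variance
    ``subject_sd**2 + trial_noise_sd**2 / trials_per_cell``; the difference of
    two independent condition means therefore has twice that variance, and

        amplitude = target_dz * sqrt(2 * (subject_sd**2 + trial_noise_sd**2 / m)).
    """
    if trial_noise_sd <= 0:
        raise CalibrationError("trial_noise_sd must be positive")
    if subject_sd < 0:
        raise CalibrationError("subject_sd must be non-negative")
    if trials_per_cell < 1:
        raise CalibrationError("trials_per_cell must be >= 1")
    var_mean = subject_sd**2 + trial_noise_sd**2 / trials_per_cell
    return float(target_dz) * math.sqrt(2.0 * var_mean)


# ---------------------------------------------------------------------------
# Pink-noise synthesis and its exact window-mean variance
# ---------------------------------------------------------------------------

def _pink_spectrum(n_samples: int, sfreq: float) -> np.ndarray:
    """rFFT amplitude shaping for 1/f noise (zero DC)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    return amp


def _pink_basis_stats(cfg: GeneratorConfig) -> tuple[float, float]:
    """(per-sample SD scale, window-functional SD) of unit-amplitude pink noise.

    The noise is a fixed linear map of complex white Gaussian coefficients, so
    both the average per-sample variance and the variance of the measured
    score (analysis-window mean minus baseline-window mean on one channel)
    are exact linear-algebra consequences of the synthesis filter.
    """
    n = n_samples(cfg)
    amp = _pink_spectrum(n, cfg.sfreq)
    k = amp.size
    b_re = np.fft.irfft(np.eye(k), n=n, axis=1)  # (k, n)
    b_im = np.fft.irfft(1j * np.eye(k), n=n, axis=1)
    var_t = (amp[:, None] ** 2 * (b_re**2 + b_im**2)).sum(axis=0)
    per_sample_var = float(var_t.mean())

    t = cfg.epoch[0] + np.arange(n) / cfg.sfreq
    win = (t >= CALIBRATION_WINDOW[0] - 1e-9) & (t < CALIBRATION_WINDOW[1] - 1e-9)
    base = (t >= cfg.epoch[0] - 1e-9) & (t < -1e-9)
    w = win.astype(float) / win.sum() - base.astype(float) / max(base.sum(), 1)
    score_var = float((amp**2 * ((b_re @ w) ** 2 + (b_im @ w) ** 2)).sum())
    return math.sqrt(per_sample_var), math.sqrt(score_var)


def pink_window_sd(cfg: GeneratorConfig) -> float:
    """SD contributed by pink noise to the measured per-trial ROI score.

    Channels carry independent noise; the ROI mean after average referencing
    has variance ``sigma_chan^2 * (1/n_roi - 1/n_channels)``.
    """
    if cfg.pink_noise_scale == 0:
        return 0.0
    per_sample_sd, score_sd_unit = _pink_basis_stats(cfg)
    scale = cfg.pink_noise_scale / per_sample_sd
    chan_sd = scale * score_sd_unit
    n_roi = len(cfg.roi_channels)
    shrink = max(1.0 / n_roi - 1.0 / cfg.n_channels, 0.0)
    return chan_sd * math.sqrt(shrink)


def n_samples(cfg: GeneratorConfig) -> int:
    return int(round((cfg.epoch[1] - cfg.epoch[0]) * cfg.sfreq))


# ---------------------------------------------------------------------------
# Condition mean model
# ---------------------------------------------------------------------------

def condition_amplitudes(cfg: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Population mean ROI-window amplitude (uV) for every design cell."""
    m = cfg.trials_per_cell
    sigma_m2 = cfg.subject_sd**2 + cfg.trial_noise_sd**2 / m
    delta_emo = calibrate_amplitude(cfg.emotion_dz, cfg.trial_noise_sd, cfg.subject_sd, m)

    amps = {}
    for val, instr in CELLS:
        a = BASELINE_AMPLITUDE
        if val != "neutral":
            a += delta_emo
        amps[(val, instr)] = a

    # instruction_dz targets the valence-POOLED per-subject contrast score
    # (the adjudication unit): pooling the two valences halves the cell-mean
    # variance, so the pooled load score 2*V - E - S has variance
    # 3 sigma_m^2 and the pooled reappraisal score E - S has sigma_m^2.
    if cfg.regime == "load":
        # Regulation reduces both instructed cells (both valences) by b;
        # the pooled load score then has mean 2b.
        b = cfg.instruction_dz * math.sqrt(3.0 * sigma_m2) / 2.0
        for val in ("pleasant", "unpleasant"):
            amps[(val, "enhance")] -= b
            amps[(val, "suppress")] -= b
    elif cfg.regime == "reappraisal":
        # Directional regulation: pooled E - S has mean delta, variance sigma_m^2.
        delta = cfg.instruction_dz * math.sqrt(sigma_m2)
        for val in ("pleasant", "unpleasant"):
            amps[(val, "enhance")] += delta / 2.0
            amps[(val, "suppress")] -= delta / 2.0
    return amps


def rating_shifts(cfg: GeneratorConfig) -> dict[str, float]:
    """Latent-scale instruction shifts for ratings (regime-independent)."""
    m = cfg.trials_per_cell
    var_mean = RATING_SUBJECT_SD**2 + RATING_TRIAL_SD**2 / m
    d_enh = cfg.rating_enhance_dz * math.sqrt(2.0 * var_mean)
    d_sup = cfg.rating_suppress_dz * math.sqrt(2.0 * var_mean)
    return {"view": 0.0, "enhance": d_enh, "suppress": -d_sup}


def _spatial_weights(cfg: GeneratorConfig) -> np.ndarray:
    """Zero-mean spatial profile with unit mean over the ROI channels.

    Zero channel mean makes the template invariant under average referencing;
    the ROI normalisation makes the amplitude parameter equal the measured
    ROI-window mean.
    """
    w = np.full(cfg.n_channels, NON_ROI_WEIGHT)
    roi_pos = np.asarray(cfg.roi_channels, dtype=int) - 1
    w[roi_pos] = 1.0
    w -= w.mean()
    return w / w[roi_pos].mean()


def _temporal_template(cfg: GeneratorConfig) -> np.ndarray:
    """Hann bump over TEMPLATE_SPAN, normalized to unit analysis-window mean."""
    t = cfg.epoch[0] + np.arange(n_samples(cfg)) / cfg.sfreq
    h = np.zeros_like(t)
    span = (t >= TEMPLATE_SPAN[0]) & (t <= TEMPLATE_SPAN[1])
    phase = (t[span] - TEMPLATE_SPAN[0]) / (TEMPLATE_SPAN[1] - TEMPLATE_SPAN[0])
    h[span] = 0.5 * (1.0 - np.cos(2.0 * math.pi * phase))
    win = (t >= CALIBRATION_WINDOW[0] - 1e-9) & (t < CALIBRATION_WINDOW[1] - 1e-9)
    return h / h[win].mean()


def _amplitude_jitter_sd(cfg: GeneratorConfig) -> float:
    """Trial amplitude jitter so total trial-level score SD equals trial_noise_sd."""
    sigma_pink = pink_window_sd(cfg)
    resid = cfg.trial_noise_sd**2 - sigma_pink**2
    if resid <= 0:
        raise CalibrationError(
            f"pink noise alone contributes {sigma_pink:.3f} uV to the trial score, "
            f"exceeding trial_noise_sd={cfg.trial_noise_sd}; increase trial_noise_sd "
            "or reduce pink_noise_scale"
        )
    return math.sqrt(resid)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class _SubjectPlan:
    """Frozen per-study constants shared by all subjects."""

    amps: dict[tuple[str, str], float]
    rshift: dict[str, float]
    weights: np.ndarray
    template: np.ndarray
    jitter_sd: float
    pink_scale: float


def _plan(cfg: GeneratorConfig) -> _SubjectPlan:
    per_sample_sd, _ = _pink_basis_stats(cfg) if cfg.pink_noise_scale else (1.0, 0.0)
    return _SubjectPlan(
        amps=condition_amplitudes(cfg),
        rshift=rating_shifts(cfg),
        weights=_spatial_weights(cfg),
        template=_temporal_template(cfg),
        jitter_sd=_amplitude_jitter_sd(cfg),
        pink_scale=(cfg.pink_noise_scale / per_sample_sd) if cfg.pink_noise_scale else 0.0,
    )


def _subject_id(i: int) -> str:
    return f"S{i + 1:03d}"


def simulate_subject(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_index: int,
    plan: _SubjectPlan | None = None,
) -> tuple[EpochSet, pd.DataFrame]:
    """One subject's epochs and trial rows (all second-presentation)."""
    plan = plan or _plan(cfg)
    m = cfg.trials_per_cell
    n_s = n_samples(cfg)
    n_trials = len(CELLS) * m

    intercept = rng.normal(0.0, SUBJECT_INTERCEPT_SD)
    cond_eff = {cell: rng.normal(0.0, cfg.subject_sd) for cell in CELLS}
    rate_eff = {cell: rng.normal(0.0, RATING_SUBJECT_SD) for cell in CELLS}

    data = np.zeros((n_trials, cfg.n_channels, n_s), dtype=np.float32)
    if plan.pink_scale:
        amp = _pink_spectrum(n_s, cfg.sfreq) * plan.pink_scale
        z = rng.normal(size=(n_trials, cfg.n_channels, amp.size)) + 1j * rng.normal(
            size=(n_trials, cfg.n_channels, amp.size)
        )
        data += np.fft.irfft(z * amp, n=n_s, axis=2).astype(np.float32)

    rows = []
    spatio_temporal = np.outer(plan.weights, plan.template).astype(np.float32)
    ti = 0
    for val, instr in CELLS:
        mu = plan.amps[(val, instr)] + intercept + cond_eff[(val, instr)]
        amps_trial = mu + rng.normal(0.0, plan.jitter_sd, size=m)
        latent_mu = RATING_BASE[val] + plan.rshift[instr] + rate_eff[(val, instr)]
        latents = latent_mu + rng.normal(0.0, RATING_TRIAL_SD, size=m)
        ratings = np.clip(np.rint(latents), 1, 7).astype(int)
        for k in range(m):
            data[ti] += amps_trial[k] * spatio_temporal
            rows.append(
                {
                    "subject_id": _subject_id(subject_index),
                    "trial_index": ti,
                    "valence": val,
                    "instruction": instr,
                    "presentation": "second",
                    "arousal": "none",
                    "rating": int(ratings[k]),
                }
            )
            ti += 1

    epochs = EpochSet(
        subject_id=_subject_id(subject_index),
        data=data,
        sfreq=cfg.sfreq,
        t0=cfg.epoch[0],
        channel_ids=np.arange(1, cfg.n_channels + 1),
    )
    return epochs, pd.DataFrame(rows)


def subject_rngs(cfg: GeneratorConfig) -> list[np.random.Generator]:
    """Per-subject independent RNG substreams derived from the master seed."""
    children = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.n_subjects)
    return [np.random.default_rng(c) for c in children]


def simulate_study(cfg: GeneratorConfig) -> tuple[list[EpochSet], pd.DataFrame]:
    """Full synthetic study: one EpochSet per subject plus the trial table.

    Fully reproducible from ``cfg.rng_seed``.  For large designs prefer
    :func:`iter_subjects`, which yields subjects one at a time.
    """
    epochs, tables = [], []
    for ep, tt in iter_subjects(cfg):
        epochs.append(ep)
        tables.append(tt)
    trials = validate_trial_table(pd.concat(tables, ignore_index=True))
    return epochs, trials


def iter_subjects(cfg: GeneratorConfig):
    """Yield ``(EpochSet, trial rows)`` per subject without holding the study in memory."""
    plan = _plan(cfg)
    for i, rng in enumerate(subject_rngs(cfg)):
        yield simulate_subject(cfg, rng, i, plan)


# ---------------------------------------------------------------------------
# Fast mean-level paths (no EEG synthesis)
# ---------------------------------------------------------------------------

def simulate_condition_means(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the subject x condition LPP mean table directly from the mean model.

    Statistically equivalent to simulating epochs and scoring them (the
    window-mean score is linear, so its distribution is exactly the mean
    model with variance ``subject_sd^2 + trial_noise_sd^2 / m``), but orders
    of magnitude faster.  Used for calibration studies and large replicate
    counts.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    amps = condition_amplitudes(cfg)
    m = cfg.trials_per_cell
    sd_mean = math.sqrt(cfg.subject_sd**2 + cfg.trial_noise_sd**2 / m)
    rows = []
    for i in range(cfg.n_subjects):
        intercept = rng.normal(0.0, SUBJECT_INTERCEPT_SD)
        for val, instr in CELLS:
            rows.append(
                {
                    "subject_id": _subject_id(i),
                    "valence": val,
                    "instruction": instr,
                    "lpp_uv": amps[(val, instr)] + intercept + rng.normal(0.0, sd_mean),
                    "n_trials": m,
                }
            )
    return pd.DataFrame(rows)


def simulate_rating_means(cfg: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Subject x condition mean-rating table from the latent rating model.

    Latent cell means are discretisation-free (the rounding noise of
    individual trials largely averages out in cell means); used by fast
    mean-level pipeline paths.
    """
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    shift = rating_shifts(cfg)
    m = cfg.trials_per_cell
    sd_mean = math.sqrt(RATING_SUBJECT_SD**2 + RATING_TRIAL_SD**2 / m)
    rows = []
    for i in range(cfg.n_subjects):
        for val, instr in CELLS:
            mu = RATING_BASE[val] + shift[instr] + rng.normal(0.0, sd_mean)
            rows.append(
                {
                    "subject_id": _subject_id(i),
                    "valence": val,
                    "instruction": instr,
                    "rating_mean": float(np.clip(mu, 1.0, 7.0)),
                    "n_trials": m,
                }
            )
    return pd.DataFrame(rows)
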