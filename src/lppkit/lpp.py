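"""LPP quantification and the minimal preprocessing stand-ins.

The published preprocessing chain (filter passbands, artifact criteria,
channel interpolation) lives in supplementary material that is not part of
this package's scope; the operations here are deliberately small, documented
stand-ins: baseline correction over a configurable pre-stimulus window,
average re-referencing, absolute-threshold artifact rejection, ROI/window
mean-amplitude scoring, and percentile winsorization of the subject-level
condition means.

All windows are half-open ``[start, end)`` on the epoch time axis so that
scores are invariant to sample rate and no sample is double-counted at the
window edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochSet, validate_means

logger = logging.getLogger(__name__)


def baseline_correct(epochs: EpochSet, window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over a pre-stimulus window."""
    if window[1] > 1e-9:
        raise ValueError(f"baseline window must end at or before stimulus onset, got {window}")
    mask = epochs.sample_mask(window)
    if not mask.any():
        raise ValueError(
            f"baseline window {window} contains no samples of epoch starting at t0={epochs.t0}"
        )
    if window[0] < epochs.t0 - 1e-9:
        raise ValueError(f"baseline window {window} starts before epoch t0={epochs.t0}")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base)


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across all channels."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference requires at least 2 channels")
    ref = epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=epochs.data - ref)


def reject_artifacts(
    epochs: EpochSet, abs_uv_threshold: float = 100.0
) -> tuple[EpochSet, pd.DataFrame]:
    """Drop trials containing any sample with ``|voltage|`` above threshold.

    Returns the cleaned EpochSet and a log with one row per rejected trial
    (subject, trial_index, worst channel label, peak absolute value).
    """
    if abs_uv_threshold <= 0:
        raise ValueError("threshold must be positive")
    absmax_per_chan = np.abs(epochs.data).max(axis=2)  # (trial, channel)
    absmax = absmax_per_chan.max(axis=1)
    bad = absmax > abs_uv_threshold
    rows = []
    for ti in np.flatnonzero(bad):
        ci = int(absmax_per_chan[ti].argmax())
        rows.append(
            {
                "subject_id": epochs.subject_id,
                "trial_index": int(epochs.trial_indices[ti]),
                "channel": int(epochs.channel_ids[ci]),
                "peak_uv": float(absmax_per_chan[ti, ci]),
            }
        )
    log = pd.DataFrame(rows, columns=["subject_id", "trial_index", "channel", "peak_uv"])
    keep = ~bad
    if not keep.any():
        logger.warning("subject %s: all trials rejected at %.1f uV", epochs.subject_id, abs_uv_threshold)
    cleaned = epochs.copy_with(data=epochs.data[keep], trial_indices=epochs.trial_indices[keep])
    return cleaned, log


def trial_window_means(
    epochs: EpochSet, roi: tuple[int, ...], window: tuple[float, float]
) -> pd.DataFrame:
    """Per-trial mean voltage over ROI channels and the half-open window."""
    pos = epochs.channel_positions(roi)
    mask = epochs.sample_mask(window)
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    t_end = epochs.t0 + epochs.n_samples / epochs.sfreq
    if window[0] < epochs.t0 - 1e-9 or window[1] > t_end + 1e-9:
        raise ValueError(f"window {window} outside epoch extent [{epochs.t0}, {t_end})")
    vals = epochs.data[:, pos][:, :, mask].mean(axis=(1, 2))
    return pd.DataFrame(
        {
            "subject_id": epochs.subject_id,
            "trial_index": epochs.trial_indices,
            "trial_uv": vals.astype(float),
        }
    )


def lpp_amplitude(
    epochs: EpochSet | list[EpochSet],
    trials: pd.DataFrame,
    roi: tuple[int, ...],
    window: tuple[float, float],
) -> pd.DataFrame:
    """Subject x valence x instruction mean LPP amplitude table.

    Per trial, the mean voltage over the ROI channels and over samples with
    ``window_start <= t < window_end``; then averaged over trials within each
    subject x valence x instruction cell.  Cells with no surviving trials are
    omitted (and logged); the trial table's design columns define the cells.
    """
    eps = [epochs] if isinstance(epochs, EpochSet) else list(epochs)
    per_trial = pd.concat([trial_window_means(ep, roi, window) for ep in eps], ignore_index=True)
    merged = per_trial.merge(
        trials[["subject_id", "trial_index", "valence", "instruction"]],
        on=["subject_id", "trial_index"],
        how="inner",
    )
    dropped = len(per_trial) - len(merged)
    if dropped:
        logger.info("%d epochs had no matching trial-table row and were ignored", dropped)
    out = (
        merged.groupby(["subject_id", "valence", "instruction"], observed=True)["trial_uv"]
        .agg(lpp_uv="mean", n_trials="size")
        .reset_index()
    )
    return validate_means(out)


def winsorize_values(values: np.ndarray, limits: tuple[float, float]) -> tuple[np.ndarray, int]:
    """Clip values to their [low, high] percentiles (linear interpolation).

    Returns the clipped array and the number of replaced values.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = np.percentile(values, limits)
    clipped = np.clip(values, lo, hi)
    return clipped, int((clipped != values).sum())


def winsorize_table(
    means: pd.DataFrame,
    limits: tuple[float, float] = (1.0, 99.0),
    scope: str = "condition",
) -> pd.DataFrame:
    """Winsorize subject-level condition means at percentile limits.

    With ``scope="condition"`` (default) percentiles are computed within each
    valence x instruction cell across subjects, so condition effects cannot
    masquerade as outliers; ``scope="pooled"`` uses a single pooled pair of
    bounds.  The number of replaced values is logged.
    """
    means = validate_means(means)
    if scope not in ("condition", "pooled"):
        raise ValueError("scope must be 'condition' or 'pooled'")
    out = means.copy()
    n_replaced = 0
    if scope == "pooled":
        clipped, n_replaced = winsorize_values(out["lpp_uv"].to_numpy(), limits)
        out["lpp_uv"] = clipped
    else:
        for _, idx in out.groupby(["valence", "instruction"], observed=True).groups.items():
            vals = out.loc[idx, "lpp_uv"].to_numpy()
            if len(vals) < 2 or np.ptp(vals) == 0:
                logger.info("winsorize: degenerate condition left unchanged")
                continue
            clipped, k = winsorize_values(vals, limits)
            out.loc[idx, "lpp_uv"] = clipped
            n_replaced += k
    logger.info("winsorize_table replaced %d values at limits %s", n_replaced, limits)
    out.attrs["winsorized_n_replaced"] = n_replaced
    return out
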