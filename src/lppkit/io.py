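"""On-disk dialects: HDF5 epoch containers, TSV trial tables, JSON results.

The epoch container stores one HDF5 group per subject (``/sub-<id>/data`` with
attributes ``sfreq``, ``t0``, ``channels`` and a ``trial_indices`` dataset).
Trial tables are TSV with a fixed header; missing ratings are encoded ``NA``.
Every read path validates the container invariants; there is no silent
coercion.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

VALENCES = ("pleasant", "unpleasant", "neutral")
INSTRUCTIONS = ("view", "enhance", "suppress")
PRESENTATIONS = ("first", "second")
AROUSALS = ("high", "low", "none")

TRIAL_TABLE_COLUMNS = [
    "subject_id",
    "trial_index",
    "valence",
    "instruction",
    "presentation",
    "arousal",
    "rating",
]

MEANS_COLUMNS = ["subject_id", "valence", "instruction", "lpp_uv", "n_trials"]


class ValidationError(ValueError):
    """A container or table violates a documented invariant."""

    def __init__(self, violations: Sequence[str] | str):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass
class EpochSet:
    """Per-subject epoched voltage data.

    ``data`` is ``(trial, channel, sample)`` in microvolts; ``t0`` is the
    epoch start relative to stimulus onset in seconds (negative means
    pre-stimulus); ``channel_ids`` are 1-based montage labels in storage
    order; ``trial_indices`` aligns the trial axis with a trial table's
    ``trial_index`` column.
    """

    subject_id: str
    data: np.ndarray
    sfreq: float
    t0: float
    channel_ids: np.ndarray
    trial_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.trial_indices is None:
            self.trial_indices = np.arange(self.data.shape[0])
        self.trial_indices = np.asarray(self.trial_indices, dtype=int)
        self.validate()

    # -- derived geometry ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (stimulus onset at 0)."""
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def sample_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean sample mask for a half-open ``[start, end)`` window."""
        t = self.times
        return (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)

    def channel_positions(self, labels: Iterable[int]) -> np.ndarray:
        """Array positions of 1-based channel labels; errors name the label."""
        lut = {int(c): i for i, c in enumerate(self.channel_ids)}
        pos = []
        for lab in labels:
            if int(lab) not in lut:
                raise ValidationError(f"channel label {int(lab)} not present for subject {self.subject_id}")
            pos.append(lut[int(lab)])
        return np.asarray(pos, dtype=int)

    def validate(self) -> None:
        violations = []
        if self.data.ndim != 3:
            violations.append(f"data must be 3-D (trial, channel, sample), got ndim={self.data.ndim}")
        else:
            if self.data.shape[1] != len(self.channel_ids):
                violations.append(
                    f"data has {self.data.shape[1]} channels but channel_ids lists {len(self.channel_ids)}"
                )
            if len(self.trial_indices) != self.data.shape[0]:
                violations.append("trial_indices length does not match trial axis")
            if self.data.size and not np.all(np.isfinite(self.data)):
                violations.append("non-finite voltage values present")
        if self.sfreq <= 0:
            violations.append(f"sfreq must be positive, got {self.sfreq}")
        elif self.data.ndim == 3:
            t_end = self.t0 + self.data.shape[2] / self.sfreq
            if self.t0 > 0 or t_end < 0.8:
                violations.append(
                    f"epoch [{self.t0:.3f}, {t_end:.3f}) must cover 0-0.8 s post-onset"
                )
        if len(np.unique(self.channel_ids)) != len(self.channel_ids):
            violations.append("channel_ids must be unique")
        if violations:
            raise ValidationError(violations)

    def copy_with(self, **kwargs) -> "EpochSet":
        out = dataclasses.replace(self, **kwargs)
        return out


# ---------------------------------------------------------------------------
# HDF5 epoch container
# ---------------------------------------------------------------------------

def write_epochs(epochs: Iterable[EpochSet], path: str | Path) -> None:
    """Write EpochSets to an HDF5 container, one group per subject."""
    epochs = list(epochs)
    with h5py.File(path, "w") as f:
        f.attrs["dialect"] = "lppkit-epochs-v1"
        for ep in epochs:
            g = f.create_group(f"sub-{ep.subject_id}")
            g.create_dataset("data", data=ep.data)
            g.create_dataset("trial_indices", data=ep.trial_indices)
            g.attrs["sfreq"] = float(ep.sfreq)
            g.attrs["t0"] = float(ep.t0)
            g.attrs["channels"] = np.asarray(ep.channel_ids, dtype=int)


def read_epochs(path: str | Path, subjects: Sequence[str] | None = None) -> list[EpochSet]:
    """Read an HDF5 epoch container back into a list of EpochSets.

    Raises :class:`IOError` for missing/corrupt files naming the offending
    field and :class:`ValidationError` when invariants fail.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"epoch container not found: {path}")
    out: list[EpochSet] = []
    try:
        f = h5py.File(path, "r")
    except OSError as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"cannot open epoch container {path}: {exc}") from exc
    with f:
        names = [k for k in f.keys() if k.startswith("sub-")]
        if subjects is not None:
            wanted = {f"sub-{s}" for s in subjects}
            missing = wanted - set(names)
            if missing:
                raise IOError(f"subjects missing from container: {sorted(missing)}")
            names = [n for n in names if n in wanted]
        for name in sorted(names):
            g = f[name]
            for attr in ("sfreq", "t0", "channels"):
                if attr not in g.attrs:
                    raise IOError(f"group {name} missing attribute '{attr}'")
            if "data" not in g:
                raise IOError(f"group {name} missing dataset 'data'")
            trial_indices = g["trial_indices"][()] if "trial_indices" in g else None
            out.append(
                EpochSet(
                    subject_id=name[len("sub-"):],
                    data=g["data"][()],
                    sfreq=float(g.attrs["sfreq"]),
                    t0=float(g.attrs["t0"]),
                    channel_ids=np.asarray(g.attrs["channels"], dtype=int),
                    trial_indices=trial_indices,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def validate_trial_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and type a trial table; returns a typed copy."""
    violations = []
    missing_cols = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError([f"missing columns: {missing_cols}"])
    df = df.loc[:, TRIAL_TABLE_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["trial_index"] = df["trial_index"].astype(int)
    for col, allowed in (
        ("valence", VALENCES),
        ("instruction", INSTRUCTIONS),
        ("presentation", PRESENTATIONS),
        ("arousal", AROUSALS),
    ):
        bad = set(df[col].unique()) - set(allowed)
        if bad:
            violations.append(f"invalid {col} values: {sorted(bad)}")
    df["rating"] = pd.to_numeric(df["rating"], errors="coerce").astype("Int64")

    if not violations:
        neutral_bad = df[(df["valence"] == "neutral") & (df["instruction"] != "view")]
        if len(neutral_bad):
            violations.append(
                "neutral trials must have instruction 'view' (neutral pictures appear "
                f"only under passive viewing); {len(neutral_bad)} offending rows"
            )
        rated = df["rating"].notna()
        out_of_range = df[rated & ~df["rating"].between(1, 7)]
        if len(out_of_range):
            violations.append(f"ratings outside 1-7 in {len(out_of_range)} rows")
        first_rated = df[(df["presentation"] == "first") & rated]
        if len(first_rated):
            violations.append(
                f"ratings present on {len(first_rated)} first-presentation rows "
                "(ratings are collected only after the second presentation)"
            )
        dup = df.duplicated(subset=["subject_id", "trial_index"])
        if dup.any():
            violations.append(f"duplicate (subject_id, trial_index) pairs: {int(dup.sum())}")
    if violations:
        raise ValidationError(violations)
    return df


def read_trial_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"trial table not found: {path}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    return validate_trial_table(df)


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    df = validate_trial_table(df)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Condition-mean tables and JSON results
# ---------------------------------------------------------------------------

def validate_means(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEANS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"means table missing columns: {missing}"])
    df = df.loc[:, MEANS_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if not np.all(np.isfinite(df["lpp_uv"].to_numpy(dtype=float))):
        raise ValidationError(["non-finite lpp_uv values"])
    dup = df.duplicated(subset=["subject_id", "valence", "instruction"])
    if dup.any():
        raise ValidationError([f"duplicate subject x condition rows: {int(dup.sum())}"])
    return df


def read_means(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError(f"means table not found: {path}")
    return validate_means(pd.read_csv(path, sep="\t", float_precision="round_trip"))


def write_means(df: pd.DataFrame, path: str | Path) -> None:
    validate_means(df).to_csv(path, sep="\t", index=False)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_json(obj, path: str | Path) -> None:
    """Serialize a (possibly nested, dataclass-bearing) result atomically."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")
    tmp.replace(path)
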