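"""Reading, trimming and quality-gating overnight SpO2 recordings.

The canonical in-memory object is :class:`OximetryRecording`: a uniformly
sampled SpO2 series (percent) with a per-sample validity mask and a half-open
sleep window ``[sleep_onset_index, sleep_offset_index)``.  All downstream
index computation operates on valid samples inside the sleep window only.

Supported on-disk formats:

* CSV — columns ``t_s`` (seconds from recording start), ``spo2`` (percent),
  optional ``quality`` (1 = usable, 0 = artifact).  Column names are
  remappable via ``column_spec``.
* EDF — first channel whose label contains ``"SpO2"`` (case-insensitive),
  read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OximetryRecording",
    "QualityReport",
    "FormatError",
    "SchemaError",
    "ValidationError",
    "read_recording",
    "write_recording",
    "trim_to_sleep",
    "quality_check",
]


class FormatError(ValueError):
    """Raised for files that parse but violate the expected structure."""


class SchemaError(ValueError):
    """Raised when a required column/channel is absent."""


class ValidationError(ValueError):
    """Raised for semantically invalid recordings or windows."""


@dataclass
class OximetryRecording:
    """A cleaned overnight SpO2 time series.

    Parameters
    ----------
    spo2 : array of float
        SpO2 in percent.  Samples flagged invalid may hold NaN.
    valid_mask : array of bool
        True where the sample is usable signal.
    sample_interval_s : float
        Seconds per sample (device resolution; 4 s for typical wrist units).
    sleep_onset_index, sleep_offset_index : int
        Half-open window of analyzed sleep, in sample indices.
    subject_id : str
        Opaque label.
    visit : str
        One of ``pre``, ``post``, ``unknown``.
    """

    spo2: np.ndarray
    valid_mask: np.ndarray
    sample_interval_s: float = 4.0
    sleep_onset_index: int = 0
    sleep_offset_index: int | None = None
    subject_id: str = ""
    visit: str = "unknown"

    def __post_init__(self) -> None:
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.sleep_offset_index is None:
            self.sleep_offset_index = len(self.spo2)
        if self.spo2.ndim != 1:
            raise ValidationError("spo2 must be one-dimensional")
        if len(self.valid_mask) != len(self.spo2):
            raise ValidationError("valid_mask and spo2 lengths differ")
        if self.sample_interval_s <= 0:
            raise ValidationError("sample_interval_s must be positive")
        if not (0 <= self.sleep_onset_index < self.sleep_offset_index <= len(self.spo2)):
            raise ValidationError(
                "sleep window must satisfy 0 <= onset < offset <= n_samples"
            )
        if self.visit not in ("pre", "post", "unknown"):
            raise ValidationError(f"unknown visit label: {self.visit!r}")
        finite = self.spo2[self.valid_mask]
        if finite.size and (np.any(~np.isfinite(finite)) or finite.min() < 0 or finite.max() > 100):
            raise ValidationError("valid samples must be finite and within [0, 100]%")

    # -- derived views -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.spo2)

    @property
    def duration_s(self) -> float:
        """Total recording span in seconds."""
        return self.n_samples * self.sample_interval_s

    @property
    def sleep_slice(self) -> slice:
        return slice(self.sleep_onset_index, self.sleep_offset_index)

    @property
    def sleep_duration_h(self) -> float:
        """Length of the sleep window in hours (valid and invalid samples)."""
        n = self.sleep_offset_index - self.sleep_onset_index
        return n * self.sample_interval_s / 3600.0

    @property
    def valid_sleep_hours(self) -> float:
        """Hours of *usable* signal in the sleep window (ODI denominator)."""
        n = int(self.valid_mask[self.sleep_slice].sum())
        return n * self.sample_interval_s / 3600.0

    def sleep_values(self) -> np.ndarray:
        """Valid SpO2 values inside the sleep window, in temporal order."""
        window = self.sleep_slice
        return self.spo2[window][self.valid_mask[window]]

    def replace(self, **changes) -> "OximetryRecording":
        return dataclasses.replace(self, **changes)


@dataclass
class QualityReport:
    """Outcome of the recording quality gate."""

    duration_h: float
    artifact_pct: float
    passes: bool
    reasons: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"time": "t_s", "spo2": "spo2", "quality": "quality"}


def read_recording(
    path: str | Path,
    format: str = "csv",
    column_spec: Mapping[str, str] | None = None,
    sample_interval_s: float | None = None,
    max_jump_pct: float | None = 4.0,
    timestamp_rtol: float = 1e-3,
    subject_id: str = "",
    visit: str = "unknown",
) -> OximetryRecording:
    """Read a recording from CSV or EDF.

    Out-of-range (outside [0, 100]%) or missing SpO2 samples are flagged
    invalid; values are never silently altered.  When the file carries no
    explicit quality column, single-sample spikes whose step exceeds
    ``max_jump_pct`` percent per sample are additionally flagged as
    physiologically implausible (set ``max_jump_pct=None`` to disable).

    Raises
    ------
    FileNotFoundError, SchemaError, FormatError
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(
            path, column_spec, sample_interval_s, max_jump_pct, timestamp_rtol,
            subject_id, visit,
        )
    if format == "edf":
        return _read_edf(path, sample_interval_s, max_jump_pct, subject_id, visit)
    raise ValueError(f"unsupported format: {format!r}")


def _read_csv(path, column_spec, sample_interval_s, max_jump_pct, timestamp_rtol,
              subject_id, visit):
    cols = dict(_DEFAULT_COLUMNS)
    if column_spec:
        cols.update(column_spec)
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as I/O failure
        raise FormatError(f"could not parse {path}: {exc}") from exc

    if cols["spo2"] not in df.columns:
        raise SchemaError(f"{path}: missing SpO2 column {cols['spo2']!r}")

    spo2 = pd.to_numeric(df[cols["spo2"]], errors="coerce").to_numpy(dtype=float)
    n = len(spo2)
    if n == 0:
        raise FormatError(f"{path}: no data rows")

    # sampling interval: from timestamps if present, else must be supplied
    if cols["time"] in df.columns:
        t = pd.to_numeric(df[cols["time"]], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            bad = int(np.flatnonzero(~np.isfinite(t))[0])
            raise FormatError(f"{path}: non-numeric timestamp at data row {bad}")
        if n > 1:
            dt = np.diff(t)
            dt0 = float(np.median(dt))
            if dt0 <= 0:
                raise FormatError(f"{path}: non-increasing timestamps")
            off = np.abs(dt - dt0) > timestamp_rtol * dt0
            if np.any(off):
                bad = int(np.flatnonzero(off)[0]) + 1
                raise FormatError(
                    f"{path}: non-uniform sampling at data row {bad} "
                    f"(dt={dt[bad - 1]:g}s, expected {dt0:g}s)"
                )
            interval = dt0
        else:
            if sample_interval_s is None:
                raise FormatError(f"{path}: single row; supply sample_interval_s")
            interval = sample_interval_s
    elif sample_interval_s is not None:
        interval = sample_interval_s
    else:
        raise SchemaError(
            f"{path}: no time column {cols['time']!r} and no sample_interval_s given"
        )

    valid = np.isfinite(spo2) & (spo2 >= 0) & (spo2 <= 100)
    if cols["quality"] in df.columns:
        q = pd.to_numeric(df[cols["quality"]], errors="coerce").to_numpy(dtype=float)
        valid &= q == 1
    elif max_jump_pct is not None:
        valid &= ~_spike_mask(spo2, valid, max_jump_pct)

    spo2 = np.where(valid, spo2, np.nan)
    return OximetryRecording(
        spo2=spo2, valid_mask=valid, sample_interval_s=float(interval),
        subject_id=subject_id or path.stem, visit=visit,
    )


def _spike_mask(spo2: np.ndarray, valid: np.ndarray, max_jump: float) -> np.ndarray:
    """Isolated single-sample spikes: a > max_jump step in and back out."""
    n = len(spo2)
    spike = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        if not (valid[i - 1] and valid[i] and valid[i + 1]):
            continue
        if (abs(spo2[i] - spo2[i - 1]) > max_jump
                and abs(spo2[i + 1] - spo2[i - 1]) <= max_jump):
            spike[i] = True
    return spike


def _read_edf(path, sample_interval_s, max_jump_pct, subject_id, visit):
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional dependency mne "
            "(pip install noxtk[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = [ch for ch in raw.ch_names if "spo2" in ch.lower()]
    if not labels:
        raise SchemaError(f"{path}: no channel label containing 'SpO2'")
    data = raw.get_data(picks=[labels[0]])[0]
    interval = sample_interval_s or 1.0 / raw.info["sfreq"]
    spo2 = np.asarray(data, dtype=float)
    valid = np.isfinite(spo2) & (spo2 >= 0) & (spo2 <= 100)
    if max_jump_pct is not None:
        valid &= ~_spike_mask(spo2, valid, max_jump_pct)
    spo2 = np.where(valid, spo2, np.nan)
    return OximetryRecording(
        spo2=spo2, valid_mask=valid, sample_interval_s=float(interval),
        subject_id=subject_id or Path(path).stem, visit=visit,
    )


def write_recording(rec: OximetryRecording, path: str | Path) -> Path:
    """Write a recording in the CSV dialect read_recording understands.

    Round-trips SpO2 values and the validity mask exactly (invalid samples
    are written with an empty SpO2 field and quality 0).
    """
    path = Path(path)
    t = np.arange(rec.n_samples) * rec.sample_interval_s
    df = pd.DataFrame(
        {
            "t_s": t,
            "spo2": np.where(rec.valid_mask, rec.spo2, np.nan),
            "quality": rec.valid_mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Trimming and quality gate
# ---------------------------------------------------------------------------

def trim_to_sleep(rec: OximetryRecording, onset_s: float, offset_s: float) -> OximetryRecording:
    """Restrict analysis to the half-open time window ``[onset_s, offset_s)``.

    Awake segments at the edges of overnight recordings are excluded this
    way; the samples stay in place, only the window indices move.
    """
    if not (0 <= onset_s < offset_s <= rec.duration_s + 1e-9):
        raise ValidationError(
            f"sleep window [{onset_s}, {offset_s}) outside recording span "
            f"[0, {rec.duration_s}) or inverted"
        )
    dt = rec.sample_interval_s
    onset_idx = math.ceil(onset_s / dt - 1e-9)
    offset_idx = math.ceil(offset_s / dt - 1e-9)
    if onset_idx >= offset_idx:
        raise ValidationError("sleep window contains no samples")
    return rec.replace(sleep_onset_index=onset_idx, sleep_offset_index=offset_idx)


def quality_check(
    rec: OximetryRecording,
    min_duration_h: float = 6.0,
    max_artifact_pct: float = 2.5,
) -> QualityReport:
    """Apply the standard overnight-oximetry quality gate.

    A recording passes when the analyzed sleep window lasts at least
    ``min_duration_h`` hours and at most ``max_artifact_pct`` percent of its
    samples are flagged invalid.  The artifact percentage depends only on the
    mask, never on the signal values.
    """
    window = rec.sleep_slice
    n = window.stop - window.start
    if n <= 0:
        raise ValidationError("empty sleep window")
    n_invalid = int((~rec.valid_mask[window]).sum())
    artifact_pct = 100.0 * n_invalid / n
    duration_h = rec.sleep_duration_h
    reasons = []
    if duration_h < min_duration_h:
        reasons.append("duration")
    if artifact_pct > max_artifact_pct:
        reasons.append("artifact")
    return QualityReport(
        duration_h=duration_h,
        artifact_pct=artifact_pct,
        passes=not reasons,
        reasons=reasons,
    )
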