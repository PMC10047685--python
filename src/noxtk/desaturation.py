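"""Desaturation event detection, ODI, clusters and the McGill oximetry score.

A desaturation event is a maximal run of valid samples whose SpO2 sits at or
below ``baseline - threshold`` and that lasts at least ``min_duration_s``
(>=3% drop for ODI3, >=4% for ODI4, >=10 s in the standard definitions).
The baseline is a trailing rolling maximum (or percentile) of the valid
signal: pulse-oximetry software reports drops "from baseline" without
defining it, so the construction here is this package's documented
convention (see docs/methods.md).

ODI is events per hour of valid analyzed sleep.  A desaturation cluster is
>=5 events within a 10-30 min span; the four-level McGill oximetry score
(MOS) combines the cluster count with how many event nadirs fall below
90/85/80% SpO2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OximetryRecording, ValidationError

__all__ = [
    "BaselineConfig",
    "DesaturationEvent",
    "DesaturationCluster",
    "MosResult",
    "track_baseline",
    "detect_desaturations",
    "compute_odi",
    "detect_clusters",
    "assign_mos",
    "events_to_frame",
    "clusters_to_frame",
]


@dataclass
class BaselineConfig:
    """How the per-sample reference saturation is tracked.

    ``rolling_max`` takes the maximum of valid SpO2 over the trailing
    ``window_s`` seconds (default 120 s — long enough to bridge ordinary
    desaturation events, short enough to follow slow drifts);
    ``rolling_percentile`` substitutes the given upper percentile, which is
    more robust to single-sample positive spikes.
    """

    method: str = "rolling_max"
    window_s: float = 120.0
    percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.method not in ("rolling_max", "rolling_percentile"):
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.window_s < 30:
            raise ValueError("window_s must be >= 30 s")
        if not (50 < self.percentile <= 100):
            raise ValueError("percentile must be in (50, 100]")


@dataclass(frozen=True)
class DesaturationEvent:
    """One detected SpO2 dip (half-open sample interval)."""

    start_index: int
    end_index: int
    baseline_spo2: float
    nadir_spo2: float
    depth: float
    duration_s: float

    def start_s(self, sample_interval_s: float = 4.0) -> float:
        return self.start_index * sample_interval_s

    def end_s(self, sample_interval_s: float = 4.0) -> float:
        return self.end_index * sample_interval_s


@dataclass(frozen=True)
class DesaturationCluster:
    """A burst of >=min_events desaturations within the cluster window."""

    start_index: int
    end_index: int
    event_count: int
    window_duration_s: float


@dataclass
class MosResult:
    """McGill oximetry score with the counts that determined it."""

    score: int
    n_clusters: int
    n_below_90: int
    n_below_85: int
    n_below_80: int


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def track_baseline(rec: OximetryRecording, cfg: BaselineConfig | None = None) -> np.ndarray:
    """Per-sample baseline SpO2 (percent), aligned with the recording.

    baseline[i] summarises the valid signal over the trailing window ending
    at (and including) sample i.  Samples with no valid data in their window
    inherit the last defined baseline (leading gaps take the first defined
    value), so the baseline is defined wherever any valid sample exists.
    """
    cfg = cfg or BaselineConfig()
    if not rec.valid_mask.any():
        raise ValidationError("cannot track a baseline: all samples invalid")
    w = max(1, int(round(cfg.window_s / rec.sample_interval_s)))
    s = pd.Series(np.where(rec.valid_mask, rec.spo2, np.nan))
    roll = s.rolling(window=w, min_periods=1)
    if cfg.method == "rolling_max":
        base = roll.max()
    else:
        base = roll.quantile(cfg.percentile / 100.0)
    base = base.ffill().bfill().to_numpy(dtype=float)
    return np.clip(base, 0.0, 100.0)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_desaturations(
    rec: OximetryRecording,
    baseline: np.ndarray,
    drop_threshold_pct: float,
    min_duration_s: float = 10.0,
    max_gap_s: float = 30.0,
) -> list[DesaturationEvent]:
    """Find desaturation events inside the sleep window.

    An event is a maximal run of valid samples with
    ``spo2 <= baseline - drop_threshold_pct``.  Invalid samples interrupt a
    run only when the gap exceeds ``max_gap_s``; shorter artifact gaps are
    bridged so that one physiological dip is not split by a dropped sample.
    Runs spanning fewer than ``ceil(min_duration_s / sample_interval_s)``
    samples are discarded (at 4 s sampling the standard 10 s minimum means
    3 samples, i.e. 12 s).  Events are returned ordered and non-overlapping.
    """
    if drop_threshold_pct <= 0:
        raise ValueError("drop_threshold_pct must be positive")
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != rec.spo2.shape:
        raise ValueError(
            f"baseline length {baseline.shape} does not match recording "
            f"{rec.spo2.shape}"
        )
    dt = rec.sample_interval_s
    min_samples = math.ceil(min_duration_s / dt - 1e-9)
    max_gap = int(max_gap_s / dt + 1e-9)

    lo, hi = rec.sleep_onset_index, rec.sleep_offset_index
    valid = rec.valid_mask
    below = np.zeros(rec.n_samples, dtype=bool)
    below[lo:hi] = valid[lo:hi] & (rec.spo2[lo:hi] <= baseline[lo:hi] - drop_threshold_pct)

    events: list[DesaturationEvent] = []
    i = lo
    while i < hi:
        if not below[i]:
            i += 1
            continue
        # extend the run, bridging invalid gaps of at most max_gap samples
        start = i
        last_below = i
        j = i + 1
        gap = 0
        while j < hi:
            if below[j]:
                last_below = j
                gap = 0
            elif not valid[j]:
                gap += 1
                if gap > max_gap:
                    break
            else:  # valid sample above threshold ends the run
                break
            j += 1
        end = last_below + 1
        if end - start >= min_samples:
            seg = rec.spo2[start:end]
            seg_valid = valid[start:end]
            nadir = float(np.min(seg[seg_valid]))
            base0 = float(baseline[start])
            events.append(
                DesaturationEvent(
                    start_index=start,
                    end_index=end,
                    baseline_spo2=base0,
                    nadir_spo2=nadir,
                    depth=base0 - nadir,
                    duration_s=(end - start) * dt,
                )
            )
        i = end if end > i else i + 1
        if j >= hi:
            break
        i = max(i, j)
    return events


def compute_odi(events: list[DesaturationEvent], analyzed_hours: float) -> float:
    """Oxygen desaturation index: qualifying events per analyzed hour."""
    if analyzed_hours <= 0:
        raise ValueError("analyzed_hours must be positive")
    return len(events) / analyzed_hours


# ---------------------------------------------------------------------------
# Clusters and McGill score
# ---------------------------------------------------------------------------

def detect_clusters(
    events: list[DesaturationEvent],
    rec: OximetryRecording,
    min_events: int = 5,
    window_min_s: float = 600.0,
    window_max_s: float = 1800.0,
) -> list[DesaturationCluster]:
    """Greedy left-to-right grouping of events into desaturation clusters.

    Scanning events in order, each maximal group of consecutive events whose
    span (first start to last end) fits within ``window_max_s`` and that
    contains at least ``min_events`` events becomes one cluster; every event
    belongs to at most one cluster.  Bursts tighter than ``window_min_s``
    still count (a denser cluster is not less pathological); their reported
    window duration is clamped up to ``window_min_s``.
    """
    dt = rec.sample_interval_s
    clusters: list[DesaturationCluster] = []
    i = 0
    n = len(events)
    while i < n:
        j = i
        while (
            j + 1 < n
            and (events[j + 1].end_index - events[i].start_index) * dt <= window_max_s
        ):
            j += 1
        count = j - i + 1
        if count >= min_events:
            span = (events[j].end_index - events[i].start_index) * dt
            clusters.append(
                DesaturationCluster(
                    start_index=events[i].start_index,
                    end_index=events[j].end_index,
                    event_count=count,
                    window_duration_s=max(span, window_min_s),
                )
            )
            i = j + 1
        else:
            i += 1
    return clusters


def assign_mos(
    events4: list[DesaturationEvent],
    clusters: list[DesaturationCluster],
) -> MosResult:
    """Assign the McGill oximetry score from 4%-threshold desaturations.

    Score 1 (inconclusive): fewer than 3 clusters, or nadir pattern matching
    no higher category.  Score 2 (mild): >=3 clusters with >=3 event nadirs
    below 90% and none below 85%.  Score 3 (moderate): >=3 clusters with >=3
    nadirs below 85% and none below 80%.  Score 4 (severe): >=3 clusters
    with >=3 nadirs below 80%.  Nadir comparisons are strict; counts are
    taken over the whole record, not only inside clusters.
    """
    nadirs = np.array([e.nadir_spo2 for e in events4], dtype=float)
    n90 = int((nadirs < 90.0).sum())
    n85 = int((nadirs < 85.0).sum())
    n80 = int((nadirs < 80.0).sum())
    nc = len(clusters)
    if nc >= 3 and n80 >= 3:
        score = 4
    elif nc >= 3 and n85 >= 3 and n80 == 0:
        score = 3
    elif nc >= 3 and n90 >= 3 and n85 == 0:
        score = 2
    else:
        score = 1
    return MosResult(score=score, n_clusters=nc,
                     n_below_90=n90, n_below_85=n85, n_below_80=n80)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def events_to_frame(events: list[DesaturationEvent], sample_interval_s: float = 4.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [e.start_index * sample_interval_s for e in events],
            "end_s": [e.end_index * sample_interval_s for e in events],
            "baseline": [e.baseline_spo2 for e in events],
            "nadir": [e.nadir_spo2 for e in events],
            "depth": [e.depth for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    )


def clusters_to_frame(clusters: list[DesaturationCluster], sample_interval_s: float = 4.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [c.start_index * sample_interval_s for c in clusters],
            "end_s": [c.end_index * sample_interval_s for c in clusters],
            "n_events": [c.event_count for c in clusters],
        }
    )
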