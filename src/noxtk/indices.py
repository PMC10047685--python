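"""Per-recording summary indices: mean/SD SpO2, CSA, and SpO2 sample entropy.

Cumulative saturation area (CSA)
    Bin the valid sleep-window SpO2 values into 1%-wide bins anchored at
    integers (value v falls in bin floor(v)).  With F(s) the cumulative
    relative frequency, in percent, of samples in bins <= s, the CSA is the
    rectangle-rule area under the ascending cumulative-frequency line,

        CSA = sum_{s = s_min}^{100} F(s),

    where s_min is the lowest occupied bin.  The index is dimensionless,
    equals exactly 100 when every sample is 100%, and grows as probability
    mass moves to lower saturations (lower mean and/or larger spread).

SpO2 sample entropy (SSE)
    SampEn(m, r) of the valid sleep-window series: with B the number of
    ordered template pairs (i != j) of length m whose Chebyshev distance is
    <= r and A the same count at length m+1 (self-matches excluded),
    SSE = -ln(A/B).  Regular traces score low; traces with frequent
    desaturations score high.  Tolerance r defaults to 0.2 x SD of the
    series, the convention of the standard reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .desaturation import (
    BaselineConfig,
    assign_mos,
    compute_odi,
    detect_clusters,
    detect_desaturations,
    track_baseline,
)
from .io import OximetryRecording, ValidationError, quality_check

__all__ = [
    "SseParams",
    "SampEnResult",
    "NoxSummary",
    "AnalysisConfig",
    "compute_csa",
    "sample_entropy",
    "compute_sse",
    "summarize",
]


@dataclass
class SseParams:
    """Sample-entropy parameters.

    m is the embedding (template) length; the tolerance is
    ``max(r_factor * SD(series), r_floor)`` in percent SpO2.  A nonzero
    ``r_floor`` guards against vanishing tolerance on near-constant signals.
    """

    m: int = 2
    r_factor: float = 0.2
    r_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.r_floor < 0:
            raise ValueError("r_floor must be >= 0")


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value with its match counts.

    ``upper_bounded`` is set when no template pair matched at length m+1
    (A = 0) or even at length m (B = 0); the value is then the finite bound
    -ln(1/(B+1)) rather than infinity, keeping downstream ROC analysis
    well-defined.
    """

    value: float
    a_count: int
    b_count: int
    upper_bounded: bool = False

    def __float__(self) -> float:
        return self.value


# ---------------------------------------------------------------------------
# CSA
# ---------------------------------------------------------------------------

def compute_csa(rec: OximetryRecording, bin_width_pct: float = 1.0) -> float:
    """Cumulative saturation area of the valid sleep-window SpO2 values."""
    if bin_width_pct <= 0:
        raise ValueError("bin_width_pct must be positive")
    values = rec.sleep_values()
    if values.size == 0:
        raise ValidationError("no valid samples in the sleep window")
    w = bin_width_pct
    k = np.floor(values / w + 1e-12).astype(np.int64)
    k_min = int(k.min())
    k_top = int(np.floor(100.0 / w + 1e-12))
    counts = np.bincount(k - k_min, minlength=k_top - k_min + 1)
    cum_freq_pct = 100.0 * np.cumsum(counts) / values.size
    return float(cum_freq_pct.sum())


# ---------------------------------------------------------------------------
# Sample entropy
# ---------------------------------------------------------------------------

def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> SampEnResult:
    """SampEn(m, r) of a 1-D series, vectorized, self-matches excluded.

    Both A (length m+1) and B (length m) count ordered pairs over the same
    n - m template start positions, the convention of the reference
    implementation, so the ratio A/B is a bona fide conditional probability.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValidationError(f"series of length {n} too short for m={m}")
    if r < 0:
        raise ValueError("tolerance r must be >= 0")

    nt = n - m  # number of templates
    # Chebyshev-match matrix built by ANDing lag-shifted scalar matches;
    # chunk the scalar comparison to bound peak memory on long recordings.
    close = _pairwise_close(x, r)
    match = close[:nt, :nt].copy()
    for k in range(1, m):
        match &= close[k : k + nt, k : k + nt]
    b_count = int(match.sum()) - nt  # drop the diagonal (self-matches)
    match &= close[m : m + nt, m : m + nt]
    a_count = int(match.sum()) - nt
    if a_count <= 0 or b_count <= 0:
        a_count = max(a_count, 0)
        b_count = max(b_count, 0)
        return SampEnResult(
            value=float(np.log(b_count + 1)),  # -ln(1/(B+1))
            a_count=a_count,
            b_count=b_count,
            upper_bounded=True,
        )
    return SampEnResult(
        value=float(-np.log(a_count / b_count)),
        a_count=a_count,
        b_count=b_count,
    )


def _pairwise_close(x: np.ndarray, r: float, chunk: int = 1024) -> np.ndarray:
    n = len(x)
    out = np.empty((n, n), dtype=bool)
    for i0 in range(0, n, chunk):
        i1 = min(i0 + chunk, n)
        np.less_equal(
            np.abs(x[i0:i1, None] - x[None, :]), r, out=out[i0:i1]
        )
    return out


def compute_sse(rec: OximetryRecording, params: SseParams | None = None) -> float:
    """SpO2 sample entropy of the concatenated valid sleep-window samples.

    Artifact gaps are closed by concatenation (the series is the valid
    samples in temporal order); at the default sub-0.5% artifact rates this
    perturbs at most a handful of templates.  A constant series returns 0.
    """
    params = params or SseParams()
    x = rec.sleep_values()
    if len(x) < params.m + 2:
        raise ValidationError(
            f"need at least m+2={params.m + 2} valid samples, got {len(x)}"
        )
    sd = float(np.std(x))
    if sd == 0 and params.r_floor == 0:
        return 0.0
    r = max(params.r_factor * sd, params.r_floor)
    return sample_entropy(x, m=params.m, r=r).value


# ---------------------------------------------------------------------------
# Full per-recording summary
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Every knob of the per-recording analysis pipeline, in one place."""

    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    odi3_threshold_pct: float = 3.0
    odi4_threshold_pct: float = 4.0
    min_event_duration_s: float = 10.0
    max_gap_s: float = 30.0
    cluster_min_events: int = 5
    cluster_window_min_s: float = 600.0
    cluster_window_max_s: float = 1800.0
    csa_bin_width_pct: float = 1.0
    sse: SseParams = field(default_factory=SseParams)
    min_duration_h: float = 6.0
    max_artifact_pct: float = 2.5

    def to_dict(self) -> dict:
        return {
            "baseline": {
                "method": self.baseline.method,
                "window_s": self.baseline.window_s,
                "percentile": self.baseline.percentile,
            },
            "odi3_threshold_pct": self.odi3_threshold_pct,
            "odi4_threshold_pct": self.odi4_threshold_pct,
            "min_event_duration_s": self.min_event_duration_s,
            "max_gap_s": self.max_gap_s,
            "cluster_min_events": self.cluster_min_events,
            "cluster_window_min_s": self.cluster_window_min_s,
            "cluster_window_max_s": self.cluster_window_max_s,
            "csa_bin_width_pct": self.csa_bin_width_pct,
            "sse": {
                "m": self.sse.m,
                "r_factor": self.sse.r_factor,
                "r_floor": self.sse.r_floor,
            },
            "min_duration_h": self.min_duration_h,
            "max_artifact_pct": self.max_artifact_pct,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        base = BaselineConfig(**d.pop("baseline", {}))
        sse = SseParams(**d.pop("sse", {}))
        return cls(baseline=base, sse=sse, **d)


@dataclass
class NoxSummary:
    """All per-recording oximetry indices, one row of the cohort table."""

    subject_id: str
    visit: str
    duration_h: float
    artifact_pct: float
    mean_spo2: float
    sd_spo2: float
    odi3: float
    odi4: float
    mos: int
    csa: float
    sse: float
    n_events3: int = 0
    n_events4: int = 0
    n_clusters: int = 0
    quality_override: bool = False

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "visit": self.visit,
            "spo2_mean": self.mean_spo2,
            "spo2_sd": self.sd_spo2,
            "odi3": self.odi3,
            "odi4": self.odi4,
            "mos": self.mos,
            "csa": self.csa,
            "sse": self.sse,
            "duration_h": self.duration_h,
            "artifact_pct": self.artifact_pct,
        }


def summarize(
    rec: OximetryRecording,
    cfg: AnalysisConfig | None = None,
    force: bool = False,
) -> NoxSummary:
    """Run the full analysis pipeline on one recording.

    Raises :class:`ValidationError` when the recording fails the quality
    gate unless ``force`` is given, in which case analysis proceeds with a
    warning and the summary is flagged ``quality_override``.
    """
    cfg = cfg or AnalysisConfig()
    qr = quality_check(rec, cfg.min_duration_h, cfg.max_artifact_pct)
    if not qr.passes:
        if not force:
            raise ValidationError(
                f"recording {rec.subject_id!r} fails quality gate: "
                f"{', '.join(qr.reasons)}"
            )
        warnings.warn(
            f"analyzing {rec.subject_id!r} despite failed quality gate "
            f"({', '.join(qr.reasons)})",
            stacklevel=2,
        )

    values = rec.sleep_values()
    if values.size == 0:
        raise ValidationError("no valid samples in the sleep window")
    mean_spo2 = float(np.mean(values))
    sd_spo2 = float(np.std(values, ddof=1)) if values.size > 1 else 0.0

    baseline = track_baseline(rec, cfg.baseline)
    events3 = detect_desaturations(
        rec, baseline, cfg.odi3_threshold_pct, cfg.min_event_duration_s, cfg.max_gap_s
    )
    events4 = detect_desaturations(
        rec, baseline, cfg.odi4_threshold_pct, cfg.min_event_duration_s, cfg.max_gap_s
    )
    hours = rec.valid_sleep_hours
    odi3 = compute_odi(events3, hours)
    odi4 = compute_odi(events4, hours)
    clusters = detect_clusters(
        events4, rec, cfg.cluster_min_events,
        cfg.cluster_window_min_s, cfg.cluster_window_max_s,
    )
    mos = assign_mos(events4, clusters)

    return NoxSummary(
        subject_id=rec.subject_id,
        visit=rec.visit,
        duration_h=qr.duration_h,
        artifact_pct=qr.artifact_pct,
        mean_spo2=mean_spo2,
        sd_spo2=sd_spo2,
        odi3=odi3,
        odi4=odi4,
        mos=mos.score,
        csa=compute_csa(rec, cfg.csa_bin_width_pct),
        sse=compute_sse(rec, cfg.sse),
        n_events3=len(events3),
        n_events4=len(events4),
        n_clusters=len(clusters),
        quality_override=not qr.passes,
    )
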