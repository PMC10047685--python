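"""Synthetic overnight SpO2 recordings with known ground truth.

The generator emulates the phenomenology of pediatric obstructive sleep
apnea screening oximetry: a slowly drifting baseline saturation, integer
quantization of the device output, desaturation events carved as
trapezoidal dips (one-sample descent, a plateau at baseline - depth, a
one-sample recovery) placed by a Poisson process, a configurable fraction
of events concentrated in periodic REM-like burst windows (which is what
creates desaturation clusters), and randomly flagged artifact samples.

It exists so every analysis stage — detection, indices, cohort statistics —
can be tested against known event times and rates without clinical data.
Default parameters emulate a pre-adenotonsillectomy severity profile
(baseline ~96.5%, ~18 qualifying desaturations/h with a long severity
tail); :meth:`SimulationConfig.post_surgery` gives the matched normalized
profile (baseline ~98.2%, ~1.2 events/h, shallow dips, no bursts).

Identical (config, seed) reproduces recordings bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import OximetryRecording, write_recording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GenerationError",
    "generate_recording",
    "generate_paired_cohort",
    "SimulatedSubject",
    "write_cohort",
]


class GenerationError(RuntimeError):
    """Raised when the requested event load cannot be placed."""


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic overnight recording.

    duration_h drawn uniformly from 6.0-7.4 h when None (typical overnight
    study lengths).  Event depths are shifted-exponential,
    ``depth_min + Exp(depth_scale)`` percent; plateau durations are
    ``duration_min_s + Exp(duration_scale_s)`` seconds capped at
    ``duration_max_s``.  ``cluster_fraction`` of events land inside
    periodic burst windows every ``rem_cycle_min`` minutes, emulating the
    REM-sleep clustering of obstructive events.
    """

    duration_h: float | None = None
    sample_interval_s: float = 4.0
    baseline_spo2: float = 96.5
    baseline_drift_sd: float = 0.15   # percent per sqrt(hour) random walk
    noise_sd: float = 0.4             # percent, before integer quantization
    event_rate_per_h: float = 17.8
    depth_min: float = 3.0
    depth_scale: float = 2.0
    duration_min_s: float = 12.0
    duration_scale_s: float = 10.0
    duration_max_s: float = 90.0
    subthreshold_rate_per_h: float = 150.0
    subthreshold_depth_lo: float = 0.8
    subthreshold_depth_hi: float = 2.6
    subthreshold_duration_lo_s: float = 4.0
    subthreshold_duration_hi_s: float = 8.0
    cluster_fraction: float = 0.7
    rem_cycle_min: float = 90.0
    burst_width_min: float = 15.0
    artifact_rate: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if not (70 < self.baseline_spo2 <= 100):
            raise ValueError("baseline_spo2 must be in (70, 100]")
        for name in ("baseline_drift_sd", "noise_sd", "event_rate_per_h",
                     "artifact_rate", "depth_scale", "duration_scale_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_min < 3:
            raise ValueError("depth_min must be >= 3 (a qualifying desaturation)")
        if not (0 <= self.cluster_fraction <= 1):
            raise ValueError("cluster_fraction must be in [0, 1]")

    @classmethod
    def pre_surgery(cls, **overrides) -> "SimulationConfig":
        """Symptomatic (pre-intervention) severity profile."""
        return cls(**overrides)

    @classmethod
    def severity_profile(cls, event_rate_per_h: float, **overrides) -> "SimulationConfig":
        """Profile in which disease severity drives the whole phenotype.

        Obstructive severity does not only raise the event rate: severe
        children desaturate deeper, cycle faster, and show more
        sub-threshold airway instability.  This couples those parameters to
        the qualifying-event rate the way the paired-cohort generator does,
        so a severity sweep changes one knob.
        """
        r = float(event_rate_per_h)
        defaults = dict(
            event_rate_per_h=r,
            depth_scale=1.2 + 0.04 * r,
            duration_scale_s=10.0 * min(1.0, 30.0 / max(r, 1.0)),
            subthreshold_rate_per_h=80.0 + 5.0 * r,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def post_surgery(cls, **overrides) -> "SimulationConfig":
        """Normalized (post-intervention) profile: few, shallow events."""
        defaults = dict(
            baseline_spo2=98.2,
            event_rate_per_h=1.2,
            depth_scale=0.5,
            duration_scale_s=4.0,
            subthreshold_rate_per_h=5.0,
            cluster_fraction=0.0,
            noise_sd=0.35,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class GroundTruth:
    """What the generator actually placed, for parameter-recovery tests."""

    event_intervals: list[tuple[float, float, float]]  # (start_s, end_s, depth)
    true_rate_per_h: float
    burst_windows: list[tuple[float, float]]

    def to_json(self) -> str:
        return json.dumps(
            {
                "event_intervals": self.event_intervals,
                "true_rate_per_h": self.true_rate_per_h,
                "burst_windows": self.burst_windows,
            }
        )


def generate_recording(
    cfg: SimulationConfig,
    subject_id: str = "sim",
    visit: str = "unknown",
) -> tuple[OximetryRecording, GroundTruth]:
    """Generate one synthetic recording plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.sample_interval_s
    dur_h = cfg.duration_h if cfg.duration_h is not None else rng.uniform(6.0, 7.4)
    n = int(round(dur_h * 3600.0 / dt))
    dur_s = n * dt

    # slowly drifting baseline: Gaussian random walk, variance ~ elapsed time
    steps = rng.normal(0.0, cfg.baseline_drift_sd * math.sqrt(dt / 3600.0), n)
    base = cfg.baseline_spo2 + np.cumsum(steps)
    base = np.clip(base, 80.0, 100.0)

    # REM-like burst windows, one per sleep cycle
    bursts: list[tuple[float, float]] = []
    t0 = cfg.rem_cycle_min * 60.0
    while t0 < dur_s:
        bursts.append((t0, min(t0 + cfg.burst_width_min * 60.0, dur_s)))
        t0 += cfg.rem_cycle_min * 60.0

    n_events = rng.poisson(cfg.event_rate_per_h * dur_h)
    intervals, occupied = _place_events(rng, cfg, n_events, n, bursts)

    delta = np.zeros(n)
    for i0, i1, depth in intervals:
        delta[i0] = 0.5 * depth            # descent sample
        delta[i0 + 1 : i1 - 1] = depth     # plateau
        delta[i1 - 1] = 0.5 * depth        # recovery sample

    # sub-threshold instability: mild obstructive episodes that dent SpO2 by
    # <3% and so never qualify as desaturations, but make the trace
    # irregular — the signal feature the entropy index responds to
    _carve_subthreshold_dips(rng, cfg, dur_h, delta, occupied)

    noise = rng.normal(0.0, cfg.noise_sd, n)
    spo2 = np.clip(np.round(base - delta + noise), 50.0, 100.0)

    valid = rng.random(n) >= cfg.artifact_rate
    spo2 = np.where(valid, spo2, np.nan)

    rec = OximetryRecording(
        spo2=spo2,
        valid_mask=valid,
        sample_interval_s=dt,
        subject_id=subject_id,
        visit=visit,
    )
    # ground-truth interval = the plateau (the portion a detector must find)
    gt = GroundTruth(
        event_intervals=[((i0 + 1) * dt, (i1 - 1) * dt, d) for i0, i1, d in intervals],
        true_rate_per_h=len(intervals) / dur_h,
        burst_windows=bursts,
    )
    return rec, gt


def _place_events(rng, cfg, n_events, n_samples, bursts):
    """Non-overlapping placement with a minimum inter-event gap.

    The 4-sample (16 s at 4 s resolution) gap guarantees at least one
    above-threshold sample between adjacent events, so detection can never
    merge two placed events.  Burst placement falls back to anywhere in the
    recording when the burst windows are saturated.
    """
    dt = cfg.sample_interval_s
    dur_s = n_samples * dt
    gap = 4
    placed: list[tuple[int, int, float]] = []
    occupied = np.zeros(n_samples, dtype=bool)
    max_retries = 2000
    for _ in range(n_events):
        depth = cfg.depth_min + rng.exponential(cfg.depth_scale)
        plateau_s = min(
            cfg.duration_min_s + rng.exponential(cfg.duration_scale_s),
            cfg.duration_max_s,
        )
        span = int(math.ceil(plateau_s / dt)) + 2  # plateau + descent + recovery
        in_burst = bool(bursts) and rng.random() < cfg.cluster_fraction
        for _try in range(max_retries):
            if in_burst and _try >= 100:  # burst windows saturated
                in_burst = False
            if in_burst:
                b0, b1 = bursts[rng.integers(len(bursts))]
                lo = int(b0 / dt)
                hi = max(lo + 1, int(b1 / dt) - span)
            else:
                lo, hi = 0, n_samples - span
            if hi <= lo:
                continue
            i0 = int(rng.integers(lo, hi))
            i1 = i0 + span
            if i1 + gap > n_samples or occupied[max(0, i0 - gap) : i1 + gap].any():
                continue
            occupied[i0:i1] = True
            placed.append((i0, i1, float(depth)))
            break
        else:
            raise GenerationError(
                f"could not place event {len(placed) + 1}/{n_events} after "
                f"{max_retries} retries (recording too crowded: "
                f"{cfg.event_rate_per_h}/h over {dur_s / 3600:.1f} h)"
            )
    placed.sort(key=lambda e: e[0])
    return placed, occupied


def _carve_subthreshold_dips(rng, cfg, dur_h, delta, occupied):
    """Shallow, brief dips between qualifying events.

    Abrupt rectangular dents of 1-2 samples (4-8 s at 4 s resolution):
    shorter than any admissible minimum event duration, so they can never
    register as desaturation events, whatever their depth.  Unplaceable
    dips are silently dropped — they are background texture, not tracked
    ground truth.
    """
    n = len(delta)
    dt = cfg.sample_interval_s
    n_mini = rng.poisson(cfg.subthreshold_rate_per_h * dur_h)
    for _ in range(n_mini):
        depth = rng.uniform(cfg.subthreshold_depth_lo, cfg.subthreshold_depth_hi)
        span = max(1, int(round(
            rng.uniform(cfg.subthreshold_duration_lo_s, cfg.subthreshold_duration_hi_s) / dt
        )))
        for _try in range(50):
            i0 = int(rng.integers(0, max(1, n - span)))
            i1 = i0 + span
            if occupied[max(0, i0 - 2) : i1 + 2].any():
                continue
            occupied[i0:i1] = True
            delta[i0:i1] = depth
            break


# ---------------------------------------------------------------------------
# Paired cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedSubject:
    subject_id: str
    pre: OximetryRecording
    pre_truth: GroundTruth
    post: OximetryRecording
    post_truth: GroundTruth


def generate_paired_cohort(
    n_subjects: int,
    pre_cfg: SimulationConfig | None = None,
    post_cfg: SimulationConfig | None = None,
    seed: int = 0,
    subject_baseline_sd: float = 0.5,
) -> list[SimulatedSubject]:
    """Correlated pre/post recordings for ``n_subjects`` children.

    Subject-level severity is drawn once per child and drives both visits:

    * pre event rate: lognormal(median 15/h, sigma 0.65) clipped to
      [3.5, 70]/h — matching the dispersion of symptomatic screening
      cohorts (mean ~18/h, SD ~13/h, range ~3-70/h);
    * pre event depth scale grows with severity (severe children desaturate
      deeper, producing the occasional nadir below 85/80%);
    * pre baseline saturation declines mildly with severity;
    * post visits use the normalized profile (~1.2 events/h median, shallow
      depths) with the same subject-level baseline offset (SD 0.5%), which
      is what makes the pairing informative.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    pre_cfg = pre_cfg or SimulationConfig.pre_surgery()
    post_cfg = post_cfg or SimulationConfig.post_surgery()
    root = np.random.SeedSequence(seed)
    subjects: list[SimulatedSubject] = []
    for k, child_ss in enumerate(root.spawn(n_subjects)):
        sub_seed, pre_seed, post_seed = [
            int(s.generate_state(1)[0] % (2**31)) for s in child_ss.spawn(3)
        ]
        rng = np.random.default_rng(sub_seed)
        offset = rng.normal(0.0, subject_baseline_sd)
        # severity draws are scaled by the supplied profiles' event rates,
        # so a zero-severity base config yields a genuinely null cohort
        pre_scale = pre_cfg.event_rate_per_h / 17.8
        post_scale = post_cfg.event_rate_per_h / 1.2
        rate_pre = float(np.clip(15.0 * rng.lognormal(0.0, 0.65), 3.5, 60.0) * pre_scale)
        rate_post = float(np.clip(0.8 * rng.lognormal(0.0, 0.6), 0.1, 1.8) * post_scale)
        dur_pre = float(rng.uniform(6.0, 7.4))
        dur_post = float(rng.uniform(6.0, 7.4))
        sid = f"S{k + 1:03d}"
        cfg_pre = replace(
            pre_cfg,
            seed=pre_seed,
            duration_h=dur_pre,
            event_rate_per_h=rate_pre,
            # severity couplings as in SimulationConfig.severity_profile,
            # scaled against the default profile they were derived for
            depth_scale=(1.2 + 0.04 * rate_pre) * (pre_cfg.depth_scale / 2.0),
            duration_scale_s=pre_cfg.duration_scale_s
            * min(1.0, 30.0 / max(rate_pre, 1.0)),
            subthreshold_rate_per_h=(80.0 + 5.0 * rate_pre)
            * (pre_cfg.subthreshold_rate_per_h / 150.0),
            baseline_spo2=float(
                np.clip(pre_cfg.baseline_spo2 + offset - 0.02 * rate_pre, 91.0, 99.0)
            ),
        )
        cfg_post = replace(
            post_cfg,
            seed=post_seed,
            duration_h=dur_post,
            event_rate_per_h=rate_post,
            baseline_spo2=float(
                np.clip(post_cfg.baseline_spo2 + offset, 96.0, 99.2)
            ),
        )
        pre_rec, pre_gt = generate_recording(cfg_pre, subject_id=sid, visit="pre")
        post_rec, post_gt = generate_recording(cfg_post, subject_id=sid, visit="post")
        subjects.append(SimulatedSubject(sid, pre_rec, pre_gt, post_rec, post_gt))
    return subjects


def write_cohort(subjects: list[SimulatedSubject], outdir: str | Path) -> Path:
    """Write recordings as CSV, ground truth as JSON, plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id,visit,path,ground_truth"]
    for s in subjects:
        for visit, rec, gt in (("pre", s.pre, s.pre_truth), ("post", s.post, s.post_truth)):
            name = f"{s.subject_id}_{visit}.csv"
            write_recording(rec, outdir / name)
            gt_name = f"{s.subject_id}_{visit}_truth.json"
            (outdir / gt_name).write_text(gt.to_json())
            rows.append(f"{s.subject_id},{visit},{name},{gt_name}")
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
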