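# Methods

This note documents the scoring conventions, the statistical procedures,
and the generative model behind `noxtk`, together with the choices made
where the field's definitions are underdetermined.

## The recording model

A recording is a uniformly sampled SpO₂ series (percent, default 4 s per
sample — the storage resolution of common wrist oximeters), a per-sample
validity mask, and a half-open sleep window `[onset, offset)` in sample
indices. Awake segments at the edges are excluded by trimming the window,
not by deleting samples. All indices are computed from valid samples
inside the window; the ODI denominator is the *valid* analyzed sleep time
in hours, so artifact bursts do not inflate event rates.

Artifacts are taken from an explicit quality column when the file has one
(the convention when a device has already done its own signal rejection).
Otherwise rule-based flags apply: non-numeric or out-of-range values
(outside [0, 100]%), and isolated single-sample spikes whose step exceeds
4%/sample and immediately reverts — a physiologically implausible
excursion at 4 s resolution. The spike rule is a stand-in for device-level
artifact rejection, not a reconstruction of any vendor's algorithm, and
can be disabled (`max_jump_pct=None`).

The quality gate passes a recording when the sleep window spans at least
6 h and at most 2.5% of its samples are invalid (both configurable).
A recording with exactly 2.5% artifacts passes: the exclusion rule is
"more than", matching how artifact-rate limits are quoted in screening
practice.

## Baseline and desaturation events

Oximetry software scores drops "from baseline" without a standard
definition of baseline. Here the baseline is a **trailing rolling maximum
of valid SpO₂ over 120 s** (configurable to a trailing percentile for
robustness to positive spikes). The window is long enough to bridge an
ordinary desaturation event — so the baseline does not follow the dip it
is supposed to measure — yet short enough to track slow drifts. Cutoffs
derived under a different baseline convention are not interchangeable
with ours.

A desaturation event is a **maximal run of valid samples with
`SpO₂ ≤ baseline − threshold`** (3% for ODI3, 4% for ODI4). There is no
re-saturation criterion: the event ends before the first valid sample
back above the threshold. Invalid gaps up to 30 s inside a run are
bridged (one physiological dip should not be split by a dropped sample);
longer gaps split the run. The ≥10 s minimum duration is applied as
`ceil(10 / 4) = 3` samples, i.e. 12 s at 4 s resolution — two samples
(8 s) cannot witness 10 s of desaturation. Event depth is the baseline at
onset minus the nadir, so depth ≥ threshold by construction.

Because detection is threshold-wise maximal-run, every 4% event lies
inside some 3% event. (ODI4 ≤ ODI3 then holds whenever distinct 4% dips
are not merged by an intervening 3%-deep segment — guaranteed on the
simulator's separated events, and checked recording-wise in the cohort
tests, but not a theorem for arbitrary signals.)

**Clusters**: scanning events left to right, each maximal group of ≥5
consecutive events spanning ≤30 min becomes one cluster; every event
belongs to at most one cluster. A burst tighter than 10 min still counts
— a denser cluster is not less pathological — with its reported window
clamped up to 10 min.

**McGill oximetry score**, from 4%-threshold events, nadir comparisons
strict, counts taken over the whole record:

| score | clusters | nadir pattern |
|---|---|---|
| 4 (severe) | ≥3 | ≥3 events < 80% |
| 3 (moderate) | ≥3 | ≥3 events < 85%, none < 80% |
| 2 (mild) | ≥3 | ≥3 events < 90%, none < 85% |
| 1 (inconclusive) | — | anything else |

The published rule table is reproduced literally, including its gap: a
record with ≥3 clusters, ≥3 nadirs <85% but only one or two <80% matches
no category above 1 and scores 1. Users comparing against manual scoring
should be aware that human raters typically round such records upward.

## CSA

Valid sleep-window values are binned at 1% width anchored at integers
(`v → floor(v)`, matching integer-percent device output). With `F(s)` the
cumulative relative frequency (percent) of bins ≤ s, ascending cumulation,

    CSA = Σ_{s = s_min}^{100} F(s),

a unit-width rectangle sum from the lowest occupied bin to 100. This is
the construction consistent with the index's stated minimum: an all-100%
recording gives exactly 100, any sample in a lower bin strictly increases
the sum, and lowering any sample never decreases it. Bin width is
configurable (the minimum of 100 is preserved because each bin
contributes its cumulative frequency once), but non-unit widths change
the index's scale and any cutoffs derived at 1%.

## Sample entropy

`SampEn(m, r) = −ln(A/B)` with `A`, `B` the numbers of ordered template
pairs (i ≠ j, self-matches excluded) of lengths m+1 and m whose Chebyshev
distance is ≤ r, both counted over the same `N − m` template positions.
Defaults `m = 2`, `r = 0.2 × SD` of the series (population SD, ddof = 0,
as in the standard reference implementation; the *reported* SD SpO₂ uses
the sample SD). A constant series returns 0. On integer-quantized SpO₂
the tolerance is usually < 1, so template matching degenerates to exact
symbol matching; an optional absolute floor `r_floor` is exposed for
near-constant signals.

Degenerate counts: when `A = 0` (or even `B = 0`) the textbook value is
infinite. The implementation instead returns the finite bound
`−ln(1/(B+1))`, flagged `upper_bounded`, keeping downstream ROC analysis
well-defined. (With `B = 0` this bound is 0 — a deliberate convention:
such series are too short or too scattered to carry regularity
information.) Artifact gaps are closed by concatenating valid samples; at
sub-0.5% artifact rates this perturbs a negligible number of templates.

The vectorized implementation is verified against a naive O(N²) double
loop to 1e-12 in the test suite.

## Evaluation statistics

- **Wilcoxon matched pairs**: zero differences dropped; exact
  (permutation-exact, valid under ties) null distribution for ≤25
  effective pairs, normal approximation with continuity correction
  otherwise; all-zero differences return p = 1 flagged degenerate.
- **ROC**: empirical curve, trapezoidal AUC. 95% CI by DeLong's
  structural-components method (deterministic default), stratified
  bootstrap (2000 resamples, seeded), or a *paired* bootstrap that
  resamples subjects keeping both visits — provided because the control
  class in a pre/post design consists of the cases' own follow-ups, so
  the two classes are correlated and the conventional unpaired AUC
  understates CI width. The point estimate ignores pairing, as is
  conventional for screening-index reports.
- **Youden cutoff**: maximizes sensitivity + specificity; ties break
  toward higher specificity (a screening-confirmation context); the
  reported cutoff is the midpoint between adjacent distinct observed
  values, to be read as ">cutoff" (or "<cutoff" for indices lowered by
  disease, i.e. mean SpO₂).
- **Spearman**: average-rank ties; constant columns yield undefined
  correlations reported as NaN with a unit diagonal by convention.

## The simulator

The generator emulates the *phenomenology* of pediatric screening
oximetry, not gas exchange: it exists to give detection and the indices a
controllable test bed with known ground truth.

Signal = slowly drifting baseline (Gaussian random walk, default
0.15%/√h) + carved desaturations + Gaussian noise (default SD 0.4%),
then rounded to integer percent (device quantization) and clipped to
[50, 100]. Qualifying events are trapezoids — one half-depth descent
sample, a plateau at `baseline − depth`, one half-depth recovery — with
shifted-exponential depths (min 3%) and durations (min 12 s, capped at
90 s), placed by a Poisson process with a minimum 16 s separation so
placed events can never merge at detection. A configurable fraction of
events (default 0.7) falls in periodic REM-like burst windows (every
90 min, 15 min wide), which is what produces desaturation clusters and
non-trivial McGill scores. Artifact samples are flagged invalid at an
independent 0.4% rate. Identical (config, seed) reproduces recordings
bit-for-bit.

**Sub-threshold instability.** Real symptomatic tracings are irregular
between scoreable events: mild obstructive episodes perturb SpO₂ without
producing a ≥3% desaturation. The generator models these as brief
rectangular dents (4–8 s, i.e. 1–2 samples — shorter than any admissible
minimum event duration, so they can never register as events — of
0.8–2.6% depth) at a default rate of 150/h. They are what gives
symptomatic recordings their elevated sample entropy; without them a
simulated trace is flat-with-dips and unrealistically regular.

**Severity profile** (`SimulationConfig.severity_profile(rate)`): disease
severity co-varies depth scale (1.2 + 0.04·rate), cycling speed, and
sub-threshold instability (80 + 5·rate per hour) with the qualifying
event rate, so a severity sweep turns one knob.

**Paired cohorts**: per-subject severity is lognormal (median 15/h,
σ = 0.65, clipped to [3.5, 60]/h) for the symptomatic visit and lognormal
(median 0.8/h, clipped to [0.1, 1.8]/h) with shallow depths for the
normalized visit; a shared subject-level baseline offset (SD 0.5%) makes
the pairing informative. These defaults reproduce the summary envelopes
reported for pediatric adenotonsillectomy screening cohorts (symptomatic
ODI3 ≈ 18 ± 13/h, mean SpO₂ ≈ 95–96% falling with severity; normalized
ODI4 ≤ 2.2/h, mean SpO₂ ≈ 98.2%).

What the simulator does **not** model: pulse-rate dynamics, true
respiratory oscillation spectra, device filtering/averaging, motion
artifacts with plausible temporal structure (artifacts are i.i.d.), and
state-dependent baselines (REM affects only event placement). Passing
tests therefore demonstrate correctness of the *analysis* under a
controlled generative model — parameter recovery, oracle equivalence,
ordering properties — not clinical performance on real tracings, whose
absolute CSA/SSE values also depend on oximeter resolution and averaging
time.

## Problem sizes and numerical choices

The test suite exercises overnight-scale recordings (6–7.4 h at 4 s,
≈5400–6700 samples). Vectorized SampEn is O(N²) in memory-light boolean
blocks (~0.4 s at N = 5400); the severity-grid recovery test uses 50
seeds per severity and 6 h recordings; the cohort pipeline test uses the
full n = 45 paired design. Half-open windows throughout; sample index i
covers time `[i·Δt, (i+1)·Δt)`; timestamps are seconds from recording
start; baselines are clamped to [0, 100]. Ties cannot arise in event
detection (maximal runs never overlap); cluster assignment is greedy
left-to-right and order-deterministic.

## Known limitations

- The baseline construction (rolling max) and the CSA
  integration/binning convention are *this package's* documented
  conventions; published cutoffs (e.g. ODI3 > 3.6/h, CSA > 293,
  SSE > 0.99) were derived under other, unpublished conventions and ship
  only as reference points, not validated thresholds.
- The literal McGill rule gap described above.
- EDF support requires the optional `mne` dependency and reads the first
  SpO₂-labelled channel only.
- The paired-cohort AUC point estimate ignores within-subject
  correlation (use the paired bootstrap CI when that matters).
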