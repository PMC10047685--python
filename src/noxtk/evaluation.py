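"""Paired pre/post comparison and diagnostic-performance evaluation.

The study design this serves is a self-controlled cohort: the same subjects
are recorded before an intervention (cases) and again after it (controls).
For each index the module provides the Wilcoxon matched-pairs signed-rank
test, the empirical ROC curve with trapezoidal AUC, a 95% CI by DeLong's
method (default) or stratified bootstrap, the Youden-optimal cutoff with
sensitivity/specificity, and a Spearman correlation matrix.

Note the control class consists of the cases' own follow-up recordings, so
the two classes are correlated; the default AUC ignores that pairing (the
conventional choice for screening-index reports), and ``ci_method=
"paired_bootstrap"`` resamples subjects keeping both visits together for a
CI that honours the dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve

from .indices import NoxSummary

__all__ = [
    "PairedCohort",
    "WilcoxonResult",
    "RocResult",
    "wilcoxon_paired",
    "roc_with_youden",
    "delong_ci",
    "spearman_matrix",
    "cohort_table",
    "diagnostic_table",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = ["spo2_mean", "spo2_sd", "odi3", "odi4", "mos", "csa", "sse"]

#: Published screening cutoffs (">value" = positive), shipped as reference
#: points only: they are cohort-derived under other groups' scoring
#: conventions (baseline construction, CSA binning, SampEn parameters) and
#: are NOT validated thresholds for this implementation.
REFERENCE_CUTOFFS = {"odi3": 3.6, "odi4": 2.2, "mos": 1, "csa": 293.0, "sse": 0.99}

#: indices where *lower* values indicate disease (all others: higher = positive)
_LESS_IS_POSITIVE = {"spo2_mean"}


@dataclass
class PairedCohort:
    """Per-subject pre/post index summaries, aligned by subject."""

    subject_ids: list[str]
    pre: list[NoxSummary]
    post: list[NoxSummary]

    def __post_init__(self) -> None:
        if not (len(self.subject_ids) == len(self.pre) == len(self.post)):
            raise ValueError("subject_ids, pre and post must align")
        if len(self.subject_ids) < 2:
            raise ValueError("paired analysis needs n >= 2 subjects")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    def frame(self) -> pd.DataFrame:
        """Long-format table: one row per recording (2n rows)."""
        rows = []
        for sid, a, b in zip(self.subject_ids, self.pre, self.post):
            rows.append({"subject_id": sid, **a.to_row()})
            rows.append({"subject_id": sid, **b.to_row()})
        return pd.DataFrame(rows)

    def values(self, index: str, visit: str) -> np.ndarray:
        group = self.pre if visit == "pre" else self.post
        return np.array([s.to_row()[index] for s in group], dtype=float)


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str
    degenerate: bool = False


@dataclass
class RocResult:
    """AUC with CI and the Youden-optimal operating point."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity_pct: float
    specificity_pct: float
    direction: str = "greater_is_positive"


# ---------------------------------------------------------------------------
# Wilcoxon matched pairs
# ---------------------------------------------------------------------------

def wilcoxon_paired(
    pre_values: Sequence[float], post_values: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution (permutation-exact, handling tied absolute differences) is
    used for n <= 25 effective pairs, the normal approximation with
    continuity correction otherwise.  All-zero differences return the
    degenerate p = 1.
    """
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D and of equal length")
    if len(pre) < 2:
        raise ValueError("need at least 2 pairs")
    d = pre - post
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    if nz.size <= 25:
        method = "exact"
        res = scipy.stats.wilcoxon(nz, zero_method="wilcox", method="exact")
    else:
        method = "approx"
        res = scipy.stats.wilcoxon(
            nz, zero_method="wilcox", method="approx", correction=True
        )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_effective=int(nz.size),
        method=method,
    )


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n - 1 and xs[j + 1] == xs[i]:
            j += 1
        ranks[i : j + 1] = 0.5 * (i + j) + 1.0
        i = j + 1
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def delong_ci(
    case_scores: np.ndarray, control_scores: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC and its DeLong (1988) confidence interval.

    Returns ``(auc, ci_low, ci_high)``.  The variance comes from the
    structural components of the Mann–Whitney statistic; for degenerate
    (perfectly separated) data the variance is 0 and the CI collapses onto
    the point estimate.
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    m, n = len(x), len(y)
    z = np.concatenate([x, y])
    tz = _midranks(z)
    tx = _midranks(x)
    ty = _midranks(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # structural components, cases
    v10 = 1.0 - (tz[m:] - ty) / m    # structural components, controls
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s01 / m + s10 / n)
    zq = scipy.stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, min(auc, auc - zq * se))
    hi = min(1.0, max(auc, auc + zq * se))
    return float(auc), float(lo), float(hi)


def roc_with_youden(
    values: Sequence[float],
    labels: Sequence[int],
    direction: str = "greater_is_positive",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
    subject_ids: Sequence[str] | None = None,
) -> RocResult:
    """Empirical ROC with trapezoidal AUC, CI and Youden-optimal cutoff.

    ``labels`` are 1 for the condition-positive class.  The cutoff maximizes
    sensitivity + specificity; ties are broken toward higher specificity.
    The reported cutoff is the midpoint between the adjacent distinct
    observed values, to be read with ">cutoff" semantics (or "<cutoff" when
    ``direction="less_is_positive"``).

    ``ci_method`` is ``"delong"`` (closed form, deterministic),
    ``"bootstrap"`` (stratified, percentile, ``n_boot`` resamples) or
    ``"paired_bootstrap"`` (resamples subjects keeping both their
    recordings; requires ``subject_ids``).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and labels must align")
    if np.any(~np.isfinite(v)):
        raise ValueError("values contain missing/non-finite entries")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes (0 and 1)")
    if direction not in ("greater_is_positive", "less_is_positive"):
        raise ValueError(f"unknown direction {direction!r}")

    score = v if direction == "greater_is_positive" else -v
    fpr, tpr, thr = roc_curve(y, score)
    auc = float(np.trapezoid(tpr, fpr))

    # Youden point: max(tpr - fpr), ties -> higher specificity (lower fpr)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    best_i = best[np.argmin(fpr[best])]
    t = thr[best_i]

    sorted_scores = np.unique(score)
    if np.isinf(t):  # degenerate: nothing predicted positive
        cutoff_score = sorted_scores[-1] + 0.5
    else:
        k = np.searchsorted(sorted_scores, t)
        if k == 0:
            cutoff_score = sorted_scores[0] - 0.5
        else:
            cutoff_score = 0.5 * (sorted_scores[k - 1] + sorted_scores[k])
    cutoff = cutoff_score if direction == "greater_is_positive" else -cutoff_score

    sens = 100.0 * tpr[best_i]
    spec = 100.0 * (1.0 - fpr[best_i])

    if ci_method == "delong":
        auc_d, lo, hi = delong_ci(score[y == 1], score[y == 0], alpha)
    elif ci_method in ("bootstrap", "paired_bootstrap"):
        lo, hi = _bootstrap_ci(
            score, y, n_boot, seed, alpha,
            paired=ci_method == "paired_bootstrap", subject_ids=subject_ids,
        )
        lo, hi = min(lo, auc), max(hi, auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return RocResult(
        auc=auc, ci_low=float(lo), ci_high=float(hi), cutoff=float(cutoff),
        sensitivity_pct=float(sens), specificity_pct=float(spec),
        direction=direction,
    )


def _auc_mw(score: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC (equals the trapezoidal empirical ROC area)."""
    x, c = score[y == 1], score[y == 0]
    r = _midranks(np.concatenate([x, c]))
    m = len(x)
    return (r[:m].sum() - m * (m + 1) / 2.0) / (m * len(c))


def _bootstrap_ci(score, y, n_boot, seed, alpha, paired=False, subject_ids=None):
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    if paired:
        if subject_ids is None:
            raise ValueError("paired_bootstrap requires subject_ids")
        sids = np.asarray(subject_ids)
        uniq = np.unique(sids)
        groups = {s: np.flatnonzero(sids == s) for s in uniq}
        for b in range(n_boot):
            pick = rng.choice(uniq, size=len(uniq), replace=True)
            idx = np.concatenate([groups[s] for s in pick])
            yb = y[idx]
            if yb.min() == yb.max():
                aucs[b] = np.nan
                continue
            aucs[b] = _auc_mw(score[idx], yb)
    else:
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        for b in range(n_boot):
            idx = np.concatenate(
                [rng.choice(pos, len(pos), replace=True),
                 rng.choice(neg, len(neg), replace=True)]
            )
            aucs[b] = _auc_mw(score[idx], y[idx])
    aucs = aucs[np.isfinite(aucs)]
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman_matrix(columns: Mapping[str, Sequence[float]] | pd.DataFrame) -> pd.DataFrame:
    """Symmetric Spearman rho matrix with unit diagonal, average-rank ties.

    A constant column has undefined rank correlation with anything else;
    those entries are reported as NaN (the diagonal stays 1 by convention).
    """
    df = pd.DataFrame(columns)
    if len(df) < 3:
        raise ValueError("need at least 3 subjects")
    names = list(df.columns)
    k = len(names)
    rho = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i] = 1.0
        xi = df[names[i]].to_numpy(dtype=float)
        for j in range(i + 1, k):
            xj = df[names[j]].to_numpy(dtype=float)
            if np.unique(xi).size < 2 or np.unique(xj).size < 2:
                continue
            r = scipy.stats.spearmanr(xi, xj).statistic
            rho[i, j] = rho[j, i] = r
    return pd.DataFrame(rho, index=names, columns=names)


# ---------------------------------------------------------------------------
# Cohort-level report tables
# ---------------------------------------------------------------------------

def cohort_table(cohort: PairedCohort, indices: Sequence[str] = INDEX_COLUMNS) -> pd.DataFrame:
    """Per-index pre/post descriptive summary with the paired Wilcoxon p.

    One row per index: mean, SD, median and range at each visit, and the
    two-sided matched-pairs signed-rank p-value for the change.
    """
    rows = []
    for name in indices:
        pre = cohort.values(name, "pre")
        post = cohort.values(name, "post")
        w = wilcoxon_paired(pre, post)
        rows.append(
            {
                "parameter": name,
                "pre_mean": pre.mean(), "pre_sd": pre.std(ddof=1),
                "pre_median": np.median(pre),
                "pre_min": pre.min(), "pre_max": pre.max(),
                "post_mean": post.mean(), "post_sd": post.std(ddof=1),
                "post_median": np.median(post),
                "post_min": post.min(), "post_max": post.max(),
                "wilcoxon_p": w.p_value,
            }
        )
    return pd.DataFrame(rows)


def diagnostic_table(
    cohort: PairedCohort,
    indices: Sequence[str] = INDEX_COLUMNS,
    ci_method: str = "delong",
    seed: int = 0,
) -> pd.DataFrame:
    """ROC/Youden evaluation of each index, pre-visit recordings as cases.

    Post-intervention recordings of the same subjects serve as the control
    class.  Direction is per-index: disease raises every index except mean
    SpO2, which it lowers.
    """
    rows = []
    for name in indices:
        pre = cohort.values(name, "pre")
        post = cohort.values(name, "post")
        values = np.concatenate([pre, post])
        labels = np.concatenate([np.ones(len(pre), int), np.zeros(len(post), int)])
        sids = list(cohort.subject_ids) * 2
        direction = (
            "less_is_positive" if name in _LESS_IS_POSITIVE else "greater_is_positive"
        )
        roc = roc_with_youden(
            values, labels, direction=direction, ci_method=ci_method,
            seed=seed, subject_ids=sids,
        )
        rows.append(
            {
                "parameter": name,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "cutoff": roc.cutoff,
                "se_pct": roc.sensitivity_pct,
                "sp_pct": roc.specificity_pct,
                "direction": roc.direction,
            }
        )
    return pd.DataFrame(rows)
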