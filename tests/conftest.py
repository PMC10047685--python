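"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results from first principles
(naive double loops, exhaustive run grouping) and must stay independent of
the production implementations they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from noxtk import OximetryRecording


def make_recording(
    spo2,
    valid=None,
    sample_interval_s: float = 4.0,
    **kwargs,
) -> OximetryRecording:
    spo2 = np.asarray(spo2, dtype=float)
    if valid is None:
        valid = np.isfinite(spo2)
    return OximetryRecording(
        spo2=spo2, valid_mask=np.asarray(valid, bool),
        sample_interval_s=sample_interval_s, **kwargs,
    )


@pytest.fixture
def constant_recording():
    """Six hours of constant 97%, all valid, at 4 s sampling."""
    n = int(6 * 3600 / 4)
    return make_recording(np.full(n, 97.0))


@pytest.fixture
def all_100_recording():
    n = int(6 * 3600 / 4)
    return make_recording(np.full(n, 100.0))


# ---------------------------------------------------------------------------
# Oracle: naive O(N^2) sample entropy
# ---------------------------------------------------------------------------

def sampen_naive(x, m: int, r: float):
    """Textbook SampEn by explicit double loop over templates.

    Counts ordered pairs i != j over the n - m template start positions at
    lengths m and m+1; returns (value, A, B) with value = -ln(A/B),
    or None value when A or B is zero.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    value = -math.log(a / b) if a > 0 and b > 0 else None
    return value, a, b


# ---------------------------------------------------------------------------
# Oracle: exhaustive desaturation run scan
# ---------------------------------------------------------------------------

def detect_desaturations_oracle(rec, baseline, threshold, min_duration_s=10.0,
                                max_gap_s=30.0):
    """Group below-threshold sample indices exhaustively.

    Two below-threshold samples belong to the same event iff no valid
    above-threshold sample lies between them and every maximal run of
    invalid samples between them has length <= max_gap_s.  Event span is
    first-to-last below sample; spans shorter than the minimum duration are
    dropped.  Returns (start, end) half-open index pairs.
    """
    dt = rec.sample_interval_s
    lo, hi = rec.sleep_onset_index, rec.sleep_offset_index
    max_gap = int(max_gap_s / dt + 1e-9)
    min_samples = math.ceil(min_duration_s / dt - 1e-9)

    below_idx = [
        i for i in range(lo, hi)
        if rec.valid_mask[i] and rec.spo2[i] <= baseline[i] - threshold
    ]
    groups = []
    for i in below_idx:
        if groups:
            prev = groups[-1][-1]
            between = range(prev + 1, i)
            splits = any(
                rec.valid_mask[k] and rec.spo2[k] > baseline[k] - threshold
                for k in between
            )
            gap_len = i - prev - 1
            if not splits and gap_len <= max_gap:
                groups[-1].append(i)
                continue
        groups.append([i])
    return [
        (g[0], g[-1] + 1)
        for g in groups
        if (g[-1] + 1 - g[0]) >= min_samples
    ]
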