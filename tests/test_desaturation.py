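"""Baseline tracking, event detection vs. oracle, ODI, clusters, MOS."""

import numpy as np
import pytest

from noxtk import (
    BaselineConfig,
    DesaturationEvent,
    assign_mos,
    compute_odi,
    detect_clusters,
    detect_desaturations,
    track_baseline,
)
from noxtk.io import ValidationError

from conftest import detect_desaturations_oracle, make_recording


def _dip(baseline, start, n_samples, depth, total=300):
    """Flat signal with one rectangular dip."""
    x = np.full(total, float(baseline))
    x[start : start + n_samples] = baseline - depth
    return make_recording(x)


class TestBaseline:
    def test_constant_signal(self):
        rec = make_recording(np.full(200, 97.0))
        base = track_baseline(rec)
        np.testing.assert_allclose(base, 97.0)

    def test_rolling_max_bridges_short_dip(self):
        # 20 s dip to 92 within a 120 s window: baseline holds at 97
        rec = _dip(97, 100, 5, 5)
        base = track_baseline(rec, BaselineConfig(window_s=120))
        np.testing.assert_allclose(base, 97.0)

    def test_tracks_monotone_decline_with_lag(self):
        # 98 -> 90 linearly over 2 h: trailing max lags by the window length
        n = int(2 * 3600 / 4)
        sig = np.linspace(98, 90, n)
        rec = make_recording(sig)
        base = track_baseline(rec, BaselineConfig(window_s=120))
        w = 30  # samples in 120 s; window ending at i starts at i - w + 1
        np.testing.assert_allclose(base[: w - 1], sig[0])
        np.testing.assert_allclose(
            base[w - 1 :], sig[w - 1 :] + (sig[0] - sig[w - 1]), rtol=1e-6
        )
        assert np.all(np.diff(base) <= 1e-12)  # declining input, declining max

    def test_all_invalid_rejected(self):
        rec = make_recording([np.nan] * 10, valid=[False] * 10)
        with pytest.raises(ValidationError):
            track_baseline(rec)

    def test_invalid_samples_excluded_from_max(self):
        sig = np.full(100, 96.0)
        valid = np.ones(100, bool)
        sig[50] = 100.0
        valid[50] = False  # flagged artifact spike must not raise baseline
        rec = make_recording(np.where(valid, sig, np.nan), valid)
        base = track_baseline(rec)
        np.testing.assert_allclose(base, 96.0)

    def test_percentile_method(self):
        rec = make_recording(np.full(100, 97.0))
        base = track_baseline(rec, BaselineConfig(method="rolling_percentile"))
        np.testing.assert_allclose(base, 97.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            BaselineConfig(window_s=10)
        with pytest.raises(ValueError):
            BaselineConfig(percentile=50)
        with pytest.raises(ValueError):
            BaselineConfig(method="median")


class TestDetect:
    def test_constant_signal_no_events(self):
        rec = make_recording(np.full(300, 97.0))
        base = track_baseline(rec)
        for thr in (1, 2, 3, 4):
            assert detect_desaturations(rec, base, thr) == []

    def test_12s_dip_is_one_event_at_3_and_4(self):
        rec = _dip(97, 100, 3, 4)  # 3 samples x 4 s = 12 s at 93%
        base = track_baseline(rec)
        for thr in (3.0, 4.0):
            events = detect_desaturations(rec, base, thr)
            assert len(events) == 1
            (e,) = events
            assert e.depth == pytest.approx(4.0)
            assert e.duration_s == pytest.approx(12.0)
            assert e.nadir_spo2 == pytest.approx(93.0)
            assert e.baseline_spo2 == pytest.approx(97.0)

    def test_8s_dip_too_short(self):
        rec = _dip(97, 100, 2, 4)  # 8 s < 10 s minimum
        base = track_baseline(rec)
        assert detect_desaturations(rec, base, 3.0) == []

    def test_two_dips_separated_by_recovery(self):
        x = np.full(300, 97.0)
        x[100:104] = 93.0
        x[110:114] = 93.0
        rec = make_recording(x)
        base = track_baseline(rec)
        assert len(detect_desaturations(rec, base, 3.0)) == 2

    def test_artifact_gap_bridged(self):
        x = np.full(300, 97.0)
        x[100:110] = 93.0
        valid = np.ones(300, bool)
        valid[104:106] = False  # 8 s dropout inside the dip
        rec = make_recording(np.where(valid, x, np.nan), valid)
        base = track_baseline(rec)
        events = detect_desaturations(rec, base, 3.0)
        assert len(events) == 1
        assert events[0].start_index == 100 and events[0].end_index == 110

    def test_long_gap_splits(self):
        x = np.full(600, 97.0)
        x[100:115] = 93.0
        valid = np.ones(600, bool)
        valid[104:112] = False  # 32 s dropout > default 30 s bridge
        rec = make_recording(np.where(valid, x, np.nan), valid)
        base = track_baseline(rec)
        events = detect_desaturations(rec, base, 3.0)
        assert [(e.start_index, e.end_index) for e in events] == [(100, 104), (112, 115)]

    def test_misaligned_baseline_rejected(self):
        rec = make_recording(np.full(50, 97.0))
        with pytest.raises(ValueError):
            detect_desaturations(rec, np.full(40, 97.0), 3.0)

    def test_events_respect_sleep_window(self):
        rec = _dip(97, 10, 5, 5).replace(sleep_onset_index=50, sleep_offset_index=300)
        base = track_baseline(rec)
        assert detect_desaturations(rec, base, 3.0) == []


def test_detection_matches_exhaustive_oracle():
    """1000 random short recordings: production == exhaustive run scan."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        n = int(rng.integers(20, 201))
        spo2 = np.round(97 + rng.normal(0, 2.5, n)).clip(60, 100)
        valid = rng.random(n) > 0.08
        spo2 = np.where(valid, spo2, np.nan)
        rec = make_recording(spo2, valid)
        if not valid.any():
            continue
        base = track_baseline(rec, BaselineConfig(window_s=60))
        thr = float(rng.choice([2.0, 3.0, 4.0]))
        got = [
            (e.start_index, e.end_index)
            for e in detect_desaturations(rec, base, thr)
        ]
        expected = detect_desaturations_oracle(rec, base, thr)
        assert got == expected


def test_translation_invariance_under_rolling_max():
    """Shifting the whole signal by a constant changes nothing downstream."""
    rng = np.random.default_rng(5)
    spo2 = np.round(93 + rng.normal(0, 2, 800)).clip(70, 97)
    rec = make_recording(spo2)
    shifted = make_recording(spo2 + 3.0)
    out = []
    for r in (rec, shifted):
        base = track_baseline(r)
        e3 = detect_desaturations(r, base, 3.0)
        e4 = detect_desaturations(r, base, 4.0)
        cl = detect_clusters(e4, r)
        mos_clusters = len(cl)
        out.append((
            [(e.start_index, e.end_index) for e in e3],
            [(e.start_index, e.end_index) for e in e4],
            mos_clusters,
        ))
    assert out[0] == out[1]


def test_every_4pct_event_inside_a_3pct_event():
    rng = np.random.default_rng(17)
    spo2 = np.round(96 + rng.normal(0, 2.2, 2000)).clip(60, 100)
    rec = make_recording(spo2)
    base = track_baseline(rec)
    e3 = detect_desaturations(rec, base, 3.0)
    e4 = detect_desaturations(rec, base, 4.0)
    for e in e4:
        assert any(
            c.start_index <= e.start_index and e.end_index <= c.end_index
            for c in e3
        )


class TestOdi:
    def test_arithmetic(self):
        events = [object()] * 12
        assert compute_odi(events, 6.0) == pytest.approx(2.0)
        assert compute_odi([], 6.0) == 0.0
        assert compute_odi([object()] * 107, 6.0) == pytest.approx(17.83, abs=0.01)

    def test_zero_hours_rejected(self):
        with pytest.raises(ValueError):
            compute_odi([], 0.0)


def _mk_events(times_s, nadir=93.0, baseline=97.0, dur_samples=3, dt=4.0):
    out = []
    for t in times_s:
        i = int(t / dt)
        out.append(
            DesaturationEvent(
                start_index=i, end_index=i + dur_samples,
                baseline_spo2=baseline, nadir_spo2=nadir,
                depth=baseline - nadir, duration_s=dur_samples * dt,
            )
        )
    return out


class TestClusters:
    def _rec(self, hours=2.0):
        n = int(hours * 3600 / 4)
        return make_recording(np.full(n, 97.0))

    def test_empty(self):
        assert detect_clusters([], self._rec()) == []

    def test_five_events_in_15_min(self):
        events = _mk_events([60, 240, 420, 600, 780])  # span 12.2 min
        (cluster,) = detect_clusters(events, self._rec())
        assert cluster.event_count == 5

    def test_four_events_not_a_cluster(self):
        events = _mk_events([60, 200, 340, 480])
        assert detect_clusters(events, self._rec()) == []

    def test_tight_burst_counts_with_clamped_window(self):
        events = _mk_events([60, 120, 180, 240, 300])  # span ~4.2 min
        (cluster,) = detect_clusters(events, self._rec())
        assert cluster.event_count == 5
        assert cluster.window_duration_s == 600.0

    def test_events_spread_beyond_30_min_split(self):
        # 8 events over 56 min: no contiguous 5 fit in 30 min
        events = _mk_events([i * 480 for i in range(8)])
        assert all(
            c.event_count >= 5 and c.window_duration_s <= 1800
            for c in detect_clusters(events, self._rec())
        )
        events_dense = _mk_events([i * 300 for i in range(10)])  # 5 fit in 25 min
        clusters = detect_clusters(events_dense, self._rec())
        assert clusters and clusters[0].event_count >= 5


class TestMos:
    def _clusters(self, n):
        return [
            object.__new__(type("C", (), {}))
            for _ in range(0)
        ] if n == 0 else detect_clusters(
            _mk_events([i * 240 + 60 for i in range(5)]),
            make_recording(np.full(3600, 97.0)),
        ) * n

    def test_score_1_no_clusters_no_deep_nadirs(self):
        events = _mk_events([100, 500], nadir=93)
        mos = assign_mos(events, [])
        assert mos.score == 1

    def test_score_2_mild(self):
        events = _mk_events([100, 500, 900], nadir=88)
        clusters = self._clusters(3)
        mos = assign_mos(events, clusters)
        assert mos.score == 2
        assert mos.n_below_90 == 3 and mos.n_below_85 == 0

    def test_score_3_moderate(self):
        events = _mk_events([100, 500, 900], nadir=83)
        mos = assign_mos(events, self._clusters(3))
        assert mos.score == 3

    def test_score_4_severe(self):
        events = _mk_events([100, 500, 900], nadir=78)
        mos = assign_mos(events, self._clusters(3))
        assert mos.score == 4

    def test_strict_nadir_inequality(self):
        events = _mk_events([100, 500, 900], nadir=90.0)  # not < 90
        mos = assign_mos(events, self._clusters(3))
        assert mos.score == 1 and mos.n_below_90 == 0

    def test_monotone_in_depth(self):
        """Deepening all nadirs together can only raise the score."""
        clusters = self._clusters(3)
        scores = [
            assign_mos(_mk_events([100, 500, 900], nadir=nad), clusters).score
            for nad in (92, 88, 83, 78)
        ]
        assert scores == sorted(scores)
        assert scores == [1, 2, 3, 4]
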