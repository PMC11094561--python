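"""Paradigm biomarker extraction: dwell preference, gap-overlap,
pupillary light reflex, oculomotor summaries, and stream round trips."""

import numpy as np
import pytest

from conftest import make_stream
from gazedx.events import FixationEvent, SaccadeEvent
from gazedx.metrics import (
    extract_child_biomarkers,
    fixation_and_pupil_summaries,
    gap_overlap_metrics,
    nonsocial_preference,
    plr_metrics,
    plr_metrics_stream,
    usable_task_gate,
)
from gazedx.streams import GEOPREF_AOIS, simulate_gaze_stream

DT = 1000.0 / 120.0


def dwell_stream(n_non, n_soc, rate=100.0):
    x = np.r_[np.full(n_non, -7.0), np.full(n_soc, 7.0)]
    return make_stream(x, np.zeros(n_non + n_soc), rate=rate)


class TestNonsocialPreference:
    def test_thirty_seventy_split(self):
        assert nonsocial_preference(dwell_stream(30, 70), GEOPREF_AOIS) == pytest.approx(30.0)

    def test_all_nonsocial(self):
        assert nonsocial_preference(dwell_stream(50, 0), GEOPREF_AOIS) == pytest.approx(100.0)

    def test_out_of_aoi_excluded_and_zero_dwell_missing(self):
        s = make_stream(np.zeros(40), np.zeros(40))  # center: in neither AOI
        assert np.isnan(nonsocial_preference(s, GEOPREF_AOIS))
        mixed = make_stream(np.r_[np.full(10, -7.0), np.zeros(30)], np.zeros(40))
        assert nonsocial_preference(mixed, GEOPREF_AOIS) == pytest.approx(100.0)

    def test_missing_aoi_rejected(self):
        with pytest.raises(ValueError, match="social"):
            nonsocial_preference(dwell_stream(5, 5), {"nonsocial": (-12, -2, -4, 4)})

    def test_roundtrip_latent_preference(self):
        stream, ann = simulate_gaze_stream(
            "geopref", {"nonsocial_preference_pct": 46.2}, noise_sd=0.0, seed=0)
        got = nonsocial_preference(stream, ann["aois"])
        assert got == pytest.approx(ann["realized"]["nonsocial_preference_pct"])
        assert got == pytest.approx(46.2, abs=0.05)


class TestGapOverlap:
    def test_rt_difference_and_noshift_difference(self):
        gt = {"overlap_gap_rt_ms": 100.0, "no_shift_gap_effect_pct": 10.0,
              "gap_rt_ms": 300.0, "gap_no_shift_pct": 10.0}
        stream, ann = simulate_gaze_stream("gap_overlap", gt, noise_sd=0.0, seed=1)
        rt, ns = gap_overlap_metrics(stream, ann)
        assert rt == pytest.approx(ann["realized"]["overlap_gap_rt_ms"])
        assert rt == pytest.approx(100.0, abs=DT)
        assert ns == pytest.approx(10.0)

    def test_equal_noshift_rates_give_zero_and_sign_can_flip(self):
        gt0 = {"overlap_gap_rt_ms": 50.0, "no_shift_gap_effect_pct": 0.0}
        stream, ann = simulate_gaze_stream("gap_overlap", gt0, noise_sd=0.0, seed=2)
        _, ns = gap_overlap_metrics(stream, ann)
        assert ns == pytest.approx(0.0)
        gtn = {"overlap_gap_rt_ms": 50.0, "no_shift_gap_effect_pct": -25.0,
               "gap_no_shift_pct": 30.0}
        stream, ann = simulate_gaze_stream("gap_overlap", gtn, noise_sd=0.0, seed=3)
        _, ns = gap_overlap_metrics(stream, ann)
        assert ns == pytest.approx(-25.0)

    def test_time_translation_invariance(self):
        gt = {"overlap_gap_rt_ms": 75.0, "no_shift_gap_effect_pct": 5.0}
        stream, ann = simulate_gaze_stream("gap_overlap", gt, noise_sd=0.0, seed=4)
        base = gap_overlap_metrics(stream, ann)
        shift = 12345.0
        moved = make_stream(stream.x_deg, stream.y_deg, rate=stream.sampling_rate,
                            pupil=stream.pupil_mm, valid=stream.valid,
                            t0=stream.time_ms[0] + shift)
        ann2 = dict(ann)
        ann2["trials"] = [
            {**tr, "t0_ms": tr["t0_ms"] + shift, "t1_ms": tr["t1_ms"] + shift,
             "onset_ms": tr["onset_ms"] + shift}
            for tr in ann["trials"]
        ]
        assert gap_overlap_metrics(moved, ann2) == pytest.approx(base)


class TestPLR:
    def test_amplitude_from_baseline_and_trough(self):
        t = np.arange(0, 3000, 10.0)
        p = np.full_like(t, 5.0)
        p[(t >= 1270)] = 3.5
        lat, amp = plr_metrics(t, p, flash_onset_ms=1000.0)
        assert amp == pytest.approx(30.0)

    def test_flat_trace_missing(self):
        t = np.arange(0, 3000, 10.0)
        lat, amp = plr_metrics(t, np.full_like(t, 5.0), flash_onset_ms=1000.0)
        assert np.isnan(lat) and np.isnan(amp)

    def test_noiseless_roundtrip_latency_within_one_sample(self):
        gt = {"plr_latency_ms": 270.0, "plr_amplitude_pct": 30.0, "baseline_mm": 5.0}
        stream, ann = simulate_gaze_stream("plr", gt, noise_sd=0.0, seed=5)
        lat, amp = plr_metrics_stream(stream, ann)
        assert abs(lat - 270.0) <= DT
        assert amp == pytest.approx(30.0, abs=0.01)
        # trace minimum is exactly 70% of baseline in the noiseless render
        assert stream.pupil_mm.min() == pytest.approx(0.70 * 5.0)


class TestSummariesAndGate:
    def test_mean_fixation_duration(self):
        fx = [FixationEvent(0, 400, 0, 0, 0, 0), FixationEvent(500, 1100, 0, 0, 0, 0)]
        out = fixation_and_pupil_summaries(fx, [], make_stream(np.zeros(5), None))
        assert out["mean_fixation_duration_ms"] == pytest.approx(500.0)

    def test_tonic_pupil_constant(self):
        s = make_stream(np.zeros(50), None, pupil=np.full(50, 4.2))
        out = fixation_and_pupil_summaries([], [], s)
        assert out["tonic_pupil_mm"] == pytest.approx(4.2)
        assert np.isnan(out["mean_fixation_duration_ms"])

    def test_saccade_summaries(self):
        sc = [SaccadeEvent(0, 30, 6.0), SaccadeEvent(100, 150, 8.0)]
        out = fixation_and_pupil_summaries([], sc, make_stream(np.zeros(5), None))
        assert out["mean_saccade_amplitude_deg"] == pytest.approx(7.0)
        assert out["mean_saccade_duration_ms"] == pytest.approx(40.0)

    def test_usable_gate_inclusive_boundary(self):
        n = 10
        valid = np.r_[np.ones(5, bool), np.zeros(5, bool)]
        s = make_stream(np.zeros(n), None, valid=valid)
        assert usable_task_gate(s, min_valid_fraction=0.5)  # exactly at threshold
        assert not usable_task_gate(s, min_valid_fraction=0.51)
        assert not usable_task_gate(None)
        s_none = make_stream(np.zeros(n), None, valid=np.zeros(n, bool))
        assert not usable_task_gate(s_none)
        s_all = make_stream(np.zeros(n), None)
        assert usable_task_gate(s_all)


class TestFixationTaskRoundtrip:
    def test_resting_recovery_within_five_percent(self):
        gt = {"mean_fixation_duration_ms": 528.0, "tonic_pupil_mm": 4.4,
              "saccade_amplitude_deg": 5.5, "saccade_duration_ms": 40.0,
              "baseline_mm": 4.4}
        stream, ann = simulate_gaze_stream("resting", gt, noise_sd=0.08, seed=6)
        out = extract_child_biomarkers({"resting": (stream, ann)})
        true_mean = ann["realized"]["mean_fixation_duration_ms"]
        assert out["resting_fixation_duration_ms"] == pytest.approx(true_mean, rel=0.05)
        assert out["tonic_pupil_mm"] == pytest.approx(4.4, abs=0.01)
        assert out["saccade_amplitude_deg"] == pytest.approx(
            ann["realized"]["saccade_amplitude_deg"], rel=0.1)

    def test_unknown_paradigm_rejected(self):
        with pytest.raises(ValueError, match="unknown paradigm"):
            simulate_gaze_stream("smooth_pursuit", {})

    def test_missing_tasks_leave_metrics_nan(self):
        out = extract_child_biomarkers({})
        assert all(np.isnan(v) for v in out.values())


def test_percentage_metrics_respect_ranges():
    rng = np.random.default_rng(8)
    for _ in range(20):
        n = int(rng.integers(10, 200))
        x = rng.uniform(-15, 15, n)
        s = make_stream(x, rng.uniform(-6, 6, n))
        p = nonsocial_preference(s, GEOPREF_AOIS)
        assert np.isnan(p) or 0.0 <= p <= 100.0
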