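"""Biomarker computation for the five eye-tracking paradigms.

Six candidate biomarkers are extracted per child:

* nonsocial preference (%) — share of in-AOI dwell time spent on the
  nonsocial (geometric) video during the paired-preference task;
* no-shift gap effect (percentage points) — overlap-minus-gap difference
  in the percentage of trials with no qualifying gaze shift to the
  peripheral target (the signed difference reading is adopted: the
  observed range of this metric spans negative values, which a
  single-condition percentage could not produce);
* overlap-gap RT (ms) — mean saccadic reaction-time cost of
  disengaging an already-fixated central stimulus;
* pupillary light reflex latency (ms) and amplitude (%) — time from
  flash to constriction onset, and relative constriction from baseline;
* resting / exploration fixation durations (ms) — plus tonic pupil size
  and saccade amplitude/duration as auxiliary metrics.

Reaction times use a [100, 1000] ms validity window: shifts earlier than
100 ms after target onset are treated as anticipatory and the trial is
discarded; a trial with no qualifying shift within 1000 ms counts as
no-shift.  PLR constriction onset is the last sample before the smoothed
pupil velocity (trailing moving average) stays below a negative
criterion for a sustained run of samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import AUX_METRICS, BIOMARKERS
from .events import GazeStream, detect_fixations, detect_saccades

__all__ = [
    "nonsocial_preference",
    "gap_overlap_metrics",
    "plr_metrics",
    "plr_metrics_stream",
    "fixation_and_pupil_summaries",
    "usable_task_gate",
    "extract_child_biomarkers",
    "extract_cohort",
]

RT_WINDOW_MS = (100.0, 1000.0)


def _in_rect(x, y, rect):
    x0, x1, y0, y1 = rect
    return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)


def nonsocial_preference(stream: GazeStream, aois: dict) -> float:
    """Percent of in-AOI dwell on the nonsocial side.

    ``aois`` maps ``"nonsocial"``/``"social"`` to ``(x0, x1, y0, y1)``
    rectangles in degrees.  Samples outside both AOIs (or invalid) are
    excluded from the denominator; zero total AOI dwell yields NaN.
    """
    for k in ("nonsocial", "social"):
        if k not in aois:
            raise ValueError(f"AOI {k!r} not defined")
    m = stream.valid
    x, y = stream.x_deg[m], stream.y_deg[m]
    n_non = int(np.sum(_in_rect(x, y, aois["nonsocial"])))
    n_soc = int(np.sum(_in_rect(x, y, aois["social"])))
    total = n_non + n_soc
    if total == 0:
        return float("nan")
    return 100.0 * n_non / total


def _trial_rt(stream: GazeStream, trial: dict, target_aoi) -> tuple[str, float]:
    """Classify one gap/overlap trial.

    Returns ``("shift", rt)``, ``("no_shift", nan)`` or
    ``("anticipatory", nan)``.
    """
    w = stream.slice_time(trial["onset_ms"], trial["t1_ms"])
    m = w.valid & _in_rect(w.x_deg, w.y_deg, target_aoi)
    if not np.any(m):
        return "no_shift", float("nan")
    rt = float(w.time_ms[m][0] - trial["onset_ms"])
    if rt < RT_WINDOW_MS[0]:
        return "anticipatory", float("nan")
    if rt > RT_WINDOW_MS[1]:
        return "no_shift", float("nan")
    return "shift", rt


def gap_overlap_metrics(stream: GazeStream, annotation: dict):
    """Overlap-gap RT difference and no-shift gap effect.

    Per-trial RT is the latency of the first sample inside the target
    AOI after target onset, kept if inside the validity window.
    ``overlap_gap_rt_ms`` is mean RT(overlap) - mean RT(gap);
    ``no_shift_gap_effect_pct`` is the percentage-point difference in
    no-shift trials, overlap minus gap.  A condition with no valid
    trials leaves the affected metric NaN.
    """
    target = annotation["target_aoi"]
    rts = {"gap": [], "overlap": []}
    noshift = {"gap": 0, "overlap": 0}
    counted = {"gap": 0, "overlap": 0}
    for trial in annotation["trials"]:
        cond = trial["condition"]
        kind, rt = _trial_rt(stream, trial, target)
        if kind == "anticipatory":
            continue
        counted[cond] += 1
        if kind == "shift":
            rts[cond].append(rt)
        else:
            noshift[cond] += 1

    def mean_rt(c):
        return float(np.mean(rts[c])) if rts[c] else float("nan")

    def ns_pct(c):
        return 100.0 * noshift[c] / counted[c] if counted[c] else float("nan")

    rt_diff = mean_rt("overlap") - mean_rt("gap")
    ns_diff = ns_pct("overlap") - ns_pct("gap")
    return float(rt_diff), float(ns_diff)


def plr_metrics(
    time_ms: np.ndarray,
    pupil_mm: np.ndarray,
    flash_onset_ms: float,
    baseline_window_ms: float = 200.0,
    velocity_criterion_mm_s: float = -0.3,
    sustain_samples: int = 3,
    smooth_ms: float = 50.0,
    search_window_ms: float = 1000.0,
) -> tuple[float, float]:
    """Latency and amplitude of the pupillary light reflex for one trial.

    Baseline is the mean pupil over ``baseline_window_ms`` before the
    flash.  Constriction onset is the last sample before the first run
    of ``sustain_samples`` consecutive samples whose smoothed velocity
    (trailing moving average of width ``smooth_ms``) falls below
    ``velocity_criterion_mm_s``; latency is onset minus flash time.
    Amplitude is ``100 * (baseline - minimum) / baseline``.  Returns
    ``(nan, nan)`` when no constriction is detected in the search
    window.
    """
    t = np.asarray(time_ms, float)
    p = np.asarray(pupil_mm, float)
    base_m = (t >= flash_onset_ms - baseline_window_ms) & (t < flash_onset_ms)
    if not np.any(base_m):
        return float("nan"), float("nan")
    baseline = float(np.mean(p[base_m]))
    if baseline <= 0:
        return float("nan"), float("nan")

    dt = float(np.median(np.diff(t)))
    w = max(int(round(smooth_ms / dt)), 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(p, kernel, mode="full")[: len(p)]  # trailing average
    smooth[: w - 1] = p[: w - 1]  # warm-up: not enough history
    vel = np.empty_like(smooth)
    vel[0] = 0.0
    vel[1:] = np.diff(smooth) / (dt / 1000.0)  # mm/s

    search = (t >= flash_onset_ms) & (t <= flash_onset_ms + search_window_ms)
    idx = np.flatnonzero(search)
    below = vel < velocity_criterion_mm_s
    onset_i = None
    run = 0
    for i in idx:
        run = run + 1 if below[i] else 0
        if run >= sustain_samples:
            onset_i = i - sustain_samples + 1
            break
    if onset_i is None:
        return float("nan"), float("nan")
    latency = float(t[max(onset_i - 1, 0)] - flash_onset_ms)

    post = (t >= flash_onset_ms) & (t <= flash_onset_ms + 1500.0)
    trough = float(np.min(p[post]))
    amplitude = 100.0 * (baseline - trough) / baseline
    return latency, amplitude


def plr_metrics_stream(stream: GazeStream, annotation: dict, **kwargs):
    """Mean PLR latency/amplitude over a multi-trial stream."""
    lats, amps = [], []
    for trial in annotation["trials"]:
        w = stream.slice_time(trial["t0_ms"], trial["t1_ms"])
        m = w.valid
        lat, amp = plr_metrics(w.time_ms[m], w.pupil_mm[m], trial["flash_ms"], **kwargs)
        if np.isfinite(lat):
            lats.append(lat)
            amps.append(amp)
    if not lats:
        return float("nan"), float("nan")
    return float(np.mean(lats)), float(np.mean(amps))


def fixation_and_pupil_summaries(fixations, saccades, stream: GazeStream) -> dict:
    """Arithmetic means of oculomotor events and valid pupil samples."""
    out = {
        "mean_fixation_duration_ms": float("nan"),
        "mean_saccade_amplitude_deg": float("nan"),
        "mean_saccade_duration_ms": float("nan"),
        "tonic_pupil_mm": float("nan"),
    }
    if fixations:
        out["mean_fixation_duration_ms"] = float(
            np.mean([f.duration_ms for f in fixations])
        )
    if saccades:
        out["mean_saccade_amplitude_deg"] = float(
            np.mean([s.amplitude_deg for s in saccades])
        )
        out["mean_saccade_duration_ms"] = float(
            np.mean([s.duration_ms for s in saccades])
        )
    m = stream.valid & np.isfinite(stream.pupil_mm)
    if np.any(m):
        out["tonic_pupil_mm"] = float(np.mean(stream.pupil_mm[m]))
    return out


def usable_task_gate(
    stream: GazeStream | None,
    min_valid_fraction: float = 0.5,
    n_valid_trials: int | None = None,
    min_valid_trials: int = 1,
) -> bool:
    """Whether a task provides usable data (thresholds are inclusive)."""
    if stream is None or len(stream) == 0:
        return False
    frac = float(np.mean(stream.valid))
    if frac < min_valid_fraction:
        return False
    if n_valid_trials is not None and n_valid_trials < min_valid_trials:
        return False
    return True


def extract_child_biomarkers(
    task_streams: dict,
    dispersion_deg: float = 1.0,
    min_duration_ms: float = 100.0,
    min_valid_fraction: float = 0.5,
) -> dict:
    """Run the full extraction for one child.

    ``task_streams`` maps paradigm name to ``(GazeStream, annotation)``;
    absent or unusable tasks leave their metrics NaN.  Returns a dict
    with one entry per biomarker/auxiliary metric.
    """
    out = {k: float("nan") for k in BIOMARKERS + AUX_METRICS}

    def usable(task):
        if task not in task_streams:
            return False
        return usable_task_gate(task_streams[task][0], min_valid_fraction)

    if usable("geopref"):
        stream, ann = task_streams["geopref"]
        out["nonsocial_preference_pct"] = nonsocial_preference(stream, ann["aois"])
    if usable("gap_overlap"):
        stream, ann = task_streams["gap_overlap"]
        rt, ns = gap_overlap_metrics(stream, ann)
        out["overlap_gap_rt_ms"] = rt
        out["no_shift_gap_effect_pct"] = ns
    if usable("plr"):
        stream, ann = task_streams["plr"]
        lat, amp = plr_metrics_stream(stream, ann)
        out["plr_latency_ms"] = lat
        out["plr_amplitude_pct"] = amp
    for task, prefix in (("resting", "resting"), ("exploration", "exploration")):
        if not usable(task):
            continue
        stream, _ = task_streams[task]
        fixes = detect_fixations(stream, dispersion_deg, min_duration_ms)
        saccs = detect_saccades(stream, fixes)
        summ = fixation_and_pupil_summaries(fixes, saccs, stream)
        out[f"{prefix}_fixation_duration_ms"] = summ["mean_fixation_duration_ms"]
        if task == "resting":
            out["tonic_pupil_mm"] = summ["tonic_pupil_mm"]
            out["saccade_amplitude_deg"] = summ["mean_saccade_amplitude_deg"]
            out["saccade_duration_ms"] = summ["mean_saccade_duration_ms"]
    return out


def extract_cohort(streams: dict, **kwargs) -> pd.DataFrame:
    """Extract biomarkers for every child; one row per ``child_id``."""
    rows = []
    for child_id, task_streams in streams.items():
        row = {"child_id": child_id}
        row.update(extract_child_biomarkers(task_streams, **kwargs))
        rows.append(row)
    return pd.DataFrame(rows)
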