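"""Raw gaze/pupil stream synthesis with known ground truth.

Each of the five task paradigms is rendered generically from latent
per-child parameters:

* ``geopref`` — side-by-side social/nonsocial areas of interest (AOIs);
  dwell is allocated so the nonsocial looking percentage equals the
  latent preference (to sample quantization).
* ``gap_overlap`` — trials with a central fixation and a peripheral
  target; shift trials jump to the target at the latent reaction time,
  no-shift trials never leave the center.
* ``plr`` — pupil traces with a flat baseline, a linear constriction of
  the latent amplitude beginning at the latent latency after the flash,
  a plateau and a recovery.
* ``resting`` / ``exploration`` — sequences of fixations with latent
  mean duration and saccade amplitude/duration, constant (tonic) pupil.

Discrete sampling means some latent values are only realizable up to
quantization (sample period; whole trials for no-shift percentages).
Every renderer therefore returns the *realized* ground truth alongside
the stream, and cohort-level rendering writes realized values back into
the cohort table so that downstream recovery is measured against what
the streams actually contain.

Fixation jitter is isotropic Gaussian; the default of 0.08 degrees SD is
small enough that dispersion-based fixation detection at a 1-degree
threshold never splits a rendered fixation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import TASK_METRICS
from .events import GazeStream

__all__ = ["simulate_gaze_stream", "render_cohort_streams", "PARADIGMS"]

PARADIGMS = ("geopref", "gap_overlap", "plr", "resting", "exploration")

#: Screen AOIs for the preference task, degrees: (x0, x1, y0, y1).
GEOPREF_AOIS = {
    "nonsocial": (-12.0, -2.0, -4.0, 4.0),
    "social": (2.0, 12.0, -4.0, 4.0),
}
GAP_TARGET_AOI = (7.0, 13.0, -3.0, 3.0)  # centered on (10, 0)

DEFAULT_DURATIONS = {
    "geopref_ms": 30000.0,
    "gap_trial_ms": 1600.0,
    "gap_onset_ms": 400.0,
    "gap_n_trials": 20,
    "plr_trial_ms": 3500.0,
    "plr_flash_ms": 1000.0,
    "plr_n_trials": 4,
    "resting_ms": 30000.0,
    "exploration_ms": 20000.0,
}


def _q(value_ms: float, dt: float) -> float:
    """Quantize a time to the sample grid."""
    return round(value_ms / dt) * dt


def _jitter(rng, n, sd):
    return rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)


def _render_geopref(gt, rate, noise_sd, rng, cfg):
    dt = 1000.0 / rate
    n = int(round(cfg["geopref_ms"] / dt))
    p = float(gt["nonsocial_preference_pct"])
    k = int(round(p / 100.0 * n))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    # fill each side in ~600 ms chunks with a per-chunk offset inside the AOI
    chunk = max(int(round(600.0 / dt)), 1)
    for start, stop, aoi in ((0, k, "nonsocial"), (k, n, "social")):
        x0, x1, y0, y1 = GEOPREF_AOIS[aoi]
        cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
        for i in range(start, stop, chunk):
            j = min(i + chunk, stop)
            x[i:j] = cx + rng.uniform(-2, 2)
            y[i:j] = cy + rng.uniform(-2, 2)
    x += _jitter(rng, n, noise_sd)
    y += _jitter(rng, n, noise_sd)
    stream = GazeStream(t, x, y, np.full(n, 4.5), np.ones(n, bool), rate)
    ann = {
        "paradigm": "geopref",
        "aois": dict(GEOPREF_AOIS),
        "realized": {"nonsocial_preference_pct": 100.0 * k / n if n else float("nan")},
    }
    return stream, ann


def _render_gap_overlap(gt, rate, noise_sd, rng, cfg):
    dt = 1000.0 / rate
    n_trials = int(cfg["gap_n_trials"])
    trial_n = int(round(cfg["gap_trial_ms"] / dt))
    onset = _q(cfg["gap_onset_ms"], dt)

    gap_rt = _q(float(gt.get("gap_rt_ms", 300.0)), dt)
    ovl_rt = _q(float(gt.get("gap_rt_ms", 300.0)) + float(gt["overlap_gap_rt_ms"]), dt)
    r_gap = float(gt.get("gap_no_shift_pct", 10.0))
    r_ovl = float(np.clip(r_gap + float(gt["no_shift_gap_effect_pct"]), 0.0, 100.0))
    m_gap = int(round(r_gap / 100.0 * n_trials))
    m_ovl = int(round(r_ovl / 100.0 * n_trials))

    plan = []
    for cond, m, rt in (("gap", m_gap, gap_rt), ("overlap", m_ovl, ovl_rt)):
        shifts = [False] * m + [True] * (n_trials - m)
        rng.shuffle(shifts)
        plan.extend((cond, s, rt) for s in shifts)
    rng.shuffle(plan)

    tx, ty = 10.0, 0.0
    times, xs, ys = [], [], []
    trials = []
    for idx, (cond, shifts, rt) in enumerate(plan):
        t0 = idx * trial_n * dt
        t_local = np.arange(trial_n) * dt
        x = np.zeros(trial_n)
        y = np.zeros(trial_n)
        if shifts:
            at_target = t_local >= onset + rt
            x[at_target] = tx
            y[at_target] = ty
        x += _jitter(rng, trial_n, noise_sd)
        y += _jitter(rng, trial_n, noise_sd)
        times.append(t0 + t_local)
        xs.append(x)
        ys.append(y)
        trials.append(
            {
                "condition": cond,
                "t0_ms": t0,
                "t1_ms": t0 + trial_n * dt,
                "onset_ms": t0 + onset,
                "true_rt_ms": rt if shifts else None,
            }
        )
    t = np.concatenate(times)
    n = len(t)
    stream = GazeStream(
        t, np.concatenate(xs), np.concatenate(ys),
        np.full(n, 4.5), np.ones(n, bool), rate,
    )
    ann = {
        "paradigm": "gap_overlap",
        "target_aoi": GAP_TARGET_AOI,
        "trials": trials,
        "realized": {
            "overlap_gap_rt_ms": ovl_rt - gap_rt,
            "no_shift_gap_effect_pct": 100.0 * (m_ovl - m_gap) / n_trials,
        },
    }
    return stream, ann


def _render_plr(gt, rate, noise_sd, rng, cfg):
    dt = 1000.0 / rate
    n_trials = int(cfg["plr_n_trials"])
    trial_n = int(round(cfg["plr_trial_ms"] / dt))
    flash = _q(cfg["plr_flash_ms"], dt)
    lat = _q(float(gt["plr_latency_ms"]), dt)
    amp = float(gt["plr_amplitude_pct"])
    base = float(gt.get("baseline_mm", 4.5))
    pupil_noise = 0.01 * noise_sd  # mm of pupil noise per degree of gaze noise

    t_local = np.arange(trial_n) * dt
    onset = flash + lat
    trough = base * (1.0 - amp / 100.0)
    # piecewise-linear: baseline | 400 ms constriction | 300 ms plateau |
    # 800 ms recovery | baseline
    knots_t = [0.0, onset, onset + 400.0, onset + 700.0, onset + 1500.0, trial_n * dt]
    knots_p = [base, base, trough, trough, base, base]
    trace = np.interp(t_local, knots_t, knots_p)

    times, xs, ys, ps = [], [], [], []
    trials = []
    for idx in range(n_trials):
        t0 = idx * trial_n * dt
        times.append(t0 + t_local)
        xs.append(_jitter(rng, trial_n, noise_sd))
        ys.append(_jitter(rng, trial_n, noise_sd))
        p = trace.copy()
        if pupil_noise > 0:
            p = p + rng.normal(0.0, pupil_noise, size=trial_n)
        ps.append(p)
        trials.append({"t0_ms": t0, "t1_ms": t0 + trial_n * dt, "flash_ms": t0 + flash})
    t = np.concatenate(times)
    n = len(t)
    stream = GazeStream(
        t, np.concatenate(xs), np.concatenate(ys),
        np.concatenate(ps), np.ones(n, bool), rate,
    )
    ann = {
        "paradigm": "plr",
        "trials": trials,
        "realized": {"plr_latency_ms": lat, "plr_amplitude_pct": amp},
    }
    return stream, ann


def _render_fixation_task(paradigm, gt, rate, noise_sd, rng, cfg):
    dt = 1000.0 / rate
    duration_key = "resting_ms" if paradigm == "resting" else "exploration_ms"
    total_n = int(round(cfg[duration_key] / dt))
    mu = float(gt["mean_fixation_duration_ms"])
    amp_mu = float(gt.get("saccade_amplitude_deg", 5.5))
    sac_dur = float(gt.get("saccade_duration_ms", 40.0))
    pupil = float(gt.get("tonic_pupil_mm", 4.5))
    pupil_noise = 0.01 * noise_sd

    k_transit = max(int(round(sac_dur / dt)) - 1, 1)
    x_parts, y_parts = [], []
    durations, amplitudes = [], []
    pos = np.array([rng.uniform(-6, 6), rng.uniform(-4, 4)])
    n_done = 0
    # render whole fixations until the nominal duration is reached; the
    # stream may overshoot by a fraction of one fixation, which keeps
    # every rendered fixation (and its realized duration) intact
    while True:
        lo, hi = 150.0, max(3 * mu, 450.0)
        d = float(np.clip(rng.normal(mu, 0.25 * mu), lo, hi))
        n_fix = max(int(round(d / dt)), int(np.ceil(lo / dt)))
        x_parts.append(np.full(n_fix, pos[0]))
        y_parts.append(np.full(n_fix, pos[1]))
        durations.append((n_fix - 1) * dt)
        n_done += n_fix
        if n_done >= total_n:
            break
        # saccade to a new point >= 3 degrees away, inside the screen
        for _ in range(100):
            amp = float(np.clip(rng.normal(amp_mu, 0.15 * amp_mu), 3.0, 12.0))
            ang = rng.uniform(0, 2 * np.pi)
            new = pos + amp * np.array([np.cos(ang), np.sin(ang)])
            if -10 <= new[0] <= 10 and -8 <= new[1] <= 8:
                break
        amplitudes.append(float(np.hypot(*(new - pos))))
        frac = np.arange(1, k_transit + 1) / (k_transit + 1)
        x_parts.append(pos[0] + frac * (new[0] - pos[0]))
        y_parts.append(pos[1] + frac * (new[1] - pos[1]))
        n_done += k_transit
        pos = new

    n = n_done
    x = np.concatenate(x_parts) + _jitter(rng, n, noise_sd)
    y = np.concatenate(y_parts) + _jitter(rng, n, noise_sd)
    t = np.arange(n) * dt
    p = np.full(n, pupil)
    if pupil_noise > 0:
        p = p + rng.normal(0.0, pupil_noise, size=n)
    stream = GazeStream(t, x, y, p, np.ones(n, bool), rate)
    realized = {"mean_fixation_duration_ms": float(np.mean(durations))}
    if paradigm == "resting":
        realized.update(
            tonic_pupil_mm=pupil,
            saccade_amplitude_deg=float(np.mean(amplitudes)) if amplitudes else float("nan"),
            saccade_duration_ms=(k_transit + 1) * dt,
        )
    ann = {"paradigm": paradigm, "realized": realized}
    return stream, ann


def simulate_gaze_stream(
    paradigm: str,
    ground_truth: dict,
    sampling_rate: float = 120.0,
    noise_sd: float = 0.08,
    seed=None,
    config: dict | None = None,
):
    """Render one task's gaze/pupil stream from latent parameters.

    Parameters
    ----------
    paradigm : str
        One of ``geopref``, ``gap_overlap``, ``plr``, ``resting``,
        ``exploration``.
    ground_truth : dict
        Latent parameters for the paradigm (see module docstring).
    noise_sd : float
        Isotropic gaze jitter SD in degrees; pupil noise is coupled at
        0.01 mm per degree, so ``noise_sd=0`` renders noiseless streams.
    seed : int, numpy Generator, or None
        Randomness source for jitter and trial ordering.

    Returns
    -------
    (GazeStream, dict)
        The stream and an annotation dict with trial/AOI structure and a
        ``"realized"`` entry: the ground truth as actually rendered
        (latent values quantized to the sample grid / trial counts).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = dict(DEFAULT_DURATIONS)
    if config:
        cfg.update(config)
    if paradigm == "geopref":
        return _render_geopref(ground_truth, sampling_rate, noise_sd, rng, cfg)
    if paradigm == "gap_overlap":
        return _render_gap_overlap(ground_truth, sampling_rate, noise_sd, rng, cfg)
    if paradigm == "plr":
        return _render_plr(ground_truth, sampling_rate, noise_sd, rng, cfg)
    if paradigm in ("resting", "exploration"):
        return _render_fixation_task(paradigm, ground_truth, sampling_rate, noise_sd, rng, cfg)
    raise ValueError(f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}")


def write_stream(stream: GazeStream, annotation: dict, prefix) -> None:
    """Persist one trial stream as ``<prefix>.csv`` plus a JSON sidecar of
    trial/AOI annotations and realized ground truth."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    stream.to_dataframe().to_csv(prefix.with_suffix(".csv"), index=False)
    meta = dict(annotation, sampling_rate=stream.sampling_rate)
    prefix.with_suffix(".json").write_text(
        json.dumps(meta, indent=2, default=float) + "\n"
    )


def read_stream(prefix) -> tuple[GazeStream, dict]:
    """Inverse of :func:`write_stream`."""
    import json
    from pathlib import Path

    prefix = Path(prefix)
    ann = json.loads(prefix.with_suffix(".json").read_text())
    stream = GazeStream.from_dataframe(
        pd.read_csv(prefix.with_suffix(".csv")), ann["sampling_rate"]
    )
    return stream, ann


def _ground_truth_for(row: pd.Series, task: str) -> dict | None:
    cols = TASK_METRICS[task]
    if any(pd.isna(row[c]) for c in cols):
        return None
    gt = {c: float(row[c]) for c in cols}
    if task == "resting":
        gt["baseline_mm"] = gt["tonic_pupil_mm"]
    if task == "exploration":
        gt["mean_fixation_duration_ms"] = gt.pop("exploration_fixation_duration_ms")
    if task == "resting":
        gt["mean_fixation_duration_ms"] = gt.pop("resting_fixation_duration_ms")
    return gt


def render_cohort_streams(
    table: pd.DataFrame,
    sampling_rate: float = 120.0,
    noise_sd: float = 0.08,
    seed: int = 0,
    config: dict | None = None,
):
    """Render gaze streams for every usable task of every child.

    Returns ``(streams, realized_table)`` where ``streams`` maps
    ``child_id -> {task: (GazeStream, annotations)}`` and
    ``realized_table`` is a copy of the cohort table with each rendered
    metric replaced by the realized (quantization-adjusted) ground truth
    embedded in the streams.  Missing tasks stay missing.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(table))
    streams: dict[str, dict] = {}
    realized = table.copy()
    for (idx, row), child_ss in zip(table.iterrows(), child_seeds):
        rng = np.random.default_rng(child_ss)
        per_child: dict[str, tuple] = {}
        for task in TASK_METRICS:
            gt = _ground_truth_for(row, task)
            if gt is None:
                continue
            stream, ann = simulate_gaze_stream(
                task, gt, sampling_rate, noise_sd, rng, config
            )
            per_child[task] = (stream, ann)
            real = ann["realized"]
            for col in TASK_METRICS[task]:
                key = col
                if task == "resting" and col == "resting_fixation_duration_ms":
                    key = "mean_fixation_duration_ms"
                if task == "exploration" and col == "exploration_fixation_duration_ms":
                    key = "mean_fixation_duration_ms"
                if key in real:
                    realized.loc[idx, col] = real[key]
        streams[row["child_id"]] = per_child
    realized.attrs.update(table.attrs)
    return streams, realized
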