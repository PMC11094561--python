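"""Fixation/saccade event detection and eye-tracking quality-control indices.

Gaze is represented in degrees of visual angle with a screen-centered
origin.  Fixations are identified with the dispersion-threshold algorithm
(I-DT): maximal runs of samples whose spatial spread, measured as
``(max(x) - min(x)) + (max(y) - min(y))``, stays within a dispersion
threshold and whose temporal span meets a minimum duration.  Invalid
samples (blinks, track loss) shorter than a bridging threshold are filled
by linear interpolation; longer gaps break the stream into independent
segments that are processed separately.

Quality control follows two conventional indices: *accuracy* is the
angular displacement between the gaze centroid and a known drift-check
target, and *precision* is the root mean square of successive
sample-to-sample Euclidean distances within fixations (lower = steadier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GazeStream",
    "FixationEvent",
    "SaccadeEvent",
    "QCRecord",
    "detect_fixations",
    "detect_saccades",
    "drift_accuracy",
    "precision_rms",
    "pooled_precision_rms",
]


@dataclass
class GazeStream:
    """Time-ordered gaze/pupil samples for one trial or task block.

    Attributes
    ----------
    time_ms, x_deg, y_deg, pupil_mm : ndarray
        Sample times (strictly increasing), gaze position in degrees of
        visual angle, and pupil diameter in millimetres.
    valid : ndarray of bool
        Per-sample validity flag (False for blinks / lost track).
    sampling_rate : float
        Nominal sampling rate in Hz.
    """

    time_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    pupil_mm: np.ndarray
    valid: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        self.pupil_mm = np.asarray(self.pupil_mm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = len(self.time_ms)
        for arr, name in (
            (self.x_deg, "x_deg"),
            (self.y_deg, "y_deg"),
            (self.pupil_mm, "pupil_mm"),
            (self.valid, "valid"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != time length {n}")
        if n > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_ms)

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    def slice_time(self, t0: float, t1: float) -> "GazeStream":
        """Samples with t0 <= time < t1."""
        m = (self.time_ms >= t0) & (self.time_ms < t1)
        return GazeStream(
            self.time_ms[m], self.x_deg[m], self.y_deg[m],
            self.pupil_mm[m], self.valid[m], self.sampling_rate,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "pupil_mm": self.pupil_mm,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sampling_rate: float) -> "GazeStream":
        return cls(
            df["time_ms"].to_numpy(),
            df["x_deg"].to_numpy(),
            df["y_deg"].to_numpy(),
            df["pupil_mm"].to_numpy(),
            df["valid"].to_numpy().astype(bool),
            sampling_rate,
        )


@dataclass
class FixationEvent:
    start_ms: float
    end_ms: float
    centroid_x_deg: float
    centroid_y_deg: float
    start_idx: int  # sample span in the source stream (inclusive)
    end_idx: int
    segment: int = 0

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class SaccadeEvent:
    start_ms: float
    end_ms: float
    amplitude_deg: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class QCRecord:
    """Session-level quality control summary."""

    drift_errors_deg: list = field(default_factory=list)
    precision_rms_deg: float = float("nan")

    @property
    def n_drift_checks(self) -> int:
        return len(self.drift_errors_deg)

    @property
    def mean_drift_error_deg(self) -> float:
        if not self.drift_errors_deg:
            return float("nan")
        return float(np.mean(self.drift_errors_deg))

    @property
    def intraindividual_sd_deg(self) -> float:
        if len(self.drift_errors_deg) < 2:
            return float("nan")
        return float(np.std(self.drift_errors_deg, ddof=1))

    def to_dict(self) -> dict:
        return {
            "drift_errors_deg": list(map(float, self.drift_errors_deg)),
            "mean_drift_error_deg": self.mean_drift_error_deg,
            "intraindividual_sd_deg": self.intraindividual_sd_deg,
            "precision_rms_deg": self.precision_rms_deg,
            "n_drift_checks": self.n_drift_checks,
        }


def events_to_dataframe(fixations, saccades=None) -> pd.DataFrame:
    """Flatten detected events to a table (one row per event)."""
    rows = [
        {"event": "fixation", "start_ms": f.start_ms, "end_ms": f.end_ms,
         "duration_ms": f.duration_ms, "x_deg": f.centroid_x_deg,
         "y_deg": f.centroid_y_deg, "amplitude_deg": float("nan")}
        for f in fixations
    ]
    for s in saccades or []:
        rows.append({"event": "saccade", "start_ms": s.start_ms,
                     "end_ms": s.end_ms, "duration_ms": s.duration_ms,
                     "x_deg": float("nan"), "y_deg": float("nan"),
                     "amplitude_deg": s.amplitude_deg})
    return pd.DataFrame(rows).sort_values("start_ms", ignore_index=True)


def _bridge_and_segment(stream: GazeStream, gap_bridge_ms: float):
    """Interpolate short invalid gaps; return (x, y, segment boundaries).

    Invalid runs spanning more than ``gap_bridge_ms`` are not bridged and
    split the stream into segments; each returned segment is a
    (start, stop) index pair (half-open) of samples that are valid or
    bridged.
    """
    t = stream.time_ms
    x = stream.x_deg.copy()
    y = stream.y_deg.copy()
    ok = stream.valid.copy()
    n = len(t)
    if n == 0:
        return x, y, []

    # locate invalid runs
    i = 0
    while i < n:
        if ok[i]:
            i += 1
            continue
        j = i
        while j < n and not ok[j]:
            j += 1
        # invalid run [i, j); bridge if bounded by valid samples and short
        if i > 0 and j < n and (t[j] - t[i - 1]) <= gap_bridge_ms:
            x[i:j] = np.interp(t[i:j], [t[i - 1], t[j]], [x[i - 1], x[j]])
            y[i:j] = np.interp(t[i:j], [t[i - 1], t[j]], [y[i - 1], y[j]])
            ok[i:j] = True
        i = j

    segments = []
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        segments.append((i, j))
        i = j
    return x, y, segments


def detect_fixations(
    stream: GazeStream,
    dispersion_deg: float = 1.0,
    min_duration_ms: float = 100.0,
    gap_bridge_ms: float = 75.0,
) -> list[FixationEvent]:
    """Identify fixations with the dispersion-threshold (I-DT) algorithm.

    A fixation is a maximal run of contiguous samples whose dispersion
    ``(max-min of x) + (max-min of y)`` is at most ``dispersion_deg`` and
    whose time span is at least ``min_duration_ms``.  Runs are grown
    greedily left to right, so events are non-overlapping and
    time-ordered.  Invalid gaps longer than ``gap_bridge_ms`` break runs;
    shorter gaps are bridged by linear interpolation.

    An empty stream yields an empty list.
    """
    if dispersion_deg <= 0 or min_duration_ms <= 0:
        raise ValueError("thresholds must be positive")
    if len(stream) == 0:
        return []

    t = stream.time_ms
    x, y, segments = _bridge_and_segment(stream, gap_bridge_ms)
    events: list[FixationEvent] = []
    for seg_id, (s0, s1) in enumerate(segments):
        i = s0
        while i < s1:
            xmin = xmax = x[i]
            ymin = ymax = y[i]
            j = i
            while j + 1 < s1:
                nx, ny = x[j + 1], y[j + 1]
                nxmin, nxmax = min(xmin, nx), max(xmax, nx)
                nymin, nymax = min(ymin, ny), max(ymax, ny)
                if (nxmax - nxmin) + (nymax - nymin) > dispersion_deg:
                    break
                xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
                j += 1
            if t[j] - t[i] >= min_duration_ms:
                events.append(
                    FixationEvent(
                        start_ms=float(t[i]),
                        end_ms=float(t[j]),
                        centroid_x_deg=float(np.mean(x[i : j + 1])),
                        centroid_y_deg=float(np.mean(y[i : j + 1])),
                        start_idx=i,
                        end_idx=j,
                        segment=seg_id,
                    )
                )
                i = j + 1
            else:
                i += 1
    return events


def detect_saccades(
    stream: GazeStream, fixations: list[FixationEvent]
) -> list[SaccadeEvent]:
    """One saccade per adjacent fixation pair within the same valid segment.

    Amplitude is the Euclidean distance between the two fixation
    centroids; duration is the gap between the first fixation's end and
    the next one's start.  Pairs separated by an unbridged invalid gap
    (different segments) produce no saccade.
    """
    out: list[SaccadeEvent] = []
    for a, b in zip(fixations, fixations[1:]):
        if a.segment != b.segment:
            continue
        amp = float(np.hypot(b.centroid_x_deg - a.centroid_x_deg,
                             b.centroid_y_deg - a.centroid_y_deg))
        out.append(SaccadeEvent(start_ms=a.end_ms, end_ms=b.start_ms, amplitude_deg=amp))
    return out


def drift_accuracy(
    check_samples: GazeStream, target_x_deg: float, target_y_deg: float
) -> float:
    """Angular displacement between the valid-sample centroid and a target.

    Returns NaN when the drift-check window contains no valid samples.
    """
    m = check_samples.valid
    if not np.any(m):
        return float("nan")
    cx = float(np.mean(check_samples.x_deg[m]))
    cy = float(np.mean(check_samples.y_deg[m]))
    return float(np.hypot(cx - target_x_deg, cy - target_y_deg))


def _successive_sq_distances(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.diff(x) ** 2 + np.diff(y) ** 2


def precision_rms(fixation_samples: GazeStream) -> float:
    """RMS of successive sample-to-sample distances within one fixation.

    Returns NaN with fewer than two valid samples.
    """
    m = fixation_samples.valid
    x = fixation_samples.x_deg[m]
    y = fixation_samples.y_deg[m]
    if len(x) < 2:
        return float("nan")
    return float(np.sqrt(np.mean(_successive_sq_distances(x, y))))


def pooled_precision_rms(
    stream: GazeStream, fixations: list[FixationEvent]
) -> float:
    """Per-child precision: RMS pooled over all fixations' successive distances."""
    sq: list[np.ndarray] = []
    for f in fixations:
        sl = slice(f.start_idx, f.end_idx + 1)
        m = stream.valid[sl]
        x = stream.x_deg[sl][m]
        y = stream.y_deg[sl][m]
        if len(x) >= 2:
            sq.append(_successive_sq_distances(x, y))
    if not sq:
        return float("nan")
    return float(np.sqrt(np.mean(np.concatenate(sq))))
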