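"""Beat segmentation and waveform-metric extraction.

Each depolarization waveform in a smoothed dF/F trace is characterized by
five metrics, all measured relative to the local baseline (mean of the two
flanking troughs):

h_max
    maximum amplitude of the waveform (peak minus baseline);
m_up, m_down
    trace slopes at the half-maximum crossings of the rising and falling
    limbs (dF/F per second, positive and negative respectively);
w
    peak width: time between the two half-maximum crossings;
h_plateau
    waveform height at the midpoint of the peak width.

Half-maximum crossing times are linearly interpolated between samples; when
several crossings exist on a limb the one nearest the peak is used, making
the metrics robust to diastolic noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .preprocess import NormalizedTrace
from .synthdata import FEATURES

#: Canonical column order of a serialized feature table.
FEATURE_COLUMNS = FEATURES + ["label", "recording_id", "membrane_id", "beat_time_s"]


@dataclass(frozen=True)
class BeatSegment:
    """One beat: its peak and the flanking troughs (indices into the trace)."""

    peak_index: int
    peak_time: float
    peak_value: float
    trough_before_index: int
    trough_before_value: float
    trough_after_index: int
    trough_after_value: float

    def __post_init__(self) -> None:
        if not self.trough_before_index < self.peak_index < self.trough_after_index:
            raise ValueError("troughs must flank the peak")
        if self.peak_value <= max(self.trough_before_value, self.trough_after_value):
            raise ValueError("peak value must exceed both trough values")


@dataclass(frozen=True)
class WaveformMetrics:
    """The five per-beat metrics plus the beat (peak) time."""

    h_max: float
    m_up: float
    m_down: float
    w: float
    h_plateau: float
    beat_time: float

    def as_dict(self) -> dict[str, float]:
        return {
            "h_max": self.h_max,
            "m_up": self.m_up,
            "m_down": self.m_down,
            "w": self.w,
            "h_plateau": self.h_plateau,
            "beat_time_s": self.beat_time,
        }


class MetricRejection(ValueError):
    """A beat whose metrics are undefined (e.g. no half-maximum crossing)."""


def estimate_noise_sd(values: np.ndarray, window: int = 151) -> float:
    """Robust baseline-noise scale via the median absolute deviation.

    The MAD (x 1.4826) is taken about a running median whose window is
    shorter than a beat, so the slowly varying waveform — whatever the beat
    duty cycle — is subtracted before the deviation is measured and the
    estimate reflects baseline noise rather than beat amplitude.
    """
    window = int(min(window, max(3, values.size // 4)))
    if window % 2 == 0:
        window += 1
    resid = values - median_filter(values, size=window, mode="nearest")
    return float(1.4826 * np.median(np.abs(resid)))


def detect_beats(
    trace: NormalizedTrace,
    min_prominence: float | None = None,
    min_separation: float = 0.2,
) -> tuple[list[BeatSegment], float]:
    """Find beats as prominent maxima; return segments and the beat rate.

    ``min_prominence`` defaults to 4x the MAD-based baseline noise sd of
    the pre-smoothing trace (recorded in the trace metadata by
    :func:`vsdwave.preprocess.smooth`).
    Troughs are the minima between consecutive peaks; the trace ends bound
    the outer troughs.  Beat rate is ``60 / median inter-peak interval``
    (beats/min), or 0 when fewer than two beats are found.  An empty result
    is valid (flat or noise-only traces).
    """
    y = trace.values
    dt = trace.line_period
    if min_prominence is None:
        # baseline noise sd: prefer the pre-smoothing estimate recorded by
        # smooth() (beat amplitudes survive smoothing, noise does not, so the
        # raw-noise scale is the conservative reference); otherwise estimate
        # from this trace directly
        sigma = trace.meta.get("noise_sd_raw")
        if sigma is None:
            sigma = estimate_noise_sd(y)
        min_prominence = max(4.0 * sigma, 1e-8 * max(np.abs(y).max(), 1.0))
    distance = max(1, int(round(min_separation / dt)))
    peaks, _ = find_peaks(y, prominence=min_prominence, distance=distance)
    if peaks.size == 0:
        return [], 0.0

    bounds = np.concatenate(([0], peaks, [y.size - 1]))
    segments = []
    for k, p in enumerate(peaks):
        lo, hi = bounds[k], bounds[k + 2]
        tb = lo + int(np.argmin(y[lo : p + 1]))
        ta = p + int(np.argmin(y[p : hi + 1]))
        if tb == p or ta == p:
            continue  # peak at a segment edge: no usable trough
        segments.append(
            BeatSegment(
                peak_index=int(p),
                peak_time=float(trace.times[p]),
                peak_value=float(y[p]),
                trough_before_index=int(tb),
                trough_before_value=float(y[tb]),
                trough_after_index=int(ta),
                trough_after_value=float(y[ta]),
            )
        )
    if len(segments) >= 2:
        intervals = np.diff([s.peak_time for s in segments])
        rate = 60.0 / float(np.median(intervals))
    else:
        rate = 0.0
    return segments, rate


def _crossing_near_peak(
    y: np.ndarray, t: np.ndarray, level: float, peak: int, bound: int, rising: bool
) -> tuple[float, int]:
    """Interpolated crossing of ``level`` nearest the peak on one limb.

    Scans outward from the peak towards ``bound``; returns the crossing time
    and the inner bracketing sample index.
    """
    if rising:
        for i in range(peak, bound, -1):  # inner sample i, outer sample i-1
            y_in, y_out = y[i], y[i - 1]
            if y_in >= level > y_out:
                frac = (y_in - level) / (y_in - y_out)
                return float(t[i] + frac * (t[i - 1] - t[i])), i
    else:
        for i in range(peak, bound):  # inner sample i, outer sample i+1
            y_in, y_out = y[i], y[i + 1]
            if y_in >= level > y_out:
                frac = (y_in - level) / (y_in - y_out)
                return float(t[i] + frac * (t[i + 1] - t[i])), i
    raise MetricRejection(
        f"no 50% crossing on the {'rising' if rising else 'falling'} limb"
    )


def _slope_at(y: np.ndarray, t: np.ndarray, time: float) -> float:
    """Trace slope at an off-grid time: central differences at the two
    bracketing samples, linearly interpolated to the crossing time."""
    n = y.size
    i = int(np.clip(np.searchsorted(t, time) - 1, 0, n - 2))

    def cd(k: int) -> float:
        k0, k1 = max(k - 1, 0), min(k + 1, n - 1)
        return (y[k1] - y[k0]) / (t[k1] - t[k0])

    s0, s1 = cd(i), cd(i + 1)
    frac = (time - t[i]) / (t[i + 1] - t[i])
    return float((1 - frac) * s0 + frac * s1)


def compute_metrics(segment: BeatSegment, trace: NormalizedTrace) -> WaveformMetrics:
    """Compute the five waveform metrics for one beat.

    Baseline is the mean of the two flanking trough values; all heights are
    baseline-relative.  Raises :class:`MetricRejection` for pathological
    beats lacking a half-maximum crossing on either limb.
    """
    y, t = trace.values, trace.times
    baseline = 0.5 * (segment.trough_before_value + segment.trough_after_value)
    h_max = segment.peak_value - baseline
    if h_max <= 0:
        raise MetricRejection("non-positive peak height")
    level = baseline + 0.5 * h_max

    t_up, _ = _crossing_near_peak(
        y, t, level, segment.peak_index, segment.trough_before_index, rising=True
    )
    t_down, _ = _crossing_near_peak(
        y, t, level, segment.peak_index, segment.trough_after_index, rising=False
    )
    m_up = _slope_at(y, t, t_up)
    m_down = _slope_at(y, t, t_down)
    if m_up <= 0 or m_down >= 0:
        raise MetricRejection("non-monotone limb at the half-maximum crossing")
    t_mid = 0.5 * (t_up + t_down)
    h_plateau = float(np.interp(t_mid, t, y)) - baseline
    if h_plateau <= 0:
        raise MetricRejection("non-positive plateau height")
    return WaveformMetrics(
        h_max=float(h_max),
        m_up=float(m_up),
        m_down=float(m_down),
        w=float(t_down - t_up),
        h_plateau=min(float(h_plateau), float(h_max)),
        beat_time=segment.peak_time,
    )


def extract_features(
    trace: NormalizedTrace,
    min_prominence: float | None = None,
    min_separation: float = 0.2,
) -> tuple[list[WaveformMetrics], float, dict]:
    """Detect beats and compute metrics, with a QC summary.

    Returns ``(metrics, beat_rate, qc)`` where ``qc`` counts detected and
    rejected beats and lists rejection reasons.
    """
    segments, rate = detect_beats(trace, min_prominence, min_separation)
    metrics, reasons = [], []
    for seg in segments:
        try:
            metrics.append(compute_metrics(seg, trace))
        except MetricRejection as err:
            reasons.append(str(err))
    qc = {
        "n_detected": len(segments),
        "n_rejected": len(reasons),
        "rejection_reasons": reasons,
    }
    return metrics, rate, qc


def build_feature_table(
    per_recording: list[tuple[list[WaveformMetrics], str, str, str]],
) -> pd.DataFrame:
    """Assemble a feature table from per-recording metric lists.

    Each entry is ``(metrics, label, recording_id, membrane_id)``.  Rows are
    ordered deterministically by (recording, membrane, beat time).
    """
    if not per_recording:
        raise ValueError("no recordings given")
    rows = []
    for metrics, label, rec_id, mem_id in per_recording:
        if not label:
            raise ValueError(f"missing condition label for recording {rec_id!r}")
        for m in metrics:
            rows.append(
                m.as_dict() | {"label": label, "recording_id": rec_id, "membrane_id": mem_id}
            )
    table = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    return table.sort_values(
        ["recording_id", "membrane_id", "beat_time_s"], kind="mergesort"
    ).reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=FEATURE_COLUMNS)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table
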