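"""Trial-level autonomic summaries.

Heart rate: R-peaks are detected from the ECG (or supplied directly),
R-R intervals are converted to instantaneous rate (60 / interval, bpm)
and resampled second-by-second, each second receiving the mean of the
instantaneous rates of the intervals overlapping it, weighted by the
overlap fraction. The last second before stimulus onset serves as the
prestimulus baseline and is subtracted from the 20 stimulation seconds.

Electrodermal activity: the value at trial start is subtracted from all
samples of the trial and the remainder is averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

STIM_SECONDS = 20
REFRACTORY_S = 0.25


@dataclass
class HrSeries:
    """Second-by-second heart rate around one trial.

    ``seconds`` are the left edges relative to stimulus onset; the first
    entry (-1) is the prestimulus baseline second. ``bpm`` may contain
    NaN for seconds not covered by any R-R interval.
    """

    seconds: np.ndarray
    bpm: np.ndarray

    def baseline_corrected(self) -> "HrSeries":
        base = self.bpm[self.seconds == -1]
        if base.size != 1 or not np.isfinite(base[0]):
            raise ValueError("baseline second missing")
        return HrSeries(self.seconds.copy(), self.bpm - base[0])


def detect_r_peaks(ecg: np.ndarray, rate_hz: float) -> np.ndarray:
    """R-peak times (s) via band-pass, squared derivative and an adaptive
    threshold with a 250 ms refractory period.

    The threshold scales with the feature signal, so the output is
    invariant to overall amplitude. Returns an empty array for traces
    without detectable beats.
    """
    ecg = np.asarray(ecg, float)
    if ecg.size < 2 * rate_hz:
        raise ValueError("trace must cover at least 2 s")
    if np.ptp(ecg) < 1e-12:
        return np.array([])
    nyq = rate_hz / 2.0
    b, a = butter(3, [5.0 / nyq, min(35.0, 0.9 * nyq) / nyq], btype="band")
    filtered = filtfilt(b, a, ecg)
    feature = np.gradient(filtered) ** 2
    # light smoothing over ~100 ms stabilizes the peak of the squared slope
    win = max(1, int(0.1 * rate_hz))
    feature = np.convolve(feature, np.ones(win) / win, mode="same")
    thr = 0.2 * np.percentile(feature, 99.5)
    if thr <= 0:
        return np.array([])
    locs, _ = find_peaks(feature, height=thr, distance=max(1, int(REFRACTORY_S * rate_hz)))
    # refine each detection to the local maximum of the band-passed ECG
    half = max(1, int(0.05 * rate_hz))
    times = []
    for loc in locs:
        lo, hi = max(0, loc - half), min(len(ecg), loc + half + 1)
        times.append((lo + int(np.argmax(filtered[lo:hi]))) / rate_hz)
    times = np.asarray(sorted(set(times)))
    if times.size > 1:  # merge refinements landing within the refractory period
        keep = np.concatenate([[True], np.diff(times) > REFRACTORY_S])
        times = times[keep]
    return times


def hr_per_second(
    r_times: np.ndarray, window_start_s: float, window_end_s: float
) -> HrSeries:
    """Overlap-weighted second-by-second heart rate.

    Each R-R interval i carries the instantaneous rate 60/(t_{i+1}-t_i);
    the value of second [s, s+1) is the average of the rates of the
    intervals overlapping it, weighted by the overlap duration. Seconds
    not covered by any interval are NaN.
    """
    r_times = np.asarray(r_times, float)
    if r_times.size < 2:
        raise ValueError("need at least 2 R-peaks")
    starts = r_times[:-1]
    ends = r_times[1:]
    rates = 60.0 / (ends - starts)
    edges = np.arange(window_start_s, window_end_s)
    bpm = np.full(edges.size, np.nan)
    for j, s in enumerate(edges):
        overlap = np.minimum(ends, s + 1.0) - np.maximum(starts, s)
        overlap = np.clip(overlap, 0.0, None)
        total = overlap.sum()
        if total > 1e-12:
            bpm[j] = float((overlap * rates).sum() / total)
    return HrSeries(seconds=edges, bpm=bpm)


@dataclass
class TrialAutonomicSummary:
    hr_deltas: np.ndarray  # 20 baseline-corrected stimulation seconds
    hr_mean_delta: float
    eda_mean_delta: float


def trial_autonomic_summary(
    r_times: np.ndarray,
    eda_t_s: np.ndarray,
    eda_uS: np.ndarray,
    onset_s: float,
    stim_seconds: int = STIM_SECONDS,
) -> TrialAutonomicSummary:
    """Baseline-corrected trial means for heart rate and skin conductance.

    HR: second-by-second series from one second before onset through the
    stimulation window; the baseline second's value is subtracted from the
    ``stim_seconds`` stimulation values. EDA: the sample at trial start
    (stimulus onset) is subtracted from all in-trial samples before
    averaging.
    """
    series = hr_per_second(r_times - onset_s, -1.0, float(stim_seconds))
    corrected = series.baseline_corrected()
    deltas = corrected.bpm[corrected.seconds >= 0]
    if np.isnan(deltas).any():
        raise ValueError("stimulation seconds not fully covered by R-R intervals")

    eda_t = np.asarray(eda_t_s, float) - onset_s
    eda = np.asarray(eda_uS, float)
    in_trial = (eda_t >= 0) & (eda_t < stim_seconds)
    if not in_trial.any():
        raise ValueError("no EDA samples within the trial")
    start_val = eda[in_trial][np.argmin(eda_t[in_trial])]
    eda_mean = float((eda[in_trial] - start_val).mean())
    return TrialAutonomicSummary(
        hr_deltas=deltas, hr_mean_delta=float(deltas.mean()), eda_mean_delta=eda_mean
    )
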