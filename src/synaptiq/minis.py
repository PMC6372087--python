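"""Miniature EPSC detection and frequency analysis.

Detection uses sliding scaled-template matching: at every lag a biexponential
template is optimally scaled and offset against the trace, and the detection
criterion is the fitted scale divided by the standard deviation of the fit
error.  Criterion maxima above threshold, separated by a refractory period,
become events.  Frequencies are reported as a centered moving average
(default 5 s window); before/after drug comparisons drop the first part of
the application period and use disjoint windows for the paired test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core_io import Sweep

__all__ = [
    "BiexpKernel", "MiniEvent", "MiniFrequencySeries",
    "detect_minis", "measure_risetime", "mini_frequency", "drug_comparison",
]


@dataclass
class BiexpKernel:
    """Biexponential mEPSC template e^{−t/τ_decay} − e^{−t/τ_rise},
    normalized to unit peak and negative-going (inward current)."""

    tau_rise: float = 0.2    # ms
    tau_decay: float = 1.5   # ms
    duration: float | None = None  # ms, default 5·tau_decay

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.duration is None:
            self.duration = 5.0 * self.tau_decay

    def sample(self, dt: float) -> np.ndarray:
        """Template sampled at ``dt`` seconds; peak value −1."""
        t = np.arange(0.0, self.duration * 1e-3, dt) * 1e3  # ms
        w = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        return -w / w.max()

    @property
    def t_peak_ms(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    def risetime_ms(self, dt_ms: float = 1e-3) -> float:
        """10–90% risetime of the noiseless template (numeric)."""
        t = np.arange(0.0, self.t_peak_ms + dt_ms, dt_ms)
        w = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        w /= w[-1]
        t10 = np.interp(0.1, w, t)
        t90 = np.interp(0.9, w, t)
        return float(t90 - t10)


@dataclass
class MiniEvent:
    t: float            # s, event onset (template start)
    amplitude: float    # pA, peak minus local baseline
    rise_10_90: float   # ms
    score: float        # detection criterion
    decay_tau: float | None = None

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not self.rise_10_90 > 0:
            raise ValueError("rise_10_90 must be > 0")


@dataclass
class MiniFrequencySeries:
    times: np.ndarray   # s, window centers
    freq: np.ndarray    # Hz
    window: float = 5.0  # s
    step: float = 1.0    # s between window centers

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        if np.any(self.freq < 0) or not self.window > 0:
            raise ValueError("freq must be >= 0 and window > 0")


def detect_minis(sweep: Sweep, template: BiexpKernel,
                 criterion_threshold: float = 3.5,
                 min_amplitude: float = 5.0,
                 refractory_ms: float = 2.0) -> list[MiniEvent]:
    """Sliding scaled-template detection (Clements-Bekkers criterion).

    For each lag the template w (unit negative peak) is fitted to the data
    window d as s·w + c by least squares; the criterion is s divided by the
    SD of the fit error.  Local criterion maxima above threshold, thinned by
    the refractory period (ties to the highest criterion), yield events with
    amplitude s.  Deterministic for fixed inputs.
    """
    d = sweep.samples
    w = template.sample(sweep.dt)
    n = w.size
    if n < 2 or d.size < 2 * n:
        raise ValueError("sweep must be at least twice the template duration")

    sw_ = float(w.sum())
    sww = float(np.dot(w, w))
    denom = sww - sw_ * sw_ / n
    # rolling window sums of the data
    c1 = np.concatenate(([0.0], np.cumsum(d)))
    c2 = np.concatenate(([0.0], np.cumsum(d * d)))
    sd_win = c1[n:] - c1[:-n]
    sdd_win = c2[n:] - c2[:-n]
    sdw = fftconvolve(d, w[::-1], mode="valid")

    scale = (sdw - sd_win * sw_ / n) / denom
    offset = (sd_win - scale * sw_) / n
    sse = (sdd_win + scale ** 2 * sww + n * offset ** 2
           - 2.0 * scale * sdw - 2.0 * offset * sd_win
           + 2.0 * scale * offset * sw_)
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = scale / np.sqrt(sse / (n - 1))
    crit[~np.isfinite(crit)] = np.inf * np.sign(scale[~np.isfinite(crit)])
    crit[scale <= 0] = 0.0

    above = np.flatnonzero(crit >= criterion_threshold)
    if above.size == 0:
        return []
    refractory = max(int(round(refractory_ms * 1e-3 / sweep.dt)), 1)
    # greedy thinning: repeatedly take the highest remaining criterion
    order = above[np.argsort(crit[above])[::-1]]
    taken: list[int] = []
    blocked = np.zeros(crit.size, dtype=bool)
    for idx in order:
        if blocked[idx]:
            continue
        taken.append(int(idx))
        lo = max(idx - refractory, 0)
        blocked[lo:idx + refractory + 1] = True
    taken.sort()

    events = []
    for idx in taken:
        amp = float(scale[idx])
        if amp < min_amplitude:
            continue
        t_on = sweep.t0 + idx * sweep.dt
        rise = measure_risetime(sweep, window=(t_on, t_on + template.duration * 1e-3))
        if not np.isfinite(rise) or rise <= 0:
            rise = template.risetime_ms()
        events.append(MiniEvent(t=t_on, amplitude=amp, rise_10_90=rise,
                                score=float(crit[idx])))
    return events


def measure_risetime(sweep: Sweep, window: tuple[float, float],
                     baseline: float | None = None) -> float:
    """10–90% risetime (ms) of the excursion within ``window`` (s, absolute).

    Baseline defaults to the first sample of the window; the peak is the
    extremum relative to baseline; crossing times of the 10% and 90% levels
    are linearly interpolated.  Returns NaN when noise prevents an ordered
    pair of crossings.
    """
    i0 = sweep.index_at(window[0])
    i1 = sweep.index_at(window[1]) + 1
    seg = sweep.samples[i0:i1]
    if seg.size < 3:
        return float("nan")
    if baseline is None:
        baseline = float(seg[0])
    dev = seg - baseline
    ipk = int(np.argmax(np.abs(dev)))
    peak = dev[ipk]
    if peak == 0 or ipk == 0:
        return float("nan")
    frac = dev[:ipk + 1] / peak  # 0 at baseline → 1 at peak

    def crossing(level: float) -> float:
        idx = np.flatnonzero(frac >= level)
        if idx.size == 0:
            return float("nan")
        j = idx[0]
        if j == 0:
            return 0.0
        f0, f1 = frac[j - 1], frac[j]
        return (j - 1 + (level - f0) / (f1 - f0)) * sweep.dt

    t10, t90 = crossing(0.1), crossing(0.9)
    if not (np.isfinite(t10) and np.isfinite(t90)) or t90 <= t10:
        return float("nan")
    return float((t90 - t10) * 1e3)


def _event_times(events) -> np.ndarray:
    if len(events) and isinstance(events[0], MiniEvent):
        return np.asarray([e.t for e in events], dtype=float)
    return np.asarray(events, dtype=float)


def mini_frequency(events, duration: float, window: float = 5.0,
                   step: float = 1.0) -> tuple[MiniFrequencySeries, dict]:
    """Centered moving-average event frequency plus summary statistics.

    Windows are truncated (not padded) at the trace edges; each value is the
    event count in the effective window divided by its effective width.
    Summary: median frequency over windows and mean amplitude over events
    (NaN when events carry no amplitudes).
    """
    if duration < window:
        raise ValueError("duration must be at least one window")
    times = _event_times(events)
    centers = np.arange(0.0, duration + 1e-12, step)
    freq = np.empty(centers.size)
    for k, c in enumerate(centers):
        lo, hi = max(c - window / 2.0, 0.0), min(c + window / 2.0, duration)
        freq[k] = np.count_nonzero((times >= lo) & (times < hi)) / (hi - lo)
    series = MiniFrequencySeries(centers, freq, window=window, step=step)
    amps = ([e.amplitude for e in events]
            if len(events) and isinstance(events[0], MiniEvent) else [])
    summary = {
        "median_frequency_hz": float(np.median(freq)) if freq.size else 0.0,
        "mean_amplitude_pa": float(np.mean(amps)) if amps else float("nan"),
        "n_events": int(times.size),
    }
    return series, summary


def drug_comparison(series: MiniFrequencySeries, application_time: float,
                    exclusion: float = 120.0) -> dict:
    """Mean mEPSC frequency before vs after drug application.

    The first ``exclusion`` seconds after application (wash-in) are dropped.
    The paired test runs on frequencies from *disjoint* windows (stride =
    window/step) because overlapping moving-average windows are autocorrelated.
    """
    from .stats_harness import select_and_compare

    t = series.times
    stride = max(int(round(series.window / series.step)), 1)
    before_mask = t + series.window / 2.0 <= application_time
    after_mask = t - series.window / 2.0 >= application_time + exclusion
    before = series.freq[before_mask][::stride]
    after = series.freq[after_mask][::stride]
    if before.size == 0:
        raise ValueError("no baseline segment before application_time")
    if after.size == 0:
        raise ValueError("no post-drug segment after application + exclusion")
    m = min(before.size, after.size)
    result = select_and_compare([before[:m], after[:m]], design="paired",
                                labels=["before", "after"])
    return {
        "before_mean_hz": float(np.mean(before)),
        "after_mean_hz": float(np.mean(after)),
        "n_pairs": int(m),
        "comparison": result,
    }
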