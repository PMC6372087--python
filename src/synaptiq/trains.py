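"""EPSC train analysis: amplitudes, Rs correction, RRP back-extrapolation.

The readily releasable pool (RRP) is estimated from a high-frequency train
(300 Hz, 30 stimuli in the study conditions) by plotting cumulative EPSC
amplitude against stimulus number, fitting a line to the steady-state segment
and back-extrapolating to stimulus 0: the intercept estimates the RRP, the
slope the replenishment rate, and the first EPSC divided by the RRP the
initial release probability P_r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core_io import TrainRecording

__all__ = [
    "EPSCTrain", "RRPEstimate", "SigmoidParams",
    "measure_train_amplitudes", "rs_offline_correct", "backextrapolate_rrp",
    "initial_pr", "normalize_train", "fit_ca_dose_response", "eval_sigmoid",
]


@dataclass
class EPSCTrain:
    """Per-stimulus EPSC amplitudes (peak minus baseline, magnitudes, pA)."""

    amplitudes: np.ndarray
    stimulus_frequency: float
    rs_remaining: float = 0.0   # MΩ uncompensated series resistance
    reversal: float = 0.0       # mV AMPAR reversal
    holding: float = -70.0      # mV postsynaptic holding

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes are magnitudes and must be >= 0")

    @property
    def n_stimuli(self) -> int:
        return self.amplitudes.size


@dataclass
class RRPEstimate:
    rrp: float                 # back-extrapolated intercept, amplitude units
    slope: float               # replenishment, amplitude units per stimulus
    slope_normalized: float    # fraction of RRP per stimulus
    pr_initial: float          # first EPSC / RRP, clipped to [0, 1]
    fit_range: tuple[int, int]  # [start, stop) stimulus indices used
    valid: bool = True
    pr_clipped: bool = False


@dataclass
class SigmoidParams:
    """f(x) = max / (1 + e^{(x_half − x)/rate}) for Ca²⁺ dose-response."""

    max: float
    x_half: float
    rate: float

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be > 0")


def eval_sigmoid(params: SigmoidParams, x) -> np.ndarray | float:
    x_arr = np.asarray(x, dtype=float)
    out = params.max / (1.0 + np.exp((params.x_half - x_arr) / params.rate))
    return out if np.ndim(x) else float(out)


def measure_train_amplitudes(rec: TrainRecording, baseline_ms: float = 0.3,
                             peak_window_ms: float = 2.0) -> EPSCTrain:
    """Extract per-stimulus amplitudes (|extremum − local baseline|).

    At 300 Hz responses overlap, so the baseline for stimulus i is the
    residual current immediately preceding it: a low-order polynomial trend
    (quadratic when the window holds enough samples, else linear/mean) fitted
    over the ``baseline_ms`` window before the stimulus and extrapolated
    under the response, so that the continuing exponential decay of the
    residual does not bias the peak measurement.  Enlarge ``baseline_ms`` on
    noisy recordings: the extrapolation trades noise amplification against
    residual-decay bias.
    """
    sw = rec.sweep
    times = rec.stimulus_times
    if times.size == 0:
        return EPSCTrain(np.empty(0), rec.stimulus_frequency)
    if times.size > 1:
        isi = float(np.min(np.diff(times)))
        if peak_window_ms * 1e-3 > isi:
            raise ValueError("peak window exceeds inter-stimulus interval")
    amps = np.empty(times.size)
    for k, t in enumerate(times):
        b0 = sw.index_at(t - baseline_ms * 1e-3)
        b1 = max(sw.index_at(t), b0 + 1)
        base_seg = sw.samples[b0:b1]
        w0, w1 = b1, sw.index_at(t + peak_window_ms * 1e-3) + 1
        seg = sw.samples[w0:w1]
        if base_seg.size >= 8:
            coeffs = np.polyfit(np.arange(b0, b1, dtype=float), base_seg, 2)
            baseline = np.polyval(coeffs, np.arange(w0, w1))
        elif base_seg.size >= 3:
            coeffs = np.polyfit(np.arange(b0, b1, dtype=float), base_seg, 1)
            baseline = np.polyval(coeffs, np.arange(w0, w1))
        else:
            baseline = np.full(seg.size, float(np.mean(base_seg)))
        dev = seg - baseline
        amps[k] = abs(dev[int(np.argmax(np.abs(dev)))])
    return EPSCTrain(amps, rec.stimulus_frequency)


def rs_offline_correct(train: EPSCTrain) -> EPSCTrain:
    """Offline-compensate the remaining series resistance to 0 MΩ.

    The corrected amplitude I satisfies the steady-state voltage-error
    relation I = I_meas · |ΔV| / (|ΔV| − I·Rs) with ΔV the driving force
    (holding − reversal) and I·Rs in mV (pA·MΩ = 1e−3 mV): iterating the
    scale factor to convergence solves a quadratic, whose stable (smaller)
    root is taken in closed form.  The relation has no solution when the
    voltage error would exceed half the driving force twice over
    (discriminant < 0); that pathological regime raises.
    """
    if train.rs_remaining == 0:
        return EPSCTrain(train.amplitudes.copy(), train.stimulus_frequency,
                         0.0, train.reversal, train.holding)
    df = abs(train.holding - train.reversal)
    if df == 0:
        raise ValueError("zero driving force; cannot correct")
    rs = train.rs_remaining * 1e-3  # mV per pA
    disc = df * df - 4.0 * rs * df * train.amplitudes
    if np.any(disc < 0):
        raise ValueError("Rs correction has no solution "
                         "(voltage error exceeds the driving force)")
    # numerically stable small root of rs*I^2 - df*I + df*I_meas = 0
    corrected = 2.0 * train.amplitudes * df / (df + np.sqrt(disc))
    return EPSCTrain(corrected, train.stimulus_frequency, 0.0,
                     train.reversal, train.holding)


def backextrapolate_rrp(train: EPSCTrain,
                        fit_range: tuple[int, int] | None = None) -> RRPEstimate:
    """Back-extrapolate cumulative EPSC amplitude to the train onset.

    Cumulative amplitude is plotted against stimulus number and an ordinary
    least-squares line over ``fit_range`` (default: the last 5 stimuli, the
    steady-state segment) is extrapolated back to time zero — the onset of
    the train, where the first stimulus sits.  The intercept is the RRP, the
    slope the raw replenishment rate, slope/RRP the normalized replenishment,
    and amplitudes[0]/RRP the initial P_r.

    A late, short steady-state window keeps the residual-depletion bias of
    the extrapolation small; the window is configurable.
    """
    n = train.n_stimuli
    if n < 10:
        raise ValueError("back-extrapolation requires at least 10 stimuli")
    if fit_range is None:
        fit_range = (n - 5, n)
    lo, hi = fit_range
    if not (0 <= lo < hi <= n):
        raise ValueError(f"fit_range {fit_range} outside train of {n} stimuli")
    cum = np.cumsum(train.amplitudes)
    x = np.arange(n, dtype=float)  # first stimulus at time zero
    slope, intercept = np.polyfit(x[lo:hi], cum[lo:hi], 1)

    if intercept <= 0:
        warnings.warn("non-positive back-extrapolated intercept; train does "
                      "not depress (estimate flagged invalid)")
        return RRPEstimate(float(intercept), float(slope), np.nan, np.nan,
                           fit_range, valid=False)
    pr = float(train.amplitudes[0] / intercept)
    clipped = not (0.0 <= pr <= 1.0)
    if clipped:
        warnings.warn(f"initial P_r {pr:.3f} outside [0, 1]; clipped")
        pr = min(max(pr, 0.0), 1.0)
    return RRPEstimate(float(intercept), float(slope),
                       float(slope / intercept), pr, fit_range,
                       valid=True, pr_clipped=clipped)


def initial_pr(first_epsc: float, rrp: float) -> tuple[float, bool]:
    """First EPSC divided by the RRP, clipped to [0, 1] (returns value, clipped)."""
    if rrp <= 0:
        raise ValueError("rrp must be > 0")
    pr = first_epsc / rrp
    clipped = not (0.0 <= pr <= 1.0)
    if clipped:
        warnings.warn(f"initial P_r {pr:.3f} outside [0, 1]; clipped")
    return min(max(pr, 0.0), 1.0), clipped


def normalize_train(train: EPSCTrain) -> np.ndarray:
    """Amplitudes normalized to the first EPSC (element 0 = 1)."""
    if train.n_stimuli == 0 or train.amplitudes[0] <= 0:
        raise ValueError("first amplitude must be > 0 to normalize")
    return train.amplitudes / train.amplitudes[0]


def fit_ca_dose_response(points, max_restarts: int = 5) -> tuple[SigmoidParams, dict]:
    """Fit f(x) = max/(1 + e^{(x_half − x)/rate}) to (Ca²⁺ mM, response) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (concentration, response) points")
    x, y = pts[:, 0], pts[:, 1]

    def model(theta, xx):
        mx, xh, log_rate = theta
        return mx / (1.0 + np.exp((xh - xx) / np.exp(log_rate)))

    x0 = np.array([float(y.max()) or 1.0, float(np.median(x)),
                   np.log(max(np.ptp(x) / 4.0, 1e-3))])
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 + 0.2 * attempt * np.array([0.5, -0.3, 0.5])
        sol = optimize.least_squares(lambda th: model(th, x) - y, start,
                                     method="lm", max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= 1e-3 * np.sum(y ** 2) + 1e-12:
            break
    if best is None or not best.success:
        raise RuntimeError("sigmoid fit did not converge")
    mx, xh, log_rate = best.x
    params = SigmoidParams(float(mx), float(xh), float(np.exp(log_rate)))
    diag = {"residual_norm": float(np.sqrt(2 * best.cost)),
            "n_points": int(x.size), "success": bool(best.success)}
    return params, diag
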