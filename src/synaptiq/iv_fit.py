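"""Presynaptic Ca²⁺ channel current-voltage analysis.

Peak IV relationships are fitted with a Hodgkin-Huxley activation model (four
independent gates by default) multiplying a Goldman-Hodgkin-Katz open-channel
driving force:

    I(V) = Γ · V · (1 − e^{−(V−E_rev)/s}) / (1 − e^{−V/s}) · m∞(V)^n
    m∞(V) = 1 / (1 + e^{−(V−V_m)/k_m})

with s = 25 mV.  The GHK factor is continuous at V = 0 through its series
limit V/(1 − e^{−V/s}) → s.  Tail currents (peak minus baseline after
repolarization) are fitted with a Boltzmann function

    I_tail(V) = I_base + I_min / (1 + e^{−(V−V_1/2)/k}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .core_io import Sweep

__all__ = [
    "IVCurve", "IVFitParams", "TailFitParams", "FitError",
    "eval_iv_model", "fit_iv", "measure_tail_peaks", "fit_boltzmann",
    "normalize_curve",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge within the bounded restarts."""


@dataclass
class IVCurve:
    """Peak (or tail) current per step potential."""

    voltages: np.ndarray        # mV, strictly increasing
    peak_currents: np.ndarray   # pA
    capacitance: float | None = None  # pF (C_slow), optional

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.peak_currents = np.asarray(self.peak_currents, dtype=float)
        if self.voltages.size != self.peak_currents.size:
            raise ValueError("voltages and peak_currents must match in length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass
class IVFitParams:
    """Parameters of the GHK × HH-gating IV model.

    gamma is the conductance scale Γ (current per mV of GHK drive), e_rev the
    reversal potential (mV), v_m the per-gate half-activation voltage (mV),
    k_m the activation slope (mV), n_gates the number of independent gates and
    ghk_slope the 25 mV constant of the GHK factor.
    """

    gamma: float
    e_rev: float
    v_m: float
    k_m: float
    n_gates: int = 4
    ghk_slope: float = 25.0

    def __post_init__(self) -> None:
        if not self.k_m > 0:
            raise ValueError("k_m must be > 0")
        if self.n_gates < 1:
            raise ValueError("n_gates must be >= 1")
        if not self.ghk_slope > 0:
            raise ValueError("ghk_slope must be > 0")


@dataclass
class TailFitParams:
    i_base: float
    i_min: float
    v_half: float
    k: float
    flipped_slope: bool = False

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("Boltzmann slope k must be nonzero")

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.i_base + self.i_min / (1.0 + np.exp(-(v - self.v_half) / self.k))


def _ghk_drive(v: np.ndarray, e_rev: float, s: float) -> np.ndarray:
    """V·(1−e^{−(V−E_rev)/s})/(1−e^{−V/s}), patched with its limit at V=0."""
    v = np.asarray(v, dtype=float)
    num = -np.expm1(-(v - e_rev) / s)
    den = -np.expm1(-v / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0.0, s * num, v * num / den)
    return out


def eval_iv_model(params: IVFitParams, v) -> np.ndarray | float:
    """Evaluate the IV model at voltage(s) ``v`` (mV); returns current in pA."""
    v_arr = np.asarray(v, dtype=float)
    gate = 1.0 / (1.0 + np.exp(-(v_arr - params.v_m) / params.k_m))
    out = params.gamma * _ghk_drive(v_arr, params.e_rev, params.ghk_slope) \
        * gate ** params.n_gates
    return out if np.ndim(v) else float(out)


def _default_init(curve: IVCurve, n_gates: int, ghk_slope: float) -> IVFitParams:
    v, i = curve.voltages, curve.peak_currents
    # E_rev: interpolated zero crossing beyond the peak, else extrapolate
    ipk = int(np.argmax(np.abs(i)))
    e_rev = v[-1] + 10.0
    for j in range(ipk, v.size - 1):
        if i[j] == 0.0:
            e_rev = v[j]
            break
        if i[j] * i[j + 1] < 0:
            e_rev = v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j])
            break
    half = np.abs(i).max() / 2.0
    above = np.flatnonzero(np.abs(i) >= half)
    v_m = float(v[above[0]]) if above.size else float(v[ipk])
    k_m = 8.0
    trial = IVFitParams(1.0, e_rev, v_m, k_m, n_gates, ghk_slope)
    model_pk = eval_iv_model(trial, v[ipk])
    gamma = i[ipk] / model_pk if model_pk != 0 else 1.0
    return IVFitParams(float(gamma), float(e_rev), v_m, k_m, n_gates, ghk_slope)


def fit_iv(curve: IVCurve, init: IVFitParams | None = None, *,
           n_gates: int = 4, ghk_slope: float = 25.0,
           max_restarts: int = 5) -> tuple[IVFitParams, dict]:
    """Least-squares fit of the IV model; returns (params, diagnostics).

    Initialization follows the standard heuristics (E_rev from the zero
    crossing, V_m from the half-maximal voltage, k_m = 8 mV, Γ from the peak)
    unless ``init`` is given.  On non-convergence the start point is perturbed
    deterministically up to ``max_restarts`` times.
    """
    v = curve.voltages
    i = curve.peak_currents
    if v.size < 5:
        raise ValueError("fit_iv requires at least 5 voltage points")
    if np.allclose(i, 0.0):
        raise ValueError("no activation detected (all currents zero)")
    if init is None:
        init = _default_init(curve, n_gates, ghk_slope)

    def resid(theta):
        gamma, e_rev, v_m, log_km = theta
        p = IVFitParams(gamma, e_rev, v_m, np.exp(log_km), n_gates, ghk_slope)
        return eval_iv_model(p, v) - i

    x0 = np.array([init.gamma, init.e_rev, init.v_m, np.log(init.k_m)])
    best = None
    for attempt in range(max_restarts + 1):
        # deterministic multiplicative perturbation ladder
        scale = 1.0 + 0.1 * attempt * np.array([1.0, -0.5, 0.5, -1.0])
        sol = optimize.least_squares(resid, x0 * scale, method="lm",
                                     max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= 1e-3 * np.sum(i ** 2) + 1e-12:
            break
    if best is None or not best.success:
        raise FitError(f"IV fit did not converge: {best.message if best else 'n/a'}")

    gamma, e_rev, v_m, log_km = best.x
    params = IVFitParams(float(gamma), float(e_rev), float(v_m),
                         float(np.exp(log_km)), n_gates, ghk_slope)
    dof = max(v.size - 4, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    diag = {
        "residual_norm": float(np.sqrt(2 * best.cost)),
        "stderr": {"gamma": float(se[0]), "e_rev": float(se[1]),
                   "v_m": float(se[2]), "log_k_m": float(se[3])},
        "n_points": int(v.size),
        "success": bool(best.success),
    }
    return params, diag


def measure_tail_peaks(sweeps: list[Sweep], baseline_window_ms: float = 5.0,
                       tail_window_ms: float = 2.0) -> IVCurve:
    """Tail amplitude (peak minus baseline) per sweep, indexed by step potential.

    Baseline is the mean over ``baseline_window_ms`` before the step onset;
    the tail peak is the signed extremum within ``tail_window_ms`` after
    repolarization (step onset + step duration).
    """
    volts, amps = [], []
    for sw in sweeps:
        if sw.step_onset is None or sw.step_duration is None:
            raise ValueError("sweep lacks step_onset/step_duration metadata")
        repol = sw.step_onset + sw.step_duration * 1e-3
        if repol + tail_window_ms * 1e-3 > sw.t0 + sw.duration + sw.dt:
            raise ValueError("tail window outside sweep")
        b0 = sw.index_at(sw.step_onset - baseline_window_ms * 1e-3)
        b1 = sw.index_at(sw.step_onset)
        baseline = float(np.mean(sw.samples[b0:max(b1, b0 + 1)]))
        w0 = sw.index_at(repol)
        w1 = sw.index_at(repol + tail_window_ms * 1e-3) + 1
        seg = sw.samples[w0:w1]
        peak = seg[int(np.argmax(np.abs(seg - baseline)))]
        volts.append(sw.step_potential if sw.step_potential is not None else np.nan)
        amps.append(float(peak - baseline))
    order = np.argsort(volts)
    return IVCurve(np.asarray(volts)[order], np.asarray(amps)[order])


def fit_boltzmann(curve: IVCurve, max_restarts: int = 5) -> tuple[TailFitParams, dict]:
    """Fit I_base + I_min/(1 + e^{−(V−V_1/2)/k}) to a tail IV curve.

    The form is invariant under (k, I_min, I_base) → (−k, −I_min, I_base+I_min);
    a converged fit with k < 0 is re-expressed with k > 0 and flagged.
    """
    v, i = curve.voltages, curve.peak_currents
    if v.size < 4:
        raise ValueError("fit_boltzmann requires at least 4 points")

    def model(theta, vv):
        i_base, i_min, v_half, k = theta
        return i_base + i_min / (1.0 + np.exp(-(vv - v_half) / k))

    span = float(v[-1] - v[0])
    x0 = np.array([i[0], i[-1] - i[0], float(np.median(v)), span / 4.0])
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 * (1.0 + 0.15 * attempt * np.array([0.5, -0.5, 0.2, 1.0]))
        if start[3] == 0:
            start[3] = span / 4.0
        sol = optimize.least_squares(lambda th: model(th, v) - i, start,
                                     method="lm", max_nfev=5000)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost <= 1e-3 * np.sum(i ** 2) + 1e-12:
            break
    if best is None or not best.success:
        raise FitError("Boltzmann fit did not converge")
    i_base, i_min, v_half, k = best.x
    flipped = k < 0
    if flipped:
        i_base, i_min, k = i_base + i_min, -i_min, -k
        warnings.warn("Boltzmann fit converged with negative slope; "
                      "re-expressed with k > 0 (flagged)")
    params = TailFitParams(float(i_base), float(i_min), float(v_half), float(k),
                           flipped_slope=bool(flipped))
    diag = {"residual_norm": float(np.sqrt(2 * best.cost)),
            "n_points": int(v.size), "success": bool(best.success)}
    return params, diag


def normalize_curve(curve: IVCurve) -> IVCurve:
    """Divide currents by the maximum |current|; preserves sign."""
    m = float(np.max(np.abs(curve.peak_currents)))
    if m == 0:
        raise ValueError("cannot normalize an all-zero curve")
    return IVCurve(curve.voltages.copy(), curve.peak_currents / m,
                   curve.capacitance)
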