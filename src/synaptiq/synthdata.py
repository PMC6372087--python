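"""Seeded generators emulating the study's raw data.

Every generator takes an explicit seed and returns ground truth alongside the
data; estimator tests consume these pairs.  Defaults follow the study
conditions: 300 Hz trains of 30 stimuli, external Ca²⁺ series
0.2–1.5 mM, ten Fura-2 standards up to 1.4 μM with K_eff = 239.95 nM,
clustered channel patterns of roughly five particles per cluster.

The depressing-train model is vesicle depletion with partial replenishment:
after each stimulus releases a fraction p of the current pool N_i, the vacant
fraction of the resting pool refills by a fraction r within the
inter-stimulus interval,

    N_{i+1} = N_i(1 − p) + r · (n0 − N_i(1 − p)),

and the EPSC is E_i = N_i · p · q (quantal amplitude q) with multiplicative
Gaussian noise.  Replenishment after release, within the interval, is the
stated order (it sets the steady state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_io import PointPattern, Sweep, VesicleProfile, CHANNEL_CLASS
from .fura import FuraCalibration, ratio_from_ca
from .iv_fit import IVCurve, IVFitParams, eval_iv_model
from .minis import BiexpKernel
from .trains import EPSCTrain

__all__ = [
    "DepletionModelParams", "ThomasProcessParams",
    "gen_train", "gen_mini_trace", "gen_point_pattern", "gen_iv_family",
    "gen_fura_series", "gen_vesicle_profile",
    "PAPER_CA_CONCENTRATIONS_MM", "FURA_STANDARDS_NM",
]

#: external Ca²⁺ concentrations of the dose-response protocol (mM)
PAPER_CA_CONCENTRATIONS_MM = (0.2, 0.5, 0.75, 1.0, 1.5)

#: ten EGTA-buffered free-Ca²⁺ standards, Ca²⁺-free up to 1.4 μM (nM)
FURA_STANDARDS_NM = tuple(float(x) for x in np.linspace(0.0, 1400.0, 10))

#: vacancy-refill fraction per inter-stimulus interval reproducing the
#: control-condition normalized replenishment (slope/RRP ≈ 0.017/stimulus)
#: through the steady state of the depletion recursion
REPLENISH_FRACTION_DEFAULT = 0.016


@dataclass
class DepletionModelParams:
    n0: float = 100.0       # initial pool, quanta
    p: float = 0.2          # release fraction per stimulus
    r: float = 0.0          # refill fraction of vacancy per interval
    q: float = 30.0         # quantal amplitude, pA
    noise_cv: float = 0.0   # multiplicative amplitude CV
    n_stimuli: int = 30
    frequency: float = 300.0  # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")
        if not 0 <= self.r <= 1:
            raise ValueError("r must be in [0, 1]")
        if not self.n0 > 0:
            raise ValueError("n0 must be > 0")


@dataclass
class ThomasProcessParams:
    parent_intensity: float = 0.4   # parents per μm²
    offspring_mean: float = 5.0     # particles per parent (Poisson mean)
    sigma: float = 20.0             # nm isotropic offspring scatter
    face_area: float = 25.0         # μm²
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.parent_intensity, self.offspring_mean,
               self.sigma, self.face_area) < 0:
            raise ValueError("all Thomas-process parameters must be positive")


def gen_train(params: DepletionModelParams) -> tuple[EPSCTrain, dict]:
    """Depressing/facilitating EPSC train from the depletion model."""
    rng = np.random.default_rng(params.seed)
    amps = np.empty(params.n_stimuli)
    n_i = params.n0
    for i in range(params.n_stimuli):
        e_clean = n_i * params.p * params.q
        eps = rng.normal(0.0, params.noise_cv) if params.noise_cv > 0 else 0.0
        amps[i] = max(e_clean * (1.0 + eps), 0.0)
        remaining = n_i * (1.0 - params.p)
        n_i = remaining + params.r * (params.n0 - remaining)
    train = EPSCTrain(amps, params.frequency)
    truth = {"n0": params.n0, "p": params.p, "r": params.r, "q": params.q,
             "rrp_amplitude": params.n0 * params.q}
    return train, truth


def gen_mini_trace(rate: float, duration: float,
                   kernel: BiexpKernel | None = None,
                   amp_mean: float = 40.0, amp_sigma: float = 0.25,
                   noise_sd: float = 4.0, dt: float = 1e-4,
                   seed: int = 0) -> tuple[Sweep, dict]:
    """Poisson-timed mEPSC trace: biexponential events + Gaussian noise.

    Event amplitudes are lognormal with median ``amp_mean`` pA and log-sd
    ``amp_sigma``; events are negative-going (inward).  Returns the sweep and
    the true event times/amplitudes.
    """
    if rate < 0 or duration <= 0:
        raise ValueError("need rate >= 0 and duration > 0")
    rng = np.random.default_rng(seed)
    kernel = kernel or BiexpKernel()
    n_samples = int(round(duration / dt))
    trace = rng.normal(0.0, noise_sd, n_samples) if noise_sd > 0 \
        else np.zeros(n_samples)
    n_ev = rng.poisson(rate * duration)
    t_ev = np.sort(rng.uniform(0.0, duration, n_ev))
    a_ev = np.exp(rng.normal(math.log(amp_mean), amp_sigma, n_ev))
    w = kernel.sample(dt)
    for t, a in zip(t_ev, a_ev):
        i0 = int(round(t / dt))
        i1 = min(i0 + w.size, n_samples)
        trace[i0:i1] += a * w[:i1 - i0]
    sweep = Sweep(dt=dt, samples=trace, label="synthetic mEPSC trace")
    return sweep, {"event_times": t_ev, "event_amplitudes": a_ev,
                   "rate": rate, "noise_sd": noise_sd}


def gen_point_pattern(params: ThomasProcessParams) -> tuple[PointPattern, dict]:
    """Thomas-process gold-particle pattern on a square P-face.

    Poisson(parent_intensity·area) parents uniform on the face;
    Poisson(offspring_mean) children per parent displaced by isotropic
    Gaussian(sigma); children falling off the face are discarded.
    """
    rng = np.random.default_rng(params.seed)
    side_nm = math.sqrt(params.face_area) * 1e3
    n_parents = rng.poisson(params.parent_intensity * params.face_area)
    parents = rng.uniform(0.0, side_nm, (n_parents, 2))
    pts = []
    for px, py in parents:
        k = rng.poisson(params.offspring_mean)
        if k:
            pts.append(np.column_stack([px, py]) +
                       rng.normal(0.0, params.sigma, (k, 2)))
    xy = np.vstack(pts) if pts else np.empty((0, 2))
    inside = np.all((xy >= 0.0) & (xy <= side_nm), axis=1) if len(xy) \
        else np.empty(0, bool)
    xy = xy[inside]
    pattern = PointPattern(xy, np.full(len(xy), CHANNEL_CLASS),
                           params.face_area)
    return pattern, {"parents": parents, "n_parents": int(n_parents),
                     "offspring_mean": params.offspring_mean,
                     "sigma": params.sigma}


def gen_iv_family(params: IVFitParams, voltages, noise_frac: float = 0.0,
                  seed: int = 0) -> IVCurve:
    """Noisy IV curve from the IV model (multiplicative Gaussian noise)."""
    v = np.asarray(voltages, dtype=float)
    i = eval_iv_model(params, v)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        i = i * (1.0 + rng.normal(0.0, noise_frac, v.size))
    return IVCurve(v, i)


def gen_fura_series(calib: FuraCalibration, true_ca,
                    noise_frac: float = 0.0, seed: int = 0) -> np.ndarray:
    """(known [Ca²⁺] nM, measured ratio) calibration table with ratio noise."""
    ca = np.asarray(true_ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("true_ca must be >= 0")
    r = ratio_from_ca(calib, ca)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        r = r * (1.0 + rng.normal(0.0, noise_frac, ca.size))
    return np.column_stack([ca, r])


def gen_vesicle_profile(az_len: float = 400.0, n_vesicles: int = 30,
                        distance_dist=None, seed: int = 0,
                        pixel_size: float = 1.0
                        ) -> tuple[VesicleProfile, dict]:
    """Vesicles at sampled perpendicular distances from a random AZ polyline.

    ``distance_dist`` maps an rng to an array of distances (nm); the default
    is uniform on [0, 200).  Vesicles are dropped perpendicular to uniformly
    chosen footpoints on the polyline; the sampled distances are returned as
    ground truth.  Footpoints keep clear of vertices so the perpendicular
    distance is exact.
    """
    if az_len <= 0 or n_vesicles < 0:
        raise ValueError("need positive az_len and n_vesicles >= 0")
    rng = np.random.default_rng(seed)
    # convex random polyline (consistent left turns); vesicles go on the
    # outer (right) side, where the perpendicular foot on a segment interior
    # is guaranteed to be the nearest point of the whole polyline
    n_seg = 4
    headings = np.cumsum(np.concatenate([[rng.uniform(0, 2 * np.pi)],
                                         rng.uniform(0.05, 0.25, n_seg - 1)]))
    seg_len = az_len / n_seg
    verts = np.vstack([[0.0, 0.0],
                       np.cumsum(np.column_stack([np.cos(headings),
                                                  np.sin(headings)]) * seg_len,
                                 axis=0)])
    verts += 1000.0  # keep coordinates positive (image convention)

    if distance_dist is None:
        dists = rng.uniform(0.0, 200.0, n_vesicles)
    else:
        dists = np.asarray(distance_dist(rng, n_vesicles), dtype=float)
    arc = rng.uniform(0.05, 0.95, n_vesicles) * az_len
    seg_idx = np.minimum((arc // seg_len).astype(int), n_seg - 1)
    frac = (arc - seg_idx * seg_len) / seg_len
    p0 = verts[seg_idx]
    p1 = verts[seg_idx + 1]
    foot = p0 + (p1 - p0) * frac[:, None]
    tang = (p1 - p0) / seg_len
    right_normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    ves = foot + right_normal * dists[:, None]
    profile = VesicleProfile(verts, ves, pixel_size=pixel_size)
    return profile, {"distances": dists, "az_length": az_len}
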