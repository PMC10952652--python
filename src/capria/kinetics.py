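"""Closed-form PCASL signal models under arbitrary excitation schedules.

Two ASL difference signals are modeled during the continuous readout that
follows each labeling period:

* an angiographic (macrovascular) signal -- a non-dispersed bolus of labeled
  blood occupying a voxel of fractional blood volume v between arrival delta_t
  and washout delta_t + tau, relaxing with the T1 of blood; and
* a perfusion (tissue) signal -- the standard single-compartment continuous-
  labeling kinetic model (Buxton) with tissue arrival Delta_t and apparent
  tissue relaxation 1/T1' = 1/T1t + f/lambda.

Because every excitation pulse consumes longitudinal magnetization, the
signal excited by pulse i is attenuated by R_i, the cumulative product of the
cosines of all earlier flip angles, and scaled by sin(alpha_i).  A variable
flip angle (VFA) schedule that rises quadratically across the readout trades
early signal for late signal, which benefits the late-arriving perfusion
component in particular.  Dispersion of the bolus is deliberately ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FlipAngleSchedule",
    "KineticParams",
    "make_schedule",
    "rf_attenuation",
    "angio_signal",
    "buxton_casl_delta_m",
    "perfusion_signal",
    "f_from_ml_per_100g_min",
]


def f_from_ml_per_100g_min(f_ml: float) -> float:
    """Convert perfusion from ml/100g/min to s^-1 (volume-normalized)."""
    return f_ml / 100.0 / 60.0


@dataclass(frozen=True)
class FlipAngleSchedule:
    """Per-pulse excitation flip angles across one readout train (degrees)."""

    alphas: np.ndarray
    kind: str            # "constant" | "quadratic-variable"
    alpha1: float
    alphaN: float

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=np.float64)
        if np.any(a <= 0.0) or np.any(a >= 90.0):
            raise ValueError("all flip angles must lie in (0, 90) degrees")
        object.__setattr__(self, "alphas", a)

    def __len__(self) -> int:
        return self.alphas.size

    @property
    def radians(self) -> np.ndarray:
        return np.deg2rad(self.alphas)


def make_schedule(kind: str, alpha1: float, alphaN: float, N: int) -> FlipAngleSchedule:
    """Build a constant or quadratically increasing flip-angle schedule.

    Quadratic: alpha_i = alpha1 + (alphaN - alpha1) * ((i-1)/(N-1))^2, so the
    first pulse uses alpha1 and the last pulse alphaN exactly.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (0.0 < alpha1 <= alphaN < 90.0):
        raise ValueError("require 0 < alpha1 <= alphaN < 90 degrees")
    if kind == "constant":
        if alpha1 != alphaN:
            raise ValueError("constant schedule requires alpha1 == alphaN")
        alphas = np.full(N, alpha1, dtype=np.float64)
    elif kind == "quadratic-variable":
        i = np.arange(N, dtype=np.float64)
        alphas = alpha1 + (alphaN - alpha1) * (i / (N - 1)) ** 2
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    return FlipAngleSchedule(alphas=alphas, kind=kind, alpha1=alpha1, alphaN=alphaN)


def rf_attenuation(schedule: FlipAngleSchedule) -> np.ndarray:
    """Cumulative RF attenuation R_i = prod_{j<i} cos(alpha_j), with R_1 = 1."""
    c = np.cos(schedule.radians)
    R = np.empty(len(schedule))
    R[0] = 1.0
    np.cumprod(c[:-1], out=R[1:])
    return R


# Literature-standard 3T defaults; the acquisition itself does not fix these.
@dataclass(frozen=True)
class KineticParams:
    """Physiological and calibration constants for the signal models.

    delta_t : macrovascular (arterial) transit time, s
    Delta_t : tissue transit time, s
    T1b     : longitudinal relaxation of arterial blood, s
    T1t     : longitudinal relaxation of tissue, s
    f       : perfusion, s^-1 (use f_from_ml_per_100g_min for clinical units;
              default corresponds to 50 ml/100g/min)
    lam     : blood-tissue partition coefficient, dimensionless
    v       : fractional macrovascular blood volume of the voxel
    M0b     : equilibrium magnetization of blood, arbitrary units
    alpha_inv : PCASL inversion efficiency
    """

    delta_t: float = 0.75
    Delta_t: float = 1.5
    T1b: float = 1.65
    T1t: float = 1.3
    f: float = f_from_ml_per_100g_min(50.0)
    lam: float = 0.9
    v: float = 1.0
    M0b: float = 1.0
    alpha_inv: float = 0.85

    def __post_init__(self) -> None:
        for name in ("delta_t", "Delta_t", "T1b", "T1t", "f", "lam", "v", "M0b", "alpha_inv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha_inv > 1.0 or self.v > 1.0:
            raise ValueError("alpha_inv and v must be <= 1")

    @property
    def T1_app(self) -> float:
        """Apparent tissue relaxation time T1' with 1/T1' = 1/T1t + f/lam."""
        return 1.0 / (1.0 / self.T1t + self.f / self.lam)

    def with_(self, **kw) -> "KineticParams":
        return replace(self, **kw)


def angio_signal(
    params: KineticParams,
    schedule: FlipAngleSchedule,
    times: np.ndarray,
    tau: float,
) -> np.ndarray:
    """Macrovascular difference signal excited by each pulse.

    S_i = 2 M0b alpha_inv v sin(alpha_i) exp(-delta_t/T1b) R_i while the
    labeled bolus occupies the voxel (delta_t < t_i <= delta_t + tau), zero
    before arrival and after washout.  Dispersion is ignored, so blood decays
    with T1b for exactly the transit time regardless of when it is imaged.
    """
    times = np.asarray(times, dtype=np.float64)
    if times.size != len(schedule):
        raise ValueError("times and schedule must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    R = rf_attenuation(schedule)
    amp = (
        2.0 * params.M0b * params.alpha_inv * params.v
        * np.sin(schedule.radians) * np.exp(-params.delta_t / params.T1b) * R
    )
    in_bolus = (times > params.delta_t) & (times <= params.delta_t + tau)
    return np.where(in_bolus, amp, 0.0)


def buxton_casl_delta_m(
    t: float | np.ndarray, params: KineticParams, tau: float
) -> np.ndarray:
    """Single-compartment continuous-labeling tissue difference signal.

    Piecewise closed form with apparent relaxation T1' (clearance by both T1
    decay and venous outflow f/lam):

    * t <  Delta_t: 0 (label not yet arrived)
    * Delta_t <= t < tau + Delta_t (inflow):
        2 M0b f alpha_inv T1' exp(-Delta_t/T1b) (1 - exp(-(t-Delta_t)/T1'))
    * t >= tau + Delta_t (washout): the inflow plateau factor
        (1 - exp(-tau/T1')) decaying as exp(-(t-tau-Delta_t)/T1')
    """
    t = np.asarray(t, dtype=np.float64)
    T1p = params.T1_app
    pre = (
        2.0 * params.M0b * params.f * params.alpha_inv * T1p
        * np.exp(-params.Delta_t / params.T1b)
    )
    dm = np.zeros_like(t)
    inflow = (t >= params.Delta_t) & (t < tau + params.Delta_t)
    washout = t >= tau + params.Delta_t
    dm[inflow] = pre * (1.0 - np.exp(-(t[inflow] - params.Delta_t) / T1p))
    dm[washout] = (
        pre * (1.0 - np.exp(-tau / T1p))
        * np.exp(-(t[washout] - tau - params.Delta_t) / T1p)
    )
    return dm


def perfusion_signal(
    params: KineticParams,
    schedule: FlipAngleSchedule,
    times: np.ndarray,
    tau: float,
) -> np.ndarray:
    """Tissue perfusion difference signal excited by each pulse.

    S_perf,i = DeltaM_B(t_i) R_i sin(alpha_i): the accumulated tissue
    magnetization at the pulse time, attenuated by all earlier pulses and
    tipped by the current one.
    """
    times = np.asarray(times, dtype=np.float64)
    if times.size != len(schedule):
        raise ValueError("times and schedule must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    R = rf_attenuation(schedule)
    return buxton_casl_delta_m(times, params, tau) * R * np.sin(schedule.radians)
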