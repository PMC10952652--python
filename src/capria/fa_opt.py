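"""Flip-angle schedule optimization for combined angiography + perfusion ASL.

The angiographic and perfusion signals are simulated over a grid of candidate
(alpha_1, alpha_N) quadratic schedules and averaged over ranges of arterial
and tissue transit times (blood volume and perfusion only scale the signals,
so they need not be searched).  Each mean-signal surface is normalized to its
grid maximum; a combined surface down-weights angiography by 1/2 because the
perfusion signal has much lower SNR.  The constant-flip-angle (CFA) optimum
is the argmax along the alpha_1 = alpha_N diagonal; the variable-flip-angle
(VFA) choice is the grid point within 95% of the combined peak that lies
closest to the origin, minimizing attenuation of late-arriving blood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinetics import (
    FlipAngleSchedule,
    KineticParams,
    angio_signal,
    make_schedule,
    perfusion_signal,
)
from .trajectory import AcquisitionConfig

__all__ = [
    "MetricGrid",
    "mean_angio_metric",
    "mean_perf_metric",
    "combined_metric",
    "compute_metric_grid",
    "select_cfa",
    "select_vfa",
    "default_delta_t_grid",
    "default_Delta_t_grid",
]


def default_delta_t_grid(n: int = 9) -> np.ndarray:
    """Arterial transit times: uniform over the healthy range 0.2-1.0 s."""
    return np.linspace(0.2, 1.0, n)


def default_Delta_t_grid(n: int = 7) -> np.ndarray:
    """Tissue transit times: uniform over the healthy range 0.5-2.0 s."""
    return np.linspace(0.5, 2.0, n)


def mean_angio_metric(
    schedule: FlipAngleSchedule,
    delta_ts: np.ndarray,
    times: np.ndarray,
    tau: float,
    params: KineticParams | None = None,
) -> float:
    """Mean angiographic signal while labeled blood is present in the voxel.

    For each arterial transit time, S_angio,i is averaged over the pulses
    with delta_t <= t_i < tau + delta_t, then averaged across the delta_t
    grid.  An empty averaging window is an error (the readout misses the
    bolus entirely for that transit time).
    """
    params = params or KineticParams()
    times = np.asarray(times, dtype=np.float64)
    vals = []
    for dt in np.atleast_1d(delta_ts):
        window = (times >= dt) & (times < tau + dt)
        if not window.any():
            raise ValueError(f"no pulses fall in the bolus window for delta_t={dt:.3f}s")
        s = angio_signal(params.with_(delta_t=float(dt)), schedule, times, tau)
        vals.append(s[window].mean())
    return float(np.mean(vals))


def mean_perf_metric(
    schedule: FlipAngleSchedule,
    Delta_ts: np.ndarray,
    times: np.ndarray,
    tau: float,
    params: KineticParams | None = None,
) -> float:
    """Mean perfusion signal after all labeled blood has reached the tissue.

    For each tissue transit time, S_perf,i is averaged over pulses with
    t_i >= tau + Delta_t (where the signal is approximately proportional to
    flow), then averaged across the Delta_t grid.  A transit time whose
    window extends beyond the readout contributes zero, with a warning.
    """
    params = params or KineticParams()
    times = np.asarray(times, dtype=np.float64)
    vals = []
    for Dt in np.atleast_1d(Delta_ts):
        window = times >= tau + Dt
        if not window.any():
            warnings.warn(
                f"readout ends before tau + Delta_t for Delta_t={Dt:.3f}s; "
                "this transit time contributes zero",
                stacklevel=2,
            )
            vals.append(0.0)
            continue
        s = perfusion_signal(params.with_(Delta_t=float(Dt)), schedule, times, tau)
        vals.append(s[window].mean())
    return float(np.mean(vals))


def combined_metric(S_angio_bar: np.ndarray, S_perf_bar: np.ndarray) -> np.ndarray:
    """Weighted sum (1/2 on angiography) of the normalized metrics, renormalized."""
    combined = 0.5 * S_angio_bar + S_perf_bar
    return combined / np.nanmax(combined)


@dataclass(frozen=True)
class MetricGrid:
    """Normalized metric surfaces over the (alpha_1, alpha_N) plane.

    Entries with alpha_1 > alpha_N (decreasing schedules) are NaN; the
    diagonal alpha_1 == alpha_N represents CFA schedules.
    """

    alpha1_axis: np.ndarray  # degrees
    alphaN_axis: np.ndarray  # degrees
    S_angio_bar: np.ndarray  # (len(alpha1), len(alphaN)), max 1
    S_perf_bar: np.ndarray
    S_combined_bar: np.ndarray


def compute_metric_grid(
    config: AcquisitionConfig | None = None,
    params: KineticParams | None = None,
    alpha_min: float = 1.0,
    alpha_max: float = 20.0,
    alpha_step: float = 0.5,
    delta_ts: np.ndarray | None = None,
    Delta_ts: np.ndarray | None = None,
) -> MetricGrid:
    """Evaluate the normalized angio/perfusion/combined metrics on a grid."""
    from .trajectory import full_protocol

    config = config or full_protocol()
    params = params or KineticParams()
    delta_ts = default_delta_t_grid() if delta_ts is None else np.asarray(delta_ts)
    Delta_ts = default_Delta_t_grid() if Delta_ts is None else np.asarray(Delta_ts)
    times = config.spoke_times()
    tau = config.tau
    N = config.n_spokes_per_prep

    axis = np.arange(alpha_min, alpha_max + 0.5 * alpha_step, alpha_step)
    n = axis.size
    A = np.full((n, n), np.nan)
    P = np.full((n, n), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # long-Delta_t windows may be empty
        for i1, a1 in enumerate(axis):
            for iN, aN in enumerate(axis):
                if aN < a1:
                    continue
                kind = "constant" if aN == a1 else "quadratic-variable"
                sched = make_schedule(kind, float(a1), float(aN), N)
                A[i1, iN] = mean_angio_metric(sched, delta_ts, times, tau, params)
                P[i1, iN] = mean_perf_metric(sched, Delta_ts, times, tau, params)
    A_bar = A / np.nanmax(A)
    P_bar = P / np.nanmax(P)
    return MetricGrid(
        alpha1_axis=axis, alphaN_axis=axis.copy(),
        S_angio_bar=A_bar, S_perf_bar=P_bar,
        S_combined_bar=combined_metric(A_bar, P_bar),
    )


def select_cfa(grid: MetricGrid) -> float:
    """Best constant flip angle: argmax of the combined metric on the diagonal.

    Ties are broken toward the smaller angle.
    """
    common = np.intersect1d(grid.alpha1_axis, grid.alphaN_axis)
    if common.size == 0:
        raise ValueError("grid has no diagonal alpha_1 == alpha_N entries")
    vals = []
    for a in common:
        i1 = int(np.argmin(np.abs(grid.alpha1_axis - a)))
        iN = int(np.argmin(np.abs(grid.alphaN_axis - a)))
        vals.append(grid.S_combined_bar[i1, iN])
    vals = np.asarray(vals)
    best = np.nanmax(vals)
    return float(common[np.flatnonzero(vals == best)[0]])


def select_vfa(grid: MetricGrid, threshold: float = 0.95) -> tuple[float, float]:
    """VFA (alpha_1, alpha_N) within ``threshold`` of the combined peak,
    closest to the origin in Euclidean (alpha_1, alpha_N) distance.

    Ties are broken by smaller alpha_N, then smaller alpha_1.
    """
    C = grid.S_combined_bar
    peak = np.nanmax(C)
    i1s, iNs = np.nonzero(np.nan_to_num(C, nan=-np.inf) >= threshold * peak)
    cands = [
        (float(grid.alpha1_axis[i1]), float(grid.alphaN_axis[iN]))
        for i1, iN in zip(i1s, iNs)
    ]
    cands.sort(key=lambda aa: (aa[0] ** 2 + aa[1] ** 2, aa[1], aa[0]))
    return cands[0]
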