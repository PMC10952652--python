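"""Split-scan repeatability statistics and the masks they are computed in.

Image quality of the nonlinearly reconstructed, heavily undersampled series
is hard to summarize with conventional SNR, so the acquisition is split into
two halves, each reconstructed independently, and the per-frame Pearson
correlation of voxel magnitudes inside a mask is used as a stability
surrogate.  Correlations are Fisher-transformed (z = atanh r) before any
averaging or statistics, which stabilizes their variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import ball

from .kinetics import KineticParams, angio_signal, make_schedule, perfusion_signal

__all__ = [
    "RepeatabilityResult",
    "vessel_mask",
    "split_half_repeatability",
    "fisher_z",
    "epi_split_correction",
    "refit_split_correction",
    "EPI_CORRECTION_COEFFS",
]

# Empirical quadratic mapping r_reduced -> r_full for 4-of-5-pair EPI data.
EPI_CORRECTION_COEFFS = (-0.2231, 1.2221, 0.0004)


@dataclass
class RepeatabilityResult:
    """Per-frame split-half correlations within one mask."""

    r_per_frame: np.ndarray
    z_per_frame: np.ndarray
    mask_id: str
    n_voxels: int
    frame_pld: np.ndarray | None = None

    def to_frame(self, **extra) -> pd.DataFrame:
        """Tidy table: one row per frame with r, z and provenance columns."""
        df = pd.DataFrame(
            {
                "frame": np.arange(1, self.r_per_frame.size + 1),
                "pld_s": self.frame_pld
                if self.frame_pld is not None
                else np.full(self.r_per_frame.size, np.nan),
                "mask": self.mask_id,
                "r": self.r_per_frame,
                "z": self.z_per_frame,
            }
        )
        for k, v in extra.items():
            df[k] = v
        return df


def vessel_mask(
    series_list,
    brain_mask: np.ndarray,
    voxel_size: float,
    threshold: float = 0.7,
    percentile: float = 99.9,
    dilation_radius_mm: float = 3.5,
) -> np.ndarray:
    """Dilated bright-vessel mask from one or more angiographic series.

    The magnitude series are averaged across reconstructions and time, masked
    to the brain, thresholded at ``threshold`` times the given percentile of
    the in-brain intensity, and dilated with a spherical structuring element
    of radius ``dilation_radius_mm`` (converted to voxels by rounding).
    """
    if not isinstance(series_list, (list, tuple)):
        series_list = [series_list]
    mean_img = np.mean(
        [np.abs(np.asarray(getattr(s, "frames", s))).mean(axis=0) for s in series_list],
        axis=0,
    )
    if mean_img.shape != brain_mask.shape:
        raise ValueError("series and brain mask must share one grid")
    masked = mean_img * brain_mask
    cut = threshold * np.percentile(masked[brain_mask > 0], percentile)
    core = masked > cut
    if not core.any():
        raise ValueError(
            f"empty vessel mask: threshold {cut:.4g} exceeds all intensities "
            f"({percentile}th percentile {cut / threshold:.4g})"
        )
    radius_vox = int(round(dilation_radius_mm / voxel_size))
    if radius_vox >= 1:
        core = ndimage.binary_dilation(core, structure=ball(radius_vox))
    return core


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    return np.arctanh(r)


def split_half_repeatability(
    series_half1,
    series_half2,
    mask: np.ndarray,
    mask_id: str = "mask",
) -> RepeatabilityResult:
    """Per-frame Pearson correlation of masked voxel magnitudes across halves.

    Frames where either half is constant within the mask have undefined
    correlation and are reported as NaN (missing), not zero.
    """
    a = np.abs(np.asarray(getattr(series_half1, "frames", series_half1)))
    b = np.abs(np.asarray(getattr(series_half2, "frames", series_half2)))
    if a.shape != b.shape:
        raise ValueError("halves must share grid and frame count")
    if a.shape[1:] != mask.shape:
        raise ValueError("mask grid mismatch")
    sel = mask > 0
    n_vox = int(sel.sum())
    if n_vox < 2:
        raise ValueError("mask must contain at least 2 voxels")
    rs = np.empty(a.shape[0])
    for f in range(a.shape[0]):
        x = a[f][sel]
        y = b[f][sel]
        if x.std() == 0 or y.std() == 0:
            rs[f] = np.nan
            continue
        rs[f] = np.corrcoef(x, y)[0, 1]
    with np.errstate(invalid="ignore"):
        zs = np.arctanh(np.clip(rs, -1 + 1e-15, 1 - 1e-15))
        zs[np.isnan(rs)] = np.nan
    pld = getattr(series_half1, "frame_pld", None)
    return RepeatabilityResult(
        r_per_frame=rs, z_per_frame=zs, mask_id=mask_id, n_voxels=n_vox,
        frame_pld=None if pld is None else np.asarray(pld),
    )


def epi_split_correction(r_reduced):
    """Map 4-of-5-pairs EPI repeatability to its full-scan-time equivalent.

    r_full = -0.2231 r^2 + 1.2221 r + 0.0004, valid for r in [0, 1]; the
    quadratic compensates the extra noise in each half when one of five
    label/control pairs is discarded.
    """
    r = np.asarray(r_reduced, dtype=np.float64)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("r_reduced must lie in [0, 1]")
    a, b, c = EPI_CORRECTION_COEFFS
    out = a * r**2 + b * r + c
    return float(out) if np.isscalar(r_reduced) else out


def refit_split_correction(
    n_signals: int = 3000,
    noise_levels=None,
    seed: int = 0,
    time_fraction: float = 4.0 / 5.0,
) -> tuple[np.ndarray, float]:
    """Regenerate an empirical reduced-to-full repeatability correction.

    Signal timecourses are drawn from the kinetic models over the phantom's
    physiological ranges (mixed macrovascular and perfusion voxels with
    random transit times and amplitudes).  For each noise level the split-
    half correlation over ``n_signals`` voxels is computed for the full scan
    (noise sigma) and for the time-reduced scan (noise sigma / time_fraction,
    i.e. 5/4 higher for a 4/5 scan); a quadratic is fit to the pooled
    (r_reduced, r_full) pairs.  Returns (coefficients highest power first,
    RMS fit residual).
    """
    rng = np.random.default_rng(seed)
    if noise_levels is None:
        noise_levels = np.geomspace(0.03, 3.0, 12)
    N, tau, dt = 216, 1.4, 1.9397 / 216
    times = tau + np.arange(N) * dt
    frames = np.arange(36 // 2, N, 36)  # one sample per broad window
    sched = make_schedule("quadratic-variable", 2.0, 9.0, N)

    sig = np.empty((n_signals, frames.size))
    for s in range(n_signals):
        if rng.random() < 0.3:
            p = KineticParams(delta_t=rng.uniform(0.2, 1.0), v=rng.uniform(0.3, 1.0))
            tc = angio_signal(p, sched, times, tau)
        else:
            p = KineticParams(
                Delta_t=rng.uniform(0.5, 2.0),
                f=rng.uniform(0.5, 1.5) * KineticParams().f,
            )
            tc = perfusion_signal(p, sched, times, tau)
        sig[s] = tc[frames] / np.abs(tc).max().clip(1e-12)

    r_red, r_full = [], []
    for sigma in np.atleast_1d(noise_levels):
        for arm, sig_arm in (("full", sigma), ("reduced", sigma / time_fraction)):
            n1 = sig + sig_arm * rng.standard_normal(sig.shape)
            n2 = sig + sig_arm * rng.standard_normal(sig.shape)
            rs = [
                np.corrcoef(n1[:, f], n2[:, f])[0, 1] for f in range(frames.size)
            ]
            (r_full if arm == "full" else r_red).extend(rs)
    r_red = np.asarray(r_red)
    r_full = np.asarray(r_full)
    ok = (r_red > -0.2) & (r_full > -0.2)
    coeffs = np.polyfit(r_red[ok], r_full[ok], 2)
    resid = float(np.sqrt(np.mean((np.polyval(coeffs, r_red[ok]) - r_full[ok]) ** 2)))
    return coeffs, resid
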