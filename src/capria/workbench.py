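"""Run configuration, YAML I/O and the end-to-end demo pipeline.

A single :class:`RunConfig` mirrors the acquisition, phantom, flip-angle,
reconstruction and assessment settings, with a global seed and a ``scale``
knob that shrinks the full protocol geometry (matrix, pair count) for desk
runs while leaving the timing untouched.  Units in files are SI (seconds,
mm); flip angles are degrees.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assess, recon
from .kinetics import FlipAngleSchedule, make_schedule
from .phantom import (
    PhantomSpec,
    RawContainer,
    default_phantom,
    make_coil_model,
    simulate_kspace,
    truth_frame_series,
)
from .recon import ReconConfig, reconstruct_series
from .trajectory import AcquisitionConfig, bin_frames, build_schedule

logger = logging.getLogger("capria")

__all__ = ["RunConfig", "simulate_run", "reconstruct_run", "assess_run", "sweep_lambda"]


@dataclass
class RunConfig:
    """Nested pipeline configuration; defaults follow the full protocol,
    scaled by ``scale`` (1.0 = full 160^3 / 88-pair geometry)."""

    scale: float = 0.3
    seed: int = 0
    n_coils: int = 8
    fa_kind: str = "quadratic-variable"
    fa_alpha1: float = 2.0
    fa_alphaN: float = 9.0
    angio_window_spokes: int = 24
    perf_window_spokes: int = 36
    perf_matrix_fraction: float = 0.325  # 52/160 of the acquisition matrix
    noise_sigma: float = 0.2
    phase_drift: float = 0.005
    acquisition: dict = field(default_factory=dict)   # AcquisitionConfig overrides
    recon: dict = field(default_factory=dict)         # ReconConfig overrides
    out_dir: str = "capria_out"

    _SCHEMA = {
        "scale": float, "seed": int, "n_coils": int, "fa_kind": str,
        "fa_alpha1": float, "fa_alphaN": float, "angio_window_spokes": int,
        "perf_window_spokes": int, "perf_matrix_fraction": float,
        "noise_sigma": float, "phase_drift": float,
        "acquisition": dict, "recon": dict, "out_dir": str,
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        errors = [k for k in raw if k not in cls._SCHEMA]
        if errors:
            raise ValueError(f"unknown config fields: {', '.join(sorted(errors))}")
        for k, v in raw.items():
            want = cls._SCHEMA[k]
            if want is float and isinstance(v, int):
                continue
            if not isinstance(v, want):
                raise ValueError(f"config field '{k}': expected {want.__name__}, got {type(v).__name__}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def acquisition_config(self) -> AcquisitionConfig:
        base = AcquisitionConfig()
        matrix = max(8, int(round(base.matrix * self.scale / 2) * 2))
        pairs = max(2, int(round(base.n_pairs * self.scale / 2) * 2))
        kw = dict(matrix=matrix, n_pairs=pairs)
        kw.update(self.acquisition)
        return AcquisitionConfig(**kw)

    def fa_schedule(self, N: int) -> FlipAngleSchedule:
        return make_schedule(self.fa_kind, self.fa_alpha1, self.fa_alphaN, N)

    def recon_config(self, solver: str = "llr") -> ReconConfig:
        kw = dict(solver=solver, seed=self.seed, n_virtual_coils=min(self.n_coils, 4))
        kw.update(self.recon)
        return ReconConfig(**kw)

    def phantom_spec(self, config: AcquisitionConfig) -> PhantomSpec:
        # noise_sigma is referenced to the 48^3 desk grid; scale with voxel
        # count so the image-domain SNR regime is matrix-independent
        return default_phantom(
            grid=config.matrix, fov=config.fov,
            noise_sigma=self.noise_sigma * (config.matrix / 48) ** 3,
            phase_drift=self.phase_drift,
            seed=self.seed,
        )


def _stage(name: str, t0: float, **params) -> None:
    digest = ",".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s wall=%.1fs %s", name, time.time() - t0, digest)


def simulate_run(cfg: RunConfig, out: Path | str | None = None) -> RawContainer:
    """Trajectory + phantom -> raw k-space container (optionally saved)."""
    t0 = time.time()
    acq = cfg.acquisition_config()
    spec = cfg.phantom_spec(acq)
    fa = cfg.fa_schedule(acq.n_spokes_per_prep)
    coils = make_coil_model(acq.matrix, acq.fov, n_coils=cfg.n_coils, seed=cfg.seed)
    sched = build_schedule(acq)
    container = simulate_kspace(spec, coils, sched, acq, fa)
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        container.save(out)
    _stage("simulate", t0, matrix=acq.matrix, pairs=acq.n_pairs, seed=cfg.seed)
    return container


def reconstruct_run(
    container: RawContainer,
    cfg: RunConfig,
    solver: str = "llr",
    out_dir: Path | str | None = None,
):
    """Angio (full matrix, short window) + perfusion (low matrix, broad window)."""
    t0 = time.time()
    acq = container.config
    dt = acq.spoke_interval
    rcfg = cfg.recon_config(solver)
    angio = reconstruct_series(container, cfg.angio_window_spokes * dt, rcfg)
    low = max(8, int(round(acq.matrix * cfg.perf_matrix_fraction / 2) * 2))
    perf = reconstruct_series(container, cfg.perf_window_spokes * dt, rcfg, matrix=low)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        angio.to_nifti(out_dir / f"angio_{solver}.nii.gz")
        perf.to_nifti(out_dir / f"perfusion_{solver}.nii.gz")
    _stage("recon", t0, solver=solver, angio_frames=angio.n_frames, perf_frames=perf.n_frames)
    return angio, perf


def assess_run(
    halves_angio: tuple,
    halves_perf: tuple,
    brain_mask: np.ndarray,
    voxel_size: float,
    method: str = "llr",
) -> pd.DataFrame:
    """Masks + per-frame r/z for angio (dilated vessel mask) and perfusion
    (brain mask) sections, as one tidy table."""
    t0 = time.time()
    vmask = assess.vessel_mask(list(halves_angio), brain_mask, voxel_size)
    rows = []
    res_a = assess.split_half_repeatability(*halves_angio, vmask, mask_id="vessel-dilated")
    rows.append(res_a.to_frame(section="angio", method=method))
    low = halves_perf[0].frames.shape[1]
    if brain_mask.shape[0] != low:
        zoom = low / brain_mask.shape[0]
        from scipy.ndimage import zoom as _zoom

        bmask_low = _zoom(brain_mask.astype(float), zoom, order=0) > 0.5
    else:
        bmask_low = brain_mask
    res_p = assess.split_half_repeatability(*halves_perf, bmask_low, mask_id="brain")
    rows.append(res_p.to_frame(section="perfusion", method=method))
    _stage("assess", t0, method=method)
    return pd.concat(rows, ignore_index=True)


def sweep_lambda(
    container: RawContainer,
    cfg: RunConfig,
    solver: str,
    lambdas,
    window_spokes: int | None = None,
    matrix: int | None = None,
) -> pd.DataFrame:
    """L-curve-style regularization sweep: data residual and truth NRMSE per lambda."""
    acq = container.config
    dt = acq.spoke_interval
    window = (window_spokes or cfg.perf_window_spokes) * dt
    rows = []
    for lam in lambdas:
        if solver == "llr":
            rcfg = replace(cfg.recon_config("llr"), lambda_llr=float(lam))
        else:
            rcfg = replace(
                cfg.recon_config("cg-sense"),
                lambda_spatial=float(lam), lambda_temporal=float(lam),
            )
        series = reconstruct_series(container, window, rcfg, matrix=matrix)
        row = {"lambda": float(lam), "solver": solver}
        hist = series.provenance.get("objective_history")
        if hist:
            row["objective"] = float(hist[-1])
        if container.spec is not None:
            binning = bin_frames(acq, window)
            truth = truth_frame_series(
                container.spec, acq, container.fa_schedule, binning
            )
            if truth.shape[1] != series.frames.shape[1]:
                from scipy.ndimage import zoom as _zoom

                z = series.frames.shape[1] / truth.shape[1]
                truth = np.stack([_zoom(t, z, order=1) for t in truth])
            scale = np.vdot(series.frames, truth).real / max(
                np.vdot(series.frames, series.frames).real, 1e-30
            )
            row["nrmse"] = float(
                np.linalg.norm(scale * np.abs(series.frames) - truth)
                / np.linalg.norm(truth)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def export_metric_grid(grid, path, plot: bool = False) -> None:
    """Persist a flip-angle metric grid as HDF5 (and optionally a contour plot)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("alpha1_axis", data=grid.alpha1_axis)
        h5.create_dataset("alphaN_axis", data=grid.alphaN_axis)
        h5.create_dataset("S_angio_bar", data=grid.S_angio_bar)
        h5.create_dataset("S_perf_bar", data=grid.S_perf_bar)
        h5.create_dataset("S_combined_bar", data=grid.S_combined_bar)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        for ax, (name, Z) in zip(
            axes,
            [
                ("angiography", grid.S_angio_bar),
                ("perfusion", grid.S_perf_bar),
                ("combined", grid.S_combined_bar),
            ],
        ):
            cs = ax.contourf(grid.alphaN_axis, grid.alpha1_axis, Z, levels=20)
            ax.plot(grid.alpha1_axis, grid.alpha1_axis, "k--", lw=1)
            ax.set_xlabel("alpha_N (deg)")
            ax.set_ylabel("alpha_1 (deg)")
            ax.set_title(name)
            fig.colorbar(cs, ax=ax)
        fig.tight_layout()
        fig.savefig(str(path).rsplit(".", 1)[0] + ".png", dpi=120)
        plt.close(fig)
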