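"""Seeded dynamic digital head phantom and multi-coil radial forward simulation.

The phantom emulates the statistical structure the reconstruction assumes: a
static head (nonzero so that coil-sensitivity estimation and phase alignment
have something to work with), a handful of vessel segments carrying the
macrovascular difference signal (each with its own arterial transit time and
blood volume), and ellipsoidal tissue regions carrying the perfusion signal
(each with its own flow and tissue arrival time).  Every spoke of the
acquisition samples the object at that spoke's pulse time, with the
flip-angle / RF-attenuation weighting of that pulse applied, so the object is
non-stationary *within* a reconstruction window exactly as in the real
sequence.

The label/control pair is synthesized as control = static + dM/2 and
label = static - dM/2: only the difference is physically modeled, and their
subtraction equals the ASL difference signal by construction.  The forward
simulator uses a wider-kernel, more oversampled NUFFT than the reconstruction
operators so the data are not generated by the same discretization the
solvers invert.

Everything is deterministic given the spec's seed; noise and phase drift are
drawn per preparation (keyed on (seed, preparation index)), so discarding
later preparations is bit-identical to never having acquired them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .kinetics import (
    FlipAngleSchedule,
    KineticParams,
    angio_signal,
    make_schedule,
    perfusion_signal,
)
from .nufft import Nufft3
from .trajectory import (
    AcquisitionConfig,
    SpokeSchedule,
    build_schedule,
    desk_protocol,
    schedule_sample_coords,
)

__all__ = [
    "VesselSegment",
    "TissueRegion",
    "PhantomSpec",
    "CoilModel",
    "make_coil_model",
    "region_maps",
    "region_timecourses",
    "truth_difference_series",
    "truth_frame_series",
    "simulate_kspace",
    "split_halves",
    "RawContainer",
    "default_phantom",
]

# Simulation-side NUFFT settings (deliberately finer than the recon default).
_SIM_NUFFT = dict(oversamp=2.0, width=6)


@dataclass(frozen=True)
class VesselSegment:
    """A straight artery segment: endpoints in mm (FOV-centered), radius mm."""

    start: tuple
    end: tuple
    radius: float
    delta_t: float  # arterial transit time, s
    v: float        # fractional blood volume inside the segment


@dataclass(frozen=True)
class TissueRegion:
    """An ellipsoidal perfused tissue region."""

    center: tuple
    semiaxes: tuple  # mm
    f: float         # perfusion, s^-1
    Delta_t: float   # tissue transit time, s
    T1t: float = 1.3


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic object; the seed fixes all randomness."""

    grid: int = 48
    fov: float = 183.0
    vessel_segments: tuple = ()
    tissue_regions: tuple = ()
    static_background: float = 1.0
    noise_sigma: float = 0.0   # complex-noise std per sample, per component
    phase_drift: float = 0.0   # rad per preparation, applied to the control
    edge_smooth_vox: float = 1.0  # Gaussian sigma of partial-volume boundaries
    seed: int = 0

    @property
    def voxel_size(self) -> float:
        return self.fov / self.grid


def default_phantom(grid: int = 48, fov: float = 183.0, **overrides) -> PhantomSpec:
    """The standard desk-scale head phantom.

    Three vessel segments mimic a basilar-like trunk feeding two branches
    with staggered arterial arrival (0.3 / 0.6 / 0.9 s); a large hemisphere-
    filling tissue region and a deep slower region carry perfusion.  The
    default noise level puts the single-frame perfusion difference signal
    near unit SNR (the regime the full-scale acquisition operates in, where
    perfusion frames are marginal and angiographic frames are clearly above
    the noise); because the k-space signal scales with the voxel count, the
    default sigma is referenced to the 48^3 grid and scaled by (grid/48)^3
    so the image-domain SNR regime is preserved at other desk scales.
    """
    kw = dict(
        grid=grid,
        fov=fov,
        vessel_segments=(
            VesselSegment((0.0, -22.0, -62.0), (0.0, -12.0, 8.0), 4.5, 0.3, 1.0),
            VesselSegment((0.0, -12.0, 8.0), (-42.0, 6.0, 38.0), 3.5, 0.6, 0.8),
            VesselSegment((0.0, -12.0, 8.0), (42.0, 6.0, 38.0), 3.5, 0.9, 0.8),
        ),
        tissue_regions=(
            TissueRegion((0.0, 0.0, 5.0), (62.0, 74.0, 58.0), 0.0100, 1.1),
            TissueRegion((0.0, 10.0, -10.0), (26.0, 30.0, 22.0), 0.0060, 1.6),
        ),
        static_background=1.0,
        noise_sigma=0.2 * (grid / 48) ** 3,
        phase_drift=0.005,
        seed=0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def _voxel_centers(grid: int, fov: float) -> np.ndarray:
    """Cell-centered voxel coordinates in mm, DC voxel at index grid//2."""
    ax = (np.arange(grid) - grid // 2) * (fov / grid)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([x, y, z], axis=-1)


def _head_mask(spec: PhantomSpec) -> np.ndarray:
    r = _voxel_centers(spec.grid, spec.fov)
    semi = np.array([0.38, 0.46, 0.36]) * spec.fov
    return np.sum((r / semi) ** 2, axis=-1) <= 1.0


def region_maps(spec: PhantomSpec) -> tuple[np.ndarray, list, np.ndarray]:
    """Rasterize the phantom.

    Returns (static image, list of (map, kind, region) for each dynamic
    region, head support mask).  Vessel/tissue overlap is resolved
    vessel-first, then in listed order; each voxel belongs to at most one
    dynamic region.  Region maps and the static image are smoothed with a
    Gaussian of ``edge_smooth_vox`` voxels: object boundaries in vivo are
    partial-volume smooth, and a voxel-sharp object would carry spectral
    energy beyond the sampled k-space ball that no acquisition of this
    nominal resolution could recover.
    """
    from scipy.ndimage import gaussian_filter

    def _smooth(img: np.ndarray) -> np.ndarray:
        if spec.edge_smooth_vox > 0:
            return gaussian_filter(img, spec.edge_smooth_vox)
        return img

    r = _voxel_centers(spec.grid, spec.fov)
    head = _head_mask(spec)
    static = _smooth(spec.static_background * head.astype(np.float64))

    claimed = np.zeros(head.shape, dtype=bool)
    regions = []
    for seg in spec.vessel_segments:
        a = np.asarray(seg.start, dtype=np.float64)
        b = np.asarray(seg.end, dtype=np.float64)
        ab = b - a
        tproj = np.clip(np.einsum("xyzk,k->xyz", r - a, ab) / (ab @ ab), 0.0, 1.0)
        dist = np.linalg.norm(r - (a + tproj[..., None] * ab), axis=-1)
        mask = (dist <= seg.radius) & ~claimed
        claimed |= mask
        regions.append((_smooth(mask.astype(np.float64)), "vessel", seg))
    for reg in spec.tissue_regions:
        c = np.asarray(reg.center, dtype=np.float64)
        semi = np.asarray(reg.semiaxes, dtype=np.float64)
        mask = (np.sum(((r - c) / semi) ** 2, axis=-1) <= 1.0) & head & ~claimed
        claimed |= mask
        regions.append((_smooth(mask.astype(np.float64)), "tissue", reg))
    return static, regions, head


def region_timecourses(
    spec: PhantomSpec,
    times: np.ndarray,
    fa_schedule: FlipAngleSchedule,
    tau: float,
) -> np.ndarray:
    """Per-pulse difference amplitude of each dynamic region, (n_regions, N)."""
    _, regions, _ = region_maps(spec)
    out = np.zeros((len(regions), np.asarray(times).size))
    for k, (_, kind, reg) in enumerate(regions):
        if kind == "vessel":
            p = KineticParams(delta_t=reg.delta_t, v=reg.v)
            out[k] = angio_signal(p, fa_schedule, times, tau)
        else:
            p = KineticParams(Delta_t=reg.Delta_t, f=reg.f, T1t=reg.T1t)
            out[k] = perfusion_signal(p, fa_schedule, times, tau)
    return out


def truth_difference_series(
    spec: PhantomSpec,
    times: np.ndarray,
    fa_schedule: FlipAngleSchedule,
    tau: float,
) -> np.ndarray:
    """Voxelwise ASL difference magnetization at each requested pulse time.

    Shape (len(times), grid, grid, grid).  Zero flip angles (or arrival
    after the readout) give identically zero frames.
    """
    _, regions, _ = region_maps(spec)
    amps = region_timecourses(spec, times, fa_schedule, tau)
    m = spec.grid
    out = np.zeros((np.asarray(times).size, m, m, m))
    for (mask, _, _), a in zip(regions, amps):
        out += a[:, None, None, None] * mask[None]
    return out


def truth_frame_series(
    spec: PhantomSpec,
    config: AcquisitionConfig,
    fa_schedule: FlipAngleSchedule,
    binning,
) -> np.ndarray:
    """Window-averaged ground-truth difference image per reconstruction frame."""
    times = config.spoke_times()
    _, regions, _ = region_maps(spec)
    amps = region_timecourses(spec, times, fa_schedule, config.tau)
    m = spec.grid
    out = np.zeros((binning.n_frames, m, m, m))
    for k, (first, last) in enumerate(binning.frame_windows):
        mean_amp = amps[:, first - 1 : last].mean(axis=1)
        for (mask, _, _), a in zip(regions, mean_amp):
            out[k] += a * mask
    return out


@dataclass
class CoilModel:
    """Smooth complex receive sensitivities over the image grid, (C, m, m, m)."""

    sens: np.ndarray

    @property
    def n_coils(self) -> int:
        return self.sens.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sens) ** 2, axis=0))


def make_coil_model(
    grid: int, fov: float, n_coils: int = 8, seed: int = 0
) -> CoilModel:
    """Gaussian-lobe sensitivities on a ring around the head with smooth phase.

    Coil c sits on a circle of radius 0.55 fov in a plane tilted along z; its
    magnitude is a broad Gaussian falloff from the coil center and its phase
    a low-order linear ramp plus a random offset (seeded).  The
    root-sum-of-squares is strictly positive over the FOV.
    """
    rng = np.random.default_rng([seed, 2305])
    r = _voxel_centers(grid, fov)
    ang = 2.0 * np.pi * np.arange(n_coils) / n_coils
    centers = 0.55 * fov * np.stack(
        [np.cos(ang), np.sin(ang), 0.25 * np.sin(2 * ang)], axis=1
    )
    sigma = 0.55 * fov
    sens = np.empty((n_coils,) + r.shape[:3], dtype=np.complex128)
    for c in range(n_coils):
        d2 = np.sum((r - centers[c]) ** 2, axis=-1)
        mag = 0.15 + np.exp(-d2 / (2.0 * sigma**2))
        ramp = rng.uniform(-0.5, 0.5, 3) / fov
        phase = 2.0 * np.pi * np.einsum("xyzk,k->xyz", r, ramp) + rng.uniform(0, 2 * np.pi)
        sens[c] = mag * np.exp(1j * phase)
    return CoilModel(sens=sens)


@dataclass
class RawContainer:
    """In-memory raw k-space container for one label/control acquisition.

    ``label``/``control`` have shape (n_spokes, n_samples, n_coils) with the
    spoke axis ordered preparation-major / within-preparation-minor (one row
    per unique spoke orientation; both conditions share the trajectory).
    """

    config: AcquisitionConfig
    schedule: SpokeSchedule          # label-condition subset, acquisition order
    coords: np.ndarray               # (S, K, 3) cycles/mm
    label: np.ndarray                # (S, K, C) complex64
    control: np.ndarray              # (S, K, C) complex64
    fa_schedule: FlipAngleSchedule
    sens_truth: np.ndarray | None = None      # (C, m, m, m) or None
    truth_static: np.ndarray | None = None
    spec: PhantomSpec | None = None

    @property
    def n_coils(self) -> int:
        return self.label.shape[2]

    @property
    def n_spokes(self) -> int:
        return self.label.shape[0]

    def save(self, path) -> None:
        """HDF5 layout: /kspace/{label,control}, /trajectory, /truth, attrs."""
        with h5py.File(path, "w") as h5:
            ks = h5.create_group("kspace")
            ks.create_dataset("label", data=self.label)
            ks.create_dataset("control", data=self.control)
            tr = h5.create_group("trajectory")
            self.schedule.to_hdf5(tr)
            tr.create_dataset("coords", data=self.coords)
            h5.attrs["fa_kind"] = self.fa_schedule.kind
            h5.attrs["fa_alpha1"] = self.fa_schedule.alpha1
            h5.attrs["fa_alphaN"] = self.fa_schedule.alphaN
            if self.sens_truth is not None:
                t = h5.create_group("truth")
                t.create_dataset("sens", data=self.sens_truth)
                t.create_dataset("static", data=self.truth_static)

    @classmethod
    def load(cls, path) -> "RawContainer":
        with h5py.File(path, "r") as h5:
            sched = SpokeSchedule.from_hdf5(h5["trajectory"])
            fa = make_schedule(
                str(h5.attrs["fa_kind"]),
                float(h5.attrs["fa_alpha1"]),
                float(h5.attrs["fa_alphaN"]),
                sched.config.n_spokes_per_prep,
            )
            sens = static = None
            if "truth" in h5:
                sens = h5["truth/sens"][()]
                static = h5["truth/static"][()]
            return cls(
                config=sched.config,
                schedule=sched,
                coords=h5["trajectory/coords"][()],
                label=h5["kspace/label"][()],
                control=h5["kspace/control"][()],
                fa_schedule=fa,
                sens_truth=sens,
                truth_static=static,
            )


def simulate_kspace(
    spec: PhantomSpec,
    coils: CoilModel,
    schedule: SpokeSchedule,
    config: AcquisitionConfig,
    fa_schedule: FlipAngleSchedule,
) -> RawContainer:
    """Forward-simulate the multi-coil label/control radial acquisition.

    For every spoke the sampled signal is the NUFFT of the coil-weighted
    object at that spoke's pulse time: static anatomy scaled by sin(alpha_i)
    plus/minus half the ASL difference of each dynamic region at its
    per-pulse amplitude.  I.i.d. complex Gaussian noise (std ``noise_sigma``
    per real/imag component) is drawn per preparation from a generator keyed
    on (seed, preparation), and the configured per-preparation phase drift is
    applied to the control condition.
    """
    if spec.grid != config.matrix or abs(spec.fov - config.fov) > 1e-9:
        raise ValueError("phantom grid/fov must match the acquisition config")
    if len(fa_schedule) != config.n_spokes_per_prep:
        raise ValueError("flip-angle schedule length must equal N")

    static, regions, _ = region_maps(spec)
    amps = region_timecourses(spec, config.spoke_times(), fa_schedule, config.tau)
    sin_a = np.sin(fa_schedule.radians)

    lab = schedule.select(schedule.cond == 0)
    order = np.lexsort((lab.within, lab.prep))
    lab = lab.select(order)
    coords = schedule_sample_coords(lab, config)  # (S, K, 3)
    S, K, _ = coords.shape
    C = coils.n_coils
    N = config.n_spokes_per_prep

    plan = Nufft3(
        coords.reshape(-1, 3), config.matrix, config.fov,
        cache_tables=False, **_SIM_NUFFT,
    )
    fields = [static] + [m for m, _, _ in regions]
    # spectra[r, c, :] = samples of coil c viewing region field r, all spokes
    spectra = np.empty((len(fields), C, S * K), dtype=np.complex128)
    for ri, fld in enumerate(fields):
        spectra[ri] = plan.forward_batch(coils.sens * fld[None])
    spectra = spectra.reshape(len(fields), C, S, K).transpose(0, 2, 3, 1)  # r,S,K,C

    i_idx = lab.within - 1                       # pulse index per spoke row
    static_part = spectra[0] * sin_a[i_idx][:, None, None]
    half_diff = np.zeros_like(static_part)
    for ri in range(len(regions)):
        half_diff += 0.5 * spectra[ri + 1] * amps[ri][i_idx][:, None, None]

    # C-contiguous so downstream reductions are bit-reproducible across
    # sliced-copy and freshly simulated containers
    control = np.ascontiguousarray((static_part + half_diff).astype(np.complex64))
    label = np.ascontiguousarray((static_part - half_diff).astype(np.complex64))

    for n in range(1, config.n_pairs + 1):
        rows = slice((n - 1) * N, n * N)
        rng = np.random.default_rng([spec.seed, n])
        if spec.noise_sigma > 0:
            shape = (2, N, K, C)
            noise = spec.noise_sigma * (
                rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
            )
            label[rows] += noise[0].astype(np.complex64)
            control[rows] += noise[1].astype(np.complex64)
        if spec.phase_drift != 0.0:
            control[rows] *= np.complex64(np.exp(1j * spec.phase_drift * (n - 1)))

    return RawContainer(
        config=config, schedule=lab, coords=coords,
        label=label, control=control, fa_schedule=fa_schedule,
        sens_truth=coils.sens, truth_static=static, spec=spec,
    )


def split_halves(container: RawContainer) -> tuple[RawContainer, RawContainer]:
    """Partition by preparation order into first / second halves.

    Because the golden-means counters continue across preparations, the first
    half is exactly the dataset a prospectively shorter scan would have
    acquired.  Odd pair counts split floor/ceil with a warning.
    """
    import warnings

    pairs = container.config.n_pairs
    if pairs < 2:
        raise ValueError("need at least 2 pairs to split")
    if pairs % 2:
        warnings.warn(f"odd pair count {pairs}: splitting {pairs // 2}/{pairs - pairs // 2}")
    n1 = pairs // 2

    def _sub(lo: int, hi: int) -> RawContainer:
        mask = (container.schedule.prep > lo) & (container.schedule.prep <= hi)
        cfg = replace(container.config, n_pairs=hi - lo)
        sched = container.schedule.select(mask)
        sched.config = cfg
        return RawContainer(
            config=cfg, schedule=sched,
            coords=container.coords[mask], label=container.label[mask],
            control=container.control[mask], fa_schedule=container.fa_schedule,
            sens_truth=container.sens_truth, truth_static=container.truth_static,
            spec=container.spec,
        )

    return _sub(0, n1), _sub(n1, pairs)


def simulate(
    spec: PhantomSpec | None = None,
    config: AcquisitionConfig | None = None,
    fa_schedule: FlipAngleSchedule | None = None,
    n_coils: int = 8,
) -> RawContainer:
    """Convenience end-to-end simulation with the desk-scale defaults."""
    config = config or desk_protocol()
    spec = spec or default_phantom(grid=config.matrix, fov=config.fov)
    fa_schedule = fa_schedule or make_schedule(
        "quadratic-variable", 2.0, 9.0, config.n_spokes_per_prep
    )
    coils = make_coil_model(spec.grid, spec.fov, n_coils=n_coils, seed=spec.seed)
    sched = build_schedule(config)
    return simulate_kspace(spec, coils, sched, config, fa_schedule)
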