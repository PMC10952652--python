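"""3D golden-means radial ("koosh-ball") spoke scheduling and sampling geometry.

The acquisition plays out a continuous train of spoiled-gradient-echo readouts
after each pseudo-continuous ASL preparation.  Spoke orientations follow the
multi-dimensional golden means so that *any* contiguous run of spokes covers
the sphere near-uniformly, letting the temporal window of the reconstruction
(and hence temporal resolution, undersampling factor and post-labeling delay)
be chosen retrospectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "AcquisitionConfig",
    "SpokeSchedule",
    "FrameBinning",
    "compute_golden_means",
    "spoke_orientation",
    "spoke_counter",
    "build_schedule",
    "readout_sample_coords",
    "undersampling_factor",
    "bin_frames",
    "full_protocol",
    "desk_protocol",
]


def compute_golden_means() -> tuple[float, float]:
    """Return the two 3D multi-dimensional golden means (phi1, phi2).

    phi2 is the real root of x^3 + x - 1 = 0 and phi1 = phi2**2; both lie in
    (0, 1).  Increments of the polar cosine by phi1 and the azimuth (in turns)
    by phi2 generate the near-uniform 3D radial ordering.
    """
    roots = np.roots([1.0, 0.0, 1.0, -1.0])
    phi2 = float(np.real(roots[np.abs(roots.imag) < 1e-9][0]))
    # polish with Newton so the defining identity holds to machine precision
    for _ in range(3):
        phi2 -= (phi2**3 + phi2 - 1.0) / (3.0 * phi2**2 + 1.0)
    phi1 = phi2 * phi2
    return phi1, phi2


def _frac(x: np.ndarray | float) -> np.ndarray | float:
    """Fractional part with an explicit floor subtraction (no drift)."""
    return x - np.floor(x)


def spoke_orientation(
    m: int | np.ndarray,
    phi1: float | None = None,
    phi2: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Polar and azimuthal angle (rad) of golden-means spoke counter ``m``.

    Even counters sample the upper hemisphere (cos(theta) = {m*phi1} >= 0);
    the direction of every other spoke is reversed (odd m: cos(theta)
    negated, azimuth rotated by half a turn) so that the asymmetric-echo
    (partial Fourier) readout still covers k-space evenly.
    """
    if phi1 is None or phi2 is None:
        phi1, phi2 = compute_golden_means()
    m = np.asarray(m)
    if np.any(m < 0):
        raise ValueError("spoke counter m must be nonnegative")
    m = m.astype(np.float64)
    odd = np.asarray(m % 2 == 1)
    cos_theta = np.where(odd, -_frac(m * phi1), _frac(m * phi1))
    phi_turns = np.where(odd, _frac(m * phi2 + 0.5), _frac(m * phi2))
    theta = np.arccos(cos_theta)
    phi = 2.0 * np.pi * phi_turns
    return theta, phi


def spoke_counter(i: int | np.ndarray, n: int | np.ndarray, M: int) -> np.ndarray:
    """Golden-means counter m = i - 1 + (n - 1) M for spoke i of preparation n.

    ``M`` is the spoke count of the maximum temporal window, so consecutive
    preparations continue the golden ordering where the previous window of
    interest left off.
    """
    i = np.asarray(i)
    n = np.asarray(n)
    if np.any(i < 1) or np.any(n < 1):
        raise ValueError("indices are 1-based: require i >= 1 and n >= 1")
    return np.asarray(i - 1 + (n - 1) * M, dtype=np.int64)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sequence timing and geometry for one combined angio/perfusion protocol.

    All times in seconds, lengths in mm.  ``spoke_interval`` (the excitation
    repetition time) is derived as readout_duration_after_label / N, which is
    treated as authoritative over any rounded printed value.
    """

    tau: float = 1.4                 # PCASL labeling duration
    readout_duration_after_label: float = 1.9397
    n_spokes_per_prep: int = 216     # N
    n_pairs: int = 88
    t_max: float = 0.3233            # maximum temporal window
    matrix: int = 160                # isotropic reconstruction matrix
    fov: float = 183.0               # isotropic field of view, mm
    pf_factor: float = 0.79          # readout partial Fourier (asymmetric echo)
    post_label_gap: float = 0.0      # dead time between labeling end and pulse 1
    pair_order: str = "label-control"  # or "control-label"

    def __post_init__(self) -> None:
        if not (0.5 < self.pf_factor <= 1.0):
            raise ValueError("pf_factor must lie in (0.5, 1] (pf <= 0.5 leaves no echo)")
        if self.n_spokes_per_prep < 1 or self.n_pairs < 1:
            raise ValueError("n_spokes_per_prep and n_pairs must be positive")
        if self.tau <= 0 or self.readout_duration_after_label <= 0 or self.t_max <= 0:
            raise ValueError("timings must be positive")
        if self.matrix < 2 or self.fov <= 0:
            raise ValueError("invalid matrix/fov")
        if self.pair_order not in ("label-control", "control-label"):
            raise ValueError("pair_order must be 'label-control' or 'control-label'")
        if self.n_spokes_per_prep % self.spokes_per_tmax != 0:
            raise ValueError(
                f"N={self.n_spokes_per_prep} must be an integer multiple of "
                f"M={self.spokes_per_tmax} so frames tile the readout"
            )

    @property
    def spoke_interval(self) -> float:
        """Time between excitations (the sequence TR), seconds."""
        return self.readout_duration_after_label / self.n_spokes_per_prep

    @property
    def spokes_per_tmax(self) -> int:
        """M = round(t_max / spoke_interval)."""
        return int(round(self.t_max / self.spoke_interval))

    @property
    def voxel_size(self) -> float:
        """Nominal isotropic voxel size, mm."""
        return self.fov / self.matrix

    @property
    def readout_samples(self) -> int:
        """Samples per spoke: round(pf_factor * full-line count)."""
        return int(round(self.pf_factor * (self.matrix + 1)))

    @property
    def k_max(self) -> float:
        """Maximum sampled spatial frequency, cycles/mm."""
        return self.matrix / (2.0 * self.fov)

    def spoke_times(self) -> np.ndarray:
        """Pulse times t_i (s, from labeling onset) for i = 1..N."""
        i = np.arange(self.n_spokes_per_prep)
        return self.tau + self.post_label_gap + i * self.spoke_interval


def full_protocol(**overrides) -> AcquisitionConfig:
    """The full-scale in vivo protocol (160^3 matrix, 88 pairs, pf 0.79)."""
    return AcquisitionConfig(**overrides)


def desk_protocol(**overrides) -> AcquisitionConfig:
    """A workstation-scale protocol with identical timing but a 48^3 matrix."""
    kw = dict(matrix=48, n_pairs=16)
    kw.update(overrides)
    return AcquisitionConfig(**kw)


@dataclass
class SpokeSchedule:
    """Ordered acquisition list: one row per excitation of the whole scan."""

    m: np.ndarray          # golden counter, int64
    theta: np.ndarray      # polar angle, rad
    phi: np.ndarray        # azimuth, rad
    prep: np.ndarray       # 1-based preparation (pair) index
    within: np.ndarray     # 1-based within-preparation spoke index i
    cond: np.ndarray       # 0 = label, 1 = control
    t: np.ndarray          # time since that preparation's labeling onset, s
    config: AcquisitionConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.m.size

    def select(self, mask: np.ndarray) -> "SpokeSchedule":
        return SpokeSchedule(
            self.m[mask], self.theta[mask], self.phi[mask], self.prep[mask],
            self.within[mask], self.cond[mask], self.t[mask], self.config,
        )

    def directions(self) -> np.ndarray:
        """Unit spoke direction vectors, shape (n_spokes, 3)."""
        st = np.sin(self.theta)
        return np.stack(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)], axis=1
        )

    def assert_paired(self) -> None:
        """Label and control schedules must be spoke-for-spoke identical."""
        lab = self.cond == 0
        ctl = self.cond == 1
        key_l = np.lexsort((self.within[lab], self.prep[lab]))
        key_c = np.lexsort((self.within[ctl], self.prep[ctl]))
        if not (
            lab.sum() == ctl.sum()
            and np.array_equal(self.m[lab][key_l], self.m[ctl][key_c])
            and np.array_equal(self.within[lab][key_l], self.within[ctl][key_c])
        ):
            raise AssertionError("label/control spoke pairing broken")

    def to_hdf5(self, group: h5py.Group) -> None:
        """Persist as datasets m, theta, phi, t, prep, within, cond.

        Byte layout: little-endian int64 for counters/indices, float64 for
        angles (rad) and times (s); cond is uint8 with 0=label, 1=control.
        """
        group.create_dataset("m", data=self.m.astype("<i8"))
        group.create_dataset("theta", data=self.theta.astype("<f8"))
        group.create_dataset("phi", data=self.phi.astype("<f8"))
        group.create_dataset("t", data=self.t.astype("<f8"))
        group.create_dataset("prep", data=self.prep.astype("<i8"))
        group.create_dataset("within", data=self.within.astype("<i8"))
        group.create_dataset("cond", data=self.cond.astype("u1"))
        if self.config is not None:
            for k, v in vars(self.config).items():
                group.attrs[k] = v

    @classmethod
    def from_hdf5(cls, group: h5py.Group) -> "SpokeSchedule":
        cfg = None
        if "tau" in group.attrs:
            attrs = {k: group.attrs[k] for k in group.attrs}
            attrs["pair_order"] = str(attrs.get("pair_order", "label-control"))
            cfg = AcquisitionConfig(
                tau=float(attrs["tau"]),
                readout_duration_after_label=float(attrs["readout_duration_after_label"]),
                n_spokes_per_prep=int(attrs["n_spokes_per_prep"]),
                n_pairs=int(attrs["n_pairs"]),
                t_max=float(attrs["t_max"]),
                matrix=int(attrs["matrix"]),
                fov=float(attrs["fov"]),
                pf_factor=float(attrs["pf_factor"]),
                post_label_gap=float(attrs["post_label_gap"]),
                pair_order=attrs["pair_order"],
            )
        return cls(
            m=group["m"][()], theta=group["theta"][()], phi=group["phi"][()],
            prep=group["prep"][()], within=group["within"][()],
            cond=group["cond"][()].astype(np.int64), t=group["t"][()], config=cfg,
        )


def build_schedule(config: AcquisitionConfig) -> SpokeSchedule:
    """Build the full interleaved label/control spoke schedule.

    Each pair acquires its label preparation immediately followed by its
    control preparation (minimal label-control separation, so the same
    k-space spokes are revisited as soon as possible); both conditions use
    identical golden counters m(i, n).
    """
    N = config.n_spokes_per_prep
    M = config.spokes_per_tmax
    pairs = config.n_pairs
    i = np.arange(1, N + 1)
    t_one = config.spoke_times()

    per_prep_m = [spoke_counter(i, n, M) for n in range(1, pairs + 1)]
    conds = (0, 1) if config.pair_order == "label-control" else (1, 0)

    m_all, prep_all, within_all, cond_all, t_all = [], [], [], [], []
    for n in range(1, pairs + 1):
        for c in conds:
            m_all.append(per_prep_m[n - 1])
            prep_all.append(np.full(N, n, dtype=np.int64))
            within_all.append(i.astype(np.int64))
            cond_all.append(np.full(N, c, dtype=np.int64))
            t_all.append(t_one)
    m = np.concatenate(m_all)
    theta, phi = spoke_orientation(m)
    sched = SpokeSchedule(
        m=m, theta=theta, phi=phi,
        prep=np.concatenate(prep_all), within=np.concatenate(within_all),
        cond=np.concatenate(cond_all), t=np.concatenate(t_all), config=config,
    )
    sched.assert_paired()
    return sched


def readout_sample_coords(
    theta: float, phi: float, config: AcquisitionConfig
) -> np.ndarray:
    """k-space sample coordinates (cycles/mm) along one spoke, shape (K, 3).

    The spoke is a diameter line through the origin along
    (sin(theta)cos(phi), sin(theta)sin(phi), cos(theta)); the asymmetric echo
    spans radial coordinate -(2 pf - 1) k_max .. +k_max with
    round(pf * full-line count) uniformly spaced samples (spacing 1/fov for
    a full echo, within rounding of it otherwise).
    """
    k_max = config.k_max
    n = config.readout_samples
    r = np.linspace(-(2.0 * config.pf_factor - 1.0) * k_max, k_max, n)
    d = np.array(
        [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
    )
    return r[:, None] * d[None, :]


def schedule_sample_coords(sched: SpokeSchedule, config: AcquisitionConfig) -> np.ndarray:
    """Sample coordinates for every spoke of a schedule, shape (S, K, 3)."""
    k_max = config.k_max
    n = config.readout_samples
    r = np.linspace(-(2.0 * config.pf_factor - 1.0) * k_max, k_max, n)
    d = sched.directions()
    return r[None, :, None] * d[:, None, :]


def undersampling_factor(matrix: int, spokes_per_frame: int) -> float:
    """Acceleration R = (pi matrix^2 / 2) / spokes relative to radial Nyquist.

    pi * matrix^2 / 2 is the number of diameter spokes needed for Nyquist
    sampling of a 3D radial trajectory at the given matrix size.
    """
    if matrix <= 0 or spokes_per_frame <= 0:
        raise ValueError("matrix and spoke count must be positive")
    return (np.pi * matrix**2 / 2.0) / spokes_per_frame


@dataclass(frozen=True)
class FrameBinning:
    """Contiguous within-preparation spoke windows defining reconstruction frames."""

    frame_windows: tuple  # ((first_i, last_i), ...) 1-based inclusive
    frame_pld: np.ndarray  # s, window-center convention
    window_duration: float  # s
    spokes_per_frame: int

    @property
    def n_frames(self) -> int:
        return len(self.frame_windows)


def bin_frames(config: AcquisitionConfig, window: float) -> FrameBinning:
    """Tile the N within-preparation spokes into frames of a given window (s).

    The requested window must round to a spoke count that divides N evenly;
    otherwise the error lists the nearest valid windows.  Frame k's
    post-labeling delay uses the window-center convention
    PLD_k = (k - 1/2) * W * spoke_interval.
    """
    N = config.n_spokes_per_prep
    dt = config.spoke_interval
    if window > config.t_max + 0.5 * dt:
        raise ValueError(f"window {window:.4f}s exceeds t_max {config.t_max:.4f}s")
    W = int(round(window / dt))
    if W < 1 or N % W != 0:
        divisors = [d for d in range(1, N + 1) if N % d == 0]
        near = sorted(divisors, key=lambda d: abs(d * dt - window))[:4]
        raise ValueError(
            f"window of {W} spokes does not tile N={N}; nearest valid windows: "
            + ", ".join(f"{d * dt:.4f}s ({d} spokes)" for d in near)
        )
    n_frames = N // W
    windows = tuple(((k * W) + 1, (k + 1) * W) for k in range(n_frames))
    pld = (np.arange(1, n_frames + 1) - 0.5) * W * dt
    return FrameBinning(
        frame_windows=windows, frame_pld=pld, window_duration=W * dt, spokes_per_frame=W
    )
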