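"""Shared fixtures: all test data are generated programmatically and seeded.

The session-scoped desk-scale fixtures (48^3 grid, 8 coils, 16 label/control
pairs, full 216-spoke timing) are the standard study conditions of the
phantom; they are simulated once and shared by the reconstruction-quality and
repeatability tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from capria.kinetics import make_schedule
from capria.phantom import (
    default_phantom,
    make_coil_model,
    simulate_kspace,
    split_halves,
)
from capria.recon import ReconConfig, reconstruct_series
from capria.trajectory import build_schedule, desk_protocol

DESK_SEED = 1


def nyquist_setup(m=24, n_coils=4, seed=0, fov=183.0):
    """Fully sampled single-frame problem with smooth truth and known coils."""
    import numpy as np

    from capria.nufft import Nufft3
    from capria.phantom import region_maps
    from capria.recon import EncodingOperator
    from capria.trajectory import readout_sample_coords, spoke_orientation

    cfg = desk_protocol(matrix=m)
    nspokes = int(np.pi * m * m / 2) + 20
    th, ph = spoke_orientation(np.arange(nspokes))
    coords = np.stack(
        [readout_sample_coords(t, p, cfg) for t, p in zip(th, ph)]
    ).reshape(-1, 3)
    spec = default_phantom(grid=m, fov=fov, noise_sigma=0, phase_drift=0)
    _, regions, _ = region_maps(spec)
    amps = [1.0, 0.6, 0.3, 0.05, 0.03]
    x_true = sum(mk * a for (mk, _, _), a in zip(regions, amps)).astype(complex)
    sens = make_coil_model(m, fov, n_coils, seed).sens
    sim = Nufft3(coords, m, fov, oversamp=2.0, width=6, cache_tables=False)
    y = sim.forward_batch(sens * x_true[None]).T  # (P, C)
    E = EncodingOperator([coords], sens, m, fov)
    return E, [y], x_true


@pytest.fixture(scope="session")
def nyquist():
    return nyquist_setup()


@pytest.fixture(scope="session")
def small_config():
    """Tiny 24^3 / 4-pair protocol for fast unit tests."""
    return desk_protocol(matrix=24, n_pairs=4)


@pytest.fixture(scope="session")
def small_clean_container(small_config):
    """Noiseless, drift-free 24^3 acquisition with 4 coils."""
    cfg = small_config
    spec = default_phantom(grid=cfg.matrix, fov=cfg.fov, noise_sigma=0.0, phase_drift=0.0)
    fa = make_schedule("quadratic-variable", 2.0, 9.0, cfg.n_spokes_per_prep)
    coils = make_coil_model(cfg.matrix, cfg.fov, n_coils=4, seed=0)
    sched = build_schedule(cfg)
    return simulate_kspace(spec, coils, sched, cfg, fa), spec, fa


@pytest.fixture(scope="session")
def desk_config():
    return desk_protocol()  # 48^3, 16 pairs, full timing


@pytest.fixture(scope="session")
def desk_vfa_container(desk_config):
    cfg = desk_config
    spec = default_phantom(grid=cfg.matrix, fov=cfg.fov, seed=DESK_SEED)
    fa = make_schedule("quadratic-variable", 2.0, 9.0, cfg.n_spokes_per_prep)
    coils = make_coil_model(cfg.matrix, cfg.fov, n_coils=8, seed=0)
    sched = build_schedule(cfg)
    return simulate_kspace(spec, coils, sched, cfg, fa), spec, fa


@pytest.fixture(scope="session")
def desk_cfa_container(desk_config):
    cfg = desk_config
    spec = default_phantom(grid=cfg.matrix, fov=cfg.fov, seed=DESK_SEED)
    fa = make_schedule("constant", 6.0, 6.0, cfg.n_spokes_per_prep)
    coils = make_coil_model(cfg.matrix, cfg.fov, n_coils=8, seed=0)
    sched = build_schedule(cfg)
    return simulate_kspace(spec, coils, sched, cfg, fa), spec, fa


def _perf_halves(container, solver: str, seed: int = 0):
    """Low-resolution perfusion reconstructions of the two scan halves."""
    cfg = dict(
        n_iters=15 if solver == "cg-sense" else 25,
        lambda_spatial=1e-3, lambda_temporal=1e-2, lambda_llr=1e-2,
        n_virtual_coils=4, seed=seed,
    )
    rc = ReconConfig(solver=solver, **cfg)
    h1, h2 = split_halves(container)
    window = 36 * container.config.spoke_interval
    return tuple(
        reconstruct_series(h, window=window, cfg=rc, matrix=16) for h in (h1, h2)
    )


@pytest.fixture(scope="session")
def vfa_perf_halves_sense(desk_vfa_container):
    return _perf_halves(desk_vfa_container[0], "cg-sense")


@pytest.fixture(scope="session")
def vfa_perf_halves_llr(desk_vfa_container):
    return _perf_halves(desk_vfa_container[0], "llr")


@pytest.fixture(scope="session")
def cfa_perf_halves_sense(desk_cfa_container):
    return _perf_halves(desk_cfa_container[0], "cg-sense")


@pytest.fixture(scope="session")
def vfa_angio_recons(desk_vfa_container):
    """Full-data angiographic series (48^3, 24-spoke window) for both solvers."""
    container, _, _ = desk_vfa_container
    window = 24 * container.config.spoke_interval
    sense = reconstruct_series(
        container, window,
        ReconConfig(solver="cg-sense", n_iters=15, lambda_spatial=1e-3,
                    lambda_temporal=1e-2, n_virtual_coils=4),
    )
    llr = reconstruct_series(
        container, window,
        ReconConfig(solver="llr", n_iters=25, lambda_llr=1e-2, patch_size=8,
                    n_virtual_coils=4, seed=0),
    )
    return sense, llr
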