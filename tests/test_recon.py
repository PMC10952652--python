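"""Encoding operator, preprocessing, CG-SENSE and LLR solver behavior."""

import numpy as np
import pytest
from capria.kinetics import make_schedule
from capria.nufft import Nufft3
from capria.phantom import (
    _head_mask,
    default_phantom,
    make_coil_model,
    region_maps,
    simulate_kspace,
)
from capria.recon import (
    EncodingOperator,
    ReconConfig,
    cg_sense,
    compress_coils,
    estimate_sensitivities,
    llr_recon,
    phase_align_subtract,
    recon_lowres_perfusion,
    reconstruct_series,
    svt,
)
from capria.trajectory import (
    build_schedule,
    desk_protocol,
    readout_sample_coords,
    spoke_orientation,
)

FOV = 183.0


class TestEncodingOperator:
    def test_adjoint_identity(self, nyquist):
        E, _, _ = nyquist
        assert E.adjoint_test(seed=0) < 1e-6

    def test_adjoint_identity_multiframe(self, small_clean_container):
        container, _, _ = small_clean_container
        cfg = container.config
        W = cfg.spokes_per_tmax
        frame_of = (container.schedule.within - 1) // W
        coords = [
            container.coords[frame_of == f].reshape(-1, 3)
            for f in range(cfg.n_spokes_per_prep // W)
        ]
        sens = container.sens_truth
        E = EncodingOperator(coords, sens, cfg.matrix, cfg.fov)
        assert E.adjoint_test(seed=1) < 1e-6


class TestPreprocessing:
    def test_sensitivity_estimates_match_truth_on_support(self, small_clean_container):
        container, spec, _ = small_clean_container
        cm, mask = estimate_sensitivities(container, container.config.matrix)
        truth = container.sens_truth
        rss = np.sqrt((np.abs(truth) ** 2).sum(axis=0))
        truth_n = truth / np.maximum(rss, 1e-30)
        support = _head_mask(spec) & mask
        for c in range(truth.shape[0]):
            a, b = cm.sens[c][support], truth_n[c][support]
            phase = np.vdot(a, b) / abs(np.vdot(a, b))
            err = np.linalg.norm(a * phase - b) / np.linalg.norm(b)
            assert err < 0.05

    def test_single_uniform_coil_estimates_to_unity(self):
        cfg = desk_protocol(matrix=16, n_pairs=2)
        spec = default_phantom(grid=16, fov=cfg.fov, noise_sigma=0, phase_drift=0)
        coils = make_coil_model(16, cfg.fov, 1, 0)
        coils.sens[:] = 1.0
        fa = make_schedule("constant", 6, 6, cfg.n_spokes_per_prep)
        c = simulate_kspace(spec, coils, build_schedule(cfg), cfg, fa)
        cm, mask = estimate_sensitivities(c, 16)
        assert np.allclose(np.abs(cm.sens[0][mask]), 1.0, atol=1e-6)

    def test_mask_excludes_low_rss_voxels(self, small_clean_container):
        container, _, _ = small_clean_container
        cfg = ReconConfig(sens_mask_threshold=0.5)
        _, mask = estimate_sensitivities(container, container.config.matrix, cfg)
        _, mask_low = estimate_sensitivities(
            container, container.config.matrix, ReconConfig(sens_mask_threshold=0.05)
        )
        assert mask.sum() < mask_low.sum()

    def test_all_zero_data_rejected(self, small_clean_container):
        from dataclasses import replace

        container, _, _ = small_clean_container
        zero = replace(
            container,
            label=np.zeros_like(container.label),
            control=np.zeros_like(container.control),
        )
        with pytest.raises(ValueError, match="all-zero"):
            estimate_sensitivities(zero, 16)

    def test_full_rank_compression_is_unitary(self, small_clean_container):
        container, _, _ = small_clean_container
        cc = compress_coils(container, container.n_coils)
        # unitary rotation preserves sample-wise norms
        n0 = np.linalg.norm(container.label.astype(np.complex128), axis=-1)
        n1 = np.linalg.norm(cc.label.astype(np.complex128), axis=-1)
        np.testing.assert_allclose(n1, n0, rtol=1e-4, atol=1e-5)

    def test_rank_limited_coils_compress_losslessly(self):
        cfg = desk_protocol(matrix=16, n_pairs=2)
        spec = default_phantom(grid=16, fov=cfg.fov, noise_sigma=0, phase_drift=0)
        coils = make_coil_model(16, cfg.fov, 4, 0)
        # make the 4 physical coils a rank-2 set
        coils.sens[2] = 0.3 * coils.sens[0] + 0.7 * coils.sens[1]
        coils.sens[3] = 0.5 * coils.sens[0] - 0.2j * coils.sens[1]
        fa = make_schedule("constant", 6, 6, cfg.n_spokes_per_prep)
        c = simulate_kspace(spec, coils, build_schedule(cfg), cfg, fa)
        cc = compress_coils(c, 2)
        e_kept = np.linalg.norm(cc.label.astype(np.complex128))
        e_full = np.linalg.norm(c.label.astype(np.complex128))
        assert e_kept == pytest.approx(e_full, rel=1e-5)

    def test_invalid_virtual_count_rejected(self, small_clean_container):
        container, _, _ = small_clean_container
        with pytest.raises(ValueError):
            compress_coils(container, 0)

    def test_no_drift_alignment_close_to_naive(self, small_clean_container):
        """Without drift the estimated rotations are tiny (bounded by the
        ASL-difference perturbation of the central phase) and aligned
        subtraction stays within a few percent of naive subtraction."""
        container, _, _ = small_clean_container
        diff, phases = phase_align_subtract(container)
        naive = container.control.astype(complex) - container.label.astype(complex)
        assert np.abs(phases).max() < 2e-3
        rel = np.linalg.norm(diff - naive) / np.linalg.norm(naive)
        assert rel < 0.05

    def test_drift_recovered_and_removed(self):
        cfg = desk_protocol(matrix=16, n_pairs=4)
        fa = make_schedule("quadratic-variable", 2, 9, cfg.n_spokes_per_prep)
        coils = make_coil_model(16, cfg.fov, 2, 0)
        sched = build_schedule(cfg)
        drift = default_phantom(grid=16, fov=cfg.fov, noise_sigma=0, phase_drift=0.05)
        clean = default_phantom(grid=16, fov=cfg.fov, noise_sigma=0, phase_drift=0.0)
        cd = simulate_kspace(drift, coils, sched, cfg, fa)
        c0 = simulate_kspace(clean, coils, sched, cfg, fa)
        dd, ph = phase_align_subtract(cd)
        d0, _ = phase_align_subtract(c0)
        true_ph = 0.05 * (cd.schedule.prep - 1)
        assert np.abs(ph - true_ph).max() < 2e-3
        assert np.linalg.norm(dd - d0) / np.linalg.norm(d0) < 1e-3

    def test_pure_noise_spokes_stay_finite(self):
        from dataclasses import replace

        cfg = desk_protocol(matrix=16, n_pairs=2)
        spec = default_phantom(grid=16, fov=cfg.fov, noise_sigma=0, phase_drift=0)
        fa = make_schedule("constant", 6, 6, cfg.n_spokes_per_prep)
        coils = make_coil_model(16, cfg.fov, 2, 0)
        c = simulate_kspace(spec, coils, build_schedule(cfg), cfg, fa)
        rng = np.random.default_rng(0)
        noise = (rng.standard_normal(c.label.shape) + 1j * rng.standard_normal(c.label.shape)).astype(np.complex64)
        c = replace(c, label=noise, control=noise.copy())
        diff, ph = phase_align_subtract(c)
        assert np.all(np.isfinite(diff)) and np.all(np.isfinite(ph))


class TestCgSense:
    def test_nyquist_noiseless_fidelity(self, nyquist):
        E, ys, x_true = nyquist
        cfg = ReconConfig(solver="cg-sense", lambda_spatial=0, lambda_temporal=0, n_iters=40)
        s = cg_sense(ys, E, cfg)
        x = s.frames[0]
        scale = np.vdot(x, x_true) / np.vdot(x, x)
        nrmse = np.linalg.norm(scale * x - x_true) / np.linalg.norm(x_true)
        assert nrmse < 0.05

    def test_objective_monotone(self, nyquist):
        E, ys, _ = nyquist
        cfg = ReconConfig(solver="cg-sense", lambda_spatial=0, lambda_temporal=0, n_iters=15)
        s = cg_sense(ys, E, cfg)
        hist = s.provenance["objective_history"]
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(hist, hist[1:]))

    def test_strong_temporal_weight_flattens_frames(self, small_clean_container):
        container, _, _ = small_clean_container
        base = ReconConfig(
            solver="cg-sense", lambda_spatial=0, lambda_temporal=0, n_iters=10,
        )
        heavy = ReconConfig(
            solver="cg-sense", lambda_spatial=0, lambda_temporal=1e6, n_iters=10,
        )
        window = container.config.t_max
        s0 = reconstruct_series(container, window, base)
        s1 = reconstruct_series(container, window, heavy)

        def spread(s):
            return np.linalg.norm(s.frames - s.frames.mean(axis=0)) / np.linalg.norm(s.frames)

        assert spread(s1) < 0.5 * spread(s0)


class TestLlr:
    def test_svt_annihilates_below_threshold(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((3, 3))
        smax = np.linalg.svd(M, compute_uv=False).max()
        assert np.allclose(svt(M, smax * 1.01), 0.0)
        # and shrinks singular values exactly otherwise
        out = svt(M, 0.1)
        s_in = np.linalg.svd(M, compute_uv=False)
        s_out = np.linalg.svd(out, compute_uv=False)
        np.testing.assert_allclose(s_out, np.maximum(s_in - 0.1, 0), atol=1e-12)

    def test_zero_weight_matches_cg_least_squares(self, nyquist):
        E, ys, _ = nyquist
        ref = cg_sense(
            ys, E,
            ReconConfig(solver="cg-sense", lambda_spatial=0, lambda_temporal=0, n_iters=40),
        ).frames
        prox_free = llr_recon(
            ys, E, ReconConfig(solver="llr", lambda_llr=0.0, n_iters=40, seed=0)
        ).frames
        num = np.linalg.norm(prox_free - ref)
        assert num / np.linalg.norm(ref) < 0.05

    def test_pogm_and_fista_agree(self, nyquist):
        E, ys, _ = nyquist
        a = llr_recon(
            ys, E,
            ReconConfig(solver="llr", lambda_llr=1e-3, n_iters=25, accel="pogm", seed=0),
        )
        b = llr_recon(
            ys, E,
            ReconConfig(solver="llr", lambda_llr=1e-3, n_iters=40, accel="fista", seed=0),
        )
        assert b.provenance["acceleration"] == "fista"
        rel = np.linalg.norm(a.frames - b.frames) / np.linalg.norm(b.frames)
        assert rel < 0.05

    def test_best_objective_nonincreasing(self, nyquist):
        E, ys, _ = nyquist
        s = llr_recon(
            ys, E, ReconConfig(solver="llr", lambda_llr=1e-2, n_iters=20, seed=0)
        )
        hist = np.array(s.provenance["objective_history"])
        best = np.minimum.accumulate(hist)
        assert np.all(np.diff(best) <= 1e-9 * best[0])

    def test_rank_one_series_favors_llr_over_sense(self):
        """A series whose every patch is rank-1 in space x time is denoised
        better by the nuclear-norm prior than by plain CG at matched noise."""
        m, F, n_coils = 16, 4, 3
        cfg = desk_protocol(matrix=m, n_pairs=2)
        rng = np.random.default_rng(5)
        spec = default_phantom(grid=m, fov=FOV, noise_sigma=0, phase_drift=0)
        _, regions, _ = region_maps(spec)
        base = sum(mk for mk, _, _ in regions)
        tc = np.array([1.0, 0.7, 0.45, 0.3])
        x_true = (tc[:, None, None, None] * base[None]).astype(complex)
        sens = make_coil_model(m, FOV, n_coils, 1).sens
        th, ph = spoke_orientation(np.arange(4 * 120))
        frames_coords = []
        ys = []
        for f in range(F):
            sl = slice(f * 120, (f + 1) * 120)
            coords = np.stack(
                [readout_sample_coords(t, p, cfg) for t, p in zip(th[sl], ph[sl])]
            ).reshape(-1, 3)
            frames_coords.append(coords)
            sim = Nufft3(coords, m, FOV, oversamp=2.0, width=6)
            yf = sim.forward_batch(sens * x_true[f][None]).T
            yf += 3.0 * (
                rng.standard_normal(yf.shape) + 1j * rng.standard_normal(yf.shape)
            )
            ys.append(yf)
        E = EncodingOperator(frames_coords, sens, m, FOV)
        sense = cg_sense(
            ys, E,
            ReconConfig(solver="cg-sense", lambda_spatial=0, lambda_temporal=0, n_iters=15),
        ).frames
        llr = llr_recon(
            ys, E,
            ReconConfig(solver="llr", lambda_llr=3e-2, patch_size=8, n_iters=25, seed=0),
        ).frames
        # the prior should help substantially at this noise level, not just tie

        def nrmse(x):
            sc = np.vdot(x, x_true) / np.vdot(x, x)
            return np.linalg.norm(sc * x - x_true) / np.linalg.norm(x_true)

        assert nrmse(llr) < nrmse(sense)


class TestLowResPerfusion:
    def test_reported_undersampling_matches_protocol_value(self):
        from capria.trajectory import undersampling_factor

        R = undersampling_factor(52, 36 * 88)
        assert round(R, 1) == 1.3

    def test_low_matrix_bound(self, small_clean_container):
        container, _, _ = small_clean_container
        with pytest.raises(ValueError):
            recon_lowres_perfusion(container, container.config.matrix, ReconConfig())

    def test_lowres_consistent_with_downsampled_fullres(self, small_clean_container):
        """On the noiseless phantom, reconstructing directly at low matrix
        agrees with Fourier-cropping the full-resolution reconstruction."""
        from scipy import fft as sfft

        container, _, _ = small_clean_container
        window = container.config.t_max
        rc = ReconConfig(
            solver="cg-sense", lambda_spatial=1e-4, lambda_temporal=0, n_iters=20
        )
        low = 12
        s_low = reconstruct_series(container, window, rc, matrix=low)
        s_full = reconstruct_series(container, window, rc)
        # Fourier-crop full frames to the low matrix
        m = container.config.matrix
        lo = (m - low) // 2
        cropped = []
        for fr in s_full.frames:
            X = sfft.fftshift(sfft.fftn(sfft.ifftshift(fr)))
            Xc = X[lo : lo + low, lo : lo + low, lo : lo + low]
            cropped.append(sfft.fftshift(sfft.ifftn(sfft.ifftshift(Xc))) * (low / m) ** 3)
        cropped = np.stack(cropped)
        # compare inside the object (outside, the sensitivity mask of the
        # low-res path is zero by construction while cropping rings)
        from scipy.ndimage import zoom

        spec = small_clean_container[1]
        head_low = zoom(_head_mask(spec).astype(float), low / m, order=0) > 0.5
        a = np.abs(s_low.frames)[:, head_low]
        b = np.abs(cropped)[:, head_low]
        sc = np.vdot(a, b).real / np.vdot(a, a).real
        assert np.linalg.norm(sc * a - b) / np.linalg.norm(b) < 0.10

    def test_provenance_reports_undersampling(self, small_clean_container):
        container, _, _ = small_clean_container
        s = recon_lowres_perfusion(
            container, 12,
            ReconConfig(solver="cg-sense", n_iters=5, lambda_spatial=1e-3, lambda_temporal=1e-3),
        )
        assert "undersampling_factor" in s.provenance
        assert s.provenance["matrix"] == 12
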