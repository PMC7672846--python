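import numpy as np
import pytest

from csiirr import (
    ConfigError,
    Image2D,
    ReconConfig,
    Sinogram,
    SupportMask,
    TiltGeometry,
    csiirr,
    estimate_unknown,
    fbp,
    iirr,
    irr,
    irr_tv,
    make_sparse_phantom,
    mmp,
    mp_classic,
    pcc,
    radon,
    simulate_tilt_series,
    split_projections,
    tv_norm,
)


class TestFBP:
    def test_full_coverage_disk_reconstruction(self, disk64):
        img, _ = disk64
        sino = simulate_tilt_series(img, -89, 89, 1)
        rec = fbp(sino)
        assert pcc(rec, img) >= 0.95

    def test_zero_sinogram_gives_zero_image(self):
        geo = TiltGeometry.all_known(np.arange(-60.0, 61.0), 32)
        assert np.all(fbp(Sinogram.zeros(geo)).values == 0.0)

    def test_missing_wedge_degrades_correlation(self, disk64):
        img, _ = disk64
        full = fbp(simulate_tilt_series(img, -89, 89, 1))
        wedge = fbp(simulate_tilt_series(img, -60, 60, 1))
        assert pcc(wedge, img) < pcc(full, img)

    def test_no_known_angles_rejected(self):
        geo = TiltGeometry(np.arange(-60.0, 61.0),
                           np.zeros(121, dtype=bool), 32)
        with pytest.raises(Exception):
            fbp(Sinogram.zeros(geo))


class TestEstimateUnknown:
    def test_zero_image_gives_zero_estimate(self, wedge_sino64):
        est = estimate_unknown(Image2D.zeros(64), wedge_sino64.geometry)
        assert np.all(est.values == 0.0)

    def test_no_unknown_angles_gives_zero_estimate(self, phantom64):
        truth, _ = phantom64
        geo = TiltGeometry.all_known(np.arange(-80.0, 81.0, 5.0), 64)
        assert np.all(estimate_unknown(truth, geo).values == 0.0)

    def test_truth_image_recovers_true_wedge_projections(self, phantom64,
                                                         wedge_sino64):
        truth, _ = phantom64
        geo = wedge_sino64.geometry
        est = estimate_unknown(truth, geo)
        full = radon(truth, geo)
        unknown = ~geo.known
        np.testing.assert_allclose(est.values[:, unknown],
                                   full.values[:, unknown], atol=1e-10)
        assert np.all(est.values[:, geo.known] == 0.0)


class TestIRRFamily:
    def test_single_iteration_equals_fbp_exactly(self, wedge_sino64):
        f1, _ = irr(wedge_sino64, ReconConfig(outer_iters=1))
        assert np.array_equal(f1.values, fbp(wedge_sino64).values)

    def test_quality_nondecreasing_on_noiseless_wedge(self, phantom64,
                                                      wedge_sino64):
        truth, support = phantom64
        _, trace = irr(wedge_sino64, ReconConfig(outer_iters=10),
                       support=support, truth=truth)
        diffs = np.diff(trace.pcc)
        assert np.all(diffs > -1e-3)

    def test_full_coverage_iterations_are_fixed_point(self, full_sino64):
        f1, _ = irr(full_sino64, ReconConfig(outer_iters=1))
        f5, _ = irr(full_sino64, ReconConfig(outer_iters=5))
        np.testing.assert_array_equal(f1.values, f5.values)

    def test_iirr_approaches_irr_as_lam_to_one(self, wedge_sino64):
        f_irr, _ = irr(wedge_sino64, ReconConfig(outer_iters=5))
        f_lam, _ = iirr(wedge_sino64, ReconConfig(lam=0.999999,
                                                  outer_iters=5))
        rel = (np.linalg.norm(f_lam.values - f_irr.values)
               / np.linalg.norm(f_irr.values))
        assert rel < 1e-3

    def test_iirr_rejects_lam_outside_unit_interval(self, wedge_sino64):
        with pytest.raises(ConfigError):
            iirr(wedge_sino64, ReconConfig(lam=1.5))

    def test_small_lam_tracks_fbp_on_noisy_data(self, phantom64):
        from csiirr import NoiseSpec, add_noise
        truth, support = phantom64
        noisy = add_noise(simulate_tilt_series(truth, -60, 60, 1),
                          NoiseSpec(snr=0.5, seed=3))
        base = fbp(noisy)
        f_small, _ = iirr(noisy, ReconConfig(lam=0.01, outer_iters=8),
                          support=support)
        f_large, _ = iirr(noisy, ReconConfig(lam=0.99, outer_iters=8),
                          support=support)
        assert pcc(f_small, base) > pcc(f_large, base)


class TestMatchingPursuit:
    def test_zero_input_terminates_immediately(self, wedge_sino64):
        geo = wedge_sino64.geometry
        support = SupportMask.inscribed_disk(64)
        img, state = mmp(Sinogram.zeros(geo), Sinogram.zeros(geo), support,
                         ReconConfig())
        assert np.all(img.values == 0.0)
        assert state.iteration == 0

    def test_sparsity_bound_holds_exactly(self, phantom64, wedge_sino64):
        _, support = phantom64
        p_known, _ = split_projections(wedge_sino64)
        cfg = ReconConfig(M=40, inner_iters=7, epsilon=0.0)
        img, state = mmp(p_known, Sinogram.zeros(wedge_sino64.geometry),
                         support, cfg)
        assert np.count_nonzero(img.values) <= state.iteration * 40

    def test_selection_stays_inside_support(self, phantom64, wedge_sino64):
        _, support = phantom64
        p_known, _ = split_projections(wedge_sino64)
        img, state = mmp(p_known, Sinogram.zeros(wedge_sino64.geometry),
                         support, ReconConfig(inner_iters=10))
        assert not np.any(state.selected & ~support.mask)
        assert np.all(img.values[~support.mask] == 0.0)

    def test_epsilon_termination_meets_residual_contract(self, phantom64,
                                                         full_sino64):
        _, support = phantom64
        p_known, _ = split_projections(full_sino64)
        r0 = np.linalg.norm(p_known.values)
        cfg = ReconConfig(epsilon=0.5 * r0, inner_iters=500)
        img, state = mmp(p_known, Sinogram.zeros(full_sino64.geometry),
                         support, cfg)
        assert state.iteration < 500  # stopped by epsilon, not budget
        achieved = np.linalg.norm(
            radon(img, full_sino64.geometry).values - p_known.values)
        assert achieved < cfg.epsilon

    def test_single_pixel_recovery(self):
        n = 32
        px = np.zeros((n, n))
        px[10, 20] = 1.0
        sino = simulate_tilt_series(Image2D(px), -89, 89, 1)
        p_known, _ = split_projections(sino)
        support = SupportMask.inscribed_disk(n)
        img, _ = mmp(p_known, Sinogram.zeros(sino.geometry), support,
                     ReconConfig(M=1, inner_iters=30))
        assert np.unravel_index(np.argmax(img.values), (n, n)) == (10, 20)

    def test_m_exceeding_support_rejected(self, wedge_sino64):
        support = SupportMask.inscribed_disk(64)
        with pytest.raises(ConfigError):
            mmp(Sinogram.zeros(wedge_sino64.geometry),
                Sinogram.zeros(wedge_sino64.geometry), support,
                ReconConfig(M=support.n_pixels + 1))

    def test_classic_mp_is_m1_special_case(self, phantom64, wedge_sino64):
        _, support = phantom64
        p_known, _ = split_projections(wedge_sino64)
        cfg = ReconConfig(inner_iters=15)
        a, _ = mp_classic(p_known, support, cfg)
        b, _ = mmp(p_known, Sinogram.zeros(wedge_sino64.geometry), support,
                   ReconConfig(M=1, inner_iters=15))
        np.testing.assert_array_equal(a.values, b.values)

    def test_mp_residual_nonincreasing_on_noiseless_data(self, phantom64,
                                                         full_sino64):
        _, support = phantom64
        p_known, _ = split_projections(full_sino64)
        _, state = mp_classic(p_known, support,
                              ReconConfig(inner_iters=60, epsilon=0.0))
        assert np.all(np.diff(state.trace.residual_norm) <= 1e-9)


class TestCSIIRR:
    def test_first_outer_iteration_equals_mmp(self, phantom64, wedge_sino64):
        _, support = phantom64
        cfg = ReconConfig(outer_iters=1)
        p_known, _ = split_projections(wedge_sino64)
        a, _ = mmp(p_known, Sinogram.zeros(wedge_sino64.geometry), support,
                   cfg)
        b, _ = csiirr(wedge_sino64, support, cfg, f0=Image2D.zeros(64))
        np.testing.assert_array_equal(a.values, b.values)

    def test_beats_iirr_on_wedge_benchmark(self, phantom64, wedge_sino64):
        truth, support = phantom64
        cfg = ReconConfig(outer_iters=5)
        f_cs, _ = csiirr(wedge_sino64, support, cfg)
        f_ii, _ = iirr(wedge_sino64, cfg, support=support)
        assert pcc(f_cs, truth) > pcc(f_ii, truth)


class TestTotalVariation:
    def test_constant_image_has_zero_tv(self):
        assert tv_norm(Image2D(np.full((8, 8), 3.0))) == 0.0

    def test_column_step_edge_value(self):
        v = np.zeros((4, 4))
        v[:, 2:] = 1.0
        assert tv_norm(Image2D(v)) == pytest.approx(4.0)

    def test_positive_homogeneity(self, rng):
        v = rng.normal(size=(10, 10))
        assert tv_norm(Image2D(2.5 * v)) == pytest.approx(
            2.5 * tv_norm(Image2D(v)))

    def test_zero_tv_steps_reduce_to_irr(self, wedge_sino64):
        cfg = ReconConfig(outer_iters=3, tv_iters=0)
        a, _ = irr_tv(wedge_sino64, cfg)
        b, _ = irr(wedge_sino64, cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_descent_reduces_tv_on_wedge_data(self, wedge_sino64):
        base, _ = irr(wedge_sino64, ReconConfig(outer_iters=2))
        smoothed, _ = irr_tv(wedge_sino64,
                             ReconConfig(outer_iters=2, tv_iters=5))
        assert tv_norm(smoothed) < tv_norm(base)

    def test_constant_image_gradient_is_noop(self):
        from csiirr.reconstruct import _tv_gradient
        g = _tv_gradient(np.full((6, 6), 2.0))
        np.testing.assert_allclose(g, 0.0, atol=1e-6)
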