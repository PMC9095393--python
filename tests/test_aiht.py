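import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aihtct as a
from aihtct.aiht import AIHTConfig, _menger_curvature, hard_threshold
from aihtct.framelet import DETAIL_INDEX, FrameletCoefficients


def _coeffs_from(data):
    return FrameletCoefficients(data, data.shape[2:])


class TestHardThreshold:
    def test_case_table(self, bank):
        data = np.zeros((3, 3, 4, 4))
        data[1, 1, 0, :3] = [0.5, 2.0, -2.0]
        out = hard_threshold(_coeffs_from(data), 1.0)
        assert list(out.data[1, 1, 0, :3]) == [0.0, 2.0, -2.0]

    def test_boundary_maps_to_zero(self):
        data = np.zeros((3, 3, 4, 4))
        data[2, 0, 1, 1] = 1.0
        out = hard_threshold(_coeffs_from(data), 1.0)
        assert out.data[2, 0, 1, 1] == 0.0

    def test_lowpass_never_thresholded(self):
        data = np.zeros((3, 3, 4, 4))
        data[0, 0] = 0.001
        out = hard_threshold(_coeffs_from(data), 100.0)
        assert np.all(out.data[0, 0] == 0.001)

    def test_zero_threshold_is_identity(self, rng):
        data = rng.normal(size=(3, 3, 5, 5))
        out = hard_threshold(_coeffs_from(data), 0.0)
        assert np.array_equal(out.data, data)

    @given(seed=st.integers(0, 500), beta=st.floats(0.0, 3.0))
    @settings(max_examples=40)
    def test_idempotence(self, seed, beta):
        data = np.random.default_rng(seed).normal(size=(3, 3, 4, 4))
        once = hard_threshold(_coeffs_from(data), beta)
        twice = hard_threshold(once, beta)
        assert np.array_equal(once.data, twice.data)

    def test_negative_threshold_rejected(self, rng):
        data = rng.normal(size=(3, 3, 4, 4))
        with pytest.raises(ValueError):
            hard_threshold(_coeffs_from(data), -0.1)

    def test_per_subband_thresholds(self):
        data = np.full((3, 3, 4, 4), 0.5)
        beta = np.zeros(len(DETAIL_INDEX))
        beta[0] = 1.0  # kills only subband (0, 1)
        out = hard_threshold(_coeffs_from(data), beta)
        assert np.all(out.data[0, 1] == 0.0)
        assert np.all(out.data[0, 2] == 0.5)


@pytest.fixture(scope="module")
def bimodal_setup():
    # piecewise-constant square gives few large edge coefficients; added
    # noise gives many small ones near 0.01
    rng = np.random.default_rng(11)
    clean = np.zeros((64, 64))
    clean[16:48, 16:48] = 0.5
    noisy = clean + rng.normal(0.0, 0.008, clean.shape)
    geom = a.limited_angle_geometry((0, 90), 45, a.default_detector_count(64))
    sino = a.forward_project(clean, geom)
    return noisy, sino


class TestLCurveSelector:
    def test_bimodal_selection_between_modes(self, bank, bimodal_setup):
        noisy, sino = bimodal_setup
        grid = np.geomspace(0.001, 0.5, 15)
        beta = a.select_threshold_lcurve(noisy, sino, bank, grid)
        assert beta.shape == (len(DETAIL_INDEX),)
        assert np.all(beta == beta[0])
        assert 0.01 < beta[0] < 0.5  # strictly between the noise and edge modes
        assert beta[0] in grid

    def test_determinism(self, bank, bimodal_setup):
        noisy, sino = bimodal_setup
        grid = np.geomspace(0.001, 0.5, 8)
        b1 = a.select_threshold_lcurve(noisy, sino, bank, grid)
        b2 = a.select_threshold_lcurve(noisy, sino, bank, grid)
        assert np.array_equal(b1, b2)

    def test_matches_exhaustive_curvature_evaluation(self, bank, bimodal_setup):
        # independent check: recompute every L-curve point and curvature
        # directly, then compare the corner
        from aihtct.aiht import hard_threshold as ht
        from aihtct.framelet import analyze, synthesize
        from aihtct.geometry import system_matrix

        noisy, sino = bimodal_setup
        grid = np.geomspace(0.001, 0.5, 10)
        coeffs = analyze(noisy, bank)
        Z, _ = system_matrix(sino.geometry, (64, 64))
        pts = []
        for t in grid:
            thr = ht(coeffs, t)
            resid = Z @ synthesize(thr, bank).pixels.ravel() - sino.values.ravel()
            pts.append((np.log10(np.linalg.norm(resid)),
                        np.log10(max(thr.detail_count_nonzero(), 1))))
        curv = [_menger_curvature(pts[k - 1], pts[k], pts[k + 1])
                for k in range(1, len(pts) - 1)]
        expected = grid[int(np.argmax(curv)) + 1]
        got = a.select_threshold_lcurve(noisy, sino, bank, grid)
        assert got[0] == expected

    def test_all_zero_details_returns_smallest(self, bank):
        flat = np.full((32, 32), 0.25)  # constant image: zero detail coeffs
        geom = a.limited_angle_geometry((0, 90), 10, a.default_detector_count(32))
        sino = a.forward_project(flat, geom)
        beta = a.select_threshold_lcurve(flat, sino, bank, [0.01, 0.1, 1.0])
        assert beta[0] == 0.01

    def test_three_point_grid_picks_middle_when_curved(self, bank, bimodal_setup):
        noisy, sino = bimodal_setup
        beta = a.select_threshold_lcurve(noisy, sino, bank, [0.001, 0.05, 0.5])
        assert beta[0] == 0.05

    def test_too_few_candidates_rejected(self, bank, bimodal_setup):
        noisy, sino = bimodal_setup
        with pytest.raises(ValueError):
            a.select_threshold_lcurve(noisy, sino, bank, [0.1, 0.2])


@pytest.fixture(scope="module")
def limited_setup():
    ph = a.default_phantom(64)
    geom = a.limited_angle_geometry((0, 90), 90, a.default_detector_count(64))
    return ph, a.forward_project(ph, geom)


class TestRunAiht:
    def test_zero_threshold_reproduces_sart(self, limited_setup):
        ph, sino = limited_setup
        cfg = AIHTConfig(n_iters=20, threshold_mode="fixed", beta_star=0.0,
                         nonneg=False)
        img, trace = a.run_aiht(sino, 64, cfg)
        ref = a.run_sart(sino, 64, 20, 1.0, nonneg=False)
        assert np.max(np.abs(img.pixels - ref.pixels)) < 1e-10
        assert len(trace) == 20

    def test_beats_sart_on_limited_angle(self, limited_setup):
        ph, sino = limited_setup
        img, _ = a.run_aiht(sino, 64, AIHTConfig(n_iters=60))
        sart = a.run_sart(sino, 64, 60, 1.0)
        assert a.rmse(img, ph) < a.rmse(sart, ph)
        assert a.psnr(img, ph) > a.psnr(sart, ph)

    def test_trace_is_deterministic_and_sane(self, limited_setup):
        ph, sino = limited_setup
        cfg = AIHTConfig(n_iters=15)
        img1, t1 = a.run_aiht(sino, 64, cfg)
        img2, t2 = a.run_aiht(sino, 64, cfg)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert t1 == t2
        n_detail_total = 8 * 64 * 64
        for entry in t1:
            assert 0 <= entry.n_surviving <= n_detail_total
            assert entry.threshold >= 0.0

    def test_nonneg_constraint_enforced(self, limited_setup):
        _, sino = limited_setup
        img, _ = a.run_aiht(sino, 64, AIHTConfig(n_iters=10, nonneg=True))
        assert img.pixels.min() >= 0.0

    def test_stop_tol_halts_early(self, limited_setup):
        _, sino = limited_setup
        img, trace = a.run_aiht(sino, 64, AIHTConfig(n_iters=300, stop_tol=1e-2))
        assert len(trace) < 300


class TestWFBaseline:
    def test_identical_to_fixed_mode_aiht(self, limited_setup):
        _, sino = limited_setup
        cfg = AIHTConfig(n_iters=10, threshold_mode="fixed", beta_star=0.03)
        img1, _ = a.run_wf_baseline(sino, 64, cfg)
        img2, _ = a.run_aiht(sino, 64, cfg)
        assert np.array_equal(img1.pixels, img2.pixels)

    def test_adaptive_config_rejected(self, limited_setup):
        _, sino = limited_setup
        with pytest.raises(ValueError):
            a.run_wf_baseline(sino, 64, AIHTConfig(threshold_mode="adaptive_lcurve"))

    def test_well_chosen_threshold_beats_sart(self, limited_setup):
        ph, sino = limited_setup
        cfg = AIHTConfig(n_iters=60, threshold_mode="fixed", beta_star=0.01)
        img, _ = a.run_wf_baseline(sino, 64, cfg)
        sart = a.run_sart(sino, 64, 60, 1.0)
        assert a.rmse(img, ph) < a.rmse(sart, ph)

    def test_huge_threshold_kills_all_details(self, limited_setup):
        _, sino = limited_setup
        cfg = AIHTConfig(n_iters=5, threshold_mode="fixed", beta_star=1e6)
        _, trace = a.run_wf_baseline(sino, 64, cfg)
        assert all(entry.n_surviving == 0 for entry in trace)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_iters": 0},
            {"g": 0.0},
            {"g": 2.5},
            {"threshold_mode": "magic"},
            {"beta_star": -1.0},
            {"lcurve_grid": [0.1, 0.2]},
            {"lcurve_grid": [0.3, 0.2, 0.1]},
            {"stop_tol": -1e-3},
        ],
    )
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ValueError):
            AIHTConfig(**kwargs)
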