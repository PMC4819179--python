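"""Evaluation procedures: correlation sweeps, mixing curves, utilities."""

import numpy as np
import pytest

from kfakit.evaluate import (
    average_then_fit,
    bvalue_grid_search,
    direction_snr_sweep,
    estimate_snr,
    fa_segmentation,
    mixture_sweep,
    pearson,
    rms_contrast,
)
from kfakit.exceptions import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from kfakit.model import AcquisitionScheme, predict_signal_many
from kfakit.simulate import NoiseSpec, synthetic_population
from kfakit.directions import load_directions


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_case(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])


class TestFaSegmentation:
    def test_band_membership(self):
        fa = np.array([0.05, 0.1, 0.2, 0.3, 0.45, 0.6, 0.7, 1.0])
        wm, gm = fa_segmentation(fa)
        np.testing.assert_array_equal(
            gm, [False, False, True, False, False, False, False, False])
        np.testing.assert_array_equal(
            wm, [False, False, False, False, False, False, True, False])


class TestRmsContrast:
    def test_constant_map_is_zero(self):
        assert rms_contrast(np.full((8, 8), 3.2)) == 0.0

    def test_binary_map(self):
        m = np.zeros(100)
        m[:50] = 1.0
        assert rms_contrast(m) == pytest.approx(0.5)

    def test_affine_invariance(self, rng):
        m = rng.random((10, 10))
        assert rms_contrast(7.0 * m - 3.0) == pytest.approx(rms_contrast(m),
                                                            abs=1e-12)


class TestEstimateSnr:
    def test_recovers_nominal_snr_from_rayleigh_background(self, rng):
        sigma = 1.0
        bg = np.hypot(sigma * rng.standard_normal(100_000),
                      sigma * rng.standard_normal(100_000))
        image = np.concatenate([np.full(1000, 50.0), bg])
        obj = np.zeros(image.size, bool)
        obj[:1000] = True
        assert estimate_snr(image, obj, ~obj) == pytest.approx(50.0,
                                                               rel=0.03)

    def test_zero_signal_object_gives_rayleigh_constant(self, rng):
        bg = np.hypot(rng.standard_normal(200_000),
                      rng.standard_normal(200_000))
        image = np.concatenate([bg[:100_000], bg[100_000:]])
        obj = np.zeros(image.size, bool)
        obj[:100_000] = True
        # Rayleigh mean over the corrected (Gaussian) sigma: sqrt(pi/2)
        expected = np.sqrt(np.pi / 2)
        assert estimate_snr(image, obj, ~obj) == pytest.approx(expected,
                                                               rel=0.02)

    def test_noise_free_image_rejected(self):
        image = np.concatenate([np.full(10, 5.0), np.zeros(10)])
        obj = np.arange(20) < 10
        with pytest.raises(InvalidInputError):
            estimate_snr(image, obj, ~obj)


@pytest.fixture(scope="module")
def sweep():
    return mixture_sweep()


@pytest.fixture(scope="module")
def population():
    return synthetic_population(300, seed=4, profile="mixed")


class TestMixtureSweep:
    def test_single_fiber_endpoint_maximizes_fa_and_kfa(self, sweep):
        first = sweep.iloc[0]
        assert first.VI == pytest.approx(1.0)
        assert first.FA_norm == pytest.approx(1.0)
        assert first.KFA_norm == pytest.approx(1.0)

    def test_fa_vanishes_but_kfa_survives_at_equal_mixture(self, sweep):
        last = sweep.iloc[-1]
        assert last.VI == pytest.approx(0.0, abs=1e-12)
        assert last.FA_norm < 0.1
        assert last.KFA_norm > 0.4

    def test_md_unaffected_by_mixing(self, sweep):
        md = sweep.MD.to_numpy()
        assert np.abs(md - md.mean()).max() / md.mean() < 0.02

    def test_proxy_tracks_kfa_direction_of_change(self, sweep):
        # the 9-direction proxy decreases with mixing like KFA, but more
        assert sweep.proxy_norm.iloc[-1] < 1.0
        assert sweep.proxy_norm.iloc[-1] < sweep.KFA_norm.iloc[-1]

    def test_invalid_alpha_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            mixture_sweep(alphas=[0.0, 0.5])


class TestAverageThenFit:
    def test_homogeneous_volume_estimators_agree(self):
        pop = synthetic_population(1, seed=21, profile="wm_like")
        scheme = AcquisitionScheme.multi_shell(
            [0.5, 1.0, 1.8, 2.5, 3.0], load_directions("15"))
        sig = predict_signal_many(pop.dt6, pop.w15, scheme)[0]
        vol = np.tile(sig, (2, 2, 2, 1))
        table = average_then_fit(vol, np.ones((2, 2, 2), bool), scheme)
        for col in ("MD", "FA", "Wbar", "KFA"):
            assert table[col].iloc[0] == pytest.approx(table[col].iloc[1],
                                                       abs=1e-6)

    def test_empty_mask_rejected(self):
        scheme = AcquisitionScheme.multi_shell([1.0, 2.0, 3.0],
                                               load_directions("9"))
        with pytest.raises(InvalidInputError):
            average_then_fit(np.ones((2, 2, 2, len(scheme))),
                             np.zeros((2, 2, 2), bool), scheme)


class TestDirectionSnrSweep:
    def test_reproducible_from_seed(self, population):
        spec = NoiseSpec(snr=80, n_realizations=5, seed=12)
        a = direction_snr_sweep(population, [9], [80], spec=spec)
        b = direction_snr_sweep(population, [9], [80], spec=spec)
        np.testing.assert_array_equal(a.mean_r, b.mean_r)

    def test_noise_free_beats_low_snr(self, population):
        spec = NoiseSpec(snr=80, n_realizations=10, seed=12)
        res = direction_snr_sweep(population, [15], [20, np.inf], spec=spec)
        assert res.mean_r[0, 1] > res.mean_r[0, 0]

    def test_three_directions_underperform(self, population):
        """N = 3 correlates worse than N = 25 at moderate SNR."""
        spec = NoiseSpec(snr=50, n_realizations=20, seed=12)
        res = direction_snr_sweep(population, [3, 25], [50], spec=spec)
        assert res.mean_r[0, 0] < res.mean_r[1, 0]

    def test_tiny_population_rejected(self):
        pop = synthetic_population(10, seed=0)
        with pytest.raises(InvalidInputError):
            direction_snr_sweep(pop, [9], [80])

    def test_frame_layout(self, population):
        spec = NoiseSpec(snr=80, n_realizations=2, seed=1)
        res = direction_snr_sweep(population, [9, 15], [80], spec=spec)
        df = res.to_frame()
        assert set(df.columns) == {"n_directions", "snr", "mean_r", "sd_r",
                                   "n"}
        assert len(df) == 2


class TestBvalueGridSearch:
    def test_diagonal_and_reversed_cells_masked(self, population):
        spec = NoiseSpec(snr=100, n_realizations=3, seed=5)
        res = bvalue_grid_search(population, [1.0, 2.0], [1.0, 2.0],
                                 spec=spec, n_voxels=125)
        assert np.isnan(res.mean_r[0, 0])   # b1 == b2
        assert np.isnan(res.mean_r[1, 0])   # b1 > b2
        assert np.isnan(res.mean_r[1, 1])
        assert np.isfinite(res.mean_r[0, 1])

    def test_higher_second_shell_helps(self, population):
        """argmax prefers a large b2 given b1 ~ 1, and beats a low-b2 pair."""
        spec = NoiseSpec(snr=100, n_realizations=25, seed=5)
        res = bvalue_grid_search(population, [1.0], [1.2, 2.5, 5.0],
                                 spec=spec, n_voxels=125)
        b1_best, b2_best = res.argmax()
        assert b2_best > 1.2
        assert np.nanmax(res.mean_r) > res.mean_r[0, 0]

    def test_subsample_is_stable(self, population):
        spec = NoiseSpec(snr=100, n_realizations=25, seed=5)
        small = bvalue_grid_search(population, [1.0], [2.5], spec=spec,
                                   n_voxels=125)
        full = bvalue_grid_search(population, [1.0], [2.5], spec=spec,
                                  n_voxels=len(population))
        assert abs(small.mean_r[0, 0] - full.mean_r[0, 0]) < 0.03

    def test_fully_masked_grid_rejected(self, population):
        with pytest.raises(InvalidParameterError):
            bvalue_grid_search(population, [2.0], [1.0],
                               spec=NoiseSpec(snr=100, seed=0))
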