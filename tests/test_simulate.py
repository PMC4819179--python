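"""Gaussian-mixture simulator: cumulants, mixing, noise, populations."""

import numpy as np
import pytest

from kfakit import (
    DiffusionTensor,
    InvalidInputError,
    InvalidParameterError,
    KurtosisTensor,
    fit_dki,
    kfa,
    md_fa,
)
from kfakit.simulate import (
    DEFAULT_ALPHAS,
    FREE_WATER_DIFFUSIVITY,
    FiberCompartment,
    NoiseSpec,
    VolumeFractionTensor,
    VoxelModel,
    add_rician_noise,
    compartment_tensor,
    default_fiber_kernel,
    gaussian_mixture_signal,
    mix_signals,
    mixture_cumulants,
    orthogonal_phantom,
    synthetic_population,
    volume_fraction_index,
)
from kfakit.model import AcquisitionScheme, predict_signal
from kfakit.tensors import quadratic_design


class TestCompartmentTensor:
    def test_axis_aligned(self):
        c = FiberCompartment(np.array([1.0, 0, 0]), 2.0, 0.5, 1.0)
        np.testing.assert_allclose(compartment_tensor(c).matrix,
                                   np.diag([2.0, 0.5, 0.5]))

    def test_isotropic_limit_ignores_orientation(self, rng):
        for _ in range(3):
            u = rng.standard_normal(3)
            c = FiberCompartment(u, 1.1, 1.1, 1.0)
            np.testing.assert_allclose(compartment_tensor(c).matrix,
                                       1.1 * np.eye(3), atol=1e-14)

    def test_eigenvalues_are_axial_pair(self, rng):
        for _ in range(10):
            c = FiberCompartment(rng.standard_normal(3), 1.9, 0.3, 1.0)
            eigs = compartment_tensor(c).eigenvalues
            np.testing.assert_allclose(eigs, [1.9, 0.3, 0.3], atol=1e-12)

    def test_invalid_diffusivities_rejected(self):
        with pytest.raises(InvalidInputError):
            FiberCompartment(np.array([0, 0, 1.0]), 0.5, 1.0, 1.0)


class TestMixtureCumulants:
    def test_single_compartment_is_gaussian(self, rng):
        vm = VoxelModel((FiberCompartment(rng.standard_normal(3),
                                          2.0, 0.4, 1.0),))
        _, w = mixture_cumulants(vm)
        np.testing.assert_allclose(w.components, 0.0, atol=1e-14)

    def test_two_isotropic_compartments(self):
        vm = VoxelModel((FiberCompartment.isotropic(1.0, 0.5),
                         FiberCompartment.isotropic(3.0, 0.5)))
        d, w = mixture_cumulants(vm)
        np.testing.assert_allclose(d.matrix, 2.0 * np.eye(3), atol=1e-14)
        # K = 3 Var(d)/mean(d)^2 = 3/4 along every direction
        np.testing.assert_allclose(w.components, 0.75 * np.array(
            [1, 1, 1, 0, 0, 0, 0, 0, 0, 1 / 3, 1 / 3, 1 / 3, 0, 0, 0]),
            atol=1e-12)
        assert kfa(w) == 0.0

    def test_three_orthogonal_fibers_isotropic_d_anisotropic_w(self):
        vm = VoxelModel(tuple(FiberCompartment(u, 2.0, 0.4, 1 / 3)
                              for u in np.eye(3)))
        d, w = mixture_cumulants(vm)
        assert md_fa(d)[1] < 1e-10
        assert kfa(w) > 0.5

    def test_per_direction_kurtosis_identity(self, rng):
        """K(n) = 3 (sum f_c D_c(n)^2 - D(n)^2) / D(n)^2 exactly."""
        pop = synthetic_population(30, seed=11, profile="mixed")
        dirs = rng.standard_normal((50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for vm, d, w in pop:
            dn = quadratic_design(dirs) @ d.components
            second = np.zeros(len(dirs))
            for c in vm.compartments:
                dc = quadratic_design(dirs) @ compartment_tensor(c).components
                second += c.fraction * dc ** 2
            k_identity = 3.0 * (second - dn ** 2) / dn ** 2
            md = d.md
            from kfakit.tensors import quartic_design
            k_tensor = md ** 2 / dn ** 2 * (quartic_design(dirs)
                                            @ w.components)
            np.testing.assert_allclose(k_tensor, k_identity, atol=1e-10)

    def test_dki_truncation_error_is_cubic_in_b(self):
        """DKI form vs exact multi-Gaussian signal: error ~ O(b^3)."""
        vm = default_fiber_kernel([0, 0, 1.0])
        d, w = mixture_cumulants(vm)
        dirs = np.array([[0.0, 0, 1], [1.0, 0, 0],
                         [np.sqrt(0.5), 0, np.sqrt(0.5)]])
        errs = []
        for b in (0.05, 0.5):
            scheme = AcquisitionScheme.multi_shell([b], dirs)
            exact = gaussian_mixture_signal(vm, scheme)
            trunc = predict_signal(1.0, d, w, scheme)
            nz = ~scheme.b0_mask
            errs.append(np.max(np.abs(trunc[nz] / exact[nz] - 1.0)))
        # 10x in b -> ~1000x in relative error
        assert errs[1] / errs[0] > 100


class TestMixSignals:
    @pytest.fixture
    def blocks(self, rng):
        return rng.random((3, 40))

    def test_alpha_zero_returns_sx(self, blocks):
        np.testing.assert_array_equal(mix_signals(*blocks, 0.0), blocks[0])

    def test_alpha_third_is_equal_mix(self, blocks):
        np.testing.assert_allclose(mix_signals(*blocks, 1 / 3),
                                   blocks.mean(axis=0), atol=1e-15)

    def test_hand_computed_weighting(self, blocks):
        got = mix_signals(*blocks, 0.15)
        want = 0.7 * blocks[0] + 0.15 * blocks[1] + 0.15 * blocks[2]
        np.testing.assert_allclose(got, want, atol=1e-15)

    def test_alpha_out_of_range_rejected(self, blocks):
        for bad in (-0.01, 0.34, 1.0):
            with pytest.raises(InvalidParameterError):
                mix_signals(*blocks, bad)

    def test_default_alpha_grid(self):
        assert DEFAULT_ALPHAS[0] == 0.0
        assert DEFAULT_ALPHAS[-1] == pytest.approx(1 / 3)
        np.testing.assert_allclose(np.diff(DEFAULT_ALPHAS[:-1]), 0.03)


class TestVolumeFractionIndex:
    @pytest.mark.parametrize("fracs, expected", [
        ((1.0, 0.0, 0.0), 1.0),
        ((1 / 3, 1 / 3, 1 / 3), 0.0),
        ((0.5, 0.25, 0.25), 1 / np.sqrt(6)),
    ])
    def test_closed_form_cases(self, fracs, expected):
        assert volume_fraction_index(VolumeFractionTensor(np.array(fracs))) \
            == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            volume_fraction_index(np.zeros(3))


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, rng):
        s = rng.random(100)
        out = add_rician_noise(s, NoiseSpec(snr=np.inf))
        np.testing.assert_array_equal(out, s)

    def test_zero_signal_background_is_rayleigh(self):
        spec = NoiseSpec(snr=10.0, seed=1)  # sigma = 0.1
        out = add_rician_noise(np.zeros(100_000), spec)
        assert out.mean() == pytest.approx(0.1 * np.sqrt(np.pi / 2),
                                           rel=0.02)

    def test_high_snr_bias_matches_rician_expansion(self):
        sigma = 0.01  # S = 100 sigma
        out = add_rician_noise(np.ones(200_000), NoiseSpec(snr=100, seed=2))
        expected = 1.0 + sigma ** 2 / 2.0
        assert out.mean() == pytest.approx(expected, rel=1e-4)

    def test_realization_reproducible_in_isolation(self, rng):
        s = rng.random(50)
        spec = NoiseSpec(snr=20, n_realizations=5, seed=77)
        a = add_rician_noise(s, spec, realization=3)
        b = add_rician_noise(s, spec, realization=3)
        c = add_rician_noise(s, spec, realization=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)


class TestSyntheticPopulation:
    def test_wm_profile_fa_band(self):
        pop = synthetic_population(500, seed=1, profile="wm_like")
        frac = np.mean((pop.fa > 0.6) & (pop.fa < 1.0))
        assert frac >= 0.8

    def test_gm_profile_fa_band(self):
        pop = synthetic_population(500, seed=1, profile="gm_like")
        frac = np.mean((pop.fa > 0.1) & (pop.fa < 0.3))
        assert frac >= 0.8

    def test_mixed_profile_spans_wide_metric_ranges(self):
        pop = synthetic_population(500, seed=1, profile="mixed")
        assert pop.kfa.min() < 0.2 and pop.kfa.max() > 0.85
        assert pop.fa.min() < 0.1 and pop.fa.max() > 0.75
        assert np.var(pop.kfa) > 0.01

    def test_deterministic_given_seed(self):
        a = synthetic_population(50, seed=123, profile="mixed")
        b = synthetic_population(50, seed=123, profile="mixed")
        np.testing.assert_array_equal(a.dt6, b.dt6)
        np.testing.assert_array_equal(a.w15, b.w15)

    def test_frame_export(self):
        df = synthetic_population(10, seed=0).to_frame()
        assert list(df.columns) == ["voxel", "n_compartments", "MD", "FA",
                                    "KFA"]
        assert len(df) == 10


@pytest.fixture(scope="module")
def phantom():
    return orthogonal_phantom()


class TestOrthogonalPhantom:
    def test_three_bundles_per_axis(self, phantom):
        axes = np.abs(phantom.orientations).argmax(axis=1)
        assert sorted(np.bincount(axes).tolist()) == [3, 3, 3]

    def test_bundle_voxel_fit_recovers_single_fiber_metrics(self, phantom):
        i, j, k = np.argwhere(phantom.labels >= 0)[0]
        fit = fit_dki(phantom.data[i, j, k], phantom.scheme)
        d_true = DiffusionTensor(phantom.gt_dt6[i, j, k])
        w_true = KurtosisTensor(phantom.gt_w15[i, j, k])
        assert md_fa(fit.diffusion)[1] \
            == pytest.approx(md_fa(d_true)[1], abs=1e-6)
        assert kfa(fit.kurtosis) == pytest.approx(kfa(w_true), abs=1e-5)

    def test_background_is_free_water(self, phantom):
        bg = np.argwhere(phantom.labels < 0)[0]
        fit = fit_dki(phantom.data[tuple(bg)], phantom.scheme)
        md, fa = md_fa(fit.diffusion)
        assert md == pytest.approx(FREE_WATER_DIFFUSIVITY, abs=1e-6)
        assert fa < 1e-6
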