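"""SMASH calibration and line synthesis: fits, oracles, exact recovery."""

import numpy as np
import pytest

import ksmash as km
from ksmash.kspace import ValidationError
from ksmash.smash import (
    fit_harmonic_weights,
    fit_weights_from_acs,
    harmonic_set,
    smash_reconstruct,
    synthesize_composite,
    target_harmonic,
)


class TestTargetHarmonic:
    def test_order_zero_is_constant_one(self):
        prof = target_harmonic(0, 1.0, np.arange(8) / 8)
        assert np.allclose(prof, 1.0)

    def test_order_one_spans_one_cycle(self):
        n = 16
        prof = target_harmonic(1, 1.0, np.arange(n) / n)
        assert np.allclose(np.abs(prof), 1.0)
        # phase advances by exactly -2*pi/N per row: one full cycle per FOV
        steps = np.angle(prof[1:] / prof[:-1])
        assert np.allclose(steps, -2 * np.pi / n)

    def test_order_two_is_square_of_order_one(self):
        y = np.arange(8) / 8
        assert np.allclose(
            target_harmonic(2, 1.0, y), target_harmonic(1, 1.0, y) ** 2
        )


class TestHarmonicSet:
    def test_forward_set_has_one_offset_per_gap(self):
        assert harmonic_set(2) == (0, 1)
        assert harmonic_set(4) == (0, 1, 2, 3)

    def test_symmetric_set_matches_classical_listing(self):
        assert harmonic_set(2, "symmetric") == (-1, 0, 1)


class TestFitHarmonicWeights:
    def test_uniform_single_coil(self):
        coils = km.CoilArray(np.ones((1, 8, 8), dtype=complex))
        w = fit_harmonic_weights(coils, (0,))
        assert w.weights[0] == pytest.approx([1.0])
        assert w.residuals[0] <= 1e-12

    def test_harmonic_coils_fit_exactly_and_select_matching_order(self):
        n_c = 4
        coils = km.make_coil_array(n_c, 64, 64, "harmonic_exact")
        w = fit_harmonic_weights(coils, (-1, 0, 1))
        orders = np.arange(n_c) - n_c // 2
        for m in (-1, 0, 1):
            assert w.residuals[m] <= 1e-10
            expected = np.where(orders == m, n_c, 0.0)
            assert np.allclose(w.weights[m], expected, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        coils = km.make_coil_array(8, 64, 64, "gaussian")
        w = fit_harmonic_weights(coils, (0, 1))
        n_c, n_y, n_x = coils.sensitivities.shape
        a = coils.sensitivities.reshape(n_c, -1).T
        y = np.arange(n_y) / n_y
        for m in (0, 1):
            t = np.repeat(np.exp(-2j * np.pi * m * y)[:, None], n_x, axis=1).ravel()
            expected = np.linalg.solve(a.conj().T @ a, a.conj().T @ t)
            rel = np.linalg.norm(w.weights[m] - expected) / np.linalg.norm(expected)
            assert rel <= 1e-8

    def test_perturbing_weights_never_improves_residual(self, rng):
        """Local optimality of the least-squares harmonic fit."""
        coils = km.make_coil_array(8, 32, 32, "gaussian")
        w = fit_harmonic_weights(coils, (0, 1))
        n_c, n_y, n_x = coils.sensitivities.shape
        a = coils.sensitivities.reshape(n_c, -1).T
        y = np.arange(n_y) / n_y
        for m in (0, 1):
            t = np.repeat(np.exp(-2j * np.pi * m * y)[:, None], n_x, axis=1).ravel()
            base = np.sqrt(np.mean(np.abs(a @ w.weights[m] - t) ** 2))
            for _ in range(10):
                direction = rng.standard_normal(n_c) + 1j * rng.standard_normal(n_c)
                direction *= 0.01 * np.linalg.norm(w.weights[m]) / np.linalg.norm(direction)
                for sign in (+1, -1):
                    perturbed = w.weights[m] + sign * direction
                    res = np.sqrt(np.mean(np.abs(a @ perturbed - t) ** 2))
                    assert res >= base - 1e-12

    def test_rank_deficiency_flagged(self):
        maps = np.ones((2, 8, 8), dtype=complex)  # two identical coils
        w = fit_harmonic_weights(km.CoilArray(maps), (0,))
        assert w.rank_deficient
        assert w.residuals[0] <= 1e-10

    def test_zero_harmonic_always_included(self):
        coils = km.make_coil_array(4, 16, 16, "harmonic_exact")
        w = fit_harmonic_weights(coils, (1,))
        assert 0 in w.harmonics


class TestFitWeightsFromAcs:
    def test_agrees_with_sensitivity_fit_on_sum_normalized_coils(
        self, sum_normalized_coils
    ):
        truth = km.make_phantom(km.default_phantom_spec(), 64, 64, 20.0, 20.0)
        full = km.encode_array(truth, sum_normalized_coils)
        und = km.undersample(full, km.UndersamplingScheme(r=2, n_acs=6))
        w_acs = fit_weights_from_acs(und, (0, 1))
        w_map = fit_harmonic_weights(sum_normalized_coils, (0, 1))
        for m in (0, 1):
            rel = np.linalg.norm(w_acs.weights[m] - w_map.weights[m])
            rel /= np.linalg.norm(w_map.weights[m])
            assert rel <= 1e-6

    def test_m0_target_reproduced_with_orthogonal_coil_data(self, rng):
        """With independent coil rows the m=0 fit recovers the composite."""
        n = 16
        stack = rng.standard_normal((3, n, n)) + 1j * rng.standard_normal((3, n, n))
        grids = [km.KSpaceGrid(s, 0.1, 0.1) for s in stack]
        data = km.MultiCoilKSpace(grids)
        w = fit_weights_from_acs(data, (0,))
        assert np.allclose(w.weights[0], np.ones(3), atol=1e-10)
        assert w.residuals[0] <= 1e-10

    def test_insufficient_acs_rows_rejected(self):
        truth = km.make_phantom(km.default_phantom_spec(), 16, 16)
        coils = km.make_coil_array(4, 16, 16, "harmonic_exact")
        data = km.undersample(
            km.encode_array(truth, coils), km.UndersamplingScheme(r=4, n_acs=2)
        )
        with pytest.raises(ValidationError, match="3"):
            fit_weights_from_acs(data, (-1, 0, 1))


class TestSynthesizeComposite:
    def test_zero_input_gives_zero_composite(self, exact_setup):
        data = exact_setup["undersampled"]
        zero = km.MultiCoilKSpace(
            [
                km.KSpaceGrid(np.zeros_like(g.samples), g.dk_x, g.dk_y, g.mask)
                for g in data.coils
            ]
        )
        comp = synthesize_composite(zero, exact_setup["weights"])
        assert np.all(comp.samples == 0)

    def test_fully_sampled_uniform_coil_passthrough(self, rng):
        img = km.ImagePlane(rng.standard_normal((8, 8)) + 0j)
        coils = km.CoilArray(np.ones((1, 8, 8), dtype=complex))
        data = km.encode_array(img, coils)
        w = fit_harmonic_weights(coils, (0,))
        comp = synthesize_composite(data, w)
        assert np.allclose(comp.samples, data.coils[0].samples, atol=1e-12)

    def test_synthesized_rows_match_fully_sampled_composite(self, exact_setup):
        comp = synthesize_composite(
            exact_setup["undersampled"], exact_setup["weights"], exact_setup["scheme"]
        )
        ref = synthesize_composite(exact_setup["full"], exact_setup["weights"])
        scale = np.abs(ref.samples).max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        assert np.all(np.abs(comp.samples - ref.samples) / scale <= 1e-8)

    def test_unreachable_rows_rejected(self, exact_setup):
        und = exact_setup["undersampled"]
        w = fit_harmonic_weights(exact_setup["coils"], (0, 2))
        with pytest.raises(ValidationError, match="unreachable"):
            synthesize_composite(und, w)


class TestSmashReconstruct:
    def test_fully_sampled_uniform_coil_equals_inverse_recon(self, rng):
        img = km.ImagePlane(rng.standard_normal((8, 8)) + 0j)
        coils = km.CoilArray(np.ones((1, 8, 8), dtype=complex))
        data = km.encode_array(img, coils)
        rec = smash_reconstruct(data, coils, km.UndersamplingScheme(r=1))
        direct = km.inverse_recon(data.coils[0])
        assert np.allclose(rec.pixels, direct.pixels, atol=1e-12)

    def test_exact_recovery_at_r2(self, exact_setup):
        rec = smash_reconstruct(
            exact_setup["undersampled"], exact_setup["coils"], exact_setup["scheme"]
        )
        ref = exact_setup["reference"]
        err_total, _ = km.err(rec, ref)
        assert err_total / np.abs(ref.pixels).sum() <= 1e-6

    def test_acs_calibration_route_exact_on_sum_normalized_coils(
        self, sum_normalized_coils
    ):
        truth = km.make_phantom(km.default_phantom_spec(), 64, 64, 20.0, 20.0)
        full = km.encode_array(truth, sum_normalized_coils)
        scheme = km.UndersamplingScheme(r=2, n_acs=6)
        und = km.undersample(full, scheme)
        rec = smash_reconstruct(und, calibration=None, scheme=scheme)
        ref = km.inverse_recon(
            synthesize_composite(full, fit_weights_from_acs(und, (0, 1)))
        )
        err_total, _ = km.err(rec, ref)
        assert err_total / np.abs(ref.pixels).sum() <= 1e-6

    def test_linear_in_kspace_data_for_fixed_weights(self, exact_setup, rng):
        w = exact_setup["weights"]
        und = exact_setup["undersampled"]
        mask = und.mask
        a, b = 1.7 - 0.3j, -0.6 + 2.1j
        noise = rng.standard_normal(und.stack().shape) * mask[None, :, None]

        def as_multicoil(stack):
            return km.MultiCoilKSpace(
                [km.KSpaceGrid(s, und.dk_x, und.dk_y, mask) for s in stack]
            )

        s1, s2 = und.stack(), noise.astype(complex)
        lhs = synthesize_composite(as_multicoil(a * s1 + b * s2), w).samples
        rhs = a * synthesize_composite(as_multicoil(s1), w).samples + (
            b * synthesize_composite(as_multicoil(s2), w).samples
        )
        assert np.allclose(lhs, rhs, atol=1e-10 * np.abs(rhs).max())

    def test_benchmark_reconstruction_is_finite_for_all_seeds(self):
        from ksmash.pipeline import RunConfig, reconstruct_method, simulate_acquisition

        config = RunConfig(method="smash")
        for seed in range(1, 21):
            acq = simulate_acquisition(config, seed=seed)
            rec = reconstruct_method(config, acq)
            assert np.all(np.isfinite(rec.pixels))
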