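"""Closed-form CSD, Monte-Carlo oracle, and band FC construction."""

import numpy as np
import pytest

from sgmfc import (DEFAULT_BANDS, DEFAULT_PARAMS, BandFC, SGMParams,
                   SharedFC, band_csd, band_fc, gamma_response, model_csd,
                   monte_carlo_csd, preprocess_sc, shared_fc)
from sgmfc.exceptions import DomainError
from sgmfc.graph import StructuralConnectome, complex_laplacian

ALPHA = DEFAULT_BANDS[2]


class TestGammaResponse:
    def test_dc_value(self):
        assert gamma_response(0.0, 0.01) == 1.0 + 0.0j

    def test_magnitude_strictly_decreasing(self):
        omegas = np.linspace(0, 500, 100)
        mags = np.abs(gamma_response(omegas, 0.01))
        assert np.all(np.diff(mags) < 0)

    def test_half_power_at_unit_omega_tau(self):
        # |1/(1+j)^2| = 1/2, by hand
        assert np.abs(gamma_response(100.0, 0.01)) == pytest.approx(0.5)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(DomainError):
            gamma_response(1.0, 0.0)


class TestModelCSD:
    def test_isolated_nodes_scalar_closed_form(self, sc16):
        # alpha = 0 decouples every region: each diagonal CSD entry is the
        # scalar 1/|j*omega + Fg/tau_g|^2 (unit eigenvalue), off-diagonals 0
        omega = 2 * np.pi * 10
        theta_free = SGMParams(0.015, 12.0, 0.0)  # outside bounds; warned
        csd = model_csd(sc16, theta_free, omega)
        expected = 1.0 / np.abs(
            1j * omega + gamma_response(omega, 0.015) / 0.015) ** 2
        np.testing.assert_allclose(np.diag(csd), expected)
        off = csd - np.diag(np.diag(csd))
        assert np.abs(off).max() < 1e-15

    def test_hermitian_psd_over_parameter_draws(self, sc6):
        rng = np.random.default_rng(3)
        for _ in range(10):
            theta = SGMParams(rng.uniform(0.005, 0.03), rng.uniform(5, 20),
                              rng.uniform(0.1, 1.0))
            omega = 2 * np.pi * rng.uniform(2, 20)
            csd = model_csd(sc6, theta, omega)
            np.testing.assert_allclose(csd, csd.conj().T)
            assert np.linalg.eigvalsh(csd).min() >= -1e-10

    def test_zero_frequency_matches_matrix_inverse(self, sc4):
        # at omega -> 0 the Laplacian is real symmetric, U orthogonal, and
        # the harmonic sum equals M M^H with M = (tau_g^-1 L)^-1
        theta = DEFAULT_PARAMS
        csd = model_csd(sc4, theta, 0.0)
        lap = complex_laplacian(sc4, 0.0, theta.alpha, theta.v)
        m = np.linalg.inv(lap / theta.tau_g)
        np.testing.assert_allclose(csd, m @ m.conj().T, atol=1e-8)

    def test_band_sum_matches_per_frequency_calls(self, sc6):
        theta = DEFAULT_PARAMS
        direct = sum(model_csd(sc6, theta, 2 * np.pi * f)
                     for f in ALPHA.frequencies)
        np.testing.assert_allclose(band_csd(sc6, theta, ALPHA), direct,
                                   atol=1e-12)


class TestMonteCarloCSD:
    def test_seeded_reproducibility(self, sc4):
        a = monte_carlo_csd(sc4, DEFAULT_PARAMS, 10.0, n_draws=5, seed=9)
        b = monte_carlo_csd(sc4, DEFAULT_PARAMS, 10.0, n_draws=5, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_hermitian_for_any_draw_count(self, sc4):
        m = monte_carlo_csd(sc4, DEFAULT_PARAMS, 10.0, n_draws=3, seed=0)
        np.testing.assert_allclose(m, m.conj().T)

    def test_converges_to_closed_form_small_delay(self, sc4):
        # the closed form assumes orthonormal harmonics, accurate at small
        # delay phase; compare at the delta-band centre
        omega = 2 * np.pi * 2.75
        closed = model_csd(sc4, DEFAULT_PARAMS, omega)
        mc = monte_carlo_csd(sc4, DEFAULT_PARAMS, omega, n_draws=20_000, seed=1)
        batches = np.array([
            monte_carlo_csd(sc4, DEFAULT_PARAMS, omega, n_draws=1000, seed=50 + k)
            for k in range(20)
        ])
        se = np.sqrt((batches.std(axis=0) ** 2 / 20).sum())
        assert np.linalg.norm(mc - closed) < 3 * se


class TestBandFC:
    def test_normalized_diagonal_is_ones_then_zeroed(self, sc6):
        s = band_csd(sc6, DEFAULT_PARAMS, ALPHA)
        d = np.diag(s).real
        normalized = s / np.sqrt(np.outer(d, d))
        np.testing.assert_allclose(np.diag(normalized).real, np.ones(6))
        fc = band_fc(sc6, DEFAULT_PARAMS, ALPHA)
        assert np.all(np.diag(fc.matrix) == 0)

    def test_invariance_to_raw_weight_rescaling(self):
        # rescaling all raw tract weights by kappa > 0 is absorbed entirely
        # by preprocessing (cap quantile and sqrt-degree normalization both
        # scale with kappa), so the band FC is unchanged
        from sgmfc import SyntheticSpec, generate_connectome
        raw = generate_connectome(SyntheticSpec(n_regions=6, seed=7))
        scaled = StructuralConnectome(
            weights=3.7 * raw.weights, distances=raw.distances,
            region_ids=raw.region_ids, hemisphere=raw.hemisphere,
            homolog_pairs=raw.homolog_pairs)
        fc1 = band_fc(preprocess_sc(raw), DEFAULT_PARAMS, ALPHA)
        fc2 = band_fc(preprocess_sc(scaled), DEFAULT_PARAMS, ALPHA)
        np.testing.assert_allclose(fc1.matrix, fc2.matrix, atol=1e-10)

    def test_entries_bounded_over_random_draws(self, sc6):
        rng = np.random.default_rng(11)
        for _ in range(50):
            theta = SGMParams(rng.uniform(0.005, 0.03), rng.uniform(5, 20),
                              rng.uniform(0.1, 1.0))
            band = ALPHA
            fc = band_fc(sc6, theta, band)
            m = fc.matrix
            assert m.min() >= 0 and m.max() <= 1
            np.testing.assert_allclose(m, m.T)
            assert np.all(np.diag(m) == 0)

    def test_sensitivity_to_each_parameter(self, sc16):
        base = band_fc(sc16, SGMParams(0.015, 12.0, 0.5), ALPHA).matrix
        for theta in [SGMParams(0.006, 12.0, 0.5), SGMParams(0.015, 19.0, 0.5),
                      SGMParams(0.015, 12.0, 0.9)]:
            other = band_fc(sc16, theta, ALPHA).matrix
            assert np.linalg.norm(base - other) > 0


class TestSharedFC:
    def test_stacked_shape_and_block_extraction(self, sc6):
        shared = shared_fc(sc6, DEFAULT_PARAMS, DEFAULT_BANDS)
        assert shared.stacked.shape == (4 * 6, 6)
        for k in range(4):
            np.testing.assert_array_equal(
                shared.stacked[k * 6:(k + 1) * 6], shared.block(k).matrix)

    def test_single_band_equals_band_fc(self, sc6):
        shared = shared_fc(sc6, DEFAULT_PARAMS, [ALPHA])
        np.testing.assert_array_equal(
            shared.stacked, band_fc(sc6, DEFAULT_PARAMS, ALPHA).matrix)

    def test_permuted_block_order_rejected(self, sc6):
        blocks = shared_fc(sc6, DEFAULT_PARAMS, DEFAULT_BANDS).blocks
        with pytest.raises(ValueError, match="ascending"):
            SharedFC((blocks[2], blocks[0], blocks[1], blocks[3]))

    def test_four_band_68_region_stack_shape(self):
        # the atlas-scale contract: four 68-region bands stack to 272 x 68
        matrices = np.zeros((4, 68, 68))
        blocks = tuple(
            BandFC(band=b, matrix=m, source="model")
            for b, m in zip(DEFAULT_BANDS, matrices))
        assert SharedFC(blocks).stacked.shape == (272, 68)
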