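"""Adaptive kernels: frozen-weight cases, convergence, exact oracles,
structural identities, stability rescues and the cancellation property."""

import numpy as np
import pytest

import fecghybrid as fh
from fecghybrid.errors import DivergenceError, ValidationError
from conftest import ridge_ls_weights


class TestFrozenAndDegenerate:
    def test_zero_step_passes_primary_through(self, short_fixture):
        d, x = short_fixture["d"], short_fixture["x"]
        for run in (fh.lms_kernel(d, x, 5, 0.0), fh.selms_kernel(d, x, 5, 0.0),
                    fh.adaline_kernel(d, x, 5, 0.0)):
            np.testing.assert_array_equal(run.fecg_est, d)

    def test_zero_reference_passes_primary_through(self, short_fixture):
        d = short_fixture["d"]
        z = np.zeros_like(d)
        for run in (fh.lms_kernel(d, z, 5, 0.05), fh.rls_kernel(d, z, 5, 1.0)):
            np.testing.assert_array_equal(run.fecg_est, d)
            assert np.all(run.weights == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fh.lms_kernel(np.zeros(10), np.zeros(9), 2, 0.01)

    def test_scalar_lms_converges_on_identical_signals(self, standard_fixture):
        x = standard_fixture["x"]
        run = fh.lms_kernel(x, x, 1, 0.05)
        rms_tail = np.sqrt(np.mean(run.fecg_est[-1000:] ** 2))
        assert rms_tail < 0.01 * np.sqrt(np.mean(x ** 2))


class TestSignErrorLms:
    def test_positive_error_saturates_updates(self):
        rng = np.random.default_rng(1)
        x = 0.1 * rng.standard_normal(2000)
        d = x + 10.0  # error stays positive throughout
        run = fh.selms_kernel(d, x, 3, 0.001)
        assert np.all(run.fecg_est > 0)
        X = np.zeros((2000, 3))
        for j in range(3):
            X[j:, j] = x[:2000 - j]
        np.testing.assert_allclose(run.weights, 0.001 * X.sum(axis=0),
                                   atol=1e-12)

    def test_differs_from_lms_on_standard_fixture(self, standard_fixture):
        d, x = standard_fixture["d"], standard_fixture["x"]
        a = fh.selms_kernel(d, x, 5, 0.01)
        b = fh.lms_kernel(d, x, 5, 0.01)
        assert not np.array_equal(a.fecg_est, b.fecg_est)


class TestAdaline:
    def test_bias_off_bit_identical_to_lms(self, standard_fixture):
        d, x = standard_fixture["d"], standard_fixture["x"]
        a = fh.adaline_kernel(d, x, 7, 0.013)
        l = fh.lms_kernel(d, x, 7, 0.013)
        assert np.array_equal(a.fecg_est, l.fecg_est)
        assert np.array_equal(a.weights, l.weights)

    def test_bias_changes_output(self, standard_fixture):
        d, x = standard_fixture["d"], standard_fixture["x"]
        a = fh.adaline_kernel(d + 0.5, x, 5, 0.01, bias=True)
        b = fh.adaline_kernel(d + 0.5, x, 5, 0.01, bias=False)
        assert a.weights.size == 6
        assert not np.array_equal(a.fecg_est, b.fecg_est)

    def test_recovers_mixing_fir(self, standard_fixture):
        d, x, h = (standard_fixture[k] for k in ("d", "x", "h"))
        run = fh.adaline_kernel(d, x, 5, 0.01)
        assert np.abs(run.weights - h).max() < 1e-2


class TestRls:
    def test_growing_window_equals_batch_least_squares(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(200)
        h = np.array([0.5, -0.3, 0.2])
        d = np.convolve(x, h)[:200] + 0.01 * rng.standard_normal(200)
        run = fh.rls_kernel(d, x, 3, 1.0, init_delta=0.01)
        np.testing.assert_allclose(run.weights,
                                   ridge_ls_weights(d, x, 3, 0.01), atol=1e-6)

    @pytest.mark.parametrize("M", [1, 4, 8, 16])
    def test_batch_identity_across_orders(self, M):
        rng = np.random.default_rng(M)
        x = rng.standard_normal(500)
        d = np.convolve(x, rng.standard_normal(M))[:500] \
            + 0.05 * rng.standard_normal(500)
        run = fh.rls_kernel(d, x, M, 1.0, init_delta=0.01)
        np.testing.assert_allclose(run.weights,
                                   ridge_ls_weights(d, x, M, 0.01), atol=1e-6)

    def test_recovers_mixing_fir(self, standard_fixture):
        d, x, h = (standard_fixture[k] for k in ("d", "x", "h"))
        run = fh.rls_kernel(d, x, 5, 0.999)
        assert np.abs(run.weights - h).max() < 1e-2

    def test_invalid_lambda_rejected(self, short_fixture):
        with pytest.raises(ValidationError):
            fh.rls_kernel(short_fixture["d"], short_fixture["x"], 3, 1.5)


class TestFtf:
    def test_matches_rls_on_short_fixture(self, short_fixture):
        d, x = short_fixture["d"], short_fixture["x"]
        f = fh.ftf_kernel(d, x, 5, 0.999)
        r = fh.rls_kernel(d, x, 5, 0.999)
        assert np.abs(f.fecg_est - r.fecg_est).max() < 1e-3

    def test_growing_window_matches_rls_exactly(self, short_fixture):
        d, x = short_fixture["d"], short_fixture["x"]
        f = fh.ftf_kernel(d, x, 5, 1.0)
        r = fh.rls_kernel(d, x, 5, 1.0)
        assert np.abs(f.fecg_est - r.fecg_est).max() < 1e-10

    def test_silent_segment_completes(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.standard_normal(300), np.zeros(300),
                            rng.standard_normal(300)])
        d = np.convolve(x, [0.5, 0.3])[:900]
        run = fh.ftf_kernel(d, x, 2, 0.98)
        assert np.all(np.isfinite(run.fecg_est))

    def test_excitation_jump_triggers_rescue_and_completes(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.standard_normal(1500),
                            1e6 * rng.standard_normal(1500)])
        d = np.convolve(x, [0.5, 0.3, -0.2, 0.1])[:3000]
        run = fh.ftf_kernel(d, x, 4, 0.999)
        assert run.rescues >= 1
        assert np.all(np.isfinite(run.fecg_est))

    def test_rescue_budget_enforced(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.standard_normal(1500),
                            1e6 * rng.standard_normal(1500)])
        d = np.convolve(x, [0.5, 0.3, -0.2, 0.1])[:3000]
        with pytest.raises(fh.InstabilityError):
            fh.ftf_kernel(d, x, 4, 0.999, rescue_budget=0)


class TestRunAdaptive:
    def test_dispatch_matches_kernels(self, short_fixture):
        d, x = short_fixture["d"], short_fixture["x"]
        cfg = fh.AdaptiveConfig(algorithm="rls", M=5, lam=0.999)
        via_dispatch = fh.run_adaptive(cfg, d, x)
        direct = fh.rls_kernel(d, x, 5, 0.999)
        assert np.array_equal(via_dispatch.fecg_est, direct.fecg_est)

    def test_kernels_are_pure(self, standard_fixture):
        d, x = standard_fixture["d"], standard_fixture["x"]
        cfg = fh.AdaptiveConfig(algorithm="ftf", M=5, lam=0.999)
        a = fh.run_adaptive(cfg, d, x)
        b = fh.run_adaptive(cfg, d, x)
        assert np.array_equal(a.fecg_est, b.fecg_est)

    def test_divergence_reports_sample_index(self, standard_fixture):
        d, x = standard_fixture["d"], standard_fixture["x"]
        with pytest.raises(DivergenceError) as exc:
            fh.lms_kernel(d, x, 30, 10.0)
        assert exc.value.sample_index is not None

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            fh.AdaptiveConfig(algorithm="nope")
        with pytest.raises(ValidationError):
            fh.AdaptiveConfig(algorithm="rls", lam=0.0)
        with pytest.raises(ValidationError):
            fh.AdaptiveConfig(M=0)

    @pytest.mark.parametrize("algorithm,kw", [
        ("lms", {"mu": 0.005, "M": 5}),
        ("selms", {"mu": 0.005, "M": 5}),
        ("adaline", {"eta": 0.01, "p": 5}),
        ("rls", {"lam": 0.999, "M": 5}),
        ("ftf", {"lam": 0.999, "M": 5}),
    ])
    def test_maternal_cancellation_at_least_10db(self, standard_fixture,
                                                 algorithm, kw):
        """Every algorithm at its fixture-tuned setting suppresses the
        maternal content of the primary by >= 10 dB (final half)."""
        d, x, m = (standard_fixture[k] for k in ("d", "x", "maternal"))
        cfg = fh.AdaptiveConfig(algorithm=algorithm, **kw)
        run = fh.run_adaptive(cfg, d, x)
        tail = slice(len(d) // 2, None)
        mt = m[tail] / np.linalg.norm(m[tail])
        before = abs(np.dot(d[tail], mt))
        after = abs(np.dot(run.fecg_est[tail], mt))
        assert 20 * np.log10(before / after) >= 10.0
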