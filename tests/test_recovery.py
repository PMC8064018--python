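import numpy as np
import pytest

from ocddm.recovery import (
    RecoveryStudyConfig,
    compare_methods,
    identifiability_index,
    recovery_matrix,
    relative_estimation_error,
    run_recovery_study,
    sample_parameters,
)


class TestREE:
    def test_exact_estimate_floors(self):
        t = np.random.default_rng(0).normal(size=(20, 3))
        ree, log_ree = relative_estimation_error(t, t.copy())
        assert np.all(ree == 0)
        assert np.all(log_ree == -30.0)

    def test_quadratic_in_error(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(50, 2))
        e1 = t + rng.normal(size=t.shape)
        e2 = t + 2 * (e1 - t)
        r1, _ = relative_estimation_error(t, e1)
        r2, _ = relative_estimation_error(t, e2)
        np.testing.assert_allclose(r2, 4 * r1, rtol=1e-12)

    def test_independent_estimates_mean_two(self):
        rng = np.random.default_rng(2)
        t = rng.standard_normal((20_000, 1))
        e = rng.standard_normal((20_000, 1))
        ree, _ = relative_estimation_error(t, e)
        assert np.mean(ree) == pytest.approx(2.0, abs=0.1)

    def test_constant_parameter_excluded(self):
        t = np.c_[np.ones(30), np.random.default_rng(3).normal(size=30)] - [1, 0]
        with pytest.warns(UserWarning):
            ree, _ = relative_estimation_error(t, t + 0.1)
        assert np.isnan(ree[:, 0]).all()


class TestRecoveryMatrix:
    def test_perfect_recovery_is_diagonal(self):
        t = np.random.default_rng(0).normal(size=(60, 4))
        M = recovery_matrix(t, t.copy())
        np.testing.assert_allclose(np.diag(M), 100.0, atol=1e-8)
        off = M - np.diag(np.diag(M))
        assert np.all(off < 1.0)

    def test_permuted_recovery_moves_mass(self):
        t = np.random.default_rng(1).normal(size=(60, 3))
        M = recovery_matrix(t, t[:, [1, 2, 0]])
        assert M[0, 1] > 99 and M[1, 2] > 99 and M[2, 0] > 99
        assert np.all(np.diag(M) < 1)

    def test_equal_noise_gives_half_diagonal(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=(4000, 2))
        e = t + rng.normal(size=t.shape)
        M = recovery_matrix(t, e)
        assert np.diag(M) == pytest.approx([50, 50], abs=4)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.normal(size=(80, 3))
        e = t + 0.3 * rng.normal(size=t.shape)
        M1 = recovery_matrix(t, e)
        M2 = recovery_matrix(t, 5.0 * e - 2.0)
        np.testing.assert_allclose(M1, M2, atol=1e-8)

    def test_too_few_replications_rejected(self):
        t = np.random.default_rng(4).normal(size=(5, 4))
        with pytest.raises(ValueError):
            recovery_matrix(t, t)

    def test_rank_deficient_design_rejected(self):
        t = np.random.default_rng(5).normal(size=(30, 2))
        t = np.c_[t, t[:, 0]]
        with pytest.raises(ValueError):
            recovery_matrix(t, t)


class TestIdentifiabilityIndex:
    def test_perfect_recovery_scores_100(self):
        M = np.diag([100.0, 100.0, 100.0])
        assert identifiability_index(M) == pytest.approx(100.0)

    def test_no_structure_scores_zero(self):
        M = np.full((3, 3), 7.0)
        assert identifiability_index(M) == pytest.approx(0.0)

    def test_permuted_recovery_negative(self):
        M = np.array([[0.0, 100.0], [100.0, 0.0]])
        assert identifiability_index(M) < 0


class TestCompareMethods:
    def test_identical_methods(self):
        a = np.random.default_rng(0).normal(size=100)
        out = compare_methods(a, a.copy())
        assert out["delta_log_ree"] == 0.0 and out["p"] == 1.0

    def test_constant_offset_detected(self):
        a = np.random.default_rng(1).normal(size=400)
        out = compare_methods(a + 0.5, a)
        assert out["delta_log_ree"] == pytest.approx(0.5)
        assert out["p"] < 1e-6
        assert out["F"] == pytest.approx((out["delta_log_ree"] / out["se"]) ** 2)

    def test_null_p_values_uniform(self):
        """Calibration: under exchangeable noise the p-value is uniform."""
        rng = np.random.default_rng(2)
        ps = []
        for _ in range(1000):
            a = rng.normal(size=40)
            b = a + rng.normal(size=40)  # same mean
            ps.append(compare_methods(a, b)["p"])
        ps = np.sort(ps)
        # Kolmogorov-Smirnov distance against the uniform CDF
        d = np.max(np.abs(ps - (np.arange(1, 1001) - 0.5) / 1000))
        assert d < 1.63 / np.sqrt(1000)  # ~1% critical value

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(np.zeros(5), np.zeros(6))


class TestSampling:
    def test_reproducible(self):
        a = sample_parameters("varying_drift", np.random.default_rng(7), 50)
        b = sample_parameters("varying_drift", np.random.default_rng(7), 50)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.drift_sequence, b.drift_sequence)

    def test_native_invariants_hold(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            d = sample_parameters("full_set", rng, 10)
            assert d.params.sigma > 0 and d.params.b > 0
            assert abs(d.params.x0) < d.params.b

    def test_decay_rates_span_zero_to_clearly_positive(self):
        rng = np.random.default_rng(9)
        om1 = [sample_parameters("collapsing_bounds", rng, 10).values["omega1"]
               for _ in range(1000)]
        om1 = np.asarray(om1)
        assert np.all(om1 >= 0)
        assert np.quantile(om1, 0.1) < 0.2
        assert np.quantile(om1, 0.9) > 1.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RecoveryStudyConfig(regime="bogus")
        with pytest.raises(ValueError):
            RecoveryStudyConfig(n_replications=1)
        with pytest.raises(ValueError):
            RecoveryStudyConfig(methods=("oca", "nope"))


class TestRegimeOrderings:
    """Benchmark orderings across estimation methods (100 replications of
    200 trials per regime)."""

    def test_fixed_drift_favors_method_of_moments(self, fixed_study):
        means = {m: float(np.mean(v)) for m, v in fixed_study.common_log_ree.items()}
        assert means["mom"] == min(means.values())

    def test_varying_drift_punishes_method_of_moments(self, varying_study):
        means = {m: float(np.mean(v)) for m, v in varying_study.common_log_ree.items()}
        assert means["mom"] == max(means.values())

    def test_collapsing_bounds_favor_overcomplete(self, collapsing_study):
        means = {m: float(np.mean(v)) for m, v in collapsing_study.common_log_ree.items()}
        assert means["oca"] == min(means.values())

    def test_varying_drift_identifiability_beats_full_set(self, varying_study):
        small = run_recovery_study(
            RecoveryStudyConfig(regime="full_set", n_replications=30,
                                methods=("oca",), seed=31)
        )
        assert varying_study.delta_v["oca"] > small.delta_v["oca"]

    def test_reports_serialize(self, varying_study):
        d = varying_study.to_json_dict()
        assert set(d["methods"]) == {"oca", "mom", "motm"}
        assert "oca-mom" in d["contrasts"] or "mom-oca" in d["contrasts"] or \
            any("oca" in k for k in d["contrasts"])
        summary = varying_study.summary()
        assert {"method", "mean_log_ree", "delta_v"} <= set(summary.columns)
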