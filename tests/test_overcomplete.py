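import numpy as np
import pytest
from scipy import stats

from ocddm import (
    Dataset,
    NativeParams,
    OptConfig,
    SimConfig,
    conditional_moments,
    enforce_moments,
    estimate_noise_trajectory,
    fit_overcomplete,
    log_joint,
    simulate_dataset,
)
from ocddm.overcomplete import InfeasibleFitError
from ocddm.params import collapsing_spec
from ocddm.selfconsistency import self_consistent_rt


def small_dataset():
    rt = np.array([1.0, 1.2, 0.9, 1.5, 1.1, 1.3, 1.05, 1.6])
    outcome = np.array([1, 1, 1, -1, -1, 1, 1, -1])
    return Dataset(
        rt=rt, outcome=outcome, drift=np.full(8, 0.5),
        censored=np.zeros(8, dtype=bool),
    )


@pytest.fixture(scope="module")
def varying_fit(ref_params):
    rng = np.random.default_rng(77)
    drifts = 0.5 * rng.standard_normal(200)
    ds = simulate_dataset(ref_params, cfg=SimConfig(seed=55, n_trials=200),
                          drift_sequence=drifts)
    return ds, fit_overcomplete(ds, regime="varying_drift")


class TestLogJoint:
    def test_equals_gaussian_density_of_residuals(self):
        ds = small_dataset()
        dummies = np.array([0.3, -1.2, 0.8, 0.5, -0.4, 1.1, -0.9, 0.2])
        lam = 1.0
        lj = log_joint(ds, np.zeros(4), dummies, lam, regime="fixed_drift",
                       drift_value=0.5)
        # reconstruct by hand through the public pieces
        labels = ds.correct_labels()
        m = conditional_moments(float(labels.mean()))
        eta = enforce_moments(dummies, labels, moments=m)  # drift > 0: sign +
        min_rt = ds.min_rt
        native = NativeParams(v=0.5, x0=0.0, b=1.0, sigma=1.0, t_nd=0.5 * min_rt)
        g = self_consistent_rt(native, None, ds.outcome, ds.rt, eta)
        r = ds.rt - np.asarray(g)
        expected_ll = float(np.sum(stats.norm.logpdf(r, scale=np.sqrt(lam))))
        from ocddm.overcomplete import PriorSpec
        p = PriorSpec()
        lam_prior = -(p.noise_shape + 1) * np.log(lam) - p.noise_rate / lam
        assert lj == pytest.approx(expected_ll - 0.5 * float(dummies @ dummies)
                                   + lam_prior, rel=1e-10)

    def test_outlier_decreases_log_joint(self):
        ds = small_dataset()
        dummies = np.linspace(-1, 1, 8)
        base = log_joint(ds, np.zeros(4), dummies, 1.0, regime="fixed_drift",
                         drift_value=0.5)
        ds_out = small_dataset()
        ds_out.rt[0] = 50.0
        worse = log_joint(ds_out, np.zeros(4), dummies, 1.0, regime="fixed_drift",
                          drift_value=0.5)
        assert worse < base

    def test_permutation_invariance(self):
        ds = small_dataset()
        dummies = np.array([0.3, -1.2, 0.8, 0.5, -0.4, 1.1, -0.9, 0.2])
        perm = np.array([3, 1, 4, 0, 2, 7, 6, 5])
        ds_p = Dataset(rt=ds.rt[perm], outcome=ds.outcome[perm],
                       drift=ds.drift[perm], censored=ds.censored[perm])
        a = log_joint(ds, np.zeros(4), dummies, 0.7, regime="fixed_drift",
                      drift_value=0.5)
        b = log_joint(ds_p, np.zeros(4), dummies[perm], 0.7,
                      regime="fixed_drift", drift_value=0.5)
        assert a == pytest.approx(b, rel=1e-12)


class TestFit:
    def test_deterministic(self, ref_params):
        rng = np.random.default_rng(3)
        drifts = 0.5 * rng.standard_normal(120)
        ds = simulate_dataset(ref_params, cfg=SimConfig(seed=60, n_trials=120),
                              drift_sequence=drifts)
        a = fit_overcomplete(ds)
        b = fit_overcomplete(ds)
        np.testing.assert_array_equal(a.phi_mean, b.phi_mean)
        assert a.lambda_est == b.lambda_est
        np.testing.assert_array_equal(a.eta_tilde_est, b.eta_tilde_est)

    def test_one_sided_outcomes_infeasible(self):
        ds = Dataset(rt=np.linspace(1, 2, 10), outcome=np.ones(10, dtype=int),
                     drift=np.full(10, 0.5), censored=np.zeros(10, dtype=bool))
        with pytest.raises(InfeasibleFitError):
            fit_overcomplete(ds, regime="fixed_drift", drift_value=0.5)

    def test_all_correct_labels_infeasible(self):
        rng = np.random.default_rng(0)
        drift = np.r_[np.full(5, 2.0), np.full(5, -2.0)]
        ds = Dataset(rt=np.linspace(1, 2, 10),
                     outcome=np.sign(drift).astype(int),
                     drift=drift, censored=np.zeros(10, dtype=bool))
        with pytest.raises(InfeasibleFitError):
            fit_overcomplete(ds, regime="varying_drift")

    def test_empty_likelihood_returns_prior(self):
        ds = small_dataset()
        fit = fit_overcomplete(ds, regime="fixed_drift", drift_value=0.5,
                               opt=OptConfig(likelihood_weight=0.0))
        np.testing.assert_array_equal(fit.phi_mean, np.zeros(4))
        np.testing.assert_array_equal(fit.phi_cov, np.eye(4))
        assert fit.converged

    def test_free_energy_trace_monotone(self, varying_fit):
        _, fit = varying_fit
        trace = fit.free_energy_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))
        assert fit.converged

    def test_posterior_covariance_positive_definite(self, varying_fit):
        _, fit = varying_fit
        evals = np.linalg.eigvalsh(fit.phi_cov)
        assert evals.min() > 0

    def test_native_point_in_ballpark(self, varying_fit):
        _, fit = varying_fit
        nat = fit.native_point
        assert 3.0 < nat.b < 30.0
        assert 1.0 < nat.sigma < 15.0
        assert 0.0 < nat.t_nd < fit.min_rt


class TestNoiseTrajectory:
    def test_eta_recovery_correlates_with_truth(self, varying_fit):
        ds, fit = varying_fit
        ok = ~ds.censored
        r = np.corrcoef(fit.eta_tilde_est, ds.eta_tilde_true[ok])[0, 1]
        assert r > 0.5

    def test_group_moments_exact(self, varying_fit):
        ds, fit = varying_fit
        traj = estimate_noise_trajectory(fit)
        labels = fit.correct_labels
        m = conditional_moments(float(labels.mean()))
        sgn = np.where(ds.drift[~ds.censored] >= 0, 1.0, -1.0)
        zeta = sgn * traj["eta_tilde_est"].to_numpy()
        assert zeta[labels].mean() == pytest.approx(m.mu_correct, abs=1e-10)
        assert zeta[labels].var() == pytest.approx(m.var_correct, abs=1e-10)
        assert zeta[~labels].mean() == pytest.approx(m.mu_error, abs=1e-10)

    def test_correct_trials_have_larger_aligned_noise(self, varying_fit):
        ds, fit = varying_fit
        labels = fit.correct_labels
        sgn = np.where(ds.drift[~ds.censored] >= 0, 1.0, -1.0)
        zeta = sgn * fit.eta_tilde_est
        assert zeta[labels].mean() > zeta[~labels].mean()


class TestCollapsingFit:
    def test_recovers_decaying_bound_direction(self):
        p = NativeParams(v=0.3, x0=0.2, b=3.0, sigma=1.2, t_nd=0.2)
        rng = np.random.default_rng(5)
        drifts = 0.6 * rng.standard_normal(200)
        ds = simulate_dataset(p, collapsing_spec(np.log(3.0), 0.6),
                              SimConfig(seed=61, n_trials=200),
                              drift_sequence=drifts)
        fit = fit_overcomplete(ds, spec=collapsing_spec(0.0, 0.0),
                               regime="varying_drift")
        assert "omega1" in fit.param_names
        assert fit.converged
        assert 0.5 < fit.native_point.b < 12.0
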