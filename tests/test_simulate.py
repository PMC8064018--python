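import numpy as np
import pytest

from ocddm import (
    Dataset,
    NativeParams,
    SimConfig,
    moment_signature,
    simulate_dataset,
    simulate_trial,
)
from ocddm.params import collapsing_spec, vanilla_spec
from ocddm.fpt import p_upper_analytic


class TestSingleTrial:
    def test_noise_free_trial_is_ballistic(self):
        p = NativeParams(v=1.0, x0=0.0, b=5.0, sigma=0.0, t_nd=0.2)
        rng = np.random.Generator(np.random.Philox(0))
        rec = simulate_trial(p, vanilla_spec(), SimConfig(dt=1e-3, max_steps=10_000), rng)
        assert rec.outcome == 1
        assert rec.hit_time == pytest.approx(5.0, abs=2e-3)
        assert rec.rt == pytest.approx(5.2, abs=2e-3)

    def test_start_on_bound_hits_immediately(self):
        p = NativeParams(v=0.5, x0=10.0, b=10.0, sigma=4.0, t_nd=0.3)
        rng = np.random.Generator(np.random.Philox(0))
        rec = simulate_trial(p, vanilla_spec(), SimConfig(dt=1e-3, max_steps=10), rng)
        assert rec.outcome == 1
        assert rec.hit_time == 0.0
        assert rec.rt == pytest.approx(0.3)

    def test_censoring_flagged_not_raised(self):
        p = NativeParams(v=0.0, x0=0.0, b=50.0, sigma=0.1, t_nd=0.0)
        rng = np.random.Generator(np.random.Philox(1))
        rec = simulate_trial(p, vanilla_spec(), SimConfig(dt=0.01, max_steps=100), rng)
        assert rec.censored and rec.outcome == 0


class TestDataset:
    def test_seed_determinism(self, ref_params):
        cfg = SimConfig(seed=42, n_trials=50)
        a = simulate_dataset(ref_params, cfg=cfg)
        b = simulate_dataset(ref_params, cfg=cfg)
        np.testing.assert_array_equal(a.rt, b.rt)
        np.testing.assert_array_equal(a.outcome, b.outcome)
        np.testing.assert_array_equal(a.eta_tilde_true, b.eta_tilde_true)

    def test_drift_sequence_length_checked(self, ref_params):
        with pytest.raises(ValueError):
            simulate_dataset(ref_params, cfg=SimConfig(n_trials=10),
                             drift_sequence=[0.5] * 9)

    def test_alternating_drift_is_symmetric(self):
        p = NativeParams(v=0.0, x0=0.0, b=5.0, sigma=2.0, t_nd=0.0)
        n = 2000
        seq = np.tile([1.0, -1.0], n // 2)
        ds = simulate_dataset(p, cfg=SimConfig(seed=3, n_trials=n), drift_sequence=seq)
        assert np.mean(ds.outcome == 1) == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_reference_error_rate(self, ref_dataset_10k):
        """~30% lower-bound decisions at the reference setting."""
        p_down = np.mean(ref_dataset_10k.outcome == -1)
        assert p_down == pytest.approx(0.30, abs=0.02)

    def test_low_censoring_at_reference(self, ref_dataset_10k):
        assert ref_dataset_10k.censored.mean() < 0.01

    def test_rt_equals_hit_time_plus_t_nd(self, ref_dataset_10k):
        ok = ~ref_dataset_10k.censored
        np.testing.assert_allclose(
            ref_dataset_10k.rt[ok], ref_dataset_10k.hit_time[ok] + 0.3, rtol=1e-12
        )

    def test_huge_noise_masks_the_drift(self):
        """With the diffusion dwarfing the drift the outcome probability
        collapses to the drift-free (martingale) value (x0+b)/(2b): the
        drift's influence is gone and entropy is near-maximal."""
        p = NativeParams(v=0.5, x0=1.0, b=10.0, sigma=400.0, t_nd=0.0)
        ds = simulate_dataset(p, cfg=SimConfig(seed=5, n_trials=4000))
        p_up = np.mean(ds.outcome == 1)
        assert p_up == pytest.approx(0.55, abs=0.03)
        # far closer to chance than the reference setting's ~0.70
        assert abs(p_up - 0.5) < 0.1


class TestScalingInvariance:
    @pytest.mark.parametrize("c", [3.0, 0.25])
    def test_joint_rescaling_preserves_choice_rt_distribution(self, ref_params, c):
        """Multiplying v, x0, b, sigma by the same factor leaves the joint
        choice/RT distribution unchanged.  With a shared seed the scaled
        accumulator path is exactly c times the base path (the adaptive step
        is scale-invariant), so outcomes and hitting times coincide
        trial by trial."""
        scaled = NativeParams(v=0.5 * c, x0=1.0 * c, b=10.0 * c, sigma=4.0 * c,
                              t_nd=0.3)
        n = 500
        a = simulate_dataset(ref_params, cfg=SimConfig(seed=11, n_trials=n))
        b = simulate_dataset(scaled, cfg=SimConfig(seed=11, n_trials=n))
        np.testing.assert_array_equal(a.outcome, b.outcome)
        np.testing.assert_allclose(a.hit_time, b.hit_time, rtol=1e-12)
        np.testing.assert_allclose(a.eta_tilde_true, b.eta_tilde_true, rtol=1e-9)

    def test_rescaling_signature_within_monte_carlo_error(self, ref_params):
        c = 3.0
        scaled = NativeParams(v=0.5 * c, x0=1.0 * c, b=10.0 * c, sigma=4.0 * c,
                              t_nd=0.3)
        n = 4000
        sig1 = moment_signature(ref_params, cfg=SimConfig(seed=11, n_trials=n))
        sig2 = moment_signature(scaled, cfg=SimConfig(seed=12, n_trials=n))
        assert sig1["p_up"] == pytest.approx(sig2["p_up"], abs=0.03)
        for key in ("mean_up", "mean_down"):
            assert sig1[key] == pytest.approx(sig2[key], rel=0.08)


class TestRefinement:
    def test_halving_dt_is_stable(self, ref_params):
        n = 10_000
        base = simulate_dataset(ref_params, cfg=SimConfig(seed=21, n_trials=n))
        fine = simulate_dataset(
            ref_params, cfg=SimConfig(dt=0.0078125, seed=22, n_trials=n)
        )
        se = 3 * np.sqrt(0.3 * 0.7 / n) + 0.01  # MC error + O(sqrt(dt)) bias
        assert abs(np.mean(base.outcome == -1) - np.mean(fine.outcome == -1)) < 2 * se
        assert np.mean(base.rt) == pytest.approx(np.mean(fine.rt), rel=0.05)


class TestMomentSignature:
    def test_symmetric_setting(self):
        p = NativeParams(v=0.0, x0=0.0, b=3.0, sigma=1.5, t_nd=0.0)
        sig = moment_signature(p, cfg=SimConfig(seed=8, n_trials=4000))
        assert sig["p_up"] == pytest.approx(0.5, abs=0.03)
        assert sig["mean_up"] == pytest.approx(sig["mean_down"], rel=0.1)

    def test_bias_accelerates_favored_boundary(self):
        lo = moment_signature(
            NativeParams(v=0.5, x0=0.0, b=10.0, sigma=4.0, t_nd=0.0),
            cfg=SimConfig(seed=9, n_trials=4000),
        )
        hi = moment_signature(
            NativeParams(v=0.5, x0=4.0, b=10.0, sigma=4.0, t_nd=0.0),
            cfg=SimConfig(seed=10, n_trials=4000),
        )
        assert hi["mean_up"] < lo["mean_up"]
        assert hi["mean_down"] > lo["mean_down"]
        assert hi["p_up"] > lo["p_up"]

    def test_higher_bound_slows_and_spreads(self):
        small = moment_signature(
            NativeParams(v=0.5, x0=0.0, b=7.0, sigma=4.0, t_nd=0.0),
            cfg=SimConfig(seed=13, n_trials=4000),
        )
        large = moment_signature(
            NativeParams(v=0.5, x0=0.0, b=14.0, sigma=4.0, t_nd=0.0),
            cfg=SimConfig(seed=14, n_trials=4000),
        )
        for side in ("up", "down"):
            assert large[f"mean_{side}"] > small[f"mean_{side}"]
            assert large[f"var_{side}"] > small[f"var_{side}"]

    def test_missing_class_flagged(self):
        p = NativeParams(v=5.0, x0=0.0, b=5.0, sigma=0.5, t_nd=0.0)
        sig = moment_signature(p, cfg=SimConfig(seed=15, n_trials=50))
        assert sig["missing_class"]
        assert np.isnan(sig["mean_down"])


class TestCollapsingSimulation:
    def test_collapse_accelerates_decisions(self):
        p = NativeParams(v=0.2, x0=0.0, b=5.0, sigma=2.0, t_nd=0.0)
        slow = simulate_dataset(p, collapsing_spec(np.log(5.0), 0.0),
                                SimConfig(seed=16, n_trials=800))
        fast = simulate_dataset(p, collapsing_spec(np.log(5.0), 0.5),
                                SimConfig(seed=17, n_trials=800))
        assert fast.rt[~fast.censored].mean() < slow.rt[~slow.censored].mean()


class TestIO:
    def test_csv_round_trip(self, ref_params, tmp_path):
        ds = simulate_dataset(ref_params, cfg=SimConfig(seed=30, n_trials=40))
        path = str(tmp_path / "d.csv")
        ds.to_csv(path)
        back = Dataset.from_csv(path)
        np.testing.assert_allclose(back.rt, ds.rt)
        np.testing.assert_array_equal(back.outcome, ds.outcome)
        np.testing.assert_allclose(back.eta_tilde_true, ds.eta_tilde_true)

    def test_schema_errors_name_the_problem(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("trial,rt,outcome\n0,-1.0,1\n")
        with pytest.raises(ValueError, match="rt"):
            Dataset.from_csv(str(bad))
        bad.write_text("trial,rt\n0,1.0\n")
        with pytest.raises(ValueError, match="outcome"):
            Dataset.from_csv(str(bad))
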