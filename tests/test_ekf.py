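"""Extended Kalman filter: discretization, Jacobians, filtering, recovery."""
import numpy as np
import pytest

from chronodose import (
    ConfigurationError,
    DoseEvent,
    EKFConfig,
    builtin_params,
    discretize,
    ekf_step,
    estimate_vb,
    jacobians,
    simulate_pk,
    synthetic_csf_record,
    vb_initial_guess,
)

DOSES = [DoseEvent(0.0, 2.0)]


class TestDiscretize:
    def test_zero_state_zero_input_fixed_point(self, passive):
        f = discretize(passive, 5.0)
        xa = np.array([0.0, 0.0, 0.0, 3.3e5])
        np.testing.assert_array_equal(f(xa, 0.0), xa)

    def test_one_euler_step_from_unit_gut_mass(self, passive):
        """With ka = 0.11/min and a 5-min sample, one mg decays to 0.45 mg."""
        f = discretize(passive, 5.0)
        nxt = f(np.array([1.0, 0.0, 0.0, 3.3e5]), 0.0)
        assert nxt[0] == pytest.approx(1.0 - 0.11 * 5.0)
        assert nxt[1] == pytest.approx(0.11 * 5.0)
        assert nxt[3] == 3.3e5  # fictitious volume state is constant

    def test_euler_converges_to_continuous_solution(self, passive):
        ref = simulate_pk(passive, DOSES, horizon=360.0, step=5.0, internal_step=0.25)
        for Ts, tol in ((5.0, 0.2), (1.0, 0.05)):
            f = discretize(passive, Ts)
            xa = np.array([passive.F * 2.0, 0.0, 0.0, passive.Vb])
            for _ in range(int(360 / Ts)):
                xa = f(xa)
            err = abs(xa[2] - ref.x3[-1]) / max(ref.x3)
            assert err < tol

    def test_unstable_step_warns(self):
        from chronodose import PKParams

        # a very low-affinity carrier makes the linearized plasma mode stiff
        stiff = PKParams(model_family="carrier_mediated", F=0.5, ka=0.01, ke=0.01,
                         Vp=1e4, Vb=1e4, kebb=0.01, Vmax=10.0, km=1e-4)
        with pytest.warns(UserWarning, match="unstable"):
            discretize(stiff, 5.0)


class TestJacobians:
    def test_passive_state_jacobian_constant_in_state(self, passive):
        A1, _ = jacobians(passive, [0.1, 0.2, 0.3, 3e5])
        A2, _ = jacobians(passive, [5.0, 1.0, 2.0, 3e5])
        np.testing.assert_array_equal(A1, A2)

    def test_measurement_row_for_brain_output(self, passive):
        x3, vb, scale = 0.3, 3e5, 1e9
        _, C = jacobians(passive, [0.0, 0.0, x3, vb], output_scale=scale)
        np.testing.assert_allclose(
            C[1], [0.0, 0.0, scale / vb, -scale * x3 / vb**2]
        )

    def test_nonpositive_volume_rejected(self, passive):
        with pytest.raises(ConfigurationError, match="positive"):
            jacobians(passive, [0.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("label", ["passive_diffusion", "carrier_amine", "nanoparticle"])
    def test_matches_central_finite_differences(self, label):
        params = builtin_params(label)
        f = discretize(params, 5.0)
        rng = np.random.default_rng(7)
        for _ in range(5):
            xa = np.array([rng.uniform(0, 1), rng.uniform(0, 1), rng.uniform(0, 1),
                           rng.uniform(1e4, 1e6)])
            A, C = jacobians(params, xa)
            num_A = np.empty((4, 4))
            for j in range(4):
                h = 1e-6 * max(abs(xa[j]), 1.0)
                hi, lo = xa.copy(), xa.copy()
                hi[j] += h
                lo[j] -= h
                num_A[:, j] = (f(hi) - f(lo)) / (2 * h)
            np.testing.assert_allclose(A, num_A, rtol=1e-5, atol=1e-8)


class TestFilterStep:
    def _setup(self, passive, **cfg_kwargs):
        config = EKFConfig(**cfg_kwargs)
        xa = np.array([passive.F * 2.0, 0.0, 0.0, passive.Vb])
        P = np.diag([1e-6, 1e-6, 1e-6, (0.5 * passive.Vb) ** 2])
        return config, xa, P

    def test_huge_measurement_noise_disables_update(self, passive):
        """As R grows without bound the gain vanishes and update = prediction."""
        config, xa, P = self._setup(passive, R=np.diag([1e30, 1e30]))
        f = discretize(passive, 5.0)
        predicted = f(xa)
        updated, *_ = ekf_step(passive, xa, P, np.array([1e3, 1e3]), 0.0, config)
        np.testing.assert_allclose(updated, predicted, rtol=1e-8, atol=1e-15)

    def test_noise_free_truth_is_fixed_point_for_vb(self, passive):
        """Exact measurements from the true volume leave the estimate at truth."""
        config = EKFConfig()
        record = synthetic_csf_record(passive, DOSES, 720.0, config, seed=0)
        truth = simulate_pk(passive, DOSES, 720.0, step=5.0, internal_step=5.0, method="euler")
        record["yp"] = config.output_scale * truth.yp[1:]
        record["yb"] = config.output_scale * truth.yb[1:]
        run = estimate_vb(record, DOSES, passive, passive.Vb, config)
        assert run.vb_estimate == pytest.approx(passive.Vb, rel=1e-6)

    def test_covariance_stays_symmetric_psd(self, passive):
        config = EKFConfig()
        record = synthetic_csf_record(passive, DOSES, 720.0, config, seed=3)
        run = estimate_vb(record, DOSES, passive, 1.5 * passive.Vb, config)
        for P in run.covariances[::10]:
            np.testing.assert_allclose(P, P.T, atol=1e-10)
            assert np.all(np.linalg.eigvalsh(P) > -1e-8)

    def test_joseph_and_literal_updates_agree_when_wellconditioned(self, passive):
        outs = []
        for joseph in (True, False):
            config = EKFConfig(joseph_form=joseph)
            record = synthetic_csf_record(passive, DOSES, 360.0, config, seed=5)
            run = estimate_vb(record, DOSES, passive, 1.2 * passive.Vb, config)
            outs.append(run.vb_estimate)
        assert outs[0] == pytest.approx(outs[1], rel=1e-3)


class TestEstimateVb:
    def test_recovery_from_fifty_percent_error(self, passive):
        """Median terminal volume error < 10% over 20 noise realizations."""
        config = EKFConfig()
        errors = []
        for seed in range(20):
            record = synthetic_csf_record(passive, DOSES, 720.0, config, seed=seed)
            run = estimate_vb(record, DOSES, passive, 1.5 * passive.Vb, config)
            errors.append(abs(run.vb_estimate - passive.Vb) / passive.Vb)
        assert np.median(errors) < 0.10

    def test_recovery_from_below(self, passive):
        config = EKFConfig()
        errors = []
        for seed in range(20):
            record = synthetic_csf_record(passive, DOSES, 720.0, config, seed=seed)
            run = estimate_vb(record, DOSES, passive, 0.5 * passive.Vb, config)
            errors.append(abs(run.vb_estimate - passive.Vb) / passive.Vb)
        assert np.median(errors) < 0.10

    def test_more_noise_widens_terminal_uncertainty(self, passive):
        config = EKFConfig()
        noisy = EKFConfig(R=np.diag([400.0, 400.0]))
        stds = []
        for cfg in (config, noisy):
            record = synthetic_csf_record(passive, DOSES, 720.0, cfg, seed=11)
            run = estimate_vb(record, DOSES, passive, 1.5 * passive.Vb, cfg)
            stds.append(np.sqrt(run.covariances[-1, 3, 3]))
        assert stds[1] > stds[0]

    def test_innovation_consistency(self, passive):
        """NIS stays near its chi-square (2 dof) expectation when Q, R match."""
        config = EKFConfig()
        record = synthetic_csf_record(passive, DOSES, 720.0, config, seed=2)
        run = estimate_vb(record, DOSES, passive, 1.5 * passive.Vb, config)
        # skip the transient while the volume estimate converges
        assert 0.5 < np.mean(run.nis[40:]) < 4.0

    def test_empty_record_rejected(self, passive):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            estimate_vb(pd.DataFrame(columns=["time_min", "yp", "yb"]), DOSES,
                        passive, passive.Vb)

    def test_volume_prior_from_auc_ratio(self, passive):
        """The AUC-ratio initialization lands within a factor 3 of truth."""
        config = EKFConfig()
        record = synthetic_csf_record(passive, DOSES, 720.0, config, seed=1)
        guess = vb_initial_guess(record, passive.Vp)
        assert 0.3 * passive.Vb < guess < 3.0 * passive.Vb

    def test_seeded_fixture_reproducible(self, passive):
        a = synthetic_csf_record(passive, DOSES, 120.0, seed=42)
        b = synthetic_csf_record(passive, DOSES, 120.0, seed=42)
        assert a.equals(b)
        c = synthetic_csf_record(passive, DOSES, 120.0, seed=43)
        assert not a.equals(c)
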