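import numpy as np
import pytest

from physikin import cekf, synth
from physikin.data import MeasurementSeries
from physikin.skeleton import (
    N_LEN,
    N_STATE,
    N_THETA,
    S_DTHETA,
    S_LEN,
    S_ROOT,
    S_THETA,
    forward_kinematics,
    measurement_jacobian,
)

from conftest import exact_init, squat_config, truth_constraints, uniform_config


class TestTransition:
    def test_velocity_integration_exact(self):
        """One step at 30 Hz moves an angle by dt * velocity exactly."""
        f = cekf.build_transition(1.0 / 30.0)
        x = np.zeros(N_STATE)
        x[S_DTHETA.start] = 0.3  # rad/s on joint 1
        x1 = f @ x
        assert x1[0] == pytest.approx(0.01, abs=1e-15)

    def test_statics_are_fixed_points(self, rng):
        f = cekf.build_transition(1.0 / 30.0)
        x = np.zeros(N_STATE)
        x[S_THETA] = rng.standard_normal(N_THETA)
        x[S_LEN] = rng.uniform(0.1, 0.5, N_LEN)
        x1 = f @ x
        np.testing.assert_array_equal(x1[S_THETA], x[S_THETA])
        np.testing.assert_array_equal(x1[S_LEN], x[S_LEN])

    def test_constant_acceleration_closed_form(self):
        dt, n = 1.0 / 30.0, 90
        f = cekf.build_transition(dt)
        x = np.zeros(N_STATE)
        th0, w0, a0 = 0.2, 0.5, -0.8
        x[0], x[S_DTHETA.start], x[2 * N_THETA] = th0, w0, a0
        for _ in range(n):
            x = f @ x
        t = n * dt
        assert x[0] == pytest.approx(th0 + t * w0 + 0.5 * t * t * a0,
                                     abs=1e-9)

    def test_rejects_non_positive_dt(self):
        with pytest.raises(ValueError):
            cekf.build_transition(0.0)


class TestPredict:
    def test_deterministic_propagation(self):
        f = cekf.build_transition(1 / 30)
        st = cekf.FilterState(x=np.zeros(N_STATE),
                              P=np.zeros((N_STATE, N_STATE)))
        pr = cekf.predict(st, f, np.zeros((N_STATE, N_STATE)))
        assert np.all(pr.P == 0)

    def test_length_covariance_untouched(self, rng):
        """Zero process-noise rows and identity transition leave the
        length covariance block exactly unchanged."""
        from physikin.tuning import assemble_Q
        f = cekf.build_transition(1 / 30)
        q = assemble_Q(np.full(N_THETA, 5.0), 1 / 30, sigma2_root=1.0)
        a = rng.standard_normal((N_STATE, N_STATE))
        p = a @ a.T
        # decouple lengths so F P F' cannot mix them
        p[S_LEN, :] = 0
        p[:, S_LEN] = 0
        idx = np.arange(S_LEN.start, S_LEN.stop)
        p[idx, idx] = rng.uniform(0.5, 2.0, N_LEN)
        st = cekf.FilterState(x=np.zeros(N_STATE), P=p)
        pr = cekf.predict(st, f, q)
        np.testing.assert_allclose(pr.P[S_LEN, S_LEN], p[S_LEN, S_LEN],
                                   atol=1e-12)
        assert np.all(q[S_LEN, :] == 0) and np.all(q[:, S_LEN] == 0)

    def test_psd_closure(self, rng):
        from physikin.tuning import assemble_Q
        f = cekf.build_transition(1 / 30)
        q = assemble_Q(rng.uniform(0.1, 10.0, N_THETA), 1 / 30,
                       sigma2_root=0.5)
        a = rng.standard_normal((N_STATE, N_STATE))
        st = cekf.FilterState(x=np.zeros(N_STATE), P=a @ a.T)
        pr = cekf.predict(st, f, q)
        assert np.linalg.eigvalsh(pr.P).min() >= -1e-10
        np.testing.assert_allclose(pr.P, pr.P.T, atol=1e-12)


def toy_update(rng, n_state=3, n_meas=2):
    """Random linear-Gaussian toy: returns everything a textbook update
    needs."""
    a = rng.standard_normal((n_state, n_state))
    p = a @ a.T + 0.1 * np.eye(n_state)
    h = rng.standard_normal((n_meas, n_state))
    r = np.diag(rng.uniform(0.1, 1.0, n_meas))
    x_prior = rng.standard_normal(n_state)
    z = h @ x_prior + rng.standard_normal(n_meas)
    s = h @ p @ h.T + r
    k = p @ h.T @ np.linalg.inv(s)
    nu = z - h @ x_prior
    x_unc = x_prior + k @ nu
    return p, h, r, x_prior, z, s, k, nu, x_unc


class TestRestrictedGain:
    def test_reduces_to_textbook_when_inactive(self, model, squat_truth,
                                               squat_clean):
        """With no active constraint the update equals the standard EKF
        update to 1e-10 (full skeleton system)."""
        truth = squat_truth
        init = exact_init(truth)
        cons = truth_constraints(model, truth)
        mats = uniform_config().matrices(model)
        prior = cekf.predict(init, mats.F, mats.Q)
        z = squat_clean.positions[1].ravel()
        post, info = cekf.restricted_update(
            prior.x, prior.P, z, model, mats.R, cons)
        # manual textbook update
        h0 = forward_kinematics(model, prior.x[S_THETA], prior.x[S_LEN],
                                prior.x[S_ROOT]).ravel()
        hm = measurement_jacobian(model, prior.x[S_THETA], prior.x[S_LEN])
        s = hm @ prior.P @ hm.T + mats.R
        k = prior.P @ hm.T @ np.linalg.inv(s)
        x_manual = prior.x + k @ (z - h0)
        assert info["n_active"] == 0
        np.testing.assert_allclose(post.x, x_manual, atol=1e-10)

    def test_toy_bound_enforced(self, rng):
        """A violated upper bound is met to machine precision."""
        for _ in range(20):
            p, h, r, x_prior, z, s, k, nu, x_unc = toy_update(rng)
            bound = x_unc[0] - abs(rng.standard_normal())  # force violation
            c = np.array([[1.0, 0.0, 0.0]])
            d = np.array([bound])
            sinv_nu = np.linalg.solve(s, nu)
            kr = cekf.correct_gain(k, nu, sinv_nu, x_unc, c, d)
            x_post = x_prior + kr @ nu
            assert x_post[0] <= bound + 1e-12

    def test_toy_oracle_comparison(self, rng):
        """Gain-corrected posterior vs the P-metric QP projection.

        With single-component constraint rows the corrected gain clamps
        exactly the violating components of the unconstrained posterior
        (documented systematic discrepancy: the equality-constrained
        minimum-variance projection in the P metric also shifts the
        correlated components, so it attains a lower P-metric distance
        while both satisfy the constraint).
        """
        for trial in range(50):
            rng_t = np.random.default_rng(9000 + trial)
            p, h, r, x_prior, z, s, k, nu, x_unc = toy_update(rng_t)
            bound = x_unc[0] - abs(rng_t.standard_normal()) - 0.01
            c = np.array([[1.0, 0.0, 0.0]])
            d = np.array([bound])
            sinv_nu = np.linalg.solve(s, nu)
            kr = cekf.correct_gain(k, nu, sinv_nu, x_unc, c, d)
            x_gain = x_prior + kr @ nu

            # oracle: min (x - x_unc)' P^-1 (x - x_unc) s.t. c x = d
            pinv = np.linalg.inv(p)
            lam = np.linalg.solve(c @ p @ c.T, c @ x_unc - d)
            x_qp = x_unc - p @ c.T @ lam

            # both satisfy the constraint ...
            assert x_gain[0] == pytest.approx(bound, abs=1e-10)
            assert (c @ x_qp)[0] == pytest.approx(bound, abs=1e-10)
            # ... the corrected gain is a componentwise clamp ...
            clamp = x_unc.copy()
            clamp[0] = bound
            np.testing.assert_allclose(x_gain, clamp, atol=1e-10)
            # ... and the QP projection is at least as close in P-metric
            def dist(x):
                e = x - x_unc
                return float(e @ pinv @ e)
            assert dist(x_qp) <= dist(x_gain) + 1e-12

    def test_vanishing_innovation_falls_back_to_clamp(self, model,
                                                      squat_truth):
        truth = squat_truth
        init = exact_init(truth)
        cons = truth_constraints(model, truth)
        mats = uniform_config().matrices(model)
        # prior outside the knee bound, measurement exactly consistent
        x_prior = init.x.copy()
        x_prior[model.joint_index("knee_r")] = np.deg2rad(-3.0) - 1e-6
        z = forward_kinematics(model, x_prior[S_THETA], x_prior[S_LEN],
                               x_prior[S_ROOT]).ravel()
        post, info = cekf.restricted_update(
            x_prior, init.P, z, model, mats.R, cons)
        assert cons.satisfied(post.x)
        assert info["n_active"] >= 1


class TestRunFilter:
    def test_clean_squat_self_consistency(self, model, squat_truth,
                                          squat_clean):
        """Noise-free measurements + exact init: observable angles track
        the ground truth to a fraction of a degree after burn-in (the
        axial rotations are gauge freedoms of the 15-point measurement
        set and are excluded)."""
        truth = squat_truth
        cons = truth_constraints(model, truth)
        cfg = squat_config(r_var=1e-8)
        res = cekf.run_filter(squat_clean, model, cfg.matrices(model),
                              cons, exact_init(truth))
        burn = 30  # 1 s
        gauge = {model.joint_index(n) for n in
                 ["hip_r_rot", "hip_l_rot", "sh_r_rot", "sh_l_rot"]}
        obs = [j for j in range(N_THETA) if j not in gauge]
        err = np.rad2deg(res.theta - truth.theta)[burn:][:, obs]
        assert np.sqrt(np.mean(err**2)) < 0.5

    def test_constraints_hold_every_frame(self, model, squat_truth,
                                          squat_clean):
        truth = squat_truth
        noisy = synth.corrupt(squat_clean, synth.NoiseModel.pooled(),
                              seed=3)
        cons = truth_constraints(model, truth)
        res = cekf.run_filter(noisy, model,
                              squat_config().matrices(model), cons,
                              exact_init(truth))
        lo = np.array([j.limit_lo for j in model.joints])
        hi = np.array([j.limit_hi for j in model.joints])
        assert np.all(res.theta >= lo - 1e-9)
        assert np.all(res.theta <= hi + 1e-9)
        assert np.all(res.lengths >= 0.8 * truth.lengths - 1e-9)
        assert np.all(res.lengths <= 1.2 * truth.lengths + 1e-9)
        assert np.all(res.lengths > 0)

    def test_static_pose_length_variance_shrinks(self, model):
        """Constant measurements with uncertain init lengths: the length
        variance decreases and the final estimate tightens."""
        rng = np.random.default_rng(7)
        theta = np.zeros(N_THETA)
        lengths = model.default_lengths
        pos = forward_kinematics(model, theta, lengths, np.zeros(3))
        n = 120
        series = MeasurementSeries(
            t=np.arange(n) / 30.0,
            positions=np.tile(pos, (n, 1, 1))
            + rng.normal(0, 0.02, (n, 15, 3)))
        x0 = np.zeros(N_STATE)
        x0[S_LEN] = lengths * rng.uniform(0.9, 1.1, N_LEN)
        init = cekf.FilterState(x=x0, P=np.eye(N_STATE))
        cons = cekf.ConstraintSet.from_model(model, 0.7 * lengths,
                                             1.3 * lengths)
        res = cekf.run_filter(series, model,
                              uniform_config(1.0).matrices(model), cons,
                              init)
        len_var = res.p_diag[:, S_LEN]
        assert np.all(len_var[-1] < len_var[0])
        # monotone decrease of the total length variance
        total = len_var.sum(axis=1)
        assert np.all(np.diff(total) <= 1e-9)

    def test_missing_frames_predicted_only(self, model, squat_truth,
                                           squat_clean):
        truth = squat_truth
        noisy = synth.corrupt(squat_clean, synth.NoiseModel.pooled(),
                              seed=3)
        noisy.validity[50] = False
        noisy.validity[51] = False
        cons = truth_constraints(model, truth)
        res = cekf.run_filter(noisy, model,
                              squat_config().matrices(model), cons,
                              exact_init(truth))
        assert res.predicted_only[50] and res.predicted_only[51]
        assert not res.predicted_only[49]
        assert np.isnan(res.innovation_rms[50])

    def test_covariance_health(self, model, squat_truth, squat_clean):
        truth = squat_truth
        noisy = synth.corrupt(squat_clean, synth.NoiseModel.pooled(),
                              seed=4)
        cons = truth_constraints(model, truth)
        res = cekf.run_filter(noisy, model,
                              squat_config().matrices(model), cons,
                              exact_init(truth))
        p = res.final_state.P
        np.testing.assert_allclose(p, p.T, atol=1e-12)
        assert np.linalg.eigvalsh(p).min() >= -1e-9
        assert np.all(res.p_diag >= -1e-9)

    def test_rejects_nonuniform_rate(self, model, squat_truth,
                                     squat_clean):
        bad = MeasurementSeries(
            t=np.concatenate([squat_clean.t[:50],
                              squat_clean.t[50:] + 0.5]),
            positions=squat_clean.positions.copy())
        cons = truth_constraints(model, squat_truth)
        with pytest.raises(ValueError, match="uniform"):
            cekf.run_filter(bad, model,
                            uniform_config().matrices(model), cons,
                            exact_init(squat_truth))

    def test_no_constraint_equivalence(self, model, squat_truth,
                                       squat_clean):
        """On a run whose unconstrained posterior never violates bounds,
        wide and physiological constraints give identical output."""
        truth = squat_truth
        # tiny noise so the filter stays far from every bound
        noisy = synth.corrupt(
            squat_clean,
            synth.NoiseModel(bias=np.zeros(3), var=np.full(3, 1e-8)),
            seed=1)
        tight = truth_constraints(model, truth)
        wide = cekf.ConstraintSet.from_model(
            model, 0.01 * truth.lengths, 100.0 * truth.lengths)
        wide.bound[:2 * N_THETA] = 50.0  # effectively unconstrained angles
        cfg = squat_config(r_var=1e-6)
        r1 = cekf.run_filter(noisy, model, cfg.matrices(model), tight,
                             exact_init(truth))
        r2 = cekf.run_filter(noisy, model, cfg.matrices(model), wide,
                             exact_init(truth))
        if not (r1.n_active > 0).any():
            np.testing.assert_allclose(r1.theta, r2.theta, atol=1e-10)
        else:
            # constraints were touched: equivalence only on frames before
            # the first activation
            first = int(np.flatnonzero(r1.n_active > 0)[0])
            np.testing.assert_allclose(r1.theta[:first],
                                       r2.theta[:first], atol=1e-10)
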