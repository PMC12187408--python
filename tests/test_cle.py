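"""Extended chemical Langevin equation and its linear-noise companion."""

import math

import numpy as np
import pytest

from burstkit import (
    FeedbackParams,
    NoiseScales,
    ToggleParams,
    integrate_dde,
    noise_amplitudes,
    noise_variance_M,
    sigma_from_spectrum,
    simulate_cle,
    simulate_lna,
    simulate_toggle_cle,
    solve_fixed_point,
    toggle_fixed_points,
)


class TestNoiseVariance:
    def test_bursting_term_at_threshold(self, npc_params):
        # at P = P0 the bursting variance is alpha_M^2/(4 lam)
        lam = 2.5
        v = noise_variance_M(npc_params.P0, npc_params,
                             NoiseScales(omega=math.inf, lam=lam), M=0.0)
        assert v == pytest.approx(npc_params.alpha_M**2 / (4 * lam), rel=1e-12)

    def test_classical_limit_without_bursting(self, npc_params):
        ns = NoiseScales(omega=50.0, lam=math.inf)
        from burstkit import hill_repression

        P, M = 1000.0, 12.0
        expected = (npc_params.alpha_M
                    * hill_repression(P, npc_params.P0, npc_params.h)
                    + npc_params.mu_M * M) / 50.0
        assert noise_variance_M(P, npc_params, ns, M) == pytest.approx(
            expected, rel=1e-12)

    def test_both_sentinels_give_zero(self, npc_params):
        assert noise_variance_M(100.0, npc_params, NoiseScales(), 5.0) == 0.0

    def test_matches_lna_amplitude_at_fixed_point(self, npc_params, fig3_noise):
        # cross-module identity: the state-dependent variance evaluated at
        # the fixed point equals the frozen LNA amplitude
        fp = solve_fixed_point(npc_params)
        amps = noise_amplitudes(npc_params, fig3_noise)
        v = noise_variance_M(fp.P, npc_params, fig3_noise, fp.M)
        assert v == pytest.approx(amps.sigma2_M, rel=1e-10)

    def test_negative_inputs_rejected(self, npc_params):
        with pytest.raises(ValueError):
            noise_variance_M(-1.0, npc_params, NoiseScales(), 0.0)


class TestCleIntegration:
    def test_zero_noise_limit_reproduces_delay_ode(self, npc_params):
        ns = NoiseScales(omega=math.inf, lam=math.inf)
        dt = 0.01
        cle = simulate_cle(npc_params, ns, T=500.0, dt=dt, seed=0,
                           init=(0.0, 0.0), history_fill=0.0, sample_dt=1.0)
        dde = integrate_dde(npc_params, history=(0.0, 0.0), T=500.0, dt=dt)
        dde_P = dde.P[:: int(round(1.0 / dt))]
        fp = solve_fixed_point(npc_params)
        assert np.max(np.abs(cle.P - dde_P)) < 0.01 * fp.P  # O(dt) schemes

    def test_absorbing_zero_with_no_production(self):
        p = FeedbackParams(alpha_M=0.0, alpha_P=0.0, mu_M=0.1, mu_P=0.1,
                           h=2.0, P0=100.0, tau=1.0)
        traj = simulate_cle(p, NoiseScales(omega=10.0, lam=5.0), T=100.0,
                            dt=0.01, seed=4, init=(0.0, 0.0), history_fill=0.0)
        # all variance terms vanish at the origin: exactly absorbing
        assert np.all(traj.M == 0.0) and np.all(traj.P == 0.0)

    def test_seed_determinism(self, npc_params, fig3_noise):
        a = simulate_cle(npc_params, fig3_noise, T=200.0, dt=0.01, seed=12)
        b = simulate_cle(npc_params, fig3_noise, T=200.0, dt=0.01, seed=12)
        assert np.array_equal(a.P, b.P)

    def test_literal_drift_variant_changes_scale(self, npc_params, fig3_noise):
        # opt-out flag drops the alpha_M factor in the mRNA drift, which
        # moves the operating point far below the default variant's
        default = simulate_cle(npc_params, fig3_noise, T=2000.0, dt=0.01,
                               seed=3, sample_dt=1.0)
        literal = simulate_cle(npc_params, fig3_noise, T=2000.0, dt=0.01,
                               seed=3, sample_dt=1.0, drift_alpha_m=False)
        assert literal.P[500:].mean() < 0.7 * default.P[500:].mean()
        assert literal.M[500:].mean() < 0.7 * default.M[500:].mean()

    def test_dt_exceeding_delay_rejected(self, npc_params, fig3_noise):
        with pytest.raises(ValueError):
            simulate_cle(npc_params, fig3_noise, T=100.0, dt=50.0)


class TestLnaSimulation:
    def test_fluctuations_decay_without_noise(self, npc_params):
        # the spiral decay is slow (period ~ hours): compare envelopes
        ns = NoiseScales(omega=math.inf, lam=math.inf)
        traj = simulate_lna(npc_params, ns, T=8000.0, dt=0.01,
                            init=(5.0, 5000.0), sample_dt=1.0)
        early = np.max(np.abs(traj.p[:2000]))
        late = np.max(np.abs(traj.p[-2000:]))
        assert late < 0.05 * early
        assert abs(traj.p[-1]) < 5.0

    def test_zero_mean_fluctuations(self, npc_params, fig3_noise):
        trajs = [simulate_lna(npc_params, fig3_noise, T=5000.0, dt=0.01,
                              seed=s, sample_dt=1.0) for s in range(5)]
        pooled = np.concatenate([t.p[500:] for t in trajs])
        sig = sigma_from_spectrum(npc_params, fig3_noise)
        # SE of the pooled mean given the known stationary sigma and an
        # oscillation correlation time of a few hundred minutes
        assert abs(pooled.mean()) < 4 * sig * math.sqrt(400.0 / (5 * 4500))

    def test_variance_scales_inversely_with_lambda(self, npc_params):
        # with Omega off, all noise power is ~ 1/lam: exact LNA scaling
        s1 = sigma_from_spectrum(npc_params, NoiseScales(lam=1.0))
        s4 = sigma_from_spectrum(npc_params, NoiseScales(lam=4.0))
        assert s1**2 == pytest.approx(4.0 * s4**2, rel=1e-8)

    def test_variance_scales_inversely_with_omega(self, npc_params):
        s1 = sigma_from_spectrum(npc_params, NoiseScales(omega=50.0))
        s4 = sigma_from_spectrum(npc_params, NoiseScales(omega=200.0))
        assert s1**2 == pytest.approx(4.0 * s4**2, rel=1e-8)


class TestToggleCle:
    def test_zero_noise_converges_to_deterministic_fixed_point(
            self, toggle_params):
        p = ToggleParams(alpha=1.0, mu=0.1, h=2.0, P0=3.0, noise=NoiseScales())
        traj = simulate_toggle_cle(p, T=2000.0, dt=0.01, seed=0,
                                   init=(1.0, 1.0), sample_dt=1.0)
        fps = toggle_fixed_points(p)
        end = (traj.A[-1], traj.B[-1])
        best = min(fps, key=lambda f: abs(f.A - end[0]) + abs(f.B - end[1]))
        assert end[0] == pytest.approx(best.A, abs=1e-6)
        assert end[1] == pytest.approx(best.B, abs=1e-6)

    def test_bistable_occupation_levels(self, toggle_params):
        traj = simulate_toggle_cle(toggle_params, T=20000.0, dt=0.01, seed=6,
                                   init=(1.0, 1.0), sample_dt=1.0)
        hi = max(traj.A[2000:].mean(), traj.B[2000:].mean())
        lo = min(traj.A[2000:].mean(), traj.B[2000:].mean())
        assert hi == pytest.approx(9.0, rel=0.15)
        assert lo == pytest.approx(1.0, rel=0.25)

    def test_classical_variance_without_bursting(self):
        # lam off reduces to the classical two-species CLE; in a monostable
        # weak-repression regime the stationary variance must match the
        # Lyapunov solution of the linearized system (independent oracle)
        from scipy.linalg import solve_continuous_lyapunov

        from burstkit import hill_derivative, hill_repression

        p = ToggleParams(alpha=1.0, mu=0.1, h=2.0, P0=30.0,
                         noise=NoiseScales(omega=200.0, lam=math.inf))
        fps = toggle_fixed_points(p)
        assert len(fps) == 1  # monostable
        s = fps[0].A
        J = np.array([
            [-p.mu, p.alpha * hill_derivative(s, p.P0, p.h)],
            [p.alpha * hill_derivative(s, p.P0, p.h), -p.mu],
        ])
        d = (p.alpha * hill_repression(s, p.P0, p.h)
             + p.mu * s) / p.noise.omega
        C = solve_continuous_lyapunov(J, -np.diag([d, d]))
        traj = simulate_toggle_cle(p, T=30000.0, dt=0.01, seed=9,
                                   init=(s, s), sample_dt=1.0)
        var = traj.A[1000:].var()
        assert var == pytest.approx(C[0, 0], rel=0.15)
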