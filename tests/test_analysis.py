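"""Stationary statistics, periodogram normalization, sweeps, dwell times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstkit import (
    Trajectory,
    ensemble_periodogram,
    relative_error,
    stationary_std,
    sweep_grid,
    waiting_times,
)
from burstkit.analysis import derive_seed


def make_traj(series, dt=1.0, name="P"):
    series = np.asarray(series, dtype=float)
    return Trajectory(times=np.arange(series.size) * dt,
                      channels={name: series})


class TestStationaryStd:
    def test_constant_series(self):
        s = stationary_std(make_traj(np.full(100, 7.0)), "P")
        assert s.Sigma == 0.0 and s.mean == 7.0

    def test_alternating_series(self):
        s = stationary_std(make_traj(np.tile([0.0, 2.0], 50)), "P")
        assert s.mean == pytest.approx(1.0)
        assert s.Sigma == pytest.approx(1.0)

    def test_discard_window(self):
        x = np.concatenate([np.full(50, 100.0), np.full(50, 2.0)])
        s = stationary_std(make_traj(x), "P", discard=50.0)
        assert s.Sigma == 0.0 and s.mean == 2.0 and s.n_effective == 50

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            stationary_std(make_traj(np.ones(10)), "P", discard=100.0)

    @given(st.integers(2, 6), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_pooling_equals_concatenation(self, k, seed):
        rng = np.random.default_rng(seed)
        trajs = [make_traj(rng.normal(rng.uniform(-5, 5), 2.0, size=200))
                 for _ in range(k)]
        pooled = stationary_std(trajs, "P").Sigma
        concat = float(np.std(np.concatenate([t.P for t in trajs])))
        assert pooled == pytest.approx(concat, rel=1e-12, abs=1e-12)


class TestRelativeError:
    @pytest.mark.parametrize("sig, ref, expected",
                             [(1.0, 1.0, 0.0), (1.37, 1.0, 0.37),
                              (0.5, 1.0, 0.5)])
    def test_values(self, sig, ref, expected):
        assert relative_error(sig, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestPeriodogram:
    def test_sinusoid_concentrates_power(self):
        dt, n, a = 0.5, 4096, 3.0
        t = np.arange(n) * dt
        w0 = 2 * math.pi * 8 / (n * dt)  # on-grid frequency
        res = ensemble_periodogram(make_traj(a * np.sin(w0 * t), dt=dt), "P")
        domega = res.omega[1] - res.omega[0]
        total = np.sum(res.S_P) * domega / (2 * math.pi)
        assert total == pytest.approx(a**2 / 2, rel=1e-9)
        peak = np.abs(res.omega[np.argmax(res.S_P)])
        assert peak == pytest.approx(w0, rel=1e-9)

    def test_white_noise_is_flat_at_v_dt(self):
        dt, n, v = 2.0, 2048, 4.0
        rng = np.random.default_rng(7)
        trajs = [make_traj(rng.normal(0, math.sqrt(v), n), dt=dt)
                 for _ in range(200)]
        res = ensemble_periodogram(trajs, "P")
        level = v * dt
        nonzero = res.omega != 0.0  # DC bin is identically 0 (mean removed)
        # each bin averages 200 exponential(level) draws: SE = level/sqrt(200)
        assert np.mean(res.S_P[nonzero]) == pytest.approx(level, rel=0.02)
        assert np.max(np.abs(res.S_P[nonzero] - level)) < 6 * level / math.sqrt(200)

    @given(st.integers(16, 512), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_discrete_parseval_exact(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n) * rng.uniform(0.1, 10)
        dt = rng.uniform(0.01, 5.0)
        traj = make_traj(x, dt=dt)
        res = ensemble_periodogram(traj, "P")
        domega = 2 * math.pi / (n * dt)
        integral = np.sum(res.S_P) * domega / (2 * math.pi)
        assert integral == pytest.approx(float(np.var(x)), rel=1e-9)

    def test_inconsistent_grids_rejected(self):
        with pytest.raises(ValueError):
            ensemble_periodogram([make_traj(np.ones(10)),
                                  make_traj(np.ones(20))], "P")


class TestSweep:
    def test_cell_seeds_are_stable_and_distinct(self):
        a = derive_seed(3, 0, 1, 2, 0)
        assert a == derive_seed(3, 0, 1, 2, 0)
        assert a != derive_seed(3, 0, 1, 2, 1)
        assert a != derive_seed(4, 0, 1, 2, 0)
        assert 0 <= a < 2**31

    def test_small_sweep_structure(self, npc_params):
        res = sweep_grid(npc_params, [1.0], [1.0],
                         tiers=("full", "cle", "lna-theory"),
                         T=2000.0, discard=500.0, n_traj=2, base_seed=5,
                         n_boot=100)
        t = res.table
        assert set(t["tier"]) == {"full", "cle", "lna-theory"}
        full = t[t.tier == "full"].iloc[0]
        assert full.r_Sigma == 0.0 and full.Sigma_P > 0
        cle = t[t.tier == "cle"].iloc[0]
        assert cle.r_Sigma == pytest.approx(
            abs(cle.Sigma_P - full.Sigma_P) / full.Sigma_P)
        assert cle.ci_lo <= cle.Sigma_P <= cle.ci_hi

    def test_deterministic_cell_is_flagged(self, npc_params):
        res = sweep_grid(npc_params, [math.inf], [math.inf],
                         tiers=("cle",), T=100.0, n_traj=1, n_boot=10)
        row = res.table.iloc[0]
        assert row.flag == "deterministic-cell"
        assert math.isnan(row.Sigma_P)

    def test_resume_skips_completed_cells(self, npc_params):
        first = sweep_grid(npc_params, [1.0], [1.0], tiers=("lna-theory",),
                           T=100.0, n_boot=10)
        again = sweep_grid(npc_params, [1.0, 2.0], [1.0],
                           tiers=("lna-theory",), T=100.0, n_boot=10,
                           existing=first.table)
        t = again.table
        assert len(t) == 2
        reused = t[(t["lambda"] == 1.0)].iloc[0]
        assert reused.Sigma_P == first.table.iloc[0].Sigma_P


class TestWaitingTimes:
    def test_square_wave_dwells(self):
        half = 2000
        period = np.concatenate([np.full(half, 8.0), np.full(half, 0.0)])
        A = np.tile(period, 10)
        B = 8.0 - A
        traj = Trajectory(times=np.arange(A.size) * 1.0,
                          channels={"A": A, "B": B})
        sample = waiting_times(traj, window=1.0, threshold=4.0)
        assert np.allclose(sample.durations, half)
        # interior runs only: first run touches the series start
        assert sample.durations.size == 9

    def test_condition_never_met(self):
        traj = Trajectory(times=np.arange(1000.0),
                          channels={"A": np.full(1000, 9.0),
                                    "B": np.full(1000, 9.0)})
        sample = waiting_times(traj, window=1.0, threshold=4.0)
        assert sample.durations.size == 0

    def test_two_state_jump_process_mean(self):
        # alternating exponential dwells with known means: the extracted
        # mean dwell in the (A high, B low) state must match the truth
        rng = np.random.default_rng(42)
        mean_hi, mean_lo, dt = 500.0, 300.0, 1.0
        segs_A = []
        state = 0
        while sum(len(s) for s in segs_A) < 400_000:
            dur = rng.exponential(mean_hi if state == 0 else mean_lo)
            n = max(int(round(dur / dt)), 1)
            segs_A.append(np.full(n, 8.0 if state == 0 else 0.0))
            state = 1 - state
        A = np.concatenate(segs_A)
        B = 8.0 - A
        traj = Trajectory(times=np.arange(A.size) * dt,
                          channels={"A": A, "B": B})
        sample = waiting_times(traj, window=1.0, threshold=4.0)
        se = mean_hi / math.sqrt(sample.durations.size)
        assert sample.durations.size > 300
        assert abs(sample.mean - mean_hi) < 3 * se

    def test_window_longer_than_series_rejected(self):
        traj = Trajectory(times=np.arange(100.0),
                          channels={"A": np.ones(100), "B": np.ones(100)})
        with pytest.raises(ValueError):
            waiting_times(traj, window=200.0)
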