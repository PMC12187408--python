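"""Extended chemical Langevin equations with transcriptional-bursting noise.

The classical chemical Langevin equation carries Gaussian copy-number noise
of variance 1/Omega per reaction.  The extension adds a second, independent
white-noise contribution to the mRNA equation of variance

    (alpha_M^2 / lam) * 2 (P/P0)^h / (1 + (P/P0)^h)^3,

the Gaussian residue of telegraph-promoter switching at large but finite
bursting parameter lam.  Both contributions switch off exactly when their
scale (Omega or lam) is infinite.  The mRNA and protein noises are
uncorrelated because no reaction changes both species.

``simulate_lna`` integrates the linearization of these equations about the
deterministic fixed point, with noise amplitudes frozen at that point; its
stationary statistics admit the closed forms in :mod:`burstkit.lna_spectra`.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .core_models import (
    FeedbackParams,
    NoiseScales,
    ToggleParams,
    Trajectory,
    hill_derivative,
    hill_repression,
    solve_fixed_point,
)

__all__ = [
    "noise_variance_M",
    "simulate_cle",
    "simulate_lna",
    "simulate_toggle_cle",
]

_MAX_SEED = 2**31 - 1


def noise_variance_M(
    P_delayed: float, params: FeedbackParams, noise: NoiseScales, M: float
) -> float:
    """Instantaneous variance density of the mRNA noise, cu^2/min.

    Sum of the bursting term (scale 1/lam) and the copy-number term
    (scale 1/Omega); each vanishes when its scale is infinite.
    """
    if P_delayed < 0 or M < 0:
        raise ValueError("noise_variance_M requires P_delayed >= 0 and M >= 0")
    var = 0.0
    if noise.bursting_noise:
        x = P_delayed / params.P0
        if x > 0:
            xh = x**params.h
            var += (params.alpha_M**2 / noise.lam) * 2.0 * xh / (1.0 + xh) ** 3
    if noise.copy_number_noise:
        f = hill_repression(P_delayed, params.P0, params.h)
        var += (params.alpha_M * f + params.mu_M * M) / noise.omega
    return var


def _resolve_init_conc(init, params) -> tuple[float, float]:
    if init == "fixed-point" or init is None:
        fp = solve_fixed_point(params)
        return fp.M, fp.P
    return float(init[0]), float(init[1])


def simulate_cle(
    params: FeedbackParams,
    noise: NoiseScales,
    T: float,
    dt: float = 0.01,
    seed: int = 0,
    init="fixed-point",
    history_fill: float | None = None,
    sample_dt: float | None = None,
    drift_alpha_m: bool = True,
) -> Trajectory:
    """Euler-Maruyama integration of the extended CLE; returns a Trajectory.

    The delayed protein value is read from a ring buffer at lag
    round(tau/dt); ``history_fill`` is the constant pre-t0 protein value
    (default: the initial P).  The state is clamped at zero after each
    step.  ``sample_dt`` thins the output grid (default: every step).
    ``drift_alpha_m=False`` drops the factor alpha_M in front of the Hill
    drift, preserving a literal variant of the mRNA equation; the default
    keeps it, consistent with the deterministic limit and the alpha_M^2
    scale of the bursting noise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.tau > 0 and dt > params.tau:
        raise ValueError("dt must not exceed the delay tau")
    M0, Pinit = _resolve_init_conc(init, params)
    if history_fill is None:
        history_fill = Pinit
    stride = 1
    if sample_dt is not None:
        stride = max(1, int(round(sample_dt / dt)))

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, _MAX_SEED))
    M, P, status = _kernels.cle_feedback(
        params.alpha_M, params.alpha_P, params.mu_M, params.mu_P,
        params.h, params.P0, params.tau,
        noise.copy_number_noise, noise.omega if noise.copy_number_noise else 1.0,
        noise.bursting_noise, noise.lam if noise.bursting_noise else 1.0,
        float(T), float(dt), kernel_seed,
        float(M0), float(Pinit), float(history_fill),
        stride, drift_alpha_m,
    )
    if status != 0:
        raise RuntimeError(f"CLE state became NaN (seed {seed}, dt {dt})")
    times = np.arange(M.shape[0]) * (dt * stride)
    return Trajectory(
        times=times,
        channels={"M": M, "P": P},
        meta={"tier": "cle", "params": params, "noise": noise, "seed": seed,
              "dt": dt, "drift_alpha_m": drift_alpha_m},
    )


def simulate_lna(
    params: FeedbackParams,
    noise: NoiseScales,
    T: float,
    dt: float = 0.01,
    seed: int = 0,
    init=(0.0, 0.0),
    sample_dt: float | None = None,
) -> Trajectory:
    """Linear-noise simulation: fluctuations (m, p) about the fixed point.

    Drift: dm = alpha_M f'(P*) p(t - tau) - mu_M m, dp = alpha_P m - mu_P p;
    constant noise amplitudes sigma_M, sigma_P evaluated at the fixed point.
    Fluctuations may be negative; nothing is clamped.
    """
    from .lna_spectra import noise_amplitudes

    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.tau > 0 and dt > params.tau:
        raise ValueError("dt must not exceed the delay tau")
    fp = solve_fixed_point(params)
    amps = noise_amplitudes(params, noise)
    aM_fprime = params.alpha_M * hill_derivative(fp.P, params.P0, params.h)
    stride = 1
    if sample_dt is not None:
        stride = max(1, int(round(sample_dt / dt)))

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, _MAX_SEED))
    m, p = _kernels.lna_feedback(
        aM_fprime, params.alpha_P, params.mu_M, params.mu_P, params.tau,
        math.sqrt(amps.sigma2_M), math.sqrt(amps.sigma2_P),
        float(T), float(dt), kernel_seed,
        float(init[0]), float(init[1]), stride,
    )
    times = np.arange(m.shape[0]) * (dt * stride)
    return Trajectory(
        times=times,
        channels={"m": m, "p": p},
        meta={"tier": "lna", "params": params, "noise": noise, "seed": seed,
              "dt": dt, "fixed_point": fp},
    )


def simulate_toggle_cle(
    params: ToggleParams,
    T: float,
    dt: float = 0.01,
    seed: int = 0,
    init=(1.0, 1.0),
    sample_dt: float | None = None,
) -> Trajectory:
    """Euler-Maruyama for the toggle-switch CLE (two mirrored channels).

    Drifts alpha*f(B) - mu*A and alpha*f(A) - mu*B with independent noise
    variances combining the bursting (1/lam) and copy-number (1/Omega)
    contributions for each channel; state clamped at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    noise = params.noise
    stride = 1
    if sample_dt is not None:
        stride = max(1, int(round(sample_dt / dt)))

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, _MAX_SEED))
    A, B, status = _kernels.cle_toggle(
        params.alpha, params.mu, params.h, params.P0,
        noise.copy_number_noise, noise.omega if noise.copy_number_noise else 1.0,
        noise.bursting_noise, noise.lam if noise.bursting_noise else 1.0,
        float(T), float(dt), kernel_seed,
        float(init[0]), float(init[1]), stride,
    )
    if status != 0:
        raise RuntimeError(f"toggle CLE state became NaN (seed {seed})")
    times = np.arange(A.shape[0]) * (dt * stride)
    return Trajectory(
        times=times,
        channels={"A": A, "B": B},
        meta={"tier": "toggle-cle", "params": params, "seed": seed, "dt": dt},
    )
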