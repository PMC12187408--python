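"""Statistically exact simulation of the discrete bursting models.

``simulate_full`` runs the delayed stochastic simulation algorithm for the
auto-negative feedback motif: a telegraph promoter whose OFF-switching rate
is lam*(P/P0)^h, transcription initiations while ON that deliver an mRNA a
fixed delay tau later, translation and first-order degradation.  The delay
is handled as a scheduled-event queue; whenever a scheduled arrival
precedes the next tentative reaction the clock advances to the arrival and
the exponential clock is redrawn, which is exact by memorylessness.
Initiated transcripts are delivered regardless of later promoter state
(production is tied to the promoter state at initiation).

With ``noise.lam == inf`` the promoter averages out and the propensity set
reduces to transcription at rate alpha_M*Omega*f(n_P/Omega) with the Hill
function f — the classical copy-number-noise-only model.

``simulate_toggle_ssa`` is a plain Gillespie simulation of the two-gene
toggle switch with telegraph promoters (no delay, no explicit mRNA).
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from . import _kernels
from .core_models import (
    FeedbackParams,
    FixedPoint,
    NoiseScales,
    ToggleParams,
    Trajectory,
    hill_repression,
    solve_fixed_point,
)

__all__ = ["simulate_full", "simulate_toggle_ssa"]

_MAX_SEED = 2**31 - 1


def _check_grid(T: float, sample_dt: float) -> None:
    n = T / sample_dt
    if abs(n - round(n)) > 1e-9:
        warnings.warn(
            "T is not a multiple of sample_dt; the final partial interval "
            "is dropped", stacklevel=3)


def _resolve_init(init, params: FeedbackParams, omega: float) -> tuple[int, int]:
    if init == "fixed-point" or init is None:
        fp = solve_fixed_point(params)
        return int(round(omega * fp.M)), int(round(omega * fp.P))
    nM, nP = init
    if nM < 0 or nP < 0:
        raise ValueError("initial counts must be nonnegative")
    return int(nM), int(nP)


def simulate_full(
    params: FeedbackParams,
    noise: NoiseScales,
    T: float,
    sample_dt: float = 1.0,
    seed: int = 0,
    init="fixed-point",
) -> Trajectory:
    """Exact delayed-SSA trajectory of the full model, in concentration units.

    ``init`` is ``"fixed-point"`` (counts rounded from Omega*(M*, P*)) or a
    ``(n_M, n_P)`` pair of molecule counts.  The initial promoter state is
    drawn Bernoulli(f(P_init)) from the seeded stream — the stationary
    conditional law of the telegraph promoter at the initial protein level.
    Sampling onto the uniform grid is zero-order hold.
    """
    if not math.isfinite(noise.omega):
        raise ValueError("simulate_full requires a finite system size Omega")
    _check_grid(T, sample_dt)
    nM0, nP0 = _resolve_init(init, params, noise.omega)

    bursting = noise.bursting_noise
    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, _MAX_SEED))
    if bursting:
        f0 = hill_repression(nP0 / noise.omega, params.P0, params.h)
        sigma0 = 1 if rng.random() < f0 else 0
    else:
        sigma0 = 1

    queue_cap = int(params.alpha_M * noise.omega * max(params.tau, 1.0) * 4) + 1024
    lam = noise.lam if bursting else 0.0
    M, P, sig, n_init, n_deliv, residue, status = _kernels.ssa_full(
        params.alpha_M, params.alpha_P, params.mu_M, params.mu_P,
        params.h, params.P0, params.tau,
        noise.omega, bursting, lam,
        float(T), float(sample_dt), kernel_seed,
        nM0, nP0, sigma0,
        queue_cap,
    )
    if status != 0:
        raise RuntimeError(
            f"delay queue overflow (capacity {queue_cap}) at seed {seed}")

    n_samp = M.shape[0]
    times = np.arange(n_samp) * sample_dt
    channels = {"M": M / noise.omega, "P": P / noise.omega}
    if bursting:
        channels["sigma"] = sig
    return Trajectory(
        times=times,
        channels=channels,
        meta={
            "tier": "full" if bursting else "copy-number-only",
            "params": params,
            "noise": noise,
            "seed": seed,
            "n_initiated": int(n_init),
            "n_delivered": int(n_deliv),
            "queue_residue": int(residue),
        },
    )


def simulate_toggle_ssa(
    params: ToggleParams,
    T: float,
    sample_dt: float = 1.0,
    seed: int = 0,
    init=(1.0, 1.0),
) -> Trajectory:
    """Gillespie trajectory of the toggle switch, concentrations in cu.

    ``init`` gives the initial concentrations (A, B) in cu; counts are
    rounded from Omega*(A, B).  Both promoters start in the state drawn
    Bernoulli(f(other protein)) from the seeded stream.
    """
    noise = params.noise
    if not (math.isfinite(noise.omega) and math.isfinite(noise.lam)):
        raise ValueError("simulate_toggle_ssa requires finite Omega and lambda")
    _check_grid(T, sample_dt)
    A0, B0 = float(init[0]), float(init[1])
    nA0 = int(round(noise.omega * A0))
    nB0 = int(round(noise.omega * B0))

    rng = np.random.default_rng(seed)
    kernel_seed = int(rng.integers(0, _MAX_SEED))
    sA0 = 1 if rng.random() < hill_repression(B0, params.P0, params.h) else 0
    sB0 = 1 if rng.random() < hill_repression(A0, params.P0, params.h) else 0

    A, B, sA, sB = _kernels.ssa_toggle(
        params.alpha, params.mu, params.h, params.P0,
        noise.omega, noise.lam,
        float(T), float(sample_dt), kernel_seed,
        nA0, nB0, sA0, sB0,
    )
    n_samp = A.shape[0]
    return Trajectory(
        times=np.arange(n_samp) * sample_dt,
        channels={
            "A": A / noise.omega,
            "B": B / noise.omega,
            "sigma_A": sA,
            "sigma_B": sB,
        },
        meta={"tier": "toggle-ssa", "params": params, "seed": seed},
    )
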