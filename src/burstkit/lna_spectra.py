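"""Closed-form linear-noise results: amplitudes, spectra, stationary sigma.

Conventions, fixed package-wide: spectra are two-sided over angular
frequency omega (1/min), normalized so that the stationary variance is
Sigma^2 = (1/2pi) * integral of S(omega) d omega over the whole line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .core_models import (
    FeedbackParams,
    NoiseScales,
    hill_derivative,
    hill_repression,
    solve_fixed_point,
)

__all__ = [
    "NoiseAmplitudes",
    "SpectrumResult",
    "noise_amplitudes",
    "spectrum_analytic",
    "sigma_from_spectrum",
]


@dataclass(frozen=True)
class NoiseAmplitudes:
    """White-noise variance densities at the fixed point, cu^2/min.

    ``sigma2_M`` splits into a copy-number part (scale 1/Omega) and a
    bursting part (scale 1/lam), kept separately recoverable; ``sigma2_P``
    is pure copy-number noise.
    """

    sigma2_M_copy: float
    sigma2_M_burst: float
    sigma2_P: float

    @property
    def sigma2_M(self) -> float:
        return self.sigma2_M_copy + self.sigma2_M_burst


@dataclass
class SpectrumResult:
    """Two-sided power spectral density on an angular-frequency grid.

    Normalization tag: Sigma^2 = (1/2pi) * integral S d omega.
    """

    omega: np.ndarray
    S_M: np.ndarray
    S_P: np.ndarray
    convention: str = "two-sided, Sigma^2 = (1/2pi) int S domega"


def noise_amplitudes(params: FeedbackParams, noise: NoiseScales) -> NoiseAmplitudes:
    """Noise variance densities evaluated at the deterministic fixed point.

    sigma_M^2 = (1/Omega)(alpha_M f(P*) + mu_M M*)
              + (1/lam) 2 (P*/P0)^h / (1 + (P*/P0)^h)^3 alpha_M^2
    sigma_P^2 = (1/Omega)(alpha_P M* + mu_P P*)

    Infinite Omega or lam zero the corresponding part exactly.
    """
    fp = solve_fixed_point(params)
    copy_M = burst_M = copy_P = 0.0
    if noise.copy_number_noise:
        f = hill_repression(fp.P, params.P0, params.h)
        copy_M = (params.alpha_M * f + params.mu_M * fp.M) / noise.omega
        copy_P = (params.alpha_P * fp.M + params.mu_P * fp.P) / noise.omega
    if noise.bursting_noise and math.isfinite(params.P0):
        xh = (fp.P / params.P0) ** params.h
        burst_M = 2.0 * xh / (1.0 + xh) ** 3 * params.alpha_M**2 / noise.lam
    return NoiseAmplitudes(
        sigma2_M_copy=copy_M, sigma2_M_burst=burst_M, sigma2_P=copy_P
    )


def _spectrum_terms(params: FeedbackParams):
    fp = solve_fixed_point(params)
    fprime = hill_derivative(fp.P, params.P0, params.h)
    return fp, params.alpha_M * fprime


def _denominator(omega, params: FeedbackParams, aM_fprime: float):
    mM, mP, aP, tau = params.mu_M, params.mu_P, params.alpha_P, params.tau
    c = aP * aM_fprime  # alpha_M alpha_P f'(P*)
    re = mM * mP - c * np.cos(omega * tau) - omega**2
    im = omega * (mM + mP) + c * np.sin(omega * tau)
    return re**2 + im**2


def spectrum_analytic(
    omega_grid, params: FeedbackParams, noise: NoiseScales
) -> SpectrumResult:
    """Analytic linear-noise spectra S_M and S_P on ``omega_grid``.

    S_M = ((omega^2 + mu_P^2) sigma_M^2 + (alpha_M f'(P*))^2 sigma_P^2)/|D|^2
    S_P = (alpha_P^2 sigma_M^2 + (omega^2 + mu_M^2) sigma_P^2)/|D|^2

    Raises if |D|^2 vanishes on the grid (resonant instability).
    """
    omega = np.asarray(omega_grid, dtype=float)
    amps = noise_amplitudes(params, noise)
    _, aM_fprime = _spectrum_terms(params)
    denom = _denominator(omega, params, aM_fprime)
    if np.any(denom <= 0.0):
        bad = omega[np.argmin(denom)]
        raise FloatingPointError(
            f"|Delta(omega)|^2 vanishes near omega = {bad}; the fixed point "
            "is resonantly unstable")
    S_M = ((omega**2 + params.mu_P**2) * amps.sigma2_M
           + aM_fprime**2 * amps.sigma2_P) / denom
    S_P = (params.alpha_P**2 * amps.sigma2_M
           + (omega**2 + params.mu_M**2) * amps.sigma2_P) / denom
    return SpectrumResult(omega=omega, S_M=S_M, S_P=S_P)


def _integrate_channel(params, noise, channel: str) -> float:
    amps = noise_amplitudes(params, noise)
    _, aM_fprime = _spectrum_terms(params)
    if channel == "P":
        num_const = params.alpha_P**2 * amps.sigma2_M + params.mu_M**2 * amps.sigma2_P
        num_om2 = amps.sigma2_P
    elif channel == "M":
        num_const = params.mu_P**2 * amps.sigma2_M + aM_fprime**2 * amps.sigma2_P
        num_om2 = amps.sigma2_M
    else:
        raise ValueError(f"unknown channel {channel!r}")

    def S(w):
        return (num_const + num_om2 * w * w) / _denominator(w, params, aM_fprime)

    # the integrand oscillates through cos/sin(omega tau): integrate
    # piecewise over one delay period at a time so quad sees a smooth piece
    tau_scale = 2.0 * math.pi / params.tau if params.tau > 0 else 0.0
    omega_max = 1e3 * max(params.mu_M, params.mu_P, tau_scale)
    seg = tau_scale if tau_scale > 0 else omega_max / 200.0

    def integrate_to(w_hi, w_lo=0.0):
        total = 0.0
        err_total = 0.0
        w = w_lo
        while w < w_hi - 1e-12:
            w_next = min(w + seg, w_hi)
            val, err = quad(S, w, w_next, limit=200, epsrel=1e-11, epsabs=0.0)
            total += val
            err_total += err
            w = w_next
        return total, err_total

    half, err = integrate_to(omega_max)
    if not math.isfinite(half) or half <= 0.0:
        raise FloatingPointError("spectral integral diverged (instability)")

    def tail_at(w):
        # analytic tail of S ~ (num_const + num_om2 w^2)/w^4 past omega_max
        return num_om2 / w + num_const / (3.0 * w**3)

    # extend omega_max until swapping quadrature for the analytic tail over
    # the next octave no longer moves the result at the target accuracy
    total = half + tail_at(omega_max)
    for _ in range(40):
        extra, err2 = integrate_to(2.0 * omega_max, omega_max)
        half += extra
        err += err2
        omega_max *= 2.0
        new_total = half + tail_at(omega_max)
        converged = abs(new_total - total) <= 1e-9 * new_total
        total = new_total
        if converged:
            break
    result = 2.0 * total / (2.0 * math.pi)
    if err > 1e-8 * half:
        raise FloatingPointError("quadrature failed to reach relative 1e-8")
    return result


def sigma_from_spectrum(
    params: FeedbackParams, noise: NoiseScales, channel: str = "P"
) -> float:
    """Stationary standard deviation Sigma via spectral integration, cu.

    Sigma^2 = (1/2pi) * int S(omega) domega, computed as twice the adaptive
    quadrature on [0, omega_max] plus the analytic 1/omega^2 tail;
    ``omega_max`` is grown until the tail is below 1e-10 of the integral.
    """
    return math.sqrt(_integrate_channel(params, noise, channel))
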