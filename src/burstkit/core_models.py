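"""Parameter containers, Hill regulation functions and deterministic dynamics.

The package models a transcription factor under delayed auto-negative
feedback: a telegraph promoter (ON/OFF) whose OFF-switching rate grows with
protein concentration, transcription with a fixed delay ``tau`` between
initiation and mRNA appearance, translation, and first-order degradation of
both species.  Two global noise scales control the stochastic tiers: the
system size ``Omega`` (copy-number noise ~ Omega^-1/2) and the bursting
parameter ``lambda`` (promoter-switching noise ~ lambda^-1/2).  Setting
either scale to ``inf`` switches the corresponding noise source off, giving
the four model tiers: full discrete model, piecewise-deterministic process,
copy-number-noise-only discrete model, and the deterministic delay ODE
implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FeedbackParams",
    "NoiseScales",
    "ToggleParams",
    "Trajectory",
    "FixedPoint",
    "ToggleFixedPoint",
    "hill_repression",
    "hill_derivative",
    "solve_fixed_point",
    "toggle_fixed_points",
    "integrate_dde",
]


def _require_positive(
    name: str, value: float, allow_inf: bool = False, allow_zero: bool = False
) -> None:
    if not (value >= 0 if allow_zero else value > 0):
        raise ValueError(f"{name} must be {'non-negative' if allow_zero else 'strictly positive'}, got {value!r}")
    if not allow_inf and math.isinf(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class FeedbackParams:
    """Rate constants of the delayed auto-negative feedback motif.

    Parameters
    ----------
    alpha_M : float
        Basal transcription rate while the promoter is ON, cu/min.
    alpha_P : float
        Translation rate per mRNA, 1/min.
    mu_M, mu_P : float
        Degradation rates of mRNA and protein, 1/min.
    h : float
        Hill coefficient of the repression function (number of protein
        molecules that must bind to silence the promoter).
    P0 : float
        Repression threshold, cu; ``inf`` disables repression (f == 1).
    tau : float
        Transcriptional delay, min; 0 means no delay.
    """

    alpha_M: float
    alpha_P: float
    mu_M: float
    mu_P: float
    h: float
    P0: float
    tau: float

    def __post_init__(self) -> None:
        # production rates may be exactly zero (silenced gene); decay may not
        _require_positive("alpha_M", self.alpha_M, allow_zero=True)
        _require_positive("alpha_P", self.alpha_P, allow_zero=True)
        _require_positive("mu_M", self.mu_M)
        _require_positive("mu_P", self.mu_P)
        _require_positive("h", self.h)
        _require_positive("P0", self.P0, allow_inf=True)
        if self.tau < 0 or not math.isfinite(self.tau):
            raise ValueError(f"tau must be finite and >= 0, got {self.tau!r}")

    @property
    def copy_number_capacity(self) -> float:
        """alpha_M*alpha_P/(mu_M*mu_P): protein level with repression off."""
        return self.alpha_M * self.alpha_P / (self.mu_M * self.mu_P)


#: Reference rate set for mouse neural progenitor cells (Hes1-type
#: ultradian oscillator): mRNA half-life 30 min, protein half-life 90 min,
#: transcriptional delay 33 min.
REFERENCE_PARAMS = FeedbackParams(
    alpha_M=39.93,
    alpha_P=21.56,
    mu_M=math.log(2) / 30.0,
    mu_P=math.log(2) / 90.0,
    h=4.78,
    P0=24201.01,
    tau=33.0,
)


@dataclass(frozen=True)
class NoiseScales:
    """System size and bursting parameter.

    ``omega`` scales molecule numbers at fixed concentration (one cu is one
    molecule per reference volume ``V0`` when omega == 1).  ``lam`` is the
    common timescale of both promoter-switching directions.  Either may be
    ``inf``, which turns the corresponding noise source off exactly.
    """

    omega: float = math.inf
    lam: float = math.inf
    V0: float = 523.0  # reference nuclear volume, fL

    def __post_init__(self) -> None:
        _require_positive("omega", self.omega, allow_inf=True)
        _require_positive("lam", self.lam, allow_inf=True)
        _require_positive("V0", self.V0)

    @property
    def copy_number_noise(self) -> bool:
        return math.isfinite(self.omega)

    @property
    def bursting_noise(self) -> bool:
        return math.isfinite(self.lam)


@dataclass(frozen=True)
class ToggleParams:
    """Symmetric two-gene toggle switch with telegraph promoters.

    Each protein represses the other gene's promoter with threshold ``P0``
    and Hill coefficient ``h``; both share production rate ``alpha`` and
    degradation rate ``mu``.  No transcriptional delay and no explicit mRNA.
    """

    alpha: float
    mu: float
    h: float
    P0: float
    noise: NoiseScales = field(default_factory=NoiseScales)

    def __post_init__(self) -> None:
        _require_positive("alpha", self.alpha, allow_zero=True)
        _require_positive("mu", self.mu)
        _require_positive("h", self.h)
        _require_positive("P0", self.P0, allow_inf=True)


@dataclass
class Trajectory:
    """Uniformly sampled time series of concentrations.

    ``channels`` maps channel names (``"M"``, ``"P"``, ``"sigma"`` for the
    feedback motif; ``"A"``, ``"B"``, ``"sigma_A"``, ``"sigma_B"`` for the
    toggle) to arrays on the common ``times`` grid.  Promoter-state channels
    take values in {0, 1} only.
    """

    times: np.ndarray
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("times must be a 1-d grid with at least 2 points")
        steps = np.diff(self.times)
        if not np.all(steps > 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        for name, series in self.channels.items():
            series = np.asarray(series, dtype=float)
            self.channels[name] = series
            if series.shape != self.times.shape:
                raise ValueError(f"channel {name!r} does not match the grid")
            if not np.all(np.isfinite(series)):
                raise ValueError(f"channel {name!r} contains non-finite values")
            if name.startswith("sigma") and not np.all(np.isin(series, (0.0, 1.0))):
                raise ValueError(f"promoter channel {name!r} must be 0/1")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __getattr__(self, name: str) -> np.ndarray:
        channels = self.__dict__.get("channels", {})
        if name in channels:
            return channels[name]
        raise AttributeError(name)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(f"no channel {name!r}; have {sorted(self.channels)}")
        return self.channels[name]


@dataclass(frozen=True)
class FixedPoint:
    """Stationary concentrations (M*, P*) of the deterministic feedback loop."""

    M: float
    P: float


@dataclass(frozen=True)
class ToggleFixedPoint:
    """Stationary concentrations (A*, B*) of the deterministic toggle switch."""

    A: float
    B: float


def hill_repression(P, P0: float, h: float):
    """Repressive Hill function f(P) = 1/(1 + (P/P0)^h).

    This is the stationary probability of finding the telegraph promoter ON
    at protein concentration ``P``, and hence the mean transcription
    activity in the fast-switching limit.  Accepts scalars or arrays; values
    lie in (0, 1].  ``P0 == inf`` gives f == 1 (repression off).
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("hill_repression requires P >= 0; clamp first")
    if math.isinf(P0):
        out = np.ones_like(P)
        return float(out) if out.ndim == 0 else out
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + (P / P0) ** h)
    return float(out) if out.ndim == 0 else out


def hill_derivative(P, P0: float, h: float):
    """df/dP = -(h/P0) (P/P0)^(h-1) / (1 + (P/P0)^h)^2, always <= 0.

    Diverges at P = 0 when h < 1 (domain error); equals -1/P0 at P = 0 when
    h == 1 and 0 when h > 1.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("hill_derivative requires P >= 0")
    if np.any(P == 0) and h < 1:
        raise ValueError("hill_derivative diverges at P = 0 for h < 1")
    if math.isinf(P0):
        out = np.zeros_like(P)
        return float(out) if out.ndim == 0 else out
    x = P / P0
    with np.errstate(over="ignore", invalid="ignore"):
        num = np.where(x > 0, x ** (h - 1.0), 1.0 if h == 1.0 else 0.0)
        out = -(h / P0) * num / (1.0 + x**h) ** 2
    out = np.where(np.isfinite(out), out, 0.0)  # x^h overflow => f' -> 0
    return float(out) if out.ndim == 0 else out


def solve_fixed_point(params: FeedbackParams, tol: float = 1e-15) -> FixedPoint:
    """Unique stationary point of the deterministic feedback equations.

    P* solves P (1 + (P/P0)^h) = K with K = alpha_M alpha_P/(mu_M mu_P);
    the left side is strictly increasing from 0 so a bisection on [0, K] is
    unconditionally convergent.  M* = mu_P P*/alpha_P.
    """
    K = params.copy_number_capacity
    if math.isinf(params.P0):
        return FixedPoint(M=params.alpha_M / params.mu_M, P=K)

    def g(P: float) -> float:
        return P * (1.0 + (P / params.P0) ** params.h) - K

    lo, hi = 0.0, K
    # bisection to `tol` in the normalized variable P/K
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:  # interval at machine resolution
            break
        if g(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if (hi - lo) <= tol * K:
            break
    P_star = 0.5 * (lo + hi)
    return FixedPoint(M=params.mu_P * P_star / params.alpha_P, P=P_star)


def toggle_fixed_points(
    params: ToggleParams, n_scan: int = 4001, tol: float = 1e-12
) -> list[ToggleFixedPoint]:
    """All nonnegative fixed points of the deterministic toggle switch.

    Solves A = (alpha/mu) f(B), B = (alpha/mu) f(A) by scanning the scalar
    composition map A -> (alpha/mu) f((alpha/mu) f(A)) for sign changes on
    [0, alpha/mu] and refining each bracket by bisection.  The result is
    symmetric under swapping (A, B); points are sorted by the A coordinate.
    """
    from scipy.optimize import brentq

    c = params.alpha / params.mu

    def B_of(A: float) -> float:
        return c * hill_repression(A, params.P0, params.h)

    def residual(A: float) -> float:
        return B_of(B_of(A)) - A

    grid = np.linspace(0.0, c, n_scan)
    vals = np.array([residual(a) for a in grid])
    roots: list[float] = []
    for i in range(n_scan - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(grid[i])
        elif a * b < 0.0:
            roots.append(brentq(residual, grid[i], grid[i + 1], xtol=tol))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe near-coincident roots
    out: list[ToggleFixedPoint] = []
    for r in sorted(roots):
        if out and abs(r - out[-1].A) < 1e-8 * max(1.0, c):
            continue
        out.append(ToggleFixedPoint(A=r, B=B_of(r)))
    return out


def _as_history(history, params: FeedbackParams) -> Callable[[float], tuple]:
    if history is None:
        history = (0.0, 0.0)
    if callable(history):
        return history
    M0, P0 = float(history[0]), float(history[1])
    return lambda t: (M0, P0)


def integrate_dde(
    params: FeedbackParams,
    history=None,
    T: float = 1000.0,
    dt: float = 0.1,
) -> Trajectory:
    """Deterministic delay ODE for the feedback motif, Heun scheme.

    dM/dt = alpha_M f(P(t - tau)) - mu_M M,  dP/dt = alpha_P M - mu_P P.

    The delayed protein value is read from a ring buffer at lag
    round(tau/dt); tau is snapped to the nearest multiple of dt (warning if
    the adjustment exceeds 1e-9 min) so the zero-noise limit of the
    stochastic integrators is step-for-step comparable.  ``history`` is a
    constant (M, P) pair or a callable t -> (M, P) for t <= 0; default (0, 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.tau > 0 and dt > params.tau:
        raise ValueError("dt must not exceed the delay tau")
    lag = int(round(params.tau / dt)) if params.tau > 0 else 0
    if params.tau > 0 and abs(lag * dt - params.tau) > 1e-9:
        warnings.warn(
            f"tau snapped from {params.tau} to {lag * dt} min to align the "
            "delay buffer", stacklevel=2)

    hist = _as_history(history, params)
    n = int(round(T / dt))
    times = np.arange(n + 1) * dt
    M = np.empty(n + 1)
    P = np.empty(n + 1)
    M[0], P[0] = hist(0.0)

    def delayed_P(i: int) -> float:
        j = i - lag
        return P[j] if j >= 0 else hist(j * dt)[1]

    aM, aP, mM, mP = params.alpha_M, params.alpha_P, params.mu_M, params.mu_P
    for i in range(n):
        Pd0 = delayed_P(i)
        Pd1 = delayed_P(i + 1)
        f0 = hill_repression(Pd0, params.P0, params.h)
        dM0 = aM * f0 - mM * M[i]
        dP0 = aP * M[i] - mP * P[i]
        Mp = M[i] + dt * dM0
        Pp = P[i] + dt * dP0
        f1 = hill_repression(max(Pd1, 0.0), params.P0, params.h)
        dM1 = aM * f1 - mM * Mp
        dP1 = aP * Mp - mP * Pp
        M[i + 1] = M[i] + 0.5 * dt * (dM0 + dM1)
        P[i + 1] = P[i] + 0.5 * dt * (dP0 + dP1)

    return Trajectory(
        times=times,
        channels={"M": M, "P": P},
        meta={"tier": "dde", "params": params, "dt": dt},
    )
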