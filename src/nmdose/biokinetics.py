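"""Retention-curve fitting, TIACs and linear compartment models.

The organ curve fitter represents the normalized activity A(t)/A0 of a
source region as a sum of exponentials, optionally damped by one or two
uptake factors:

    direct   A/A0 = sum_j a_j exp(-lambda_j t)
    uptake1  A/A0 = (1 - exp(-mu1 t)) * sum_j a_j exp(-lambda_j t)
    uptake2  A/A0 = (1 - exp(-mu1 t)) (1 - exp(-mu2 t)) * sum_j ...

with 1-3 retention components.  Every model expands into a plain sum of
exponential terms, so the time-integrated activity coefficient (TIAC)

    A~/A0 = integral_0^T_D A(t)/A0 dt   [h]

has a closed form for any integration period, including T_D = infinity.
Rates are per hour; activities MBq.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import least_squares, nnls

__all__ = [
    "FitSystem",
    "ActivityCurve",
    "RetentionFit",
    "FitError",
    "fit_retention",
    "tiac_from_fit",
    "solve_compartments",
    "CLI_SYSTEM_MENU",
]


class FitError(ValueError):
    pass


class FitSystem(str, enum.Enum):
    DIRECT = "direct"
    UPTAKE1 = "uptake1"
    UPTAKE2 = "uptake2"


#: The five system x component combinations exposed in the CLI menu
#: (the library itself accepts all nine).
CLI_SYSTEM_MENU = [
    (FitSystem.DIRECT, 1),
    (FitSystem.DIRECT, 2),
    (FitSystem.DIRECT, 3),
    (FitSystem.UPTAKE1, 1),
    (FitSystem.UPTAKE2, 1),
]


@dataclass
class ActivityCurve:
    """Measured time-activity samples of one source region.

    ``decay_corrected`` records whether the samples were corrected for
    physical decay (biological rates fitted) or not (effective rates
    fitted); the flag is carried explicitly so the TIAC step knows
    whether to add the physical decay constant.
    """

    region: str
    t_h: np.ndarray
    a_mbq: np.ndarray
    a0_mbq: float
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.t_h, dtype=float)
        a = np.asarray(self.a_mbq, dtype=float)
        self.t_h, self.a_mbq = t, a
        if t.ndim != 1 or a.shape != t.shape:
            raise FitError("time and activity arrays must be 1-D and equal length")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise FitError("times must be >= 0 and strictly increasing")
        if np.any(a < 0):
            raise FitError("activities must be non-negative")
        if self.a0_mbq <= 0:
            raise FitError("administered activity must be positive")

    @property
    def fraction(self) -> np.ndarray:
        return self.a_mbq / self.a0_mbq


@dataclass
class RetentionFit:
    """A fitted retention model.

    ``amplitudes`` are fractions of A0, ``rates`` the retention rate
    constants (per hour) and ``uptake_rates`` the 0-2 uptake rate
    constants; ``sse`` is the fit objective at the optimum.
    """

    system: FitSystem
    amplitudes: np.ndarray
    rates: np.ndarray
    uptake_rates: np.ndarray = field(default_factory=lambda: np.array([]))
    sse: float = float("nan")

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        self.uptake_rates = np.atleast_1d(np.asarray(self.uptake_rates, dtype=float)) \
            if np.size(self.uptake_rates) else np.array([])
        if self.amplitudes.shape != self.rates.shape:
            raise FitError("one rate per amplitude required")
        if np.any(self.rates <= 0) or np.any(self.uptake_rates <= 0):
            raise FitError("rates must be positive")
        n_up = {FitSystem.DIRECT: 0, FitSystem.UPTAKE1: 1, FitSystem.UPTAKE2: 2}
        if self.uptake_rates.size != n_up[self.system]:
            raise FitError(
                f"{self.system.value} needs {n_up[self.system]} uptake rate(s)"
            )

    def exponential_terms(self) -> list[tuple[float, float]]:
        """Expand the model into (coefficient, rate) exponential terms."""
        terms: list[tuple[float, float]] = []
        for a, lam in zip(self.amplitudes, self.rates):
            base = [(a, lam)]
            for mu in self.uptake_rates:
                base = [(c, r) for c, r in base] + [(-c, r + mu) for c, r in base]
            terms.extend(base)
        return terms

    def evaluate(self, t_h) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        out = np.zeros_like(t)
        for c, r in self.exponential_terms():
            out += c * np.exp(-r * t)
        return out


def _model_from_params(system: FitSystem, n_ret: int, params: np.ndarray) -> RetentionFit:
    n_up = {FitSystem.DIRECT: 0, FitSystem.UPTAKE1: 1, FitSystem.UPTAKE2: 2}[system]
    amps = params[:n_ret]
    rates = np.exp(params[n_ret : 2 * n_ret])
    ups = np.exp(params[2 * n_ret : 2 * n_ret + n_up])
    return RetentionFit(system=system, amplitudes=amps, rates=rates, uptake_rates=ups)


def _amplitudes_given_rates(
    system: FitSystem, rates: np.ndarray, ups: np.ndarray, t: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Non-negative linear LS amplitudes at fixed rates (variable projection)."""
    damp = np.ones_like(t)
    for mu in ups:
        damp = damp * (1.0 - np.exp(-mu * t))
    basis = np.stack([damp * np.exp(-lam * t) for lam in rates], axis=1)
    try:
        amps, _ = nnls(basis, y)
    except Exception:
        amps = np.full(rates.size, max(y.max(), 1e-6) / rates.size)
    return np.maximum(amps, 1e-12)


def fit_retention(
    curve: ActivityCurve,
    system: FitSystem | str,
    n_retention: int,
    relative_weighting: bool = False,
    n_rate_starts: int = 5,
    seed: int = 0,
) -> RetentionFit:
    """Nonlinear least-squares retention fit of one activity curve.

    Multistart over rate initials log-spaced between 1/(10*t_max) and
    10/t_min, with amplitudes initialized by non-negative linear least
    squares at each rate guess; the best-SSE solution is returned.
    With ``relative_weighting`` residuals are divided by the data
    (log-residual-like objective); default is unweighted SSE on the
    normalized activities.
    """
    system = FitSystem(system)
    if not 1 <= n_retention <= 3:
        raise FitError("n_retention must be 1, 2 or 3")
    n_up = {FitSystem.DIRECT: 0, FitSystem.UPTAKE1: 1, FitSystem.UPTAKE2: 2}[system]
    n_free = 2 * n_retention + n_up
    t = curve.t_h
    y = curve.fraction
    mask = t > 0 if system is not FitSystem.DIRECT else np.ones_like(t, bool)
    if np.count_nonzero(mask) < n_free:
        raise FitError(
            f"need at least {n_free} usable samples for {system.value} "
            f"x {n_retention}, got {int(np.count_nonzero(mask))}"
        )
    t_fit, y_fit = t[mask], y[mask]
    t_min = t_fit[t_fit > 0].min() if np.any(t_fit > 0) else 1.0
    t_max = t_fit.max()
    rate_grid = np.geomspace(1.0 / (10.0 * t_max), 10.0 / t_min, n_rate_starts)

    scale = np.where(y_fit > 0, y_fit, max(y_fit.max(), 1e-12)) if relative_weighting else 1.0

    def residuals(params: np.ndarray) -> np.ndarray:
        fit = _model_from_params(system, n_retention, params)
        return (fit.evaluate(t_fit) - y_fit) / scale

    best: RetentionFit | None = None
    best_cost = math.inf
    rate_combos = list(itertools.combinations(rate_grid, n_retention))
    up_starts = [np.array([])] if n_up == 0 else [
        np.full(n_up, g) for g in np.geomspace(1.0 / t_max, 10.0 / t_min, 3)
    ]
    for rates0 in rate_combos:
        rates0 = np.asarray(rates0)
        for ups0 in up_starts:
            amps0 = _amplitudes_given_rates(system, rates0, ups0, t_fit, y_fit)
            x0 = np.concatenate([amps0, np.log(rates0), np.log(ups0) if n_up else []])
            lb = np.concatenate([np.zeros(n_retention), np.full(n_retention + n_up, -50.0)])
            ub = np.concatenate([np.full(n_retention, 10.0), np.full(n_retention + n_up, 50.0)])
            try:
                sol = least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
            except Exception:
                continue
            if sol.cost < best_cost:
                best_cost = sol.cost
                best = _model_from_params(system, n_retention, sol.x)
                best.sse = float(np.sum((best.evaluate(t_fit) - y_fit) ** 2))
    if best is None:
        raise FitError(
            f"no start converged for {system.value} x {n_retention}; "
            f"rate grid {rate_grid}"
        )
    return best


def tiac_from_fit(
    fit: RetentionFit, lambda_phys_per_h: float = 0.0, t_d_h: float = math.inf
) -> float:
    """Time-integrated activity coefficient of a fitted curve (hours).

    Analytic integral of the exponential expansion; ``lambda_phys_per_h``
    is added to every rate (pass the physical decay constant when the
    curve was decay-corrected, 0 when the rates are already effective).
    """
    if lambda_phys_per_h < 0:
        raise FitError("physical decay constant must be >= 0")
    if t_d_h < 0:
        raise FitError("integration period must be >= 0")
    total = 0.0
    for c, r in fit.exponential_terms():
        k = r + lambda_phys_per_h
        if k == 0.0:
            if math.isinf(t_d_h):
                if c != 0.0:
                    raise FitError("divergent TIAC: zero total rate with T_D = inf")
                continue
            total += c * t_d_h
        elif math.isinf(t_d_h):
            total += c / k
        else:
            total += c * (1.0 - math.exp(-k * t_d_h)) / k
    return total


def solve_compartments(
    transfer_per_h: np.ndarray,
    initial_mbq: np.ndarray,
    times_h,
    lambda_phys_per_h: float = 0.0,
) -> np.ndarray:
    """Activities of a first-order linear compartment system.

    ``transfer_per_h`` is the rate matrix M with non-negative
    off-diagonal transfer rates (column j's diagonal holds minus its
    total outflow), solved as A(t) = exp((M - lambda_phys I) t) A(0).

    Returns shape (n_compartments, n_times), MBq.
    """
    m = np.asarray(transfer_per_h, dtype=float)
    a0 = np.asarray(initial_mbq, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise FitError("transfer matrix must be square")
    off = m.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise FitError("off-diagonal transfer rates must be non-negative")
    times = np.atleast_1d(np.asarray(times_h, dtype=float))
    gen = m - lambda_phys_per_h * np.eye(m.shape[0])
    out = np.empty((m.shape[0], times.size))
    for j, t in enumerate(times):
        out[:, j] = expm(gen * t) @ a0
    return out
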