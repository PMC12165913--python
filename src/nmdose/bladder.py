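"""Dynamic urinary bladder: content activity, voiding and wall dose.

Urine (and with it activity cleared through the kidneys) accumulates in
the bladder between voids; the content->wall S-value shrinks as the
content volume grows, so the wall dose depends on the full time course
rather than only on the cumulated activity.  Between voids

    dV/dt   = urine flow (+ hydration flow inside its window)
    dA_c/dt = inflow(t) - lambda_phys * A_c

and at each void the volume drops to the residual volume while the
activity is removed in proportion to the removed volume (well-mixed
urine).  The wall dose integrates A_c(t) * S(V(t)) over time; the
content TIAC (for irradiating other organs through the static SAFs) is
the plain time integral of A_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad, solve_ivp

from .dose import TIAC_S_TO_MGY_PER_MBQ

__all__ = [
    "BladderParams",
    "WallSvalueCurve",
    "BladderSolution",
    "BladderError",
    "bladder_content",
    "wall_dose_dynamic",
    "content_tiac",
]


class BladderError(ValueError):
    pass


@dataclass(frozen=True)
class BladderParams:
    """Biological bladder parameters.

    urine_flow_ml_h : baseline urine production (mL/h)
    voiding_interval_h : time between voids (default 3.5 h, the usual
        static-model assumption); first void at t = interval
    residual_volume_ml : urine left in the bladder after a void
    initial_volume_ml : content volume at administration
    hydration_flow_ml_h / hydration_window_h : optional extra flow over
        a (start, stop) window, modelling drinking to speed up voiding
    """

    urine_flow_ml_h: float
    voiding_interval_h: float = 3.5
    residual_volume_ml: float = 0.0
    initial_volume_ml: float = 0.0
    hydration_flow_ml_h: float = 0.0
    hydration_window_h: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.urine_flow_ml_h <= 0:
            raise BladderError("urine flow must be positive")
        if self.voiding_interval_h <= 0:
            raise BladderError("voiding interval must be positive")
        if self.residual_volume_ml < 0 or self.initial_volume_ml < 0:
            raise BladderError("volumes must be non-negative")
        if self.hydration_flow_ml_h < 0:
            raise BladderError("hydration flow must be non-negative")
        w0, w1 = self.hydration_window_h
        if w1 < w0:
            raise BladderError("hydration window must be (start, stop) with stop >= start")

    def flow_at(self, t_h: float) -> float:
        f = self.urine_flow_ml_h
        w0, w1 = self.hydration_window_h
        if self.hydration_flow_ml_h > 0 and w0 <= t_h < w1:
            f += self.hydration_flow_ml_h
        return f

    def flow_integral(self, t0: float, t1: float) -> float:
        """Urine volume produced over [t0, t1] (mL)."""
        vol = self.urine_flow_ml_h * (t1 - t0)
        w0, w1 = self.hydration_window_h
        overlap = max(0.0, min(t1, w1) - max(t0, w0))
        return vol + self.hydration_flow_ml_h * overlap


@dataclass(frozen=True)
class WallSvalueCurve:
    """Content->wall S-value versus content volume for one phantom."""

    phantom_id: str
    volume_ml: np.ndarray
    s_gy_per_nt: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volume_ml, dtype=float)
        s = np.asarray(self.s_gy_per_nt, dtype=float)
        object.__setattr__(self, "volume_ml", v)
        object.__setattr__(self, "s_gy_per_nt", s)
        if v.ndim != 1 or v.size < 1 or np.any(np.diff(v) <= 0):
            raise BladderError("volume grid must be 1-D and strictly increasing")
        if s.shape != v.shape or np.any(s <= 0):
            raise BladderError("S(V) must be positive on the volume grid")
        if v.size > 1 and np.any(np.diff(s) > 0):
            import logging

            logging.getLogger(__name__).warning(
                "%s: content->wall S-value is not decreasing in volume",
                self.phantom_id,
            )

    def s_at(self, volume_ml: float) -> float:
        """Log-log interpolation in volume, clamped outside the grid."""
        v, s = self.volume_ml, self.s_gy_per_nt
        if volume_ml <= v[0]:
            return float(s[0])
        if volume_ml >= v[-1]:
            return float(s[-1])
        return float(
            np.exp(np.interp(np.log(volume_ml), np.log(v), np.log(s)))
        )


@dataclass
class _Segment:
    t0: float
    t1: float
    v0: float
    a_interp: Callable[[float], float]


@dataclass
class BladderSolution:
    """Piecewise content activity and volume with the void schedule."""

    params: BladderParams
    lambda_phys_per_h: float
    horizon_h: float
    void_times: list[float]
    segments: list[_Segment]
    voided_activity_mbq_h: float  # sum of activity removed at voids (MBq)
    inflow: Callable[[float], float] = field(repr=False, default=None)

    def _segment(self, t: float) -> _Segment:
        for seg in self.segments:
            if seg.t0 <= t <= seg.t1:
                return seg
        raise BladderError(f"time {t} outside solved horizon {self.horizon_h}")

    def activity(self, t_h: float) -> float:
        """Content activity at time t (MBq per administered MBq)."""
        seg = self._segment(t_h)
        return float(seg.a_interp(t_h))

    def volume(self, t_h: float) -> float:
        """Content volume at time t (mL)."""
        seg = self._segment(t_h)
        return seg.v0 + self.params.flow_integral(seg.t0, t_h)


def bladder_content(
    in_rate_mbq_h: Callable[[float], float],
    params: BladderParams,
    lambda_phys_per_h: float,
    horizon_h: float,
    initial_activity_mbq: float = 0.0,
    void_times: list[float] | None = None,
    rtol: float = 1e-10,
) -> BladderSolution:
    """Solve the content activity and volume over [0, horizon].

    ``in_rate_mbq_h`` is the activity inflow to the bladder (MBq/h per
    administered MBq, i.e. the excretion rate of the biokinetic model);
    physical decay acts on the content.  Voids occur at multiples of the
    voiding interval (or at the explicit ``void_times``); at each void
    the volume drops to the residual and the activity is scaled by
    residual/V (well-mixed urine).
    """
    if horizon_h <= 0:
        raise BladderError("horizon must be positive")
    if lambda_phys_per_h < 0:
        raise BladderError("decay constant must be >= 0")
    if void_times is None:
        k = 1
        void_times = []
        while k * params.voiding_interval_h < horizon_h:
            void_times.append(k * params.voiding_interval_h)
            k += 1
    else:
        void_times = sorted(t for t in void_times if 0.0 < t < horizon_h)

    bounds = [0.0, *void_times, horizon_h]
    segments: list[_Segment] = []
    a = float(initial_activity_mbq)
    v = params.initial_volume_ml
    voided = 0.0
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 > t0:
            w0, w1 = params.hydration_window_h
            interior = [x for x in (w0, w1) if t0 < x < t1]
            sol = solve_ivp(
                lambda t, y: [in_rate_mbq_h(t) - lambda_phys_per_h * y[0]],
                (t0, t1),
                [a],
                dense_output=True,
                rtol=rtol,
                atol=1e-16,
                max_step=max((t1 - t0) / 4.0, 1e-3),
                t_eval=None,
                method="DOP853",
            )
            if not sol.success:
                raise BladderError(f"content ODE failed on [{t0}, {t1}]: {sol.message}")
            interp = sol.sol
            segments.append(_Segment(t0, t1, v, lambda t, f=interp: float(f(t)[0])))
            a = float(interp(t1)[0])
            v = v + params.flow_integral(t0, t1)
        if t1 in void_times:
            v_pre = v
            v = params.residual_volume_ml
            keep = 0.0 if v_pre <= 0 else min(1.0, params.residual_volume_ml / v_pre)
            voided += a * (1.0 - keep)
            a *= keep
    return BladderSolution(
        params=params,
        lambda_phys_per_h=lambda_phys_per_h,
        horizon_h=horizon_h,
        void_times=list(void_times),
        segments=segments,
        voided_activity_mbq_h=voided,
        inflow=in_rate_mbq_h,
    )


def _integrate_segments(sol: BladderSolution, f, horizon_h: float) -> float:
    total = 0.0
    for seg in sol.segments:
        t1 = min(seg.t1, horizon_h)
        if t1 <= seg.t0:
            break
        w0, w1 = sol.params.hydration_window_h
        pts = [x for x in (w0, w1) if seg.t0 < x < t1] or None
        val, _ = quad(f, seg.t0, t1, points=pts, limit=200, epsabs=1e-13, epsrel=1e-10)
        total += val
    return total


def wall_dose_dynamic(
    sol: BladderSolution, curve: WallSvalueCurve, horizon_h: float | None = None
) -> float:
    """Absorbed dose to the bladder wall (mGy per administered MBq).

    D = integral A_c(t) * S(V(t)) dt with the volume-dependent
    content->wall S-value, honoring void discontinuities (integration is
    per inter-void segment).
    """
    horizon = sol.horizon_h if horizon_h is None else horizon_h
    if horizon <= 0:
        raise BladderError("horizon must be positive")
    integral = _integrate_segments(
        sol, lambda t: sol.activity(t) * curve.s_at(sol.volume(t)), horizon
    )
    return integral * TIAC_S_TO_MGY_PER_MBQ


def content_tiac(sol: BladderSolution, horizon_h: float | None = None) -> float:
    """TIAC of the bladder content (hours per administered MBq), used
    with the static SAFs for every target other than the wall."""
    horizon = sol.horizon_h if horizon_h is None else horizon_h
    if horizon == 0:
        return 0.0
    if horizon < 0:
        raise BladderError("horizon must be >= 0")
    return _integrate_segments(sol, sol.activity, horizon)
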