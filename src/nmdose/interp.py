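"""Interpolation of organ doses to an arbitrary age or body weight.

Organ absorbed doses computed on the fixed reference phantoms (newborn,
1, 5, 10, 15 y, adult = 20 y; optionally the derived 100-day infant) are
interpolated piecewise-linearly in age, or in reference total body
weight (3.5-73 kg male, 3.5-64 kg female).  The effective dose at the
interpolated age/weight is NOT interpolated directly: it is recomputed
from the interpolated organ doses through the weighting scheme, so it
stays internally consistent with them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose import DoseResult, WeightingConfig, effective_dose

__all__ = [
    "PhantomNode",
    "InterpError",
    "interp_by_age",
    "interp_by_weight",
    "interpolated_effective_dose",
    "AGE_RANGE_Y",
    "WEIGHT_RANGE_KG",
]

AGE_RANGE_Y = (0.0, 20.0)
#: Reference weight ranges per sex (kg): newborn 3.5 kg up to the adult
#: reference weight.
WEIGHT_RANGE_KG = {"male": (3.5, 73.0), "female": (3.5, 64.0)}


class InterpError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomNode:
    """One fixed phantom with its reference age, weight and dose result."""

    age_y: float
    weight_kg: float
    result: DoseResult

    @property
    def sex(self) -> str:
        return self.result.sex


def _check_nodes(nodes: list[PhantomNode], key) -> list[PhantomNode]:
    if len(nodes) < 2:
        raise InterpError("need at least two phantom nodes")
    nodes = sorted(nodes, key=key)
    xs = [key(n) for n in nodes]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise InterpError("phantom nodes must be strictly ordered on the abscissa")
    sexes = {n.sex for n in nodes}
    if len(sexes) > 1:
        raise InterpError(f"nodes mix sexes: {sexes}")
    return nodes


def _interp_result(
    nodes: list[PhantomNode], xs: np.ndarray, x: float, log_scale: bool
) -> DoseResult:
    i = int(np.searchsorted(xs, x, side="right") - 1)
    i = min(max(i, 0), len(nodes) - 2)
    x0, x1 = xs[i], xs[i + 1]
    lo, hi = nodes[i].result, nodes[i + 1].result
    f = (x - x0) / (x1 - x0)

    def mix(a: float, b: float) -> float:
        if log_scale and a > 0 and b > 0:
            return math.exp((1 - f) * math.log(a) + f * math.log(b))
        return (1 - f) * a + f * b

    targets = set(lo.doses) & set(hi.doses)
    doses = {t: mix(lo.doses[t], hi.doses[t]) for t in targets}
    by_type = {}
    for rtype in set(lo.by_type) & set(hi.by_type):
        by_type[rtype] = {
            t: mix(lo.by_type[rtype].get(t, 0.0), hi.by_type[rtype].get(t, 0.0))
            for t in targets
        }
    return DoseResult(
        phantom_id=f"interp({lo.phantom_id},{hi.phantom_id})",
        sex=lo.sex,
        doses=doses,
        by_type=by_type,
    )


def interp_by_age(
    nodes: list[PhantomNode], age_y: float, log_scale: bool = False
) -> DoseResult:
    """Per-organ dose at an arbitrary age in [0, 20] years.

    Piecewise linear between the bracketing phantom nodes (exact at the
    nodes, no extrapolation); ``log_scale`` interpolates log-dose
    instead, useful when paediatric doses span decades.
    """
    nodes = _check_nodes(nodes, key=lambda n: n.age_y)
    xs = np.array([n.age_y for n in nodes])
    if not xs[0] <= age_y <= xs[-1]:
        raise InterpError(f"age {age_y} y outside node range [{xs[0]}, {xs[-1]}]")
    exact = np.nonzero(xs == age_y)[0]
    if exact.size:
        return nodes[int(exact[0])].result
    return _interp_result(nodes, xs, age_y, log_scale)


def interp_by_weight(
    nodes: list[PhantomNode], weight_kg: float, sex: str, log_scale: bool = False
) -> DoseResult:
    """Per-organ dose at an arbitrary reference body weight.

    Abscissa is the reference total body weight of each phantom; the
    valid range is sex specific (3.5-73 kg male, 3.5-64 kg female)."""
    lo, hi = WEIGHT_RANGE_KG[sex]
    if not lo <= weight_kg <= hi:
        raise InterpError(
            f"weight {weight_kg} kg outside the {sex} range [{lo}, {hi}] kg"
        )
    nodes = _check_nodes(nodes, key=lambda n: n.weight_kg)
    xs = np.array([n.weight_kg for n in nodes])
    if not xs[0] <= weight_kg <= xs[-1]:
        raise InterpError(
            f"weight {weight_kg} kg outside node range [{xs[0]}, {xs[-1]}]"
        )
    exact = np.nonzero(xs == weight_kg)[0]
    if exact.size:
        return nodes[int(exact[0])].result
    return _interp_result(nodes, xs, weight_kg, log_scale)


def interpolated_effective_dose(
    male_nodes: list[PhantomNode],
    female_nodes: list[PhantomNode],
    cfg: WeightingConfig,
    age_y: float | None = None,
    weight_kg: float | None = None,
    log_scale: bool = False,
) -> float:
    """Effective dose at an arbitrary age or weight (mSv/MBq), recomputed
    from the interpolated per-organ doses of both sexes."""
    if (age_y is None) == (weight_kg is None):
        raise InterpError("give exactly one of age_y or weight_kg")
    if age_y is not None:
        m = interp_by_age(male_nodes, age_y, log_scale)
        f = interp_by_age(female_nodes, age_y, log_scale)
    else:
        m = interp_by_weight(male_nodes, weight_kg, "male", log_scale)
        f = interp_by_weight(female_nodes, weight_kg, "female", log_scale)
    return effective_dose(m, f, cfg)
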