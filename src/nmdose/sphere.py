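"""Absorbed dose to spheres of tissue with progeny in-growth.

For therapy-style lesion dosimetry the absorbed dose is computed for
homogeneous spheres (volumes 0.01-3000 cm^3, up to 21 tissue materials)
from tabulated absorbed fractions AF(E, V) per radiation type.  The
sphere S-value is the usual per-transformation sum with
Phi = AF / mass; the photon, electron(+beta) and alpha contributions are
kept separate.  Decay-chain progeny assumed produced and retained in
place contribute through their Bateman in-growth from the parent's
retention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decay import DecayChain, EmissionKind, Nuclide
from .dose import MEV_TO_J, TIAC_S_TO_MGY_PER_MBQ

__all__ = [
    "SphereAFTable",
    "SphereError",
    "VOLUME_RANGE_CM3",
    "sphere_s",
    "sphere_dose_with_progeny",
]

VOLUME_RANGE_CM3 = (0.01, 3000.0)


class SphereError(ValueError):
    pass


@dataclass
class SphereAFTable:
    """Absorbed fractions AF(E, V) of one spherical tissue material.

    ``af`` maps radiation type -> array of shape (n_volumes, n_energies)
    with values in [0, 1]; AF should be non-decreasing in volume at
    fixed energy (larger spheres absorb more) — violations only warn.
    """

    tissue_id: int
    density_g_cm3: float
    volumes_cm3: dict[str, np.ndarray] = field(default_factory=dict)
    energies_mev: dict[str, np.ndarray] = field(default_factory=dict)
    af: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise SphereError("density must be positive")

    def set_af(self, rtype: str, volumes_cm3, energies_mev, af) -> None:
        v = np.asarray(volumes_cm3, dtype=float)
        e = np.asarray(energies_mev, dtype=float)
        a = np.asarray(af, dtype=float)
        if np.any(np.diff(v) <= 0) or np.any(np.diff(e) <= 0):
            raise SphereError("volume and energy grids must be strictly increasing")
        if a.shape != (v.size, e.size):
            raise SphereError("AF array must be (n_volumes, n_energies)")
        if np.any(a < 0) or np.any(a > 1):
            raise SphereError("absorbed fractions must lie in [0, 1]")
        if np.any(np.diff(a, axis=0) < -1e-12):
            import logging

            logging.getLogger(__name__).warning(
                "tissue %s (%s): AF not non-decreasing in volume", self.tissue_id, rtype
            )
        self.volumes_cm3[rtype] = v
        self.energies_mev[rtype] = e
        self.af[rtype] = a

    def af_at(self, rtype: str, volume_cm3: float, e_mev: float) -> float:
        """Bilinear log-log interpolation in (V, E), clamped at the grid
        edges; exact on grid nodes."""
        if rtype not in self.af:
            raise SphereError(f"no AF table for radiation type {rtype!r}")
        v, e, a = self.volumes_cm3[rtype], self.energies_mev[rtype], self.af[rtype]

        def frac(x: float, xs: np.ndarray) -> tuple[int, float]:
            if x <= xs[0]:
                return 0, 0.0
            if x >= xs[-1]:
                return xs.size - 2, 1.0
            i = int(np.searchsorted(xs, x, side="right") - 1)
            i = min(i, xs.size - 2)
            return i, (math.log(x) - math.log(xs[i])) / (
                math.log(xs[i + 1]) - math.log(xs[i])
            )

        if v.size == 1 and e.size == 1:
            return float(a[0, 0])
        if v.size == 1:
            j, fe = frac(e_mev, e)
            return float((1 - fe) * a[0, j] + fe * a[0, j + 1])
        if e.size == 1:
            i, fv = frac(volume_cm3, v)
            return float((1 - fv) * a[i, 0] + fv * a[i + 1, 0])
        i, fv = frac(volume_cm3, v)
        j, fe = frac(e_mev, e)
        return float(
            (1 - fv) * (1 - fe) * a[i, j]
            + (1 - fv) * fe * a[i, j + 1]
            + fv * (1 - fe) * a[i + 1, j]
            + fv * fe * a[i + 1, j + 1]
        )


_KIND_TO_RTYPE = {
    EmissionKind.PHOTON: "photon",
    EmissionKind.ELECTRON: "electron",
    EmissionKind.ALPHA: "alpha",
}


def sphere_s(
    nuclide: Nuclide, table: SphereAFTable, volume_cm3: float
) -> tuple[float, dict[str, float]]:
    """Sphere S-value (Gy/nt) with the photon/electron/alpha/beta split.

    Phi = AF(E, V) / mass with mass = density * volume; the beta
    spectrum is integrated over the electron AF grid.
    """
    lo, hi = VOLUME_RANGE_CM3
    if not lo <= volume_cm3 <= hi:
        raise SphereError(f"volume {volume_cm3} cm^3 outside [{lo}, {hi}]")
    mass_kg = table.density_g_cm3 * volume_cm3 * 1e-3
    comps = {"photon": 0.0, "electron": 0.0, "alpha": 0.0, "beta": 0.0}
    for em in nuclide.emissions:
        rtype = _KIND_TO_RTYPE[em.kind]
        af = table.af_at(rtype, volume_cm3, em.energy_mev)
        comps[rtype] += em.energy_mev * em.yield_per_nt * af / mass_kg * MEV_TO_J
    if nuclide.beta is not None:
        e = nuclide.beta.energy_mev
        af = np.array([table.af_at("electron", volume_cm3, x) for x in e])
        comps["beta"] = (
            float(np.trapezoid(e * nuclide.beta.density * af, e)) / mass_kg * MEV_TO_J
        )
    return sum(comps.values()), comps


def sphere_dose_with_progeny(
    chain: DecayChain,
    table: SphereAFTable,
    volume_cm3: float,
    tiac_parent_h: float,
) -> dict[str, float]:
    """Absorbed dose to the sphere per chain member (mGy/MBq administered).

    The parent's retention in the sphere is taken as the mono-exponential
    with the same TIAC (effective clearance rate 1/TIAC per hour, which
    folds biological washout and physical decay together).  Progeny are
    assumed produced in place with no washout, so over an infinite
    integration period every progeny atom produced also decays in the
    sphere and the Bateman in-growth integral collapses to

        TIAC_child = (product of branch fractions) * TIAC_parent

    for radioactive members; a stable member contributes no dose.
    """
    if tiac_parent_h < 0:
        raise SphereError("parent TIAC must be >= 0")
    doses: dict[str, float] = {}
    branch_product = 1.0
    for i, member in enumerate(chain.members):
        if i > 0:
            branch_product *= chain.branch_fractions[i - 1]
        if member.stable:
            doses[member.id] = 0.0
            continue
        tiac = tiac_parent_h * branch_product
        s, _ = sphere_s(member, table, volume_cm3)
        doses[member.id] = tiac * s * TIAC_S_TO_MGY_PER_MBQ
    return doses
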