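"""Reference phantoms, region masses, blood fractions and SAF tables.

A specific absorbed fraction (SAF) Phi(r_T <- r_S, E) is the fraction of
the energy emitted in source region r_S at energy E that is absorbed per
unit mass of target region r_T (kg^-1), tabulated on an energy grid per
radiation type.  This module stores those tables, interpolates them in
energy, composes the model-specific source region "Other" as the
mass-weighted mean of the soft-tissue sources a biokinetic model leaves
unclaimed, folds circulating-blood sub-regions into Other when a model
does not carry Blood explicitly, and derives the 100-day infant
S-coefficient from the newborn and 1-year phantoms.

SAF fixture dialect (CSV, long format):

    saf.csv     phantom, rtype, target, source, E_MeV, phi_per_kg
    masses.csv  phantom, region, mass_kg
    blood.csv   phantom, region, blood_fraction
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Sex",
    "AgeClass",
    "Phantom",
    "SAFTable",
    "PhantomError",
    "INFANT_FRACTION_100D",
    "normalize_region",
    "saf_at_energy",
    "compose_other_saf",
    "apply_blood_rule",
    "infant_s",
    "read_saf_fixture",
    "write_saf_fixture",
]


class PhantomError(ValueError):
    """Raised for invalid phantom or SAF data and lookups."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class AgeClass(str, enum.Enum):
    NEWBORN = "newborn_0d"
    Y1 = "1y"
    Y5 = "5y"
    Y10 = "10y"
    Y15 = "15y"
    ADULT = "adult"


#: Reference ages (years) attached to each phantom age class; adult = 20 y.
REFERENCE_AGE_Y = {
    AgeClass.NEWBORN: 0.0,
    AgeClass.Y1: 1.0,
    AgeClass.Y5: 5.0,
    AgeClass.Y10: 10.0,
    AgeClass.Y15: 15.0,
    AgeClass.ADULT: 20.0,
}

#: Weight of the 1-year term in the 100-day infant S-coefficient
#: interpolation between the newborn and 1-year phantoms.
INFANT_FRACTION_100D = 0.6528

# Canonical region vocabulary: aliases seen in common input map onto one
# spelling.  Unknown names pass through unchanged unless strict=True —
# fixture phantoms use free-form region names.
_ALIASES = {
    "urinary bladder wall": "UB-wall",
    "bladder wall": "UB-wall",
    "urinary bladder content": "UB-content",
    "bladder content": "UB-content",
    "red bone marrow": "R-marrow",
    "red (active) bone marrow": "R-marrow",
    "active marrow": "R-marrow",
    "bone surface": "Endosteum",
    "endosteum (bone surface)": "Endosteum",
    "remainder": "Other",
    "total-body": "Total body",
    "whole body": "Total body",
}


def normalize_region(name: str, strict: bool = False, known: set[str] | None = None) -> str:
    """Map a region name onto the canonical vocabulary spelling.

    Unknown names are returned unchanged; with ``strict=True`` and a
    ``known`` set, an unknown name raises listing the available regions.
    """
    canonical = _ALIASES.get(name.strip().lower(), name.strip())
    if strict and known is not None and canonical not in known:
        raise PhantomError(
            f"unknown region {name!r}; known regions: {', '.join(sorted(known))}"
        )
    return canonical


@dataclass
class Phantom:
    """One reference individual: sex, age class, and per-region masses.

    ``blood_fractions`` give the share of total blood volume residing in
    each region; ``other_constituents`` lists the soft-tissue source
    regions eligible to enter the composite source "Other" (organ
    contents and air are not eligible — only tissues in exchange with
    the circulating blood).
    """

    sex: Sex
    age_class: AgeClass
    total_mass_kg: float
    region_masses: dict[str, float]
    blood_fractions: dict[str, float] = field(default_factory=dict)
    other_constituents: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_mass_kg <= 0:
            raise PhantomError("total mass must be positive")
        for r, m in self.region_masses.items():
            if m <= 0:
                raise PhantomError(f"region {r!r}: mass must be positive, got {m}")
        total_bf = 0.0
        for r, f in self.blood_fractions.items():
            if f < 0:
                raise PhantomError(f"region {r!r}: negative blood fraction {f}")
            total_bf += f
        if total_bf > 1.0 + 1e-9:
            raise PhantomError(f"blood fractions sum to {total_bf} > 1")

    @property
    def id(self) -> str:
        return f"{self.age_class.value}_{self.sex.value}"

    def mass(self, region: str) -> float:
        try:
            return self.region_masses[region]
        except KeyError:
            raise PhantomError(
                f"no mass for region {region!r} in phantom {self.id}"
            ) from None


class SAFTable:
    """SAF values Phi(r_T <- r_S, E) for one phantom.

    Per radiation type the table holds one increasing energy grid (MeV)
    and, per (target, source) pair, the Phi values (kg^-1) on that grid.
    """

    def __init__(self, phantom_id: str):
        self.phantom_id = phantom_id
        self.energy_grids: dict[str, np.ndarray] = {}
        self._phi: dict[tuple[str, str, str], np.ndarray] = {}

    def set_grid(self, rtype: str, energies_mev) -> None:
        e = np.asarray(energies_mev, dtype=float)
        if e.ndim != 1 or e.size < 1 or np.any(np.diff(e) <= 0):
            raise PhantomError("energy grid must be 1-D and strictly increasing")
        self.energy_grids[rtype] = e

    def set_phi(self, rtype: str, target: str, source: str, values) -> None:
        if rtype not in self.energy_grids:
            raise PhantomError(f"no energy grid registered for rtype {rtype!r}")
        v = np.asarray(values, dtype=float)
        if v.shape != self.energy_grids[rtype].shape:
            raise PhantomError("Phi values must match the energy grid length")
        if np.any(v < 0):
            raise PhantomError("Phi must be non-negative")
        self._phi[(rtype, target, source)] = v

    def phi(self, rtype: str, target: str, source: str) -> np.ndarray:
        try:
            return self._phi[(rtype, target, source)]
        except KeyError:
            avail = sorted({s for (rt, _t, s) in self._phi if rt == rtype})
            raise PhantomError(
                f"no SAF for ({target!r} <- {source!r}) rtype {rtype!r}; "
                f"available sources: {', '.join(avail) or 'none'}"
            ) from None

    def has_pair(self, rtype: str, target: str, source: str) -> bool:
        return (rtype, target, source) in self._phi

    def rtypes(self) -> list[str]:
        return sorted(self.energy_grids)

    def targets(self, rtype: str) -> list[str]:
        return sorted({t for (rt, t, _s) in self._phi if rt == rtype})

    def sources(self, rtype: str) -> list[str]:
        return sorted({s for (rt, _t, s) in self._phi if rt == rtype})

    def validate_energy_balance(self, masses: dict[str, float], rtol: float = 1e-6) -> None:
        """Check sum_T m_T * Phi(T<-S, E) <= 1 for every source/energy."""
        for rtype in self.rtypes():
            for source in self.sources(rtype):
                total = np.zeros_like(self.energy_grids[rtype])
                for target in self.targets(rtype):
                    if self.has_pair(rtype, target, source):
                        total += masses[target] * self.phi(rtype, target, source)
                if np.any(total > 1.0 + rtol):
                    raise PhantomError(
                        f"absorbed fraction exceeds emitted energy for source "
                        f"{source!r} ({rtype}): max {total.max():.6g}"
                    )


# ---------------------------------------------------------------------------
# Energy interpolation
# ---------------------------------------------------------------------------

def _loglog_interp(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Log-log linear interpolation with end clamping; exact at nodes.

    Segments with a zero endpoint fall back to linear interpolation in
    log-x (a zero has no logarithm; linear keeps the value finite and
    the node identity exact)."""
    if x <= xs[0]:
        return float(ys[0])
    if x >= xs[-1]:
        return float(ys[-1])
    i = int(np.searchsorted(xs, x, side="right") - 1)
    if xs[i] == x:
        return float(ys[i])
    x0, x1 = xs[i], xs[i + 1]
    y0, y1 = ys[i], ys[i + 1]
    f = (math.log(x) - math.log(x0)) / (math.log(x1) - math.log(x0))
    if y0 > 0 and y1 > 0:
        return float(math.exp((1 - f) * math.log(y0) + f * math.log(y1)))
    return float((1 - f) * y0 + f * y1)


def saf_at_energy(table: SAFTable, target: str, source: str, rtype: str, e_mev: float) -> float:
    """Phi(r_T <- r_S, E) at an arbitrary energy (kg^-1).

    Log-log linear interpolation on the stored grid; at a grid node the
    stored value is returned exactly; outside the grid the end value is
    used (clamping avoids unphysical extrapolation).
    """
    if e_mev <= 0:
        raise PhantomError(f"energy must be positive, got {e_mev}")
    grid = table.energy_grids.get(rtype)
    if grid is None:
        raise PhantomError(f"no SAF grid for radiation type {rtype!r}")
    return _loglog_interp(e_mev, grid, table.phi(rtype, target, source))


# ---------------------------------------------------------------------------
# Composite source "Other" and the blood rule
# ---------------------------------------------------------------------------

def compose_other_saf(
    table: SAFTable,
    model_source_regions: set[str],
    phantom: Phantom,
    weights: dict[str, float] | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """SAF of the composite source "Other" for every target and energy.

    Other is the mass-weighted mean over the phantom's eligible
    soft-tissue sources not claimed by the biokinetic model:

        Phi(r_T <- Other, E) = (1/M_Other) * sum_S M_S * Phi(r_T <- S, E)

    ``weights`` overrides the constituent->weight map (used by the blood
    rule); by default constituents carry their reference masses.

    Returns ``{(rtype, target): values-on-grid}``.
    """
    if weights is None:
        constituents = [
            r for r in phantom.other_constituents if r not in model_source_regions
        ]
        weights = {r: phantom.mass(r) for r in constituents}
    if not weights:
        raise PhantomError("source region 'Other' has no constituents")
    m_other = sum(weights.values())
    if m_other <= 0:
        raise PhantomError("total Other weight must be positive")
    out: dict[tuple[str, str], np.ndarray] = {}
    for rtype in table.rtypes():
        for target in table.targets(rtype):
            acc = np.zeros_like(table.energy_grids[rtype])
            ok = False
            for region, w in weights.items():
                if table.has_pair(rtype, target, region):
                    acc += w * table.phi(rtype, target, region)
                    ok = True
                else:
                    raise PhantomError(
                        f"Other constituent {region!r} missing SAF for "
                        f"target {target!r} ({rtype})"
                    )
            if ok:
                out[(rtype, target)] = acc / m_other
    return out


def add_other_source(
    table: SAFTable,
    model_source_regions: set[str],
    phantom: Phantom,
    weights: dict[str, float] | None = None,
) -> None:
    """Insert the composed "Other" column into the table in place."""
    composed = compose_other_saf(table, model_source_regions, phantom, weights)
    for (rtype, target), values in composed.items():
        table.set_phi(rtype, target, "Other", values)


def apply_blood_rule(
    model_source_regions: set[str], phantom: Phantom
) -> dict[str, float]:
    """Constituent weights for "Other" after accounting for circulating blood.

    Biokinetic models built on the systemic framework carry the
    circulating blood as its own source region.  If the model does NOT
    list Blood, the blood-bearing sub-regions that no other source
    represents (large vessels, heart content, ...) would be silently
    dropped; this rule folds them into Other with weight equal to their
    share of the regional blood volume.  If Blood IS an explicit source
    the composition is unchanged (no double counting).

    Returns the full constituent->weight map to feed compose_other_saf.
    """
    weights = {
        r: phantom.mass(r)
        for r in phantom.other_constituents
        if r not in model_source_regions
    }
    if "Blood" in model_source_regions:
        return weights
    for region, frac in phantom.blood_fractions.items():
        if frac <= 0:
            continue
        if region in model_source_regions or region in weights:
            continue
        weights[region] = frac
    if not weights:
        raise PhantomError("blood rule left 'Other' with no constituents")
    return weights


# ---------------------------------------------------------------------------
# 100-day infant derivation
# ---------------------------------------------------------------------------

def infant_s(s_1yr, s_0day):
    """S-coefficient of the 100-day reference infant.

    Linear interpolation between the newborn (0 day) and 1-year phantom
    S-coefficients with the 100-day weight 0.6528:

        S_100d = 0.6528 * (S_1yr - S_0day) + S_0day

    Applies elementwise to arrays / whole S-matrices.
    """
    s1 = np.asarray(s_1yr, dtype=float)
    s0 = np.asarray(s_0day, dtype=float)
    if s1.shape != s0.shape:
        raise PhantomError(f"shape mismatch {s1.shape} vs {s0.shape}")
    out = INFANT_FRACTION_100D * (s1 - s0) + s0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Fixture dialect I/O
# ---------------------------------------------------------------------------

def write_saf_fixture(
    path: str, phantoms: dict[str, Phantom], tables: dict[str, SAFTable]
) -> None:
    os.makedirs(path, exist_ok=True)
    saf_rows = []
    for pid, tab in tables.items():
        for rtype in tab.rtypes():
            grid = tab.energy_grids[rtype]
            for target in tab.targets(rtype):
                for source in tab.sources(rtype):
                    if not tab.has_pair(rtype, target, source):
                        continue
                    for e, phi in zip(grid, tab.phi(rtype, target, source)):
                        saf_rows.append((pid, rtype, target, source, e, phi))
    pd.DataFrame(
        saf_rows, columns=["phantom", "rtype", "target", "source", "E_MeV", "phi_per_kg"]
    ).to_csv(os.path.join(path, "saf.csv"), index=False)

    mass_rows = []
    blood_rows = []
    meta_rows = []
    for pid, ph in phantoms.items():
        meta_rows.append((pid, ph.sex.value, ph.age_class.value, ph.total_mass_kg,
                          ";".join(ph.other_constituents)))
        for r, m in ph.region_masses.items():
            mass_rows.append((pid, r, m))
        for r, f in ph.blood_fractions.items():
            blood_rows.append((pid, r, f))
    pd.DataFrame(
        meta_rows, columns=["phantom", "sex", "age_class", "total_mass_kg", "other_constituents"]
    ).to_csv(os.path.join(path, "phantoms.csv"), index=False)
    pd.DataFrame(mass_rows, columns=["phantom", "region", "mass_kg"]).to_csv(
        os.path.join(path, "masses.csv"), index=False
    )
    pd.DataFrame(blood_rows, columns=["phantom", "region", "blood_fraction"]).to_csv(
        os.path.join(path, "blood.csv"), index=False
    )


def read_saf_fixture(path: str) -> tuple[dict[str, Phantom], dict[str, SAFTable]]:
    meta = pd.read_csv(os.path.join(path, "phantoms.csv"))
    masses = pd.read_csv(os.path.join(path, "masses.csv"))
    blood_path = os.path.join(path, "blood.csv")
    blood = pd.read_csv(blood_path) if os.path.exists(blood_path) else pd.DataFrame(
        columns=["phantom", "region", "blood_fraction"]
    )
    phantoms: dict[str, Phantom] = {}
    for _, row in meta.iterrows():
        pid = str(row["phantom"])
        pm = masses[masses["phantom"] == pid]
        pb = blood[blood["phantom"] == pid]
        oc = str(row["other_constituents"]) if not pd.isna(row["other_constituents"]) else ""
        phantoms[pid] = Phantom(
            sex=Sex(str(row["sex"])),
            age_class=AgeClass(str(row["age_class"])),
            total_mass_kg=float(row["total_mass_kg"]),
            region_masses=dict(zip(pm["region"].astype(str), pm["mass_kg"].astype(float))),
            blood_fractions=dict(
                zip(pb["region"].astype(str), pb["blood_fraction"].astype(float))
            ),
            other_constituents=[s for s in oc.split(";") if s],
        )

    saf = pd.read_csv(os.path.join(path, "saf.csv"))
    tables: dict[str, SAFTable] = {}
    for pid, pgrp in saf.groupby("phantom", sort=False):
        tab = SAFTable(str(pid))
        for rtype, rgrp in pgrp.groupby("rtype", sort=False):
            grid = np.sort(rgrp["E_MeV"].unique())
            tab.set_grid(str(rtype), grid)
            for (target, source), grp in rgrp.groupby(["target", "source"], sort=False):
                grp = grp.sort_values("E_MeV")
                if not np.allclose(grp["E_MeV"].to_numpy(float), grid):
                    raise PhantomError(
                        f"{pid}/{rtype}: pair ({target},{source}) not on the common grid"
                    )
                tab.set_phi(str(rtype), str(target), str(source), grp["phi_per_kg"].to_numpy(float))
        tables[str(pid)] = tab
    return phantoms, tables


def read_icrp133(path: str):
    """Adapter entry point for the user-supplied ICRP Publication 133/155
    SAF electronic supplements (never bundled); convert them to the CSV
    fixture dialect and use read_saf_fixture()."""
    raise NotImplementedError(
        "ICRP 133/155 SAF supplements are user-supplied; convert to the "
        "fixture dialect (saf.csv + masses.csv + blood.csv) and use "
        "read_saf_fixture()."
    )
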