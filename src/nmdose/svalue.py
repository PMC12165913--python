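"""Radionuclide S-values from decay schemes and SAF tables.

The S-value S(r_T <- r_S) is the mean absorbed dose to the target per
nuclear transformation in the source (Gy/nt):

    S = sum_i E_i * Y_i * Phi(r_T <- r_S, E_i)     (discrete lines)
      + integral E * n(E) * Phi_electron(r_T <- r_S, E) dE   (beta)

with energies converted MeV -> J so the result is Gy per transformation.
The beta integral runs on the spectrum's own (denser) grid with the
electron SAF interpolated to each spectrum node.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .decay import EmissionKind, Nuclide
from .dose import MEV_TO_J
from .phantom import Phantom, SAFTable, add_other_source, saf_at_energy

__all__ = ["SMatrix", "s_value", "s_beta", "s_matrix", "SValueError"]

log = logging.getLogger(__name__)

# Radiation types carried in the breakdown; beta is kept separate from
# discrete electrons even though both use the electron SAF grid.
_KIND_TO_RTYPE = {
    EmissionKind.PHOTON: "photon",
    EmissionKind.ELECTRON: "electron",
    EmissionKind.ALPHA: "alpha",
}


class SValueError(ValueError):
    pass


@dataclass
class SMatrix:
    """Dense S-values over (target, source) pairs for one nuclide and
    phantom, with a per-radiation-type breakdown."""

    nuclide_id: str
    phantom_id: str
    targets: list[str]
    sources: list[str]
    total: np.ndarray  # (n_targets, n_sources), Gy/nt
    by_type: dict[str, np.ndarray] = field(default_factory=dict)
    sex: str = ""

    def value(self, target: str, source: str, rtype: str | None = None) -> float:
        i = self.targets.index(target)
        j = self.sources.index(source)
        if rtype is None:
            return float(self.total[i, j])
        return float(self.by_type[rtype][i, j])

    def map_values(self, fn) -> "SMatrix":
        """Apply fn elementwise to the total and every breakdown member."""
        return SMatrix(
            nuclide_id=self.nuclide_id,
            phantom_id=self.phantom_id,
            targets=list(self.targets),
            sources=list(self.sources),
            total=fn(self.total),
            by_type={r: fn(m) for r, m in self.by_type.items()},
            sex=self.sex,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (target, source) pair."""
        rows = []
        for i, t in enumerate(self.targets):
            for j, s in enumerate(self.sources):
                row = {
                    "nuclide": self.nuclide_id,
                    "phantom": self.phantom_id,
                    "target": t,
                    "source": s,
                    "S_Gy_per_nt": self.total[i, j],
                }
                for rtype, mat in self.by_type.items():
                    row[rtype] = mat[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def _s_components(
    nuclide: Nuclide, table: SAFTable, target: str, source: str
) -> dict[str, float]:
    comps = {"photon": 0.0, "electron": 0.0, "alpha": 0.0, "beta": 0.0}
    for em in nuclide.emissions:
        rtype = _KIND_TO_RTYPE[em.kind]
        if rtype not in table.energy_grids:
            raise SValueError(
                f"{nuclide.id}: emission type {rtype!r} has no SAF grid in "
                f"phantom {table.phantom_id}"
            )
        phi = saf_at_energy(table, target, source, rtype, em.energy_mev)
        comps[rtype] += em.energy_mev * em.yield_per_nt * phi * MEV_TO_J
    comps["beta"] = s_beta(nuclide, table, target, source)
    return comps


def s_value(nuclide: Nuclide, table: SAFTable, target: str, source: str) -> float:
    """S(r_T <- r_S) in Gy per nuclear transformation."""
    return sum(_s_components(nuclide, table, target, source).values())


def s_beta(nuclide: Nuclide, table: SAFTable, target: str, source: str) -> float:
    """Beta contribution to the S-value (Gy/nt).

    Replaces the discrete summation with the trapezoidal integral of
    E * n(E) * Phi_electron(E) over the tabulated beta spectrum.
    Returns 0 when the nuclide simply has no beta branch.
    """
    if nuclide.beta is None:
        log.debug("%s: no beta spectrum, S_beta = 0", nuclide.id)
        return 0.0
    if "electron" not in table.energy_grids:
        raise SValueError(
            f"{nuclide.id}: beta spectrum present but phantom "
            f"{table.phantom_id} has no electron SAF grid"
        )
    e = nuclide.beta.energy_mev
    phi = np.array([saf_at_energy(table, target, source, "electron", x) for x in e])
    return float(np.trapezoid(e * nuclide.beta.density * phi, e)) * MEV_TO_J


def s_matrix(
    nuclide: Nuclide,
    phantom: Phantom,
    table: SAFTable,
    sources: list[str],
    targets: list[str],
    other_weights: dict[str, float] | None = None,
) -> SMatrix:
    """Assemble the dense S-matrix over the requested region pairs.

    If "Other" is requested as a source and absent from the table, its
    SAF column is composed first (mass-weighted soft-tissue mean, or the
    blood-rule ``other_weights`` when given).
    """
    needs_other = "Other" in sources and not any(
        table.has_pair(rt, t, "Other") for rt in table.rtypes() for t in targets
    )
    if needs_other:
        add_other_source(table, set(sources), phantom, weights=other_weights)

    rtypes = ["photon", "electron", "alpha", "beta"]
    by_type = {r: np.zeros((len(targets), len(sources))) for r in rtypes}
    for j, src in enumerate(sources):
        for i, tgt in enumerate(targets):
            comps = _s_components(nuclide, table, tgt, src)
            for r in rtypes:
                by_type[r][i, j] = comps[r]
    total = sum(by_type.values())
    return SMatrix(
        nuclide_id=nuclide.id,
        phantom_id=table.phantom_id,
        targets=list(targets),
        sources=list(sources),
        total=total,
        by_type=by_type,
        sex=phantom.sex.value,
    )
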