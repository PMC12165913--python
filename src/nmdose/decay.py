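"""Nuclear decay schemes and serial-decay (Bateman) solving.

A decay scheme holds the physical half-life, the list of discrete
emissions (photons, electrons, alphas), an optional tabulated beta
spectrum, and the progeny branches of one radionuclide.  The energy
bookkeeping unit is MeV per nuclear transformation (nt); one nt is one
decay event (Bq*s).  Times are hours and activities MBq throughout.

The fixture dialect read and written here mirrors the *structure* of the
ICRP Publication 107 electronic files (index + emission records + beta
spectra) without bundling any of their data: a directory holding

    nuclides.yaml   id, half_life_s, progeny ([{id, fraction}, ...])
    emissions.csv   id, kind, E_MeV, yield
    beta.csv        id, E_MeV, density
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

__all__ = [
    "EmissionKind",
    "Emission",
    "BetaSpectrum",
    "Nuclide",
    "DecayChain",
    "DecayDataError",
    "delta_per_transformation",
    "bateman_activities",
    "read_decay_fixture",
    "write_decay_fixture",
    "read_icrp107",
]

LN2 = math.log(2.0)

#: Relative difference below which two decay constants are treated as
#: degenerate and the chain is routed to the confluent (matrix
#: exponential) solution instead of the distinct-eigenvalue closed form.
DEGENERACY_RTOL = 1e-9


class DecayDataError(ValueError):
    """Raised for malformed or unphysical decay data."""


class EmissionKind(str, enum.Enum):
    PHOTON = "photon"
    ELECTRON = "electron"
    ALPHA = "alpha"


@dataclass(frozen=True)
class Emission:
    """One discrete radiation line.

    Parameters
    ----------
    kind : EmissionKind
        Radiation type of the line.
    energy_mev : float
        Energy per particle (MeV); must be positive.
    yield_per_nt : float
        Particles emitted per nuclear transformation; non-negative.
    """

    kind: EmissionKind
    energy_mev: float
    yield_per_nt: float

    def __post_init__(self) -> None:
        if self.yield_per_nt < 0:
            raise DecayDataError(f"negative yield {self.yield_per_nt}")
        if self.energy_mev <= 0:
            raise DecayDataError(f"non-positive energy {self.energy_mev} MeV")


@dataclass(frozen=True)
class BetaSpectrum:
    """Tabulated beta energy distribution.

    ``density`` is particles per MeV per nuclear transformation on a
    strictly increasing ``energy_mev`` grid; its trapezoidal integral is
    the beta branch yield.
    """

    energy_mev: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_mev, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "energy_mev", e)
        object.__setattr__(self, "density", d)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise DecayDataError("beta energy grid must be 1-D and strictly increasing")
        if d.shape != e.shape:
            raise DecayDataError("beta density/grid shape mismatch")
        if np.any(d < 0):
            raise DecayDataError("beta density must be non-negative")

    @property
    def total_yield(self) -> float:
        """Beta particles per transformation (trapezoidal integral)."""
        return float(np.trapezoid(self.density, self.energy_mev))


@dataclass
class Nuclide:
    """Decay scheme of one radionuclide.

    ``progeny`` lists ``(child id, branching fraction)`` pairs; the
    fractions must lie in [0, 1] and sum to at most 1.  A stable member
    at the end of a chain is represented with ``half_life_s = inf``.
    """

    id: str
    half_life_s: float
    emissions: list[Emission] = field(default_factory=list)
    beta: BetaSpectrum | None = None
    progeny: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise DecayDataError("nuclide id must be non-empty")
        if not self.half_life_s > 0:
            raise DecayDataError(f"{self.id}: half-life must be positive")
        total = 0.0
        for child, frac in self.progeny:
            if not 0.0 <= frac <= 1.0:
                raise DecayDataError(f"{self.id}->{child}: branching {frac} outside [0,1]")
            total += frac
        if total > 1.0 + 1e-9:
            raise DecayDataError(f"{self.id}: branching fractions sum to {total} > 1")

    @property
    def stable(self) -> bool:
        return math.isinf(self.half_life_s)

    @property
    def lambda_per_h(self) -> float:
        """Decay constant in h^-1 (0 for a stable member)."""
        return 0.0 if self.stable else LN2 / (self.half_life_s / 3600.0)

    def total_delta_mev(self) -> float:
        """Total emitted energy per transformation (MeV/nt)."""
        out = sum(delta_per_transformation(e) for e in self.emissions)
        if self.beta is not None:
            out += delta_per_transformation(self.beta)
        return out


@dataclass
class DecayChain:
    """Linear serial chain: member i feeds member i+1 with the given
    branch fraction.  The first member is the administered parent."""

    members: list[Nuclide]
    branch_fractions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise DecayDataError("chain must have at least one member")
        ids = [n.id for n in self.members]
        if len(set(ids)) != len(ids):
            raise DecayDataError(f"cyclic or duplicated chain: {ids}")
        if not self.branch_fractions:
            self.branch_fractions = [1.0] * (len(self.members) - 1)
        if len(self.branch_fractions) != len(self.members) - 1:
            raise DecayDataError("need one branch fraction per consecutive pair")
        for b in self.branch_fractions:
            if not 0.0 <= b <= 1.0:
                raise DecayDataError(f"branch fraction {b} outside [0,1]")
        for n in self.members[:-1]:
            if n.stable:
                raise DecayDataError(f"{n.id}: stable member cannot feed a chain")


# ---------------------------------------------------------------------------
# Energy per transformation
# ---------------------------------------------------------------------------

def delta_per_transformation(e: Emission | BetaSpectrum) -> float:
    """Emitted energy per nuclear transformation, Delta = E*Y (MeV/nt).

    For a discrete line this is the product energy x yield; for a beta
    spectrum it is the trapezoidal integral of E*density over the grid.
    """
    if isinstance(e, Emission):
        return e.energy_mev * e.yield_per_nt
    if isinstance(e, BetaSpectrum):
        return float(np.trapezoid(e.energy_mev * e.density, e.energy_mev))
    raise TypeError(f"unsupported emission object {type(e)!r}")


# ---------------------------------------------------------------------------
# Bateman serial decay
# ---------------------------------------------------------------------------

def _chain_matrix(lambdas: np.ndarray, branches: np.ndarray) -> np.ndarray:
    n = lambdas.size
    m = np.zeros((n, n))
    m[np.diag_indices(n)] = -lambdas
    for i in range(n - 1):
        m[i + 1, i] = branches[i] * lambdas[i]
    return m


def bateman_activities(chain: DecayChain, a0_mbq: float, times_h) -> np.ndarray:
    """Activity of every chain member at the requested times.

    Closed-form Bateman solution with branching; chains whose decay
    constants come within ``DEGENERACY_RTOL`` relative of one another are
    evaluated through the matrix exponential of the chain generator,
    which is the exact confluent limit and free of the catastrophic
    cancellation the distinct-eigenvalue form suffers there.

    Parameters
    ----------
    chain : DecayChain
    a0_mbq : float
        Parent activity at t=0 (MBq); all other members start at zero.
    times_h : array_like
        Times in hours, all >= 0.

    Returns
    -------
    ndarray of shape (n_members, n_times), activities in MBq.
    """
    times = np.atleast_1d(np.asarray(times_h, dtype=float))
    if np.any(times < 0):
        raise DecayDataError("times must be non-negative")
    lambdas = np.array([n.lambda_per_h for n in chain.members])
    branches = np.asarray(chain.branch_fractions, dtype=float)
    n = lambdas.size

    finite = lambdas[lambdas > 0]
    degenerate = False
    if finite.size > 1:
        lam_sorted = np.sort(finite)
        rel = np.diff(lam_sorted) / lam_sorted[:-1]
        degenerate = bool(np.any(rel < DEGENERACY_RTOL))

    if degenerate:
        m = _chain_matrix(lambdas, branches)
        n0 = np.zeros(n)
        # work with N in units of (MBq*h); A = lambda * N
        n0[0] = a0_mbq / lambdas[0]
        out = np.empty((n, times.size))
        for j, t in enumerate(times):
            out[:, j] = lambdas * (expm(m * t) @ n0)
        return out

    # distinct-eigenvalue closed form (atom numbers, then A = lambda*N)
    n0_parent = a0_mbq / lambdas[0]
    acts = np.zeros((n, times.size))
    acts[0] = a0_mbq * np.exp(-lambdas[0] * times)
    for k in range(1, n):
        lam = lambdas[: k + 1]
        prod = n0_parent * np.prod(branches[:k] * lambdas[:k])
        if prod == 0.0:
            continue
        nk = np.zeros_like(times)
        for j in range(k + 1):
            denom = np.prod(np.delete(lam, j) - lam[j])
            nk += np.exp(-lam[j] * times) / denom
        if lambdas[k] > 0:
            acts[k] = lambdas[k] * prod * nk
    return acts


# ---------------------------------------------------------------------------
# Fixture dialect I/O
# ---------------------------------------------------------------------------

_INDEX = "nuclides.yaml"
_EMISSIONS = "emissions.csv"
_BETA = "beta.csv"


def write_decay_fixture(nuclides: dict[str, Nuclide], path: str) -> None:
    """Write a nuclide set in the fixture dialect (directory of
    nuclides.yaml + emissions.csv + beta.csv)."""
    os.makedirs(path, exist_ok=True)
    index = []
    em_rows = []
    beta_rows = []
    for nid in sorted(nuclides):
        nuc = nuclides[nid]
        index.append(
            {
                "id": nuc.id,
                "half_life_s": "inf" if nuc.stable else float(nuc.half_life_s),
                "progeny": [{"id": c, "fraction": float(f)} for c, f in nuc.progeny],
            }
        )
        for e in nuc.emissions:
            em_rows.append((nuc.id, e.kind.value, e.energy_mev, e.yield_per_nt))
        if nuc.beta is not None:
            for e_mev, d in zip(nuc.beta.energy_mev, nuc.beta.density):
                beta_rows.append((nuc.id, float(e_mev), float(d)))
    with open(os.path.join(path, _INDEX), "w") as fh:
        yaml.safe_dump({"nuclides": index}, fh, sort_keys=False)
    pd.DataFrame(em_rows, columns=["id", "kind", "E_MeV", "yield"]).to_csv(
        os.path.join(path, _EMISSIONS), index=False
    )
    pd.DataFrame(beta_rows, columns=["id", "E_MeV", "density"]).to_csv(
        os.path.join(path, _BETA), index=False
    )


def read_decay_fixture(path: str) -> dict[str, Nuclide]:
    """Read a nuclide set written in the fixture dialect.

    Returns a fully validated ``{id: Nuclide}`` mapping.  Progeny ids
    that do not resolve within the set are allowed (chains may point at
    nuclides supplied elsewhere) but are reported via a logged notice.
    """
    index_path = os.path.join(path, _INDEX)
    with open(index_path) as fh:
        raw = yaml.safe_load(fh) or {}
    entries = raw.get("nuclides", [])

    em_path = os.path.join(path, _EMISSIONS)
    emissions: dict[str, list[Emission]] = {}
    if os.path.exists(em_path):
        df = pd.read_csv(em_path)
        for i, row in df.iterrows():
            try:
                kind = EmissionKind(str(row["kind"]))
                em = Emission(kind, float(row["E_MeV"]), float(row["yield"]))
            except (ValueError, DecayDataError) as exc:
                raise DecayDataError(f"{em_path} line {i + 2}: {exc}") from exc
            emissions.setdefault(str(row["id"]), []).append(em)

    beta_path = os.path.join(path, _BETA)
    betas: dict[str, BetaSpectrum] = {}
    if os.path.exists(beta_path):
        df = pd.read_csv(beta_path)
        for nid, grp in df.groupby("id", sort=False):
            try:
                betas[str(nid)] = BetaSpectrum(
                    grp["E_MeV"].to_numpy(float), grp["density"].to_numpy(float)
                )
            except DecayDataError as exc:
                raise DecayDataError(f"{beta_path} [{nid}]: {exc}") from exc

    out: dict[str, Nuclide] = {}
    for i, rec in enumerate(entries):
        try:
            nid = str(rec["id"])
            hl = rec["half_life_s"]
            hl = math.inf if hl in ("inf", None) else float(hl)
            progeny = [(str(p["id"]), float(p["fraction"])) for p in rec.get("progeny", [])]
            out[nid] = Nuclide(
                id=nid,
                half_life_s=hl,
                emissions=emissions.get(nid, []),
                beta=betas.get(nid),
                progeny=progeny,
            )
        except (KeyError, TypeError, ValueError, DecayDataError) as exc:
            raise DecayDataError(f"{index_path} record {i}: {exc}") from exc

    unknown = {
        child
        for nuc in out.values()
        for child, _ in nuc.progeny
        if child not in out
    }
    if unknown:
        import logging

        logging.getLogger(__name__).info(
            "progeny ids not in this set: %s", ", ".join(sorted(unknown))
        )
    return out


def read_icrp107(ndx_path: str, rad_path: str, bet_path: str) -> dict[str, Nuclide]:
    """Adapter entry point for user-supplied ICRP Publication 107
    electronic files (ICRP-07.NDX/RAD/BET).

    The files are licensed data and are never bundled; convert them to
    the fixture dialect (``write_decay_fixture``) or implement this
    adapter against your local copies.
    """
    raise NotImplementedError(
        "ICRP-107 electronic files are user-supplied; convert them to the "
        "fixture dialect (nuclides.yaml + emissions.csv + beta.csv) and use "
        "read_decay_fixture()."
    )
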