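"""Organ absorbed doses, Remainder tissues, and effective dose.

Combines time-integrated activity coefficients (TIACs, hours) with
S-matrices (Gy per nuclear transformation) into organ absorbed doses
(mGy/MBq), forms the Remainder-tissues dose, and recombines per-organ
doses into the effective dose of the ICRP 60 and ICRP 103 tissue
weighting schemes plus the non-sex-averaged ("detriment adjusted")
variant.

All unit conversions of the package are centralized here:

    1 MBq*h  =  1e6 Bq * 3600 s  =  3.6e9 nuclear transformations
    D [mGy/MBq]  =  TIAC [h] * 3.6e9 [nt/(MBq*h)] * S [Gy/nt] * 1e3 [mGy/Gy]

so the net multiplier from TIAC*S to mGy/MBq is 3.6e12.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MEV_TO_J",
    "NT_PER_MBQ_H",
    "TIAC_S_TO_MGY_PER_MBQ",
    "WeightingConfig",
    "DoseResult",
    "DoseError",
    "weighting_config",
    "absorbed_dose",
    "remainder_dose",
    "effective_dose",
    "detriment_adjusted",
    "round_sigfigs",
]

#: Joules per MeV (CODATA exact, via the elementary charge).
MEV_TO_J = 1.602176634e-13

#: Nuclear transformations per MBq*hour of cumulated activity.
NT_PER_MBQ_H = 3.6e9

#: Net multiplier: TIAC [h] x S [Gy/nt] -> absorbed dose [mGy/MBq].
TIAC_S_TO_MGY_PER_MBQ = NT_PER_MBQ_H * 1e3


class DoseError(ValueError):
    """Raised for inconsistent dose inputs."""


# ---------------------------------------------------------------------------
# Tissue and radiation weighting factors
# ---------------------------------------------------------------------------

#: Radiation weighting factors: photons and electrons 1, alphas 20.
W_R = {"photon": 1.0, "electron": 1.0, "beta": 1.0, "alpha": 20.0}

# ICRP Publication 103 tissue weighting factors (sum = 1).
_WT_103 = {
    "Gonads": 0.08,
    "R-marrow": 0.12,
    "Colon": 0.12,
    "Lungs": 0.12,
    "Stomach": 0.12,
    "Breast": 0.12,
    "Remainder": 0.12,
    "UB-wall": 0.04,
    "Oesophagus": 0.04,
    "Liver": 0.04,
    "Thyroid": 0.04,
    "Endosteum": 0.01,
    "Brain": 0.01,
    "Salivary glands": 0.01,
    "Skin": 0.01,
}

# ICRP Publication 60 tissue weighting factors (sum = 1).
_WT_60 = {
    "Gonads": 0.20,
    "R-marrow": 0.12,
    "Colon": 0.12,
    "Lungs": 0.12,
    "Stomach": 0.12,
    "UB-wall": 0.05,
    "Breast": 0.05,
    "Liver": 0.05,
    "Oesophagus": 0.05,
    "Thyroid": 0.05,
    "Skin": 0.01,
    "Endosteum": 0.01,
    "Remainder": 0.05,
}

# Remainder tissues of ICRP 103: arithmetic mean of 13 organs/tissues,
# the 13th being sex specific (prostate male / uterus-cervix female).
_REMAINDER_103_COMMON = [
    "Adrenals",
    "ET region",
    "Gallbladder",
    "Heart wall",
    "Kidneys",
    "Lymphatic nodes",
    "Muscle",
    "Oral mucosa",
    "Pancreas",
    "Small intestine",
    "Spleen",
    "Thymus",
]
_REMAINDER_103_SEX = {"male": "Prostate", "female": "Uterus/cervix"}

# Remainder of ICRP 60 (10 tissues, mass-averaged historically; the mean
# is used here for scheme symmetry).
_REMAINDER_60_COMMON = [
    "Adrenals",
    "Brain",
    "Small intestine",
    "Kidneys",
    "Muscle",
    "Pancreas",
    "Spleen",
    "Thymus",
    "Upper large intestine",
]
_REMAINDER_60_SEX = {"male": "Prostate", "female": "Uterus/cervix"}

# Sex-specific organ resolution: each sex contributes the equivalent
# dose of its own organ to the sex average (ICRP convention).
_SEX_ORGANS = {
    "Gonads": {"male": "Testes", "female": "Ovaries"},
    "Prostate": {"male": "Prostate", "female": None},
    "Uterus/cervix": {"male": None, "female": "Uterus/cervix"},
}

# Checksums of the canonical JSON serialization of the shipped weighting
# tables, verified at config construction so silent edits are caught.
_WT_CHECKSUMS = {
    "ICRP103": "e52f888d75c8f9468ae2c5b12472bf6a1a04766e198a51b82ef026efe4b186a5",
    "ICRP60": "7c1ea7609c6eca1cbd08b2105fc6e3dcf0fba77bf3891ef6b118474c1cdb6151",
}


def _table_checksum(table: dict[str, float]) -> str:
    return hashlib.sha256(
        json.dumps(table, sort_keys=True).encode("utf-8")
    ).hexdigest()


@dataclass(frozen=True)
class WeightingConfig:
    """Tissue and radiation weighting factors of one scheme."""

    scheme: str
    w_t: dict[str, float]
    w_r: dict[str, float]
    remainder_common: tuple[str, ...]
    remainder_sex: dict[str, str]

    def __post_init__(self) -> None:
        total = sum(self.w_t.values())
        if abs(total - 1.0) > 1e-12:
            raise DoseError(f"{self.scheme}: tissue weights sum to {total}, not 1")
        for r, w in self.w_r.items():
            if w <= 0:
                raise DoseError(f"non-positive radiation weight for {r!r}")

    def remainder_members(self, sex: str) -> list[str]:
        organ = self.remainder_sex[sex]
        return list(self.remainder_common) + [organ]


def weighting_config(scheme: str) -> WeightingConfig:
    """Shipped weighting configuration for 'ICRP103' or 'ICRP60'.

    The tables are verified against their recorded checksums."""
    scheme = scheme.upper().replace(" ", "")
    if scheme == "ICRP103":
        table, common, sexed = _WT_103, _REMAINDER_103_COMMON, _REMAINDER_103_SEX
    elif scheme == "ICRP60":
        table, common, sexed = _WT_60, _REMAINDER_60_COMMON, _REMAINDER_60_SEX
    else:
        raise DoseError(f"unknown weighting scheme {scheme!r}")
    digest = _table_checksum(table)
    if digest != _WT_CHECKSUMS[scheme]:
        raise DoseError(f"{scheme} weighting table fails its checksum ({digest})")
    return WeightingConfig(
        scheme=scheme,
        w_t=dict(table),
        w_r=dict(W_R),
        remainder_common=tuple(common),
        remainder_sex=dict(sexed),
    )


# ---------------------------------------------------------------------------
# Absorbed dose (Eq. 1 recombination)
# ---------------------------------------------------------------------------

@dataclass
class DoseResult:
    """Per-target absorbed doses for one phantom of one sex.

    ``doses`` are mGy per administered MBq; ``by_type`` carries the
    radiation-type breakdown (same units) used by the effective-dose
    radiation weighting.
    """

    phantom_id: str
    sex: str
    doses: dict[str, float]
    by_type: dict[str, dict[str, float]] = field(default_factory=dict)

    def equivalent_dose(self, target: str, w_r: dict[str, float]) -> float:
        """Radiation-weighted (equivalent) dose of one target, mSv/MBq."""
        if self.by_type:
            missing = [r for r in self.by_type if r not in w_r]
            if missing:
                raise DoseError(f"no radiation weight for type(s) {missing}")
            return sum(
                w_r[r] * comp.get(target, 0.0) for r, comp in self.by_type.items()
            )
        return self.doses.get(target, 0.0)


def absorbed_dose(
    tiac_h: dict[str, float],
    smatrix,
    mass_overrides: dict[str, float] | None = None,
    reference_masses: dict[str, float] | None = None,
) -> DoseResult:
    """Organ absorbed doses from TIACs and an S-matrix (Eq. 1 form).

    D(r_T) = sum_S TIAC(r_S) * S(r_T <- r_S), converted to mGy/MBq with
    the centralized multiplier ``TIAC_S_TO_MGY_PER_MBQ``.

    ``mass_overrides`` rescales the self-irradiation terms of the listed
    targets by M_ref/M_new (patient-specific target-mass adjustment);
    ``reference_masses`` must then provide the reference masses.
    """
    for region, value in tiac_h.items():
        if value < 0:
            raise DoseError(f"negative TIAC for {region!r}")
        if region not in smatrix.sources:
            raise DoseError(
                f"TIAC source {region!r} has no S-matrix column; available: "
                f"{', '.join(smatrix.sources)}"
            )
    if mass_overrides and reference_masses is None:
        raise DoseError("mass_overrides requires reference_masses")

    def scale(target: str, source: str) -> float:
        if mass_overrides and target == source and target in mass_overrides:
            return reference_masses[target] / mass_overrides[target]
        return 1.0

    doses: dict[str, float] = {}
    by_type: dict[str, dict[str, float]] = {r: {} for r in smatrix.by_type}
    for target in smatrix.targets:
        total = 0.0
        for source, tiac in tiac_h.items():
            total += tiac * smatrix.value(target, source) * scale(target, source)
        doses[target] = total * TIAC_S_TO_MGY_PER_MBQ
        for rtype, mat in smatrix.by_type.items():
            comp = 0.0
            for source, tiac in tiac_h.items():
                comp += tiac * smatrix.value(target, source, rtype) * scale(target, source)
            by_type[rtype][target] = comp * TIAC_S_TO_MGY_PER_MBQ
    return DoseResult(
        phantom_id=smatrix.phantom_id, sex=getattr(smatrix, "sex", ""), doses=doses,
        by_type=by_type,
    )


def remainder_dose(result: DoseResult, sex: str, cfg: WeightingConfig) -> float:
    """Remainder-tissues dose: unweighted arithmetic mean of the scheme's
    constituent organs (13 for ICRP 103, sex-specific 13th member)."""
    members = cfg.remainder_members(sex)
    missing = [m for m in members if m not in result.doses]
    if missing:
        raise DoseError(f"Remainder constituents missing doses: {', '.join(missing)}")
    return sum(result.doses[m] for m in members) / len(members)


def _remainder_equivalent(result: DoseResult, sex: str, cfg: WeightingConfig) -> float:
    members = cfg.remainder_members(sex)
    missing = [m for m in members if m not in result.doses]
    if missing:
        raise DoseError(f"Remainder constituents missing doses: {', '.join(missing)}")
    return sum(result.equivalent_dose(m, cfg.w_r) for m in members) / len(members)


def _tissue_equivalent(result: DoseResult, tissue: str, sex: str, cfg: WeightingConfig):
    """Equivalent dose of one weighted tissue for one sex; None when the
    tissue does not exist in that sex (sex-specific organs)."""
    if tissue == "Remainder":
        return _remainder_equivalent(result, sex, cfg)
    organ = _SEX_ORGANS.get(tissue, {}).get(sex, tissue) if tissue in _SEX_ORGANS else tissue
    if organ is None:
        return None
    if organ not in result.doses and not any(
        organ in comp for comp in result.by_type.values()
    ):
        raise DoseError(f"weighted tissue {tissue!r} ({organ!r}) has no dose for {sex}")
    return result.equivalent_dose(organ, cfg.w_r)


def effective_dose(
    male: DoseResult, female: DoseResult, cfg: WeightingConfig
) -> float:
    """Effective dose (mSv/MBq): sex-averaged, radiation- and
    tissue-weighted recombination of the per-organ doses.

    E = sum_T w_T * [H_T(male) + H_T(female)] / 2, where H_T is the
    radiation-weighted (equivalent) dose.  A sex-specific organ (testes/
    ovaries, prostate/uterus) contributes its single-sex equivalent dose
    as that sex's term of the average.
    """
    total = 0.0
    for tissue, w in cfg.w_t.items():
        h_m = _tissue_equivalent(male, tissue, "male", cfg)
        h_f = _tissue_equivalent(female, tissue, "female", cfg)
        if h_m is None and h_f is None:
            raise DoseError(f"tissue {tissue!r} absent in both sexes")
        if h_m is None:
            h_m = h_f
        if h_f is None:
            h_f = h_m
        total += w * (h_m + h_f) / 2.0
    return total


def detriment_adjusted(result: DoseResult, sex: str, cfg: WeightingConfig) -> float:
    """Detriment-adjusted (sex-specific) dose: the effective-dose
    recombination without the sex average, per sex (mSv/MBq)."""
    total = 0.0
    for tissue, w in cfg.w_t.items():
        h = _tissue_equivalent(result, tissue, sex, cfg)
        if h is None:
            continue  # other-sex organ: no contribution for this sex
        total += w * h
    return total


def round_sigfigs(x: float, n: int = 2) -> float:
    """Round to n significant figures (printed-table report style)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))
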