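"""Miniature, analytically solvable fixture inputs.

Every sub-module of the package can be exercised without any external
data: this module generates small phantoms whose SAF tables conserve
energy exactly (enabling whole-body closure checks), toy nuclides with
known total emitted energy, sphere absorbed-fraction tables monotone in
volume, content->wall S-value curves, and noisy time-activity curves
with stored ground truth.  All generation is seeded and bit
reproducible; the emulated scale (a handful of regions, short energy
grids) is deliberate — these are ground-truth miniatures, not
statistically realistic patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biokinetics import ActivityCurve, RetentionFit
from .bladder import WallSvalueCurve
from .decay import BetaSpectrum, DecayChain, Emission, EmissionKind, Nuclide
from .phantom import AgeClass, Phantom, SAFTable, Sex
from .sphere import SphereAFTable

__all__ = [
    "FixtureSpec",
    "make_conserving_phantom",
    "make_toy_nuclide",
    "make_time_activity",
    "make_sphere_af",
    "make_wall_s_curve",
    "make_weighted_phantom",
    "SCENARIOS",
    "generate_scenario",
]

_DEFAULT_GRID = (0.01, 0.1, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the fixture generator.

    seed : base seed; identical specs generate identical fixtures
    n_regions : number of phantom regions (default 5)
    energy_grid_mev : SAF energy grid
    noise_sigma : multiplicative lognormal noise of time-activity data
    scenario : free-form scenario label
    """

    seed: int = 0
    n_regions: int = 5
    energy_grid_mev: tuple[float, ...] = _DEFAULT_GRID
    noise_sigma: float = 0.05
    scenario: str = "default"

def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    # derive the per-stream offset stably (never via the salted hash())
    offset = sum(ord(c) * (31**i) for i, c in enumerate(stream)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([spec.seed, offset]))


def make_conserving_phantom(
    spec: FixtureSpec,
    sex: Sex = Sex.MALE,
    age_class: AgeClass = AgeClass.ADULT,
    energy_dependent: bool = False,
) -> tuple[Phantom, SAFTable]:
    """Random small phantom whose SAFs conserve energy exactly.

    For every source the absorbed-energy fractions over targets are
    drawn from a Dirichlet distribution and divided by the target
    masses, so sum_T m_T * Phi(T<-S, E) = 1 identically: all emitted
    energy is absorbed somewhere in the phantom.  By default the
    fractions are constant in energy, which keeps the closure exact at
    ANY emission energy (interpolation of a constant is the constant),
    beta spectra included; with ``energy_dependent=True`` each grid
    energy gets its own draw and closure is exact only on grid nodes.
    """
    if spec.n_regions < 2:
        raise ValueError("need at least 2 regions")
    rng = _rng(spec, f"phantom-{sex.value}-{age_class.value}")
    regions = [f"region_{i}" for i in range(spec.n_regions)]
    masses = {r: float(m) for r, m in zip(regions, rng.uniform(0.2, 3.0, spec.n_regions))}
    phantom = Phantom(
        sex=sex,
        age_class=age_class,
        total_mass_kg=sum(masses.values()),
        region_masses=masses,
        blood_fractions={},
        other_constituents=list(regions),
    )
    table = SAFTable(phantom.id)
    grid = np.asarray(spec.energy_grid_mev, dtype=float)
    for rtype in ("photon", "electron", "alpha"):
        table.set_grid(rtype, grid)
        for source in regions:
            size = grid.size if energy_dependent else None
            fractions = rng.dirichlet(np.ones(spec.n_regions), size=size)
            if not energy_dependent:
                fractions = np.tile(fractions, (grid.size, 1))  # (E, T)
            for j, target in enumerate(regions):
                table.set_phi(rtype, target, source, fractions[:, j] / masses[target])
    return phantom, table


def make_toy_nuclide(spec: FixtureSpec, kind: str) -> Nuclide | DecayChain:
    """Toy decay schemes with known energy totals.

    kind: 'gamma' (one 0.14 MeV photon line, Y=0.89), 'beta' (uniform
    spectrum on [0, 1] MeV, unit yield), 'alpha' (one 5 MeV line),
    'mixed' (all three), or 'chain' (2-member chain, 1 h and 3 h
    half-lives, unit branching).
    """
    if kind == "gamma":
        return Nuclide(
            id="toy-gamma",
            half_life_s=6.0 * 3600.0,
            emissions=[Emission(EmissionKind.PHOTON, 0.14, 0.89)],
        )
    if kind == "beta":
        grid = np.linspace(0.0, 1.0, 101)
        grid[0] = 1e-12  # strictly positive energies
        return Nuclide(
            id="toy-beta",
            half_life_s=8.0 * 3600.0,
            beta=BetaSpectrum(grid, np.ones_like(grid)),
        )
    if kind == "alpha":
        return Nuclide(
            id="toy-alpha",
            half_life_s=24.0 * 3600.0,
            emissions=[Emission(EmissionKind.ALPHA, 5.0, 1.0)],
        )
    if kind == "mixed":
        grid = np.linspace(0.0, 1.0, 101)
        grid[0] = 1e-12
        return Nuclide(
            id="toy-mixed",
            half_life_s=6.0 * 3600.0,
            emissions=[
                Emission(EmissionKind.PHOTON, 0.14, 0.89),
                Emission(EmissionKind.ELECTRON, 0.05, 0.2),
                Emission(EmissionKind.ALPHA, 5.0, 0.01),
            ],
            beta=BetaSpectrum(grid, 0.5 * np.ones_like(grid)),
        )
    if kind == "chain":
        parent = Nuclide(
            id="toy-parent",
            half_life_s=1.0 * 3600.0,
            emissions=[Emission(EmissionKind.PHOTON, 0.2, 1.0)],
            progeny=[("toy-child", 1.0)],
        )
        child = Nuclide(
            id="toy-child",
            half_life_s=3.0 * 3600.0,
            emissions=[Emission(EmissionKind.ELECTRON, 0.5, 1.0)],
        )
        return DecayChain(members=[parent, child])
    raise ValueError(f"unknown toy nuclide kind {kind!r}")


def make_time_activity(
    spec: FixtureSpec,
    truth: RetentionFit,
    region: str = "Liver",
    n_points: int = 10,
    t_max_h: float = 48.0,
    a0_mbq: float = 100.0,
) -> tuple[ActivityCurve, RetentionFit]:
    """Sample a true retention model at log-spaced times with seeded
    multiplicative lognormal noise; returns (curve, truth)."""
    rng = _rng(spec, f"tac-{region}")
    t = np.geomspace(t_max_h / 200.0, t_max_h, n_points)
    frac = truth.evaluate(t)
    if spec.noise_sigma > 0:
        frac = frac * rng.lognormal(0.0, spec.noise_sigma, size=t.size)
    curve = ActivityCurve(
        region=region,
        t_h=t,
        a_mbq=frac * a0_mbq,
        a0_mbq=a0_mbq,
        decay_corrected=True,
    )
    return curve, truth


def make_sphere_af(spec: FixtureSpec, tissue_id: int = 1) -> SphereAFTable:
    """Sphere AF table monotone non-decreasing in volume, decreasing in
    energy: AF = V^a / (V^a + c*E^b), clipped to [0, 1]."""
    table = SphereAFTable(tissue_id=tissue_id, density_g_cm3=1.0)
    volumes = np.geomspace(0.01, 3000.0, 7)
    energies = np.geomspace(0.01, 3.0, 6)
    vv, ee = np.meshgrid(volumes, energies, indexing="ij")
    for rtype, (a, b, c) in {
        "photon": (0.33, 1.0, 5.0),
        "electron": (0.33, 1.0, 0.5),
        "alpha": (0.1, 1.0, 0.001),
    }.items():
        af = vv**a / (vv**a + c * ee**b)
        table.set_af(rtype, volumes, energies, np.clip(af, 0.0, 1.0))
    return table


def make_wall_s_curve(
    spec: FixtureSpec, phantom_id: str = "adult_male", s_ref: float = 1e-15
) -> WallSvalueCurve:
    """Content->wall S-value decreasing with volume roughly like the
    inverse content mass (geometric dilution)."""
    volumes = np.geomspace(10.0, 700.0, 8)
    s = s_ref * (volumes[0] / volumes) ** 0.7
    return WallSvalueCurve(phantom_id=phantom_id, volume_ml=volumes, s_gy_per_nt=s)


def make_weighted_phantom(
    spec: FixtureSpec,
    sex: Sex = Sex.MALE,
    age_class: AgeClass = AgeClass.ADULT,
    uniform: bool = False,
) -> tuple[Phantom, SAFTable, list[str]]:
    """Conserving phantom whose regions are named after the targets of
    the tissue-weighting schemes, so effective dose can be exercised
    end to end.  With ``uniform=True`` every pair gets
    Phi = 1/M_total, which still conserves energy and gives every
    target the same absorbed dose (the effective-dose identity fixture).
    Returns (phantom, table, target names)."""
    from .dose import _REMAINDER_60_COMMON, _REMAINDER_103_COMMON, _WT_103

    targets = [t for t in _WT_103 if t not in ("Remainder", "Gonads")]
    targets += ["Testes" if sex is Sex.MALE else "Ovaries"]
    targets += list(_REMAINDER_103_COMMON)
    targets += [t for t in _REMAINDER_60_COMMON if t not in targets]
    targets += ["Prostate" if sex is Sex.MALE else "Uterus/cervix"]
    # the rng stream ignores sex: the male/female pair of one age class
    # shares masses and SAF draws, with only the sex-specific organ
    # names swapped (keeps sex-averaged identities exact at toy scale)
    rng = _rng(spec, f"weighted-{age_class.value}")
    masses = {t: float(m) for t, m in zip(targets, rng.uniform(0.05, 2.0, len(targets)))}
    total_mass = sum(masses.values())
    phantom = Phantom(
        sex=sex,
        age_class=age_class,
        total_mass_kg=total_mass,
        region_masses=masses,
        other_constituents=list(targets),
    )
    table = SAFTable(phantom.id)
    grid = np.asarray(spec.energy_grid_mev, dtype=float)
    n = len(targets)
    for rtype in ("photon", "electron", "alpha"):
        table.set_grid(rtype, grid)
        for source in targets:
            if uniform:
                for target in targets:
                    table.set_phi(rtype, target, source,
                                  np.full(grid.size, 1.0 / total_mass))
                continue
            fractions = np.tile(rng.dirichlet(np.ones(n)), (grid.size, 1))
            for j, target in enumerate(targets):
                table.set_phi(rtype, target, source, fractions[:, j] / masses[target])
    return phantom, table, targets


# ---------------------------------------------------------------------------
# Scenario generation (complete runnable input sets on disk)
# ---------------------------------------------------------------------------

def _scenario_basic(spec: FixtureSpec, outdir: str) -> list[str]:
    import os

    from .decay import write_decay_fixture
    from .phantom import write_saf_fixture

    phantom, table = make_conserving_phantom(spec)
    write_saf_fixture(outdir, {phantom.id: phantom}, {phantom.id: table})
    nuc = make_toy_nuclide(spec, "mixed")
    write_decay_fixture({nuc.id: nuc}, os.path.join(outdir, "decay"))
    import pandas as pd

    tiac = pd.DataFrame(
        {"region": list(phantom.region_masses), "tiac_h": 1.0}
    )
    tiac_path = os.path.join(outdir, "tiac.csv")
    tiac.to_csv(tiac_path, index=False)
    return ["saf.csv", "masses.csv", "blood.csv", "phantoms.csv", "decay", "tiac.csv"]


SCENARIOS = {"basic": _scenario_basic}


def generate_scenario(name: str, outdir: str, seed: int = 0) -> list[str]:
    """Emit a complete runnable input set for the named scenario."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    import os

    os.makedirs(outdir, exist_ok=True)
    return SCENARIOS[name](FixtureSpec(seed=seed, scenario=name), outdir)
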