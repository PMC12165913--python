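"""S-value assembly from decay schemes and SAF tables."""

import numpy as np
import pytest

from nmdose.decay import BetaSpectrum, Emission, EmissionKind, Nuclide
from nmdose.dose import MEV_TO_J
from nmdose.phantom import AgeClass, Phantom, SAFTable, Sex, saf_at_energy
from nmdose.svalue import SValueError, s_beta, s_matrix, s_value


def self_absorbing_table(mass_kg=1.0, grid=(0.01, 0.1, 1.0, 5.0)):
    """One-region phantom absorbing everything locally: Phi = 1/M."""
    tab = SAFTable("adult_male")
    for rtype in ("photon", "electron", "alpha"):
        tab.set_grid(rtype, grid)
        tab.set_phi(rtype, "organ", "organ", np.full(len(grid), 1.0 / mass_kg))
    return tab


class TestSValue:
    def test_no_emissions_gives_zero(self):
        nuc = Nuclide("empty", half_life_s=3600.0)
        assert s_value(nuc, self_absorbing_table(), "organ", "organ") == 0.0

    def test_single_electron_line_local_absorption(self):
        # E*Y/M in joules: 1 MeV * 1 / 1 kg = 1.602176634e-13 Gy/nt
        nuc = Nuclide("e1", half_life_s=3600.0,
                      emissions=[Emission(EmissionKind.ELECTRON, 1.0, 1.0)])
        s = s_value(nuc, self_absorbing_table(1.0), "organ", "organ")
        assert s == pytest.approx(1.602176634e-13, rel=1e-12)

    def test_linearity_in_emission_list(self):
        e1 = Emission(EmissionKind.PHOTON, 0.3, 0.8)
        e2 = Emission(EmissionKind.ELECTRON, 1.2, 0.1)
        tab = self_absorbing_table(2.0)
        single = [
            s_value(Nuclide("a", 1.0, emissions=[e]), tab, "organ", "organ")
            for e in (e1, e2)
        ]
        both = s_value(Nuclide("b", 1.0, emissions=[e1, e2]), tab, "organ", "organ")
        assert both == pytest.approx(sum(single), rel=1e-12)

    def test_doubling_yields_doubles_s(self):
        tab = self_absorbing_table(0.5)
        nuc = Nuclide("a", 1.0, emissions=[Emission(EmissionKind.PHOTON, 0.2, 0.4),
                                           Emission(EmissionKind.ALPHA, 5.0, 0.01)])
        dbl = Nuclide("a2", 1.0,
                      emissions=[Emission(EmissionKind.PHOTON, 0.2, 0.8),
                                 Emission(EmissionKind.ALPHA, 5.0, 0.02)])
        assert s_value(dbl, tab, "organ", "organ") == pytest.approx(
            2 * s_value(nuc, tab, "organ", "organ"), rel=1e-12
        )

    def test_missing_rtype_grid_names_the_type(self):
        tab = SAFTable("x")
        tab.set_grid("photon", [0.1, 1.0])
        tab.set_phi("photon", "organ", "organ", [1.0, 1.0])
        nuc = Nuclide("a", 1.0, emissions=[Emission(EmissionKind.ALPHA, 5.0, 1.0)])
        with pytest.raises(SValueError, match="alpha"):
            s_value(nuc, tab, "organ", "organ")


class TestSBeta:
    def test_zero_density_gives_zero(self):
        grid = np.linspace(1e-6, 1.0, 11)
        nuc = Nuclide("b", 1.0, beta=BetaSpectrum(grid, np.zeros_like(grid)))
        assert s_beta(nuc, self_absorbing_table(), "organ", "organ") == 0.0

    def test_uniform_spectrum_constant_phi(self):
        # integral E dE over [0,1] = 0.5, Phi = 1/1 kg
        grid = np.linspace(0.0, 1.0, 501)
        grid[0] = 1e-9
        nuc = Nuclide("b", 1.0, beta=BetaSpectrum(grid, np.ones_like(grid)))
        s = s_beta(nuc, self_absorbing_table(1.0), "organ", "organ")
        assert s == pytest.approx(0.5 * 1.602176634e-13, rel=1e-5)

    @pytest.mark.parametrize("width", [1e-2, 1e-3, 1e-4])
    def test_narrow_triangle_approaches_discrete_line(self, width):
        # triangular density at E0 with area Y behaves like a discrete line
        e0, yld = 0.5, 0.8
        grid = np.array([e0 - width, e0, e0 + width])
        density = np.array([0.0, yld / width, 0.0])
        nuc = Nuclide("b", 1.0, beta=BetaSpectrum(grid, density))
        tab = self_absorbing_table(1.0)
        s = s_beta(nuc, tab, "organ", "organ")
        discrete = e0 * yld / 1.0 * MEV_TO_J
        assert s == pytest.approx(discrete, rel=5 * width)

    def test_no_spectrum_returns_zero(self):
        nuc = Nuclide("g", 1.0, emissions=[Emission(EmissionKind.PHOTON, 1.0, 1.0)])
        assert s_beta(nuc, self_absorbing_table(), "organ", "organ") == 0.0

    def test_spectrum_without_electron_grid_errors(self):
        tab = SAFTable("x")
        tab.set_grid("photon", [0.1, 1.0])
        grid = np.linspace(1e-6, 1.0, 11)
        nuc = Nuclide("b", 1.0, beta=BetaSpectrum(grid, np.ones_like(grid)))
        with pytest.raises(SValueError, match="electron"):
            s_beta(nuc, tab, "organ", "organ")


class TestSMatrix:
    def test_1x1_matches_s_value(self, conserving_phantom, mixed_nuclide):
        ph, tab = conserving_phantom
        r = list(ph.region_masses)[0]
        sm = s_matrix(mixed_nuclide, ph, tab, [r], [r])
        assert sm.value(r, r) == pytest.approx(
            s_value(mixed_nuclide, tab, r, r), rel=1e-12
        )

    def test_matches_brute_force_oracle(self, conserving_phantom, mixed_nuclide):
        # independent elementwise loop over emissions and region pairs
        ph, tab = conserving_phantom
        regions = list(ph.region_masses)
        sm = s_matrix(mixed_nuclide, ph, tab, regions, regions)
        for i, t in enumerate(regions):
            for j, s in enumerate(regions):
                brute = 0.0
                for em in mixed_nuclide.emissions:
                    rtype = {"photon": "photon", "electron": "electron",
                             "alpha": "alpha"}[em.kind.value]
                    brute += (em.energy_mev * em.yield_per_nt
                              * saf_at_energy(tab, t, s, rtype, em.energy_mev)
                              * MEV_TO_J)
                e = mixed_nuclide.beta.energy_mev
                phi = np.array([saf_at_energy(tab, t, s, "electron", x) for x in e])
                brute += np.trapezoid(
                    e * mixed_nuclide.beta.density * phi, e) * MEV_TO_J
                assert sm.total[i, j] == pytest.approx(brute, rel=1e-12)

    def test_target_permutation_permutes_rows(self, conserving_phantom, mixed_nuclide):
        ph, tab = conserving_phantom
        regions = list(ph.region_masses)
        sm = s_matrix(mixed_nuclide, ph, tab, regions, regions)
        perm = list(reversed(regions))
        sm_p = s_matrix(mixed_nuclide, ph, tab, regions, perm)
        for t in regions:
            for s in regions:
                assert sm_p.value(t, s) == sm.value(t, s)

    def test_breakdown_members_nonnegative_and_sum_to_total(
        self, conserving_phantom, mixed_nuclide
    ):
        ph, tab = conserving_phantom
        regions = list(ph.region_masses)
        sm = s_matrix(mixed_nuclide, ph, tab, regions, regions)
        acc = np.zeros_like(sm.total)
        for mat in sm.by_type.values():
            assert np.all(mat >= 0)
            acc += mat
        np.testing.assert_allclose(acc, sm.total, rtol=1e-9)

    def test_whole_body_closure_on_conserving_fixture(
        self, conserving_phantom, mixed_nuclide
    ):
        # sum_T m_T S(T<-S) equals the total emitted energy per nt (in J)
        ph, tab = conserving_phantom
        regions = list(ph.region_masses)
        sm = s_matrix(mixed_nuclide, ph, tab, regions, regions)
        delta_j = mixed_nuclide.total_delta_mev() * MEV_TO_J
        for j in range(len(regions)):
            total = sum(ph.region_masses[t] * sm.total[i, j]
                        for i, t in enumerate(regions))
            assert total == pytest.approx(delta_j, rel=1e-6)

    def test_other_column_composed_on_demand(self, conserving_phantom, mixed_nuclide):
        ph, tab = conserving_phantom
        import copy

        tab = copy.deepcopy(tab)
        regions = list(ph.region_masses)
        model = {regions[0]}
        sm = s_matrix(mixed_nuclide, ph, tab, [regions[0], "Other"], regions)
        # Other = mass-weighted mean over the remaining constituents
        rest = regions[1:]
        m_tot = sum(ph.region_masses[r] for r in rest)
        for i, t in enumerate(regions):
            manual = sum(
                ph.region_masses[r] * s_value(mixed_nuclide, tab, t, r) for r in rest
            ) / m_tot
            assert sm.value(t, "Other") == pytest.approx(manual, rel=1e-10)
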