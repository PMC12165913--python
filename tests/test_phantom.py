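"""SAF storage, energy interpolation, Other composition, blood rule,
and the 100-day infant derivation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nmdose.phantom import (
    INFANT_FRACTION_100D,
    AgeClass,
    Phantom,
    PhantomError,
    SAFTable,
    Sex,
    apply_blood_rule,
    compose_other_saf,
    infant_s,
    normalize_region,
    read_saf_fixture,
    saf_at_energy,
    write_saf_fixture,
)


def small_table(grid, phi_by_pair, rtype="photon"):
    tab = SAFTable("adult_male")
    tab.set_grid(rtype, grid)
    for (t, s), v in phi_by_pair.items():
        tab.set_phi(rtype, t, s, v)
    return tab


def two_region_phantom(masses, **kw):
    return Phantom(
        sex=Sex.MALE,
        age_class=AgeClass.ADULT,
        total_mass_kg=sum(masses.values()),
        region_masses=masses,
        **kw,
    )


class TestSafInterpolation:
    def test_grid_node_returns_stored_value(self):
        tab = small_table([0.1, 1.0], {("t", "s"): [1e-2, 1e-3]})
        assert saf_at_energy(tab, "t", "s", "photon", 0.1) == 1e-2
        assert saf_at_energy(tab, "t", "s", "photon", 1.0) == 1e-3

    def test_loglog_midpoint_is_geometric_mean(self):
        # E = 10^-0.5 is the log-midpoint of [0.1, 1.0]; log-log linear
        # interpolation of {1e-2, 1e-3} gives 10^-2.5
        tab = small_table([0.1, 1.0], {("t", "s"): [1e-2, 1e-3]})
        got = saf_at_energy(tab, "t", "s", "photon", 10 ** -0.5)
        assert got == pytest.approx(10 ** -2.5, rel=1e-12)

    def test_constant_phi_everywhere(self):
        tab = small_table([0.01, 0.1, 1.0], {("t", "s"): [0.7, 0.7, 0.7]})
        for e in [0.001, 0.05, 0.3, 5.0]:
            assert saf_at_energy(tab, "t", "s", "photon", e) == pytest.approx(0.7)

    def test_clamps_outside_grid(self):
        tab = small_table([0.1, 1.0], {("t", "s"): [3.0, 5.0]})
        assert saf_at_energy(tab, "t", "s", "photon", 1e-4) == 3.0
        assert saf_at_energy(tab, "t", "s", "photon", 50.0) == 5.0

    def test_monotone_between_monotone_nodes(self):
        tab = small_table([0.1, 0.5, 2.0], {("t", "s"): [1.0, 2.0, 8.0]})
        energies = np.geomspace(0.1, 2.0, 40)
        values = [saf_at_energy(tab, "t", "s", "photon", e) for e in energies]
        assert np.all(np.diff(values) >= -1e-15)

    def test_unknown_pair_lists_available_sources(self):
        tab = small_table([0.1, 1.0], {("t", "s"): [1.0, 1.0]})
        with pytest.raises(PhantomError, match="available sources: s"):
            saf_at_energy(tab, "t", "nope", "photon", 0.5)

    def test_zero_phi_segment_falls_back_linearly(self):
        tab = small_table([0.1, 1.0], {("t", "s"): [0.0, 2.0]})
        v = saf_at_energy(tab, "t", "s", "photon", 10 ** -0.5)
        assert v == pytest.approx(1.0)  # log-midpoint, linear mix of 0 and 2


class TestComposeOther:
    grid = [0.1, 1.0]

    def test_single_constituent_reproduces_its_phi(self):
        tab = small_table(self.grid, {("t", "a"): [4.0, 2.0]})
        ph = two_region_phantom({"a": 1.5, "t": 1.0}, other_constituents=["a"])
        out = compose_other_saf(tab, set(), ph)
        np.testing.assert_allclose(out[("photon", "t")], [4.0, 2.0])

    def test_equal_masses_give_arithmetic_mean(self):
        tab = small_table(self.grid, {("t", "a"): [4.0, 4.0], ("t", "b"): [8.0, 8.0]})
        ph = two_region_phantom({"a": 2.0, "b": 2.0, "t": 1.0},
                                other_constituents=["a", "b"])
        out = compose_other_saf(tab, set(), ph)
        np.testing.assert_allclose(out[("photon", "t")], [6.0, 6.0])

    def test_mass_weighted_mean(self):
        # (1*4 + 3*8) / 4 = 7
        tab = small_table(self.grid, {("t", "a"): [4.0, 4.0], ("t", "b"): [8.0, 8.0]})
        ph = two_region_phantom({"a": 1.0, "b": 3.0, "t": 1.0},
                                other_constituents=["a", "b"])
        out = compose_other_saf(tab, set(), ph)
        np.testing.assert_allclose(out[("photon", "t")], [7.0, 7.0])

    def test_model_sources_are_excluded(self):
        tab = small_table(self.grid, {("t", "a"): [4.0, 4.0], ("t", "b"): [8.0, 8.0]})
        ph = two_region_phantom({"a": 1.0, "b": 3.0, "t": 1.0},
                                other_constituents=["a", "b"])
        out = compose_other_saf(tab, {"a"}, ph)
        np.testing.assert_allclose(out[("photon", "t")], [8.0, 8.0])

    def test_empty_constituents_error(self):
        tab = small_table(self.grid, {("t", "a"): [4.0, 4.0]})
        ph = two_region_phantom({"a": 1.0, "t": 1.0}, other_constituents=["a"])
        with pytest.raises(PhantomError, match="no constituents"):
            compose_other_saf(tab, {"a"}, ph)

    def test_composition_respects_conservation_bound(self, conserving_phantom):
        ph, tab = conserving_phantom
        out = compose_other_saf(tab, set(), ph)
        for rtype in tab.rtypes():
            total = sum(
                ph.region_masses[t] * out[(rtype, t)] for t in tab.targets(rtype)
            )
            assert np.all(total <= 1.0 + 1e-9)


class TestBloodRule:
    def make_phantom(self, blood):
        return two_region_phantom(
            {"liver": 1.8, "spleen": 0.15, "muscle": 29.0},
            blood_fractions=blood,
            other_constituents=["liver", "spleen", "muscle"],
        )

    def test_explicit_blood_leaves_composition_unchanged(self):
        ph = self.make_phantom({"large_vessels": 0.07})
        w = apply_blood_rule({"Blood", "liver"}, ph)
        assert w == {"spleen": 0.15, "muscle": 29.0}

    def test_missing_blood_folds_vessel_share_into_other(self):
        ph = self.make_phantom({"large_vessels": 0.07})
        w = apply_blood_rule({"liver"}, ph)
        assert w["large_vessels"] == pytest.approx(0.07)
        assert set(w) == {"spleen", "muscle", "large_vessels"}

    def test_all_zero_blood_fractions_match_no_rule(self):
        ph = self.make_phantom({"large_vessels": 0.0})
        assert apply_blood_rule({"liver"}, ph) == {"spleen": 0.15, "muscle": 29.0}


class TestInfantDerivation:
    def test_equal_inputs_are_a_fixed_point(self):
        assert infant_s(3.3, 3.3) == pytest.approx(3.3, rel=1e-15)

    def test_unit_difference_gives_published_fraction(self):
        assert infant_s(1.0, 0.0) == INFANT_FRACTION_100D == 0.6528

    def test_complement_weight(self):
        assert infant_s(0.0, 1.0) == pytest.approx(0.3472, rel=1e-12)

    def test_elementwise_on_matrices(self):
        s1 = np.array([[1.0, 2.0], [0.0, 4.0]])
        s0 = np.zeros((2, 2))
        np.testing.assert_allclose(infant_s(s1, s0), 0.6528 * s1)

    @settings(derandomize=True, max_examples=50)
    @given(
        s0=st.floats(0, 1e3, allow_nan=False),
        s1=st.floats(0, 1e3, allow_nan=False),
    )
    def test_order_preserving_between_endpoints(self, s0, s1):
        lo, hi = min(s0, s1), max(s0, s1)
        assert lo - 1e-9 <= infant_s(s1, s0) <= hi + 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(PhantomError):
            infant_s(np.ones(3), np.ones(2))


class TestVocabularyAndIO:
    def test_alias_normalization(self):
        assert normalize_region("Urinary bladder wall") == "UB-wall"
        assert normalize_region("remainder") == "Other"
        assert normalize_region("Liver") == "Liver"

    def test_strict_mode_rejects_unknown(self):
        with pytest.raises(PhantomError, match="known regions"):
            normalize_region("Flux capacitor", strict=True, known={"Liver"})

    def test_saf_fixture_roundtrip(self, tmp_path, conserving_phantom):
        ph, tab = conserving_phantom
        path = str(tmp_path / "saf")
        write_saf_fixture(path, {ph.id: ph}, {ph.id: tab})
        phantoms, tables = read_saf_fixture(path)
        ph2, tab2 = phantoms[ph.id], tables[ph.id]
        assert ph2.region_masses == pytest.approx(ph.region_masses)
        assert ph2.other_constituents == ph.other_constituents
        for rtype in tab.rtypes():
            np.testing.assert_allclose(tab2.energy_grids[rtype],
                                       tab.energy_grids[rtype])
            for t in tab.targets(rtype):
                for s in tab.sources(rtype):
                    np.testing.assert_allclose(
                        tab2.phi(rtype, t, s), tab.phi(rtype, t, s)
                    )

    def test_energy_balance_validation(self, conserving_phantom):
        ph, tab = conserving_phantom
        tab.validate_energy_balance(ph.region_masses)
        bad = SAFTable("x")
        bad.set_grid("photon", [1.0])
        bad.set_phi("photon", "t", "s", [3.0])
        with pytest.raises(PhantomError, match="exceeds emitted energy"):
            bad.validate_energy_balance({"t": 1.0})

    def test_negative_mass_rejected(self):
        with pytest.raises(PhantomError):
            two_region_phantom({"a": -1.0})
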