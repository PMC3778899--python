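"""Mass arithmetic, scan definitions and species notation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidflux.errors import ConfigurationError
from lipidflux.registry import (
    HEAD_GROUP_SCANS,
    Label,
    LipidClass,
    LipidSpecies,
    chain_delta,
    class_anchor,
    enumerate_species,
    format_species,
    monoisotopic_mz,
    parse_species,
    species_mz,
    total_carbons,
)

# Even-carbon PC/PS/PI lattice species for property tests.
gpl_species = st.builds(
    LipidSpecies,
    lipid_class=st.sampled_from([LipidClass.PC, LipidClass.PS, LipidClass.PI]),
    carbons=st.integers(14, 24).map(lambda c: 2 * c),
    double_bonds=st.integers(0, 6),
)


class TestChainDelta:
    @pytest.mark.parametrize(
        "a, b, expected",
        [((34, 1), (36, 2), 26), ((36, 2), (36, 2), 0), ((36, 2), (36, 1), 2)],
    )
    def test_ladder_steps(self, a, b, expected):
        assert chain_delta(*a, *b) == expected

    @given(st.tuples(st.integers(24, 48), st.integers(0, 8)),
           st.tuples(st.integers(24, 48), st.integers(0, 8)))
    def test_antisymmetric(self, a, b):
        assert chain_delta(*a, *b) == -chain_delta(*b, *a)


class TestPrintedPeakPositions:
    """The one-decimal ladder must reproduce every printed peak position."""

    @pytest.mark.parametrize(
        "text, label, expected",
        [
            ("PC 16:0/18:1", Label.NONE, 760.8),
            ("PC 18:0/18:2", Label.NONE, 786.8),
            ("PC 16:0/18:1", Label.D9_CHOLINE, 769.8),
            ("PC 18:0/18:2", Label.D9_CHOLINE, 795.8),
            ("PS 18:0/18:1", Label.NONE, 788.9),
            # the source rounds this one to 763.8; the ladder value is 763.9
            ("PS 16:0/18:1", Label.D3_SERINE, 763.9),
            ("PS 18:0/18:2", Label.D3_SERINE, 789.9),
            ("PS 18:0/18:1", Label.D3_SERINE, 791.9),
            ("PS 18:0/20:4", Label.D3_SERINE, 813.9),
        ],
    )
    def test_head_group_ladder(self, text, label, expected):
        assert species_mz(parse_species(text, label)) == pytest.approx(expected, abs=1e-9)

    def test_pi_anchor_derived_from_monoisotopic(self):
        anchor = class_anchor(LipidClass.PI)
        assert anchor.anchor_species == parse_species("PI 18:0/20:4")
        assert anchor.anchor_mz == pytest.approx(885.5)
        assert monoisotopic_mz(anchor.anchor_species) == pytest.approx(885.5499, abs=5e-4)


class TestScanDefinitions:
    @pytest.mark.parametrize(
        "name, cls, label, diagnostic, polarity",
        [
            ("P184+", LipidClass.PC, Label.NONE, 184.0, "+"),
            ("P193+", LipidClass.PC, Label.D9_CHOLINE, 193.0, "+"),
            ("P241-", LipidClass.PI, Label.NONE, 241.0, "-"),
            ("P247-", LipidClass.PI, Label.D6_INOSITOL, 247.0, "-"),
            ("NL87-", LipidClass.PS, Label.NONE, 87.0, "-"),
            ("NL90-", LipidClass.PS, Label.D3_SERINE, 90.0, "-"),
        ],
    )
    def test_diagnostics(self, name, cls, label, diagnostic, polarity):
        scan = HEAD_GROUP_SCANS[name]
        assert scan.lipid_class is cls
        assert scan.label is label
        assert scan.diagnostic == diagnostic
        assert scan.polarity == polarity


class TestSpeciesMz:
    @given(gpl_species)
    def test_label_shift_exact(self, sp):
        label = {LipidClass.PC: Label.D9_CHOLINE, LipidClass.PS: Label.D3_SERINE,
                 LipidClass.PI: Label.D6_INOSITOL}[sp.lipid_class]
        shift = species_mz(sp.with_label(label)) - species_mz(sp)
        assert shift == pytest.approx(label.n_deuterium, abs=1e-9)

    @pytest.mark.parametrize("mode", ["paper_nominal", "monoisotopic"])
    def test_both_modes_affine_in_composition(self, mode):
        # f(c+2,d) - f(c,d) and f(c,d+1) - f(c,d) constant over the lattice
        def f(c, d):
            return species_mz(LipidSpecies(LipidClass.PC, c, d), mode)

        c_steps = {round(f(c + 2, 2) - f(c, 2), 6) for c in (30, 32, 34, 36)}
        d_steps = {round(f(34, d + 1) - f(34, d), 6) for d in (0, 1, 2, 3)}
        assert len(c_steps) == 1
        assert len(d_steps) == 1

    def test_monoisotopic_known_ions(self):
        # literature monoisotopic adduct masses
        assert monoisotopic_mz(parse_species("PC 16:0/18:1")) == pytest.approx(760.5851, abs=1e-3)
        assert monoisotopic_mz(parse_species("PS 18:0/18:1")) == pytest.approx(788.5447, abs=1e-3)
        assert monoisotopic_mz(parse_species("Cer 16:0")) == pytest.approx(538.5194, abs=1e-3)

    def test_monoisotopic_label_shift(self):
        sp = parse_species("PC 16:0/18:1")
        shift = monoisotopic_mz(sp.with_label(Label.D9_CHOLINE)) - monoisotopic_mz(sp)
        assert shift == pytest.approx(9 * 1.00628, abs=1e-4)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            species_mz(parse_species("PC 34:1"), "average")

    def test_total_carbons_includes_backbone_and_head(self):
        assert total_carbons(parse_species("PC 34:1")) == 42
        assert total_carbons(parse_species("PC 36:2")) == 44
        assert total_carbons(parse_species("PI 38:4")) == 47


class TestEnumerate:
    def test_small_lattices(self):
        assert len(enumerate_species(LipidClass.PC, (32, 34), (0, 1))) == 4
        assert enumerate_species(LipidClass.PI, (38, 38), (4, 4)) == [
            LipidSpecies(LipidClass.PI, 38, 4)
        ]
        assert len(enumerate_species(LipidClass.PC, (28, 44), (0, 6))) == 63

    def test_empty_range(self):
        assert enumerate_species(LipidClass.PC, (34, 32), (0, 1)) == []

    def test_sorted_strictly_increasing_no_ties(self):
        species = enumerate_species(LipidClass.PC, (28, 44), (0, 6))
        mzs = [species_mz(sp) for sp in species]
        assert all(b > a for a, b in zip(mzs, mzs[1:]))

    def test_odd_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            enumerate_species(LipidClass.PC, (29, 43), (0, 6))


class TestNotation:
    @given(gpl_species)
    def test_round_trip_totals(self, sp):
        assert parse_species(format_species(sp)) == sp
        assert format_species(parse_species(format_species(sp))) == format_species(sp)

    @pytest.mark.parametrize("text", ["PC 16:0/18:1", "PS 18:0/20:4", "Cer 24:1",
                                      "Sph 18:0", "TAG 52:2", "Chol", "CL 72:8"])
    def test_round_trip_text(self, text):
        assert format_species(parse_species(text)) == text

    def test_sn_alias_equals_total_composition(self):
        assert parse_species("PC 16:0/18:1") == parse_species("PC 34:1")
        assert hash(parse_species("PC 16:0/18:1")) == hash(parse_species("PC 34:1"))

    def test_inconsistent_sn_rejected(self):
        with pytest.raises(ConfigurationError):
            LipidSpecies(LipidClass.PC, 34, 1, sn_name="16:0/18:2")

    @pytest.mark.parametrize("bad", ["XX 34:1", "PC", "PC 34", "PC a:b"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            parse_species(bad)


class TestValidation:
    def test_odd_glycerophospholipid_rejected(self):
        with pytest.raises(ConfigurationError):
            LipidSpecies(LipidClass.PC, 33, 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            LipidSpecies(LipidClass.PC, 50, 1)
        with pytest.raises(ConfigurationError):
            LipidSpecies(LipidClass.PC, 34, 9)

    def test_label_chemistry_enforced(self):
        with pytest.raises(ConfigurationError):
            LipidSpecies(LipidClass.PC, 34, 1, Label.D6_INOSITOL)
        with pytest.raises(ConfigurationError):
            LipidSpecies(LipidClass.PS, 36, 1, Label.D9_CHOLINE)
        # the matching label is fine
        LipidSpecies(LipidClass.PI, 38, 4, Label.D6_INOSITOL)

    def test_odd_carbon_standards_allowed_for_sphingolipids(self):
        assert parse_species("Cer 17:0").carbons == 17
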