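"""Nomenclature parsing, formatting and structural categorisation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from shotgunlipids.lipid_model import (
    GAP_CLOSED_SCHEME,
    LITERAL_SCHEME,
    LipidClass,
    LipidNameError,
    LipidSpecies,
    MissingBaseError,
    NotCategorizableError,
    PartitionGapError,
    SchemeConfigurationError,
    SphingoidBase,
    UnknownLipidClassError,
    carbon_bin,
    category_scheme,
    chain_length_category,
    double_bond_bin,
    format_species_name,
    parse_species_name,
    saturation_category,
    sn1_base_partition,
)


class TestParsing:
    def test_ceramide_base_acyl_dialect(self):
        sp = parse_species_name("Cer d18:1/6:0")
        assert sp.lipid_class is LipidClass.CER
        assert sp.base == SphingoidBase(18, 1, 6, 0)
        assert sp.total_carbons == 24 and sp.total_double_bonds == 1

    @pytest.mark.parametrize(
        "name, cls, carbons, dbs",
        [
            ("PC aa C30:0", LipidClass.PC_AA, 30, 0),
            ("PC ae C40:6", LipidClass.PC_AE, 40, 6),
            ("Lyso-PC C18:1", LipidClass.LYSO_PC, 18, 1),
            ("SM C34:1", LipidClass.SM, 34, 1),
            ("TAG C52:3", LipidClass.TAG, 52, 3),
            ("Cer C34:1", LipidClass.CER, 34, 1),
        ],
    )
    def test_sum_composition_dialect(self, name, cls, carbons, dbs):
        sp = parse_species_name(name)
        assert (sp.lipid_class, sp.total_carbons, sp.total_double_bonds) == (cls, carbons, dbs)
        assert sp.base is None

    def test_cholesterol_is_chainless(self):
        sp = parse_species_name("Cholesterol")
        assert sp.lipid_class is LipidClass.CHOL
        assert sp.total_carbons == 0

    def test_unknown_class_prefix(self):
        with pytest.raises(UnknownLipidClassError, match="XYZ"):
            parse_species_name("XYZ C10:1")

    @pytest.mark.parametrize("bad", ["", "  ", "PC aa 30:0", "SM C34", "Cer d18:1"])
    def test_malformed_names(self, bad):
        with pytest.raises(LipidNameError):
            parse_species_name(bad)

    def test_impossible_double_bond_count_rejected(self):
        with pytest.raises(ValueError, match="double bonds"):
            parse_species_name("SM C10:9")

    @pytest.mark.parametrize(
        "species, expected",
        [
            (LipidSpecies(LipidClass.LYSO_PC, 18, 1), "Lyso-PC C18:1"),
            (LipidSpecies(LipidClass.SM, 34, 1), "SM C34:1"),
            (LipidSpecies(LipidClass.CHOL, 0, 0), "Cholesterol"),
        ],
    )
    def test_canonical_formatting(self, species, expected):
        assert format_species_name(species) == expected

    def test_round_trip_over_full_panel(self, panel):
        for name in panel["name"]:
            assert format_species_name(parse_species_name(name)) == name

    @given(
        cls=st.sampled_from([LipidClass.PC_AA, LipidClass.PC_AE, LipidClass.LYSO_PC,
                             LipidClass.SM, LipidClass.TAG]),
        carbons=st.integers(2, 60),
        data=st.data(),
    )
    def test_round_trip_property(self, cls, carbons, data):
        dbs = data.draw(st.integers(0, carbons // 2))
        sp = LipidSpecies(cls, carbons, dbs)
        assert parse_species_name(format_species_name(sp)) == sp


class TestSaturation:
    @pytest.mark.parametrize(
        "name, cat",
        [
            ("PC aa C36:0", "SFA"),
            ("PC ae C34:1", "MUFA"),
            ("Lyso-PC C20:4", "PUFA"),
            ("Cer d18:1/24:0", "SFA"),  # classified on the N-acyl chain
            ("Cer d18:1/24:1", "MUFA"),
        ],
    )
    def test_categories(self, name, cat):
        assert saturation_category(parse_species_name(name)) == cat

    def test_cholesterol_not_categorizable(self):
        with pytest.raises(NotCategorizableError):
            saturation_category(parse_species_name("Cholesterol"))

    @given(carbons=st.integers(12, 50), dbs=st.integers(0, 5))
    def test_more_double_bonds_never_less_unsaturated(self, carbons, dbs):
        order = {"SFA": 0, "MUFA": 1, "PUFA": 2}
        a = saturation_category(LipidSpecies(LipidClass.SM, carbons, dbs))
        b = saturation_category(LipidSpecies(LipidClass.SM, carbons, dbs + 1))
        assert order[b] >= order[a]


class TestChainLength:
    @pytest.mark.parametrize(
        "name, bin_",
        [
            ("PC aa C30:0", "short"),
            ("PC aa C32:0", "medium"),
            ("PC aa C38:2", "long"),
            ("Lyso-PC C18:1", "medium"),
            ("SM C42:2", "long"),
            ("SM C32:1", "medium"),   # gap-closed assigns the printed gap
            ("SM C40:1", "long"),
            ("Cer d18:1/14:0", "short"),
            ("Cer d18:1/18:0", "medium"),
            ("Cer d18:1/22:0", "long"),
        ],
    )
    def test_default_scheme(self, name, bin_):
        assert chain_length_category(parse_species_name(name), GAP_CLOSED_SCHEME) == bin_

    def test_literal_scheme_leaves_sm_gaps(self):
        assert chain_length_category(parse_species_name("SM C34:1"), LITERAL_SCHEME) == "medium"
        with pytest.raises(PartitionGapError):
            chain_length_category(parse_species_name("SM C32:1"), LITERAL_SCHEME)
        with pytest.raises(PartitionGapError):
            chain_length_category(parse_species_name("SM C40:1"), LITERAL_SCHEME)

    def test_gap_closed_scheme_partitions_whole_panel(self, panel):
        for name in panel["name"]:
            sp = parse_species_name(name)
            if sp.lipid_class is LipidClass.CHOL:
                continue
            assert chain_length_category(sp, GAP_CLOSED_SCHEME) in ("short", "medium", "long")

    def test_unknown_scheme_and_missing_class(self):
        with pytest.raises(SchemeConfigurationError):
            category_scheme("nope")
        with pytest.raises(NotCategorizableError):
            chain_length_category(parse_species_name("Cholesterol"))


class TestProfileBins:
    @pytest.mark.parametrize(
        "name, label",
        [("PC ae C40:6", "X:6"), ("Cer d18:1/24:0", "X:0"), ("SM C34:1", "X:1")],
    )
    def test_double_bond_bin(self, name, label):
        assert double_bond_bin(parse_species_name(name)) == label

    @pytest.mark.parametrize(
        "name, label",
        [("PC aa C30:2", "C30:X"), ("Lyso-PC C6:0", "C6:X"), ("Cer d18:1/18:0", "C18:X")],
    )
    def test_carbon_bin(self, name, label):
        assert carbon_bin(parse_species_name(name)) == label

    def test_carbon_bin_cer_total_option(self):
        sp = parse_species_name("Cer d18:1/2:0")
        assert carbon_bin(sp) == "C2:X"
        assert carbon_bin(sp, cer_carbons="total") == "C20:X"


class TestSn1Partition:
    def test_partition_by_base(self):
        sps = [parse_species_name("Cer d18:1/16:0"), parse_species_name("Cer d18:2/16:0")]
        part = sn1_base_partition(sps)
        assert part == {"C18:1": [sps[0]], "C18:2": [sps[1]]}

    def test_default_panel_has_two_bases(self, panel):
        cer = [parse_species_name(n) for n in panel.loc[panel["lipid_class"] == "CER", "name"]]
        part = sn1_base_partition(cer)
        assert set(part) == {"C18:1", "C18:2"}
        assert sum(len(v) for v in part.values()) == len(cer)

    def test_total_form_ceramide_rejected(self):
        with pytest.raises(MissingBaseError):
            sn1_base_partition([parse_species_name("Cer C34:1")])
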