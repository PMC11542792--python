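"""Parsing, canonical formatting and chemical predicates of lipid names."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidtraffic import (
    FattyAcyl,
    LipidNameError,
    contains_fatty_acid,
    format_lipid_name,
    is_essential_pufa_containing,
    is_odd_chain,
    parse_lipid_name,
    species_dictionary,
)
from lipidtraffic.nomenclature import AmbiguousResolutionWarning


@pytest.mark.parametrize(
    "name, cls, chains, sum_c, sum_d, resolution",
    [
        ("TG(15:0/16:0/18:1)", "TG", [(15, 0), (16, 0), (18, 1)], 49, 1, "molecular"),
        ("TG(52:6)", "TG", [], 52, 6, "sum"),
        ("PI(18:1/20:5)", "PI", [(18, 1), (20, 5)], 38, 6, "molecular"),
        ("PC(34:1)", "PC", [], 34, 1, "sum"),
        ("AC(16:0)", "AC", [(16, 0)], 16, 0, "molecular"),
        ("LPC(22:6)", "LPC", [(22, 6)], 22, 6, "molecular"),
    ],
)
def test_parse_structured_identity(name, cls, chains, sum_c, sum_d, resolution):
    sp = parse_lipid_name(name)
    assert sp.class_code == cls
    assert [(c.carbons, c.double_bonds) for c in sp.chains] == chains
    assert sp.sum_carbons == sum_c
    assert sp.sum_double_bonds == sum_d
    assert sp.resolution == resolution


@pytest.mark.parametrize(
    "bad",
    ["XX(1:2)", "TG", "TG()", "TG(16:0/seventeen:1)", "TG(16:0//18:1)", "(16:0)", "TG(16:-1)"],
)
def test_rejection_names_offending_token(bad):
    with pytest.raises(LipidNameError):
        parse_lipid_name(bad)


def test_chain_order_is_not_meaningful():
    a = parse_lipid_name("TG(18:1/16:0/15:0)")
    b = parse_lipid_name("TG(15:0/16:0/18:1)")
    assert a.identity == b.identity
    assert a.name == b.name


def test_adduct_stripped_from_identity():
    plain = parse_lipid_name("TG(16:0/18:1/18:2)")
    adduct = parse_lipid_name("TG(16:0/18:1/18:2)+NH4")
    assert adduct.adduct == "NH4"
    assert adduct.identity == plain.identity


def test_sphingolipids_map_to_sls_and_keep_base_distinct():
    sm = parse_lipid_name("SM(d18:1/16:0)")
    assert sm.analysis_class() == "SLs"
    assert sm.class_code == "SM"
    # the sphingoid base d18:1 is not an acyl FA(18:1)
    assert not contains_fatty_acid(sm, FattyAcyl(18, 1))
    assert contains_fatty_acid(sm, FattyAcyl(16, 0))


def test_dg_merge_flag():
    dg = parse_lipid_name("DG(18:1/18:2)")
    assert dg.is_fragment
    assert dg.analysis_class() == "TG"
    assert dg.analysis_class(merge_dg=False) == "DG"


def test_ether_species_flagged_and_excluded_from_odd_chain():
    sp = parse_lipid_name("PC(O-33:2)")
    assert sp.ether == "O"
    assert not is_odd_chain(sp)
    assert is_odd_chain(sp, include_ether=True)


@pytest.mark.parametrize(
    "name, fa, expected",
    [
        ("TG(16:0/16:0/22:6)", (22, 6), True),
        ("TG(16:0/16:0/16:0)", (22, 6), False),
    ],
)
def test_contains_fatty_acid(name, fa, expected):
    assert contains_fatty_acid(parse_lipid_name(name), FattyAcyl(*fa)) is expected


def test_contains_fatty_acid_unknown_at_sum_resolution():
    sp = parse_lipid_name("TG(52:6)")
    with pytest.warns(AmbiguousResolutionWarning):
        assert contains_fatty_acid(sp, FattyAcyl(22, 6)) is False


@pytest.mark.parametrize(
    "name, expected",
    [
        ("TG(15:0/16:0/18:2)", True),
        ("TG(51:3)", True),
        ("TG(18:1/18:1/18:1)", False),
        ("TG(52:6)", False),
    ],
)
def test_is_odd_chain(name, expected):
    assert is_odd_chain(parse_lipid_name(name)) is expected


def test_essential_pufa_predicate():
    assert is_essential_pufa_containing(parse_lipid_name("TG(18:2/18:2/22:6)"))
    assert not is_essential_pufa_containing(parse_lipid_name("TG(18:1/18:1/18:1)"))
    assert is_essential_pufa_containing(
        parse_lipid_name("PC(16:0/22:5)"), {FattyAcyl(22, 5)}
    )


def test_essential_pufa_implies_polyunsaturated_chain():
    for name in ["TG(18:2/18:2/22:6)", "PC(16:0/22:5)", "TG(16:0/16:0/22:6)"]:
        sp = parse_lipid_name(name)
        if is_essential_pufa_containing(sp):
            assert any(c.is_polyunsaturated for c in sp.chains)


_chain = st.tuples(st.integers(2, 30), st.integers(0, 6)).filter(lambda cd: cd[1] <= cd[0])


@given(
    cls=st.sampled_from(["TG", "PC", "PE", "PI", "PS", "PG"]),
    chains=st.lists(_chain, min_size=2, max_size=3),
    data=st.data(),
)
def test_round_trip_and_sum_consistency(cls, chains, data):
    """format(parse(name)) preserves identity under any chain permutation."""
    order = data.draw(st.permutations(chains))
    name = f"{cls}({'/'.join(f'{c}:{d}' for c, d in order)})"
    sp = parse_lipid_name(name)
    assert sp.sum_carbons == sum(c for c, _ in chains)
    assert sp.sum_double_bonds == sum(d for _, d in chains)
    again = parse_lipid_name(format_lipid_name(sp))
    assert again.identity == sp.identity


def test_species_dictionary_round_trip():
    names = ["TG(52:6)", "SM(d18:1/16:0)", "PC(16:0/18:1)+NH4", "DG(18:1/18:2)"]
    d = species_dictionary(names)
    assert list(d["raw_name"]) == names
    assert set(d.columns) >= {"name", "analysis_class", "resolution", "odd_chain"}
    assert d.loc[d["raw_name"] == "SM(d18:1/16:0)", "analysis_class"].item() == "SLs"
    assert d.loc[d["raw_name"] == "DG(18:1/18:2)", "analysis_class"].item() == "TG"
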