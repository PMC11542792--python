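"""A/B/U/N2/Nk typing against the definition and a brute-force oracle."""

from itertools import combinations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidtraffic import (
    SwitchAnalysis,
    classify_pattern,
    classify_presence_sets,
    classify_traffic,
    call_presence,
    generate_cohort,
    SyntheticDesign,
)


def oracle_type(pattern, compartments, edges):
    """Independent restatement of the typing rule by direct enumeration."""
    pattern = set(pattern)
    if not pattern:
        return "absent"
    if pattern == set(compartments):
        return "A"
    if len(pattern) == 1:
        return "U"
    has_edge = any(
        (a, b) in edges or (b, a) in edges for a, b in combinations(sorted(pattern), 2)
    )
    if has_edge:
        return "B"
    return "N2" if len(pattern) == 2 else f"N{len(pattern)}"


def test_definition_examples(mouse_net):
    all10 = set(mouse_net.compartments)
    assert classify_pattern(all10, mouse_net) == "A"
    assert classify_pattern({"liver"}, mouse_net) == "U"
    assert classify_pattern({"plasma", "liver"}, mouse_net) == "B"
    assert classify_pattern({"heart", "eWAT"}, mouse_net) == "N2"
    assert classify_pattern({"plasma", "heart", "eWAT"}, mouse_net) == "B"
    assert classify_pattern({"liver", "heart", "eWAT"}, mouse_net) == "N3"
    assert classify_pattern(set(), mouse_net) == "absent"


def test_network_dependence_of_pair_typing(mouse_net):
    from lipidtraffic import default_network

    linked = default_network("adipose_linked")
    assert classify_pattern({"BAT", "iWAT"}, mouse_net) == "N2"
    assert classify_pattern({"BAT", "iWAT"}, linked) == "B"


def test_legacy_b_mode_has_no_n_types(path_net):
    assert classify_pattern({"a", "c"}, path_net) == "N2"
    assert classify_pattern({"a", "c"}, path_net, mode="legacy_b") == "B"
    assert classify_pattern({"a", "c", "e"}, path_net, mode="legacy_b") == "B"


def test_unknown_compartment_rejected(path_net):
    with pytest.raises(ValueError, match="unknown compartment"):
        classify_pattern({"a", "zz"}, path_net)


@given(
    patterns=st.dictionaries(
        st.sampled_from([f"TG(5{i}:1)" for i in range(8)]),
        st.sets(st.sampled_from(["a", "b", "c", "d", "e"]), min_size=1),
        min_size=1,
        max_size=8,
    )
)
def test_matches_oracle_and_partitions(patterns):
    from lipidtraffic.network import CompartmentNetwork

    net = CompartmentNetwork.from_parts(
        ["a", "b", "c", "d", "e"],
        [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
    )
    edges = {("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")}
    types = classify_presence_sets(patterns, net)
    for sp, pat in patterns.items():
        assert types[sp] == oracle_type(pat, net.compartments, edges)
    # mutually exclusive and exhaustive over species present somewhere
    assert set(types) == set(patterns)


def test_edge_and_unique_lists(mouse_net):
    design = SyntheticDesign(
        class_counts={"TG": {"A": 3, "B": 6, "U": 6, "N2": 3}}, seed=11
    )
    table, truth = generate_cohort(design)
    presence = call_presence(table)
    classified = classify_traffic(presence, mouse_net)
    for g, cls in classified.items():
        a_species = set(cls.species_of_type("A"))
        b_species = set(cls.species_of_type("B"))
        on_edges = set()
        for (ca, cb), species in cls.edge_species.items():
            on_edges |= set(species)
            for sp in species:  # edge list = present in both endpoints, non-A
                assert {ca, cb} <= cls.presence[sp]
                assert cls.types[sp] != "A"
        # every B species appears on at least one edge list, and only B species do
        assert b_species <= on_edges
        assert on_edges == b_species
        assert not (a_species & on_edges)
        # every U species sits in exactly one compartment list
        u_listed = [sp for comp in cls.compartment_unique.values() for sp in comp]
        assert sorted(u_listed) == sorted(cls.species_of_type("U"))
        assert len(set(u_listed)) == len(u_listed)


def test_type_counts_partition_present_species(mouse_net):
    design = SyntheticDesign(
        class_counts={"PC": {"A": 2, "B": 5, "U": 4, "N2": 3}}, seed=3
    )
    table, _ = generate_cohort(design)
    presence = call_presence(table)
    classified = classify_traffic(presence, mouse_net)
    for cls in classified.values():
        counts = cls.type_counts()
        assert counts.loc["all", "present"] == len(cls.present_species)
        assert (
            counts.loc["all", ["A", "B", "U", "N2", "Nk"]].sum()
            == counts.loc["all", "present"]
        )
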