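"""Group comparison (the switch output): alignment, gained/lost, antisymmetry."""

import pytest

from lipidtraffic import (
    SyntheticDesign,
    PresenceEdit,
    call_presence,
    classify_traffic,
    compare_groups,
    generate_cohort,
)


def _classify(table, net):
    return classify_traffic(call_presence(table), net)


def test_identical_groups_show_no_changes(mouse_net):
    design = SyntheticDesign(class_counts={"TG": {"A": 2, "B": 4, "U": 4, "N2": 2}}, seed=5)
    table, _ = generate_cohort(design)
    cls = _classify(table, mouse_net)
    cmp = compare_groups(cls["Room temp."], cls["Cold Exposed"])
    assert cmp.lost == () and cmp.gained == ()
    assert not cmp.species_status["type_changed"].any()
    for changes in (cmp.type_changes, cmp.edge_changes, cmp.compartment_changes):
        for d in changes.values():
            assert d["lost"] == () and d["gained"] == ()


def test_a_type_contraction_reported_as_loss(mouse_net):
    # one A-type species loses a compartment on exposure: A list shrinks by it
    design = SyntheticDesign(
        class_counts={"TG": {"A": 3, "B": 2, "U": 2, "N2": 1}},
        seed=9,
    )
    table, truth = generate_cohort(design)
    a_species = sorted(
        s for s, t in truth.types["Room temp."].items() if t == "A"
    )[0]
    design2 = SyntheticDesign(
        class_counts=design.class_counts,
        seed=9,
        switches=(PresenceEdit(a_species, "heart", "Cold Exposed", present=False),),
    )
    table2, truth2 = generate_cohort(design2)
    cls = _classify(table2, mouse_net)
    cmp = compare_groups(cls["Room temp."], cls["Cold Exposed"])
    assert cmp.type_changes["A"]["lost"] == (a_species,)
    assert truth2.types["Cold Exposed"][a_species] == "B"  # still widespread, now non-A
    assert cmp.species_status.loc[a_species, "status"] == "shared"


def test_planted_switch_moves_unique_species(mouse_net):
    # a liver-unique species relocates to heart in the exposed group
    design = SyntheticDesign(
        class_counts={"PC": {"U": 4}},
        seed=21,
    )
    _, truth = generate_cohort(design)
    liver_unique = [
        s for s, p in truth.presence["Room temp."].items() if p == frozenset({"liver"})
    ]
    if not liver_unique:  # force one into liver deterministically
        sp = sorted(truth.presence["Room temp."])[0]
        design = SyntheticDesign(
            class_counts={"PC": {"U": 4}},
            seed=21,
            switches=(
                PresenceEdit(sp, next(iter(truth.presence["Room temp."][sp])), "Room temp.", False),
                PresenceEdit(sp, "liver", "Room temp.", True),
                PresenceEdit(sp, next(iter(truth.presence["Cold Exposed"][sp])), "Cold Exposed", False),
                PresenceEdit(sp, "liver", "Cold Exposed", True),
            ),
        )
        _, truth = generate_cohort(design)
        liver_unique = [sp]
    sp = liver_unique[0]
    moved = SyntheticDesign(
        class_counts=design.class_counts,
        seed=design.seed,
        switches=design.switches
        + (
            PresenceEdit(sp, "liver", "Cold Exposed", present=False),
            PresenceEdit(sp, "heart", "Cold Exposed", present=True),
        ),
    )
    table, truth_moved = generate_cohort(moved)
    assert truth_moved.presence["Cold Exposed"][sp] == frozenset({"heart"})
    cls = _classify(table, mouse_net)
    cmp = compare_groups(cls["Room temp."], cls["Cold Exposed"])
    assert sp in cmp.compartment_changes["liver"]["lost"]
    assert sp in cmp.compartment_changes["heart"]["gained"]


def test_comparison_is_antisymmetric(mouse_net):
    design = SyntheticDesign(
        class_counts={"TG": {"A": 2, "B": 5, "U": 5, "N2": 2}},
        seed=13,
        switches=(
            PresenceEdit("dummy", "liver", "Cold Exposed", False),
        ),
    )
    # pick a real species for the switch
    base = SyntheticDesign(class_counts=design.class_counts, seed=13)
    _, truth = generate_cohort(base)
    some = sorted(truth.presence["Room temp."])[0]
    design = SyntheticDesign(
        class_counts=design.class_counts,
        seed=13,
        switches=(PresenceEdit(some, "liver", "Cold Exposed", False),
                  PresenceEdit(some, "lung", "Cold Exposed", True)),
    )
    table, _ = generate_cohort(design)
    cls = _classify(table, mouse_net)
    fwd = compare_groups(cls["Room temp."], cls["Cold Exposed"])
    rev = compare_groups(cls["Cold Exposed"], cls["Room temp."])
    assert fwd.lost == rev.gained and fwd.gained == rev.lost
    for t, d in fwd.type_changes.items():
        assert d["lost"] == rev.type_changes[t]["gained"]
        assert d["gained"] == rev.type_changes[t]["lost"]
    for e, d in fwd.edge_changes.items():
        assert d["lost"] == rev.edge_changes[e]["gained"]
    for c, d in fwd.compartment_changes.items():
        assert d["lost"] == rev.compartment_changes[c]["gained"]


def test_mismatched_networks_rejected(mouse_net, path_net):
    design = SyntheticDesign(class_counts={"TG": {"U": 2}}, seed=1)
    table, _ = generate_cohort(design)
    cls = _classify(table, mouse_net)
    with pytest.raises(ValueError, match="different"):
        other = classify_traffic(call_presence(table), mouse_net, mode="legacy_b")
        compare_groups(cls["Room temp."], other["Cold Exposed"])
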