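"""Error-normalised fold change: the formula, qualifiers, oracle agreement."""

import math

import numpy as np
import pandas as pd
import pytest

from lipidtraffic import (
    EnfcAnalysis,
    FoldEffect,
    GroupSummary,
    SyntheticDesign,
    class_total_enfc,
    enfc,
    generate_cohort,
    subset_ratio_enfc,
)
from conftest import table_from_signals


def test_hand_computed_value():
    # log10(100/10) / ((1+1)/2) = 1 / 1 = 1
    r = enfc(GroupSummary(100, 10, 1, 1, 6, 6))
    assert r.enfc == pytest.approx(1.0, abs=1e-15)
    assert r.qualifier == "defined"


def test_equal_means_give_zero():
    r = enfc(GroupSummary(37.5, 37.5, 2.0, 5.0, 6, 6))
    assert r.enfc == 0.0 and r.qualifier == "defined"


def test_antisymmetry_under_group_swap():
    s = GroupSummary(80.0, 12.5, 3.0, 1.5, 6, 6)
    assert enfc(s).enfc == pytest.approx(-enfc(s.swapped()).enfc, abs=1e-15)


@pytest.mark.parametrize(
    "form, expected",
    [
        ("half_sum_sq", 1.0 / 1.0),         # (1+1)/2 = 1
        ("rms", 1.0 / 1.0),                 # sqrt((1+1)/2) = 1
        ("root_sum_sq", 1.0 / math.sqrt(2)),
    ],
)
def test_error_combination_options(form, expected):
    r = enfc(GroupSummary(100, 10, 1, 1, 6, 6), error_form=form)
    assert r.enfc == pytest.approx(expected, abs=1e-12)


def test_unknown_error_form_rejected():
    with pytest.raises(ValueError, match="error_form"):
        enfc(GroupSummary(1, 1, 1, 1, 2, 2), error_form="geometric")


@pytest.mark.parametrize(
    "xe, xc, qualifier, value_nan",
    [
        (0.0, 0.0, "undefined", False),       # value 0, flagged
        (5.0, 0.0, "zero-mean-control", True),
        (0.0, 5.0, "zero-mean-exposed", True),
    ],
)
def test_zero_mean_qualifiers(xe, xc, qualifier, value_nan):
    r = enfc(GroupSummary(xe, xc, 1, 1, 3, 3))
    assert r.qualifier == qualifier
    assert math.isnan(r.enfc) is value_nan
    if not value_nan:
        assert r.enfc == 0.0


def test_zero_error_qualifier():
    r = enfc(GroupSummary(100, 10, 0.0, 0.0, 3, 3))
    assert r.qualifier == "zero-error" and math.isnan(r.enfc)
    r0 = enfc(GroupSummary(10, 10, 0.0, 0.0, 3, 3))
    assert r0.enfc == 0.0


def test_scale_invariance_under_log_errors():
    rng = np.random.default_rng(0)
    e, c = rng.lognormal(3, 0.3, 6), rng.lognormal(2.5, 0.3, 6)
    base = enfc(GroupSummary.from_replicates(e, c, error_scale="log10"))
    scaled = enfc(GroupSummary.from_replicates(1e4 * e, 1e4 * c, error_scale="log10"))
    assert scaled.enfc == pytest.approx(base.enfc, rel=1e-12)


def _two_group_table():
    """Two TG species and one PC in two tissues, asymmetric groups."""
    cells = {}
    sig = {
        ("TG(16:0/16:0/16:0)", "liver", "control"): [100, 110, 90, 105],
        ("TG(16:0/16:0/16:0)", "liver", "exposed"): [210, 190, 200, 220],
        ("TG(16:0/16:0/22:6)", "liver", "control"): [50, 55, 45, 52],
        ("TG(16:0/16:0/22:6)", "liver", "exposed"): [48, 51, 55, 47],
        ("TG(16:0/16:0/16:0)", "heart", "control"): [80, 85, 78, 82],
        ("TG(16:0/16:0/16:0)", "heart", "exposed"): [40, 42, 38, 41],
        ("TG(16:0/16:0/22:6)", "heart", "control"): [20, 22, 19, 21],
        ("TG(16:0/16:0/22:6)", "heart", "exposed"): [21, 20, 22, 19],
        ("PC(16:0/18:1)", "liver", "control"): [10, 12, 9, 11],
        ("PC(16:0/18:1)", "liver", "exposed"): [11, 10, 12, 9],
        ("PC(16:0/18:1)", "heart", "control"): [5, 6, 5, 6],
        ("PC(16:0/18:1)", "heart", "exposed"): [6, 5, 6, 5],
    }
    for (lip, tis, grp), s in sig.items():
        cells[(lip, "TG" if lip.startswith("TG") else "PC", tis, grp)] = s
    return table_from_signals(cells)


def test_class_total_agrees_with_brute_force_oracle():
    t = _two_group_table()
    rec = class_total_enfc(t, "TG", "liver", control="control", exposed="exposed")
    # oracle: sum per replicate, then means/SDs, by hand with numpy only
    ctrl = np.array([100 + 50, 110 + 55, 90 + 45, 105 + 52], float)
    expo = np.array([210 + 48, 190 + 51, 200 + 55, 220 + 47], float)
    num = np.log10(expo.mean() / ctrl.mean())
    den = (expo.std(ddof=1) ** 2 + ctrl.std(ddof=1) ** 2) / 2
    assert rec.enfc == pytest.approx(num / den, abs=1e-12)


def test_subset_ratio_agrees_with_brute_force_oracle():
    t = _two_group_table()
    subset = {"TG(16:0/16:0/22:6)"}
    rec = subset_ratio_enfc(
        t, subset, "TG", "heart", control="control", exposed="exposed"
    )
    r_ctrl = np.array([20 / 80, 22 / 85, 19 / 78, 21 / 82])
    r_expo = np.array([21 / 40, 20 / 42, 22 / 38, 19 / 41])
    num = np.log10(r_expo.mean() / r_ctrl.mean())
    den = (r_expo.std(ddof=1) ** 2 + r_ctrl.std(ddof=1) ** 2) / 2
    assert rec.enfc == pytest.approx(num / den, abs=1e-12)


def test_all_zero_subset_gives_zero_flagged():
    cells = {
        ("TG(16:0/16:0/22:6)", "TG", "liver", "control"): [0, 0, 0],
        ("TG(16:0/16:0/22:6)", "TG", "liver", "exposed"): [0, 0, 0],
        ("TG(16:0/16:0/16:0)", "TG", "liver", "control"): [10, 11, 9],
        ("TG(16:0/16:0/16:0)", "TG", "liver", "exposed"): [10, 9, 11],
    }
    rec = subset_ratio_enfc(
        table_from_signals(cells), {"TG(16:0/16:0/22:6)"}, "TG", "liver",
        control="control", exposed="exposed",
    )
    assert rec.enfc == 0.0 and rec.qualifier == "undefined"


def test_zero_complement_replicate_excluded_with_warning():
    cells = {
        ("TG(16:0/16:0/22:6)", "TG", "liver", "control"): [5, 5, 5],
        ("TG(16:0/16:0/22:6)", "TG", "liver", "exposed"): [5, 5, 5],
        ("TG(16:0/16:0/16:0)", "TG", "liver", "control"): [10, 0, 10],  # r2 complement = 0
        ("TG(16:0/16:0/16:0)", "TG", "liver", "exposed"): [10, 10, 10],
    }
    with pytest.warns(UserWarning, match="excluded 1 replicate"):
        rec = subset_ratio_enfc(
            table_from_signals(cells), {"TG(16:0/16:0/22:6)"}, "TG", "liver",
            control="control", exposed="exposed",
        )
    assert rec.summary.n_control == 2 and rec.summary.n_exposed == 3


def test_planted_halving_detected_only_in_target_compartment(mouse_net):
    design = SyntheticDesign(
        class_counts={"TG": {"A": 6}},
        log10_sd=0.05,
        seed=4,
        effects=(FoldEffect("TG", "heart", 0.5),),
    )
    table, _ = generate_cohort(design)
    est = EnfcAnalysis(error_scale="log10").fit(table)
    tg = est.class_totals_[est.class_totals_["class"] == "TG"].set_index("compartment")
    assert tg.loc["heart", "enfc"] < 0
    others = tg.drop(index="heart")
    assert (others["enfc"].abs() < abs(tg.loc["heart", "enfc"]) / 2).all()


def test_estimator_group_swap_negates_every_defined_record():
    design = SyntheticDesign(class_counts={"PC": {"B": 8, "U": 4}}, seed=8)
    table, _ = generate_cohort(design)
    fwd = EnfcAnalysis().fit(table).class_totals_
    rev = EnfcAnalysis(control="Cold Exposed", exposed="Room temp.").fit(table).class_totals_
    merged = fwd.merge(rev, on=["class", "compartment"], suffixes=("_f", "_r"))
    defined = merged[merged["qualifier_f"] == "defined"]
    assert len(defined) > 0
    assert np.allclose(defined["enfc_f"], -defined["enfc_r"], atol=1e-12)
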