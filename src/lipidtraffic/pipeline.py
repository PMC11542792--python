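"""Estimator API: the switch and abundance analyses as fit-able objects.

:class:`SwitchAnalysis` and :class:`EnfcAnalysis` follow the scikit-learn
estimator convention — hyperparameters in ``__init__``, ``fit(X)`` on a
tidy abundance DataFrame, results in trailing-underscore attributes — so
they compose with sklearn tooling (``get_params``/``set_params``, cloning)
and so a whole analysis is one object that can be inspected or re-run.
The module-level functions in :mod:`lipidtraffic.presence`,
:mod:`lipidtraffic.classify`, :mod:`lipidtraffic.enfc` and
:mod:`lipidtraffic.jaccard` remain the functional core these estimators
drive.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .classify import TYPE_ORDER, classify_traffic, compare_groups
from .enfc import EnfcRecord, GroupSummary
from .enfc import class_total_enfc as _class_total_enfc
from .enfc import enfc as _enfc_of_summary
from .enfc import subset_ratio_enfc as _subset_ratio_enfc
from .io import infer_groups, prepare_table
from .jaccard import jaccard_test
from .network import CompartmentNetwork, default_network, load_network
from .nomenclature import (
    AmbiguousResolutionWarning,
    DEFAULT_ESSENTIAL_PUFAS,
    FattyAcyl,
    is_essential_pufa_containing,
    parse_lipid_name,
)
from .presence import DEFAULT_THRESHOLD, PresenceMatrix, call_presence

__all__ = ["PresenceCaller", "SwitchAnalysis", "EnfcAnalysis", "compartment_order"]

#: Compartment order used for RADAR-ready exports, so plots are comparable
#: across classes and runs.  Compartments outside this list follow, sorted.
CANONICAL_COMPARTMENT_ORDER = (
    "plasma", "liver", "heart", "lung", "kidney", "small intestine",
    "gastrocnemius", "BAT", "iWAT", "eWAT",
)


def compartment_order(compartments: Iterable[str]) -> list[str]:
    comps = list(dict.fromkeys(compartments))
    known = [c for c in CANONICAL_COMPARTMENT_ORDER if c in comps]
    rest = sorted(c for c in comps if c not in CANONICAL_COMPARTMENT_ORDER)
    return known + rest


def _resolve_network(network) -> CompartmentNetwork:
    if network is None:
        return default_network()
    if isinstance(network, CompartmentNetwork):
        return network
    if isinstance(network, str) and network in ("default", "adipose_linked"):
        return default_network(network)
    return load_network(network)


class PresenceCaller(BaseEstimator):
    """Binary presence calling of lipid variables, sklearn-transformer style.

    ``fit(X)`` computes detection fractions from a tidy abundance table;
    ``transform`` (or the fitted ``matrix_``) exposes the
    :class:`~lipidtraffic.presence.PresenceMatrix`.
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD, merge_dg: bool = True):
        self.threshold = threshold
        self.merge_dg = merge_dg

    def fit(self, X: pd.DataFrame, y=None) -> "PresenceCaller":
        table, species, issues = prepare_table(X, merge_dg=self.merge_dg)
        self.table_ = table
        self.species_ = species
        self.issues_ = issues
        self.matrix_: PresenceMatrix = call_presence(table, threshold=self.threshold)
        return self

    def transform(self, X: pd.DataFrame | None = None) -> PresenceMatrix:
        if X is not None:
            return PresenceCaller(**self.get_params()).fit(X).matrix_
        return self.matrix_

    def fit_transform(self, X: pd.DataFrame, y=None) -> PresenceMatrix:
        return self.fit(X).matrix_


class SwitchAnalysis(BaseEstimator):
    """The switch analysis: presence calling, traffic typing, group alignment
    and Jaccard-Tanimoto statistics, end to end.

    Parameters
    ----------
    network : CompartmentNetwork, path, "default", "adipose_linked" or None
    threshold : presence rule (fraction of replicates with signal > 0).
    mode : "v3" (A/B/U/N2/Nk hierarchy) or "legacy_b" (no N2: every
        multi-compartment non-A variable is B).
    control, exposed : group labels; inferred from the table when omitted.
    n_perm, seed, tie_break : permutation settings for the Jaccard p-values.
    compute_jaccard : skip the permutation stage when False.

    Fitted attributes: ``table_``, ``species_``, ``presence_``,
    ``classification_`` (group -> TrafficClassification), ``comparison_``,
    ``counts_`` (the per-class type-count table), ``jaccard_``.
    """

    def __init__(
        self,
        network=None,
        threshold: float = DEFAULT_THRESHOLD,
        mode: str = "v3",
        control: str | None = None,
        exposed: str | None = None,
        n_perm: int = 10_000,
        seed: int = 0,
        tie_break: str = "smoothed",
        merge_dg: bool = True,
        compute_jaccard: bool = True,
    ):
        self.network = network
        self.threshold = threshold
        self.mode = mode
        self.control = control
        self.exposed = exposed
        self.n_perm = n_perm
        self.seed = seed
        self.tie_break = tie_break
        self.merge_dg = merge_dg
        self.compute_jaccard = compute_jaccard

    # ------------------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "SwitchAnalysis":
        net = _resolve_network(self.network)
        table, species, issues = prepare_table(X, merge_dg=self.merge_dg)
        control, exposed = infer_groups(table["group"], self.control, self.exposed)
        self.network_ = net
        self.table_ = table
        self.species_ = species
        self.issues_ = issues
        self.groups_ = (control, exposed)
        self.species_class_: dict[str, str] = dict(
            zip(species["name"], species["analysis_class"])
        )

        self.presence_ = call_presence(table, threshold=self.threshold)
        self.classification_ = classify_traffic(self.presence_, net, mode=self.mode)
        self.comparison_ = compare_groups(
            self.classification_[control], self.classification_[exposed]
        )
        self.counts_ = self._counts_table()
        self.jaccard_ = self._jaccard_table() if self.compute_jaccard else None
        return self

    # ------------------------------------------------------------------
    def _counts_table(self) -> pd.DataFrame:
        """Per-class layout: detected and present totals, then each type per group."""
        control, exposed = self.groups_
        detected = (
            self.species_.groupby("analysis_class")["name"].nunique().rename("total_detected")
        )
        present_union = sorted(
            self.classification_[control].present_species
            | self.classification_[exposed].present_species
        )
        union_counts = (
            pd.Series([self.species_class_[s] for s in present_union])
            .value_counts()
            .rename("total_present")
        )
        parts = [detected, union_counts]
        for g in self.groups_:
            tc = self.classification_[g].type_counts(self.species_class_)
            tc.columns = [f"{c} ({g})" for c in tc.columns]
            parts.append(tc)
        out = pd.concat(parts, axis=1).fillna(0).astype(int)
        cols = ["total_detected", "total_present"]
        for t in ("present", *TYPE_ORDER, "Nk"):
            cols += [f"{t} ({g})" for g in self.groups_]
        out.index.name = "class"
        return out.reindex(columns=cols).fillna(0).astype(int).sort_index()

    def _jaccard_table(self) -> pd.DataFrame:
        """J and permutation p per class at system, edge and compartment scope.

        Universe per class = all detected species of the class.  Scopes with
        both lists empty are reported with NaN J ("undefined" note) rather
        than a fake 0/0.
        """
        control, exposed = self.groups_
        cls_c = self.classification_[control]
        cls_e = self.classification_[exposed]
        by_class: dict[str, set] = {}
        for sp, cl in self.species_class_.items():
            by_class.setdefault(cl, set()).add(sp)

        rows = []
        counter = 0

        def _one(scope: str, cl: str, a: set, b: set, universe: set):
            nonlocal counter
            seed = (self.seed * 1_000_003 + counter) % (2**31)
            counter += 1
            if not a and not b:
                rows.append(
                    {"scope": scope, "class": cl, "j": np.nan, "p": np.nan,
                     "n_common": 0, "n_only_control": 0, "n_only_exposed": 0,
                     "note": "undefined (both lists empty)"}
                )
                return
            res = jaccard_test(
                a, b, universe, n_perm=self.n_perm, seed=seed, tie_break=self.tie_break
            )
            rows.append(
                {"scope": scope, "class": cl, "j": res.j, "p": res.p,
                 "n_common": res.n_common, "n_only_control": res.n_only_a,
                 "n_only_exposed": res.n_only_b, "note": ""}
            )

        for cl, universe in sorted(by_class.items()):
            _one(
                "system", cl,
                cls_c.present_species & universe,
                cls_e.present_species & universe,
                universe,
            )
            for e in sorted(cls_c.edge_species):
                _one(
                    f"edge:{e[0]}|{e[1]}", cl,
                    set(cls_c.edge_species[e]) & universe,
                    set(cls_e.edge_species[e]) & universe,
                    universe,
                )
            for c in cls_c.compartment_unique:
                _one(
                    f"compartment:{c}", cl,
                    set(cls_c.compartment_unique[c]) & universe,
                    set(cls_e.compartment_unique[c]) & universe,
                    universe,
                )
        return pd.DataFrame(rows)

    # -- convenience views ---------------------------------------------
    def edge_lists(self) -> pd.DataFrame:
        rows = [
            {"group": g, "compartment_a": e[0], "compartment_b": e[1], "species": sp}
            for g, cls in self.classification_.items()
            for e, species in cls.edge_species.items()
            for sp in species
        ]
        return pd.DataFrame(rows, columns=["group", "compartment_a", "compartment_b", "species"])

    def unique_lists(self) -> pd.DataFrame:
        rows = [
            {"group": g, "compartment": c, "species": sp}
            for g, cls in self.classification_.items()
            for c, species in cls.compartment_unique.items()
            for sp in species
        ]
        return pd.DataFrame(rows, columns=["group", "compartment", "species"])


class EnfcAnalysis(BaseEstimator):
    """Quantitative abundance analysis: ENFC per class total, named species
    and essential-PUFA subset ratio, per compartment.

    ``fit(X)`` computes class-total ENFCs for every (class, compartment);
    :meth:`species_enfc` and :meth:`ratio_enfc` answer targeted queries on
    the fitted table; ``radar_wide`` reshapes any of these into the fixed
    compartment order used for RADAR plots.
    """

    def __init__(
        self,
        error_form: str = "half_sum_sq",
        error_scale: str = "raw",
        control: str | None = None,
        exposed: str | None = None,
        merge_dg: bool = True,
        pufa_set: Iterable[FattyAcyl] | None = None,
    ):
        self.error_form = error_form
        self.error_scale = error_scale
        self.control = control
        self.exposed = exposed
        self.merge_dg = merge_dg
        self.pufa_set = pufa_set

    def fit(self, X: pd.DataFrame, y=None) -> "EnfcAnalysis":
        table, species, issues = prepare_table(X, merge_dg=self.merge_dg)
        control, exposed = infer_groups(table["group"], self.control, self.exposed)
        self.table_ = table
        self.species_ = species
        self.issues_ = issues
        self.groups_ = (control, exposed)
        self.compartments_ = compartment_order(table["tissue"].unique())
        self.classes_ = sorted(table["class"].unique())
        self.class_totals_ = self._all_class_totals()
        return self

    def _record_row(self, rec: EnfcRecord, cls: str | None = None) -> dict:
        row = {
            "target": rec.target,
            "compartment": rec.compartment,
            "enfc": rec.enfc,
            "qualifier": rec.qualifier,
            "mean_exposed": rec.summary.mean_exposed,
            "mean_control": rec.summary.mean_control,
            "sd_exposed": rec.summary.sd_exposed,
            "sd_control": rec.summary.sd_control,
        }
        if cls is not None:
            row["class"] = cls
        return row

    def _all_class_totals(self) -> pd.DataFrame:
        control, exposed = self.groups_
        rows = []
        for cls in self.classes_:
            for comp in self.compartments_:
                rec = _class_total_enfc(
                    self.table_, cls, comp, control, exposed,
                    error_form=self.error_form, error_scale=self.error_scale,
                )
                rows.append(self._record_row(rec, cls))
        return pd.DataFrame(rows)

    def species_enfc(self, targets: Iterable[str]) -> pd.DataFrame:
        """ENFC of named species across compartments; unknown names are rejected."""
        control, exposed = self.groups_
        known = set(self.table_["lipid"])
        rows = []
        for raw in targets:
            name = parse_lipid_name(raw).name
            if name not in known:
                raise ValueError(f"target species {raw!r} not present in the input table")
            sub = self.table_[self.table_["lipid"] == name]
            for comp in self.compartments_:
                sig = {
                    g: sub[(sub["tissue"] == comp) & (sub["group"] == g)]
                    .set_index("replicate")["signal"]
                    for g in self.groups_
                }
                if sig[control].empty or sig[exposed].empty:
                    continue
                summary = GroupSummary.from_replicates(
                    sig[exposed], sig[control], error_scale=self.error_scale
                )
                rec = _enfc_of_summary(summary, self.error_form, target=name, compartment=comp)
                rows.append(self._record_row(rec))
        return pd.DataFrame(rows)

    def ratio_enfc(self, class_code: str, subset: Iterable[str] | None = None) -> pd.DataFrame:
        """ENFC of the subset/complement abundance ratio per compartment.

        Default subset: species of the class containing an essential PUFA
        (the configured ``pufa_set``, DHA + DPA when unset); sum-resolution
        species, whose chains are unknown, fall in the complement.
        """
        control, exposed = self.groups_
        if subset is None:
            pufas = frozenset(self.pufa_set) if self.pufa_set else DEFAULT_ESSENTIAL_PUFAS
            members = set()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", AmbiguousResolutionWarning)
                for name in self.species_.loc[
                    self.species_["analysis_class"] == class_code, "name"
                ]:
                    if is_essential_pufa_containing(parse_lipid_name(name), pufas):
                        members.add(name)
            target = f"{class_code} essential-PUFA ratio"
        else:
            members = {parse_lipid_name(s).name for s in subset}
            target = f"{class_code} subset ratio"
        rows = []
        for comp in self.compartments_:
            rec = _subset_ratio_enfc(
                self.table_, members, class_code, comp, control, exposed,
                error_form=self.error_form, error_scale=self.error_scale, target=target,
            )
            rows.append(self._record_row(rec, class_code))
        return pd.DataFrame(rows)

    def radar_wide(self, records: pd.DataFrame, value: str = "enfc") -> pd.DataFrame:
        """Pivot a long ENFC record table to target x compartment (fixed order)."""
        wide = records.pivot_table(
            index="target", columns="compartment", values=value, aggfunc="first", dropna=False
        )
        return wide.reindex(columns=[c for c in self.compartments_ if c in wide.columns])
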