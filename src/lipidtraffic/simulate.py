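"""Synthetic multi-compartment lipidomics cohorts with planted ground truth.

The generator emits a tidy two-group abundance table in exactly the dialect
the analysis reads, together with the truth it planted: each species'
presence pattern (hence traffic type) per group, any presence switches
between groups, and any abundance fold effects.  Every pipeline stage can
therefore be checked against a known answer without any external data.

The default design emulates the structure of the cold-exposure mouse
study: 10 compartments (plasma + 9 tissues), two groups ("Room temp."
control and "Cold Exposed"), 6 replicates per group, and per-class planted
A/B/U/N2 counts at the scale of the published class table (~920 species
over 8 analysis classes).  Abundances are log-normal per species —
the standard intensity model for lipidomics signals — with per-species
log10 means drawn uniformly to create realistic rank structure, and
dropout implemented by zeroing a replicate's signal (the failure mode the
">0 in >=66% of samples" presence rule is exposed to).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import classify_presence_sets, classify_traffic
from .network import CompartmentNetwork, default_network
from .nomenclature import FattyAcyl, LipidSpecies, parse_lipid_name
from .presence import DEFAULT_THRESHOLD, call_presence

__all__ = [
    "DesignError",
    "PresenceEdit",
    "FoldEffect",
    "SyntheticDesign",
    "SyntheticTruth",
    "DEFAULT_CLASS_COUNTS",
    "generate_cohort",
    "perturb_for_power",
    "recovered_types",
]


class DesignError(ValueError):
    """The requested design is infeasible on the given network or name space."""


@dataclass(frozen=True)
class PresenceEdit:
    """Planted switch: force a species present/absent in one compartment of one group."""

    species: str
    compartment: str
    group: str
    present: bool


@dataclass(frozen=True)
class FoldEffect:
    """Planted abundance effect: multiply the exposed group's signals.

    ``target`` is a canonical species name or an analysis class code; the
    multiplier applies in ``compartment`` only.
    """

    target: str
    compartment: str
    multiplier: float


#: Planted A/B/U/N2 counts per analysis class for the default design,
#: matching the scale of the published class table (control column).
DEFAULT_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "AC": {"A": 0, "B": 4, "U": 3, "N2": 1},
    "PC": {"A": 9, "B": 112, "U": 85, "N2": 43},
    "PE": {"A": 0, "B": 25, "U": 37, "N2": 20},
    "PG": {"A": 0, "B": 4, "U": 28, "N2": 6},
    "PI": {"A": 2, "B": 22, "U": 12, "N2": 12},
    "PS": {"A": 0, "B": 4, "U": 26, "N2": 18},
    "SLs": {"A": 4, "B": 51, "U": 92, "N2": 83},
    "TG": {"A": 34, "B": 49, "U": 98, "N2": 37},
}


@dataclass(frozen=True)
class SyntheticDesign:
    """Everything that determines a cohort; deterministic given ``seed``."""

    network: CompartmentNetwork = field(default_factory=default_network)
    n_replicates: int = 6
    class_counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_COUNTS.items()}
    )
    dropout: float = 0.0
    log10_mean_range: tuple[float, float] = (3.0, 6.0)
    log10_sd: float = 0.2
    threshold: float = DEFAULT_THRESHOLD
    group_labels: tuple[str, str] = ("Room temp.", "Cold Exposed")  # (control, exposed)
    switches: tuple[PresenceEdit, ...] = ()
    effects: tuple[FoldEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise DesignError("need >=2 replicates per group")
        if not (0 <= self.dropout < 1):
            raise DesignError(f"dropout must be in [0, 1), got {self.dropout}")
        if len(set(self.group_labels)) != 2:
            raise DesignError("group_labels must be two distinct labels")


# -- species name pools ----------------------------------------------------

_ACYL_POOL: tuple[FattyAcyl, ...] = tuple(
    FattyAcyl(c, d)
    for c, d in [
        (14, 0), (15, 0), (15, 1), (16, 0), (16, 1), (17, 0), (17, 1),
        (18, 0), (18, 1), (18, 2), (18, 3), (19, 0), (19, 1), (20, 0),
        (20, 1), (20, 3), (20, 4), (20, 5), (22, 4), (22, 5), (22, 6),
        (24, 0), (24, 1),
    ]
)
_SPHINGOID_BASES: tuple[FattyAcyl, ...] = tuple(
    FattyAcyl(c, d, "d") for c, d in [(18, 1), (18, 0), (16, 1), (17, 1)]
)
_SL_SUBCLASSES = ("SM", "Cer", "HexCer")


def _candidate_names(analysis_cls: str, rng: np.random.Generator, sum_fraction: float) -> list[str]:
    """Deterministically enumerate, then shuffle, candidate names for a class."""
    names: list[str] = []
    if analysis_cls == "AC":
        names = [f"AC({fa})" for fa in _ACYL_POOL]
    elif analysis_cls in ("PC", "PE", "PG", "PI", "PS"):
        names = [
            f"{analysis_cls}({a}/{b})"
            for a, b in combinations_with_replacement(_ACYL_POOL, 2)
        ]
    elif analysis_cls == "TG":
        names = [
            f"TG({a}/{b}/{c})"
            for a, b, c in combinations_with_replacement(_ACYL_POOL, 3)
        ]
    elif analysis_cls == "SLs":
        names = [
            f"{sub}({base}/{fa})"
            for sub in _SL_SUBCLASSES
            for base in _SPHINGOID_BASES
            for fa in _ACYL_POOL
        ]
    else:
        raise DesignError(f"no name generator for analysis class {analysis_cls!r}")

    idx = rng.permutation(len(names))
    shuffled = [names[i] for i in idx]

    if sum_fraction > 0 and analysis_cls in ("PC", "PE", "PG", "PI", "PS", "TG"):
        # render a fraction as sum-composition species, deduplicated by identity
        out: list[str] = []
        seen: set = set()
        for i, nm in enumerate(shuffled):
            sp = parse_lipid_name(nm)
            if rng.random() < sum_fraction:
                nm = f"{analysis_cls}({sp.sum_carbons}:{sp.sum_double_bonds})"
                sp = parse_lipid_name(nm)
            if sp.identity not in seen:
                seen.add(sp.identity)
                out.append(sp.name)
        return out
    return shuffled


# -- presence patterns -----------------------------------------------------

def _independent_set(
    network: CompartmentNetwork, k: int, rng: np.random.Generator
) -> frozenset | None:
    """A random k-set of mutually non-adjacent compartments, or None."""
    comps = list(network.compartments)
    for _ in range(200):
        order = [comps[i] for i in rng.permutation(len(comps))]
        chosen: list[str] = []
        for c in order:
            if all(not network.are_adjacent(c, o) for o in chosen):
                chosen.append(c)
                if len(chosen) == k:
                    return frozenset(chosen)
    return None


def _pattern_for_type(
    type_name: str, network: CompartmentNetwork, rng: np.random.Generator
) -> frozenset:
    comps = list(network.compartments)
    edges = sorted(tuple(sorted(e)) for e in network.edges)
    if type_name == "A":
        return frozenset(comps)
    if type_name == "U":
        return frozenset([comps[rng.integers(len(comps))]])
    if type_name == "B":
        if not edges:
            raise DesignError("B-type requested but the network has no edges")
        return frozenset(edges[rng.integers(len(edges))])
    if type_name == "N2":
        pairs = network.non_adjacent_pairs()
        if not pairs:
            raise DesignError(
                "N2-type requested but every compartment pair is adjacent "
                f"on network {network.name!r} (complete graph)"
            )
        return frozenset(pairs[rng.integers(len(pairs))])
    if type_name.startswith("N") and type_name[1:].isdigit():
        k = int(type_name[1:])
        if k < 3:
            raise DesignError(f"use 'N2' rather than {type_name!r}")
        s = _independent_set(network, k, rng)
        if s is None:
            raise DesignError(
                f"{type_name} requested but no {k} mutually non-adjacent "
                f"compartments exist on network {network.name!r}"
            )
        return s
    raise DesignError(f"unknown planted type {type_name!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """What the generator planted, for checking recovery.

    ``types``/``presence`` reflect the dropout-free patterns after any
    planted switches, classified at the design's own threshold — what a
    perfect analysis should recover.
    """

    types: Mapping[str, Mapping[str, str]]  # group -> species -> type
    presence: Mapping[str, Mapping[str, frozenset]]
    species_class: Mapping[str, str]
    lost: tuple[str, ...]  # present in control, absent in exposed
    gained: tuple[str, ...]
    type_changes: Mapping[str, dict]
    effects: tuple[FoldEffect, ...]
    seed: int


def generate_cohort(design: SyntheticDesign) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one cohort.  Deterministic: the same design (incl. seed)
    yields a byte-identical CSV."""
    rng = np.random.default_rng(design.seed)
    net = design.network
    comps = list(net.compartments)
    control, exposed = design.group_labels

    if design.dropout > 0 and design.dropout > 1 - design.threshold:
        warnings.warn(
            f"dropout {design.dropout} exceeds 1 - threshold ({1 - design.threshold:.2f}) "
            "and risks flipping presence calls of planted types",
            UserWarning,
            stacklevel=2,
        )

    # 1. species and base patterns (shared by both groups before switches)
    species: list[str] = []
    species_class: dict[str, str] = {}
    base_pattern: dict[str, frozenset] = {}
    declared: dict[str, str] = {}
    for cls in sorted(design.class_counts):
        counts = design.class_counts[cls]
        n_needed = sum(counts.values())
        pool = _candidate_names(cls, rng, sum_fraction=0.15)
        if n_needed > len(pool):
            raise DesignError(
                f"class {cls!r}: {n_needed} species requested but only "
                f"{len(pool)} distinct names available"
            )
        names = pool[:n_needed]
        i = 0
        for type_name in sorted(counts):
            for _ in range(counts[type_name]):
                nm = names[i]
                i += 1
                species.append(nm)
                species_class[nm] = cls
                declared[nm] = type_name
                base_pattern[nm] = _pattern_for_type(type_name, net, rng)

    # design check: every planted pattern classifies back to its declared type
    check = classify_presence_sets(base_pattern, net, mode="v3")
    bad = {s for s in species if check[s] != declared[s]}
    if bad:
        raise DesignError(f"planted patterns inconsistent with declared types: {sorted(bad)[:5]}")

    # 2. apply planted switches per group
    patterns: dict[str, dict[str, frozenset]] = {
        g: dict(base_pattern) for g in design.group_labels
    }
    for edit in design.switches:
        if edit.group not in design.group_labels:
            raise DesignError(f"switch references unknown group {edit.group!r}")
        if edit.compartment not in comps:
            raise DesignError(f"switch references unknown compartment {edit.compartment!r}")
        if edit.species not in species_class:
            raise DesignError(f"switch references unknown species {edit.species!r}")
        pat = set(patterns[edit.group][edit.species])
        (pat.add if edit.present else pat.discard)(edit.compartment)
        patterns[edit.group][edit.species] = frozenset(pat)

    # 3. signals: log-normal per species, zero where absent, dropout within present cells
    n_sp, n_c, n_r = len(species), len(comps), design.n_replicates
    mu = rng.uniform(*design.log10_mean_range, size=n_sp)
    comp_idx = {c: j for j, c in enumerate(comps)}
    frames = []
    for g in design.group_labels:
        mask = np.zeros((n_sp, n_c), dtype=bool)
        for i, sp in enumerate(species):
            for c in patterns[g][sp]:
                mask[i, comp_idx[c]] = True
        sig = 10.0 ** rng.normal(mu[:, None, None], design.log10_sd, size=(n_sp, n_c, n_r))
        sig *= mask[:, :, None]
        if design.dropout > 0:
            drop = rng.random((n_sp, n_c, n_r)) < design.dropout
            sig[drop] = 0.0
        if g == exposed:
            for eff in design.effects:
                if eff.compartment not in comp_idx:
                    raise DesignError(f"effect references unknown compartment {eff.compartment!r}")
                j = comp_idx[eff.compartment]
                if eff.target in species_class:
                    rows = [species.index(eff.target)]
                else:
                    rows = [i for i, sp in enumerate(species) if species_class[sp] == eff.target]
                    if not rows:
                        raise DesignError(f"effect target {eff.target!r} matches nothing")
                sig[rows, j, :] *= eff.multiplier
        df = pd.DataFrame(
            {
                "lipid": np.repeat(species, n_c * n_r),
                "class": np.repeat([species_class[s] for s in species], n_c * n_r),
                "tissue": np.tile(np.repeat(comps, n_r), n_sp),
                "group": g,
                "replicate": np.tile([f"r{i + 1}" for i in range(n_r)], n_sp * n_c),
                "signal": sig.reshape(-1),
            }
        )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)

    # 4. truth: classify the dropout-free post-switch patterns
    truth_types = {
        g: classify_presence_sets(patterns[g], net, mode="v3") for g in design.group_labels
    }
    present_control = {s for s, p in patterns[control].items() if p}
    present_exposed = {s for s, p in patterns[exposed].items() if p}
    all_types = sorted(set(truth_types[control].values()) | set(truth_types[exposed].values()))
    type_changes = {}
    for t in all_types:
        in_c = {s for s, ty in truth_types[control].items() if ty == t}
        in_e = {s for s, ty in truth_types[exposed].items() if ty == t}
        type_changes[t] = {"lost": tuple(sorted(in_c - in_e)), "gained": tuple(sorted(in_e - in_c))}
    truth = SyntheticTruth(
        types={
            g: {s: t for s, t in truth_types[g].items() if t != "absent"}
            for g in design.group_labels
        },
        presence={
            g: {s: p for s, p in patterns[g].items() if p} for g in design.group_labels
        },
        species_class=species_class,
        lost=tuple(sorted(present_control - present_exposed)),
        gained=tuple(sorted(present_exposed - present_control)),
        type_changes=type_changes,
        effects=design.effects,
        seed=design.seed,
    )
    return table, truth


def recovered_types(
    table: pd.DataFrame,
    network: CompartmentNetwork,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "v3",
) -> dict[str, dict[str, str]]:
    """Run the presence + classification pipeline; group -> species -> type."""
    presence = call_presence(table, threshold=threshold)
    classified = classify_traffic(presence, network, mode=mode)
    return {g: dict(c.types) for g, c in classified.items()}


def perturb_for_power(
    design: SyntheticDesign,
    dropout_grid: Sequence[float] = (),
    fold_grid: Sequence[float] = (),
    effect_class: str = "TG",
    effect_compartment: str | None = None,
) -> tuple[list[tuple[SyntheticDesign, pd.DataFrame, SyntheticTruth]], pd.DataFrame]:
    """Sweep dropout rates and fold effects; returns (cohorts, manifest).

    The manifest has one row per generated cohort with the planted
    perturbation and the recovered answer: type misclassification rate
    (recovered vs planted, over both groups) for dropout rows, recovered
    class-total ENFC for fold rows.
    """
    from .enfc import class_total_enfc  # local import to keep module deps one-way

    comp = effect_compartment or design.network.compartments[1]
    control, exposed = design.group_labels
    cohorts = []
    rows = []
    for i, d in enumerate(dropout_grid):
        dd = replace(design, dropout=float(d), seed=design.seed + 101 + i)
        table, truth = generate_cohort(dd)
        rec = recovered_types(table, dd.network, threshold=dd.threshold)
        total, wrong = 0, 0
        for g in dd.group_labels:
            for sp, t in truth.types[g].items():
                total += 1
                wrong += rec.get(g, {}).get(sp, "absent") != t
        cohorts.append((dd, table, truth))
        rows.append(
            {"kind": "dropout", "value": float(d), "seed": dd.seed,
             "misclassification_rate": wrong / total if total else 0.0,
             "recovered_enfc": np.nan}
        )
    for i, f in enumerate(fold_grid):
        dd = replace(
            design,
            effects=(FoldEffect(effect_class, comp, float(f)),),
            seed=design.seed + 201 + i,
        )
        table, truth = generate_cohort(dd)
        # rms error on the log10 scale: recovered ENFC is then comparable
        # across effect sizes (invariant to the cohort's intensity units)
        rec = class_total_enfc(
            table, effect_class, comp, control=control, exposed=exposed,
            error_form="rms", error_scale="log10",
        )
        cohorts.append((dd, table, truth))
        rows.append(
            {"kind": "fold", "value": float(f), "seed": dd.seed,
             "misclassification_rate": np.nan, "recovered_enfc": rec.enfc}
        )
    manifest = pd.DataFrame(rows, columns=["kind", "value", "seed", "misclassification_rate", "recovered_enfc"])
    return cohorts, manifest
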