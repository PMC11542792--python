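"""Traffic typing of lipid variables over the compartment network.

For each phenotype group, every variable present somewhere is assigned one
mutually exclusive type from its presence pattern:

* **A** — present in every compartment of the network ("found throughout
  the system");
* **U** — present in exactly one compartment (listed under that
  compartment);
* **B** — present in at least one metabolically adjacent pair of
  compartments (both endpoints of an edge);
* **N2** — present in exactly two compartments that are *not* adjacent;
* **Nk** (k >= 3) — present in k compartments none of which form an
  adjacent pair.  Reported separately rather than forced into N2.

``mode="legacy_b"`` reproduces the pre-N2 behaviour in which every
multi-compartment (non-A) variable is B regardless of adjacency.

Group comparison aligns the two groups' typed lists and reports, per type,
per edge and per compartment, which variables were gained or lost on
exposure — the switch output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .network import CompartmentNetwork
from .presence import PresenceMatrix

__all__ = [
    "TrafficClassification",
    "TrafficComparison",
    "classify_pattern",
    "classify_presence_sets",
    "classify_traffic",
    "compare_groups",
    "TYPE_ORDER",
]

TYPE_ORDER = ("A", "B", "U", "N2")


def classify_pattern(
    present: Iterable[str],
    network: CompartmentNetwork,
    mode: str = "v3",
) -> str:
    """Type a single presence pattern (set of compartments) on a network.

    Returns "absent" for the empty pattern, otherwise "A", "U", "B", "N2"
    or "N{k}".  This is the whole classification rule; everything else in
    the module is bookkeeping around it.
    """
    if mode not in ("v3", "legacy_b"):
        raise ValueError(f"unknown classification mode {mode!r}")
    comps = frozenset(present)
    unknown = comps - set(network.compartments)
    if unknown:
        raise ValueError(f"presence pattern references unknown compartment(s) {sorted(unknown)}")
    k = len(comps)
    if k == 0:
        return "absent"
    if k == len(network.compartments):
        return "A"
    if k == 1:
        return "U"
    if network.has_any_adjacent_pair(comps):
        return "B"
    if mode == "legacy_b":
        return "B"
    return "N2" if k == 2 else f"N{k}"


def classify_presence_sets(
    presence_sets: Mapping[str, Iterable[str]],
    network: CompartmentNetwork,
    mode: str = "v3",
) -> dict[str, str]:
    """Vector form of :func:`classify_pattern`: species -> type.

    Patterns are classified once per distinct compartment set, so large
    cohorts (many species, few distinct patterns) stay fast.
    """
    cache: dict[frozenset, str] = {}
    out: dict[str, str] = {}
    for sp, comps in presence_sets.items():
        key = frozenset(comps)
        t = cache.get(key)
        if t is None:
            t = cache[key] = classify_pattern(key, network, mode)
        out[sp] = t
    return out


@dataclass(frozen=True)
class TrafficClassification:
    """One group's typed variable lists.

    ``types`` maps each species present somewhere to its type;
    ``edge_species`` lists, per network edge, the (non-A) species present
    in both endpoints — by construction these are exactly the B-type
    variables of that edge; ``compartment_unique`` lists each
    compartment's U-type species.
    """

    group: str
    network: CompartmentNetwork
    mode: str
    types: Mapping[str, str]
    presence: Mapping[str, frozenset]
    edge_species: Mapping[tuple[str, str], tuple[str, ...]]
    compartment_unique: Mapping[str, tuple[str, ...]]

    def species_of_type(self, type_name: str) -> tuple[str, ...]:
        return tuple(sorted(s for s, t in self.types.items() if t == type_name))

    @property
    def present_species(self) -> frozenset:
        return frozenset(self.types)

    def type_counts(
        self, species_class: Mapping[str, str] | None = None
    ) -> pd.DataFrame:
        """Counts by type; one row per analysis class if a class map is given.

        Each species is counted once per group regardless of how many edge
        lists it appears on.  N_k types (k >= 3) are pooled into an "Nk"
        column.
        """
        rows: dict[str, dict[str, int]] = {}
        for sp, t in self.types.items():
            cls = species_class.get(sp, "all") if species_class else "all"
            bucket = rows.setdefault(cls, {})
            col = t if t in TYPE_ORDER else "Nk"
            bucket[col] = bucket.get(col, 0) + 1
            bucket["present"] = bucket.get("present", 0) + 1
        cols = ["present", *TYPE_ORDER, "Nk"]
        df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols).fillna(0).astype(int)
        return df.sort_index()


def classify_traffic(
    presence: PresenceMatrix,
    network: CompartmentNetwork,
    mode: str = "v3",
) -> dict[str, TrafficClassification]:
    """Classify every group of a presence matrix; returns group -> classification."""
    extra = set(presence.compartments) - set(network.compartments)
    if extra:
        raise ValueError(
            f"presence matrix has compartment(s) {sorted(extra)} not in network "
            f"{network.name!r}"
        )
    out = {}
    for g in presence.groups:
        sets = presence.presence_sets(g)
        types = classify_presence_sets(sets, network, mode)
        edge_species = {}
        for e in sorted(tuple(sorted(e)) for e in network.edges):
            a, b = e
            edge_species[e] = tuple(
                sorted(
                    sp
                    for sp, comps in sets.items()
                    if a in comps and b in comps and types[sp] != "A"
                )
            )
        compartment_unique = {
            c: tuple(
                sorted(sp for sp, t in types.items() if t == "U" and c in sets[sp])
            )
            for c in network.compartments
        }
        out[g] = TrafficClassification(
            group=g,
            network=network,
            mode=mode,
            types=types,
            presence=sets,
            edge_species=edge_species,
            compartment_unique=compartment_unique,
        )
    return out


@dataclass(frozen=True)
class TrafficComparison:
    """Aligned switch output between a control and an exposed classification.

    "lost" always means present/typed in the control group but not the
    exposed one; "gained" the reverse.  Swapping the groups swaps the two
    lists exactly.
    """

    control: str
    exposed: str
    species_status: pd.DataFrame
    type_changes: Mapping[str, dict]
    edge_changes: Mapping[tuple[str, str], dict]
    compartment_changes: Mapping[str, dict]

    @property
    def lost(self) -> tuple[str, ...]:
        s = self.species_status
        return tuple(s.index[s["status"] == "control-only"])

    @property
    def gained(self) -> tuple[str, ...]:
        s = self.species_status
        return tuple(s.index[s["status"] == "exposed-only"])

    def summary(self, species_class: Mapping[str, str] | None = None) -> pd.DataFrame:
        """Per-class counts of shared / control-only / exposed-only variables."""
        s = self.species_status.copy()
        s["class"] = (
            s.index.map(lambda sp: species_class.get(sp, "all")) if species_class else "all"
        )
        return (
            s.groupby(["class", "status"], observed=True)
            .size()
            .unstack("status")
            .reindex(columns=["shared", "control-only", "exposed-only"])
            .fillna(0)
            .astype(int)
        )


def _list_diff(a: Iterable[str], b: Iterable[str]) -> dict:
    sa, sb = set(a), set(b)
    return {"lost": tuple(sorted(sa - sb)), "gained": tuple(sorted(sb - sa))}


def compare_groups(
    cls_control: TrafficClassification,
    cls_exposed: TrafficClassification,
) -> TrafficComparison:
    """Align two groups' classifications into the switch report."""
    if cls_control.network.hash_hex != cls_exposed.network.hash_hex:
        raise ValueError("classifications were made on different networks")
    if cls_control.mode != cls_exposed.mode:
        raise ValueError("classifications used different modes")

    universe = sorted(cls_control.present_species | cls_exposed.present_species)
    rows = []
    for sp in universe:
        tc = cls_control.types.get(sp, "absent")
        te = cls_exposed.types.get(sp, "absent")
        if tc == "absent":
            status = "exposed-only"
        elif te == "absent":
            status = "control-only"
        else:
            status = "shared"
        rows.append(
            {
                "species": sp,
                "type_control": tc,
                "type_exposed": te,
                "status": status,
                "type_changed": tc != te,
            }
        )
    species_status = pd.DataFrame(rows).set_index("species")

    all_types = sorted(
        set(cls_control.types.values()) | set(cls_exposed.types.values()),
        key=lambda t: (TYPE_ORDER.index(t) if t in TYPE_ORDER else 99, t),
    )
    type_changes = {
        t: _list_diff(cls_control.species_of_type(t), cls_exposed.species_of_type(t))
        for t in all_types
    }
    edge_changes = {
        e: _list_diff(cls_control.edge_species[e], cls_exposed.edge_species[e])
        for e in cls_control.edge_species
    }
    compartment_changes = {
        c: _list_diff(cls_control.compartment_unique[c], cls_exposed.compartment_unique[c])
        for c in cls_control.compartment_unique
    }
    return TrafficComparison(
        control=cls_control.group,
        exposed=cls_exposed.group,
        species_status=species_status,
        type_changes=type_changes,
        edge_changes=edge_changes,
        compartment_changes=compartment_changes,
    )
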