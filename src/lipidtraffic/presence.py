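"""Presence calling: which lipid variables are detected where, per phenotype group.

A variable counts as present in a (group, compartment) cell when its signal
is > 0 in at least a fraction ``threshold`` of that cell's replicates
(default 0.66, i.e. >=66% of samples per group; the comparison is ``>=``,
so 2 of 3 replicates = 0.667 passes).  The denominator is the number of
replicates of that group in that compartment, so tissues with unequal n are
handled correctly.  Detection fractions are kept alongside the binary calls
so threshold sensitivity can be explored without re-reading the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = ["PresenceMatrix", "PresenceError", "call_presence", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.66


class PresenceError(ValueError):
    """Presence calling cannot proceed (empty cell, bad threshold ...)."""


@dataclass(frozen=True)
class PresenceMatrix:
    """Detection fractions per group, plus the threshold used for binary calls.

    ``fraction[group]`` is a species x compartment DataFrame of detection
    fractions in [0, 1]; ``replicate_counts`` is a group x compartment
    DataFrame of denominators.  Presence is ``fraction >= threshold``.
    """

    fraction: Mapping[str, pd.DataFrame]
    replicate_counts: pd.DataFrame
    threshold: float = DEFAULT_THRESHOLD

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.fraction)

    @property
    def compartments(self) -> tuple[str, ...]:
        first = next(iter(self.fraction.values()))
        return tuple(first.columns)

    @property
    def species(self) -> tuple[str, ...]:
        first = next(iter(self.fraction.values()))
        return tuple(first.index)

    def present(self, group: str, threshold: float | None = None) -> pd.DataFrame:
        """Boolean species x compartment presence matrix for one group."""
        thr = self.threshold if threshold is None else _check_threshold(threshold)
        return self.fraction[group] >= thr

    def presence_sets(
        self, group: str, threshold: float | None = None
    ) -> dict[str, frozenset]:
        """Species -> set of compartments in which it is present (empty sets dropped)."""
        pres = self.present(group, threshold)
        out: dict[str, frozenset] = {}
        for sp, row in pres.iterrows():
            comps = frozenset(row.index[row])
            if comps:
                out[sp] = comps
        return out

    def with_threshold(self, threshold: float) -> "PresenceMatrix":
        return PresenceMatrix(
            fraction=self.fraction,
            replicate_counts=self.replicate_counts,
            threshold=_check_threshold(threshold),
        )


def _check_threshold(threshold: float) -> float:
    if not (0 < threshold <= 1):
        raise PresenceError(f"threshold must be in (0, 1], got {threshold}")
    return float(threshold)


def call_presence(table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> PresenceMatrix:
    """Compute detection fractions and presence calls from a tidy abundance table.

    ``table`` must carry columns lipid/tissue/group/replicate/signal (see
    :mod:`lipidtraffic.io`).  A (group, compartment) cell with zero
    replicates anywhere in the observed grid is rejected by name rather
    than silently producing a 0/0.
    """
    _check_threshold(threshold)
    if table.empty:
        raise PresenceError("abundance table is empty")

    n_reps = (
        table.groupby(["group", "tissue"], observed=True)["replicate"].nunique().unstack("tissue")
    )
    missing = n_reps.isna() | (n_reps == 0)
    if missing.to_numpy().any():
        cells = [
            f"(group={g!r}, compartment={t!r})"
            for (g, t) in missing.stack()[missing.stack()].index
        ]
        raise PresenceError("no replicates for cell(s): " + ", ".join(cells))

    detected = (
        table[table["signal"] > 0]
        .groupby(["group", "lipid", "tissue"], observed=True)["replicate"]
        .nunique()
    )
    species = sorted(table["lipid"].unique())
    compartments = sorted(table["tissue"].unique())
    groups = sorted(table["group"].unique())

    fractions: dict[str, pd.DataFrame] = {}
    for g in groups:
        if g in detected.index.get_level_values(0):
            counts = detected.loc[g].unstack("tissue")
        else:  # group with no nonzero signal at all
            counts = pd.DataFrame(index=species, columns=compartments, dtype=float)
        counts = counts.reindex(index=species, columns=compartments).fillna(0.0)
        fractions[g] = counts.div(n_reps.loc[g], axis=1)

    return PresenceMatrix(
        fraction=fractions,
        replicate_counts=n_reps.reindex(columns=compartments),
        threshold=float(threshold),
    )
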