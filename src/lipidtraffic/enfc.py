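"""Error-Normalised Fold Change (ENFC): quantitative abundance analysis.

For a target (a species, a class total, or a subset/complement ratio) in a
compartment, with exposed-group mean x̄_E and control mean x̄_C and group
standard deviations a and b:

    ENFC = log10(x̄_E / x̄_C) / f(a, b)

The sign gives the direction of change on exposure; the magnitude is the
fold change on a log10 scale relative to the combined measurement error.
The default error combination is the literal ``f(a, b) = (a² + b²) / 2``;
``"rms"`` (sqrt((a²+b²)/2)) and ``"root_sum_sq"`` (sqrt(a²+b²)) are
selectable for sensitivity analysis.  Errors may be taken on the raw
signal scale (default) or on log10 signals, under which ENFC is invariant
to rescaling the instrument units.

Zero means are never imputed: such records carry a qualifier instead of an
infinite value (presence/absence is the switch analysis's job, not this
module's).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Collection, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GroupSummary",
    "EnfcRecord",
    "ERROR_FORMS",
    "enfc",
    "class_total_enfc",
    "subset_ratio_enfc",
    "replicate_class_totals",
]

ERROR_FORMS: dict[str, Callable[[float, float], float]] = {
    "half_sum_sq": lambda a, b: (a * a + b * b) / 2.0,
    "rms": lambda a, b: math.sqrt((a * a + b * b) / 2.0),
    "root_sum_sq": lambda a, b: math.sqrt(a * a + b * b),
}


@dataclass(frozen=True)
class GroupSummary:
    """Group means, errors (SDs) and replicate counts feeding one ENFC."""

    mean_exposed: float
    mean_control: float
    sd_exposed: float
    sd_control: float
    n_exposed: int
    n_control: int

    def __post_init__(self) -> None:
        if self.mean_exposed < 0 or self.mean_control < 0:
            raise ValueError("group means must be non-negative")
        for sd in (self.sd_exposed, self.sd_control):
            if not math.isnan(sd) and sd < 0:
                raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_replicates(
        cls,
        exposed: Collection[float],
        control: Collection[float],
        error_scale: str = "raw",
    ) -> "GroupSummary":
        """Summarise replicate signals.  Means are always of raw signals;
        with ``error_scale="log10"`` the SDs are taken over log10 of the
        positive replicate values (an all-or-mostly-zero group then has an
        undefined error and the record is qualified downstream)."""
        e = np.asarray(list(exposed), dtype=float)
        c = np.asarray(list(control), dtype=float)
        if e.size < 2 or c.size < 2:
            raise ValueError("need >=2 replicates per group for a defined SD")
        if error_scale == "raw":
            sd_e, sd_c = float(np.std(e, ddof=1)), float(np.std(c, ddof=1))
        elif error_scale == "log10":
            def _log_sd(x: np.ndarray) -> float:
                pos = x[x > 0]
                return float(np.std(np.log10(pos), ddof=1)) if pos.size >= 2 else math.nan
            sd_e, sd_c = _log_sd(e), _log_sd(c)
        else:
            raise ValueError(f"unknown error_scale {error_scale!r}")
        return cls(
            mean_exposed=float(e.mean()),
            mean_control=float(c.mean()),
            sd_exposed=sd_e,
            sd_control=sd_c,
            n_exposed=int(e.size),
            n_control=int(c.size),
        )

    def swapped(self) -> "GroupSummary":
        return GroupSummary(
            mean_exposed=self.mean_control,
            mean_control=self.mean_exposed,
            sd_exposed=self.sd_control,
            sd_control=self.sd_exposed,
            n_exposed=self.n_control,
            n_control=self.n_exposed,
        )


@dataclass(frozen=True)
class EnfcRecord:
    """One ENFC value with its qualifier and provenance.

    ``qualifier`` is "defined" for a finite computed value; "zero-mean-control"
    / "zero-mean-exposed" when one group mean is zero (value NaN, direction
    implied by the qualifier); "zero-error" when the combined error vanishes
    or is undefined; "undefined" when both means are zero (value 0 by the
    equal-means convention, flagged)."""

    target: str
    compartment: str
    enfc: float
    qualifier: str
    summary: GroupSummary


def enfc(
    summary: GroupSummary,
    error_form: str = "half_sum_sq",
    target: str = "",
    compartment: str = "",
) -> EnfcRecord:
    """ENFC of one group summary; see module docstring for the formula."""
    try:
        form = ERROR_FORMS[error_form]
    except KeyError:
        raise ValueError(
            f"unknown error_form {error_form!r}; choose from {sorted(ERROR_FORMS)}"
        ) from None
    xe, xc = summary.mean_exposed, summary.mean_control
    if xe == 0 and xc == 0:
        value, qualifier = 0.0, "undefined"
    elif xc == 0:
        value, qualifier = math.nan, "zero-mean-control"
    elif xe == 0:
        value, qualifier = math.nan, "zero-mean-exposed"
    else:
        num = math.log10(xe / xc)
        a, b = summary.sd_exposed, summary.sd_control
        if math.isnan(a) or math.isnan(b):
            den = math.nan
        else:
            den = form(a, b)
        if den == 0 or math.isnan(den):
            value, qualifier = (0.0, "zero-error") if num == 0 else (math.nan, "zero-error")
        else:
            value, qualifier = num / den, "defined"
    return EnfcRecord(
        target=target, compartment=compartment, enfc=value, qualifier=qualifier, summary=summary
    )


def replicate_class_totals(
    table: pd.DataFrame,
    class_code: str,
    compartment: str,
    group: str,
) -> pd.Series:
    """Per-replicate summed signal of one class in one (compartment, group) cell.

    The replicate universe is every replicate id observed for that cell in
    the whole table, so a replicate in which the class was entirely absent
    contributes a total of 0 rather than disappearing.
    """
    cell = table[(table["tissue"] == compartment) & (table["group"] == group)]
    if cell.empty:
        raise ValueError(f"no data for compartment {compartment!r}, group {group!r}")
    reps = sorted(cell["replicate"].unique())
    totals = (
        cell[cell["class"] == class_code].groupby("replicate")["signal"].sum()
    )
    return totals.reindex(reps).fillna(0.0)


def class_total_enfc(
    table: pd.DataFrame,
    class_code: str,
    compartment: str,
    control: str,
    exposed: str,
    error_form: str = "half_sum_sq",
    error_scale: str = "raw",
) -> EnfcRecord:
    """ENFC of a class's total abundance in one compartment.

    Replicate-level class totals are formed first; the ENFC is then taken
    on the totals' group means and SDs.
    """
    te = replicate_class_totals(table, class_code, compartment, exposed)
    tc = replicate_class_totals(table, class_code, compartment, control)
    summary = GroupSummary.from_replicates(te, tc, error_scale=error_scale)
    return enfc(summary, error_form, target=f"total {class_code}", compartment=compartment)


def subset_ratio_enfc(
    table: pd.DataFrame,
    subset: Collection[str] | Callable[[str], bool],
    class_code: str,
    compartment: str,
    control: str,
    exposed: str,
    error_form: str = "half_sum_sq",
    error_scale: str = "raw",
    target: str = "",
) -> EnfcRecord:
    """ENFC of the per-replicate ratio subset / complement within a class.

    ``subset`` is a set of species names or a predicate on names; the
    complement is every other species of the class.  A replicate whose
    complement total is zero has an undefined ratio and is excluded with a
    warning.
    """
    in_subset = (
        (lambda s: s in set(subset)) if not callable(subset) else subset
    )
    cls_rows = table[table["class"] == class_code]
    if cls_rows.empty:
        raise ValueError(f"class {class_code!r} absent from the table")
    member = cls_rows["lipid"].map(in_subset).astype(bool)

    def _ratios(group: str) -> np.ndarray:
        cell = cls_rows[(cls_rows["tissue"] == compartment) & (cls_rows["group"] == group)]
        if cell.empty:
            raise ValueError(f"no {class_code!r} data for {compartment!r} in group {group!r}")
        memb = member.loc[cell.index]
        sub = cell[memb].groupby("replicate")["signal"].sum()
        comp = cell[~memb].groupby("replicate")["signal"].sum()
        reps = sorted(cell["replicate"].unique())
        sub = sub.reindex(reps).fillna(0.0)
        comp = comp.reindex(reps).fillna(0.0)
        ok = comp > 0
        if (~ok).any():
            warnings.warn(
                f"{compartment}/{group}: excluded {(~ok).sum()} replicate(s) with zero "
                f"complement total for {class_code}",
                UserWarning,
                stacklevel=3,
            )
        return (sub[ok] / comp[ok]).to_numpy()

    re_, rc = _ratios(exposed), _ratios(control)
    summary = GroupSummary.from_replicates(re_, rc, error_scale=error_scale)
    return enfc(
        summary,
        error_form,
        target=target or f"{class_code} subset ratio",
        compartment=compartment,
    )
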