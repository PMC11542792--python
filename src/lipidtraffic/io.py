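"""Reading, validating and canonicalising tidy abundance tables.

The input is one row per measured signal:

    lipid, class, tissue, group, replicate, signal

``lipid`` is a shorthand name (any adduct annotation is stripped and adduct
rows of the same species are summed within a replicate), ``tissue`` a
compartment label, ``group`` a phenotype label, ``signal`` a non-negative
intensity in arbitrary units.  Column names in a file can differ; pass a
``column_map`` to rename them on read.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .nomenclature import LipidNameError, parse_lipid_name, species_dictionary

__all__ = [
    "REQUIRED_COLUMNS",
    "CONTROL_ALIASES",
    "AbundanceTableError",
    "read_abundance_csv",
    "validate_abundance",
    "prepare_table",
    "infer_groups",
    "file_sha256",
]

REQUIRED_COLUMNS: tuple[str, ...] = ("lipid", "class", "tissue", "group", "replicate", "signal")

#: Group labels recognised as the control phenotype when none is given.
CONTROL_ALIASES = frozenset({"control", "ctrl", "room temp.", "room temp", "rt"})


class AbundanceTableError(ValueError):
    """Systemic fault in an input table (missing columns, empty table ...)."""


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def read_abundance_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a tidy abundance CSV, optionally renaming columns via ``column_map``.

    ``column_map`` maps file column names to the canonical names in
    :data:`REQUIRED_COLUMNS` (e.g. ``{"Lipid name": "lipid"}``).
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_abundance(df)


def validate_abundance(df: pd.DataFrame) -> pd.DataFrame:
    """Check structure and dtypes of a tidy abundance table; returns a clean copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AbundanceTableError(f"input table missing required column(s): {missing}")
    if df.empty:
        raise AbundanceTableError("input table has no rows")
    out = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    out["signal"] = pd.to_numeric(out["signal"], errors="coerce")
    bad_signal = out.index[out["signal"].isna()].tolist()
    if bad_signal:
        raise AbundanceTableError(
            f"non-numeric signal values at row index {bad_signal[:10]}"
            + ("..." if len(bad_signal) > 10 else "")
        )
    neg = out.index[out["signal"] < 0].tolist()
    if neg:
        raise AbundanceTableError(
            f"negative signal values at row index {neg[:10]}" + ("..." if len(neg) > 10 else "")
        )
    for col in ("lipid", "tissue", "group"):
        out[col] = out[col].astype(str)
    return out


def prepare_table(
    df: pd.DataFrame,
    merge_dg: bool = True,
    errors: str = "collect",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Canonicalise lipid names and collapse adducts.

    Returns ``(table, species, issues)``:

    * ``table`` — validated rows with ``lipid`` replaced by the canonical
      species name, ``class`` replaced by the analysis class derived from
      the name (sphingolipid subclasses -> SLs, DG -> TG when ``merge_dg``),
      and adduct duplicates summed within each replicate;
    * ``species`` — the species dictionary (one row per distinct raw name);
    * ``issues`` — row-level problems (unparseable names, class-column
      disagreements).  With ``errors="collect"`` offending rows are dropped
      and reported here; ``errors="raise"`` aborts on the first problem.
    """
    df = validate_abundance(df)
    issues: list[dict] = []

    raw_names = pd.unique(df["lipid"])
    canonical: dict[str, str] = {}
    aclass: dict[str, str] = {}
    bad_names: set[str] = set()
    for raw in raw_names:
        try:
            sp = parse_lipid_name(raw)
        except LipidNameError as exc:
            if errors == "raise":
                raise
            bad_names.add(raw)
            for idx in df.index[df["lipid"] == raw]:
                issues.append({"row": int(idx), "lipid": raw, "issue": str(exc)})
            continue
        canonical[raw] = sp.name
        aclass[raw] = sp.analysis_class(merge_dg=merge_dg)

    kept = df[~df["lipid"].isin(bad_names)].copy()
    if kept.empty:
        raise AbundanceTableError("no parseable lipid names in input")

    declared = kept.groupby("lipid")["class"].first()
    mismatch = [
        raw for raw, cls in declared.items() if str(cls) not in ("", "nan") and str(cls) != aclass[raw]
        and str(cls) != parse_lipid_name(raw).class_code
    ]
    if mismatch:
        warnings.warn(
            f"class column disagrees with parsed class for {len(mismatch)} name(s); "
            "using the class derived from the name",
            UserWarning,
            stacklevel=2,
        )
        for raw in mismatch:
            issues.append(
                {"row": -1, "lipid": raw, "issue": f"declared class {declared[raw]!r} != parsed {aclass[raw]!r}"}
            )

    kept["lipid"] = kept["lipid"].map(canonical)
    kept["class"] = kept["lipid"].map(
        {canonical[r]: aclass[r] for r in canonical}
    )
    collapsed = (
        kept.groupby(["lipid", "class", "tissue", "group", "replicate"], as_index=False)["signal"]
        .sum()
        .sort_values(["class", "lipid", "tissue", "group", "replicate"], kind="stable")
        .reset_index(drop=True)
    )
    species = species_dictionary(sorted(canonical), merge_dg=merge_dg)
    return collapsed, species, pd.DataFrame(issues, columns=["row", "lipid", "issue"])


def infer_groups(
    labels: Sequence[str],
    control: str | None = None,
    exposed: str | None = None,
) -> tuple[str, str]:
    """Resolve (control, exposed) group labels from a table's group column.

    Explicit labels win; otherwise a label matching a known control alias
    (case-insensitive) is taken as control.  Exactly two groups are required.
    """
    uniq = sorted(set(map(str, labels)))
    if control is not None and exposed is not None:
        for lbl in (control, exposed):
            if lbl not in uniq:
                raise AbundanceTableError(f"group {lbl!r} not present; table has {uniq}")
        return control, exposed
    if len(uniq) != 2:
        raise AbundanceTableError(
            f"expected exactly two groups to compare, found {uniq}; pass control/exposed"
        )
    a, b = uniq
    if control is not None:
        if control not in uniq:
            raise AbundanceTableError(f"group {control!r} not present; table has {uniq}")
        return control, b if control == a else a
    if exposed is not None:
        if exposed not in uniq:
            raise AbundanceTableError(f"group {exposed!r} not present; table has {uniq}")
        return b if exposed == a else a, exposed
    la, lb = a.lower(), b.lower()
    if la in CONTROL_ALIASES:
        return a, b
    if lb in CONTROL_ALIASES:
        return b, a
    warnings.warn(
        f"could not identify the control group among {uniq}; using {a!r} as control "
        "(alphabetical). Pass control=/exposed= to override.",
        UserWarning,
        stacklevel=2,
    )
    return a, b
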