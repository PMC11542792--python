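"""Lipid shorthand nomenclature: parsing, canonical formatting and chemical predicates.

Lipid species are written in the shorthand used throughout lipidomics,
``CLASS(c:d)`` for a sum composition (total acyl carbons ``c`` and total
double bonds ``d``) or ``CLASS(c1:d1/c2:d2[/c3:d3])`` when the individual
fatty acyl chains are resolved ("molecular" resolution).  Examples:
``TG(52:6)``, ``TG(16:0/16:0/22:6)``, ``PC(34:1)``, ``SM(d18:1/16:0)``.

Chain order carries no meaning here (sn-position is not encoded): two names
that list the same chains in a different order describe the same species,
and the canonical formatter sorts chains so that equality of
:attr:`LipidSpecies.identity` captures that.

Adduct annotations appended by peak-picking software (``+NH4``, ``+H`` ...)
are stripped and recorded; downstream analyses collapse all adducts of a
species into one variable.  Ether/plasmalogen prefixes (``O-``, ``P-``) are
accepted and flagged.  Diglycerides (``DG``) are retained but flagged as
in-source fragments of TGs, lyso species (``LPC``) as lyso forms.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "FattyAcyl",
    "LipidSpecies",
    "LipidNameError",
    "AmbiguousResolutionWarning",
    "KNOWN_CLASS_CODES",
    "SPHINGOLIPID_CODES",
    "SINGLE_CHAIN_CODES",
    "DEFAULT_ESSENTIAL_PUFAS",
    "parse_lipid_name",
    "format_lipid_name",
    "analysis_class",
    "contains_fatty_acid",
    "is_odd_chain",
    "is_essential_pufa_containing",
    "species_dictionary",
]


class LipidNameError(ValueError):
    """Raised when a lipid name cannot be parsed; the message names the offending token."""


class AmbiguousResolutionWarning(UserWarning):
    """A chain-level predicate was asked of a sum-resolution species: the answer is unknown."""


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl chain ``carbons:double_bonds``, e.g. FA(22:6) for DHA.

    ``sphingoid_prefix`` keeps the long-chain-base markers of sphingolipid
    shorthand (``d`` di-hydroxy, ``t`` tri-hydroxy, ``m`` mono-hydroxy), so a
    sphingoid base d18:1 never compares equal to an acyl FA(18:1).
    """

    carbons: int
    double_bonds: int
    sphingoid_prefix: str = ""

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise LipidNameError(f"fatty acyl needs >=1 carbon, got {self.carbons}")
        if self.double_bonds < 0:
            raise LipidNameError(f"negative double bond count: {self.double_bonds}")
        if self.double_bonds > self.carbons:
            raise LipidNameError(
                f"chain {self.carbons}:{self.double_bonds} has more double bonds than carbons"
            )
        if self.sphingoid_prefix not in ("", "d", "t", "m"):
            raise LipidNameError(f"unknown sphingoid prefix {self.sphingoid_prefix!r}")

    def __str__(self) -> str:
        return f"{self.sphingoid_prefix}{self.carbons}:{self.double_bonds}"

    @property
    def is_odd(self) -> bool:
        return self.carbons % 2 == 1

    @property
    def is_polyunsaturated(self) -> bool:
        return self.double_bonds >= 2


#: Class codes accepted by the parser.  SM/Cer/HexCer/DhSph are sphingolipid
#: subclasses reported together as the umbrella analysis class "SLs".
KNOWN_CLASS_CODES = frozenset(
    {"AC", "PC", "PE", "PG", "PI", "PS", "SM", "Cer", "HexCer", "DhSph", "TG", "DG", "LPC"}
)
SPHINGOLIPID_CODES = frozenset({"SM", "Cer", "HexCer", "DhSph"})
#: Classes whose single composition token is a single resolved chain rather
#: than an unresolved sum (acyl carnitines, lyso-PC, sphingoid bases).
SINGLE_CHAIN_CODES = frozenset({"AC", "LPC", "DhSph"})

_CODE_BY_UPPER = {c.upper(): c for c in KNOWN_CLASS_CODES}

#: Essential polyunsaturates used by the PUFA-ratio analysis: DHA 22:6 and DPA 22:5.
DEFAULT_ESSENTIAL_PUFAS = frozenset({FattyAcyl(22, 6), FattyAcyl(22, 5)})


def _chain_sort_key(chain: FattyAcyl) -> tuple:
    # sphingoid base conventionally printed first
    return (chain.sphingoid_prefix == "", chain.carbons, chain.double_bonds, chain.sphingoid_prefix)


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid identity.

    ``resolution`` is ``"molecular"`` when per-chain composition is known
    (``chains`` non-empty) and ``"sum"`` when only the total composition is.
    """

    raw_name: str
    class_code: str
    chains: tuple[FattyAcyl, ...]
    sum_carbons: int
    sum_double_bonds: int
    resolution: str
    ether: str = ""  # "", "O" or "P"
    adduct: str = ""

    def __post_init__(self) -> None:
        if self.class_code not in KNOWN_CLASS_CODES:
            raise LipidNameError(f"unknown lipid class code {self.class_code!r}")
        if self.resolution not in ("sum", "molecular"):
            raise LipidNameError(f"unknown resolution {self.resolution!r}")
        if self.chains:
            if self.sum_carbons != sum(c.carbons for c in self.chains):
                raise LipidNameError(
                    f"{self.raw_name!r}: sum carbons {self.sum_carbons} != chain total"
                )
            if self.sum_double_bonds != sum(c.double_bonds for c in self.chains):
                raise LipidNameError(
                    f"{self.raw_name!r}: sum double bonds {self.sum_double_bonds} != chain total"
                )

    # -- identity ---------------------------------------------------------
    @property
    def identity(self) -> tuple:
        """Hashable identity ignoring raw spelling, chain order and adduct."""
        if self.resolution == "molecular":
            comp: tuple = tuple(sorted(self.chains, key=_chain_sort_key))
        else:
            comp = (self.sum_carbons, self.sum_double_bonds)
        return (self.class_code, self.ether, self.resolution, comp)

    @property
    def name(self) -> str:
        """Canonical shorthand name (adduct stripped, chains in canonical order)."""
        return format_lipid_name(self)

    @property
    def is_fragment(self) -> bool:
        """DG species, retained as in-source fragments of TGs."""
        return self.class_code == "DG"

    @property
    def is_lyso(self) -> bool:
        return self.class_code == "LPC"

    def analysis_class(self, merge_dg: bool = True) -> str:
        return analysis_class(self, merge_dg=merge_dg)


_NAME_RE = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z][A-Za-z0-9]*)\s*
        \(\s*(?P<comp>[^()]+?)\s*\)
        \s*(?:\+\s*(?P<adduct>[A-Za-z0-9+\-]+))?
        \s*$""",
    re.VERBOSE,
)
_CHAIN_RE = re.compile(r"^(?P<sph>[dtm])?(?P<c>\d+):(?P<d>\d+)$")


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a structured :class:`LipidSpecies`.

    Raises :class:`LipidNameError` (naming the offending token) for unknown
    class codes or malformed compositions; a name is never silently dropped.
    """
    if not isinstance(name, str):
        raise LipidNameError(f"lipid name must be text, got {type(name).__name__}")
    m = _NAME_RE.match(name)
    if m is None:
        raise LipidNameError(f"unparseable lipid name {name!r}")
    cls_token = m.group("cls")
    class_code = _CODE_BY_UPPER.get(cls_token.upper())
    if class_code is None:
        raise LipidNameError(f"unknown lipid class code {cls_token!r} in {name!r}")

    comp = m.group("comp")
    ether = ""
    em = re.match(r"^([OP])-\s*(.+)$", comp)
    if em:
        ether, comp = em.group(1), em.group(2)

    tokens = [t.strip() for t in comp.split("/")]
    if any(not t for t in tokens):
        raise LipidNameError(f"empty chain token in {name!r}")
    parsed = []
    for tok in tokens:
        cm = _CHAIN_RE.match(tok)
        if cm is None:
            raise LipidNameError(f"malformed composition token {tok!r} in {name!r}")
        parsed.append(
            FattyAcyl(int(cm.group("c")), int(cm.group("d")), cm.group("sph") or "")
        )

    molecular = len(parsed) > 1 or class_code in SINGLE_CHAIN_CODES
    adduct = m.group("adduct") or ""
    if molecular:
        chains = tuple(sorted(parsed, key=_chain_sort_key))
        return LipidSpecies(
            raw_name=name,
            class_code=class_code,
            chains=chains,
            sum_carbons=sum(c.carbons for c in chains),
            sum_double_bonds=sum(c.double_bonds for c in chains),
            resolution="molecular",
            ether=ether,
            adduct=adduct,
        )
    (only,) = parsed
    if only.sphingoid_prefix:
        raise LipidNameError(f"sphingoid prefix on a sum composition in {name!r}")
    return LipidSpecies(
        raw_name=name,
        class_code=class_code,
        chains=(),
        sum_carbons=only.carbons,
        sum_double_bonds=only.double_bonds,
        resolution="sum",
        ether=ether,
        adduct=adduct,
    )


def format_lipid_name(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; ``parse(format(s))`` preserves identity."""
    prefix = f"{species.ether}-" if species.ether else ""
    if species.resolution == "molecular":
        comp = "/".join(str(c) for c in sorted(species.chains, key=_chain_sort_key))
    else:
        comp = f"{species.sum_carbons}:{species.sum_double_bonds}"
    return f"{species.class_code}({prefix}{comp})"


def analysis_class(species: LipidSpecies, merge_dg: bool = True) -> str:
    """Map a species to the class used for reporting.

    Sphingolipid subclasses collapse to "SLs"; DGs merge into TG by default
    (they arise from in-source fragmentation of TGs during acquisition).
    """
    if species.class_code in SPHINGOLIPID_CODES:
        return "SLs"
    if species.class_code == "DG" and merge_dg:
        return "TG"
    return species.class_code


# -- chemical predicates ---------------------------------------------------

def contains_fatty_acid(species: LipidSpecies, query: FattyAcyl) -> bool:
    """True iff a resolved chain equals ``query`` exactly.

    Sum-resolution species cannot answer: an :class:`AmbiguousResolutionWarning`
    is emitted and False returned.
    """
    if species.resolution != "molecular":
        warnings.warn(
            f"{species.raw_name}: chain content unknown at sum resolution; "
            f"cannot test for FA({query})",
            AmbiguousResolutionWarning,
            stacklevel=2,
        )
        return False
    return any(chain == query for chain in species.chains)


def is_odd_chain(species: LipidSpecies, include_ether: bool = False) -> bool:
    """True iff the species carries an odd-carbon chain (OCFA).

    At molecular resolution: any chain with odd carbons.  At sum resolution:
    odd total carbons (an odd sum implies at least one odd chain).
    Ether/plasmalogen species are excluded by default, as the O-/P- linkage
    shifts the parity bookkeeping of the glycerol-bound chains.
    """
    if species.ether and not include_ether:
        return False
    if species.resolution == "molecular":
        return any(c.is_odd for c in species.chains)
    return species.sum_carbons % 2 == 1


def is_essential_pufa_containing(
    species: LipidSpecies, pufa_set: Iterable[FattyAcyl] | None = None
) -> bool:
    """True iff any resolved chain is one of the essential PUFAs.

    Default set is {FA(22:6) DHA, FA(22:5) DPA}, the essential polyunsaturates
    of the ratio analysis.  Sum-resolution species warn and return False.
    """
    pufas = frozenset(pufa_set) if pufa_set is not None else DEFAULT_ESSENTIAL_PUFAS
    if not pufas:
        raise ValueError("pufa_set must be non-empty")
    if species.resolution != "molecular":
        warnings.warn(
            f"{species.raw_name}: chain content unknown at sum resolution; "
            "essential-PUFA status unknown",
            AmbiguousResolutionWarning,
            stacklevel=2,
        )
        return False
    return any(chain in pufas for chain in species.chains)


def species_dictionary(names: Iterable[str], merge_dg: bool = True) -> pd.DataFrame:
    """Parse many raw names into the exported species dictionary.

    One row per input name: canonical name, class, analysis class, sum
    composition, chain list and flags.  Unparseable names raise.
    """
    rows = []
    for raw in names:
        sp = parse_lipid_name(raw)
        rows.append(
            {
                "raw_name": raw,
                "name": sp.name,
                "class_code": sp.class_code,
                "analysis_class": sp.analysis_class(merge_dg=merge_dg),
                "resolution": sp.resolution,
                "sum_carbons": sp.sum_carbons,
                "sum_double_bonds": sp.sum_double_bonds,
                "chains": "/".join(str(c) for c in sp.chains),
                "ether": sp.ether,
                "adduct": sp.adduct,
                "is_fragment": sp.is_fragment,
                "is_lyso": sp.is_lyso,
                "odd_chain": is_odd_chain(sp),
            }
        )
    return pd.DataFrame(rows)
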