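"""Lipid shorthand nomenclature and species-level mass arithmetic.

Grammar (hyphen and en-dash both accepted between moieties)::

    annotation  := class " " body
    class       := "TAG" | "PC" | "PE" | "PS" | "PI" | "SM" | "FA"
    body        := sum | molecular
    sum         := acyl                      # e.g. "TAG 52:2", "SM 35:1;2"
    molecular   := acyl ("-" acyl)+          # e.g. "PC 16:0-18:1"
                 | lcb "/" acyl              # SM only, e.g. "SM 18:1;2/17:0"
    acyl        := carbons ":" double_bonds (";" hydroxyls)?

The ``-`` separator carries no sn-position meaning: ``TAG 16:0-18:1-18:1``
denotes a multiset of fatty acyl moieties. A sum-composition annotation
gives only the totals over the (unresolved) moieties.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .elements import ADDUCTS, Adduct, Formula, monoisotopic_mz

__all__ = [
    "FattyAcyl",
    "LipidAnnotation",
    "ParseError",
    "parse_annotation",
    "format_annotation",
    "elemental_composition",
    "species_mz",
    "enumerate_candidates",
    "Candidate",
    "CLASS_ADDUCTS",
    "DEFAULT_LCB",
    "LIPID_CLASSES",
]

LIPID_CLASSES = ("TAG", "PC", "PE", "PS", "PI", "SM")
_ALL_CLASSES = LIPID_CLASSES + ("FA",)

# Default adduct per class and polarity: ammoniated TAG in positive mode,
# protonated PC/SM for headgroup detection, formate adducts for PC at the
# FA level, deprotonated PE/PS/PI.
CLASS_ADDUCTS: dict[tuple[str, str], str] = {
    ("TAG", "+"): "+NH4",
    ("PC", "+"): "+H",
    ("SM", "+"): "+H",
    ("PC", "-"): "+HCOO",
    ("PE", "-"): "-H",
    ("PS", "-"): "-H",
    ("PI", "-"): "-H",
}


class ParseError(ValueError):
    """A shorthand annotation that does not conform to the grammar."""


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A fatty acyl moiety (or sphingoid long-chain base when ``is_lcb``).

    ``carbons:double_bonds`` with an optional ``;hydroxyls`` suffix; free
    fatty acids are ``CnH(2n-2d)O2``, long-chain bases ``CnH(2n+3-2d)N O(h)``.
    """

    carbons: int
    double_bonds: int
    hydroxyls: int = 0
    is_lcb: bool = False

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"fatty acyl needs >= 2 carbons, got {self.carbons}")
        if not 0 <= self.double_bonds <= self.carbons // 2:
            raise ValueError(
                f"double bonds {self.double_bonds} out of range for {self.carbons} carbons"
            )
        if self.hydroxyls < 0:
            raise ValueError("hydroxyl count must be >= 0")

    @property
    def shorthand(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            s += f";{self.hydroxyls}"
        return s

    @property
    def acid_formula(self) -> Formula:
        """Elemental formula of the free fatty acid CnH(2n-2d)O2."""
        if self.is_lcb:
            raise ValueError("a long-chain base has no free-acid formula")
        return Formula(
            C=self.carbons,
            H=2 * self.carbons - 2 * self.double_bonds,
            O=2 + self.hydroxyls,
        )

    @property
    def lcb_formula(self) -> Formula:
        """Elemental formula of the free sphingoid base CnH(2n+3-2d)N O(h)."""
        if not self.is_lcb:
            raise ValueError("not a long-chain base")
        return Formula(
            C=self.carbons,
            H=2 * self.carbons + 3 - 2 * self.double_bonds,
            N=1,
            O=self.hydroxyls,
        )

    def __str__(self) -> str:
        return self.shorthand


#: The dihydroxy 18:1 sphingoid base every SM species is built on.
DEFAULT_LCB = FattyAcyl(18, 1, hydroxyls=2, is_lcb=True)


@dataclass(frozen=True)
class LipidAnnotation:
    """A parsed shorthand lipid name at sum or molecular level."""

    lipid_class: str
    level: str  # "sum" | "molecular"
    sum_carbons: int
    sum_double_bonds: int
    sum_hydroxyls: int = 0
    moieties: tuple[FattyAcyl, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.lipid_class not in _ALL_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.level not in ("sum", "molecular"):
            raise ValueError(f"unknown annotation level {self.level!r}")
        if self.level == "molecular":
            expected = _moiety_count(self.lipid_class)
            if len(self.moieties) != expected:
                raise ValueError(
                    f"{self.lipid_class} molecular species needs {expected} moieties, "
                    f"got {len(self.moieties)}"
                )
            if self.lipid_class == "SM":
                n_lcb = sum(m.is_lcb for m in self.moieties)
                if n_lcb != 1:
                    raise ValueError("SM molecular species needs exactly one LCB")
            totals = (
                sum(m.carbons for m in self.moieties),
                sum(m.double_bonds for m in self.moieties),
                sum(m.hydroxyls for m in self.moieties),
            )
            if totals != (self.sum_carbons, self.sum_double_bonds, self.sum_hydroxyls):
                raise ValueError("sum composition inconsistent with moieties")

    @property
    def sum_key(self) -> tuple[str, int, int]:
        return (self.lipid_class, self.sum_carbons, self.sum_double_bonds)

    @property
    def sorted_moieties(self) -> tuple[FattyAcyl, ...]:
        return tuple(sorted(self.moieties))

    def as_sum(self) -> "LipidAnnotation":
        """The sum-composition view of this annotation."""
        return LipidAnnotation(
            self.lipid_class,
            "sum",
            self.sum_carbons,
            self.sum_double_bonds,
            self.sum_hydroxyls,
        )

    def __str__(self) -> str:
        return format_annotation(self)


def _moiety_count(lipid_class: str) -> int:
    if lipid_class == "TAG":
        return 3
    if lipid_class == "FA":
        return 1
    return 2  # glycerophospholipids and SM (LCB + FA)


def molecular(lipid_class: str, moieties: Sequence[FattyAcyl]) -> LipidAnnotation:
    """Build a molecular-level annotation from a moiety list."""
    ms = tuple(moieties)
    return LipidAnnotation(
        lipid_class,
        "molecular",
        sum(m.carbons for m in ms),
        sum(m.double_bonds for m in ms),
        sum(m.hydroxyls for m in ms),
        ms,
    )


_ACYL_RE = re.compile(r"^(\d+):(\d+)(?:;(\d+))?$")


def _parse_acyl(token: str, is_lcb: bool = False) -> FattyAcyl:
    m = _ACYL_RE.match(token)
    if not m:
        raise ParseError(f"malformed fatty acyl token {token!r} (expected C:D[;OH])")
    try:
        return FattyAcyl(
            int(m.group(1)), int(m.group(2)), int(m.group(3) or 0), is_lcb=is_lcb
        )
    except ValueError as exc:
        raise ParseError(f"invalid fatty acyl {token!r}: {exc}") from exc


def parse_annotation(text: str) -> LipidAnnotation:
    """Parse a shorthand lipid name such as ``TAG 52:2`` or ``PC 16:0-18:1``."""
    if not text or not text.strip():
        raise ParseError("empty annotation")
    t = text.strip().replace("–", "-")  # en-dash accepted
    parts = t.split(None, 1)
    if len(parts) != 2:
        raise ParseError(f"annotation {text!r} lacks a composition body")
    cls, body = parts
    if cls not in _ALL_CLASSES:
        raise ParseError(f"unknown lipid class {cls!r} in {text!r}")

    if cls == "SM":
        if "/" in body:
            lcb_tok, _, fa_tok = body.partition("/")
            lcb = _parse_acyl(lcb_tok, is_lcb=True)
            if lcb.hydroxyls == 0:
                raise ParseError(f"SM long-chain base {lcb_tok!r} needs a ;OH count")
            fa = _parse_acyl(fa_tok)
            return molecular("SM", (lcb, fa))
        acyl = _parse_acyl(body)
        hydroxyls = acyl.hydroxyls or 2  # dihydroxy backbone assumed
        return LipidAnnotation("SM", "sum", acyl.carbons, acyl.double_bonds, hydroxyls)

    tokens = body.split("-")
    if len(tokens) == 1:
        acyl = _parse_acyl(tokens[0])
        if cls == "FA":
            return molecular("FA", (acyl,))
        return LipidAnnotation(cls, "sum", acyl.carbons, acyl.double_bonds)
    expected = _moiety_count(cls)
    if len(tokens) != expected:
        raise ParseError(
            f"{cls} molecular species needs {expected} moieties, got {len(tokens)} in {text!r}"
        )
    return molecular(cls, tuple(_parse_acyl(tok) for tok in tokens))


def format_annotation(ann: LipidAnnotation) -> str:
    """Format an annotation; emits hyphen separators and ``LCB/FA`` for SM."""
    if ann.level == "sum":
        body = f"{ann.sum_carbons}:{ann.sum_double_bonds}"
        if ann.lipid_class == "SM":
            body += f";{ann.sum_hydroxyls}"
        return f"{ann.lipid_class} {body}"
    if ann.lipid_class == "SM":
        lcb = next(m for m in ann.moieties if m.is_lcb)
        fa = next(m for m in ann.moieties if not m.is_lcb)
        return f"SM {lcb.shorthand}/{fa.shorthand}"
    return f"{ann.lipid_class} " + "-".join(m.shorthand for m in ann.moieties)


# --- elemental composition ---------------------------------------------------
# Neutral species = backbone residue + sum of free chains - one H2O per
# ester/amide bond. Backbone residues (free alcohol forms):
#   TAG: glycerol;  PC: glycerophosphocholine;  PE: glycerophosphoethanolamine;
#   PS: glycerophosphoserine;  PI: glycerophosphoinositol.
# SM = LCB + FA - H2O (amide) + phosphocholine residue C5H12NO3P.
_H2O = Formula(H=2, O=1)
_BACKBONES: dict[str, tuple[Formula, int]] = {
    "TAG": (Formula(C=3, H=8, O=3), 3),
    "PC": (Formula(C=8, H=20, N=1, O=6, P=1), 2),
    "PE": (Formula(C=5, H=14, N=1, O=6, P=1), 2),
    "PS": (Formula(C=6, H=14, N=1, O=8, P=1), 2),
    "PI": (Formula(C=9, H=19, O=11, P=1), 2),
}
_SM_HEADGROUP = Formula(C=5, H=12, N=1, O=3, P=1)


def elemental_composition(ann: LipidAnnotation) -> Formula:
    """Neutral elemental formula of a species (sum level fixes it per class)."""
    cls = ann.lipid_class
    n, d = ann.sum_carbons, ann.sum_double_bonds
    if cls == "FA":
        return ann.moieties[0].acid_formula
    if cls == "SM":
        # LCB(a:dl;h) + FA - H2O + C5H12NO3P depends only on the totals.
        h = ann.sum_hydroxyls
        return Formula(C=n + 5, H=2 * n + 13 - 2 * d, N=2, O=h + 4, P=1)
    if cls not in _BACKBONES:
        raise ValueError(f"unsupported lipid class {cls!r}")
    backbone, n_chains = _BACKBONES[cls]
    chains = Formula(C=n, H=2 * n - 2 * d, O=2 * n_chains)  # sum of free acids
    return backbone + chains - n_chains * _H2O


def species_mz(ann: LipidAnnotation, adduct: Adduct | str) -> float:
    """Precursor m/z of a species under an adduct."""
    return monoisotopic_mz(elemental_composition(ann), adduct)


# --- candidate enumeration ----------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    species: LipidAnnotation
    adduct: str
    mz: float


def enumerate_candidates(
    fa_pool: Iterable[FattyAcyl],
    classes: Iterable[str],
    mz_range: tuple[float, float] = (400.0, 1000.0),
    adducts: dict[str, str] | None = None,
    lcb: FattyAcyl = DEFAULT_LCB,
) -> list[Candidate]:
    """All molecular species over an FA pool whose adduct m/z is in range.

    TAG species are multisets of three pool FAs, glycerophospholipids
    multisets of two, SM the fixed LCB plus one pool FA. Deduplicated and
    deterministically ordered by (class, m/z).
    """
    pool = sorted(set(fa_pool))
    lo, hi = mz_range
    default_adducts = {
        "TAG": "+NH4", "PC": "+H", "SM": "+H", "PE": "-H", "PS": "-H", "PI": "-H",
    }
    adducts = {**default_adducts, **(adducts or {})}
    out: list[Candidate] = []
    for cls in sorted(set(classes)):
        if cls not in LIPID_CLASSES:
            raise ValueError(f"unsupported lipid class {cls!r}")
        add = adducts[cls]
        if add not in ADDUCTS:
            raise ValueError(f"unknown adduct {add!r}")
        if cls == "SM":
            combos: Iterable[tuple[FattyAcyl, ...]] = (((lcb, fa)) for fa in pool)
        else:
            k = _moiety_count(cls)
            combos = itertools.combinations_with_replacement(pool, k)
        for moieties in combos:
            ann = molecular(cls, moieties)
            mz = species_mz(ann, add)
            if lo <= mz <= hi:
                out.append(Candidate(ann, add, mz))
    out.sort(key=lambda c: (c.species.lipid_class, c.mz, str(c.species)))
    return out


def default_fa_pool(
    carbons: tuple[int, int] = (4, 20), double_bonds: tuple[int, int] = (0, 5)
) -> list[FattyAcyl]:
    """The default fatty-acyl search pool (TAG: 4-20 C, 0-5 double bonds)."""
    lo_c, hi_c = carbons
    lo_d, hi_d = double_bonds
    return [
        FattyAcyl(c, d)
        for c in range(lo_c, hi_c + 1)
        for d in range(lo_d, min(hi_d, c // 2) + 1)
    ]


def gpl_fa_pool() -> list[FattyAcyl]:
    """FA pool for glycerophospholipids (no short-chain moieties < 12 C)."""
    return default_fa_pool(carbons=(12, 22))
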