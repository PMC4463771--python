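"""Elemental formulas and monoisotopic mass arithmetic.

The element mass table ships as a plain-text resource
(``milklip/data/elements.tsv``) so the provenance of every printed m/z is a
single versioned file. Formulas are immutable mappings over {C, H, N, O, P};
ion m/z arithmetic accounts for the electron mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

__all__ = [
    "ELEMENT_MASS",
    "ELECTRON_MASS",
    "Formula",
    "Adduct",
    "ADDUCTS",
    "monoisotopic_mz",
]


def _load_element_masses() -> dict[str, float]:
    text = resources.files("milklip.data").joinpath("elements.tsv").read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        table[symbol] = float(mass)
    return table


_TABLE = _load_element_masses()
ELECTRON_MASS: float = _TABLE.pop("e-")
ELEMENT_MASS: Mapping[str, float] = dict(_TABLE)

# Canonical (Hill-ish) element order used for formatting.
_ORDER = ("C", "H", "N", "O", "P")


@dataclass(frozen=True)
class Formula:
    """An elemental composition over {C, H, N, O, P}.

    Neutral species formulas must have non-negative counts; signed counts are
    permitted so that adduct deltas (e.g. loss of a proton) can be expressed
    and applied with the same arithmetic.
    """

    counts: tuple[tuple[str, int], ...] = field(default=())

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in ELEMENT_MASS:
                    raise ValueError(f"unknown element {el!r}")
                merged[el] = merged.get(el, 0) + int(n)
        ordered = tuple((el, merged[el]) for el in _ORDER if merged.get(el, 0) != 0)
        object.__setattr__(self, "counts", ordered)

    def __getitem__(self, el: str) -> int:
        return dict(self.counts).get(el, 0)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __add__(self, other: "Formula") -> "Formula":
        d = dict(self.counts)
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return Formula(d)

    def __sub__(self, other: "Formula") -> "Formula":
        d = dict(self.counts)
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
        return Formula(d)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.counts})

    __rmul__ = __mul__

    @property
    def mass(self) -> float:
        """Monoisotopic mass in u (valid for non-negative counts)."""
        if any(n < 0 for _, n in self.counts):
            raise ValueError(f"negative element count in {self}")
        return sum(ELEMENT_MASS[el] * n for el, n in self.counts)

    def __str__(self) -> str:
        parts = []
        for el, n in self.counts:
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts) or "(empty)"


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: a formula delta plus a charge delta of +/-1."""

    name: str
    delta: Formula
    charge: int

    def __post_init__(self) -> None:
        if self.charge not in (-1, 1):
            raise ValueError("only singly charged adducts are supported")


ADDUCTS: dict[str, Adduct] = {
    "+NH4": Adduct("+NH4", Formula(N=1, H=4), +1),
    "+H": Adduct("+H", Formula(H=1), +1),
    "-H": Adduct("-H", Formula(H=-1), -1),
    "+HCOO": Adduct("+HCOO", Formula(C=1, H=1, O=2), -1),
}
# Unicode minus variants accepted as aliases.
ADDUCTS["−H"] = ADDUCTS["-H"]


def monoisotopic_mz(formula: Formula, adduct: Adduct | str) -> float:
    """m/z of ``formula`` ionized by ``adduct``, electron mass included.

    One electron mass is subtracted per positive charge and added per
    negative charge; singly charged ions only, so m/z equals the ion mass.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None
    ion = formula + adduct.delta
    if any(n < 0 for _, n in ion.counts):
        raise ValueError(f"adduct {adduct.name} not applicable to {formula}")
    return ion.mass - adduct.charge * ELECTRON_MASS
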