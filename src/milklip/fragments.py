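"""Structure-specific fragment prediction per lipid class and polarity.

Positive mode: ammoniated TAG species lose one fatty acid plus ammonia,
leaving a diacylglycerol-like fragment whose m/z identifies the lost FA;
protonated PC and SM yield the phosphocholine headgroup ion at m/z 184.0733.
Negative mode: glycerophospholipids release their fatty acyls as carboxylate
anions (PC via its formate adduct), and PS additionally loses the serine
headgroup (87.0320 u) from the deprotonated precursor.

Which fragment kinds apply to which class/polarity is data, not code: see
``milklip/data/fragment_rules.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .elements import ELECTRON_MASS, Formula
from .nomenclature import FattyAcyl, LipidAnnotation, species_mz

__all__ = [
    "FragmentRule",
    "load_fragment_rules",
    "allowed_kinds",
    "tag_neutral_loss_fragments",
    "gpl_fragments",
    "fa_anion_mz",
    "nl_label",
    "fa_label",
    "HEADGROUP_LABEL",
    "SERINE_LOSS_LABEL",
    "PHOSPHOCHOLINE_MZ",
    "SERINE_LOSS_MASS",
]

_NH3 = Formula(N=1, H=3)
_PHOSPHOCHOLINE_ION = Formula(C=5, H=15, N=1, O=4, P=1)  # protonated headgroup
PHOSPHOCHOLINE_MZ = _PHOSPHOCHOLINE_ION.mass - ELECTRON_MASS
SERINE_LOSS_MASS = Formula(C=3, H=5, N=1, O=2).mass  # dehydroalanine-like loss

HEADGROUP_LABEL = "headgroup 184.0733"
SERINE_LOSS_LABEL = "NL serine"


def nl_label(fa: FattyAcyl) -> str:
    return f"NL FA {fa.shorthand}"


def fa_label(fa: FattyAcyl) -> str:
    return f"FA {fa.shorthand}"


@dataclass(frozen=True)
class FragmentRule:
    lipid_class: str
    polarity: str
    kind: str


_KINDS = {"neutral-loss-of-fa", "fa-anion", "headgroup", "serine-loss"}


def load_fragment_rules() -> tuple[FragmentRule, ...]:
    text = resources.files("milklip.data").joinpath("fragment_rules.tsv").read_text()
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, pol, kind = line.split("\t")
        if kind not in _KINDS:
            raise ValueError(f"unknown fragment kind {kind!r}")
        if pol not in "+-":
            raise ValueError(f"bad polarity {pol!r}")
        rules.append(FragmentRule(cls, pol, kind))
    return tuple(rules)


_RULES = load_fragment_rules()


def allowed_kinds(lipid_class: str, polarity: str) -> set[str]:
    return {r.kind for r in _RULES if r.lipid_class == lipid_class and r.polarity == polarity}


def fa_anion_mz(fa: FattyAcyl) -> float:
    """m/z of the fatty acid carboxylate anion [FA - H]-."""
    return fa.acid_formula.mass - Formula(H=1).mass + ELECTRON_MASS


def tag_neutral_loss_fragments(
    species: LipidAnnotation, adduct: str = "+NH4"
) -> list[tuple[FattyAcyl, float]]:
    """Neutral-loss fragments of a molecular TAG, one per distinct FA.

    fragment m/z = precursor m/z - (free fatty acid mass + NH3 mass); the
    ammonium adduct leaves as ammonia together with the acid.
    """
    if species.lipid_class != "TAG" or species.level != "molecular":
        raise ValueError("neutral-loss prediction needs a molecular-level TAG")
    precursor = species_mz(species, adduct)
    out = []
    for fa in sorted(set(species.moieties)):
        out.append((fa, precursor - fa.acid_formula.mass - _NH3.mass))
    return out


def gpl_fragments(species: LipidAnnotation, polarity: str) -> list[tuple[str, float]]:
    """Class-specific fragments of a glycerophospholipid or PC/SM species.

    Positive PC/SM (any level): the phosphocholine ion. Negative PE/PI/PC
    (molecular): both FA carboxylate anions. Negative PS: FA anions plus the
    serine-loss fragment at precursor m/z - 87.0320.
    """
    kinds = allowed_kinds(species.lipid_class, polarity)
    if not kinds:
        raise ValueError(
            f"no fragment rule for class {species.lipid_class} in polarity {polarity!r}"
        )
    frags: list[tuple[str, float]] = []
    if "headgroup" in kinds:
        frags.append((HEADGROUP_LABEL, PHOSPHOCHOLINE_MZ))
    if "fa-anion" in kinds:
        if species.level != "molecular":
            raise ValueError("FA-anion prediction needs a molecular-level species")
        for fa in sorted(set(species.moieties)):
            if fa.is_lcb:
                continue
            frags.append((fa_label(fa), fa_anion_mz(fa)))
    if "serine-loss" in kinds:
        precursor = species_mz(species, "-H")
        frags.append((SERINE_LOSS_LABEL, precursor - SERINE_LOSS_MASS))
    return frags
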