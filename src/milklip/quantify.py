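"""Internal-standard quantification and composite indices.

A species' molar amount follows from the ratio of its summed structure-
specific fragment intensities to those of its class internal standard::

    pmol(species) = spike_pmol(class std) * sum(evidence) / sum(evidence std)

where the evidence sum is over neutral-loss intensities for TAG, FA-anion
intensities for glycerophospholipids, and the headgroup intensity for PC/SM
sum species. Being a ratio, the estimate is invariant under any global
intensity scaling and exactly linear in a species' fragment intensities.

The TAG FA index gives, per TAG sum composition, the proportion of each FA
esterified to it (neutral-loss intensity shares); the FA profile aggregates
indices over species weighted by pmol; the unsaturation index bins the
profile by double-bond count (0-5). No isomeric-TAG stoichiometry is
deconvolved: the FA index is the deliberate alternative.
"""

from __future__ import annotations

import logging

import pandas as pd

from .identify import Identification

logger = logging.getLogger(__name__)

__all__ = [
    "quantify",
    "class_composition",
    "tag_fa_index",
    "tag_fa_profile",
    "unsaturation_index",
    "evidence_sum",
    "quant_to_tsv",
    "profile_to_tsv",
]


def evidence_sum(ident: Identification) -> float:
    """Quantification-relevant fragment intensity sum for one record."""
    if ident.species.lipid_class == "TAG":
        keys = [k for k in ident.evidence if k.startswith("NL FA ")]
    elif ident.level == "molecular":
        keys = [k for k in ident.evidence if k.startswith("FA ")]
    else:  # sum-level PC/SM via the headgroup ion
        keys = [k for k in ident.evidence if k.startswith("headgroup")]
    return float(sum(ident.evidence[k] for k in keys))


def quantify(
    identifications: list[Identification],
    spike_sheet: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Quantification table (pmol and mol%) from identifications.

    Each lipid class with sample identifications must carry exactly one
    internal-standard identification with non-zero evidence; standards are
    excluded from the output rows and from all mol% denominators.
    ``spike_sheet`` may override the spike amounts attached during
    identification.
    """
    by_class_std: dict[str, Identification] = {}
    samples: list[Identification] = []
    for ident in identifications:
        if ident.internal_standard:
            cls = ident.species.lipid_class
            if cls in by_class_std:
                raise ValueError(f"more than one internal standard for class {cls}")
            by_class_std[cls] = ident
        else:
            samples.append(ident)

    missing = sorted(
        {i.species.lipid_class for i in samples} - set(by_class_std)
    )
    if missing:
        raise ValueError(f"missing internal standard for class(es): {', '.join(missing)}")

    rows = []
    for ident in samples:
        cls = ident.species.lipid_class
        std = by_class_std[cls]
        std_sum = evidence_sum(std)
        if std_sum <= 0:
            raise ValueError(f"zero internal-standard intensity for class {cls}")
        spike = std.spike_pmol
        if spike_sheet is not None:
            for name, pmol in spike_sheet.items():
                from .nomenclature import parse_annotation

                ann = parse_annotation(name)
                if ann.lipid_class == cls:
                    spike = pmol
        if spike is None:
            raise ValueError(f"no spike amount known for class {cls} standard")
        pmol = spike * evidence_sum(ident) / std_sum
        rows.append(
            {
                "species": str(ident.species),
                "lipid_class": cls,
                "level": ident.level,
                "pmol": pmol,
                "_ident": ident,
            }
        )
    if not rows:
        raise ValueError("no sample identifications to quantify")
    df = pd.DataFrame(rows)
    total = df["pmol"].sum()
    if total <= 0:
        raise ValueError("all quantified amounts are zero")
    df["mol_pct_total"] = 100.0 * df["pmol"] / total
    df["mol_pct_class"] = 100.0 * df["pmol"] / df.groupby("lipid_class")["pmol"].transform("sum")
    return df


def class_composition(quant: pd.DataFrame) -> pd.Series:
    """Lipid class mol% of the total quantified lipidome."""
    if quant.empty or quant["pmol"].sum() <= 0:
        raise ValueError("empty or all-zero quantification table")
    return quant.groupby("lipid_class")["mol_pct_total"].sum().sort_index()


def tag_fa_index(identifications: list[Identification]) -> pd.DataFrame:
    """Per-TAG-sum-composition FA proportions from neutral-loss shares.

    Rows: TAG sum compositions; columns: FA shorthand; every row sums to 1.
    Species with zero total neutral-loss evidence are excluded (logged).
    """
    rows = {}
    for ident in identifications:
        if ident.species.lipid_class != "TAG" or ident.internal_standard:
            continue
        nl = {
            k.removeprefix("NL FA "): v
            for k, v in ident.evidence.items()
            if k.startswith("NL FA ")
        }
        total = sum(nl.values())
        if total <= 0:
            logger.info("TAG %s: zero neutral-loss evidence, excluded", ident.species)
            continue
        rows[str(ident.species)] = {fa: v / total for fa, v in nl.items()}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return df.sort_index()[sorted(df.columns, key=_fa_sort_key)] if not df.empty else df


def _fa_sort_key(fa: str) -> tuple[int, int]:
    c, _, d = fa.partition(":")
    return (int(c), int(d))


def tag_fa_profile(quant: pd.DataFrame, fa_index: pd.DataFrame) -> dict[str, float]:
    """Percentage of each FA across all TAG molecules (pmol-weighted index)."""
    tag = quant[quant["lipid_class"] == "TAG"]
    weights = tag.set_index("species")["pmol"]
    common = fa_index.index.intersection(weights.index)
    if len(common) == 0:
        raise ValueError("no TAG species shared between quant table and FA index")
    w = weights.loc[common]
    contrib = fa_index.loc[common].multiply(w, axis=0).sum(axis=0)
    pct = 100.0 * contrib / w.sum()
    return {fa: float(pct[fa]) for fa in pct.index}


def unsaturation_index(
    fa_profile: dict[str, float], max_double_bonds: int = 5
) -> dict[int, float]:
    """Distribution of TAG-esterified FAs over double-bond counts 0..max."""
    out = {d: 0.0 for d in range(max_double_bonds + 1)}
    for fa, pct in fa_profile.items():
        _, d = _fa_sort_key(fa)
        if d > max_double_bonds:
            raise ValueError(
                f"FA {fa} exceeds the double-bond cap of {max_double_bonds}"
            )
        out[d] += pct
    return out


def quant_to_tsv(quant: pd.DataFrame) -> str:
    df = quant[["species", "lipid_class", "level", "pmol", "mol_pct_total", "mol_pct_class"]]
    df = df.copy()
    for col in ("mol_pct_total", "mol_pct_class"):
        df[col] = df[col].round(2)
    return df.to_csv(sep="\t", index=False, float_format="%.4f")


def profile_to_tsv(profile: dict, value_name: str = "percent") -> str:
    lines = [f"key\t{value_name}"]
    lines += [f"{k}\t{v:.2f}" for k, v in profile.items()]
    return "\n".join(lines) + "\n"
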