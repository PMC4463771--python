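"""Matching candidate lipid species to MS/MS^ALL experiments.

Identification is MS/MS-only (no precursor survey scan): a species is looked
for in the spectrum of the unit step whose isolation window contains its
precursor m/z, and is accepted on structure-specific fragment evidence:

* TAG (sum composition, positive mode): neutral-loss fragments of
  chemically consistent FA moieties; at least ``min_tag_fragments`` distinct
  losses required (a single-fragment TAG is indistinguishable from noise).
* glycerophospholipids (molecular, negative mode): both FA carboxylate
  anions, whose moieties must add up to the precursor sum composition;
  PS additionally requires the serine-loss fragment.
* PC/SM (sum composition, positive mode): the phosphocholine headgroup ion
  at m/z 184.0733 plus a candidate precursor in the step window.

Internal standards from the spike sheet are identified by direct molecular
matching (their identity is known a priori) and flagged; the minimum-
fragment threshold does not apply to them.

Co-isolated candidates in one window are searched independently; shared
peaks may support several precursors (type-II interference is not
corrected).
"""

from __future__ import annotations

import bisect
import itertools
import logging
from dataclasses import dataclass, field, replace

from . import fragments as frag
from .nomenclature import (
    CLASS_ADDUCTS,
    DEFAULT_LCB,
    FattyAcyl,
    LipidAnnotation,
    default_fa_pool,
    gpl_fa_pool,
    molecular,
    species_mz,
)
from .spectra import Experiment, MsMsSpectrum, PRECURSOR_STEP_RANGE, step_of

logger = logging.getLogger(__name__)

__all__ = [
    "MatchSettings",
    "Identification",
    "match_fragments",
    "identify_tag",
    "identify_gpl",
    "identify_headgroup_species",
    "identify_all",
    "identifications_to_tsv",
]

GPL_CLASSES = ("PC", "PE", "PI", "PS")


@dataclass(frozen=True)
class MatchSettings:
    """Tolerances and evidence thresholds for fragment matching."""

    tolerance: float = 0.01  # absolute m/z, TOF-like
    min_tag_fragments: int = 2
    intensity_floor: float = 0.0
    headgroup_max_db: int = 6  # candidate cap for 184.0733-based sum species

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("fragment tolerance must be > 0")


@dataclass(frozen=True)
class Identification:
    """A species matched in an experiment, with per-fragment intensities."""

    species: LipidAnnotation
    step: int
    polarity: str
    evidence: dict[str, float] = field(hash=False)
    internal_standard: bool = False
    spike_pmol: float | None = None

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("identification requires non-empty evidence")

    @property
    def level(self) -> str:
        return self.species.level


def match_fragments(
    spectrum: MsMsSpectrum,
    predicted: list[tuple[str, float]],
    settings: MatchSettings,
) -> dict[str, float]:
    """Match predictions to nearest peaks within tolerance.

    Each prediction takes the single nearest peak within tolerance (on an
    exact distance tie, the lower-m/z peak). A peak may serve several
    predictions only when their predicted m/z differ by less than the
    tolerance (logged); otherwise later predictions fall back to the
    nearest unclaimed peak. Matches at or below the intensity floor drop.
    """
    mzs = spectrum.mzs
    evidence: dict[str, float] = {}
    claimed: dict[int, float] = {}  # peak index -> predicted m/z that claimed it
    for label, pred in sorted(predicted, key=lambda lp: lp[1]):
        lo = bisect.bisect_left(mzs, pred - settings.tolerance)
        hi = bisect.bisect_right(mzs, pred + settings.tolerance)
        best = None
        for i in range(lo, hi):
            if i in claimed and abs(claimed[i] - pred) >= settings.tolerance:
                continue
            d = abs(mzs[i] - pred)
            if best is None or d < best[0]:  # strict: ties keep lower m/z
                best = (d, i)
        if best is None:
            continue
        i = best[1]
        if i in claimed:
            logger.debug(
                "peak %.4f shared by predictions %.4f and %.4f", mzs[i], claimed[i], pred
            )
        else:
            claimed[i] = pred
        intensity = spectrum.peaks[i].intensity
        if intensity <= settings.intensity_floor and settings.intensity_floor > 0:
            continue
        evidence[label] = intensity
    return evidence


def _in_acquisition(mz: float) -> bool:
    lo, hi = PRECURSOR_STEP_RANGE
    return lo - 0.5 <= mz < hi + 0.5


def _flag_standards(
    idents: list[Identification], experiment: Experiment
) -> list[Identification]:
    """Mark identifications matching a spike-sheet species and attach pmol."""
    spikes = experiment.parsed_spikes().values()
    out = []
    for ident in idents:
        hit = None
        for ann, pmol in spikes:
            if ann.lipid_class != ident.species.lipid_class:
                continue
            if ident.level == "molecular":
                if ident.species.sorted_moieties == ann.sorted_moieties:
                    hit = pmol
            elif ident.species.sum_key == ann.sum_key:
                hit = pmol
        if hit is not None:
            ident = replace(ident, internal_standard=True, spike_pmol=hit)
        out.append(ident)
    return out


def _identify_tag_standards(
    experiment: Experiment, settings: MatchSettings
) -> list[Identification]:
    out = []
    for ann, pmol in experiment.parsed_spikes().values():
        if ann.lipid_class != "TAG":
            continue
        mz = species_mz(ann, "+NH4")
        if not _in_acquisition(mz):
            continue
        spec = experiment.spectrum(step_of(mz), "+")
        if spec is None:
            continue
        predicted = [
            (frag.nl_label(fa), fmz) for fa, fmz in frag.tag_neutral_loss_fragments(ann)
        ]
        evidence = match_fragments(spec, predicted, settings)
        if evidence:
            out.append(
                Identification(
                    ann.as_sum(), spec.precursor_step, "+", evidence,
                    internal_standard=True, spike_pmol=pmol,
                )
            )
    return out


def identify_tag(
    experiment: Experiment,
    settings: MatchSettings = MatchSettings(),
    fa_pool: list[FattyAcyl] | None = None,
) -> list[Identification]:
    """Sum-composition TAG identification with per-FA neutral-loss evidence.

    For every sum composition reachable from the FA pool whose ammoniated
    precursor falls in an acquired step, neutral losses are predicted for
    each pool FA that can be complemented by two further pool FAs to the sum
    composition; the species is accepted when at least
    ``settings.min_tag_fragments`` distinct losses match.
    """
    pool = sorted(set(fa_pool if fa_pool is not None else default_fa_pool()))
    pair_sums = {
        (a.carbons + b.carbons, a.double_bonds + b.double_bonds)
        for a, b in itertools.combinations_with_replacement(pool, 2)
    }
    triple_sums = {
        (c + fa.carbons, d + fa.double_bonds) for (c, d) in pair_sums for fa in pool
    }
    std_sums = {
        ann.sum_key
        for ann, _ in experiment.parsed_spikes().values()
        if ann.lipid_class == "TAG"
    }

    out = _identify_tag_standards(experiment, settings)
    for n, d in sorted(triple_sums):
        ann = LipidAnnotation("TAG", "sum", n, d)
        if ann.sum_key in std_sums:
            continue  # internal standard handled by direct matching
        mz = species_mz(ann, "+NH4")
        if not _in_acquisition(mz):
            continue
        spec = experiment.spectrum(step_of(mz), "+")
        if spec is None:
            continue
        predicted = []
        for fa in pool:
            rest = (n - fa.carbons, d - fa.double_bonds)
            if rest not in pair_sums:
                continue
            predicted.append(
                (frag.nl_label(fa), mz - fa.acid_formula.mass - _NH3_MASS)
            )
        evidence = match_fragments(spec, predicted, settings)
        if len(evidence) >= settings.min_tag_fragments:
            out.append(Identification(ann, spec.precursor_step, "+", evidence))
    return out


_NH3_MASS = frag.Formula(N=1, H=3).mass


def identify_gpl(
    experiment: Experiment,
    settings: MatchSettings = MatchSettings(),
    fa_pool: list[FattyAcyl] | None = None,
    classes: tuple[str, ...] = GPL_CLASSES,
) -> list[Identification]:
    """Molecular glycerophospholipid identification from FA-anion pairs.

    A molecular species FA1-FA2 is accepted iff all its distinct FA anions
    match in the negative spectrum of the step containing its precursor
    (PE/PI/PS deprotonated, PC as formate adduct); the moiety totals equal
    the precursor sum composition by construction. PS additionally requires
    the serine-loss fragment.

    PC formate candidates are exact isobars of deprotonated PS species three
    carbons and one double bond away ([PC n:d + HCOO]- and [PS (n+3):(d-1)
    - H]- share one elemental formula), so a molecular PC is only accepted
    when the positive spectrum at its [M+H]+ step confirms the
    phosphocholine headgroup ion (skipped when no positive spectra were
    acquired at all).
    """
    pool = sorted(set(fa_pool if fa_pool is not None else gpl_fa_pool()))
    have_positive = any(pol == "+" for _, pol in experiment.spectra)
    out = []
    for cls in classes:
        adduct = CLASS_ADDUCTS[(cls, "-")]
        for pair in itertools.combinations_with_replacement(pool, 2):
            ann = molecular(cls, pair)
            mz = species_mz(ann, adduct)
            if not _in_acquisition(mz):
                continue
            spec = experiment.spectrum(step_of(mz), "-")
            if spec is None:
                continue
            predicted = frag.gpl_fragments(ann, "-")
            evidence = match_fragments(spec, predicted, settings)
            required = {label for label, _ in predicted}
            if not required <= set(evidence):
                continue
            if cls == "PC" and have_positive:
                pos_mz = species_mz(ann, "+H")
                pos_spec = (
                    experiment.spectrum(step_of(pos_mz), "+")
                    if _in_acquisition(pos_mz)
                    else None
                )
                confirmed = pos_spec is not None and match_fragments(
                    pos_spec,
                    [(frag.HEADGROUP_LABEL, frag.PHOSPHOCHOLINE_MZ)],
                    settings,
                )
                if not confirmed:
                    logger.info(
                        "PC %s rejected: no headgroup confirmation at its "
                        "[M+H]+ step (isobaric with a PS species)", ann,
                    )
                    continue
            out.append(Identification(ann, spec.precursor_step, "-", evidence))
    return _flag_standards(out, experiment)


def identify_headgroup_species(
    experiment: Experiment,
    settings: MatchSettings = MatchSettings(),
    fa_pool: list[FattyAcyl] | None = None,
    lcb: FattyAcyl = DEFAULT_LCB,
) -> list[Identification]:
    """Sum-level PC/SM identification via the phosphocholine fragment.

    Each positive step holding a 184.0733-tolerant peak and containing a
    candidate protonated PC or SM precursor yields a sum-level record with
    the headgroup intensity as evidence. Candidates are sum compositions
    reachable from the FA pool (PC: pairs; SM: fixed LCB + one FA), capped
    at ``settings.headgroup_max_db`` total double bonds.
    """
    pool = sorted(set(fa_pool if fa_pool is not None else gpl_fa_pool()))
    candidates: list[tuple[LipidAnnotation, float]] = []
    seen = set()
    for pair in itertools.combinations_with_replacement(pool, 2):
        ann = molecular("PC", pair).as_sum()
        if ann.sum_double_bonds > settings.headgroup_max_db or ann.sum_key in seen:
            continue
        seen.add(ann.sum_key)
        candidates.append((ann, species_mz(ann, "+H")))
    for fa in pool:
        ann = molecular("SM", (lcb, fa)).as_sum()
        if ann.sum_double_bonds > settings.headgroup_max_db or ann.sum_key in seen:
            continue
        seen.add(ann.sum_key)
        candidates.append((ann, species_mz(ann, "+H")))

    out = []
    for (step, pol), spec in sorted(experiment.spectra.items()):
        if pol != "+":
            continue
        evidence = match_fragments(
            spec, [(frag.HEADGROUP_LABEL, frag.PHOSPHOCHOLINE_MZ)], settings
        )
        if not evidence:
            continue
        in_window = [
            (ann, mz)
            for ann, mz in candidates
            if _in_acquisition(mz) and step_of(mz) == step
        ]
        if not in_window:
            logger.info("step %d: headgroup peak with no PC/SM candidate", step)
            continue
        if len(in_window) > 1:
            logger.warning(
                "step %d: headgroup intensity shared by %d candidates (%s)",
                step, len(in_window), ", ".join(str(a) for a, _ in in_window),
            )
        for ann, _ in in_window:
            out.append(Identification(ann, step, "+", dict(evidence)))
    return _flag_standards(out, experiment)


def identify_all(
    experiment: Experiment,
    settings: MatchSettings = MatchSettings(),
    tag_pool: list[FattyAcyl] | None = None,
    gpl_pool: list[FattyAcyl] | None = None,
) -> list[Identification]:
    """Run all identification routes and merge duplicate PC records.

    A PC species found both as a molecular species (negative mode) and as a
    sum composition (headgroup route) keeps only the molecular record.
    """
    tags = identify_tag(experiment, settings, tag_pool)
    gpls = identify_gpl(experiment, settings, gpl_pool)
    heads = identify_headgroup_species(experiment, settings, gpl_pool)
    molecular_pc_sums = {
        i.species.sum_key for i in gpls if i.species.lipid_class == "PC"
    }
    merged = [
        h
        for h in heads
        if not (h.species.lipid_class == "PC" and h.species.sum_key in molecular_pc_sums)
    ]
    return tags + gpls + merged


def identifications_to_tsv(idents: list[Identification]) -> str:
    """Serialize identifications (species, level, step, polarity, evidence)."""
    lines = ["species\tlevel\tstep\tpolarity\tinternal_standard\tevidence"]
    for i in idents:
        ev = ";".join(f"{k}={v:.4f}" for k, v in sorted(i.evidence.items()))
        lines.append(
            f"{i.species}\t{i.level}\t{i.step}\t{i.polarity}\t"
            f"{int(i.internal_standard)}\t{ev}"
        )
    return "\n".join(lines) + "\n"
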