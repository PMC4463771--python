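"""Synthetic milk lipidomes and forward simulation of MS/MS^ALL and GC data.

The generator defines the study conditions: three milk-like ground-truth
compositions (human milk, cow milk, and a phospholipid-enriched formula
concentrate, "lacprodan") plus a second human profile differing by a seeded
+/-10% inter-individual perturbation of TAG abundances. Human and cow milk
are TAG-dominated (> 97 mol%); cow milk carries a short-chain-FA TAG arm
(4-10 C moieties) that the formula shares, while the formula's class makeup
is 25/35/18/8/9/5 mol% (TAG/PE/PC/SM/PS/PI) dominated by PC 16:0-18:1,
PE 18:1-18:1, PI 18:0-18:1 and PS 18:0-18:1.

Forward model: each species (and each internal-standard spike) contributes
total fragment intensity ``SCALE * pmol * response_factor`` placed in the
spectrum of its precursor's step and polarity, split equally over its
esterified chains (so a twice-esterified FA carries twice the neutral-loss
intensity) with class-extra fragments (PS serine loss) taking one equal
share; headgroup-detected species put the full intensity on the 184.0733
ion. Co-isolated species superimpose additively. Noise: Gaussian ppm m/z
jitter, multiplicative log-normal intensity noise of a given CV, and
uniform random baseline peaks; everything is deterministic under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fragments as frag
from .gcfame import CalibrationCurve, FameName, GcPeak
from .nomenclature import LipidAnnotation, parse_annotation, species_mz
from .spectra import (
    Experiment,
    FRAGMENT_MZ_RANGE,
    FragmentPeak,
    MsMsSpectrum,
    PRECURSOR_STEP_RANGE,
    step_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthComposition",
    "NoiseModel",
    "DEFAULT_SPIKE_SHEET",
    "FIXTURE_NAMES",
    "make_fixture",
    "simulate_msmsall",
    "simulate_gc",
    "default_rt_library",
    "default_calibrations",
    "chain_fa_amounts",
    "chain_fa_percentages",
    "expected_species",
    "truth_class_mol_pct",
]

#: Detector response in intensity counts per pmol (arbitrary units).
SCALE = 100.0

#: Internal-standard spikes: one molecular species of known amount per class.
DEFAULT_SPIKE_SHEET: dict[str, float] = {
    "TAG 17:1-17:1-17:1": 93.0,
    "PE 17:0-14:1": 94.0,
    "PS 17:0-14:1": 94.0,
    "PC 17:0-14:1": 96.0,
    "PI 17:0-14:1": 98.0,
    "SM 18:1;2/17:0": 100.0,
}


@dataclass
class GroundTruthComposition:
    """A named list of molecular species with molar amounts (pmol)."""

    name: str
    species: list[tuple[LipidAnnotation, float]]
    response_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ann, pmol in self.species:
            if ann.level != "molecular":
                raise ValueError(f"ground truth species {ann} is not molecular-level")
            if pmol <= 0:
                raise ValueError(f"non-positive amount for {ann}")

    def rf(self, lipid_class: str) -> float:
        return self.response_factors.get(lipid_class, 1.0)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition noise: ppm m/z jitter, intensity CV, baseline peaks."""

    mz_jitter_ppm: float = 0.0
    intensity_cv: float = 0.0
    baseline_rate: float = 0.0  # expected baseline peaks per spectrum
    baseline_intensity: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mz_jitter_ppm, self.intensity_cv, self.baseline_rate) < 0:
            raise ValueError("noise parameters must be >= 0")


# --- fixture compositions -----------------------------------------------------
# pmol values are calibrated once to the published characteristics of each
# sample type (class fractions, short-chain FA share, FA 16:0 + 18:1
# dominance) and then frozen; see docs/methods.md.

_HUMAN1_TAG: dict[str, float] = {
    "TAG 16:0-18:1-18:1": 125,
    "TAG 16:0-18:0-18:2": 80,
    "TAG 16:0-18:1-18:2": 110,
    "TAG 14:0-16:0-18:1": 70,
    "TAG 14:0-16:1-18:1": 70,
    "TAG 12:0-18:1-18:2": 60,
    "TAG 18:1-18:1-18:2": 75,
    "TAG 16:0-18:2-18:2": 55,
    "TAG 12:0-16:0-18:1": 50,
    "TAG 8:0-16:0-18:1": 45,
    "TAG 16:0-18:1-20:3": 35,
    "TAG 14:0-16:0-16:0": 35,
    "TAG 12:0-14:0-18:1": 45,
    "TAG 18:0-18:1-18:3": 40,
    "TAG 14:0-18:1-20:4": 30,
}
_HUMAN1_OTHER: dict[str, float] = {
    "PC 16:0-18:1": 8,
    "PE 18:1-18:1": 7,
    "SM 18:1;2/16:0": 8,
}

_COW: dict[str, float] = {
    "TAG 4:0-16:0-16:0": 110,
    "TAG 4:0-14:0-18:1": 105,
    "TAG 6:0-14:0-16:0": 80,
    "TAG 14:0-16:0-18:1": 95,
    "TAG 16:0-16:0-18:1": 70,
    "TAG 14:0-16:0-16:0": 50,
    "TAG 16:0-18:1-18:1": 60,
    "TAG 14:0-14:0-16:0": 55,
    "TAG 12:0-14:0-18:0": 55,
    "TAG 16:0-18:0-18:1": 50,
    "TAG 12:0-16:0-18:0": 45,
    "TAG 16:0-18:1-18:2": 35,
    "TAG 10:0-14:0-18:0": 40,
    "TAG 14:0-14:0-18:0": 15,
    "PC 16:0-18:1": 7,
    "PE 16:0-18:1": 6,
    "SM 18:1;2/22:0": 6,
}

_LACPRODAN: dict[str, float] = {
    # TAG, 250 pmol
    "TAG 4:0-16:0-16:0": 60,
    "TAG 6:0-16:0-18:1": 35,
    "TAG 14:0-16:0-18:1": 35,
    "TAG 16:0-18:1-18:1": 32,
    "TAG 16:0-18:0-18:1": 30,
    "TAG 16:0-16:0-18:2": 25,
    "TAG 18:0-18:1-18:2": 10,
    "TAG 14:0-18:0-18:2": 15,
    "TAG 18:0-18:2-18:2": 8,
    # PE, 350 pmol; PE 18:1-18:1 = 34 mol% of class
    "PE 18:1-18:1": 119,
    "PE 16:0-18:1": 25,
    "PE 16:0-18:2": 60,
    "PE 18:0-18:1": 35,
    "PE 18:0-20:4": 45,
    "PE 16:0-22:5": 20,
    "PE 18:0-18:2": 21,
    "PE 18:2-18:2": 25,
    # PC, 180 pmol; PC 16:0-18:1 = 23 mol% of class
    "PC 16:0-18:1": 41.4,
    "PC 16:0-16:0": 14,
    "PC 18:0-18:1": 30,
    "PC 16:0-18:2": 30,
    "PC 18:1-18:1": 25,
    "PC 18:0-18:2": 39.6,
    # SM, 80 pmol
    "SM 18:1;2/16:0": 30,
    "SM 18:1;2/22:0": 35,
    "SM 18:1;2/18:0": 15,
    # PS, 90 pmol; PS 18:0-18:1 = 38 mol% of class
    "PS 18:0-18:1": 34.2,
    "PS 18:0-18:2": 25,
    "PS 18:1-18:1": 20,
    "PS 18:0-20:4": 10.8,
    # PI, 50 pmol; PI 18:0-18:1 = 39 mol% of class
    "PI 18:0-18:1": 19.5,
    "PI 16:0-18:1": 8,
    "PI 18:0-18:2": 16,
    "PI 18:0-20:4": 6.5,
}

FIXTURE_NAMES = ("human1", "human2", "cow", "lacprodan")


def make_fixture(name: str) -> GroundTruthComposition:
    """Deterministic ground-truth composition for a named sample profile."""
    if name == "human1":
        table = {**_HUMAN1_TAG, **_HUMAN1_OTHER}
    elif name == "human2":
        # Same profile with a seeded +/-10% perturbation of TAG abundances,
        # mimicking inter-individual variation.
        rng = np.random.default_rng(20150404)
        factors = rng.uniform(0.9, 1.1, size=len(_HUMAN1_TAG))
        table = {
            sp: pmol * f for (sp, pmol), f in zip(_HUMAN1_TAG.items(), factors)
        }
        table.update(_HUMAN1_OTHER)
    elif name == "cow":
        table = dict(_COW)
    elif name == "lacprodan":
        table = dict(_LACPRODAN)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    species = [(parse_annotation(sp), float(pmol)) for sp, pmol in table.items()]
    return GroundTruthComposition(name, species)


# --- forward MS/MS^ALL simulation --------------------------------------------


def _fragment_placements(
    ann: LipidAnnotation, intensity: float
) -> list[tuple[int, str, float, float]]:
    """(step, polarity, fragment m/z, intensity) placements for one species.

    Raises ValueError when the species' precursor lies outside the
    acquisition range for every route of its class.
    """
    cls = ann.lipid_class
    placements: list[tuple[int, str, float, float]] = []
    routes = 0

    def precursor_step(adduct: str) -> int | None:
        nonlocal routes
        mz = species_mz(ann, adduct)
        lo, hi = PRECURSOR_STEP_RANGE
        if not lo - 0.5 <= mz < hi + 0.5:
            return None
        routes += 1
        return step_of(mz)

    if cls == "TAG":
        step = precursor_step("+NH4")
        if step is not None:
            precursor = species_mz(ann, "+NH4")
            share = intensity / len(ann.moieties)
            for chain in ann.moieties:  # repeated chains accumulate shares
                fmz = precursor - chain.acid_formula.mass - _NH3_MASS
                placements.append((step, "+", fmz, share))
    elif cls in ("PE", "PI", "PS"):
        step = precursor_step("-H")
        if step is not None:
            chains = [m for m in ann.moieties]
            extra = 1 if cls == "PS" else 0
            share = intensity / (len(chains) + extra)
            for chain in chains:
                placements.append((step, "-", frag.fa_anion_mz(chain), share))
            if cls == "PS":
                precursor = species_mz(ann, "-H")
                placements.append((step, "-", precursor - frag.SERINE_LOSS_MASS, share))
    elif cls == "PC":
        step = precursor_step("+H")
        if step is not None:
            placements.append((step, "+", frag.PHOSPHOCHOLINE_MZ, intensity))
        step = precursor_step("+HCOO")
        if step is not None:
            share = intensity / len(ann.moieties)
            for chain in ann.moieties:
                placements.append((step, "-", frag.fa_anion_mz(chain), share))
    elif cls == "SM":
        step = precursor_step("+H")
        if step is not None:
            placements.append((step, "+", frag.PHOSPHOCHOLINE_MZ, intensity))
    else:
        raise ValueError(f"cannot simulate class {cls!r}")

    if routes == 0:
        raise ValueError(f"{ann}: precursor outside acquisition range 400-1000")
    lo, hi = FRAGMENT_MZ_RANGE
    return [p for p in placements if lo <= p[2] <= hi]


_NH3_MASS = frag.Formula(N=1, H=3).mass


def simulate_msmsall(
    composition: GroundTruthComposition,
    spike_sheet: dict[str, float] | None = None,
    noise: NoiseModel = NoiseModel(),
) -> tuple[Experiment, pd.DataFrame]:
    """Simulate an MS/MS^ALL experiment; returns it with a truth sidecar.

    The sidecar lists every species (sample and spike) with its pmol and
    whether it was excluded for lying outside the precursor range.
    """
    if spike_sheet is None:
        spike_sheet = dict(DEFAULT_SPIKE_SHEET)
    members: list[tuple[LipidAnnotation, float, bool]] = [
        (ann, pmol, False) for ann, pmol in composition.species
    ]
    members += [
        (parse_annotation(name), pmol, True) for name, pmol in spike_sheet.items()
    ]

    accum: dict[tuple[int, str], dict[float, float]] = {}
    sidecar_rows = []
    for ann, pmol, is_spike in members:
        intensity = SCALE * pmol * composition.rf(ann.lipid_class)
        try:
            placements = _fragment_placements(ann, intensity)
        except ValueError as exc:
            logger.warning("excluded from simulation: %s", exc)
            sidecar_rows.append(
                {"species": str(ann), "pmol": pmol, "is_spike": is_spike, "excluded": True}
            )
            continue
        sidecar_rows.append(
            {"species": str(ann), "pmol": pmol, "is_spike": is_spike, "excluded": False}
        )
        for step, pol, fmz, share in placements:
            spec = accum.setdefault((step, pol), {})
            spec[fmz] = spec.get(fmz, 0.0) + share

    rng = np.random.default_rng(noise.seed)
    sigma = float(np.sqrt(np.log1p(noise.intensity_cv**2)))
    experiment = Experiment(sample=composition.name, spike_sheet=dict(spike_sheet))
    keys = sorted(accum)
    if noise.baseline_rate > 0:
        lo, hi = PRECURSOR_STEP_RANGE
        keys = sorted(
            set(keys) | {(s, p) for s in range(lo, hi + 1) for p in "+-"}
        )
    for key in keys:
        step, pol = key
        raw = sorted(accum.get(key, {}).items())
        merged = _merge_centroids(raw)
        peaks = []
        for mz, inten in merged:
            if noise.mz_jitter_ppm > 0:
                mz = mz + rng.standard_normal() * noise.mz_jitter_ppm * 1e-6 * mz
            else:
                rng.standard_normal()  # keep the draw stream aligned across jitter scales
            if noise.intensity_cv > 0:
                inten = inten * float(
                    np.exp(sigma * rng.standard_normal() - sigma**2 / 2)
                )
            else:
                rng.standard_normal()
            lo_f, hi_f = FRAGMENT_MZ_RANGE
            if lo_f <= mz <= hi_f:
                peaks.append((mz, inten))
        if noise.baseline_rate > 0:
            n_base = rng.poisson(noise.baseline_rate)
            for _ in range(n_base):
                bmz = rng.uniform(*FRAGMENT_MZ_RANGE)
                peaks.append((bmz, noise.baseline_intensity * rng.uniform(0.5, 1.5)))
        if not peaks:
            continue
        peaks.sort()
        experiment.add(
            MsMsSpectrum(step, pol, [FragmentPeak(mz, i) for mz, i in peaks])
        )
    sidecar = pd.DataFrame(sidecar_rows)
    return experiment, sidecar


def _merge_centroids(
    peaks: list[tuple[float, float]], width: float = 1e-3
) -> list[tuple[float, float]]:
    """Merge peaks closer than ``width`` into intensity-weighted centroids."""
    merged: list[tuple[float, float]] = []
    for mz, inten in peaks:
        if merged and mz - merged[-1][0] < width:
            pmz, pint = merged[-1]
            tot = pint + inten
            merged[-1] = ((pmz * pint + mz * inten) / tot, tot)
        else:
            merged.append((mz, inten))
    return merged


# --- ground-truth views -------------------------------------------------------


def truth_class_mol_pct(composition: GroundTruthComposition) -> dict[str, float]:
    totals: dict[str, float] = {}
    for ann, pmol in composition.species:
        totals[ann.lipid_class] = totals.get(ann.lipid_class, 0.0) + pmol
    grand = sum(totals.values())
    return {cls: 100.0 * v / grand for cls, v in sorted(totals.items())}


def expected_species(composition: GroundTruthComposition) -> dict[str, float]:
    """Ground truth keyed at the level the pipeline reports.

    TAG and SM aggregate to sum compositions; glycerophospholipids stay
    molecular (moieties in sorted order).
    """
    out: dict[str, float] = {}
    for ann, pmol in composition.species:
        if ann.lipid_class in ("TAG", "SM"):
            key = str(ann.as_sum())
        else:
            from .nomenclature import molecular

            key = str(molecular(ann.lipid_class, ann.sorted_moieties))
        out[key] = out.get(key, 0.0) + pmol
    return out


def chain_fa_amounts(
    composition: GroundTruthComposition,
    classes: tuple[str, ...] | None = None,
    min_carbons: int = 0,
) -> dict[tuple[int, int], float]:
    """Total FA amounts by (carbons, double_bonds), one count per chain."""
    out: dict[tuple[int, int], float] = {}
    for ann, pmol in composition.species:
        if classes is not None and ann.lipid_class not in classes:
            continue
        for chain in ann.moieties:
            if chain.is_lcb or chain.carbons < min_carbons:
                continue
            key = (chain.carbons, chain.double_bonds)
            out[key] = out.get(key, 0.0) + pmol
    return out


def chain_fa_percentages(
    composition: GroundTruthComposition,
    classes: tuple[str, ...] | None = None,
    min_carbons: int = 0,
) -> dict[tuple[int, int], float]:
    amounts = chain_fa_amounts(composition, classes, min_carbons)
    total = sum(amounts.values())
    return {k: 100.0 * v / total for k, v in sorted(amounts.items())}


# --- GC simulation ------------------------------------------------------------

GC_MIN_CARBONS = 10  # short-chain FAs evaporate during FAME preparation


def default_rt_library(fames: list[FameName]) -> dict[FameName, float]:
    """Deterministic FAME retention times (min): longer and more unsaturated
    chains elute later; spacing stays above the assignment window."""
    return {f: 8.0 + 1.9 * (f.carbons - 10) + 0.33 * f.double_bonds for f in fames}


def default_calibrations(fames: list[FameName]) -> dict[FameName, CalibrationCurve]:
    """Per-FAME linear calibrations (pmol per area unit), zero intercept."""
    out = {}
    for f in fames:
        slope = 0.002 + 0.0003 * ((f.carbons * 7 + f.double_bonds * 3) % 5)
        out[f] = CalibrationCurve(f, slope, 0.0, 0.0, 1e9)
    return out


def simulate_gc(
    composition: GroundTruthComposition,
    curves: dict[FameName, CalibrationCurve] | None = None,
    rt_library: dict[FameName, float] | None = None,
    seed: int = 0,
    rt_jitter: float = 0.02,
) -> tuple[list[GcPeak], dict[FameName, float], dict[FameName, CalibrationCurve]]:
    """Simulate a GC-FAME peak table from a composition.

    FA amounts are per esterified chain; moieties below 10 carbons are
    omitted (the GC blind spot). Areas invert the calibration curves;
    retention times get a uniform jitter of at most ``rt_jitter`` minutes.
    Returns (peaks, rt_library, curves) so the round trip is self-contained.
    """
    amounts = chain_fa_amounts(composition, min_carbons=GC_MIN_CARBONS)
    fames = sorted(FameName(c, d) for c, d in amounts)
    if rt_library is None:
        rt_library = default_rt_library(fames)
    if curves is None:
        curves = default_calibrations(fames)
    missing = [f for f in fames if f not in rt_library or f not in curves]
    if missing:
        raise ValueError(
            "library/calibration gaps for: " + ", ".join(str(f) for f in missing)
        )
    rng = np.random.default_rng(seed)
    peaks = []
    for f in fames:
        curve = curves[f]
        area = (amounts[f.key] - curve.intercept) / curve.slope
        rt = rt_library[f] + rng.uniform(-rt_jitter, rt_jitter)
        peaks.append(GcPeak(rt, area))
    peaks.sort(key=lambda p: p.rt_min)
    return peaks, rt_library, curves
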