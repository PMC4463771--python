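"""End-to-end orchestration: simulate -> identify -> quantify -> indices ->
GC profile -> GC-vs-MS comparison, with deterministic file outputs."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .gcfame import identify_fames, fa_percentages
from .identify import MatchSettings, identifications_to_tsv, identify_all
from .quantify import (
    class_composition,
    profile_to_tsv,
    quant_to_tsv,
    quantify,
    tag_fa_index,
    tag_fa_profile,
    unsaturation_index,
)
from .simulate import (
    DEFAULT_SPIKE_SHEET,
    NoiseModel,
    make_fixture,
    simulate_gc,
    simulate_msmsall,
)
from .spectra import Experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_ms_workflow", "compare_fa_profiles", "attribution_divergence"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    fixture: str | None = None
    experiment_path: str | None = None
    spike_sheet_path: str | None = None
    out_dir: str = "out"
    seed: int = 0
    noise: NoiseModel = field(default_factory=NoiseModel)
    settings: MatchSettings = field(default_factory=MatchSettings)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "fixture": self.fixture,
                "experiment_path": self.experiment_path,
                "spike_sheet_path": self.spike_sheet_path,
                "seed": self.seed,
                "noise": vars(self.noise) | {},
                "settings": vars(self.settings) | {},
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_ms_workflow(
    experiment: Experiment,
    settings: MatchSettings = MatchSettings(),
    out_dir: str | Path | None = None,
) -> dict:
    """Identify and quantify one experiment; optionally write TSV outputs.

    Returns a dict with identifications, the quantification table, class
    composition, TAG FA index/profile and the unsaturation index.
    """
    idents = identify_all(experiment, settings)
    n_by_class: dict[str, int] = {}
    for i in idents:
        n_by_class[i.species.lipid_class] = n_by_class.get(i.species.lipid_class, 0) + 1
    logger.info("identifications per class: %s", n_by_class)

    quant = quantify(idents)
    classes = class_composition(quant)
    fa_index = tag_fa_index(idents)
    has_tag = not fa_index.empty and (quant["lipid_class"] == "TAG").any()
    profile = tag_fa_profile(quant, fa_index) if has_tag else {}
    unsat = unsaturation_index(profile) if profile else {}
    logger.info("quantified %d species across %d classes", len(quant), len(classes))

    result = {
        "identifications": idents,
        "quant": quant,
        "class_composition": classes,
        "fa_index": fa_index,
        "fa_profile": profile,
        "unsaturation_index": unsat,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "identifications.tsv").write_text(identifications_to_tsv(idents))
        (out / "quant.tsv").write_text(quant_to_tsv(quant))
        (out / "class_composition.tsv").write_text(
            profile_to_tsv(classes.to_dict(), "mol_pct")
        )
        fa_index.round(4).to_csv(out / "fa_index.tsv", sep="\t")
        (out / "fa_profile.tsv").write_text(profile_to_tsv(profile))
        (out / "unsaturation_index.tsv").write_text(profile_to_tsv(unsat))
    return result


def simulate_and_run(
    fixture: str,
    noise: NoiseModel = NoiseModel(),
    settings: MatchSettings = MatchSettings(),
    out_dir: str | Path | None = None,
) -> dict:
    """Convenience wrapper: build a fixture, simulate, run the MS workflow."""
    comp = make_fixture(fixture)
    experiment, sidecar = simulate_msmsall(comp, DEFAULT_SPIKE_SHEET, noise)
    result = run_ms_workflow(experiment, settings, out_dir)
    result["composition"] = comp
    result["sidecar"] = sidecar
    return result


def _unsaturated_share(profile: dict[tuple[int, int], float]) -> float:
    return sum(pct for (c, d), pct in profile.items() if d > 0)


def compare_fa_profiles(
    gc_profile: dict[tuple[int, int], float],
    ms_tag_profile: dict[tuple[int, int], float],
    ms_gpl_profile: dict[tuple[int, int], float],
    tag_amount: float = 1.0,
    gpl_amount: float = 1.0,
    l1_threshold: float = 5.0,
) -> dict:
    """Compare total-FA views of one sample and attribute them to classes.

    All profiles are percentages keyed by (carbons, double_bonds) on a
    common key space. The report carries the GC and the combined MS total FA
    profile with their L1 distance, the per-FA attribution (which share of
    each FA the TAG pool vs the glycerophospholipid pool carries), and
    unsaturated-FA shares per source and per class. ``agrees`` flags L1
    distance below ``l1_threshold`` percentage points.
    """
    if not gc_profile or not (ms_tag_profile or ms_gpl_profile):
        raise ValueError("empty FA profile(s)")
    keys = sorted(set(gc_profile) | set(ms_tag_profile) | set(ms_gpl_profile))
    w_tag, w_gpl = tag_amount, gpl_amount
    w_tot = w_tag + w_gpl
    ms_total = {
        k: (w_tag * ms_tag_profile.get(k, 0.0) + w_gpl * ms_gpl_profile.get(k, 0.0)) / w_tot
        for k in keys
    }
    attribution = {}
    for k in keys:
        t = w_tag * ms_tag_profile.get(k, 0.0)
        g = w_gpl * ms_gpl_profile.get(k, 0.0)
        attribution[k] = {"TAG": t / (t + g) if t + g > 0 else 0.0,
                          "GPL": g / (t + g) if t + g > 0 else 0.0}
    l1 = sum(abs(gc_profile.get(k, 0.0) - ms_total[k]) for k in keys)
    unsat_tag = _unsaturated_share(ms_tag_profile)
    unsat_gpl = _unsaturated_share(ms_gpl_profile)
    tot_unsat_ms = _unsaturated_share(ms_total)
    carried = {
        "TAG": w_tag * unsat_tag / w_tot,
        "GPL": w_gpl * unsat_gpl / w_tot,
    }
    return {
        "keys": keys,
        "gc_total": dict(gc_profile),
        "ms_total": ms_total,
        "l1_distance": l1,
        "agrees": l1 < l1_threshold,
        "attribution": attribution,
        "unsaturated_share": {
            "GC": _unsaturated_share(gc_profile),
            "MS": tot_unsat_ms,
            "TAG": unsat_tag,
            "GPL": unsat_gpl,
        },
        "unsaturation_carried_by": carried,
    }


def attribution_divergence(
    report_a: dict,
    report_b: dict,
    l1_threshold: float = 5.0,
    attribution_threshold: float = 20.0,
) -> dict:
    """Flag two samples whose total FA profiles agree while the lipid class
    carrying the (un)saturation differs.

    ``flag`` is raised when the L1 distance between the samples' total MS FA
    profiles is below ``l1_threshold`` percentage points but the share of
    unsaturation carried by the TAG pool differs by more than
    ``attribution_threshold`` points.
    """
    keys = sorted(set(report_a["ms_total"]) | set(report_b["ms_total"]))
    l1 = sum(
        abs(report_a["ms_total"].get(k, 0.0) - report_b["ms_total"].get(k, 0.0))
        for k in keys
    )
    ca = report_a["unsaturation_carried_by"]["TAG"]
    cb = report_b["unsaturation_carried_by"]["TAG"]
    divergence = abs(ca - cb)
    return {
        "total_l1": l1,
        "tag_unsaturation_share_a": ca,
        "tag_unsaturation_share_b": cb,
        "attribution_divergence": divergence,
        "flag": l1 < l1_threshold and divergence > attribution_threshold,
    }


def gc_profile_of(
    composition, seed: int = 0
) -> tuple[dict[tuple[int, int], float], dict]:
    """Simulate + re-identify a GC run; returns the measured FA percentages."""
    peaks, rt_library, curves = simulate_gc(composition, seed=seed)
    fame_areas = identify_fames(peaks, rt_library)
    pct, amounts, totals = fa_percentages(fame_areas, curves)
    return {f.key: p for f, p in pct.items()}, {"amounts": amounts, "totals": totals}
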