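"""Fragment matching and species identification against simulated truth."""

import pytest

from milklip.identify import (
    MatchSettings,
    identify_all,
    identify_gpl,
    identify_headgroup_species,
    identify_tag,
    match_fragments,
)
from milklip.simulate import (
    DEFAULT_SPIKE_SHEET,
    NoiseModel,
    expected_species,
    make_fixture,
    simulate_msmsall,
)
from milklip.spectra import Experiment, FragmentPeak, MsMsSpectrum


def spectrum_of(peaks):
    return MsMsSpectrum(877, "+", [FragmentPeak(mz, i) for mz, i in peaks])


class TestMatchFragments:
    settings = MatchSettings(tolerance=0.01)

    def test_within_tolerance_matches(self):
        spec = spectrum_of([(603.5351, 7.0)])
        ev = match_fragments(spec, [("x", 603.5347)], self.settings)
        assert ev == {"x": 7.0}

    def test_outside_tolerance_unmatched(self):
        spec = spectrum_of([(603.60, 7.0)])
        assert match_fragments(spec, [("x", 603.5347)], self.settings) == {}

    def test_equidistant_tie_breaks_to_lower_mz(self):
        spec = spectrum_of([(603.530, 1.0), (603.540, 2.0)])
        ev = match_fragments(spec, [("x", 603.535)], self.settings)
        assert ev == {"x": 1.0}

    def test_nearest_peak_wins(self):
        spec = spectrum_of([(603.531, 1.0), (603.5346, 2.0)])
        ev = match_fragments(spec, [("x", 603.5347)], self.settings)
        assert ev == {"x": 2.0}

    def test_intensity_floor_drops_weak_matches(self):
        spec = spectrum_of([(603.5347, 0.5)])
        ev = match_fragments(
            spec, [("x", 603.5347)], MatchSettings(intensity_floor=1.0)
        )
        assert ev == {}


@pytest.fixture(scope="module")
def clean_runs():
    out = {}
    for name in ("human1", "human2", "cow", "lacprodan"):
        comp = make_fixture(name)
        experiment, _ = simulate_msmsall(comp, DEFAULT_SPIKE_SHEET, NoiseModel())
        out[name] = (comp, experiment)
    return out


def test_zero_noise_identifications_equal_ground_truth(clean_runs):
    """On noise-free simulations, the identified species set equals the
    seeded species set exactly: no false positives, no false negatives."""
    for name, (comp, experiment) in clean_runs.items():
        idents = identify_all(experiment)
        got = {str(i.species) for i in idents if not i.internal_standard}
        want = set(expected_species(comp))
        assert got == want, f"{name}: {got ^ want}"


def test_internal_standards_flagged_with_spike_amounts(clean_runs):
    _, experiment = clean_runs["lacprodan"]
    idents = identify_all(experiment)
    stds = {i.species.lipid_class: i for i in idents if i.internal_standard}
    assert set(stds) == {"TAG", "PC", "PE", "PS", "PI", "SM"}
    assert stds["TAG"].spike_pmol == 93.0
    assert str(stds["TAG"].species) == "TAG 51:3"  # TAG 17:1-17:1-17:1
    assert stds["SM"].spike_pmol == 100.0


def test_tag_52_2_composite_yields_four_nl_evidence_entries():
    """A TAG 52:2 composite of 16:0-18:1-18:1 and 16:0-18:0-18:2 is found as
    one sum-composition identification with four neutral-loss fragments."""
    from milklip.nomenclature import parse_annotation
    from milklip.simulate import GroundTruthComposition

    comp = GroundTruthComposition(
        "tag522",
        [
            (parse_annotation("TAG 16:0-18:1-18:1"), 100.0),
            (parse_annotation("TAG 16:0-18:0-18:2"), 50.0),
        ],
    )
    experiment, _ = simulate_msmsall(comp, {"TAG 17:1-17:1-17:1": 93.0}, NoiseModel())
    idents = [i for i in identify_tag(experiment) if not i.internal_standard]
    assert len(idents) == 1
    ident = idents[0]
    assert str(ident.species) == "TAG 52:2"
    assert set(ident.evidence) == {
        "NL FA 16:0", "NL FA 18:0", "NL FA 18:1", "NL FA 18:2"
    }


def test_single_fragment_tag_rejected_by_threshold():
    spec = MsMsSpectrum(877, "+", [FragmentPeak(603.5347, 10.0)])
    experiment = Experiment(sample="x")
    experiment.add(spec)
    assert identify_tag(experiment) == []


def test_inconsistent_anion_pair_not_assigned():
    """FA anions 16:0 and 18:1 in the step of PE 34:2 do not support
    PE 16:0-18:1 (its own precursor lies in a different step)."""
    from milklip.fragments import fa_anion_mz
    from milklip.nomenclature import FattyAcyl, molecular, species_mz
    from milklip.spectra import step_of

    step = step_of(species_mz(molecular(
        "PE", (FattyAcyl(16, 0), FattyAcyl(18, 2))), "-H"))
    spec = MsMsSpectrum(step, "-", sorted(
        [FragmentPeak(fa_anion_mz(FattyAcyl(16, 0)), 10.0),
         FragmentPeak(fa_anion_mz(FattyAcyl(18, 1)), 10.0)],
        key=lambda p: p.mz))
    experiment = Experiment(sample="x")
    experiment.add(spec)
    assert identify_gpl(experiment) == []


def test_ps_without_serine_loss_rejected():
    from milklip.fragments import fa_anion_mz
    from milklip.nomenclature import FattyAcyl, molecular, species_mz
    from milklip.spectra import step_of

    species = molecular("PS", (FattyAcyl(18, 0), FattyAcyl(18, 1)))
    step = step_of(species_mz(species, "-H"))
    spec = MsMsSpectrum(step, "-", sorted(
        [FragmentPeak(fa_anion_mz(FattyAcyl(18, 0)), 10.0),
         FragmentPeak(fa_anion_mz(FattyAcyl(18, 1)), 10.0)],
        key=lambda p: p.mz))
    experiment = Experiment(sample="x")
    experiment.add(spec)
    assert identify_gpl(experiment, classes=("PS",)) == []


def test_headgroup_without_candidate_yields_nothing():
    spec = MsMsSpectrum(500, "+", [FragmentPeak(184.0733, 10.0)])
    experiment = Experiment(sample="x")
    experiment.add(spec)
    assert identify_headgroup_species(experiment) == []


def test_sm_identified_via_headgroup(clean_runs):
    _, experiment = clean_runs["lacprodan"]
    idents = identify_headgroup_species(experiment)
    sm = {str(i.species) for i in idents if i.species.lipid_class == "SM"
          and not i.internal_standard}
    assert sm == {"SM 34:1;2", "SM 36:1;2", "SM 40:1;2"}


def test_pc_merged_to_molecular_level(clean_runs):
    _, experiment = clean_runs["lacprodan"]
    idents = identify_all(experiment)
    pc = [i for i in idents if i.species.lipid_class == "PC"]
    assert pc and all(i.level == "molecular" for i in pc)


def test_identification_invariant_to_peak_permutation_and_scaling(clean_runs):
    comp, experiment = clean_runs["cow"]
    scaled = Experiment(sample="cow*", spike_sheet=experiment.spike_sheet)
    for (step, pol), spec in reversed(sorted(experiment.spectra.items())):
        peaks = [FragmentPeak(p.mz, p.intensity * 37.0) for p in reversed(spec.peaks)]
        scaled.add(MsMsSpectrum(step, pol, peaks))
    a = {str(i.species) for i in identify_all(experiment)}
    b = {str(i.species) for i in identify_all(scaled)}
    assert a == b


def test_distinct_fragment_count_bounds_molecular_species(clean_runs):
    """Each TAG has at most 3 distinct FAs, so the number of co-isolated
    molecular TAG species is at least ceil(distinct NL count / 3)."""
    import math

    comp, experiment = clean_runs["human1"]
    truth_molecular = {}
    for ann, _ in comp.species:
        if ann.lipid_class == "TAG":
            key = str(ann.as_sum())
            truth_molecular[key] = truth_molecular.get(key, 0) + 1
    for ident in identify_tag(experiment):
        if ident.internal_standard:
            continue
        key = str(ident.species)
        assert truth_molecular[key] >= math.ceil(len(ident.evidence) / 3)
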