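"""Synthetic-data generator: fixture properties, determinism, noise model,
GC simulation and the GC <-> MS consistency invariant."""

import pytest

from milklip.gcfame import identify_fames, fa_percentages
from milklip.identify import identify_all
from milklip.quantify import quantify, tag_fa_index, tag_fa_profile
from milklip.simulate import (
    DEFAULT_SPIKE_SHEET,
    GroundTruthComposition,
    NoiseModel,
    chain_fa_percentages,
    expected_species,
    make_fixture,
    simulate_gc,
    simulate_msmsall,
    truth_class_mol_pct,
)
from milklip.spectra import write_experiment


def test_unknown_fixture_rejected():
    with pytest.raises(ValueError):
        make_fixture("goat")


def test_lacprodan_class_fractions():
    """The formula-concentrate fixture reproduces the published class
    fractions 25/35/18/8/9/5 (TAG/PE/PC/SM/PS/PI)."""
    pct = truth_class_mol_pct(make_fixture("lacprodan"))
    assert pct == pytest.approx(
        {"TAG": 25, "PE": 35, "PC": 18, "SM": 8, "PS": 9, "PI": 5}, abs=1e-9
    )


@pytest.mark.parametrize("name", ["human1", "human2", "cow"])
def test_milk_fixtures_are_tag_dominated(name):
    pct = truth_class_mol_pct(make_fixture(name))
    assert pct["TAG"] > 97.0


def test_lacprodan_dominant_species_per_class():
    comp = make_fixture("lacprodan")
    best = {}
    totals = {}
    for ann, pmol in comp.species:
        cls = ann.lipid_class
        totals[cls] = totals.get(cls, 0.0) + pmol
        if cls not in best or pmol > best[cls][1]:
            best[cls] = (str(ann), pmol)
    assert best["PC"][0] == "PC 16:0-18:1"
    assert best["PE"][0] == "PE 18:1-18:1"
    assert best["PI"][0] == "PI 18:0-18:1"
    assert best["PS"][0] == "PS 18:0-18:1"
    # within-class shares match the published dominances
    assert 100 * best["PC"][1] / totals["PC"] == pytest.approx(23, abs=1)
    assert 100 * best["PE"][1] / totals["PE"] == pytest.approx(34, abs=1)
    assert 100 * best["PI"][1] / totals["PI"] == pytest.approx(39, abs=1)
    assert 100 * best["PS"][1] / totals["PS"] == pytest.approx(38, abs=1)


def test_short_chain_fa_shares_match_sample_types():
    """Cow milk and the formula concentrate carry ~12-13% short-chain
    (4-10 C) FAs in their TAG pools; human milk only ~1.5%."""
    def short_share(name):
        pct = chain_fa_percentages(make_fixture(name), classes=("TAG",))
        return sum(p for (c, d), p in pct.items() if 4 <= c <= 10)

    assert 12.0 <= short_share("cow") <= 13.0
    assert 12.0 <= short_share("lacprodan") <= 13.0
    assert 1.0 <= short_share("human1") <= 2.0


def test_gc_16_0_18_1_dominance():
    """FA 16:0 + FA 18:1 make up 55-60% of GC-quantifiable (>= 10 C) FAs in
    every sample type."""
    for name in ("human1", "cow", "lacprodan"):
        pct = chain_fa_percentages(make_fixture(name), min_carbons=10)
        combined = pct.get((16, 0), 0.0) + pct.get((18, 1), 0.0)
        assert 55.0 <= combined <= 60.0, name


def test_same_seed_gives_byte_identical_experiments(tmp_path):
    noise = NoiseModel(5.0, 0.05, baseline_rate=1.0, seed=7)
    comp = make_fixture("cow")
    p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    for p in (p1, p2):
        experiment, _ = simulate_msmsall(comp, DEFAULT_SPIKE_SHEET, noise)
        write_experiment(experiment, p)
    assert p1.read_bytes() == p2.read_bytes()


def test_shared_step_of_tag_52_2_composite_has_four_nl_peaks():
    from milklip.nomenclature import parse_annotation

    comp = GroundTruthComposition(
        "t", [
            (parse_annotation("TAG 16:0-18:1-18:1"), 100.0),
            (parse_annotation("TAG 16:0-18:0-18:2"), 50.0),
        ],
    )
    experiment, _ = simulate_msmsall(comp, {}, NoiseModel())
    spec = experiment.spectrum(877, "+")
    assert spec is not None and len(spec.peaks) == 4
    assert spec.mzs == pytest.approx([575.503, 577.519, 579.535, 603.535], abs=5e-4)


def test_out_of_range_species_excluded_with_sidecar_flag():
    from milklip.nomenclature import parse_annotation

    comp = GroundTruthComposition(
        "t", [
            (parse_annotation("TAG 16:0-18:1-18:1"), 10.0),
            (parse_annotation("TAG 4:0-4:0-4:0"), 10.0),  # precursor < 400
        ],
    )
    experiment, sidecar = simulate_msmsall(comp, {}, NoiseModel())
    flags = sidecar.set_index("species")["excluded"]
    assert bool(flags["TAG 4:0-4:0-4:0"]) is True
    assert bool(flags["TAG 16:0-18:1-18:1"]) is False


def test_recall_non_increasing_in_mz_jitter():
    """At fixed tolerance and seed, identification recall cannot grow as the
    m/z jitter scale grows (jitter offsets scale with the same draws)."""
    comp = make_fixture("lacprodan")
    want = set(expected_species(comp))
    recalls = []
    for ppm in (0.0, 5.0, 40.0, 120.0, 400.0):
        experiment, _ = simulate_msmsall(
            comp, DEFAULT_SPIKE_SHEET, NoiseModel(ppm, 0.0, seed=11)
        )
        got = {str(i.species) for i in identify_all(experiment) if not i.internal_standard}
        recalls.append(len(got & want) / len(want))
    assert all(a >= b for a, b in zip(recalls, recalls[1:]))
    assert recalls[0] == 1.0


# --- GC simulation ------------------------------------------------------------


def test_gc_round_trip_recovers_chain_percentages():
    """Re-identifying and quantifying simulated GC peaks reproduces the
    composition-derived FA percentages (>= 10 C) to 1e-9."""
    comp = make_fixture("human1")
    peaks, rt_library, curves = simulate_gc(comp, seed=3)
    pct, _, _ = fa_percentages(identify_fames(peaks, rt_library), curves)
    want = chain_fa_percentages(comp, min_carbons=10)
    got = {f.key: p for f, p in pct.items()}
    assert set(got) == set(want)
    for key in want:
        assert got[key] == pytest.approx(want[key], abs=1e-9)


def test_gc_blind_to_short_chains_present_in_ms_profile():
    """The cow TAG pool contains 4-10 C FAs that the GC profile omits."""
    comp = make_fixture("cow")
    experiment, _ = simulate_msmsall(comp, DEFAULT_SPIKE_SHEET, NoiseModel())
    idents = identify_all(experiment)
    q = quantify(idents)
    ms_profile = tag_fa_profile(q, tag_fa_index(idents))
    ms_fas = {tuple(map(int, k.split(":"))) for k in ms_profile}
    peaks, rt_library, curves = simulate_gc(comp, seed=0)
    pct, _, _ = fa_percentages(identify_fames(peaks, rt_library), curves)
    gc_fas = {f.key for f in pct}
    short_only_in_ms = {k for k in ms_fas - gc_fas if k[0] < 10}
    assert short_only_in_ms  # e.g. 4:0 and 6:0
    assert all(c >= 10 for c, _ in gc_fas)


def test_gc_determinism_under_fixed_seed():
    comp = make_fixture("cow")
    a, _, _ = simulate_gc(comp, seed=5)
    b, _, _ = simulate_gc(comp, seed=5)
    assert [(p.rt_min, p.area) for p in a] == [(p.rt_min, p.area) for p in b]


def test_gc_library_gap_raises():
    comp = make_fixture("cow")
    _, rt_library, curves = simulate_gc(comp, seed=0)
    incomplete = dict(list(rt_library.items())[:-1])
    with pytest.raises(ValueError, match="gaps"):
        simulate_gc(comp, curves=curves, rt_library=incomplete)


def test_gc_ms_fa_profile_consistency_at_zero_noise():
    """For a TAG-only composition, the GC FA percentages (>= 10 C) and the
    pmol-weighted MS FA profile agree to 1e-9: complementary views of one
    ground truth."""
    for name in ("human1", "cow", "lacprodan"):
        comp = make_fixture(name)
        tag_only = GroundTruthComposition(
            name + "_tag",
            [(a, p) for a, p in comp.species if a.lipid_class == "TAG"],
        )
        experiment, _ = simulate_msmsall(tag_only, DEFAULT_SPIKE_SHEET, NoiseModel())
        idents = identify_all(experiment)
        q = quantify(idents)
        profile = tag_fa_profile(q, tag_fa_index(idents))
        ms = {tuple(map(int, k.split(":"))): v for k, v in profile.items()}
        ms10 = {k: v for k, v in ms.items() if k[0] >= 10}
        scale = 100.0 / sum(ms10.values())
        ms10 = {k: v * scale for k, v in ms10.items()}
        peaks, rt_library, curves = simulate_gc(tag_only, seed=1)
        pct, _, _ = fa_percentages(identify_fames(peaks, rt_library), curves)
        gc = {f.key: p for f, p in pct.items()}
        assert set(gc) == set(ms10)
        for key in gc:
            assert ms10[key] == pytest.approx(gc[key], abs=1e-9)
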