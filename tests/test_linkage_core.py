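"""Multipoint engine vs exhaustive enumeration, plus engine invariants."""

import numpy as np
import pytest

import oracle
from xlinkmeta.consensus_map import ConsensusMap, MarkerRecord
from xlinkmeta.linkage_core import (FamilyEngine, LiabilityClass,
                                    LinkageError, MendelianError,
                                    PenetranceModel, estimate_allele_freqs,
                                    haldane_theta)
from xlinkmeta.pedigree_io import FEMALE, MALE, strip_genotypes
from conftest import family, ind, small_map

MODEL = PenetranceModel()


def site_freqs(ped, extra_alleles=("1", "2", "7", "9")):
    """Site table over a fixed allele universe (uniform over unobserved)."""
    freqs = {}
    for k, m in enumerate(ped.marker_list):
        seen = {}
        for mem in ped.members:
            call = mem.genotypes[k]
            if call:
                for a in call:
                    seen[a] = seen.get(a, 0) + 1
        universe = sorted(set(extra_alleles) | set(seen))
        tot = sum(seen.values()) + len(universe)  # add-one smoothing
        freqs[m] = {a: (seen.get(a, 0) + 1) / tot for a in universe}
    return freqs


def oracle_markers(ped, cmap, freqs):
    return [
        (r.cm, ped.marker_list.index(r.marker_id), freqs[r.marker_id])
        for r in cmap.records if r.source != "dummy"
    ]


# -- allele frequency counting ----------------------------------------------


def test_allele_counting_examples():
    ped = family("1", [
        ind("w", sex=FEMALE, genos=[("1", "2")]),
        ind("m", sex=MALE, genos=[("1",)]),
    ], markers=["M1"])
    tab = estimate_allele_freqs([ped])["site0"]["M1"]
    assert tab == {"1": pytest.approx(2 / 3), "2": pytest.approx(1 / 3)}

    ped2 = family("2", [
        ind("a", genos=[None]), ind("b", genos=[("4",)]),
    ], markers=["M1"])
    assert estimate_allele_freqs([ped2])["site0"]["M1"] == {"4": 1.0}


def test_allele_counting_matches_bruteforce_tally(rng):
    markers = ["A", "B"]
    members = []
    for k in range(12):
        sex = MALE if k % 2 else FEMALE
        genos = []
        for _ in markers:
            if rng.random() < 0.2:
                genos.append(None)
            elif sex == MALE:
                genos.append((str(rng.integers(1, 5)),))
            else:
                genos.append(tuple(sorted(
                    str(x) for x in rng.integers(1, 5, 2))))
        members.append(ind(f"i{k}", sex=sex, genos=genos))
    ped = family("f", members, markers)
    got = estimate_allele_freqs([ped])["site0"]
    for mk, idx in zip(markers, range(2)):
        tally = {}
        for m in ped.members:
            call = m.genotypes[idx]
            if call:
                for a in call:
                    tally[a] = tally.get(a, 0) + 1
        tot = sum(tally.values())
        for a, c in tally.items():
            assert got[mk][a] == pytest.approx(c / tot)
        assert sum(got[mk].values()) == pytest.approx(1.0, abs=1e-9)


def test_zero_call_marker_raises():
    ped = family("1", [ind("a", genos=[None])], markers=["M1"])
    with pytest.raises(LinkageError, match="M1"):
        estimate_allele_freqs([ped])


# -- posterior ---------------------------------------------------------------


def test_posterior_uniform_without_data(brothers_informative):
    ped = strip_genotypes(brothers_informative)
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), {}, MODEL)
    post = eng.posteriors(np.array([10.0, 15.0, 20.0]))
    assert np.allclose(post, 0.25, atol=1e-12)


def test_posterior_matches_enumeration(brothers_informative):
    ped = brothers_informative
    cmap = small_map([10.0, 20.0])
    freqs = site_freqs(ped)
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    positions = np.array([10.0, 13.0, 20.0])
    post = eng.posteriors(positions)
    marks = oracle_markers(ped, cmap, freqs)
    nf = oracle.nonfounder_ids(ped)
    for i, x in enumerate(positions):
        exact = oracle.multipoint_posterior(ped, marks, float(x))
        for v_idx in range(eng.n_states):
            bits = {m: (v_idx >> eng.bit_of[m]) & 1 for m in nf}
            key = tuple(sorted(bits.items()))
            assert post[i, v_idx] == pytest.approx(exact.get(key, 0.0),
                                                   abs=1e-9)


def test_posterior_rows_normalized(three_gen_family):
    ped = three_gen_family
    cmap = small_map([10.0, 20.0])
    eng = FamilyEngine(ped, cmap, site_freqs(ped), MODEL)
    post = eng.posteriors(np.linspace(5.0, 25.0, 9))
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)


def test_posterior_far_from_markers_mixes_to_uniform(brothers_informative):
    ped = brothers_informative
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), site_freqs(ped), MODEL)
    post = eng.posteriors(np.array([700.0]))
    assert np.allclose(post, 0.25, atol=1e-6)


def test_mendelian_inconsistency_names_marker():
    # mother 1/1 but son carries allele 2: impossible on X
    ped = family("bad", [
        ind("f", genos=[("9",)]),
        ind("m", sex=FEMALE, genos=[("1", "1")]),
        ind("s", "f", "m", affected=True, genos=[("2",)]),
    ], markers=["M1"])
    with pytest.raises(MendelianError, match="M1"):
        FamilyEngine(ped, small_map([10.0]), site_freqs(ped), MODEL)


def test_state_guard_rejects_huge_families():
    members = [ind("f"), ind("m", sex=FEMALE)]
    members += [ind(f"s{k}", "f", "m") for k in range(21)]
    ped = family("big", members, markers=["M1"])
    with pytest.raises(LinkageError, match="split"):
        FamilyEngine(ped, small_map([10.0]), {"M1": {"1": 1.0}}, MODEL)


# -- parametric LOD ----------------------------------------------------------


def test_lod_zero_without_affecteds(brothers_informative):
    ped = brothers_informative
    for m in ped.members:
        m.affection = "unknown"
        m.onset_age = None
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), site_freqs(ped), MODEL)
    post = eng.posteriors(np.array([10.0, 15.0]))
    assert np.allclose(eng.parametric_lod(post), 0.0, atol=1e-12)


def test_lod_zero_far_from_markers(brothers_informative):
    ped = brothers_informative
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), site_freqs(ped), MODEL)
    post = eng.posteriors(np.array([700.0]))
    assert abs(eng.parametric_lod(post)[0]) < 1e-6


@pytest.mark.parametrize("fixture", ["brothers_informative",
                                     "three_gen_family"])
@pytest.mark.parametrize("founder_mode", ["population", "segregating"])
def test_lod_matches_bruteforce(request, fixture, founder_mode):
    """Engine LOD equals full enumeration over vectors x disease configs."""
    ped = request.getfixturevalue(fixture)
    cmap = small_map([10.0, 20.0])
    freqs = site_freqs(ped)
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    positions = np.array([10.0, 14.0, 20.0])
    lods = eng.parametric_lod(eng.posteriors(positions), founder_mode)
    marks = oracle_markers(ped, cmap, freqs)
    eligible = (eng.segregating_slots()
                if founder_mode == "segregating" else None)
    for i, x in enumerate(positions):
        expect = oracle.parametric_lod(ped, marks, float(x), MODEL,
                                       founder_mode, eligible)
        assert lods[i] == pytest.approx(expect, abs=1e-9)


def test_lod_invariant_under_allele_relabeling(three_gen_family):
    ped = three_gen_family
    cmap = small_map([10.0, 20.0])
    freqs = site_freqs(ped)
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    pos = np.array([10.0, 15.0, 20.0])
    base = eng.parametric_lod(eng.posteriors(pos))

    relabel = {"1": "5", "2": "6", "7": "8", "9": "3"}
    members2 = []
    for m in ped.members:
        genos = [
            None if g is None else tuple(sorted(relabel[a] for a in g))
            for g in m.genotypes
        ]
        members2.append(ind(m.individual_id, m.father_id, m.mother_id, m.sex,
                            m.is_affected, m.onset_age, m.liability_class,
                            genos))
    ped2 = family(ped.family_id, members2, ped.marker_list)
    freqs2 = {
        mk: {relabel.get(a, a): p for a, p in tab.items()}
        for mk, tab in freqs.items()
    }
    eng2 = FamilyEngine(ped2, cmap, freqs2, MODEL)
    assert np.allclose(base, eng2.parametric_lod(eng2.posteriors(pos)),
                       atol=1e-12)


def test_dummy_marker_is_a_noop(three_gen_family):
    ped = three_gen_family
    cmap = small_map([10.0, 20.0])
    freqs = site_freqs(ped)
    pos = np.array([10.0, 15.0, 20.0])
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    base_lod = eng.parametric_lod(eng.posteriors(pos))
    base_z, _ = eng.sharing_z(eng.posteriors(pos))

    recs = cmap.records + [MarkerRecord("DUMMY", 10 ** 9, 10 ** 9, None,
                                        25.0, "dummy")]
    cmap2 = ConsensusMap(recs)
    eng2 = FamilyEngine(ped, cmap2, freqs, MODEL)
    lod2 = eng2.parametric_lod(eng2.posteriors(pos))
    z2, _ = eng2.sharing_z(eng2.posteriors(pos))
    assert np.allclose(base_lod, lod2, atol=1e-9)
    assert np.allclose(base_z, z2, atol=1e-9)


def test_missing_liability_class_raises(brothers_informative):
    ped = brothers_informative
    ped.member("s1").liability_class = 7
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), site_freqs(ped), MODEL)
    with pytest.raises(LinkageError, match="liability class 7"):
        eng.phenotype_likelihoods()


# -- allele sharing ----------------------------------------------------------


def test_sharing_zero_without_data(brothers_informative):
    ped = strip_genotypes(brothers_informative)
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), {}, MODEL)
    z, informative = eng.sharing_z(eng.posteriors(np.array([10.0, 15.0])))
    assert informative
    assert np.allclose(z, 0.0, atol=1e-12)


def test_single_affected_flagged_uninformative(brothers_informative):
    ped = brothers_informative
    ped.member("s2").affection = "unknown"
    ped.member("s2").onset_age = None
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), site_freqs(ped), MODEL)
    z, informative = eng.sharing_z(eng.posteriors(np.array([10.0])))
    assert not informative
    assert np.allclose(z, 0.0)


def test_certain_sharing_equals_enumeration_extreme(brothers_informative):
    ped = brothers_informative
    cmap = small_map([10.0, 20.0])
    freqs = site_freqs(ped)
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    post = eng.posteriors(np.array([10.0]))
    s = eng.sharing_scores("all")
    z, _ = eng.sharing_z(post, "all")
    z_max = (s.max() - s.mean()) / s.std()
    # both brothers share the maternal allele essentially with certainty
    assert z[0] == pytest.approx(z_max, rel=5e-3)


@pytest.mark.parametrize("scorer", ["pairs", "all"])
def test_sharing_matches_bruteforce(three_gen_family, scorer):
    ped = three_gen_family
    cmap = small_map([10.0, 20.0])
    freqs = site_freqs(ped)
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    positions = np.array([10.0, 14.0, 20.0])
    z, informative = eng.sharing_z(eng.posteriors(positions), scorer)
    assert informative
    marks = oracle_markers(ped, cmap, freqs)
    for i, x in enumerate(positions):
        assert z[i] == pytest.approx(
            oracle.sharing_zbar(ped, marks, float(x), scorer), abs=1e-9)


def test_pairs_equals_all_for_two_affecteds(brothers_informative):
    ped = brothers_informative
    eng = FamilyEngine(ped, small_map([10.0, 20.0]), site_freqs(ped), MODEL)
    post = eng.posteriors(np.array([10.0, 15.0, 20.0]))
    z_pairs, _ = eng.sharing_z(post, "pairs")
    z_all, _ = eng.sharing_z(post, "all")
    assert np.allclose(z_pairs, z_all, atol=1e-12)


# -- single-marker consistency ----------------------------------------------


def test_multipoint_on_single_marker_equals_single_point(three_gen_family):
    """With one marker, the multipoint LOD at the marker equals the direct
    single-point computation from exhaustive enumeration."""
    ped = three_gen_family
    cmap = small_map([10.0])
    freqs = site_freqs(ped)
    eng = FamilyEngine(ped, cmap, freqs, MODEL)
    lod = eng.parametric_lod(eng.posteriors(np.array([10.0])))
    expect = oracle.parametric_lod(
        ped, oracle_markers(ped, cmap, freqs), 10.0, MODEL)
    assert lod[0] == pytest.approx(expect, abs=1e-9)


def test_haldane_mapping():
    assert haldane_theta(0.0) == 0.0
    assert haldane_theta(1e9) == pytest.approx(0.5)
    assert haldane_theta(10.0) == pytest.approx(0.0906346, abs=1e-6)
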