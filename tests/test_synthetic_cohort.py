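"""Cohort simulator: transmission laws, ascertainment, observation model."""

import numpy as np
import pytest

from xlinkmeta import consensus_map as cmod
from xlinkmeta import linkage_core as lc
from xlinkmeta import meta_analysis as ma
from xlinkmeta import synthetic_cohort as sim
from xlinkmeta.pedigree_io import FEMALE, MALE, validate_pedigree


@pytest.fixture(scope="module")
def gws_map():
    return cmod.load_xq_map()


def small_cfg(gws_map, **kw):
    defaults = dict(n_families=25, seed=7, cmap=gws_map,
                    site_panels={"s0": set(gws_map.marker_ids)}, n_sites=1)
    defaults.update(kw)
    return sim.CohortSimConfig(**defaults)


def test_cohort_is_deterministic(gws_map):
    a = sim.simulate_cohort(small_cfg(gws_map))
    b = sim.simulate_cohort(small_cfg(gws_map))
    for fa, fb in zip(a, b):
        assert fa.linked == fb.linked and fa.template == fb.template
        for ma_, mb_ in zip(fa.pedigree.members, fb.pedigree.members):
            assert ma_.genotypes == mb_.genotypes
            assert ma_.affection == mb_.affection


def test_families_are_valid_and_multiplex(gws_map):
    fams = sim.simulate_cohort(small_cfg(gws_map))
    for f in fams:
        assert len(f.pedigree.affected) >= 2
        assert all(m.sex == MALE for m in f.pedigree.affected)
        assert validate_pedigree(f.pedigree) == []
        if not f.linked:
            assert f.carrier_ids == []
        else:
            assert f.carrier_ids  # the planted allele reached someone


def test_linked_fraction_within_binomial_bounds(gws_map):
    n = 400
    fams = sim.simulate_cohort(small_cfg(gws_map, n_families=n, seed=11))
    k = sum(f.linked for f in fams)
    p = 0.5
    se = np.sqrt(n * p * (1 - p))
    assert abs(k - n * p) < 2.58 * se  # 99% bounds


def test_impossible_ascertainment_raises(gws_map):
    model = lc.PenetranceModel(
        risk_allele_freq=0.003,
        classes={1: lc.LiabilityClass(0.9, 0.0),
                 2: lc.LiabilityClass(0.6, 0.0)})
    cfg = small_cfg(gws_map, n_families=2, linked_fraction=0.0, model=model)
    with pytest.raises(sim.SimulationError, match="budget"):
        sim.simulate_cohort(cfg)


# -- X transmission laws -----------------------------------------------------


def _rows_trio():
    return [("f", None, None, MALE), ("m", None, None, FEMALE),
            ("s", "f", "m", MALE), ("d", "f", "m", FEMALE)]


def test_fathers_allele_in_every_daughter_never_in_sons(rng):
    loci = np.array([0.0, 10.0])
    for _ in range(50):
        haps, _ = sim.gene_drop_x(
            _rows_trio(), loci,
            {"f": [np.array([77, 77])], "m": [np.array([1, 1]),
                                              np.array([2, 2])]},
            rng)
        assert np.array_equal(haps["d"][1], [77, 77])  # paternal X unchanged
        assert len(haps["s"]) == 1
        assert 77 not in haps["s"][0]


def test_zero_cm_gap_never_recombines(rng):
    loci = np.array([5.0, 5.0])
    for _ in range(200):
        haps, bits = sim.gene_drop_x(
            _rows_trio(), loci,
            {"f": [np.array([9, 9])], "m": [np.array([1, 1]),
                                            np.array([2, 2])]},
            rng)
        assert bits["s"][0] == bits["s"][1]


def test_haldane_recombination_rate_recovered(rng):
    """Recombinant fraction over 10,000 maternal meioses matches Haldane."""
    d = 10.0
    loci = np.array([0.0, d])
    n = 10_000
    rec = 0
    rows = [("m", None, None, FEMALE), ("s", None, "m", MALE)]
    # a lone maternal meiosis per drop; father absent is fine for males
    rows = [("f", None, None, MALE), ("m", None, None, FEMALE),
            ("s", "f", "m", MALE)]
    fh = {"f": [np.array([9, 9])], "m": [np.array([1, 1]), np.array([2, 2])]}
    for _ in range(n):
        _, bits = sim.gene_drop_x(rows, loci, fh, rng)
        rec += int(bits["s"][0] != bits["s"][1])
    theta = lc.haldane_theta(d)
    se = np.sqrt(n * theta * (1 - theta))
    assert abs(rec - n * theta) < 3 * se


def test_founder_allele_frequency_conservation(gws_map, rng):
    """Founder marker alleles converge to the generating spectrum (LLN)."""
    cfg = small_cfg(gws_map, n_families=1400, seed=23, linked_fraction=0.0)
    mf = sim._draw_marker_freqs(gws_map, cfg, np.random.default_rng(cfg.seed))
    fams = sim.simulate_cohort(cfg)
    marker = gws_map.marker_ids[0]
    counts: dict[str, int] = {}
    total = 0
    for f in fams:
        for m in f.pedigree.members:
            if not m.is_founder:
                continue
            call = m.genotypes[0]
            for a in call:
                counts[a] = counts.get(a, 0) + 1
                total += 1
    assert total >= 5000
    gen = mf[marker]
    for idx, p in enumerate(gen):
        obs = counts.get(str(idx + 1), 0)
        se = np.sqrt(total * p * (1 - p))
        assert abs(obs - total * p) <= 3 * se + 1e-9


# -- observation model -------------------------------------------------------


def test_observation_identity_with_full_panel(gws_map):
    fams = sim.simulate_cohort(small_cfg(gws_map))
    obs = sim.apply_site_observation(
        fams, {"s0": set(gws_map.marker_ids)}, 0.0, seed=1)
    for f, o in zip(fams, obs):
        for mt, mo in zip(f.pedigree.members, o.members):
            if mt.individual_id in f.unobserved_ids:
                assert all(c is None for c in mo.genotypes)
            else:
                assert mt.genotypes == mo.genotypes


def test_observation_missing_rate_binomial(gws_map):
    fams = sim.simulate_cohort(small_cfg(gws_map, n_families=80, seed=3))
    rate = 0.3
    obs = sim.apply_site_observation(
        fams, {"s0": set(gws_map.marker_ids)}, rate, seed=2)
    n = miss = 0
    for f, o in zip(fams, obs):
        for mt, mo in zip(f.pedigree.members, o.members):
            if mt.individual_id in f.unobserved_ids:
                continue
            for ct, co in zip(mt.genotypes, mo.genotypes):
                if ct is not None:
                    n += 1
                    miss += int(co is None)
    se = np.sqrt(n * rate * (1 - rate))
    assert n > 10_000
    assert abs(miss - n * rate) < 3 * se


def test_all_missing_gives_flat_curves(gws_map):
    fams = sim.simulate_cohort(small_cfg(gws_map, n_families=5))
    panels = {"s0": set(gws_map.marker_ids)}
    obs = sim.apply_site_observation(fams, panels, 1.0, seed=4)
    smaps = cmod.insert_dummy_anchors(gws_map, panels)
    obs = sim.add_dummy_genotypes(obs, smaps)
    # no observable calls anywhere: frequencies cannot be counted, so supply
    # a nominal table; curves must be identically zero
    freqs = {"s0": {m: {"1": 1.0} for m in gws_map.marker_ids}}
    pos = np.array([100.0, 134.0, 160.0])
    curves = lc.compute_family_curves(obs, smaps, freqs, positions=pos)
    for c in curves:
        assert np.allclose(c.parametric_lod, 0.0, atol=1e-9)
        assert np.allclose(c.z_score, 0.0, atol=1e-9)


def test_panel_masking_restricts_marker_list(gws_map):
    panel = set(gws_map.marker_ids[2:10])
    fams = sim.simulate_cohort(small_cfg(gws_map, site_panels={"s0": panel}))
    obs = sim.apply_site_observation(fams, {"s0": panel}, 0.0, seed=5)
    assert set(obs[0].marker_list) == panel


def test_site_panels_cover_terminal_markers_or_not(gws_map, rng):
    panels = sim.default_site_panels(gws_map, 11, rng)
    assert len(panels) == 11
    ids = set(gws_map.marker_ids)
    for site, panel in panels.items():
        assert panel <= ids and len(panel) >= 5
    # at least one site misses a terminal marker (exercises dummy anchors)
    first, last = gws_map.marker_ids[0], gws_map.marker_ids[-1]
    assert any(first not in p or last not in p for p in panels.values())


# -- structural enrichment ---------------------------------------------------


def test_consistent_x_subset_carries_more_signal_than_paternal():
    """Cohorts of linked maternal-structure families against unlinked
    paternal-structure families concentrate the linkage signal in the
    transmission-consistent subset."""
    from xlinkmeta.classification import build_subsets

    cmap = cmod.load_xq_map()
    diffs = []
    for seed in (101, 102, 103):
        cfg = sim.CohortSimConfig(
            n_families=200, linked_fraction=0.55, seed=seed, cmap=cmap,
            structure_mix={"maternal_uncle": 0.55,
                           "three_generation_paternal": 0.45},
            site_panels={"s0": set(cmap.marker_ids)}, n_sites=1,
            missing_rate=0.0)
        fams = sim.simulate_cohort(cfg)
        # plant linkage only in maternal-structure families: replace others
        keep = [f for f in fams
                if f.linked == (f.template == "maternal_uncle")]
        obs = sim.apply_site_observation(keep, cfg.site_panels, 0.0, seed)
        smaps = cmod.insert_dummy_anchors(cmap, cfg.site_panels)
        freqs = lc.estimate_allele_freqs(obs)
        pos = np.array([130.0, 134.0, 138.0])
        curves = lc.compute_family_curves(obs, smaps, freqs, positions=pos)
        subsets = build_subsets(obs)
        by_id = {c.family_id: c for c in curves}
        def peak(name):
            fams_n = subsets.get(name, [])
            if not fams_n:
                return 0.0
            return ma.hlod_curve([by_id[f] for f in fams_n]).peak.value
        diffs.append(peak("mm:consistent_x") - peak("mm:not_consistent"))
    assert np.mean(diffs) > 0


def test_matched_model_and_ascertainment_ratio(gws_map):
    cfg = small_cfg(gws_map)
    model = sim.matched_penetrance_model(cfg)
    # joint class rates sum to the generative lifetime risks
    p_car = sum(c.f_carrier for c in model.classes.values())
    p_phe = sum(c.f_phenocopy for c in model.classes.values())
    assert p_car == pytest.approx(0.75, abs=1e-9)
    assert p_phe == pytest.approx(0.045, abs=1e-9)
    gamma = sim.ascertainment_ratio(cfg, model, n_mc=300)
    # multiplex ascertainment strongly favors linked families
    assert 0.5 < gamma < 2.5
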