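"""Synthetic multi-site family cohorts with X-linked locus heterogeneity.

The generator emulates the statistical structure the analysis pipeline
assumes: a collection of small-to-moderate multiple-case prostate-cancer
pedigrees gathered by several sites, in which a fraction ``linked_fraction``
of families segregates an X-linked dominant risk allele at ``trait_cm``
while the remainder are affected through phenocopies only; affection is
male-limited and age-dependent; each site genotyped its own marker panel
with missing calls.

Families are drawn from four structural templates (nuclear sibships, a
paternal three-generation line, an affected maternal uncle constellation,
and a bare sibship with uninformative parents), gene-dropped over the
marker map plus the trait locus with Haldane recombination on maternal
meioses only, and kept only when at least two men are confirmed affected
(rejection sampling, emulating multiple-case ascertainment).

Everything is reproducible from the config seed, and the hidden truth
(linked status, carrier ids, inheritance paths) is retained for power and
recovery studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .consensus_map import DUMMY_ALLELE, ConsensusMap, load_xq_map
from .linkage_core import PenetranceModel, haldane_theta
from .pedigree_io import (AFFECTED, FEMALE, MALE, UNKNOWN, Individual,
                          Pedigree)

TEMPLATES = (
    "nuclear_2_3_affected",
    "three_generation_paternal",
    "maternal_uncle",
    "sibship_only",
)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class OnsetAgeModel:
    """Truncated-normal onset ages (years) for carriers and phenocopies."""

    carrier_mean: float = 62.0
    phenocopy_mean: float = 70.0
    sd: float = 7.0
    lo: float = 40.0
    hi: float = 90.0


@dataclass
class CohortSimConfig:
    n_families: int = 200
    linked_fraction: float = 0.5
    model: PenetranceModel = field(default_factory=PenetranceModel)
    trait_cm: float = 134.0
    cmap: Optional[ConsensusMap] = None  # defaults to the bundled GWS map
    n_sites: int = 11
    site_panels: Optional[dict] = None  # site -> marker-id set
    allele_count_range: tuple[int, int] = (6, 10)
    dirichlet_conc: float = 1.0
    structure_mix: dict = field(default_factory=lambda: {
        "nuclear_2_3_affected": 0.45,
        "three_generation_paternal": 0.20,
        "maternal_uncle": 0.20,
        "sibship_only": 0.15,
    })
    missing_rate: float = 0.05
    onset: OnsetAgeModel = field(default_factory=OnsetAgeModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.linked_fraction <= 1.0:
            raise ValueError("linked_fraction must be in [0, 1]")
        w = sum(self.structure_mix.values())
        if not math.isclose(w, 1.0, rel_tol=1e-9):
            raise ValueError(f"structure_mix weights sum to {w}, not 1")
        unknown = set(self.structure_mix) - set(TEMPLATES)
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")
        if self.cmap is None:
            self.cmap = load_xq_map()
        lo, hi = self.cmap.span
        if not lo <= self.trait_cm <= hi:
            raise ValueError(
                f"trait locus {self.trait_cm} cM outside map span {lo}-{hi}")


@dataclass
class SimulatedFamily:
    pedigree: Pedigree          # truth genotypes on the full consensus panel
    linked: bool
    carrier_ids: list[str]
    trait_cm: float
    template: str
    unobserved_ids: list[str]   # members never genotyped (e.g. sibship parents)


# ---------------------------------------------------------------------------
# structures


def _template_structure(name: str, rng: np.random.Generator):
    """Member tuples (id, father, mother, sex) + carrier founder + unobserved."""
    rows: list[tuple[str, Optional[str], Optional[str], str]] = []
    unobserved: list[str] = []
    if name == "nuclear_2_3_affected":
        rows += [("f", None, None, MALE), ("m", None, None, FEMALE)]
        n_sons = int(rng.integers(3, 7))
        for i in range(n_sons):
            rows.append((f"s{i + 1}", "f", "m", MALE))
        if rng.random() < 0.5:
            rows.append(("d1", "f", "m", FEMALE))
        carrier = "m"
    elif name == "three_generation_paternal":
        rows += [("gf", None, None, MALE), ("gm", None, None, FEMALE),
                 ("fa", "gf", "gm", MALE), ("mo", None, None, FEMALE)]
        for i in range(int(rng.integers(2, 4))):
            rows.append((f"s{i + 1}", "fa", "mo", MALE))
        carrier = "mo"
    elif name == "maternal_uncle":
        # grandmaternal branch structure: 1-2 uncles and 1-2 daughters, each
        # daughter with her own sibship; capped at 9 maternal meioses so the
        # inheritance-state space stays at <= 512 states
        rows += [("gf", None, None, MALE), ("gm", None, None, FEMALE)]
        n_uncles = int(rng.integers(1, 3))
        n_daughters = int(rng.integers(1, 3))
        sons_per = [int(rng.integers(2, 4)) for _ in range(n_daughters)]
        while n_uncles + n_daughters + sum(sons_per) > 9:
            k = int(rng.integers(0, n_daughters))
            if sons_per[k] > 2:
                sons_per[k] -= 1
            elif n_uncles > 1:
                n_uncles -= 1
            else:
                n_daughters -= 1
                sons_per = sons_per[:n_daughters]
        for i in range(n_uncles):
            rows.append((f"un{i + 1}", "gf", "gm", MALE))
        s = 0
        for j in range(n_daughters):
            rows.append((f"mo{j + 1}", "gf", "gm", FEMALE))
            rows.append((f"fa{j + 1}", None, None, MALE))
            for _ in range(sons_per[j]):
                s += 1
                rows.append((f"s{s}", f"fa{j + 1}", f"mo{j + 1}", MALE))
        carrier = "gm"
    elif name == "sibship_only":
        rows += [("f", None, None, MALE), ("m", None, None, FEMALE)]
        for i in range(int(rng.integers(3, 5))):
            rows.append((f"s{i + 1}", "f", "m", MALE))
        carrier = "m"
        unobserved = ["f", "m"]
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(name)
    return rows, carrier, unobserved


# ---------------------------------------------------------------------------
# gene dropping


def gene_drop_x(rows, loci_cm: np.ndarray, founder_haps: dict,
                rng: np.random.Generator):
    """Drop X haplotypes through a structure with maternal recombination.

    ``rows`` are (id, father, mother, sex) tuples in an order where parents
    precede children.  ``founder_haps[id]`` holds one haplotype (array over
    loci) for founder men and two for founder women.  Daughters receive the
    father's X unchanged plus a maternal recombinant; sons receive only a
    maternal recombinant.  Returns (haplotypes, inheritance bit vectors).
    """
    L = len(loci_cm)
    thetas = np.array([
        haldane_theta(loci_cm[i + 1] - loci_cm[i]) for i in range(L - 1)
    ])
    haps: dict[str, list[np.ndarray]] = {}
    bits: dict[str, np.ndarray] = {}
    for ind, father, mother, sex in rows:
        if father is None:
            haps[ind] = [h.copy() for h in founder_haps[ind]]
            continue
        b = np.empty(L, dtype=np.int8)
        b[0] = rng.integers(0, 2)
        flips = rng.random(L - 1) < thetas
        for i in range(1, L):
            b[i] = b[i - 1] ^ int(flips[i - 1])
        mhaps = haps[mother]
        maternal = np.where(b == 0, mhaps[0], mhaps[1])
        bits[ind] = b
        if sex == MALE:
            haps[ind] = [maternal]
        else:
            haps[ind] = [maternal, haps[father][0].copy()]
    return haps, bits


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_marker_freqs(cmap: ConsensusMap, cfg: CohortSimConfig,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    lo, hi = cfg.allele_count_range
    freqs = {}
    for rec in cmap.records:
        k = int(rng.integers(lo, hi + 1))
        freqs[rec.marker_id] = rng.dirichlet(np.full(k, cfg.dirichlet_conc))
    return freqs


def default_site_panels(cmap: ConsensusMap, n_sites: int,
                        rng: np.random.Generator) -> dict[str, set[str]]:
    """Randomly thinned per-site panels; some sites miss a terminal marker."""
    ids = cmap.marker_ids
    panels: dict[str, set[str]] = {}
    for s in range(n_sites):
        site = f"site{s:02d}"
        if s < 2:
            panels[site] = set(ids)
            continue
        keep = {mid for mid in ids[1:-1] if rng.random() < 0.75}
        # keep panels dense enough to be informative
        while len(keep) < max(5, len(ids) // 2):
            keep.add(ids[int(rng.integers(1, len(ids) - 1))])
        if rng.random() < 0.5:
            keep.add(ids[0])
        if rng.random() < 0.5:
            keep.add(ids[-1])
        panels[site] = keep
    return panels


def matched_penetrance_model(cfg: "CohortSimConfig") -> PenetranceModel:
    """Analysis model matched to this generator's affection process.

    Liability classes are returned as joint (affected & class) rates —
    lifetime risk times the probability the onset age falls in the class's
    window under the truncated-normal onset model — so that analyses
    conditioning on the observed class, and the ascertainment correction
    (which sums the classes back to lifetime risk), are both correctly
    specified for simulated cohorts.  Recovery studies of the heterogeneity
    proportion should analyze under this model with the ``"segregating"``
    founder mode.
    """
    from scipy.stats import norm

    from .linkage_core import LiabilityClass

    p_car, p_phe = _affection_probs(cfg.model)
    o = cfg.onset

    def p_class1(mean: float) -> float:
        z = lambda x: norm.cdf((x - mean) / o.sd)  # noqa: E731
        return (z(65.0) - z(o.lo)) / (z(o.hi) - z(o.lo))

    c1_car, c1_phe = p_class1(o.carrier_mean), p_class1(o.phenocopy_mean)
    return PenetranceModel(
        # frequency is irrelevant under the segregating founder mode
        risk_allele_freq=0.5,
        classes={
            1: LiabilityClass(p_car * c1_car, p_phe * c1_phe),
            2: LiabilityClass(p_car * (1 - c1_car), p_phe * (1 - c1_phe)),
        },
    )


def ascertainment_ratio(cfg: "CohortSimConfig",
                        model: Optional[PenetranceModel] = None,
                        n_mc: int = 2000,
                        seed: int = 20_200_134) -> float:
    """Design constant for full-likelihood admixture analyses.

    Returns log10 of the ratio of marginal multiple-case ascertainment
    probabilities, linked over unlinked, under the cohort's family-structure
    distribution (Monte Carlo over the template mix).  ``model`` defaults to
    the generator-matched analysis model.
    """
    import math

    from .consensus_map import ConsensusMap
    from .linkage_core import FamilyEngine

    model = model or matched_penetrance_model(cfg)
    rng = np.random.default_rng(seed)
    names = list(cfg.structure_mix)
    weights = np.array([cfg.structure_mix[n] for n in names])
    empty_map = ConsensusMap([], cfg.cmap.grid_step if cfg.cmap else 1.0)
    acc_l = acc_u = 0.0
    for _ in range(n_mc):
        template = str(rng.choice(names, p=weights))
        rows, _, _ = _template_structure(template, rng)
        members = [
            Individual(individual_id=i, father_id=f, mother_id=m, sex=s,
                       genotypes=[])
            for i, f, m, s in rows
        ]
        ped = Pedigree("asc_mc", members, "mc", [])
        eng = FamilyEngine(ped, empty_map, {}, model)
        a, u = eng.ascertainment_prob()
        acc_l += a
        acc_u += u
    return math.log10(acc_l / acc_u)


def _affection_probs(model: PenetranceModel) -> tuple[float, float]:
    """Lifetime risk for carrier and phenocopy men: class-mean penetrances."""
    cls = list(model.classes.values())
    return (
        float(np.mean([c.f_carrier for c in cls])),
        float(np.mean([c.f_phenocopy for c in cls])),
    )


def _draw_onset(carrier: bool, onset: OnsetAgeModel,
                rng: np.random.Generator) -> float:
    mean = onset.carrier_mean if carrier else onset.phenocopy_mean
    while True:
        a = rng.normal(mean, onset.sd)
        if onset.lo <= a <= onset.hi:
            return round(a, 1)


def _simulate_family(
    fam_id: str, site_id: str, cfg: CohortSimConfig,
    marker_freqs: dict[str, np.ndarray], rng: np.random.Generator,
    rejection_budget: list[int],
) -> SimulatedFamily:
    cmap = cfg.cmap
    marker_ids = cmap.marker_ids
    marker_cm = np.array([r.cm for r in cmap.records])
    loci_cm = np.sort(np.append(marker_cm, cfg.trait_cm))
    # marker index within loci (handles the trait coinciding with a marker)
    order = np.argsort(np.append(marker_cm, cfg.trait_cm), kind="stable")
    pos_of = np.empty(len(order), dtype=int)
    pos_of[order] = np.arange(len(order))
    marker_loci_idx = pos_of[: len(marker_ids)]
    trait_idx = int(pos_of[len(marker_ids)])

    names = list(cfg.structure_mix)
    weights = np.array([cfg.structure_mix[n] for n in names])
    p_aff_carrier, p_aff_pheno = _affection_probs(cfg.model)

    linked = bool(rng.random() < cfg.linked_fraction)
    template = str(rng.choice(names, p=weights))
    cum_freqs = {m: np.cumsum(f) for m, f in marker_freqs.items()}

    def draw_founder_haps(rows):
        haps = {}
        for ind, father, _, sex in rows:
            if father is not None:
                continue
            hs = []
            for _ in range(1 if sex == MALE else 2):
                h = np.zeros(len(loci_cm), dtype=int)
                u = rng.random(len(marker_ids))
                for k, (mid, li) in enumerate(zip(marker_ids, marker_loci_idx)):
                    h[li] = int(np.searchsorted(cum_freqs[mid], u[k])) + 1
                hs.append(h)
            haps[ind] = hs
        return haps

    while True:
        if rejection_budget[0] <= 0:
            raise SimulationError(
                "ascertainment rejection budget exhausted; the configured "
                "penetrances/phenocopy rates make multiple-case families "
                "too rare — adjust the model or structure mix"
            )
        rejection_budget[0] -= 1
        rows, carrier_founder, unobserved = _template_structure(template, rng)
        haps = None
        if linked:
            # the risk allele (coded -1) rides one haplotype of the designated
            # carrier founder; affection then depends on the gene drop
            founder_haps = draw_founder_haps(rows)
            hs = founder_haps[carrier_founder]
            hs[int(rng.integers(0, len(hs)))][trait_idx] = -1
            haps, _bits = gene_drop_x(rows, loci_cm, founder_haps, rng)
            carrier_of = {
                ind: any(h[trait_idx] == -1 for h in haps[ind])
                for ind, *_ in rows
            }
        else:
            # no carrier anywhere: affection is independent of the genotypes,
            # so ascertainment can be decided before the gene drop
            carrier_of = {ind: False for ind, *_ in rows}

        affection_of = {}
        onset_of = {}
        n_affected_men = 0
        for ind, father, mother, sex in rows:
            affection_of[ind] = UNKNOWN
            onset_of[ind] = None
            if sex == MALE:
                p = p_aff_carrier if carrier_of[ind] else p_aff_pheno
                if rng.random() < p:
                    affection_of[ind] = AFFECTED
                    onset_of[ind] = _draw_onset(carrier_of[ind], cfg.onset, rng)
                    n_affected_men += 1
        if n_affected_men >= 2:
            break

    if haps is None:
        haps, _bits = gene_drop_x(rows, loci_cm, draw_founder_haps(rows), rng)

    members = []
    carriers = [ind for ind, *_ in rows if carrier_of[ind]]
    for ind, father, mother, sex in rows:
        onset_age = onset_of[ind]
        genos = []
        for li in marker_loci_idx:
            alleles = tuple(sorted(str(h[li]) for h in haps[ind]))
            genos.append(alleles if sex == FEMALE else (alleles[0],))
        members.append(Individual(
            individual_id=ind, father_id=father, mother_id=mother,
            sex=sex, affection=affection_of[ind], onset_age=onset_age,
            liability_class=1 if (onset_age is not None and onset_age < 65) else 2,
            genotypes=genos,
        ))

    ped = Pedigree(family_id=fam_id, members=members, site_id=site_id,
                   marker_list=list(marker_ids))
    return SimulatedFamily(ped, linked, carriers, cfg.trait_cm, template,
                           unobserved)


def simulate_cohort(cfg: CohortSimConfig) -> list[SimulatedFamily]:
    """Draw a reproducible multi-site cohort of ascertained families."""
    rng = np.random.default_rng(cfg.seed)
    cmap = cfg.cmap
    marker_freqs = _draw_marker_freqs(cmap, cfg, rng)
    panels = cfg.site_panels or default_site_panels(cmap, cfg.n_sites, rng)
    cfg.site_panels = panels  # record the panels actually used
    sites = sorted(panels)
    budget = [10 ** 6]
    out = []
    for i in range(cfg.n_families):
        site = sites[int(rng.integers(0, len(sites)))]
        fam = _simulate_family(f"fam{i + 1:04d}", site, cfg, marker_freqs,
                               rng, budget)
        out.append(fam)
    return out


def apply_site_observation(
    families: Sequence[SimulatedFamily],
    site_panels: dict[str, set[str]],
    missing_rate: float,
    seed: int,
) -> list[Pedigree]:
    """Observed pedigrees: panel masking plus independent missing calls.

    Markers outside the family's site panel disappear from its marker list;
    retained calls are masked independently at ``missing_rate``; members the
    site never genotyped lose all calls.  Structure and phenotypes are
    untouched.
    """
    rng = np.random.default_rng(seed)
    out = []
    for fam in families:
        ped = fam.pedigree
        panel = site_panels[ped.site_id]
        keep_idx = [i for i, m in enumerate(ped.marker_list) if m in panel]
        marker_list = [ped.marker_list[i] for i in keep_idx]
        members = []
        for m in ped.members:
            genos = []
            for i in keep_idx:
                call = m.genotypes[i]
                if m.individual_id in fam.unobserved_ids:
                    call = None
                elif call is not None and rng.random() < missing_rate:
                    call = None
                genos.append(call)
            members.append(replace(m, genotypes=genos))
        out.append(Pedigree(ped.family_id, members, ped.site_id, marker_list))
    return out


def add_dummy_genotypes(peds: Sequence[Pedigree],
                        site_maps: dict[str, ConsensusMap]) -> list[Pedigree]:
    """Extend pedigrees with homozygous calls at their site's dummy anchors."""
    out = []
    for ped in peds:
        smap = site_maps[ped.site_id]
        dummy_ids = [r.marker_id for r in smap.records if r.source == "dummy"]
        if not dummy_ids:
            out.append(ped)
            continue
        members = []
        for m in ped.members:
            extra = [
                (DUMMY_ALLELE,) if m.sex == MALE else (DUMMY_ALLELE, DUMMY_ALLELE)
                for _ in dummy_ids
            ]
            members.append(replace(m, genotypes=list(m.genotypes) + extra))
        out.append(Pedigree(ped.family_id, members, ped.site_id,
                            list(ped.marker_list) + dummy_ids))
    return out


def truth_frame(families: Sequence[SimulatedFamily]):
    """Truth sidecar: family_id, site, template, linked, carriers, trait_cm."""
    import pandas as pd

    return pd.DataFrame([
        {
            "family_id": f.pedigree.family_id,
            "site_id": f.pedigree.site_id,
            "template": f.template,
            "linked": int(f.linked),
            "carrier_ids": ",".join(f.carrier_ids),
            "trait_cm": f.trait_cm,
        }
        for f in families
    ])
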