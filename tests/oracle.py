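"""Independent brute-force reference implementations.

Everything here enumerates exhaustively (inheritance vectors per locus,
founder-allele assignments, disease-allele configurations) with plain
Python, deliberately avoiding the package's HMM/forward-backward machinery
so it can serve as an oracle for it.  Only usable on tiny families.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

from xlinkmeta.pedigree_io import FEMALE, MALE, Pedigree


def haldane(d_cm: float) -> float:
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


# -- structure ---------------------------------------------------------------


def founder_slots(ped: Pedigree) -> dict[str, list[int]]:
    """Founder id -> X-haplotype slot ids (1 for men, 2 for women)."""
    slots: dict[str, list[int]] = {}
    k = 0
    for m in ped.members:
        if m.is_founder:
            n = 1 if m.sex == MALE else 2
            slots[m.individual_id] = list(range(k, k + n))
            k += n
    return slots


def n_slots(ped: Pedigree) -> int:
    return sum(len(v) for v in founder_slots(ped).values())


def nonfounder_ids(ped: Pedigree) -> list[str]:
    return [m.individual_id for m in ped.members if not m.is_founder]


def resolve_slots(ped: Pedigree, bits: dict[str, int]) -> dict[str, list[int]]:
    """Member id -> founder-slot ids of their X allele(s) under one vector."""
    fs = founder_slots(ped)
    memo: dict[str, list[int]] = {}

    def alleles_of(ind_id: str) -> list[int]:
        if ind_id in memo:
            return memo[ind_id]
        m = ped.member(ind_id)
        if m.is_founder:
            memo[ind_id] = list(fs[ind_id])
            return memo[ind_id]
        mother_alleles = alleles_of(m.mother_id)  # [maternal, paternal?]
        maternal = mother_alleles[bits[ind_id]]
        if m.sex == MALE:
            memo[ind_id] = [maternal]
        else:
            memo[ind_id] = [maternal, alleles_of(m.father_id)[0]]
        return memo[ind_id]

    for m in ped.members:
        alleles_of(m.individual_id)
    return memo


def all_vectors(ped: Pedigree):
    nf = nonfounder_ids(ped)
    for combo in product((0, 1), repeat=len(nf)):
        yield dict(zip(nf, combo))


# -- marker emission ---------------------------------------------------------


def emission(ped: Pedigree, marker_idx: int, freq: dict[str, float],
             bits: dict[str, int]) -> float:
    """P(observed calls at one marker | inheritance vector), exact.

    Sums over every assignment of alleles (the frequency table's support) to
    every founder slot.
    """
    resolved = resolve_slots(ped, bits)
    alleles = sorted(freq)
    S = n_slots(ped)
    total = 0.0
    for assign in product(alleles, repeat=S):
        ok = True
        for m in ped.members:
            call = m.genotypes[marker_idx]
            if call is None:
                continue
            have = sorted(assign[s] for s in resolved[m.individual_id])
            if m.sex == MALE:
                want = [call[0]]
            else:
                want = sorted(call)
            if have != want:
                ok = False
                break
        if ok:
            total += math.prod(freq[a] for a in assign)
    return total


# -- multipoint posterior ----------------------------------------------------


def multipoint_posterior(ped: Pedigree, markers: list[tuple[float, int, dict]],
                         x_cm: float) -> dict[tuple, float]:
    """Exact posterior over the inheritance vector at ``x_cm``.

    ``markers`` are (position_cm, genotype_index, freq_table) triples.
    Enumerates joint vector sequences over all loci with Haldane
    transitions per maternal meiosis.
    """
    nf = nonfounder_ids(ped)
    loci = sorted({cm for cm, _, _ in markers} | {x_cm})
    x_pos = loci.index(x_cm)
    emis_by_locus: list[list[tuple[int, dict]]] = [[] for _ in loci]
    for cm, gi, fr in markers:
        emis_by_locus[loci.index(cm)].append((gi, fr))

    vecs = [dict(zip(nf, combo)) for combo in product((0, 1), repeat=len(nf))]
    e_cache = [
        [math.prod(emission(ped, gi, fr, v) for gi, fr in emis_by_locus[li])
         for v in vecs]
        for li in range(len(loci))
    ]
    post: dict[tuple, float] = {}
    for seq in product(range(len(vecs)), repeat=len(loci)):
        p = 1.0 / (2 ** len(nf))
        for li in range(1, len(loci)):
            th = haldane(loci[li] - loci[li - 1])
            va, vb = vecs[seq[li - 1]], vecs[seq[li]]
            for ind in nf:
                p *= th if va[ind] != vb[ind] else (1 - th)
        for li in range(len(loci)):
            p *= e_cache[li][seq[li]]
        key = tuple(sorted(vecs[seq[x_pos]].items()))
        post[key] = post.get(key, 0.0) + p
    tot = sum(post.values())
    return {k: v / tot for k, v in post.items()}


# -- phenotype likelihood and LOD --------------------------------------------


def pheno_lik(ped: Pedigree, bits: dict[str, int], model,
              founder_mode: str = "population",
              eligible_slots: list[int] | None = None) -> float:
    """P(affection pattern | vector) by enumerating disease configurations."""
    resolved = resolve_slots(ped, bits)
    aff = [m for m in ped.affected]
    S = n_slots(ped)
    q = model.risk_allele_freq

    def pattern_prob(carrier_slots: set[int]) -> float:
        p = 1.0
        for m in aff:
            lia = model.liability(m.liability_class)
            carrier = resolved[m.individual_id][0] in carrier_slots
            p *= lia.f_carrier if carrier else lia.f_phenocopy
        return p

    if founder_mode == "segregating":
        slots = eligible_slots if eligible_slots is not None else list(range(S))
        return sum(pattern_prob({s}) for s in slots) / len(slots)
    total = 0.0
    for config in product((0, 1), repeat=S):
        prior = math.prod(q if c else (1 - q) for c in config)
        total += prior * pattern_prob({s for s, c in enumerate(config) if c})
    return total


def parametric_lod(ped: Pedigree, markers, x_cm: float, model,
                   founder_mode: str = "population",
                   eligible_slots=None) -> float:
    """Multipoint parametric LOD at one position, fully enumerated."""
    post = multipoint_posterior(ped, markers, x_cm)
    nf = nonfounder_ids(ped)
    num = 0.0
    den = 0.0
    n_v = 0
    for combo in product((0, 1), repeat=len(nf)):
        bits = dict(zip(nf, combo))
        pl = pheno_lik(ped, bits, model, founder_mode, eligible_slots)
        key = tuple(sorted(bits.items()))
        num += post.get(key, 0.0) * pl
        den += pl
        n_v += 1
    return math.log10(num / (den / n_v))


# -- allele sharing ----------------------------------------------------------


def sharing_score(ped: Pedigree, bits: dict[str, int], scorer: str) -> float:
    resolved = resolve_slots(ped, bits)
    aff = ped.affected
    sets = [resolved[m.individual_id] for m in aff]
    if scorer == "pairs":
        s = 0.0
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                s += sum(1 for a in sets[i] for b in sets[j] if a == b)
        return s
    # S_all
    total = 0.0
    selections = list(product(*[range(len(s)) for s in sets]))
    for sel in selections:
        counts: dict[int, int] = {}
        for i, c in enumerate(sel):
            counts[sets[i][c]] = counts.get(sets[i][c], 0) + 1
        total += math.prod(math.factorial(n) for n in counts.values())
    return total / len(selections)


def sharing_zbar(ped: Pedigree, markers, x_cm: float, scorer: str) -> float:
    nf = nonfounder_ids(ped)
    scores = []
    keys = []
    for combo in product((0, 1), repeat=len(nf)):
        bits = dict(zip(nf, combo))
        scores.append(sharing_score(ped, bits, scorer))
        keys.append(tuple(sorted(bits.items())))
    scores = np.array(scores)
    mu, sd = scores.mean(), scores.std()
    if sd < 1e-12:
        return 0.0
    post = multipoint_posterior(ped, markers, x_cm)
    z = (scores - mu) / sd
    return float(sum(post.get(k, 0.0) * zz for k, zz in zip(keys, z)))


# -- meta statistics ---------------------------------------------------------


def hlod_grid(lods, step: float = 0.001) -> tuple[float, float]:
    lods = np.asarray(lods, dtype=float)
    ratios = 10.0 ** lods
    alphas = np.arange(0.0, 1.0 + step / 2, step)
    vals = np.log10(alphas[:, None] * ratios[None, :]
                    + (1 - alphas[:, None])).sum(axis=1)
    k = int(np.argmax(vals))
    return max(0.0, float(vals[k])), float(alphas[k])


def kong_cox_grid(zbars, delta_bound: float = 4.0,
                  step: float = 0.0005) -> tuple[float, float]:
    z = np.asarray(zbars, dtype=float)
    m = z.size
    gz = z / math.sqrt(m)
    d_max = delta_bound
    neg = gz[gz < 0]
    if neg.size:
        d_max = min(delta_bound, float((1.0 - 1e-9) / (-neg).max()))
    deltas = np.arange(0.0, d_max + step / 2, step)
    vals = np.log10(1.0 + deltas[:, None] * gz[None, :]).sum(axis=1)
    k = int(np.argmax(vals))
    return max(0.0, float(vals[k])), float(deltas[k])
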