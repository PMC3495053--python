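"""Per-family X-chromosome multipoint linkage engine.

The engine is the X-restricted inheritance-vector HMM: on the non-PAR X a
son receives a single maternally-derived (possibly recombinant) X and no
paternal X, while a daughter receives her father's X unchanged, so only
maternal meioses carry an inheritance bit.  A family with ``b`` non-founders
therefore has a state space of ``2^b`` inheritance vectors — exponentially
smaller than the autosomal ``2^(2n)``.

For each family the engine produces, on a shared cM grid:

* the parametric multipoint LOD under a dominant X-linked, sex-limited,
  two-liability-class, affecteds-only model (risk-allele frequency ``q``,
  per-class carrier and phenocopy penetrances for men, zero penetrance for
  women), and
* the normalized expected allele-sharing score ``Z`` (Whittemore–Halpern
  ``pairs`` or ``all`` scoring over the affected men's maternal X alleles),
  standardized exactly against the uniform inheritance distribution.

Transitions between grid positions use the Haldane map function on female
(maternal) meiosis distances; marker emissions sum founder-allele
assignments at site-specific allele frequencies over the phase choices of
unphased female genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .consensus_map import DUMMY_ALLELE, ConsensusMap, grid_positions
from .pedigree_io import FEMALE, MALE, Pedigree

STATE_GUARD = 2 ** 20


class LinkageError(ValueError):
    pass


class MendelianError(LinkageError):
    """Observed genotypes are impossible on the X given the pedigree."""


@dataclass(frozen=True)
class LiabilityClass:
    f_carrier: float
    f_phenocopy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_phenocopy <= self.f_carrier <= 1.0):
            raise LinkageError(
                f"need 0 <= phenocopy <= carrier <= 1, got "
                f"{self.f_phenocopy}/{self.f_carrier}"
            )


@dataclass(frozen=True)
class PenetranceModel:
    """Dominant X-linked, sex-limited (male-only) penetrance model.

    Defaults: rare risk allele (q = 0.003) with an early-onset class
    (onset < 65: carrier 0.90, phenocopy 0.02) and a late-onset class
    (carrier 0.60, phenocopy 0.07).  All parameters are overridable; the
    analyses built on this engine are oracle- and recovery-based rather than
    tied to these numbers.
    """

    risk_allele_freq: float = 0.003
    classes: dict = field(
        default_factory=lambda: {
            1: LiabilityClass(0.90, 0.02),
            2: LiabilityClass(0.60, 0.07),
        }
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.risk_allele_freq < 1.0):
            raise LinkageError("risk allele frequency must be in (0, 1)")

    def liability(self, cls: int) -> LiabilityClass:
        try:
            return self.classes[cls]
        except KeyError:
            raise LinkageError(
                f"penetrance model has no liability class {cls}"
            ) from None


def haldane_theta(d_cm: float) -> float:
    """Map distance (cM) to recombination fraction, no interference."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


# ---------------------------------------------------------------------------
# allele frequencies


def estimate_allele_freqs(peds: Sequence[Pedigree]) -> dict:
    """Site- and marker-wise allele frequencies by direct allele counting.

    Every observed allele is counted across all individuals of a site,
    ignoring relationships: men contribute their single X allele, women two.
    Returns ``{site_id: {marker_id: {allele: freq}}}``.
    """
    counts: dict[str, dict[str, dict[str, float]]] = {}
    markers_by_site: dict[str, list[str]] = {}
    for ped in peds:
        site = counts.setdefault(ped.site_id, {})
        markers_by_site.setdefault(ped.site_id, ped.marker_list)
        for m in ped.members:
            for k, marker in enumerate(ped.marker_list):
                call = m.genotypes[k]
                if call is None:
                    continue
                tab = site.setdefault(marker, {})
                for allele in call:
                    tab[allele] = tab.get(allele, 0.0) + 1.0
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    for site_id, site in counts.items():
        freqs[site_id] = {}
        for marker in markers_by_site[site_id]:
            tab = site.get(marker, {})
            if not tab:
                raise LinkageError(
                    f"marker {marker} has zero genotype calls at site {site_id}"
                )
            total = sum(tab.values())
            freqs[site_id][marker] = {a: c / total for a, c in tab.items()}
    return freqs


# ---------------------------------------------------------------------------
# the inheritance-vector engine


@dataclass
class FamilyLodCurve:
    family_id: str
    site_id: str
    positions: np.ndarray
    parametric_lod: np.ndarray
    z_score: np.ndarray
    informative: bool = True
    # position-independent terms for full-likelihood admixture analyses of
    # ascertained cohorts: log10 LR of the affection pattern, and log10 of
    # the linked/unlinked ascertainment-probability ratio
    pheno_log10_lr: float = 0.0
    asc_log10_lr: float = 0.0


class FamilyEngine:
    """Inheritance-vector HMM for one family on one site map.

    States are bitmasks with one bit per non-founder (its maternal meiosis);
    bit 0 means the grandmaternal, bit 1 the grandpaternal allele of the
    mother was transmitted.
    """

    def __init__(self, ped: Pedigree, site_map: ConsensusMap,
                 marker_freqs: dict, model: Optional[PenetranceModel] = None):
        self.ped = ped
        self.site_map = site_map
        self.freqs = marker_freqs
        self.model = model or PenetranceModel()
        self._setup_states()
        self._setup_slots()
        self._setup_markers()

    # -- state space ------------------------------------------------------

    def _setup_states(self) -> None:
        ped = self.ped
        self.nonfounders = [m for m in ped.members if not m.is_founder]
        self.n_bits = len(self.nonfounders)
        if 2 ** self.n_bits > STATE_GUARD:
            raise LinkageError(
                f"family {ped.family_id}: {self.n_bits} maternal meioses "
                f"exceed the inheritance-state guard (2^{self.n_bits} states); "
                "split the family"
            )
        self.n_states = 2 ** self.n_bits
        self.bit_of = {
            m.individual_id: i for i, m in enumerate(self.nonfounders)
        }

    def _setup_slots(self) -> None:
        """Founder X-allele slots and, per state, each member's slot indices."""
        ped = self.ped
        S = self.n_states
        states = np.arange(S)
        self.slot_owner: list[str] = []  # founder id per slot (females twice)
        founder_slots: dict[str, tuple] = {}
        for m in ped.members:
            if not m.is_founder:
                continue
            if m.sex == MALE:
                founder_slots[m.individual_id] = (len(self.slot_owner),)
                self.slot_owner.append(m.individual_id)
            else:
                founder_slots[m.individual_id] = (
                    len(self.slot_owner), len(self.slot_owner) + 1)
                self.slot_owner.append(m.individual_id)
                self.slot_owner.append(m.individual_id)
        self.n_slots = len(self.slot_owner)

        # maternal-allele slot (everyone) and paternal-allele slot (females),
        # as arrays over states, resolved in topological order
        mat: dict[str, np.ndarray] = {}
        pat: dict[str, np.ndarray] = {}
        remaining = list(ped.members)
        while remaining:
            progressed = False
            still = []
            for m in remaining:
                if m.is_founder:
                    slots = founder_slots[m.individual_id]
                    mat[m.individual_id] = np.full(S, slots[0])
                    if m.sex == FEMALE:
                        pat[m.individual_id] = np.full(S, slots[1])
                    progressed = True
                    continue
                mother, father = m.mother_id, m.father_id
                if mother not in mat or (
                    ped.member(mother).sex == FEMALE and mother not in pat
                ):
                    still.append(m)
                    continue
                if m.sex == FEMALE and father not in mat:
                    still.append(m)
                    continue
                bit = (states >> self.bit_of[m.individual_id]) & 1
                mat[m.individual_id] = np.where(
                    bit == 0, mat[mother], pat[mother])
                if m.sex == FEMALE:
                    pat[m.individual_id] = mat[father]  # father's only X
                progressed = True
            if not progressed:
                raise LinkageError(
                    f"family {self.ped.family_id}: unresolvable parentage order"
                )
            remaining = still
        self.mat_slot = mat
        self.pat_slot = pat

    def member_slots(self, member) -> list[np.ndarray]:
        """Founder-slot arrays (over states) of this member's X allele(s)."""
        if member.sex == MALE:
            return [self.mat_slot[member.individual_id]]
        return [self.mat_slot[member.individual_id],
                self.pat_slot[member.individual_id]]

    # -- marker emissions -------------------------------------------------

    def _setup_markers(self) -> None:
        ped = self.ped
        self.marker_cm: list[float] = []
        self.marker_emission: list[np.ndarray] = []
        geno_idx = {m: i for i, m in enumerate(ped.marker_list)}
        for rec in self.site_map.records:
            if rec.source == "dummy":
                continue  # constant emission: contributes nothing
            if rec.marker_id not in geno_idx:
                raise LinkageError(
                    f"family {ped.family_id}: site map marker {rec.marker_id} "
                    "absent from the pedigree's marker list"
                )
            e = self._emission(rec.marker_id, geno_idx[rec.marker_id])
            if e is None:
                continue  # no observed calls: uninformative marker
            if not np.any(e > 0):
                raise MendelianError(
                    f"family {ped.family_id}: genotypes at {rec.marker_id} "
                    "are incompatible with X-linked transmission"
                )
            self.marker_cm.append(rec.cm)
            self.marker_emission.append(e)

    def _emission(self, marker_id: str, gi: int) -> Optional[np.ndarray]:
        """P(observed genotypes at one marker | state), up to a constant."""
        freq = self.freqs.get(marker_id, {DUMMY_ALLELE: 1.0})
        obs = []  # (member, call)
        for m in self.ped.members:
            call = m.genotypes[gi]
            if call is not None:
                obs.append((m, call))
        if not obs:
            return None
        S = self.n_states
        # phase enumeration: heterozygous females have two orderings of
        # (maternal, paternal) allele; males and homozygotes are forced
        het = [
            (m, call) for m, call in obs
            if m.sex == FEMALE and call[0] != call[1]
        ]
        het_ids = [m.individual_id for m, _ in het]
        total = np.zeros(S)
        for combo in range(2 ** len(het)):
            slots, alleles = [], []
            for m, call in obs:
                if m.sex == MALE:
                    slots.append(self.mat_slot[m.individual_id])
                    alleles.append(call[0])
                    continue
                a, b = call
                if a != b and (combo >> het_ids.index(m.individual_id)) & 1:
                    a, b = b, a
                slots.append(self.mat_slot[m.individual_id])
                alleles.append(a)
                slots.append(self.pat_slot[m.individual_id])
                alleles.append(b)
            try:
                f = [freq[a] for a in alleles]
            except KeyError as exc:
                raise LinkageError(
                    f"allele {exc.args[0]} at {marker_id} missing from the "
                    "site allele-frequency table"
                ) from None
            # product of allele frequencies over distinct founder slots;
            # conflicting assignments to one slot kill the state
            contrib = np.ones(S)
            ok = np.ones(S, dtype=bool)
            for j in range(len(slots)):
                dup_same = np.zeros(S, dtype=bool)
                for i in range(j):
                    same_slot = slots[i] == slots[j]
                    if alleles[i] == alleles[j]:
                        dup_same |= same_slot
                    else:
                        ok &= ~same_slot
                contrib *= np.where(dup_same, 1.0, f[j])
            total += contrib * ok
        return total

    # -- HMM --------------------------------------------------------------

    def _transition(self, p: np.ndarray, theta: float) -> np.ndarray:
        """Bitwise symmetric channel: each maternal meiosis flips w.p. theta."""
        if theta <= 0 or self.n_bits == 0:
            return p
        q = p.reshape((2,) * self.n_bits)
        for axis in range(self.n_bits):
            q = (1 - theta) * q + theta * np.flip(q, axis=axis)
        return q.reshape(-1)

    def posteriors(self, positions: np.ndarray) -> np.ndarray:
        """Posterior over inheritance states at every requested position.

        Returns an array of shape (len(positions), n_states); rows sum to 1.
        """
        positions = np.asarray(positions, dtype=float)
        if self.n_states == 1:
            return np.ones((len(positions), 1))
        # merge requested positions with marker positions
        marker_cm = np.round(np.asarray(self.marker_cm, dtype=float), 9)
        allpos = np.union1d(np.round(positions, 9), marker_cm)
        K = len(allpos)
        S = self.n_states
        E = np.ones((K, S))
        for cm, e in zip(marker_cm, self.marker_emission):
            E[int(np.searchsorted(allpos, cm))] *= e
        alpha = np.empty((K, S))
        prev = np.full(S, 1.0 / S)
        for k in range(K):
            if k > 0:
                prev = self._transition(
                    prev, haldane_theta(allpos[k] - allpos[k - 1]))
            cur = prev * E[k]
            tot = cur.sum()
            if tot == 0:
                raise MendelianError(
                    f"family {self.ped.family_id}: zero likelihood at "
                    f"{allpos[k]} cM"
                )
            alpha[k] = cur / tot
            prev = alpha[k]
        beta = np.empty((K, S))
        beta[K - 1] = 1.0
        nxt = beta[K - 1]
        for k in range(K - 2, -1, -1):
            msg = self._transition(
                nxt * E[k + 1], haldane_theta(allpos[k + 1] - allpos[k]))
            msg /= msg.sum()
            beta[k] = msg
            nxt = msg
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        idx = np.searchsorted(allpos, np.round(positions, 9))
        return post[idx]

    # -- parametric LOD ---------------------------------------------------

    def phenotype_likelihoods(self, founder_mode: str = "population"
                              ) -> np.ndarray:
        """P(affection pattern | state) under the penetrance model, per state.

        Under affecteds-only scoring, phenotype-unknown members contribute a
        factor 1; women have zero penetrance (sex-limited trait), so only
        affected men enter.

        ``founder_mode`` selects the disease-locus founder model:

        * ``"population"`` — founder X alleles carry the risk allele
          independently at frequency ``q`` (the classic admixture-model
          parametrization); the likelihood factorizes over founder slots.
        * ``"segregating"`` — exactly one risk allele is present, uniformly
          distributed over the X-haplotype slots of founder women from which
          a transmission path to at least one affected man exists.  This
          matches a cohort in which every linked family carries a mutation
          introduced by a female ancestor, and is the correctly specified
          linked hypothesis for recovery studies on such cohorts.
        """
        model = self.model
        q = model.risk_allele_freq
        aff = [m for m in self.ped.affected]
        if any(m.sex == FEMALE for m in aff):
            raise LinkageError(
                f"family {self.ped.family_id}: affected female under a "
                "sex-limited male model"
            )
        if not aff:
            return np.ones(self.n_states)
        fcar = np.array([model.liability(m.liability_class).f_carrier for m in aff])
        fphe = np.array([model.liability(m.liability_class).f_phenocopy for m in aff])
        slot_arrays = np.stack(
            [self.mat_slot[m.individual_id] for m in aff])  # (n_aff, S)
        S = self.n_states
        if founder_mode == "segregating":
            eligible = self.segregating_slots()
            # mean over the carrier slot of prod_i f(class_i, carrier_i)
            out = np.zeros(S)
            for s in eligible:
                carrier = slot_arrays == s  # (n_aff, S)
                out += np.prod(np.where(carrier, fcar[:, None],
                                        fphe[:, None]), axis=0)
            return out / len(eligible)
        if founder_mode != "population":
            raise LinkageError(f"unknown founder mode {founder_mode!r}")
        out = np.empty(S)
        for v in range(S):
            per_slot: dict[int, list[int]] = {}
            for i in range(len(aff)):
                per_slot.setdefault(int(slot_arrays[i, v]), []).append(i)
            lik = 1.0
            for idxs in per_slot.values():
                pc = 1.0
                pp = 1.0
                for i in idxs:
                    pc *= fcar[i]
                    pp *= fphe[i]
                lik *= q * pc + (1.0 - q) * pp
            out[v] = lik
        return out

    def parametric_lod(self, posteriors: np.ndarray,
                       founder_mode: str = "population") -> np.ndarray:
        """Multipoint LOD curve from state posteriors at each position."""
        pl = self.phenotype_likelihoods(founder_mode)
        denom = pl.mean()  # uniform (unlinked) inheritance distribution
        num = posteriors @ pl
        return np.log10(num / denom)

    def segregating_slots(self) -> list[int]:
        """Founder slots eligible to carry a segregating risk allele.

        Structural rule, independent of the affection data: the X-haplotype
        slots of the founder woman whose X can reach the largest number of
        men in the pedigree (the matriline the mutation is assumed to enter
        through).  Falls back to all slots in pedigrees without founder
        women.
        """
        best: Optional[tuple[int, list[int]]] = None
        men_slots = [
            set(int(s) for s in np.unique(self.mat_slot[m.individual_id]))
            for m in self.ped.members if m.sex == MALE
        ]
        for f in self.ped.founders:
            if f.sex != FEMALE:
                continue
            slots = [
                s for s, owner in enumerate(self.slot_owner)
                if owner == f.individual_id
            ]
            n_reach = sum(1 for ms in men_slots if ms & set(slots))
            if best is None or n_reach > best[0]:
                best = (n_reach, slots)
        if best is None:
            return list(range(self.n_slots))
        return best[1]

    # -- ascertainment correction -----------------------------------------

    def _male_lifetime_risks(self) -> tuple[float, float]:
        """Carrier/non-carrier lifetime affection risk implied by the model.

        Coherent when the liability classes are parametrized as joint
        (affected & class) rates, so that they sum to the lifetime risk (see
        :func:`matched_penetrance_model`).
        """
        cls = self.model.classes.values()
        return (sum(c.f_carrier for c in cls), sum(c.f_phenocopy for c in cls))

    def ascertainment_prob(self, min_affected: int = 2,
                           founder_mode: str = "segregating"
                           ) -> tuple[float, float]:
        """P(>= min_affected affected men) under the linked and unlinked models.

        The linked probability averages over the carrier slot (as in
        ``founder_mode``) and the uniform inheritance distribution; men are
        then affected independently at the model's carrier / non-carrier
        lifetime risks (Poisson-binomial tail).
        """
        p_car, p_phe = self._male_lifetime_risks()
        men = [m for m in self.ped.members if m.sex == MALE]
        if not men:
            return 0.0, 0.0

        def tail(p_by_state: np.ndarray) -> np.ndarray:
            # Poisson-binomial P(#affected >= min_affected) per state;
            # p_by_state has shape (n_men, S)
            S = p_by_state.shape[1]
            counts = np.zeros((min_affected, S))  # P(exactly k so far), k < min
            counts[0] = 1.0
            passed = np.zeros(S)  # absorbing mass at >= min_affected
            for p in p_by_state:
                passed = passed + counts[min_affected - 1] * p
                for k in range(min_affected - 1, 0, -1):
                    counts[k] = counts[k] * (1 - p) + counts[k - 1] * p
                counts[0] = counts[0] * (1 - p)
            return passed

        # unlinked: everyone at the phenocopy rate
        p_u = np.full((len(men), 1), p_phe)
        asc_u = float(tail(p_u)[0])
        if self.n_slots == 0:
            return asc_u, asc_u
        vals = []
        for s in self.segregating_slots():
            carrier = np.stack([
                self.mat_slot[m.individual_id] == s for m in men
            ])  # (n_men, S)
            p = np.where(carrier, p_car, p_phe)
            vals.append(tail(p).mean())
        asc_l = float(np.mean(vals))
        return asc_l, asc_u

    def pheno_log10_lr(self, founder_mode: str = "segregating") -> float:
        """log10 LR of the full affection pattern: linked vs unlinked.

        This is the position-independent term a full-likelihood admixture
        analysis adds to each family's LOD curve; without it the admixture
        proportion is estimated from marker sharing alone and is biased
        upward whenever affection patterns correlate with linked status
        (which multiple-case ascertainment guarantees).  Pair it with
        :meth:`asc_log10_lr`, which enters the admixture likelihood as its
        own term and normalizes for the ascertainment.

        Unlike the affecteds-only LOD, this term needs a true density of the
        pattern, so men not recorded affected contribute survival factors
        ``1 - lifetime risk``: appropriate when non-affected men are known
        unaffected (as in simulated cohorts), an approximation when their
        status is censored.  Requires the joint-rate liability-class
        parametrization (see the lifetime-risk note on
        :meth:`ascertainment_prob`).
        """
        if founder_mode != "segregating":
            raise LinkageError(
                "phenotype LR is defined for the segregating founder mode")
        p_car, p_phe = self._male_lifetime_risks()
        men = [m for m in self.ped.members if m.sex == MALE]
        if not men:
            return 0.0

        def factors(carrier: np.ndarray, member) -> np.ndarray:
            lia = self.model.liability(member.liability_class)
            if member.is_affected:
                return np.where(carrier, lia.f_carrier, lia.f_phenocopy)
            return np.where(carrier, 1.0 - p_car, 1.0 - p_phe)

        p_u = 1.0
        for m in men:
            p_u *= float(factors(np.zeros(1, dtype=bool), m)[0])
        eligible = self.segregating_slots()
        acc = 0.0
        for s in eligible:
            prod = np.ones(self.n_states)
            for m in men:
                prod *= factors(self.mat_slot[m.individual_id] == s, m)
            acc += prod.mean()
        p_l = acc / len(eligible)
        if p_u == 0 or p_l == 0:
            raise LinkageError(
                f"family {self.ped.family_id}: zero-probability affection "
                "pattern; check the penetrance parametrization"
            )
        return math.log10(p_l) - math.log10(p_u)

    def asc_log10_lr(self, min_affected: int = 2,
                     founder_mode: str = "segregating") -> float:
        """log10 of P(ascertained | linked) / P(ascertained | unlinked)."""
        asc_l, asc_u = self.ascertainment_prob(min_affected, founder_mode)
        if asc_l == 0 or asc_u == 0:
            raise LinkageError(
                f"family {self.ped.family_id}: degenerate ascertainment "
                "probabilities; check the penetrance parametrization"
            )
        return math.log10(asc_l) - math.log10(asc_u)

    # -- allele sharing ---------------------------------------------------

    def sharing_scores(self, scorer: str = "all") -> np.ndarray:
        """Raw Whittemore–Halpern score S(v) per state over affected members."""
        aff = self.ped.affected
        allele_sets = [self.member_slots(m) for m in aff]  # per aff: 1-2 arrays
        S = self.n_states
        out = np.zeros(S)
        if len(aff) < 2:
            return out
        if scorer == "pairs":
            for i in range(len(aff)):
                for j in range(i + 1, len(aff)):
                    for a in allele_sets[i]:
                        for b in allele_sets[j]:
                            out += (a == b).astype(float)
            return out
        if scorer != "all":
            raise LinkageError(f"unknown scorer {scorer!r}")
        # S_all: average over one-allele-per-affected selections of the
        # product of factorials of founder-allele multiplicities
        from itertools import product as iproduct
        from math import factorial

        choices = list(iproduct(*[range(len(s)) for s in allele_sets]))
        for v in range(S):
            acc = 0.0
            for sel in choices:
                counts: dict[int, int] = {}
                for i, c in enumerate(sel):
                    slot = int(allele_sets[i][c][v])
                    counts[slot] = counts.get(slot, 0) + 1
                prod = 1
                for n in counts.values():
                    prod *= factorial(n)
                acc += prod
            out[v] = acc / len(choices)
        return out

    def sharing_z(self, posteriors: np.ndarray,
                  scorer: str = "all") -> tuple[np.ndarray, bool]:
        """Expected normalized sharing Z̄ at each position.

        Returns (curve, informative).  Families whose score has zero variance
        under the uniform inheritance distribution (e.g. a single affected)
        are flagged uninformative with a flat-zero curve.
        """
        s = self.sharing_scores(scorer)
        mu = s.mean()
        sd = s.std()
        if sd < 1e-12:
            return np.zeros(posteriors.shape[0]), False
        z = (s - mu) / sd
        return posteriors @ z, True


# ---------------------------------------------------------------------------
# batch driver


def compute_family_curves(
    peds: Sequence[Pedigree],
    site_maps: dict[str, ConsensusMap],
    freqs: dict,
    model: Optional[PenetranceModel] = None,
    positions: Optional[np.ndarray] = None,
    scorer: str = "all",
    founder_mode: str = "population",
    ascertainment_lr: bool = False,
) -> list[FamilyLodCurve]:
    """Per-family parametric LOD and Z̄ curves on a common position grid.

    ``positions`` defaults to the grid of the first site map (all site maps
    span the same interval once dummy anchors are in place).  With
    ``ascertainment_lr`` each curve also carries the position-independent
    phenotype log10 LR needed for full-likelihood admixture analyses of
    multiple-case-ascertained cohorts.
    """
    if positions is None:
        first = next(iter(site_maps.values()))
        positions = grid_positions(first)
    positions = np.asarray(positions, dtype=float)
    curves = []
    for ped in peds:
        smap = site_maps[ped.site_id]
        eng = FamilyEngine(ped, smap, freqs[ped.site_id], model)
        post = eng.posteriors(positions)
        lod = eng.parametric_lod(post, founder_mode)
        z, informative = eng.sharing_z(post, scorer)
        pheno = asc = 0.0
        if ascertainment_lr:
            pheno = eng.pheno_log10_lr(founder_mode=founder_mode)
            asc = eng.asc_log10_lr(founder_mode=founder_mode)
        curves.append(
            FamilyLodCurve(ped.family_id, ped.site_id, positions, lod, z,
                           informative, pheno, asc)
        )
    return curves


def curves_to_frame(curves: Sequence[FamilyLodCurve]):
    """Long-format DataFrame (site_id, family_id, position_cm, lod, z)."""
    import pandas as pd

    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "site_id": c.site_id,
            "family_id": c.family_id,
            "position_cm": c.positions,
            "parametric_lod": c.parametric_lod,
            "z_score": c.z_score,
        }))
    return pd.concat(frames, ignore_index=True)


def curves_from_frame(df) -> list[FamilyLodCurve]:
    out = []
    for (site, fam), g in df.groupby(["site_id", "family_id"], sort=False):
        g = g.sort_values("position_cm")
        z = g["z_score"].to_numpy()
        out.append(FamilyLodCurve(
            str(fam), str(site), g["position_cm"].to_numpy(),
            g["parametric_lod"].to_numpy(), z,
            informative=bool(np.any(z != 0.0)),
        ))
    return out
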