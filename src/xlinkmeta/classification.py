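"""Stratification of hereditary prostate-cancer families for subset analyses.

Families are labelled on four axes used to form analysis subsets:

* Carter criteria for hereditary prostate cancer — three consecutive
  affected generations along a line of descent, OR three affecteds within
  one first-degree cluster, OR two or more affecteds with onset <= 55 years.
* Consistency with X-linked transmission — male-to-male transmission
  (affected father-son pair, affected paternal uncle/grandfather, or a
  bilineal affected man) is incompatible with a purely X-linked risk
  allele; families whose affected men have exclusively maternal-side
  affected relatives are consistent; bare affected sibships with no
  informative side history are unclear.
* Mean onset age of affected men (< 65 vs >= 65).
* Number of confirmed affected men, binned 2-3 / 4-5 / 6+.

Side-of-family calls are structural: an affected relative is on a man's
maternal side if the relative (or one of the relative's ancestors) lies on
the mother's ancestor line, and on the paternal side via the father's line.
Relatives connecting to both lines — his own full sibship, descendants,
or a sibling's offspring — carry no side information and are ignored for
side evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .pedigree_io import MALE, Pedigree

MM_CONSISTENT = "consistent_x"
MM_UNCLEAR = "unclear"
MM_NOT_CONSISTENT = "not_consistent"

AFFECTED_BINS = ("2-3", "4-5", "6+")
MM_CLASSES = (MM_CONSISTENT, MM_UNCLEAR, MM_NOT_CONSISTENT)


@dataclass
class FamilyLabels:
    family_id: str
    site_id: str
    n_affected: int
    carter: bool
    mm_class: str
    mean_onset_lt65: Optional[bool]
    n_affected_bin: Optional[str]  # None for <2 affecteds (excluded families)


def _ancestors(ped: Pedigree, ind_id: str) -> set[str]:
    """All resolvable ancestors of an individual (exclusive)."""
    out: set[str] = set()
    stack = [ind_id]
    while stack:
        cur = ped.member(stack.pop())
        for p in (cur.father_id, cur.mother_id):
            if p is not None and p in ped and p not in out:
                out.add(p)
                stack.append(p)
    return out


def _sides_of_relative(ped: Pedigree, man_id: str, rel_id: str) -> set[str]:
    """Which of the man's parental ancestor lines the relative connects to.

    The maternal line is the mother plus her ancestors, the paternal line the
    father plus his.  A relative (taken with their own ancestors) touching
    only one line is on that side; touching both (full siblings, descendants,
    a sibling's offspring) is side-uninformative and yields both labels;
    touching neither (married-in relatives) yields none.
    """
    man = ped.member(man_id)
    if man.is_founder:
        return set()
    maternal_line = {man.mother_id} | _ancestors(ped, man.mother_id)
    paternal_line = {man.father_id} | _ancestors(ped, man.father_id)
    rel_closure = {rel_id} | _ancestors(ped, rel_id)
    sides = set()
    if rel_closure & maternal_line:
        sides.add("maternal")
    if rel_closure & paternal_line:
        sides.add("paternal")
    return sides


def _full_siblings(ped: Pedigree, a_id: str, b_id: str) -> bool:
    a, b = ped.member(a_id), ped.member(b_id)
    return (
        a.father_id is not None
        and a.father_id == b.father_id
        and a.mother_id == b.mother_id
    )


def _is_parent(ped: Pedigree, parent_id: str, child_id: str) -> bool:
    c = ped.member(child_id)
    return parent_id in (c.father_id, c.mother_id)


def _first_degree(ped: Pedigree, a_id: str, b_id: str) -> bool:
    return (
        _is_parent(ped, a_id, b_id)
        or _is_parent(ped, b_id, a_id)
        or _full_siblings(ped, a_id, b_id)
    )


def classify_carter(ped: Pedigree) -> bool:
    """Carter criteria for hereditary prostate cancer."""
    affected = [m for m in ped.affected]
    aff_ids = {m.individual_id for m in affected}

    # (a) three consecutive affected generations along a line of descent
    for top in affected:
        for child in ped.children_of(top.individual_id):
            if child.individual_id not in aff_ids:
                continue
            for grandchild in ped.children_of(child.individual_id):
                if grandchild.individual_id in aff_ids:
                    return True

    # (b) three affecteds within one first-degree cluster: some affected
    # individual with >=2 affected first-degree relatives
    for m in affected:
        n_fd = sum(
            1
            for r in affected
            if r.individual_id != m.individual_id
            and _first_degree(ped, m.individual_id, r.individual_id)
        )
        if n_fd >= 2:
            return True

    # (c) two or more affecteds with onset at or under 55
    n_early = sum(
        1 for m in affected if m.onset_age is not None and m.onset_age <= 55
    )
    return n_early >= 2


def classify_mm_transmission(ped: Pedigree) -> str:
    """Consistency of the affection pattern with X-linked transmission."""
    affected = [m for m in ped.affected if m.sex == MALE]
    aff_ids = {m.individual_id for m in affected}

    def affected_id(ind_id: Optional[str]) -> bool:
        return ind_id is not None and ind_id in aff_ids

    # explicit male-to-male triggers
    for m in affected:
        if affected_id(m.father_id):
            return MM_NOT_CONSISTENT  # affected father-son pair
        if m.father_id is not None and m.father_id in ped:
            father = ped.member(m.father_id)
            if affected_id(father.father_id):
                return MM_NOT_CONSISTENT  # affected paternal grandfather
            # paternal uncle: male sibling of the father (sharing >=1 parent)
            for u in ped.members:
                if (
                    u.sex == MALE
                    and u.individual_id != father.individual_id
                    and u.individual_id in aff_ids
                    and not u.is_founder
                    and (
                        (u.father_id is not None and u.father_id == father.father_id)
                        or (u.mother_id is not None and u.mother_id == father.mother_id)
                    )
                ):
                    return MM_NOT_CONSISTENT

    any_maternal = False
    any_paternal = False
    for m in affected:
        maternal_here = False
        paternal_here = False
        for r in affected:
            if r.individual_id == m.individual_id:
                continue
            if _full_siblings(ped, m.individual_id, r.individual_id):
                continue  # own sibship: uninformative
            sides = _sides_of_relative(ped, m.individual_id, r.individual_id)
            if sides == {"maternal"}:
                maternal_here = True
            elif sides == {"paternal"}:
                paternal_here = True
            # both sides (via a full sibling) or descendants: uninformative
        if maternal_here and paternal_here:
            return MM_NOT_CONSISTENT  # bilineal affected man
        any_maternal |= maternal_here
        any_paternal |= paternal_here

    if any_paternal:
        # paternal-side evidence short of the explicit triggers (e.g. an
        # affected paternal cousin): not exclusively maternal, not proof of
        # male-to-male transmission either
        return MM_UNCLEAR
    if any_maternal:
        return MM_CONSISTENT
    return MM_UNCLEAR


def mean_onset_flag(ped: Pedigree) -> Optional[bool]:
    """True if the mean recorded onset age of affected members is < 65 years."""
    ages = [m.onset_age for m in ped.affected if m.onset_age is not None]
    if not ages:
        return None
    return sum(ages) / len(ages) < 65


def affected_bin(n_affected: int) -> Optional[str]:
    if n_affected < 2:
        return None
    if n_affected <= 3:
        return "2-3"
    if n_affected <= 5:
        return "4-5"
    return "6+"


def label_family(ped: Pedigree) -> FamilyLabels:
    n_aff = len(ped.affected)
    return FamilyLabels(
        family_id=ped.family_id,
        site_id=ped.site_id,
        n_affected=n_aff,
        carter=classify_carter(ped),
        mm_class=classify_mm_transmission(ped),
        mean_onset_lt65=mean_onset_flag(ped),
        n_affected_bin=affected_bin(n_aff),
    )


def build_subsets(
    peds: list[Pedigree],
    exclude: Optional[set[str]] = None,
    subset_names: Optional[list[str]] = None,
) -> dict[str, list[str]]:
    """Build the named analysis subsets (family-id lists).

    Families with fewer than two confirmed affected men are dropped from every
    subset (the collection design requires multiple-case families).  An
    ``exclude`` set (e.g. families from a previously published report) is
    removed from all subsets.  ``subset_names`` optionally restricts the
    output; an unknown name raises ``KeyError``.
    """
    import warnings

    labels = [label_family(p) for p in peds]
    kept: list[FamilyLabels] = []
    for lab in labels:
        if lab.n_affected_bin is None:
            warnings.warn(
                f"family {lab.family_id} has {lab.n_affected} confirmed "
                "affected men (<2); excluded from analysis subsets"
            )
            continue
        if exclude and lab.family_id in exclude:
            continue
        kept.append(lab)

    subsets: dict[str, list[str]] = {"all": [l.family_id for l in kept]}
    for mm in MM_CLASSES:
        subsets[f"mm:{mm}"] = [l.family_id for l in kept if l.mm_class == mm]
    subsets["onset_lt65"] = [l.family_id for l in kept if l.mean_onset_lt65 is True]
    subsets["onset_ge65"] = [l.family_id for l in kept if l.mean_onset_lt65 is False]
    for b in AFFECTED_BINS:
        subsets[f"bin:{b}"] = [l.family_id for l in kept if l.n_affected_bin == b]
    for b in AFFECTED_BINS:
        for mm in MM_CLASSES:
            subsets[f"cell:{b}|{mm}"] = [
                l.family_id
                for l in kept
                if l.n_affected_bin == b and l.mm_class == mm
            ]
    subsets["carter"] = [l.family_id for l in kept if l.carter]
    subsets["carter_2-3"] = [
        l.family_id for l in kept if l.carter and l.n_affected_bin == "2-3"
    ]

    if subset_names is not None:
        missing = [n for n in subset_names if n not in subsets]
        if missing:
            raise KeyError(f"unknown subset name(s): {missing}")
        subsets = {n: subsets[n] for n in subset_names}
    return subsets


def labels_table(peds: list[Pedigree]):
    """Labels as a tidy DataFrame (the `classify` CLI output)."""
    import pandas as pd

    rows = []
    for p in peds:
        lab = label_family(p)
        rows.append(
            {
                "family_id": lab.family_id,
                "site_id": lab.site_id,
                "n_affected": lab.n_affected,
                "carter": int(lab.carter),
                "mm_class": lab.mm_class,
                "mean_onset_lt65": (
                    "" if lab.mean_onset_lt65 is None else int(lab.mean_onset_lt65)
                ),
                "bin": lab.n_affected_bin or "",
            }
        )
    return pd.DataFrame(rows)
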