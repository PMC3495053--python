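"""Reading, validation and writing of LINKAGE-style pedigree collections.

The on-disk format is the whitespace-delimited pre-makeped layout::

    family  id  father  mother  sex  liability  affection  a1 a2  a1 a2 ...

with one pair of allele columns per marker (``0 0`` = missing call) and
``0`` for an absent parent.  Sex is coded 1 = male, 2 = female; affection
2 = confirmed affected, 0/1 = unknown (the analysis is affecteds-only, so
no individual is ever stored as "unaffected").

X-chromosome conventions: a hemizygous male is written to file as a
homozygote (standard LINKAGE X coding) but stored internally as a single
allele, so downstream allele counting never double-counts male alleles.

Onset ages are not part of the LINKAGE layout; they travel in an optional
sidecar TSV (family_id, individual_id, onset_age) handled by the same
reader/writer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

MALE = "male"
FEMALE = "female"
AFFECTED = "affected"
UNKNOWN = "unknown"

MISSING = None  # missing genotype call


class PedigreeError(ValueError):
    """Structural problem in a pedigree file (unresolvable parent, bad row)."""


class GenotypeValidationError(ValueError):
    """Genotype violates X-chromosome coding rules (e.g. heterozygous male)."""


@dataclass
class Individual:
    individual_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: str
    affection: str = UNKNOWN
    onset_age: Optional[float] = None
    liability_class: int = 2
    # aligned with the pedigree's marker_list; each entry is None (missing),
    # a 1-tuple (male, hemizygous) or a sorted 2-tuple (female, unphased)
    genotypes: list = field(default_factory=list)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def is_affected(self) -> bool:
        return self.affection == AFFECTED


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual]
    site_id: str = "site0"
    marker_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}

    def member(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [m for m in self.members if not m.is_founder]

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.is_affected]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            m
            for m in self.members
            if individual_id in (m.father_id, m.mother_id)
        ]

    def graph(self) -> nx.DiGraph:
        """Parent -> child directed graph over resolvable ids."""
        g = nx.DiGraph()
        g.add_nodes_from(m.individual_id for m in self.members)
        for m in self.members:
            for p in (m.father_id, m.mother_id):
                if p is not None and p in self:
                    g.add_edge(p, m.individual_id)
        return g


@dataclass
class Violation:
    rule: str
    family_id: str
    individual_id: Optional[str]
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        who = f" individual {self.individual_id}" if self.individual_id else ""
        return f"[{self.rule}] family {self.family_id}{who}: {self.detail}"


def _parse_call(a: str, b: str, sex: str, marker_id: str, fam: str, ind: str):
    if a == "0" or b == "0":
        return MISSING
    if sex == MALE:
        if a != b:
            raise GenotypeValidationError(
                f"family {fam} individual {ind}: male heterozygous X call "
                f"{a}/{b} at marker {marker_id}"
            )
        return (a,)
    return tuple(sorted((a, b)))


def derive_liability_class(onset_age: Optional[float], cutoff: float = 65.0) -> int:
    """Age-based two-class assignment: class 1 if onset < cutoff, else class 2.

    Unknown onset falls in class 2 (the lower-penetrance-ratio, conservative
    stratum).
    """
    if onset_age is None:
        return 2
    return 1 if onset_age < cutoff else 2


def read_pedigrees(
    path,
    marker_list: Sequence[str],
    site_id: str = "site0",
    onset_path=None,
    liability_from_onset: bool = False,
) -> list[Pedigree]:
    """Read a pre-makeped pedigree file into validated :class:`Pedigree` objects.

    ``marker_list`` supplies the marker order (it comes from the map file, not
    the pedigree file).  ``onset_path`` optionally points at the onset-age
    sidecar TSV.  With ``liability_from_onset`` the liability column is
    ignored and re-derived from onset age (class 1 if onset < 65).
    """
    marker_list = list(marker_list)
    onsets: dict[tuple[str, str], float] = {}
    if onset_path is not None:
        for line in Path(onset_path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("family_id"):
                continue
            fam, ind, age = line.split("\t")
            onsets[(fam, ind)] = float(age)

    rows_by_family: dict[str, list[Individual]] = {}
    order: list[str] = []
    n_geno_cols = 2 * len(marker_list)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7 + n_geno_cols:
            raise PedigreeError(
                f"line {lineno}: expected {7 + n_geno_cols} columns "
                f"({len(marker_list)} markers), got {len(fields)}"
            )
        fam, ind, father, mother, sex_c, lia, aff = fields[:7]
        sex = {"1": MALE, "2": FEMALE}.get(sex_c)
        if sex is None:
            raise PedigreeError(f"line {lineno}: bad sex code {sex_c!r}")
        affection = AFFECTED if aff == "2" else UNKNOWN
        genos = []
        for k, marker_id in enumerate(marker_list):
            a, b = fields[7 + 2 * k], fields[8 + 2 * k]
            genos.append(_parse_call(a, b, sex, marker_id, fam, ind))
        onset = onsets.get((fam, ind))
        lia_class = (
            derive_liability_class(onset) if liability_from_onset else int(lia)
        )
        member = Individual(
            individual_id=ind,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=sex,
            affection=affection,
            onset_age=onset,
            liability_class=lia_class,
            genotypes=genos,
        )
        if fam not in rows_by_family:
            rows_by_family[fam] = []
            order.append(fam)
        rows_by_family[fam].append(member)

    peds = [
        Pedigree(family_id=fam, members=rows_by_family[fam], site_id=site_id,
                 marker_list=marker_list)
        for fam in order
    ]
    for ped in peds:
        violations = validate_pedigree(ped)
        structural = [v for v in violations if v.rule != "sex_limited"]
        if structural:
            raise PedigreeError("; ".join(str(v) for v in structural))
    return peds


def write_pedigrees(peds: Iterable[Pedigree], path, onset_path=None) -> None:
    """Write pedigrees back to the pre-makeped layout (and onset sidecar).

    All pedigrees must share one marker list; member order is preserved.
    """
    peds = list(peds)
    if peds:
        ref = peds[0].marker_list
        for ped in peds[1:]:
            if ped.marker_list != ref:
                raise PedigreeError(
                    f"family {ped.family_id} has a different marker list than "
                    f"family {peds[0].family_id}; cannot write one file"
                )
    lines = []
    onset_lines = ["family_id\tindividual_id\tonset_age"]
    for ped in peds:
        for m in ped.members:
            cols = [
                ped.family_id,
                m.individual_id,
                m.father_id or "0",
                m.mother_id or "0",
                "1" if m.sex == MALE else "2",
                str(m.liability_class),
                "2" if m.is_affected else "1",
            ]
            for call in m.genotypes:
                if call is MISSING:
                    cols += ["0", "0"]
                elif len(call) == 1:
                    cols += [call[0], call[0]]
                else:
                    cols += [call[0], call[1]]
            lines.append(" ".join(cols))
            if m.onset_age is not None:
                onset_lines.append(
                    f"{ped.family_id}\t{m.individual_id}\t{m.onset_age:g}"
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    if onset_path is not None:
        Path(onset_path).write_text("\n".join(onset_lines) + "\n")


def validate_pedigree(ped: Pedigree) -> list[Violation]:
    """Check structural and X-coding invariants; violations are data, not errors."""
    out: list[Violation] = []

    def add(rule, ind, detail):
        out.append(Violation(rule, ped.family_id, ind, detail))

    for m in ped.members:
        if (m.father_id is None) != (m.mother_id is None):
            add("parent_pair", m.individual_id,
                "exactly one parent recorded; need both or neither")
        for pid, want_sex, role in (
            (m.father_id, MALE, "father"),
            (m.mother_id, FEMALE, "mother"),
        ):
            if pid is None:
                continue
            if pid not in ped:
                add("parent_missing", m.individual_id,
                    f"{role} {pid} not a member of family {ped.family_id}")
            elif ped.member(pid).sex != want_sex:
                add("parent_sex", m.individual_id,
                    f"{role} {pid} recorded with sex={ped.member(pid).sex}")
        if m.sex == MALE:
            for marker_idx, call in enumerate(m.genotypes):
                if call is not MISSING and len(call) == 2 and call[0] != call[1]:
                    marker = (
                        ped.marker_list[marker_idx]
                        if marker_idx < len(ped.marker_list)
                        else f"#{marker_idx}"
                    )
                    add("male_het_x", m.individual_id,
                        f"heterozygous X call at {marker}")
        if m.is_affected and m.sex == FEMALE:
            add("sex_limited", m.individual_id,
                "affected female in a male-limited trait")
        if m.onset_age is not None and not m.is_affected:
            add("onset_without_affection", m.individual_id,
                "onset age recorded for a non-affected individual")
        if m.liability_class < 1:
            add("liability_class", m.individual_id,
                f"non-positive liability class {m.liability_class}")

    g = ped.graph()
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        add("cycle", cyc[0][0], f"ancestry cycle through {cyc[0][0]}")
    for m in ped.members:
        if m.father_id == m.individual_id or m.mother_id == m.individual_id:
            # covered by the DAG check unless the edge was dropped; be explicit
            if not any(v.rule == "cycle" for v in out):
                add("cycle", m.individual_id, "individual is its own parent")
    return out


def strip_genotypes(ped: Pedigree) -> Pedigree:
    """Copy of ``ped`` with every genotype call set missing (used by no-data nulls)."""
    members = [
        replace(m, genotypes=[MISSING] * len(m.genotypes)) for m in ped.members
    ]
    return Pedigree(ped.family_id, members, ped.site_id, list(ped.marker_list))
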