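"""Shared fixtures: hand-built pedigrees and small marker maps."""

from __future__ import annotations

import numpy as np
import pytest

from xlinkmeta.consensus_map import ConsensusMap, MarkerRecord
from xlinkmeta.pedigree_io import (AFFECTED, FEMALE, MALE, UNKNOWN,
                                   Individual, Pedigree)


def ind(iid, father=None, mother=None, sex=MALE, affected=False, onset=None,
        lia=None, genos=None):
    if lia is None:
        lia = 1 if (onset is not None and onset < 65) else 2
    return Individual(
        individual_id=iid, father_id=father, mother_id=mother, sex=sex,
        affection=AFFECTED if affected else UNKNOWN, onset_age=onset,
        liability_class=lia, genotypes=list(genos or []),
    )


def pad_genotypes(members, n_markers):
    for m in members:
        while len(m.genotypes) < n_markers:
            m.genotypes.append(None)
    return members


def family(fam_id, members, markers=(), site="site0"):
    return Pedigree(fam_id, pad_genotypes(members, len(markers)), site,
                    list(markers))


def small_map(cms, prefix="M"):
    """Evenly spread markers at the given cM positions (bp 1e6 apart)."""
    recs = [
        MarkerRecord(f"{prefix}{k + 1}", 10 ** 6 * (k + 1),
                     10 ** 6 * (k + 1) + 100, cm, cm, "decode")
        for k, cm in enumerate(cms)
    ]
    return ConsensusMap(recs)


@pytest.fixture
def brothers_informative():
    """Two affected brothers; mother het at both markers, father distinct."""
    markers = ["M1", "M2"]
    members = [
        ind("f", sex=MALE, genos=[("9",), ("9",)]),
        ind("m", sex=FEMALE, genos=[("1", "2"), ("1", "2")]),
        ind("s1", "f", "m", MALE, affected=True, onset=60,
            genos=[("1",), ("1",)]),
        ind("s2", "f", "m", MALE, affected=True, onset=62,
            genos=[("1",), ("1",)]),
    ]
    return family("famB", members, markers)


@pytest.fixture
def three_gen_family():
    """Maternal three-generation family: affected uncle and two nephews."""
    markers = ["M1", "M2"]
    members = [
        ind("gf", sex=MALE, genos=[("7",), ("7",)]),
        ind("gm", sex=FEMALE, genos=[("1", "2"), ("1", "2")]),
        ind("un", "gf", "gm", MALE, affected=True, onset=58,
            genos=[("1",), ("1",)]),
        ind("mo", "gf", "gm", FEMALE, genos=[("1", "7"), ("1", "7")]),
        ind("fa", sex=MALE, genos=[("9",), ("9",)]),
        ind("s1", "fa", "mo", MALE, affected=True, onset=61,
            genos=[("1",), ("1",)]),
        ind("s2", "fa", "mo", MALE, affected=True, onset=66,
            genos=[("1",), ("1",)]),
    ]
    return family("fam3G", members, markers)


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_923)
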