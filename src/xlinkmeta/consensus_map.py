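"""Consensus genetic map construction for the Xq27-28 marker panel.

Each contributing site genotyped its own marker subset, so a single shared
coordinate system is needed before per-family curves can be combined.
Markers are ordered by physical position (bp), carry their reference
genetic-map (deCode) position where one exists, and otherwise receive a
centimorgan position by linear interpolation in bp between the nearest
flanking reference-mapped markers.  Sites whose panel misses the first or
last consensus marker get a dummy, completely non-informative anchor marker
at the terminal position so that every site's analysis spans the identical
1-cM grid.

The bundled 40-marker Xq panel (bp from UCSC Goldenpath hg13, cM from the
deCode map) ships as package data; ``load_xq_map`` returns it with the
published positions as-is, while ``build_consensus_map`` recomputes the
interpolation from scratch.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np
import pandas as pd

DUMMY_ALLELE = "1"


class MapError(ValueError):
    pass


@dataclass
class MarkerRecord:
    marker_id: str
    bp_start: int
    bp_end: int
    decode_cm: Optional[float] = None
    cm: Optional[float] = None
    source: str = "decode"  # decode | interpolated | dummy
    gws: bool = True

    def __post_init__(self) -> None:
        if self.bp_start > self.bp_end:
            raise MapError(
                f"{self.marker_id}: bp_start {self.bp_start} > bp_end {self.bp_end}"
            )


@dataclass
class ConsensusMap:
    records: list[MarkerRecord]
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        bps = [r.bp_start for r in self.records]
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            # dummy anchors share terminal positions; tolerate equality there
            for r1, r2 in zip(self.records, self.records[1:]):
                if r2.bp_start < r1.bp_start:
                    raise MapError("records not sorted by bp_start")
        cms = [r.cm for r in self.records]
        if any(c is None for c in cms):
            raise MapError("finished map has records without cm")
        if any(c2 < c1 for c1, c2 in zip(cms, cms[1:])):
            raise MapError("cm positions decrease along the map")

    @property
    def marker_ids(self) -> list[str]:
        return [r.marker_id for r in self.records]

    @property
    def span(self) -> tuple[float, float]:
        return (self.records[0].cm, self.records[-1].cm)

    def record(self, marker_id: str) -> MarkerRecord:
        for r in self.records:
            if r.marker_id == marker_id:
                return r
        raise KeyError(marker_id)

    def subset(self, marker_ids: Iterable[str]) -> "ConsensusMap":
        wanted = set(marker_ids)
        recs = [r for r in self.records if r.marker_id in wanted]
        return ConsensusMap(recs, self.grid_step)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding: exact half rounds away from zero (as printed maps do)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def interpolate_cm(marker: MarkerRecord,
                   anchors: list[MarkerRecord]) -> float:
    """Linear bp -> cM interpolation between the flanking reference anchors.

    ``anchors`` must be reference-mapped records sorted by bp with
    non-decreasing cm.  A marker whose bp coincides with an anchor's gets that
    anchor's position.  Full precision is returned; round for display with
    :func:`round_half_up`.
    """
    usable = [a for a in anchors if a.decode_cm is not None]
    if len(usable) < 2:
        raise MapError("need at least two reference-mapped anchors")
    bp = marker.bp_start
    for a in usable:
        if a.bp_start == bp:
            return float(a.decode_cm)
    left = [a for a in usable if a.bp_start < bp]
    right = [a for a in usable if a.bp_start > bp]
    if not left or not right:
        raise MapError(
            f"{marker.marker_id}: bp {bp} outside anchor span; refusing to "
            "extrapolate"
        )
    lo, hi = left[-1], right[0]
    if hi.bp_start == lo.bp_start:
        raise MapError(f"degenerate anchors at bp {lo.bp_start}")
    frac = (bp - lo.bp_start) / (hi.bp_start - lo.bp_start)
    return float(lo.decode_cm) + frac * (float(hi.decode_cm) - float(lo.decode_cm))


def build_consensus_map(records: list[MarkerRecord],
                        grid_step: float = 1.0) -> ConsensusMap:
    """Order by bp, keep reference positions, interpolate the rest."""
    recs = sorted(records, key=lambda r: r.bp_start)
    anchors = [r for r in recs if r.decode_cm is not None]
    if len(anchors) < 2:
        raise MapError("need at least two reference-mapped markers")
    out = []
    for r in recs:
        if r.decode_cm is not None:
            out.append(replace(r, cm=float(r.decode_cm), source="decode"))
        else:
            out.append(replace(r, cm=interpolate_cm(r, anchors),
                               source="interpolated"))
    bad = [
        (a.marker_id, b.marker_id)
        for a, b in zip(out, out[1:])
        if b.cm < a.cm
    ]
    if bad:
        raise MapError(f"cm decreases after bp sort for pairs: {bad}")
    return ConsensusMap(out, grid_step)


def insert_dummy_anchors(
    cmap: ConsensusMap, site_panels: dict[str, set[str]]
) -> dict[str, ConsensusMap]:
    """Per-site maps, padding panels that miss either terminal marker.

    The dummy marker is single-allele (frequency 1, every call homozygous for
    :data:`DUMMY_ALLELE`), so it anchors the grid without contributing any
    linkage information.
    """
    known = set(cmap.marker_ids)
    first, last = cmap.records[0], cmap.records[-1]
    out: dict[str, ConsensusMap] = {}
    for site, panel in site_panels.items():
        if not panel:
            raise MapError(f"site {site}: empty marker panel")
        unknown = panel - known
        if unknown:
            raise MapError(f"site {site}: markers not on consensus map: {sorted(unknown)}")
        recs = [r for r in cmap.records if r.marker_id in panel]
        if recs[0].marker_id != first.marker_id:
            recs.insert(0, MarkerRecord(
                f"__dummy_left_{site}", first.bp_start, first.bp_start,
                None, first.cm, "dummy", gws=True))
        if recs[-1].marker_id != last.marker_id:
            recs.append(MarkerRecord(
                f"__dummy_right_{site}", last.bp_start, last.bp_start,
                None, last.cm, "dummy", gws=True))
        out[site] = ConsensusMap(recs, cmap.grid_step)
    return out


def grid_positions(cmap: ConsensusMap) -> np.ndarray:
    """Evaluation grid: step-points across the span plus every marker position."""
    lo, hi = cmap.span
    n_steps = int(np.floor((hi - lo) / cmap.grid_step + 1e-9)) + 1
    steps = lo + cmap.grid_step * np.arange(n_steps)
    pos = np.union1d(np.round(steps, 6), np.round([r.cm for r in cmap.records], 6))
    return pos


def read_marker_table(path) -> list[MarkerRecord]:
    """Read a marker TSV (marker_id, bp_start, bp_end, decode_cm[, gws])."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    recs = []
    for row in df.itertuples(index=False):
        decode = getattr(row, "decode_cm", None)
        decode = None if pd.isna(decode) else float(decode)
        gws = bool(int(getattr(row, "gws", 1)))
        recs.append(MarkerRecord(
            marker_id=row.marker_id, bp_start=int(row.bp_start),
            bp_end=int(row.bp_end), decode_cm=decode, gws=gws))
    return recs


def write_map(cmap: ConsensusMap, path) -> None:
    df = pd.DataFrame(
        {
            "marker_id": [r.marker_id for r in cmap.records],
            "bp_start": [r.bp_start for r in cmap.records],
            "bp_end": [r.bp_end for r in cmap.records],
            "decode_cm": [r.decode_cm for r in cmap.records],
            "cm": [round_half_up(r.cm) for r in cmap.records],
            "source": [r.source for r in cmap.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _bundled_table() -> pd.DataFrame:
    ref = importlib.resources.files("xlinkmeta.data").joinpath("xq_markers.tsv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def load_xq_table() -> pd.DataFrame:
    """The bundled Xq panel table, published cM positions included."""
    return _bundled_table()


def load_xq_map(gws_only: bool = True, grid_step: float = 1.0,
                as_published: bool = True) -> ConsensusMap:
    """The bundled Xq consensus map.

    With ``as_published`` the printed positions are used verbatim (one marker,
    DXS1232, was published with a position that straight bp interpolation does
    not reproduce; it is kept as printed).  Otherwise positions are rebuilt
    with :func:`build_consensus_map`.
    """
    df = _bundled_table()
    if gws_only:
        df = df[df["gws"] == 1]
    recs = []
    for row in df.itertuples(index=False):
        decode = None if pd.isna(row.decode_cm) else float(row.decode_cm)
        recs.append(MarkerRecord(
            marker_id=row.marker_id, bp_start=int(row.bp_start),
            bp_end=int(row.bp_end), decode_cm=decode, gws=bool(row.gws)))
    if not as_published:
        m = build_consensus_map(recs, grid_step)
        return m
    out = []
    for rec, row in zip(recs, df.itertuples(index=False)):
        cm = float(row.published_cm)
        src = "decode" if rec.decode_cm is not None else "interpolated"
        out.append(replace(rec, cm=cm, source=src))
    out.sort(key=lambda r: r.bp_start)
    return ConsensusMap(out, grid_step)
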