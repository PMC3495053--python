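"""End-to-end driver: simulate -> classify -> per-family linkage -> combine.

Deterministic given (config, seed): every output TSV carries a header line
naming the config hash and seed, and repeated runs produce byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classification, consensus_map, linkage_core, meta_analysis
from . import synthetic_cohort as sim
from .linkage_core import PenetranceModel

log = logging.getLogger("xlinkmeta")


@dataclass
class RunConfig:
    seed: int = 0
    n_families: int = 100
    linked_fraction: float = 0.5
    trait_cm: float = 134.0
    n_sites: int = 11
    missing_rate: float = 0.05
    grid_step: float = 1.0
    scorer: str = "all"
    delta_bound: float = 4.0
    risk_allele_freq: float = 0.003
    penetrances: dict = field(default_factory=lambda: {
        1: [0.90, 0.02], 2: [0.60, 0.07]})
    subsets: list = field(default_factory=list)  # empty = all named subsets
    exclusion_file: str | None = None
    out_dir: str = "xlinkmeta_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "penetrances" in raw:
            raw["penetrances"] = {
                int(k): list(v) for k, v in raw["penetrances"].items()}
        return cls(**raw)

    def model(self) -> PenetranceModel:
        return PenetranceModel(
            risk_allele_freq=self.risk_allele_freq,
            classes={
                k: linkage_core.LiabilityClass(*v)
                for k, v in self.penetrances.items()
            },
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # hash the analysis, not where it lands
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def render_table2(results: dict) -> pd.DataFrame:
    """3x3 grid of allele-sharing peaks: 'LOD (cM, n)' per bin x mm-class cell."""
    rows = []
    for b in classification.AFFECTED_BINS:
        row = {"n_affected": b}
        for mm in classification.MM_CLASSES:
            name = f"cell:{b}|{mm}"
            if name in results:
                k = results[name][1]
                row[mm] = (
                    f"{k.peak.value:.2f} ({k.peak.position_cm:g} cM, "
                    f"{k.peak.n_families})"
                )
            else:
                row[mm] = "—"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full pipeline; returns the in-memory result bundle."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# xlinkmeta run seed={cfg.seed} config={cfg.config_hash()}\n"
    logpath = out / "run_log.jsonl"
    events = []

    def event(stage, **kw):
        rec = {"stage": stage, "elapsed_s": round(time.time() - t0, 3), **kw}
        events.append(rec)
        log.info("%s %s", stage, kw)

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    # --- simulate ------------------------------------------------------
    try:
        cmap = consensus_map.load_xq_map(grid_step=cfg.grid_step)
        sim_cfg = sim.CohortSimConfig(
            n_families=cfg.n_families, linked_fraction=cfg.linked_fraction,
            model=cfg.model(), trait_cm=cfg.trait_cm, cmap=cmap,
            n_sites=cfg.n_sites, missing_rate=cfg.missing_rate, seed=cfg.seed,
        )
        families = sim.simulate_cohort(sim_cfg)
        panels = sim_cfg.site_panels  # panels actually used by the draw
        observed = sim.apply_site_observation(
            families, panels, cfg.missing_rate, seed=cfg.seed + 1)
        event("simulate", n_families=len(families),
              n_linked=sum(f.linked for f in families))
    except Exception as exc:
        fail("simulate", exc)

    # --- maps ----------------------------------------------------------
    try:
        site_maps = consensus_map.insert_dummy_anchors(cmap, panels)
        observed = sim.add_dummy_genotypes(observed, site_maps)
        positions = consensus_map.grid_positions(cmap)
        event("map", n_markers=len(cmap.records), n_positions=len(positions))
    except Exception as exc:
        fail("map", exc)

    # --- classify ------------------------------------------------------
    try:
        labels = classification.labels_table(observed)
        exclude = None
        if cfg.exclusion_file:
            exclude = {
                line.strip()
                for line in Path(cfg.exclusion_file).read_text().splitlines()
                if line.strip()
            }
        subsets = classification.build_subsets(
            observed, exclude=exclude,
            subset_names=cfg.subsets or None)
        event("classify", n_subsets=len(subsets))
    except Exception as exc:
        fail("classify", exc)

    # --- per-family linkage -------------------------------------------
    try:
        freqs = linkage_core.estimate_allele_freqs(observed)
        curves = linkage_core.compute_family_curves(
            observed, site_maps, freqs, cfg.model(), positions, cfg.scorer)
        event("linkage", n_curves=len(curves))
    except Exception as exc:
        fail("linkage", exc)

    # --- combine -------------------------------------------------------
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = meta_analysis.combine_subsets(
                curves, subsets, cfg.delta_bound)
        peaks = meta_analysis.peaks_frame(results)
        table2 = render_table2(results)
        event("combine", n_results=len(results))
    except Exception as exc:
        fail("combine", exc)

    # --- write ---------------------------------------------------------
    _write_tsv(labels, out / "labels.tsv", header)
    _write_tsv(linkage_core.curves_to_frame(curves),
               out / "family_curves.tsv", header)
    _write_tsv(peaks, out / "peak_summary.tsv", header)
    _write_tsv(table2, out / "table2.tsv", header)
    _write_tsv(sim.truth_frame(families), out / "truth.tsv", header)
    subset_rows = pd.DataFrame(
        [{"subset": n, "family_id": f} for n, fams in subsets.items()
         for f in fams])
    _write_tsv(subset_rows, out / "subsets.tsv", header)
    curve_rows = []
    for name, (h, k) in results.items():
        curve_rows.append(pd.DataFrame({
            "subset": name, "position_cm": h.positions, "hlod": h.hlod,
            "alpha": h.alpha_hat, "as_lod": k.as_lod, "delta": k.delta_hat,
        }))
    _write_tsv(pd.concat(curve_rows, ignore_index=True),
               out / "subset_curves.tsv", header)
    event("write", out_dir=str(out))
    with open(logpath, "w") as fh:
        for rec in events:
            fh.write(json.dumps(rec) + "\n")

    return {
        "families": families,
        "observed": observed,
        "labels": labels,
        "subsets": subsets,
        "curves": curves,
        "results": results,
        "peaks": peaks,
        "table2": table2,
    }
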