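"""Cross-site combination of per-family linkage curves.

Two one-parameter meta-statistics are maximized position-by-position over
the per-family curves of a subset:

* the heterogeneity LOD (admixture model): only a proportion ``alpha`` of
  families is linked, ``HLOD(x) = max_a sum_i log10(a*10^lod_i(x) + 1-a)``;
* the Kong–Cox allele-sharing LOD: a linear likelihood-ratio model in the
  per-family normalized sharing scores,
  ``LOD(x) = max_{d>=0} sum_i log10(1 + d*g_i*Zbar_i(x))`` with equal
  weights ``g_i = 1/sqrt(m)`` over the ``m`` informative families, ``d``
  kept inside the positivity region of every factor.

Both statistics are one-sided (the null parameter value 0 gives 0), so the
curves are non-negative.  Peaks are reported at grid resolution with ties
broken toward the smaller (centromere-proximal) position, and support
intervals as the widest contiguous span within ``drop`` LOD units of the
peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .linkage_core import FamilyLodCurve


class MetaError(ValueError):
    pass


@dataclass
class PeakSummary:
    position_cm: float
    value: float
    parameter: float  # alpha_hat or delta_hat at the peak
    n_families: int


@dataclass
class HlodCurve:
    subset_name: str
    positions: np.ndarray
    hlod: np.ndarray
    alpha_hat: np.ndarray
    peak: PeakSummary


@dataclass
class KongCoxCurve:
    subset_name: str
    positions: np.ndarray
    as_lod: np.ndarray
    delta_hat: np.ndarray
    peak: PeakSummary


def _maximize(neg_obj, lo: float, hi: float, coarse: int = 21
              ) -> tuple[float, float]:
    """Coarse grid then bounded scalar refinement; returns (argmax, max).

    Both meta-objectives are sums of logs of functions linear in the
    parameter, hence concave, so a bounded search bracketted by a light
    safety grid finds the global maximum.
    """
    if hi <= lo:
        return lo, -neg_obj(lo)
    xs = np.linspace(lo, hi, coarse)
    vals = np.array([-neg_obj(x) for x in xs])
    k = int(np.argmax(vals))
    a = xs[max(0, k - 1)]
    b = xs[min(len(xs) - 1, k + 1)]
    res = minimize_scalar(neg_obj, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-7})
    cands = [(xs[k], vals[k]), (float(res.x), -float(res.fun))]
    x, v = max(cands, key=lambda t: t[1])
    return x, v


def hlod(lods: Sequence[float]) -> tuple[float, float]:
    """Heterogeneity LOD and maximizing linked proportion at one position.

    Value at ``alpha = 0`` is 0 by construction, so the returned HLOD is
    non-negative; when no positive alpha improves on 0 the reported
    ``alpha_hat`` is 0.
    """
    lods = np.asarray(lods, dtype=float)
    if lods.size == 0:
        raise MetaError("empty family curve list")
    ratios = np.power(10.0, lods)

    def neg(a: float) -> float:
        return -float(np.sum(np.log10(a * ratios + (1.0 - a))))

    a_hat, val = _maximize(neg, 0.0, 1.0)
    if val <= 0.0:
        return 0.0, 0.0
    return val, a_hat


def kong_cox(zbars: Sequence[float], delta_bound: float = 4.0,
             informative: Optional[Sequence[bool]] = None
             ) -> tuple[float, float]:
    """Kong–Cox allele-sharing LOD and maximizing delta at one position.

    Families flagged uninformative (flat Z from zero sharing variance) are
    excluded from the weight count ``m``; with none informative the
    statistic is 0 with a warning.
    """
    z = np.asarray(zbars, dtype=float)
    if informative is not None:
        z = z[np.asarray(informative, dtype=bool)]
    m = z.size
    if m == 0:
        warnings.warn("no informative families for the sharing statistic")
        return 0.0, 0.0
    gamma = 1.0 / np.sqrt(m)
    gz = gamma * z
    neg_gz = gz[gz < 0]
    d_max = delta_bound
    if neg_gz.size:
        d_max = min(d_max, float((1.0 - 1e-9) / (-neg_gz).max()))
    if d_max <= 0:
        return 0.0, 0.0

    def neg(d: float) -> float:
        return -float(np.sum(np.log10(1.0 + d * gz)))

    d_hat, val = _maximize(neg, 0.0, d_max)
    if val <= 0.0:
        return 0.0, 0.0
    return val, d_hat


def hlod_full(lods: Sequence[float], pheno_lrs: Sequence[float],
              asc_log10_ratio: float) -> tuple[float, float]:
    """Full-likelihood admixture statistic for an ascertained cohort.

    The log-likelihood of the linked proportion ``a`` over ascertained
    families is::

        sum_i log10( a * 10^(lod_i + rho_i - gamma) + 1 - a )

    with ``rho_i`` each family's phenotype log10 LR and ``gamma`` the single
    design constant log10 of the ratio of marginal ascertainment
    probabilities (linked over unlinked) under the cohort's family-structure
    distribution.  Unlike the markers-only admixture LOD, its maximizer is a
    consistent estimator of the linked proportion under multiple-case
    ascertainment.
    """
    lods = np.asarray(lods, dtype=float)
    ratios = np.power(
        10.0, lods + np.asarray(pheno_lrs, dtype=float) - asc_log10_ratio)

    def neg(a: float) -> float:
        return -float(np.sum(np.log10(a * ratios + (1.0 - a))))

    a_hat, val = _maximize(neg, 0.0, 1.0)
    if val <= 0.0:
        return 0.0, 0.0
    return val, a_hat


def hlod_curve(curves: Sequence[FamilyLodCurve], subset_name: str = "all",
               asc_log10_ratio: Optional[float] = None) -> HlodCurve:
    """Admixture-model curve over a subset of family curves.

    Passing ``asc_log10_ratio`` (the cohort's ascertainment design constant)
    switches to the full-likelihood admixture of :func:`hlod_full`, using the
    position-independent phenotype LR carried by each curve; under
    multiple-case ascertainment only that form estimates the linked
    proportion consistently.
    """
    if not curves:
        raise MetaError(f"subset {subset_name}: no family curves")
    positions = curves[0].positions
    lod_mat = np.stack([c.parametric_lod for c in curves])
    vals = np.empty(len(positions))
    alphas = np.empty(len(positions))
    if asc_log10_ratio is not None:
        rho = [c.pheno_log10_lr for c in curves]
        for k in range(len(positions)):
            vals[k], alphas[k] = hlod_full(lod_mat[:, k], rho, asc_log10_ratio)
    else:
        for k in range(len(positions)):
            vals[k], alphas[k] = hlod(lod_mat[:, k])
    kp = _peak_index(vals)
    peak = PeakSummary(float(positions[kp]), float(vals[kp]),
                       float(alphas[kp]), len(curves))
    return HlodCurve(subset_name, positions, vals, alphas, peak)


def kong_cox_curve(curves: Sequence[FamilyLodCurve], subset_name: str = "all",
                   delta_bound: float = 4.0) -> KongCoxCurve:
    if not curves:
        raise MetaError(f"subset {subset_name}: no family curves")
    positions = curves[0].positions
    informative = [c.informative for c in curves]
    z_mat = np.stack([c.z_score for c in curves])
    vals = np.empty(len(positions))
    deltas = np.empty(len(positions))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k in range(len(positions)):
            vals[k], deltas[k] = kong_cox(z_mat[:, k], delta_bound, informative)
    n_inf = int(sum(informative))
    if n_inf == 0:
        warnings.warn(f"subset {subset_name}: all families uninformative "
                      "for allele sharing")
    kp = _peak_index(vals)
    peak = PeakSummary(float(positions[kp]), float(vals[kp]),
                       float(deltas[kp]), len(curves))
    return KongCoxCurve(subset_name, positions, vals, deltas, peak)


def _peak_index(vals: np.ndarray) -> int:
    # ties toward the centromere-proximal (smaller cM) position
    return int(np.argmax(vals))


def combine_subsets(
    curves: Sequence[FamilyLodCurve],
    subsets: dict[str, list[str]],
    delta_bound: float = 4.0,
) -> dict[str, tuple[HlodCurve, KongCoxCurve]]:
    """HLOD and Kong–Cox curves for every named family subset."""
    by_id = {c.family_id: c for c in curves}
    unknown = {
        fid for fams in subsets.values() for fid in fams if fid not in by_id
    }
    if unknown:
        raise MetaError(f"subsets reference unknown families: {sorted(unknown)}")
    out = {}
    for name, fam_ids in subsets.items():
        sub = [by_id[f] for f in fam_ids]
        if not sub:
            warnings.warn(f"subset {name} resolves to zero families; skipped")
            continue
        out[name] = (
            hlod_curve(sub, name),
            kong_cox_curve(sub, name, delta_bound),
        )
    return out


def support_interval(positions: np.ndarray, values: np.ndarray,
                     drop: float = 2.0) -> tuple[float, float]:
    """Widest contiguous span around the peak within ``drop`` units of it."""
    values = np.asarray(values, dtype=float)
    if np.allclose(values, values[0]):
        raise MetaError("flat curve: support interval undefined")
    kp = _peak_index(values)
    thr = values[kp] - drop
    lo = kp
    while lo > 0 and values[lo - 1] >= thr:
        lo -= 1
    hi = kp
    while hi < len(values) - 1 and values[hi + 1] >= thr:
        hi += 1
    return float(positions[lo]), float(positions[hi])


def peaks_frame(results: dict[str, tuple[HlodCurve, KongCoxCurve]]):
    """Peak-summary table (one row per subset)."""
    import pandas as pd

    rows = []
    for name, (h, k) in results.items():
        rows.append({
            "subset": name,
            "n_families": h.peak.n_families,
            "hlod": h.peak.value,
            "hlod_cm": h.peak.position_cm,
            "alpha": h.peak.parameter,
            "as_lod": k.peak.value,
            "as_lod_cm": k.peak.position_cm,
            "delta": k.peak.parameter,
        })
    return pd.DataFrame(rows)
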