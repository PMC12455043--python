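"""Extended haplotype homozygosity statistics: EHH, iHH, iHS and xpEHH.

EHH at distance x from a core site is the probability that two haplotypes
carrying the chosen core allele are identical at every site between the
core and x.  iHH is the area under the EHH decay curve against physical
position (no recombination map exists for the system, so bp substitutes
for genetic distance), truncated where EHH first drops below the cutoff
with linear interpolation to the crossing.  iHS is the log ratio of
ancestral to derived iHH, standardised within derived-allele-frequency
bins; xpEHH is the cross-population log ratio of pooled-allele iHH,
standardised genome-wide (negative values mean longer homozygosity in
population B).

The site-by-site decay loop is numba-compiled: founder-structured panels
can hold homozygosity tracts over hundreds of sites, which a Python loop
cannot traverse within the pipeline's runtime budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .model import HaplotypePanel, Window

logger = logging.getLogger("polyscan")

__all__ = [
    "EhhCurve",
    "ehh_curve",
    "integrated_ehh",
    "ihs_scan",
    "xpehh_scan",
    "window_mean_abs",
]


@njit(cache=True)
def _ehh_side_kernel(haps, positions, core, step, cutoff, max_gap, max_extend,
                     rows, out_ehh, out_pos):
    """Walk outward from ``core`` refining haplotype groups site by site.

    ``rows`` indexes the carrier haplotypes scored by this call; per-step
    work scales with the carrier count, so small allele classes with long
    homozygosity tracts stay cheap.  Groups are seeded with the core allele
    so identity always includes the core site.  Returns
    (steps_written, gap_aborted).
    """
    m = haps.shape[1]
    n = rows.shape[0]
    cap = out_pos.shape[0]
    g = np.empty(n, dtype=np.int64)
    for i in range(n):
        g[i] = haps[rows[i], core]
    mapping = np.full(2 * n + 2, -1, dtype=np.int64)
    keys = np.empty(n, dtype=np.int64)
    counts = np.zeros(n + 2, dtype=np.int64)
    denom = n * (n - 1) / 2.0

    pos_core = positions[core]
    prev_pos = pos_core
    j = core + step
    t = 0
    while 0 <= j < m and t < cap:
        d = positions[j] - prev_pos
        if d < 0:
            d = -d
        if d > max_gap:
            return t, True
        d = positions[j] - pos_core
        if d < 0:
            d = -d
        if d > max_extend:
            break
        # split groups by the allele at site j, with compact relabelling
        next_id = 0
        for i in range(n):
            keys[i] = 2 * g[i] + haps[rows[i], j]
        for i in range(n):
            if mapping[keys[i]] == -1:
                mapping[keys[i]] = next_id
                next_id += 1
            g[i] = mapping[keys[i]]
        for i in range(n):
            mapping[keys[i]] = -1
        for q in range(next_id):
            counts[q] = 0
        for i in range(n):
            counts[g[i]] += 1
        hom = 0.0
        for q in range(next_id):
            hom += counts[q] * (counts[q] - 1) / 2.0
        e = hom / denom if denom > 0 else 0.0
        out_ehh[0, t] = e
        out_pos[t] = positions[j]
        prev_pos = positions[j]
        t += 1
        if e < cutoff:
            break
        j += step
    return t, False


@njit(cache=True)
def _side_area_kernel(haps, positions, core, step, cutoff, max_gap, max_extend, rows):
    """Truncated trapezoid area of one EHH decay side, integrated on the fly.

    Returns (area, gap_aborted); the final segment is linearly interpolated
    to the cutoff crossing.
    """
    m = haps.shape[1]
    n = rows.shape[0]
    g = np.empty(n, dtype=np.int64)
    for i in range(n):
        g[i] = haps[rows[i], core]
    mapping = np.full(2 * n + 2, -1, dtype=np.int64)
    keys = np.empty(n, dtype=np.int64)
    counts = np.zeros(n + 2, dtype=np.int64)
    denom = n * (n - 1) / 2.0

    pos_core = positions[core]
    prev_pos = pos_core
    prev_e = 1.0
    area = 0.0
    j = core + step
    while 0 <= j < m:
        d = positions[j] - prev_pos
        if d < 0:
            d = -d
        if d > max_gap:
            return area, True
        dc = positions[j] - pos_core
        if dc < 0:
            dc = -dc
        if dc > max_extend:
            break
        next_id = 0
        for i in range(n):
            keys[i] = 2 * g[i] + haps[rows[i], j]
        for i in range(n):
            if mapping[keys[i]] == -1:
                mapping[keys[i]] = next_id
                next_id += 1
            g[i] = mapping[keys[i]]
        for i in range(n):
            mapping[keys[i]] = -1
        for q in range(next_id):
            counts[q] = 0
        for i in range(n):
            counts[g[i]] += 1
        hom = 0.0
        for q in range(next_id):
            hom += counts[q] * (counts[q] - 1) / 2.0
        e = hom / denom if denom > 0 else 0.0
        prev_d = prev_pos - pos_core
        if prev_d < 0:
            prev_d = -prev_d
        if e < cutoff:
            # interpolate to the crossing and stop
            xc = prev_d + (prev_e - cutoff) * (dc - prev_d) / (prev_e - e)
            area += 0.5 * (prev_e + cutoff) * (xc - prev_d)
            return area, False
        area += 0.5 * (prev_e + e) * (dc - prev_d)
        prev_pos = positions[j]
        prev_e = e
        j += step
    return area, False


@njit(cache=True)
def _ihs_kernel(haps, positions, cores, derived_state, cutoff, max_gap, max_extend, out):
    """iHH_A / iHH_D for every core; out[idx] = (ihh_anc, ihh_der, valid)."""
    n = haps.shape[0]
    rows_a = np.empty(n, dtype=np.int64)
    rows_d = np.empty(n, dtype=np.int64)
    for idx in range(cores.shape[0]):
        core = cores[idx]
        na = nd = 0
        for i in range(n):
            if haps[i, core] == derived_state[idx]:
                rows_d[nd] = i
                nd += 1
            else:
                rows_a[na] = i
                na += 1
        out[idx, 2] = 0.0
        if na < 2 or nd < 2:
            continue
        ok = True
        for c in range(2):
            rows = rows_a[:na] if c == 0 else rows_d[:nd]
            total = 0.0
            for step in (-1, 1):
                area, aborted = _side_area_kernel(haps, positions, core, step,
                                                 cutoff, max_gap, max_extend, rows)
                if aborted:
                    ok = False
                    break
                total += area
            if not ok:
                break
            out[idx, c] = total
        out[idx, 2] = 1.0 if ok else 0.0


@njit(cache=True)
def _pooled_ihh_kernel(haps, positions, cutoff, max_gap, max_extend, out):
    """Pooled-allele iHH at every site; out[j] = (ihh, valid)."""
    n, m = haps.shape
    rows = np.arange(n)
    for j in range(m):
        total = 0.0
        ok = True
        for step in (-1, 1):
            area, aborted = _side_area_kernel(haps, positions, j, step,
                                              cutoff, max_gap, max_extend, rows)
            if aborted:
                ok = False
                break
            total += area
        out[j, 0] = total
        out[j, 1] = 1.0 if ok else 0.0


@dataclass
class EhhCurve:
    """EHH decay on one side of a core site (core point included)."""

    core_pos: int
    direction: str  # 'left' | 'right'
    allele: str     # 'anc' | 'der' | 'pooled'
    positions: np.ndarray
    ehh: np.ndarray
    gap_aborted: bool = False


def _side_caps(positions: np.ndarray, core: int, max_extend: int) -> tuple[int, int]:
    lo = int(np.searchsorted(positions, positions[core] - max_extend, side="left"))
    hi = int(np.searchsorted(positions, positions[core] + max_extend, side="right"))
    return core - lo, hi - core - 1


class _Scratch:
    """Reusable kernel output buffers; avoids per-core allocation churn."""

    def __init__(self, cap: int):
        self.ehh = np.empty((1, max(cap, 1)))
        self.pos = np.empty(max(cap, 1), dtype=np.int64)


def _ehh_sides(panel: HaplotypePanel, core: int, rows: np.ndarray,
               cutoff: float, max_gap: int, max_extend: int):
    """Run the kernel on both sides for one carrier set."""
    H, P = panel.haplotypes, panel.positions
    cap_l, cap_r = _side_caps(P, core, max_extend)
    out = {}
    for direction, step, cap in (("left", -1, cap_l), ("right", 1, cap_r)):
        buf = _Scratch(cap)
        t, aborted = _ehh_side_kernel(H, P, core, step, cutoff, max_gap, max_extend,
                                      rows, buf.ehh, buf.pos)
        out[direction] = (buf.pos[:t].copy(), buf.ehh[0, :t].copy(), aborted)
    return out


def ehh_curve(panel: HaplotypePanel, core: int, allele: str, side: str,
              cutoff: float = 0.05, max_gap: int = 200_000,
              max_extend: int = 500_000) -> EhhCurve | None:
    """EHH decay curve for one core site, allele class and side.

    ``allele`` is 'anc', 'der' (conditioned on carriers of the ancestral /
    derived allele) or 'pooled' (all haplotypes).  Returns None when the
    chosen class has fewer than two carrier haplotypes.
    """
    alleles = panel.haplotypes[:, core]
    derived_state = 1 if panel.ancestral_is_ref[core] else 0
    if allele == "der":
        mask = alleles == derived_state
    elif allele == "anc":
        mask = alleles != derived_state
    elif allele == "pooled":
        mask = np.ones(alleles.size, dtype=bool)
    else:
        raise ValueError("allele must be 'anc', 'der' or 'pooled'")
    if mask.sum() < 2:
        return None
    rows = np.nonzero(mask)[0].astype(np.int64)
    sides = _ehh_sides(panel, core, rows, cutoff, max_gap, max_extend)
    pos, ehh, aborted = sides[side]
    core_pos = int(panel.positions[core])
    return EhhCurve(core_pos, side, allele,
                    np.concatenate(([core_pos], pos)),
                    np.concatenate(([1.0], ehh)), aborted)


def _area_one_side(positions: np.ndarray, ehh: np.ndarray, core_pos: int,
                   cutoff: float) -> float:
    """Trapezoid area of one truncated decay curve (core point included)."""
    dist = np.abs(positions.astype(float) - core_pos)
    below = np.nonzero(ehh < cutoff)[0]
    if below.size:
        i = int(below[0])  # first point under the cutoff; interpolate to crossing
        if i == 0:
            return 0.0
        d0, d1 = dist[i - 1], dist[i]
        e0, e1 = ehh[i - 1], ehh[i]
        xc = d0 + (e0 - cutoff) * (d1 - d0) / (e0 - e1)
        area = np.trapezoid(ehh[:i], dist[:i])
        area += 0.5 * (e0 + cutoff) * (xc - d0)
        return float(area)
    return float(np.trapezoid(ehh, dist))


def integrated_ehh(left: EhhCurve | None, right: EhhCurve | None,
                   cutoff: float = 0.05) -> float:
    """iHH in bp: summed truncated areas of the left and right curves."""
    total = 0.0
    for curve in (left, right):
        if curve is None or curve.positions.size == 0:
            continue
        total += _area_one_side(curve.positions, curve.ehh, curve.core_pos, cutoff)
    return total


# ---------------------------------------------------------------------------
# scans


def _as_panel_dict(panels) -> dict[str, HaplotypePanel]:
    if isinstance(panels, HaplotypePanel):
        return {panels.chrom: panels}
    return dict(panels)


def _apply_polarisation(panel: HaplotypePanel, ancestral: str) -> HaplotypePanel:
    if ancestral == "major":
        panel.ancestral_is_ref = panel.alt_frequencies() <= 0.5
    return panel


def ihs_scan(panels, maf_min: float = 0.05, bins: int = 20, cutoff: float = 0.05,
             max_gap: int = 200_000, max_extend: int = 500_000,
             ancestral: str = "reference", standardize: bool = True) -> pd.DataFrame:
    """Integrated haplotype score at every core with derived frequency in
    [maf_min, 1 - maf_min], standardised within derived-frequency bins.

    Returns one row per scored core: chrom, pos, daf, ihh_a, ihh_d,
    ihs_unstd, bin, ihs (NaN where unscorable).
    """
    frames = []
    for chrom, panel in _as_panel_dict(panels).items():
        panel = _apply_polarisation(panel, ancestral)
        daf = panel.derived_frequencies()
        cores = np.nonzero((daf >= maf_min) & (daf <= 1 - maf_min))[0].astype(np.int64)
        derived_state = np.where(panel.ancestral_is_ref, 1, 0).astype(np.int8)[cores]
        out = np.zeros((cores.size, 3))
        _ihs_kernel(panel.haplotypes, panel.positions, cores, derived_state,
                    cutoff, max_gap, max_extend, out)
        keep = (out[:, 2] > 0) & (out[:, 0] > 0) & (out[:, 1] > 0)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": panel.positions[cores[keep]],
            "daf": daf[cores[keep]],
            "ihh_a": out[keep, 0],
            "ihh_d": out[keep, 1],
            "ihs_unstd": np.log(out[keep, 0] / out[keep, 1]),
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "daf", "ihh_a", "ihh_d", "ihs_unstd"])
    if standardize:
        df = _standardize_ihs(df, maf_min, bins)
    return df


def _standardize_ihs(df: pd.DataFrame, maf_min: float, bins: int) -> pd.DataFrame:
    df = df.copy()
    edges = np.linspace(maf_min, 1 - maf_min, bins + 1)
    df["bin"] = np.clip(np.searchsorted(edges, df["daf"], side="right") - 1, 0, bins - 1)
    df["ihs"] = np.nan
    for b, grp in df.groupby("bin"):
        if len(grp) < 2 or grp["ihs_unstd"].std(ddof=1) == 0:
            logger.warning("iHS bin %d has <2 usable sites; scores nulled", b)
            continue
        df.loc[grp.index, "ihs"] = (
            (grp["ihs_unstd"] - grp["ihs_unstd"].mean()) / grp["ihs_unstd"].std(ddof=1)
        )
    return df


def xpehh_scan(panels_a, panels_b, cutoff: float = 0.05, max_gap: int = 200_000,
               max_extend: int = 500_000, standardize: bool = True) -> pd.DataFrame:
    """Cross-population EHH score on a shared site grid.

    Uses pooled-allele EHH per population; xpehh_unstd = ln(iHH_A / iHH_B),
    standardised by the genome-wide mean and s.d.  Negative scores mean
    longer haplotype homozygosity in population B.
    """
    panels_a = _as_panel_dict(panels_a)
    panels_b = _as_panel_dict(panels_b)
    frames = []
    for chrom in panels_a:
        pa, pb = panels_a[chrom], panels_b[chrom]
        if not np.array_equal(pa.positions, pb.positions):
            raise ValueError(f"panels disagree on the site grid of {chrom}")
        out_a = np.zeros((pa.n_sites, 2))
        out_b = np.zeros((pb.n_sites, 2))
        _pooled_ihh_kernel(pa.haplotypes, pa.positions, cutoff, max_gap, max_extend, out_a)
        _pooled_ihh_kernel(pb.haplotypes, pb.positions, cutoff, max_gap, max_extend, out_b)
        keep = (out_a[:, 1] > 0) & (out_b[:, 1] > 0) & (out_a[:, 0] > 0) & (out_b[:, 0] > 0)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pa.positions[keep],
            "ihh_pop_a": out_a[keep, 0],
            "ihh_pop_b": out_b[keep, 0],
            "xpehh_unstd": np.log(out_a[keep, 0] / out_b[keep, 0]),
        }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "ihh_pop_a", "ihh_pop_b", "xpehh_unstd"])
    if standardize:
        mu = df["xpehh_unstd"].mean()
        sd = df["xpehh_unstd"].std(ddof=1)
        df["xpehh"] = (df["xpehh_unstd"] - mu) / sd if sd > 0 else np.nan
    return df


def window_mean_abs(scores: pd.DataFrame, windows: list[Window],
                    column: str) -> np.ndarray:
    """Mean |score| per window; NaN for windows without scored sites."""
    out = np.full(len(windows), np.nan)
    by_chrom = {c: g.sort_values("pos") for c, g in scores.groupby("chrom")}
    for i, w in enumerate(windows):
        g = by_chrom.get(w.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lo, hi = np.searchsorted(pos, [w.start, w.end])
        vals = g[column].to_numpy()[lo:hi]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[i] = np.abs(vals).mean()
    return out
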