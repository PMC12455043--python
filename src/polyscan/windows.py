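"""Sliding-window diversity and differentiation statistics.

Implements per-window nucleotide diversity (pi) for each population,
absolute divergence (dXY), Hudson-style window FST (1 - pi_within /
pi_between), Tajima's D, and the per-site Weir & Cockerham (1984) theta used
by the per-locus scans.  Denominators are accessible-site counts, i.e.
genotyped positions including monomorphic ones, as supplied by an
accessibility mask; windows with too few accessible sites are nulled (NaN)
rather than zeroed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ScanConfig
from .model import GenomeLayout, HaplotypePanel, Window

__all__ = [
    "make_windows",
    "window_diversity",
    "wc_fst_site",
    "tajima_coefficients",
    "tajimas_d",
    "compute_window_stats",
]


def make_windows(layout: GenomeLayout, size: int = 50_000, step: int = 25_000) -> list[Window]:
    """Sliding windows from position 0, advancing by ``step``.

    Windows are truncated at the chromosome end; a truncated window is kept
    only while more than one step of sequence remains (the leading window is
    always emitted, so short chromosomes yield a single short window).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if step > size:
        raise ValueError("step must not exceed window size")
    windows: list[Window] = []
    for chrom, length in layout.items():
        start = 0
        while start < length:
            if start > 0 and length - start <= step:
                break
            windows.append(Window(chrom, start, min(start + size, length)))
            start += step
    return windows


# ---------------------------------------------------------------------------
# per-site building blocks


def _unbiased_het(p: np.ndarray, n: int) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 p(1-p) n/(n-1) from n haplotypes."""
    return 2.0 * p * (1.0 - p) * n / (n - 1)


def window_diversity(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    window: Window,
) -> tuple[float, float, float, float]:
    """pi_A, pi_B, dXY and Hudson FST for one window.

    ``window.n_accessible`` must already be set; it is the denominator for
    all per-site rates.  FST is null (NaN) when dXY is zero.
    """
    if window.n_accessible <= 0:
        return (np.nan, np.nan, np.nan, np.nan)
    sl = panel_a.site_slice(window.start, window.end)
    pa = panel_a.haplotypes[:, sl].mean(axis=0)
    pb = panel_b.haplotypes[:, sl].mean(axis=0)
    na, nb = panel_a.n_haplotypes, panel_b.n_haplotypes
    acc = window.n_accessible
    pi_a = float(_unbiased_het(pa, na).sum() / acc)
    pi_b = float(_unbiased_het(pb, nb).sum() / acc)
    dxy = float((pa * (1 - pb) + pb * (1 - pa)).sum() / acc)
    fst = np.nan if dxy == 0 else 1.0 - 0.5 * (pi_a + pi_b) / dxy
    return pi_a, pi_b, dxy, fst


def wc_fst_site(genotypes_by_pop: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) theta at one biallelic site.

    ``genotypes_by_pop`` holds one (n_i, 2) array of allele indices per
    population, with -1 marking missing alleles; individuals with any
    missing allele are excluded (pairwise-available treatment).  Returns
    theta = a / (a + b + c) from the among-population (a), among-individual
    (b) and within-individual (c) variance components; NaN when undefined.
    """
    n_i, p_i, h_i = [], [], []
    for g in genotypes_by_pop:
        g = np.asarray(g)
        ok = np.all(g >= 0, axis=1)
        g = g[ok]
        if g.shape[0] == 0:
            continue
        n_i.append(g.shape[0])
        p_i.append(g.mean())
        h_i.append(np.mean(g[:, 0] != g[:, 1]))
    r = len(n_i)
    if r < 2:
        return np.nan
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)

    nbar = n_i.mean()
    if nbar <= 1:
        return np.nan
    n_total = n_i.sum()
    nc = (n_total - (n_i**2).sum() / n_total) / (r - 1)
    pbar = (n_i * p_i).sum() / n_total
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / n_total

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    if denom == 0:
        return np.nan
    return float(a / denom)


def tajima_coefficients(n: int) -> dict[str, float]:
    """Constants of Tajima's variance formula for ``n`` haplotypes."""
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(panel: HaplotypePanel, window: Window) -> float:
    """Tajima's D in one window; NaN when there are no segregating sites."""
    n = panel.n_haplotypes
    coef = tajima_coefficients(n)
    sl = panel.site_slice(window.start, window.end)
    p = panel.haplotypes[:, sl].mean(axis=0)
    seg = (p > 0) & (p < 1)
    S = int(seg.sum())
    if S == 0:
        return np.nan
    pi_total = float(_unbiased_het(p[seg], n).sum())
    var = coef["e1"] * S + coef["e2"] * S * (S - 1)
    return (pi_total - S / coef["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# whole-genome driver


def _mask_overlap(mask: np.ndarray, start: int, end: int) -> int:
    """Total overlap of [start, end) with a (k, 2) interval array."""
    if mask.size == 0:
        return 0
    lo = np.maximum(mask[:, 0], start)
    hi = np.minimum(mask[:, 1], end)
    return int(np.maximum(hi - lo, 0).sum())


def compute_window_stats(
    panels_a: dict[str, HaplotypePanel],
    panels_b: dict[str, HaplotypePanel],
    layout: GenomeLayout,
    config: ScanConfig | None = None,
    accessible: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Window table of pi_A, pi_B, dXY, Hudson FST and Tajima's D.

    ``accessible`` maps chromosome -> (k, 2) array of accessible intervals;
    when omitted, every VCF position (including monomorphic records, had any
    been loaded) counts, i.e. the union of panel positions.
    """
    config = config or ScanConfig()
    windows = make_windows(layout, config.window_size, config.window_step)
    rows = []
    for chrom in layout.names:
        pa = panels_a.get(chrom)
        pb = panels_b.get(chrom)
        chrom_windows = [w for w in windows if w.chrom == chrom]
        taj_panel = pb if config.tajima_pop == "popB" else pa
        for w in chrom_windows:
            if accessible is not None and chrom in accessible:
                n_acc = _mask_overlap(accessible[chrom], w.start, w.end)
            elif pa is not None:
                n_acc = int(pa.site_slice(w.start, w.end).stop - pa.site_slice(w.start, w.end).start)
            else:
                n_acc = 0
            if pa is None or pb is None:
                n_var = 0
            else:
                sl = pa.site_slice(w.start, w.end)
                p_all = np.concatenate([pa.haplotypes[:, sl], pb.haplotypes[:, sl]]).mean(axis=0)
                n_var = int(((p_all > 0) & (p_all < 1)).sum())
            w = Window(w.chrom, w.start, w.end, n_accessible=n_acc, n_variant=max(n_var, 0))
            min_acc = config.min_accessible_fraction * (w.end - w.start)
            if pa is None or pb is None or w.n_accessible < min_acc:
                rows.append((w.chrom, w.start, w.end, w.n_accessible, w.n_variant,
                             np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            pi_a, pi_b, dxy, fst = window_diversity(pa, pb, w)
            taj = tajimas_d(taj_panel, w)
            rows.append((w.chrom, w.start, w.end, w.n_accessible, w.n_variant,
                         pi_a, pi_b, dxy, fst, taj))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_accessible", "n_variant",
                 "pi_A", "pi_B", "dxy", "fst_hudson", "tajima_d"],
    )
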