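"""Gene-proximity annotation, enrichment, fixed differences and summaries.

Outlier features (DCMS regions, SV and STR loci) are related to
protein-coding genes with the proximity rule — a hit is any >= 1 bp overlap
with the gene span extended by 8 kb (half the mean intergenic distance)
on both sides.  A permutation test re-places each feature uniformly on its
own chromosome (length preserved) to ask whether outliers sit near genes
more or less often than chance given their lengths.  Fixed inter-population
SNP differences are located against gene models and classified as
synonymous / missense / nonsense / non-coding from the reference codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import CandidateGeneList, GeneModel, GenomeLayout, GenotypeMatrix

logger = logging.getLogger("polyscan")

__all__ = [
    "gene_proximity",
    "PermutationResult",
    "permutation_enrichment",
    "fixed_differences",
    "classify_coding_effect",
    "str_cds_density",
    "crossref_candidates",
    "summary_compare",
    "genotype_pca",
    "outlier_exclusivity",
]


def gene_proximity(features: pd.DataFrame, genes: list[GeneModel],
                   distance: int = 8_000) -> pd.DataFrame:
    """Features within ``distance`` bp of a gene (>= 1 bp overlap rule).

    ``features`` needs columns feature_id, chrom, start, end (points are
    1 bp intervals); a ``kind`` column is carried through when present.
    The returned table has one row per (feature, gene) hit with the gap
    distance (0 when the feature overlaps the gene body).
    """
    rows = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for f in features.itertuples(index=False):
        for g in by_chrom.get(f.chrom, []):
            if f.end <= g.start - distance or f.start >= g.end + distance:
                continue
            gap = max(0, g.start - f.end, f.start - g.end)
            rows.append((f.feature_id, getattr(f, "kind", "feature"), g.gene_id, gap,
                         "overlaps_gene" if gap == 0 else "within_8kb"))
    return pd.DataFrame(rows, columns=["feature_id", "kind", "gene_id", "distance", "relation"])


def _merged_extended_genes(genes: list[GeneModel], distance: int) -> dict[str, np.ndarray]:
    """Per chromosome, merged sorted (start, end) of gene spans +- distance."""
    out = {}
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((max(0, g.start - distance), g.end + distance))
    for chrom, iv in by_chrom.items():
        iv.sort()
        merged = [list(iv[0])]
        for s, e in iv[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.array(merged, dtype=np.int64)
    return out


def _count_hits(starts: np.ndarray, ends: np.ndarray, merged: np.ndarray) -> int:
    """Features with >= 1 bp overlap against merged disjoint intervals."""
    if merged.size == 0:
        return 0
    idx = np.searchsorted(merged[:, 1], starts, side="right")
    ok = idx < merged.shape[0]
    hits = np.zeros(starts.size, dtype=bool)
    hits[ok] = merged[idx[ok], 0] < ends[ok]
    return int(hits.sum())


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p: float
    seed: int


def permutation_enrichment(features: pd.DataFrame, genes: list[GeneModel],
                           layout: GenomeLayout, n_perm: int = 1_000,
                           distance: int = 8_000, seed: int = 0) -> PermutationResult:
    """Two-sided permutation test of gene proximity.

    Each permutation re-places every feature uniformly at random on its own
    chromosome, preserving its length; the statistic is the number of
    features with at least one gene within ``distance``.
    p = 2 * min(P(null >= obs), P(null <= obs)) with add-one correction.
    """
    if len(features) == 0:
        raise ValueError("feature set is empty")
    merged = _merged_extended_genes(genes, distance)
    rng = np.random.default_rng(seed)
    obs = 0
    per_chrom: dict[str, list[int]] = {}
    for f in features.itertuples(index=False):
        length = f.end - f.start
        chrom_len = layout.length_of(f.chrom)
        if length > chrom_len:
            raise ValueError(f"feature {f.feature_id} longer than chromosome {f.chrom}")
        per_chrom.setdefault(f.chrom, []).append(length)
        obs += _count_hits(np.array([f.start]), np.array([f.end]),
                           merged.get(f.chrom, np.empty((0, 2), dtype=np.int64)))
    null = np.zeros(n_perm, dtype=np.int64)
    for chrom, lengths in per_chrom.items():
        lengths = np.asarray(lengths, dtype=np.int64)
        chrom_len = layout.length_of(chrom)
        m = merged.get(chrom, np.empty((0, 2), dtype=np.int64))
        highs = np.maximum(chrom_len - lengths, 1)
        for b in range(n_perm):
            starts = (rng.random(lengths.size) * highs).astype(np.int64)
            null[b] += _count_hits(starts, starts + lengths, m)
    p_hi = (1 + (null >= obs).sum()) / (n_perm + 1)
    p_lo = (1 + (null <= obs).sum()) / (n_perm + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    return PermutationResult(obs, null, float(p), seed)


def fixed_differences(gm: GenotypeMatrix, pop_a: list[str], pop_b: list[str]) -> pd.DataFrame:
    """Sites where one population is homozygous reference and the other
    homozygous alternate, with no missing genotype in either population."""
    idx = {s: i for i, s in enumerate(gm.samples)}
    ga = gm.genotypes[[idx[s] for s in pop_a]]
    gb = gm.genotypes[[idx[s] for s in pop_b]]
    complete = np.all(ga >= 0, axis=(0, 2)) & np.all(gb >= 0, axis=(0, 2))
    a_ref = np.all(ga == 0, axis=(0, 2))
    a_alt = np.all(ga == 1, axis=(0, 2))
    b_ref = np.all(gb == 0, axis=(0, 2))
    b_alt = np.all(gb == 1, axis=(0, 2))
    fixed = complete & ((a_ref & b_alt) | (a_alt & b_ref))
    return pd.DataFrame({
        "chrom": gm.chrom,
        "pos": gm.positions[fixed],
        "alt_fixed_in": np.where(b_alt[fixed], "popB", "popA"),
    })


_CODON_TABLE = {}


def _translate(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE.get(codon.upper(), "X")


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def _seq_slice(reference, chrom: str, start: int, end: int) -> str:
    """Reference substring as str, whatever the backing store (pyfaidx
    record, plain str, or bytes)."""
    piece = reference[chrom][start:end]
    if isinstance(piece, (bytes, bytearray)):
        return piece.decode()
    return str(piece)


def classify_coding_effect(chrom: str, pos: int, ref: str, alt: str,
                           genes: list[GeneModel], reference) -> dict:
    """Locate a site against gene models and classify its coding effect.

    ``reference`` maps chromosome name to sequence (string-like, indexable
    by slice).  Context precedence is CDS > intron > intergenic; for CDS
    sites the codon is rebuilt from the spliced CDS in transcript
    orientation and the alternate allele substituted.
    """
    ref_base = _seq_slice(reference, chrom, pos, pos + 1).upper()
    if ref_base != ref.upper():
        raise ValueError(f"reference mismatch at {chrom}:{pos}: VCF {ref} vs FASTA {ref_base}")
    context, gene_hit = "intergenic", None
    for g in genes:
        if g.chrom != chrom or not (g.start <= pos < g.end):
            continue
        in_cds = any(s <= pos < e for s, e, _ in g.cds)
        if in_cds:
            context, gene_hit = "CDS", g
            break
        if context != "CDS":
            context, gene_hit = "intron", g
    if context != "CDS":
        return {"chrom": chrom, "pos": pos, "context": context, "effect": "non_coding",
                "gene_id": gene_hit.gene_id if gene_hit else None}
    g = gene_hit
    order = g.cds if g.strand == "+" else g.cds[::-1]
    spliced = ""
    offset = None
    for s, e, _ in order:
        segment = _seq_slice(reference, chrom, s, e).upper()
        if g.strand == "-":
            segment = _revcomp(segment)
        if s <= pos < e:
            within = (pos - s) if g.strand == "+" else (e - 1 - pos)
            offset = len(spliced) + within
        spliced += segment
    phase0 = order[0][2]
    if (len(spliced) - phase0) % 3 != 0 or offset is None or offset < phase0:
        return {"chrom": chrom, "pos": pos, "context": "CDS", "effect": "unclassifiable",
                "gene_id": g.gene_id}
    codon_index = (offset - phase0) // 3
    codon_start = phase0 + 3 * codon_index
    codon = spliced[codon_start:codon_start + 3]
    if len(codon) < 3:
        return {"chrom": chrom, "pos": pos, "context": "CDS", "effect": "unclassifiable",
                "gene_id": g.gene_id}
    pos_in_codon = offset - codon_start
    alt_base = alt.upper() if g.strand == "+" else _COMPLEMENT[alt.upper()]
    alt_codon = codon[:pos_in_codon] + alt_base + codon[pos_in_codon + 1:]
    aa_ref, aa_alt = _translate(codon), _translate(alt_codon)
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return {"chrom": chrom, "pos": pos, "context": "CDS", "effect": effect,
            "gene_id": g.gene_id}


def str_cds_density(strs, genes: list[GeneModel], bandwidth=None,
                    span: int = 50_000, n_grid: int = 501) -> pd.DataFrame:
    """Kernel density of signed STR distance to the nearest CDS boundary.

    Distances are orientation-aware (negative = upstream of the boundary in
    transcript direction) and computed separately for CDS starts and ends;
    one Gaussian KDE per repeat period, Silverman bandwidth unless given,
    normalised to integrate to 1 over the +-span range.
    """
    if len(strs) < 2:
        raise ValueError("need >=2 STRs for the density estimate")
    if not genes:
        raise ValueError("no genes supplied")
    boundaries = {"start": {}, "end": {}}
    for g in genes:
        for s, e, _ in g.cds:
            if g.strand == "+":
                b_start, b_end = s, e - 1
                sign = 1
            else:
                b_start, b_end = e - 1, s
                sign = -1
            boundaries["start"].setdefault(g.chrom, []).append((b_start, sign))
            boundaries["end"].setdefault(g.chrom, []).append((b_end, sign))
    for kind in boundaries:
        for chrom in boundaries[kind]:
            arr = np.array(sorted(boundaries[kind][chrom]), dtype=np.int64)
            boundaries[kind][chrom] = arr

    grid = np.linspace(-span, span, n_grid)
    rows = []
    periods = sorted({r.period for r in strs})
    for period in periods:
        recs = [r for r in strs if r.period == period]
        for kind in ("start", "end"):
            dists = []
            for r in recs:
                b = boundaries[kind].get(r.chrom)
                if b is None or b.shape[0] == 0:
                    continue
                i = np.searchsorted(b[:, 0], r.pos)
                best, best_d = None, None
                for j in (i - 1, i):
                    if 0 <= j < b.shape[0]:
                        d = abs(r.pos - b[j, 0])
                        if best_d is None or d < best_d:
                            best, best_d = j, d
                dists.append((r.pos - b[best, 0]) * b[best, 1])
            dists = np.asarray(dists, dtype=float)
            if dists.size < 2 or np.all(dists == dists[0]):
                continue
            kde = sps.gaussian_kde(dists, bw_method=bandwidth or "silverman")
            dens = kde(grid)
            area = np.trapezoid(dens, grid)
            if area > 0:
                dens = dens / area
            for x, y in zip(grid, dens):
                rows.append((period, kind, x, y))
    return pd.DataFrame(rows, columns=["period", "boundary", "distance", "density"])


_KIND_ORDER = ("SNP", "SV", "STR", "fixed")


def crossref_candidates(gene_hits: pd.DataFrame,
                        candidates: CandidateGeneList) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-reference outlier genes against a curated candidate list.

    ``gene_hits`` holds (gene_id, kind) pairs; returns (full table, matched
    table), one row per gene with a 'method' string listing the supporting
    variant types in fixed order.
    """
    rows = []
    for gene_id, grp in gene_hits.groupby("gene_id"):
        kinds = sorted(set(grp["kind"]), key=lambda k: _KIND_ORDER.index(k)
                       if k in _KIND_ORDER else len(_KIND_ORDER))
        rows.append((gene_id, ", ".join(kinds), gene_id in candidates))
    full = pd.DataFrame(rows, columns=["gene_id", "method", "in_candidate_list"])
    matched = full[full["in_candidate_list"]].drop(columns="in_candidate_list")
    return full, matched.reset_index(drop=True)


def outlier_exclusivity(gene_sets: dict[str, set]) -> pd.DataFrame:
    """Venn-style summary: per gene, which variant types detected it."""
    all_genes = set().union(*gene_sets.values()) if gene_sets else set()
    rows = []
    for gene in sorted(all_genes):
        kinds = [k for k in _KIND_ORDER if gene in gene_sets.get(k, set())]
        kinds += [k for k in gene_sets if k not in _KIND_ORDER and gene in gene_sets[k]]
        rows.append((gene, ", ".join(kinds), len(kinds) == 1))
    return pd.DataFrame(rows, columns=["gene_id", "methods", "exclusive"])


def summary_compare(window_stats: pd.DataFrame, outlier_mask) -> dict:
    """Pearson correlations among window statistics and outlier-vs-rest
    Wilcoxon rank-sum tests (normal approximation with midranks)."""
    df = window_stats.copy()
    df["pi_mean"] = 0.5 * (df["pi_A"] + df["pi_B"])
    outlier_mask = np.asarray(outlier_mask, dtype=bool)
    pairs = [("pi_A", "pi_B"), ("dxy", "pi_mean"), ("fst_hudson", "dxy"),
             ("fst_hudson", "pi_mean")]
    out: dict = {"pearson": {}, "wilcoxon": {}}
    for scope, mask in (("genome", np.ones(len(df), bool)), ("outlier", outlier_mask)):
        out["pearson"][scope] = {}
        for x, y in pairs:
            sub = df.loc[mask, [x, y]].dropna()
            key = f"{x}~{y}"
            if len(sub) < 3 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
                logger.warning("correlation %s (%s) undefined", key, scope)
                out["pearson"][scope][key] = {"r": np.nan, "p": np.nan, "n": len(sub)}
                continue
            r, p = sps.pearsonr(sub[x], sub[y])
            out["pearson"][scope][key] = {"r": float(r), "p": float(p), "n": len(sub)}
    for col in ("fst_hudson", "dxy", "pi_A", "pi_B"):
        a = df.loc[outlier_mask, col].dropna()
        b = df.loc[~outlier_mask, col].dropna()
        if len(a) < 3 or len(b) < 3:
            out["wilcoxon"][col] = {"stat": np.nan, "p": np.nan}
            continue
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                                   use_continuity=True)
        out["wilcoxon"][col] = {"stat": float(stat), "p": float(p),
                                "median_outlier": float(a.median()),
                                "median_other": float(b.median())}
    return out


def genotype_pca(dosage: np.ndarray, samples: list[str],
                 scale_biallelic: bool = True, n_components: int = 10) -> pd.DataFrame:
    """PCA of an (n_samples, n_loci) dosage matrix.

    Loci are mean-centred; biallelic dosages (0..2) are scaled by
    sqrt(p(1-p)) with p the allele frequency (Patterson scaling).  Missing
    entries (negative) are mean-imputed.  Returns sample coordinates with
    explained-variance fractions in ``DataFrame.attrs``.
    """
    X = np.asarray(dosage, dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >=3 samples and >=2 loci for PCA")
    X = X.copy()
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    keep = np.nanstd(X, axis=0) > 0
    if not keep.any():
        raise ValueError("zero-variance genotype matrix")
    X = X[:, keep]
    col_mean = col_mean[keep]
    Xc = X - col_mean
    if scale_biallelic and np.nanmax(X) <= 2:
        p = col_mean / 2.0
        denom = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        Xc = Xc / denom
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, S.size)
    coords = U[:, :k] * S[:k]
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "sample", list(samples))
    total = (S**2).sum()
    df.attrs["explained_variance_fraction"] = (S[:k] ** 2 / total).tolist()
    return df
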