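"""End-to-end orchestration of the three scan tracks.

Thin glue over the statistic modules: build the window table (diversity +
haplotype statistics), run the DCMS composite, the SV and STR locus scans,
and the annotation/reporting layer.  Both in-memory objects (from the
simulator) and on-disk datasets (VCF + GFF3 + popmap) are accepted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as ann
from . import io as pio
from .config import ScanConfig
from .dcms import composite_scan
from .haplotypes import ihs_scan, window_mean_abs, xpehh_scan
from .loci import str_scan, sv_scan
from .model import GenomeLayout, HaplotypePanel, PopulationMap, Window
from .windows import compute_window_stats

logger = logging.getLogger("polyscan")

__all__ = ["window_scan", "run_full_scan", "fixed_snp_sites", "sv_dosage",
           "str_dosage", "snp_dosage", "load_dataset"]


def fixed_snp_sites(panels: dict[str, HaplotypePanel], popmap: PopulationMap,
                    genes=None, reference=None) -> pd.DataFrame:
    """Fixed homozygous SNP differences between the two scan populations,
    classified against gene models when annotation is available.

    A site qualifies when every population-A haplotype carries one allele
    and every population-B haplotype the other (phased panels carry no
    missing calls).  REF/ALT bases come from the panel when the VCF
    supplied them, else from the reference sequence with the writer's
    deterministic alternate-base rule.
    """
    from .io import _ALT_OF

    rows = []
    for chrom in sorted(panels):
        panel = panels[chrom]
        ha = panel.subset_samples(popmap.samples(popmap.pop_a)).haplotypes
        hb = panel.subset_samples(popmap.samples(popmap.pop_b)).haplotypes
        a0 = np.all(ha == 0, axis=0)
        a1 = np.all(ha == 1, axis=0)
        b0 = np.all(hb == 0, axis=0)
        b1 = np.all(hb == 1, axis=0)
        for j in np.nonzero((a0 & b1) | (a1 & b0))[0]:
            pos = int(panel.positions[j])
            if panel.ref_alleles is not None:
                ref, alt = panel.ref_alleles[j], panel.alt_alleles[j]
            elif reference is not None:
                ref = ann._seq_slice(reference, chrom, pos, pos + 1).upper()
                alt = _ALT_OF.get(ref, "T")
            else:
                ref = alt = None
            entry = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "alt_fixed_in": "popB" if b1[j] else "popA",
                     "context": None, "effect": None, "gene_id": None}
            if genes and reference is not None and ref is not None:
                cls = ann.classify_coding_effect(chrom, pos, ref, alt, genes, reference)
                entry.update(context=cls["context"], effect=cls["effect"],
                             gene_id=cls["gene_id"])
            rows.append(entry)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_fixed_in",
                                       "context", "effect", "gene_id"])


def window_scan(
    panels_a: dict[str, HaplotypePanel],
    panels_b: dict[str, HaplotypePanel],
    layout: GenomeLayout,
    config: ScanConfig | None = None,
    accessible: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Window table with diversity, differentiation and haplotype columns."""
    config = config or ScanConfig()
    ws = compute_window_stats(panels_a, panels_b, layout, config, accessible)
    ihs_panels = panels_b if config.within_pop == "popB" else panels_a
    ihs = ihs_scan(ihs_panels, maf_min=config.ihs_maf_min, bins=config.ihs_bins,
                   cutoff=config.ehh_cutoff, max_gap=config.max_gap,
                   max_extend=config.max_extend, ancestral=config.ancestral)
    xp = xpehh_scan(panels_a, panels_b, cutoff=config.ehh_cutoff,
                    max_gap=config.max_gap, max_extend=config.max_extend)
    wins = [Window(r.chrom, r.start, r.end) for r in ws.itertuples(index=False)]
    ws["mean_abs_ihs"] = window_mean_abs(ihs, wins, "ihs")
    ws["mean_abs_xpehh"] = window_mean_abs(xp, wins, "xpehh")
    ws.attrs["ihs"] = ihs
    ws.attrs["xpehh"] = xp
    return ws


def sv_dosage(svs, samples) -> np.ndarray:
    """(n_samples, n_svs) alternate-allele dosage; -1 where missing."""
    cols = []
    for rec in svs:
        idx = [rec.samples.index(s) for s in samples]
        g = rec.genotypes[idx]
        d = g.sum(axis=1).astype(float)
        d[np.any(g < 0, axis=1)] = -1
        cols.append(d)
    return np.stack(cols, axis=1)


def str_dosage(strs, samples) -> np.ndarray:
    """(n_samples, n_strs) summed repeat counts; -1 where missing."""
    cols = []
    for rec in strs:
        idx = [rec.samples.index(s) for s in samples]
        g = rec.genotypes[idx].astype(float)
        d = g.sum(axis=1)
        d[np.any(g < 0, axis=1)] = -1
        cols.append(d)
    return np.stack(cols, axis=1)


def snp_dosage(panels: dict[str, HaplotypePanel], samples) -> np.ndarray:
    """(n_samples, n_sites) alternate-allele dosage from phased panels."""
    blocks = []
    for chrom in sorted(panels):
        panel = panels[chrom].subset_samples(list(samples))
        blocks.append((panel.haplotypes[0::2] + panel.haplotypes[1::2]).astype(float))
    return np.concatenate(blocks, axis=1)


def load_dataset(data_dir: str | Path, config: ScanConfig | None = None):
    """Load a simulated (or equivalently structured) dataset directory."""
    data_dir = Path(data_dir)
    popmap = PopulationMap.from_tsv(data_dir / "popmap.tsv")
    layout = pio.read_layout_from_vcf(data_dir / "snps.vcf")
    panels = pio.load_genotypes(data_dir / "snps.vcf", "snp", popmap, phased=True)
    svs = pio.load_genotypes(data_dir / "svs.vcf", "sv", popmap)
    strs = pio.load_genotypes(data_dir / "strs.vcf", "str", popmap)
    genes, reference = pio.load_annotation(data_dir / "genes.gff3", data_dir / "ref.fa")
    accessible = None
    if (data_dir / "accessible.bed").exists():
        accessible = pio.read_bed(data_dir / "accessible.bed")
    return {"popmap": popmap, "layout": layout, "panels": panels, "svs": svs,
            "strs": strs, "genes": genes, "reference": reference,
            "accessible": accessible}


def run_full_scan(data: dict, config: ScanConfig | None = None,
                  candidates=None, out_dir: str | Path | None = None) -> dict:
    """All three scan tracks + annotation on a loaded dataset dict."""
    config = (config or ScanConfig()).validate()
    popmap: PopulationMap = data["popmap"]
    layout: GenomeLayout = data["layout"]
    panels = data["panels"]
    pa = {c: p.subset_samples(popmap.samples(popmap.pop_a)) for c, p in panels.items()}
    pb = {c: p.subset_samples(popmap.samples(popmap.pop_b)) for c, p in panels.items()}

    ws = window_scan(pa, pb, layout, config, data.get("accessible"))
    dcms_table, regions = composite_scan(ws, config)
    sv_table, sv_fixed = sv_scan(data["svs"], popmap, config)
    str_table = str_scan(data["strs"], popmap, config)
    fixed_sites = fixed_snp_sites(panels, popmap, data.get("genes"),
                                  data.get("reference"))
    try:
        str_density = ann.str_cds_density(data["strs"], data["genes"])
    except ValueError as exc:
        logger.warning("STR-to-CDS density skipped: %s", exc)
        str_density = pd.DataFrame(columns=["period", "boundary", "distance", "density"])

    genes = data["genes"]
    supported = regions[regions["supported"]]
    feat_frames = []
    if len(supported):
        f = supported[["chrom", "start", "end"]].copy()
        f.insert(0, "feature_id", [f"region_{i + 1}" for i in range(len(supported))])
        f["kind"] = "SNP"
        feat_frames.append(f)
    sv_out = sv_table[sv_table["outlier"]]
    if len(sv_out):
        f = sv_out[["chrom", "start"]].copy()
        f["end"] = f["start"] + 1
        f.insert(0, "feature_id", sv_out["locus_id"].to_numpy())
        f["kind"] = "SV"
        feat_frames.append(f)
    str_out = str_table[str_table["outlier"]]
    if len(str_out):
        f = str_out[["chrom", "pos"]].rename(columns={"pos": "start"}).copy()
        f["end"] = f["start"] + 1
        f.insert(0, "feature_id", str_out["locus_id"].to_numpy())
        f["kind"] = "STR"
        feat_frames.append(f)
    if len(fixed_sites):
        f = fixed_sites[["chrom", "pos"]].rename(columns={"pos": "start"}).copy()
        f["end"] = f["start"] + 1
        f.insert(0, "feature_id",
                 [f"fixed_{c}_{p}" for c, p in zip(fixed_sites["chrom"], fixed_sites["pos"])])
        f["kind"] = "fixed"
        feat_frames.append(f)
    features = (pd.concat(feat_frames, ignore_index=True) if feat_frames
                else pd.DataFrame(columns=["feature_id", "chrom", "start", "end", "kind"]))
    hits = ann.gene_proximity(features, genes, config.proximity)

    permutation = {}
    for kind, grp in features.groupby("kind"):
        permutation[kind] = ann.permutation_enrichment(
            grp, genes, layout, config.n_permutations, config.proximity, seed=config.seed)

    gene_sets = {k: set(hits.loc[hits["kind"] == k, "gene_id"]) for k in hits["kind"].unique()}
    exclusivity = ann.outlier_exclusivity(gene_sets)
    crossref_full = crossref_matched = None
    if candidates is not None:
        crossref_full, crossref_matched = ann.crossref_candidates(hits, candidates)

    outlier_mask = np.zeros(len(ws), dtype=bool)
    for r in supported.itertuples(index=False):
        outlier_mask |= ((ws["chrom"] == r.chrom) & (ws["start"] < r.end)
                         & (ws["end"] > r.start)).to_numpy()
    summary = ann.summary_compare(ws, outlier_mask)

    scan_samples = popmap.scan_samples
    pca = {
        "snp": ann.genotype_pca(snp_dosage(panels, scan_samples), scan_samples),
        "sv": ann.genotype_pca(sv_dosage(data["svs"], scan_samples), scan_samples),
        "str": ann.genotype_pca(str_dosage(data["strs"], scan_samples), scan_samples,
                                scale_biallelic=False),
    }

    results = {
        "window_stats": ws,
        "dcms": dcms_table,
        "regions": regions,
        "sv": sv_table,
        "sv_fixed": sv_fixed,
        "str": str_table,
        "fixed_sites": fixed_sites,
        "str_cds_density": str_density,
        "gene_hits": hits,
        "exclusivity": exclusivity,
        "permutation": permutation,
        "summary": summary,
        "pca": pca,
        "crossref": (crossref_full, crossref_matched),
        "outlier_window_mask": outlier_mask,
    }
    if out_dir is not None:
        tables = {
            "window_stats": ws.drop(columns=[], errors="ignore"),
            "dcms": dcms_table,
            "outlier_regions_all": regions,
            "outlier_regions": supported,
            "sv_outliers": sv_table,
            "sv_fixed": sv_fixed,
            "str_outliers": str_table,
            "fixed_sites": fixed_sites,
            "str_cds_density": str_density,
            "gene_hits": hits,
            "exclusivity": exclusivity,
        }
        if crossref_full is not None:
            tables["candidate_genes"] = crossref_full
        pio.write_tables(tables, out_dir, config=config, seed=config.seed)
    return results
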