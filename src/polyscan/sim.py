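"""Synthetic two-population dataset with planted divergent loci.

The generator emulates the statistical structure that the downstream scans
consume, at desk scale, without a full coalescent:

* **SNPs** — sites are placed by a Poisson process whose density is
  calibrated so the expected per-bp heterozygosity matches the configured
  ancestral diversity.  Per-population allele frequencies follow the
  Balding–Nichols model around a uniform ancestral frequency; founder
  haplotypes are drawn site-wise from those frequencies and sample
  haplotypes are founder mosaics with a small per-bp switch rate, which
  creates realistic long-range haplotype sharing for the EHH statistics.
* **Sweeps** — inside each planted region, population-B sample haplotypes
  are replaced by a designated sweep founder with probability ``f_sweep``,
  producing low pi, high FST, negative Tajima's D and long homozygosity.
* **SVs / STRs** — biallelic SVs genotyped from Balding–Nichols
  frequencies, a small fraction given strongly divergent frequencies; STR
  allele distributions are discretised Gaussians over repeat counts, with
  divergent loci shifted between populations by >= 2 repeat units.
* **Annotation** — genes laid left-to-right with exponential intergenic
  gaps (mean 16 kb, so half the mean gap reproduces the 8 kb proximity
  constant), 2–8 CDS segments each, on a random reference sequence with
  valid start/stop codons.

Everything is reproducible from a single seed and the planted truth is
emitted in machine-readable form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SimConfig
from .model import GeneModel, GenomeLayout, HaplotypePanel, PopulationMap, StrRecord, SvRecord

__all__ = [
    "SimTruth",
    "SimResult",
    "balding_nichols_freqs",
    "mosaic_panel_with_sweep",
    "simulate_marker_loci",
    "generate_annotation",
    "simulate_dataset",
]

_SV_TYPES = ("DEL", "INS", "DUP", "INV")
_SV_WEIGHTS = (0.7, 0.1, 0.1, 0.1)
_STR_PERIOD_WEIGHTS = (0.35, 0.35, 0.10, 0.08, 0.07, 0.05)
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimTruth:
    """Machine-readable record of every planted signal."""

    sweep_regions: list[tuple[str, int, int]] = field(default_factory=list)
    divergent_svs: list[str] = field(default_factory=list)
    divergent_strs: list[str] = field(default_factory=list)
    sweep_genes: list[str] = field(default_factory=list)
    sv_freqs: dict[str, tuple[float, float]] = field(default_factory=dict)
    str_means: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class SimResult:
    config: SimConfig
    layout: GenomeLayout
    popmap: PopulationMap
    panels: dict[str, HaplotypePanel]  # all samples, per chromosome
    svs: list[SvRecord]
    strs: list[StrRecord]
    genes: list[GeneModel]
    reference: dict[str, bytes]
    accessible: dict[str, np.ndarray]
    truth: SimTruth

    def panel_for(self, pop: str) -> dict[str, HaplotypePanel]:
        samples = self.popmap.samples(pop)
        return {c: p.subset_samples(samples) for c, p in self.panels.items()}


def balding_nichols_freqs(p_anc: float, F: float, n_pops: int, rng) -> np.ndarray:
    """Per-population allele frequencies under the Balding–Nichols model.

    Each population's frequency is an independent
    Beta(p(1-F)/F, (1-p)(1-F)/F) draw around the ancestral frequency, so
    E[p_i] = p_anc and Var[p_i] = F p_anc (1 - p_anc).
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if not (0 < F < 1):
        raise ValueError("F must lie strictly in (0, 1)")
    if np.any(p_anc <= 0) or np.any(p_anc >= 1):
        raise ValueError("p_anc must lie strictly in (0, 1)")
    scale = (1.0 - F) / F
    shape = (n_pops,) + p_anc.shape
    return rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=shape)


def _expected_het_uniform(freq_min: float) -> float:
    """E[2 p (1-p)] for p ~ Uniform(freq_min, 1 - freq_min)."""
    a, b = freq_min, 1.0 - freq_min
    e_p2 = (b**3 - a**3) / (3.0 * (b - a))
    return 2.0 * (0.5 - e_p2)


def _mosaic_haplotypes(
    founders: np.ndarray, positions: np.ndarray, n_haps: int, switch_rate: float,
    chrom_length: int, rng,
) -> np.ndarray:
    """Sample haplotypes as founder mosaics with Poisson switch points."""
    n_f, m = founders.shape
    out = np.empty((n_haps, m), dtype=np.int8)
    cols = np.arange(m)
    for h in range(n_haps):
        n_switch = rng.poisson(switch_rate * chrom_length)
        if n_switch == 0:
            out[h] = founders[rng.integers(n_f)]
            continue
        breaks = np.sort(rng.integers(0, chrom_length, size=n_switch))
        seg_ids = rng.integers(n_f, size=n_switch + 1)
        fid = seg_ids[np.searchsorted(breaks, positions, side="right")]
        out[h] = founders[fid, cols]
    return out


def mosaic_panel_with_sweep(
    config: SimConfig,
    chrom: str,
    rng,
    sweep_regions: list[tuple[int, int]] | None = None,
    sample_names: dict[str, list[str]] | None = None,
) -> HaplotypePanel:
    """Phased SNP panel for one chromosome, all populations combined.

    Sweep regions (coordinates on this chromosome) apply to population B
    only: each B sample haplotype is independently replaced by the sweep
    founder across the whole region with probability ``f_sweep``.
    """
    length = config.layout.length_of(chrom)
    sweep_regions = sweep_regions or []
    for s, e in sweep_regions:
        if not (0 <= s < e <= length):
            raise ValueError(f"sweep region [{s}, {e}) outside chromosome {chrom}")

    e_het = _expected_het_uniform(config.freq_min)
    density = config.theta_anc / e_het
    n_sites = rng.poisson(density * length)
    positions = np.sort(rng.choice(length, size=n_sites, replace=False)).astype(np.int64)

    p_anc = rng.uniform(config.freq_min, 1.0 - config.freq_min, size=n_sites)
    p_pop = balding_nichols_freqs(p_anc, config.background_f, 2, rng)

    founders = {}
    for k, pop in enumerate(("popA", "popB")):
        founders[pop] = (rng.random((config.n_founders, n_sites)) < p_pop[k]).astype(np.int8)

    # diversity scaling: monomorphise a fraction of sites in population B
    drop = rng.random(n_sites) >= config.diversity_scale_b
    if drop.any():
        major = (p_pop[1][drop] > 0.5).astype(np.int8)
        founders["popB"][:, drop] = major[None, :]

    n_haps = 2 * config.n_diploids
    haps = {
        pop: _mosaic_haplotypes(founders[pop], positions, n_haps, config.switch_rate, length, rng)
        for pop in ("popA", "popB")
    }

    sweep_founder = founders["popB"][0]
    for s, e in sweep_regions:
        lo, hi = np.searchsorted(positions, [s, e])
        carriers = rng.random(n_haps) < config.f_sweep
        haps["popB"][np.where(carriers)[0][:, None], np.arange(lo, hi)[None, :]] = sweep_founder[lo:hi]

    blocks = [haps["popA"], haps["popB"]]
    names = (sample_names or _default_names(config))
    samples = list(names["popA"]) + list(names["popB"])
    if config.n_hybrids > 0:
        pool = np.concatenate([founders["popA"], founders["popB"]])
        blocks.append(
            _mosaic_haplotypes(pool, positions, 2 * config.n_hybrids, config.switch_rate, length, rng)
        )
        samples += list(names["hybrid"])
    return HaplotypePanel(chrom, positions, np.concatenate(blocks), tuple(samples))


def _default_names(config: SimConfig) -> dict[str, list[str]]:
    return {
        "popA": [f"popA_{i + 1:02d}" for i in range(config.n_diploids)],
        "popB": [f"popB_{i + 1:02d}" for i in range(config.n_diploids)],
        "hybrid": [f"hyb_{i + 1:02d}" for i in range(config.n_hybrids)],
    }


def _place_sweeps(config: SimConfig, rng) -> list[tuple[str, int, int]]:
    """Non-overlapping sweep intervals, split round-robin over chromosomes."""
    per_chrom: dict[str, int] = {c: 0 for c in config.layout.names}
    for i in range(config.n_sweeps):
        per_chrom[config.layout.names[i % len(config.layout.names)]] += 1
    regions = []
    margin = config.sweep_length
    L_sw = config.sweep_length
    for chrom, k in per_chrom.items():
        if k == 0:
            continue
        length = config.layout.length_of(chrom)
        free = length - 2 * margin - k * L_sw
        if free < 0:
            raise ValueError(f"sweep regions do not fit on {chrom}")
        gaps = np.sort(rng.integers(0, free + 1, size=k))
        for i, g in enumerate(gaps):
            start = margin + int(g) + i * L_sw
            regions.append((chrom, start, start + L_sw))
    return sorted(regions)


# ---------------------------------------------------------------------------
# marker panels


def _genotype_from_freq(p: float, n: int, rng) -> np.ndarray:
    """(n, 2) diploid allele pairs as two independent Bernoulli draws."""
    return (rng.random((n, 2)) < p).astype(np.int8)


def simulate_marker_loci(
    config: SimConfig, rng, sample_names: dict[str, list[str]] | None = None
) -> tuple[list[SvRecord], list[StrRecord], SimTruth]:
    """SV and STR genotype panels with planted divergent loci."""
    if config.sv_divergent_fraction > 1 or config.str_divergent_fraction > 1:
        raise ValueError("divergent fraction cannot exceed 1")
    names = sample_names or _default_names(config)
    samples = tuple(names["popA"] + names["popB"] + names["hybrid"])
    n_a = len(names["popA"])
    n_b = len(names["popB"])
    n_h = len(names["hybrid"])
    truth = SimTruth()

    layout = config.layout
    total_len = sum(layout.lengths)
    chrom_p = np.array(layout.lengths, dtype=float) / total_len

    def _genotypes(p_a: float, p_b: float) -> np.ndarray:
        parts = [
            _genotype_from_freq(p_a, n_a, rng),
            _genotype_from_freq(p_b, n_b, rng),
        ]
        if n_h:
            parts.append(_genotype_from_freq(0.5 * (p_a + p_b), n_h, rng))
        return np.concatenate(parts)

    # --- SVs
    svs: list[SvRecord] = []
    n_div_sv = int(round(config.n_svs * config.sv_divergent_fraction))
    div_idx = set(rng.choice(config.n_svs, size=n_div_sv, replace=False).tolist())
    for i in range(config.n_svs):
        chrom = layout.names[rng.choice(len(layout.names), p=chrom_p)]
        length_chrom = layout.length_of(chrom)
        svtype = _SV_TYPES[rng.choice(4, p=_SV_WEIGHTS)]
        sv_len = int(np.exp(rng.uniform(np.log(50), np.log(100_000))))
        start = int(rng.integers(0, length_chrom - 1))
        if svtype == "INS":
            end = start + 1
        else:
            end = min(start + sv_len, length_chrom)
            sv_len = end - start
        if i in div_idx:
            delta = rng.uniform(config.sv_delta_p, min(0.8, config.sv_delta_p + 0.2))
            centre = rng.uniform(0.1 + delta / 2, 0.9 - delta / 2)
            p_a, p_b = centre - delta / 2, centre + delta / 2
            if rng.random() < 0.5:
                p_a, p_b = p_b, p_a
        else:
            p_anc = rng.uniform(config.freq_min, 1 - config.freq_min)
            p_a, p_b = balding_nichols_freqs(p_anc, config.background_f, 2, rng)
        sv_id = f"sv_{i + 1:05d}"
        svs.append(SvRecord(sv_id, chrom, start, end, svtype, sv_len, _genotypes(p_a, p_b), samples))
        truth.sv_freqs[sv_id] = (float(p_a), float(p_b))
        if i in div_idx:
            truth.divergent_svs.append(sv_id)

    # --- STRs
    strs: list[StrRecord] = []
    n_div_str = int(round(config.n_strs * config.str_divergent_fraction))
    div_idx = set(rng.choice(config.n_strs, size=n_div_str, replace=False).tolist())
    counts = np.arange(3, 61)
    for i in range(config.n_strs):
        chrom = layout.names[rng.choice(len(layout.names), p=chrom_p)]
        pos = int(rng.integers(0, layout.length_of(chrom)))
        period = 1 + int(rng.choice(6, p=_STR_PERIOD_WEIGHTS))
        m0 = rng.uniform(8, 20)
        if i in div_idx:
            shift = rng.uniform(config.str_shift, config.str_shift + 2.0)
            if rng.random() < 0.5:
                shift = -shift
            mean_a, mean_b = m0, m0 + shift
        else:
            mean_a = m0 + rng.normal(0, config.str_neutral_jitter)
            mean_b = m0 + rng.normal(0, config.str_neutral_jitter)

        def _draw(mean: float, n: int) -> np.ndarray:
            w = np.exp(-0.5 * ((counts - mean) / config.str_sd) ** 2)
            w /= w.sum()
            return rng.choice(counts, size=(n, 2), p=w).astype(np.int16)

        parts = [_draw(mean_a, n_a), _draw(mean_b, n_b)]
        if n_h:
            parts.append(_draw(0.5 * (mean_a + mean_b), n_h))
        geno = np.concatenate(parts)
        if rng.random() < config.str_missing_fraction:
            geno[rng.integers(geno.shape[0])] = -1
        str_id = f"str_{i + 1:05d}"
        strs.append(StrRecord(str_id, chrom, pos, period, geno, samples))
        truth.str_means[str_id] = (float(mean_a), float(mean_b))
        if i in div_idx:
            truth.divergent_strs.append(str_id)

    return svs, strs, truth


# ---------------------------------------------------------------------------
# annotation + reference


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def generate_annotation(
    config: SimConfig, rng
) -> tuple[list[GeneModel], dict[str, bytearray]]:
    """Gene models with exponential intergenic gaps, plus a reference.

    Genes carry 2–8 CDS segments whose total length is a multiple of three;
    start and stop codons are written into the reference in the transcript
    frame.  Gaps between consecutive genes are exponential with the
    configured mean, so half the mean observed gap recovers the
    gene-proximity constant.
    """
    genes: list[GeneModel] = []
    reference: dict[str, bytearray] = {}
    gene_no = 0
    for chrom, length in config.layout.items():
        seq = bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())
        pos = int(rng.exponential(config.mean_intergenic_gap))
        while True:
            k = int(rng.integers(2, 9))
            cds_lens = rng.integers(60, 301, size=k)
            cds_lens[-1] -= int(cds_lens.sum() % 3)
            introns = rng.integers(100, 2001, size=k - 1)
            gene_len = int(cds_lens.sum() + introns.sum())
            if pos + gene_len > length - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            segs: list[tuple[int, int]] = []
            cursor = pos
            for j in range(k):
                segs.append((cursor, cursor + int(cds_lens[j])))
                cursor += int(cds_lens[j])
                if j < k - 1:
                    cursor += int(introns[j])
            # phases in transcript order
            order = segs if strand == "+" else segs[::-1]
            cds = []
            cum = 0
            for s, e in order:
                cds.append((s, e, (3 - cum % 3) % 3))
                cum += e - s
            cds.sort()
            gene_no += 1
            gene_id = f"gene_{gene_no:04d}"
            genes.append(
                GeneModel(gene_id, chrom, pos, pos + gene_len, strand,
                          cds=cds, exons=[(s, e) for s, e, _ in cds])
            )
            # start / stop codons in transcript orientation
            first_s, first_e = order[0][0], order[0][1]
            last_s, last_e = order[-1][0], order[-1][1]
            if strand == "+":
                seq[first_s:first_s + 3] = b"ATG"
                seq[last_e - 3:last_e] = b"TAA"
            else:
                seq[first_e - 3:first_e] = b"CAT"  # revcomp(ATG)
                seq[last_s:last_s + 3] = b"TTA"    # revcomp(TAA)
            pos += gene_len + int(rng.exponential(config.mean_intergenic_gap))
        reference[chrom] = seq
    return genes, reference


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate the full dataset; write all files when ``out_dir`` is given."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = _default_names(config)
    assignments: dict[str, str] = {}
    for s in names["popA"]:
        assignments[s] = "popA"
    for s in names["popB"]:
        assignments[s] = "popB"
    for s in names["hybrid"]:
        assignments[s] = "hybrid"
    popmap = PopulationMap(assignments)

    sweeps = _place_sweeps(config, rng)
    truth = SimTruth(sweep_regions=sweeps)

    panels = {}
    for chrom in config.layout.names:
        chrom_sweeps = [(s, e) for c, s, e in sweeps if c == chrom]
        panels[chrom] = mosaic_panel_with_sweep(config, chrom, rng, chrom_sweeps, names)

    svs, strs, marker_truth = simulate_marker_loci(config, rng, names)
    truth.divergent_svs = marker_truth.divergent_svs
    truth.divergent_strs = marker_truth.divergent_strs
    truth.sv_freqs = marker_truth.sv_freqs
    truth.str_means = marker_truth.str_means

    genes, reference = generate_annotation(config, rng)
    sweep_lookup = {c: [(s, e) for cc, s, e in sweeps if cc == c] for c in config.layout.names}
    for g in genes:
        if any(g.start < e and s < g.end for s, e in sweep_lookup.get(g.chrom, [])):
            truth.sweep_genes.append(g.gene_id)

    accessible = {c: np.array([[0, L]], dtype=np.int64) for c, L in config.layout.items()}
    result = SimResult(config, config.layout, popmap, panels, svs, strs, genes,
                       {c: bytes(s) for c, s in reference.items()}, accessible, truth)
    if out_dir is not None:
        write_dataset(result, Path(out_dir))
    return result


def write_dataset(result: SimResult, out_dir: Path) -> None:
    """Emit snps.vcf, svs.vcf, strs.vcf, genes.gff3, ref.fa, popmap.tsv,
    accessible.bed and the truth files."""
    from . import io as _io  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _io.write_snp_vcf(out_dir / "snps.vcf", result.panels, result.layout, result.reference)
    _io.write_sv_vcf(out_dir / "svs.vcf", result.svs, result.layout)
    _io.write_str_vcf(out_dir / "strs.vcf", result.strs, result.layout)
    _io.write_gff3(out_dir / "genes.gff3", result.genes, result.layout)
    _io.write_fasta(out_dir / "ref.fa", result.reference)
    _io.write_bed(out_dir / "accessible.bed",
                  [(c, int(s), int(e)) for c, arr in result.accessible.items() for s, e in arr])
    with open(out_dir / "popmap.tsv", "w") as fh:
        for s, p in result.popmap.assignments.items():
            fh.write(f"{s}\t{p}\n")
    _io.write_bed(out_dir / "truth_regions.bed", result.truth.sweep_regions)
    with open(out_dir / "truth_loci.tsv", "w") as fh:
        fh.write("locus_id\tkind\tdivergent\tparam_A\tparam_B\n")
        div = set(result.truth.divergent_svs)
        for sv_id, (pa, pb) in result.truth.sv_freqs.items():
            fh.write(f"{sv_id}\tsv\t{int(sv_id in div)}\t{pa:.6f}\t{pb:.6f}\n")
        div = set(result.truth.divergent_strs)
        for str_id, (ma, mb) in result.truth.str_means.items():
            fh.write(f"{str_id}\tstr\t{int(str_id in div)}\t{ma:.6f}\t{mb:.6f}\n")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(
            {
                "sweep_regions": [[c, s, e] for c, s, e in result.truth.sweep_regions],
                "divergent_svs": result.truth.divergent_svs,
                "divergent_strs": result.truth.divergent_strs,
                "sweep_genes": result.truth.sweep_genes,
                "seed": result.config.seed,
            },
            fh,
            indent=1,
        )
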