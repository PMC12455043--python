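"""Readers and writers for the on-disk formats.

VCF is read through cyvcf2, GFF3 through gffutils and FASTA through
pyfaidx; writing uses plain deterministic text emission.  All coordinates
are converted to the internal 0-based half-open convention at this
boundary: VCF POS and GFF3 start are 1-based, BED output is 0-based
half-open.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    GeneModel,
    GenomeLayout,
    GenotypeMatrix,
    HaplotypePanel,
    PopulationMap,
    StrRecord,
    SvRecord,
)

logger = logging.getLogger("polyscan")

__all__ = [
    "load_genotypes",
    "load_annotation",
    "write_tables",
    "write_snp_vcf",
    "write_sv_vcf",
    "write_str_vcf",
    "write_gff3",
    "write_fasta",
    "write_bed",
    "read_bed",
    "read_layout_from_vcf",
]

_SV_TYPES = {"DEL", "INS", "DUP", "INV"}
_STR_UNITS = ("A", "AC", "ACG", "ACGT", "ACGTA", "ACGTAC")


# ---------------------------------------------------------------------------
# reading


def _scan_sample_columns(vcf, popmap: PopulationMap | None):
    """Indices (into the VCF sample list) of the samples to keep."""
    if popmap is None:
        return list(range(len(vcf.samples))), tuple(vcf.samples)
    wanted = set(popmap.scan_samples)
    keep, names = [], []
    for i, s in enumerate(vcf.samples):
        if s in wanted:
            keep.append(i)
            names.append(s)
        else:
            logger.warning("sample %s absent from population map; excluded", s)
    missing = wanted - set(names)
    if missing:
        raise ValueError(f"popmap samples missing from VCF: {sorted(missing)}")
    return keep, tuple(names)


def load_genotypes(path, mode: str, popmap: PopulationMap | None = None, phased: bool = True):
    """Load a VCF as haplotype panels, a genotype matrix, or SV/STR records.

    mode='snp' with ``phased=True`` returns {chrom: HaplotypePanel} and
    requires '|' separators; with ``phased=False`` it returns
    {chrom: GenotypeMatrix} and tolerates missing genotypes.  mode='sv' /
    'str' return record lists.  Samples are restricted to the two scan
    populations of ``popmap`` when given.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    keep, names = _scan_sample_columns(vcf, popmap)
    if mode == "snp":
        return _load_snps(vcf, keep, names, phased)
    if mode == "sv":
        return _load_svs(vcf, keep, names)
    if mode == "str":
        return _load_strs(vcf, keep, names)
    raise ValueError(f"unknown mode {mode!r}")


def _load_snps(vcf, keep, names, phased):
    per_chrom: dict[str, list] = {}
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        arr = v.genotype.array()[keep]
        alleles = arr[:, :2]
        if phased:
            if np.any(alleles < 0):
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS} in phased panel")
            if np.any(arr[:, 2] == 0):
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS}")
        per_chrom.setdefault(v.CHROM, []).append(
            (v.POS - 1, alleles.astype(np.int8), v.REF, v.ALT[0]))
    if n_multi:
        logger.warning("excluded %d multi-allelic SNP records", n_multi)
    out = {}
    for chrom, rows in per_chrom.items():
        positions = np.array([p for p, *_ in rows], dtype=np.int64)
        geno = np.stack([g for _, g, *_ in rows], axis=1)  # (n_samples, m, 2)
        ref = np.array([r for *_, r, _ in rows], dtype=object)
        alt = np.array([a for *_, a in rows], dtype=object)
        if phased:
            haps = np.empty((2 * len(names), positions.size), dtype=np.int8)
            haps[0::2] = geno[:, :, 0]
            haps[1::2] = geno[:, :, 1]
            out[chrom] = HaplotypePanel(chrom, positions, haps, names,
                                        ref_alleles=ref, alt_alleles=alt)
        else:
            out[chrom] = GenotypeMatrix(chrom, positions, geno, names)
    return out


def _load_svs(vcf, keep, names):
    records = []
    for v in vcf:
        svtype = v.INFO.get("SVTYPE")
        if svtype not in _SV_TYPES:
            logger.warning("rejecting SV %s with unknown SVTYPE=%s", v.ID, svtype)
            continue
        if len(v.ALT) != 1:
            logger.warning("rejecting multi-allelic SV %s", v.ID)
            continue
        start = v.POS - 1
        end = int(v.INFO.get("END", v.POS))
        svlen = abs(int(v.INFO.get("SVLEN", end - start)))
        arr = v.genotype.array()[keep, :2].astype(np.int8)
        records.append(SvRecord(v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, start, end,
                                svtype, max(svlen, 1), arr, names))
    return records


def _load_strs(vcf, keep, names):
    records = []
    for v in vcf:
        ru = v.INFO.get("RU")
        if not ru:
            logger.warning("rejecting STR %s without RU annotation", v.ID)
            continue
        period = len(ru)
        alleles = [v.REF] + list(v.ALT)
        counts = []
        bad = False
        for a in alleles:
            if len(a) % period != 0:
                bad = True
                break
            counts.append(len(a) // period)
        if bad:
            logger.warning("rejecting STR %s: allele length not a multiple of unit", v.ID)
            continue
        counts = np.array(counts, dtype=np.int16)
        arr = v.genotype.array()[keep, :2].astype(np.int64)
        geno = np.where(arr >= 0, counts[np.clip(arr, 0, None)], -1).astype(np.int16)
        records.append(StrRecord(v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS - 1,
                                 period, geno, names))
    return records


def load_annotation(gff_path, fasta_path=None):
    """Gene models from GFF3 (+ reference sequences when FASTA given).

    One GeneModel per gene; when a gene has several mRNAs the one with the
    longest total CDS is retained.  GFF3 1-based inclusive intervals become
    0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    reference = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        reference = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if reference is not None and gene.seqid not in reference:
            raise ValueError(f"gene {gene.id} on contig {gene.seqid} absent from FASTA")
        best_cds: list = []
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = []
            for c in db.children(mrna, featuretype="CDS"):
                if c.frame in (".", None):
                    logger.warning("CDS of %s lacks phase; assuming 0", gene.id)
                    phase = 0
                else:
                    phase = int(c.frame)
                cds.append((c.start - 1, c.end, phase))
            if sum(e - s for s, e, _ in cds) > sum(e - s for s, e, _ in best_cds):
                best_cds = cds
        exons = [(s, e) for s, e, _ in sorted(best_cds)]
        genes.append(GeneModel(gene.id, gene.seqid, gene.start - 1, gene.end,
                               gene.strand, cds=sorted(best_cds), exons=exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return (genes, reference) if fasta_path is not None else (genes, None)


def read_bed(path) -> dict[str, np.ndarray]:
    """BED intervals as {chrom: (k, 2) int array}."""
    out: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return {c: np.array(v, dtype=np.int64) for c, v in out.items()}


def read_layout_from_vcf(path) -> GenomeLayout:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names, lengths = [], []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(","))
            names.append(fields["ID"])
            lengths.append(int(fields["length"]))
    return GenomeLayout(tuple(names), tuple(lengths))


# ---------------------------------------------------------------------------
# writing


def write_bed(path, intervals) -> None:
    """Write (chrom, start, end[, name...]) tuples, sorted, 0-based half-open."""
    with open(path, "w") as fh:
        for row in sorted(intervals):
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_fasta(path, sequences: dict[str, bytes], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            s = seq.decode() if isinstance(seq, (bytes, bytearray)) else str(seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def _vcf_header(layout: GenomeLayout, samples, extra_lines=()) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in layout.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.extend(extra_lines)
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    return "\n".join(lines) + "\n"


_GT_PHASED = np.array(["0|0", "0|1", "1|0", "1|1"])
_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}


def write_snp_vcf(path, panels: dict[str, HaplotypePanel], layout: GenomeLayout,
                  reference: dict[str, bytes] | None = None) -> None:
    """Phased biallelic SNP VCF; REF is the reference base (= ancestral)."""
    first = next(iter(panels.values()))
    samples = first.samples
    with open(path, "w") as fh:
        fh.write(_vcf_header(layout, samples))
        for chrom in layout.names:
            if chrom not in panels:
                continue
            panel = panels[chrom]
            code = 2 * panel.haplotypes[0::2].astype(np.int16) + panel.haplotypes[1::2]
            gt = _GT_PHASED[code]  # (n_samples, m)
            seq = reference.get(chrom) if reference else None
            for j, pos in enumerate(panel.positions):
                ref = chr(seq[pos]) if seq is not None else "A"
                alt = _ALT_OF.get(ref, "T")
                fh.write(
                    f"{chrom}\t{pos + 1}\tsnp_{chrom}_{pos + 1}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                    + "\t".join(gt[:, j]) + "\n"
                )


_GT_UNPHASED = np.array(["0/0", "0/1", "1/0", "1/1"])


def write_sv_vcf(path, svs: list[SvRecord], layout: GenomeLayout) -> None:
    extra = [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
    ]
    svs = sorted(svs, key=lambda r: (r.chrom, r.start))
    samples = svs[0].samples if svs else ()
    with open(path, "w") as fh:
        fh.write(_vcf_header(layout, samples, extra))
        for r in svs:
            gts = []
            for a, b in r.genotypes:
                gts.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            info = f"SVTYPE={r.svtype};END={r.end};SVLEN={r.length}"
            fh.write(f"{r.chrom}\t{r.start + 1}\t{r.sv_id}\tN\t<{r.svtype}>\t.\tPASS\t{info}\tGT\t"
                     + "\t".join(gts) + "\n")


def write_str_vcf(path, strs: list[StrRecord], layout: GenomeLayout) -> None:
    extra = [
        '##INFO=<ID=RU,Number=1,Type=String,Description="Repeat unit">',
        '##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="Repeat unit length">',
    ]
    strs = sorted(strs, key=lambda r: (r.chrom, r.pos))
    samples = strs[0].samples if strs else ()
    with open(path, "w") as fh:
        fh.write(_vcf_header(layout, samples, extra))
        for r in strs:
            unit = _STR_UNITS[r.period - 1]
            counts = r.alleles()
            if counts.size == 0:
                continue
            index = {int(c): i for i, c in enumerate(counts)}
            ref = unit * int(counts[0])
            alts = ",".join(unit * int(c) for c in counts[1:]) or "."
            gts = []
            for a, b in r.genotypes:
                gts.append("./." if a < 0 or b < 0 else f"{index[int(a)]}/{index[int(b)]}")
            info = f"RU={unit};PERIOD={r.period}"
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.str_id}\t{ref}\t{alts}\t.\tPASS\t{info}\tGT\t"
                     + "\t".join(gts) + "\n")


def write_gff3(path, genes: list[GeneModel], layout: GenomeLayout) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in layout.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(f"{g.chrom}\tpolyscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tpolyscan\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna_id};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tpolyscan\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna_id}.exon{k};Parent={mrna_id}\n")
            for k, (s, e, phase) in enumerate(g.cds, 1):
                fh.write(f"{g.chrom}\tpolyscan\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
                         f"ID={mrna_id}.cds{k};Parent={mrna_id}\n")


def write_tables(results: dict[str, pd.DataFrame], out_dir, config=None, seed=None) -> None:
    """Write each result frame as TSV (and BED for interval frames).

    Output is deterministic: fixed column order, fixed float format, rows
    sorted by (chrom, start) when those columns exist.  A run log records
    the configuration and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in results.items():
        df = df.copy()
        if {"chrom", "start"} <= set(df.columns):
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        if {"chrom", "start", "end"} <= set(df.columns):
            write_bed(out_dir / f"{name}.bed",
                      df[["chrom", "start", "end"]].itertuples(index=False, name=None))
    log = {"seed": seed}
    if config is not None:
        log["config"] = {k: v for k, v in vars(config).items() if not k.startswith("_")
                         and isinstance(v, (int, float, str, bool, type(None)))}
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
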