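"""Shared data model for the divergence-scan pipeline.

All coordinates are 0-based, half-open.  VCF (1-based) and GFF3 (1-based,
inclusive) intervals are converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "PopulationMap",
    "HaplotypePanel",
    "GenotypeMatrix",
    "SvRecord",
    "StrRecord",
    "GeneModel",
    "CandidateGeneList",
    "Window",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if any(L <= 0 for L in self.lengths):
            raise ValueError("chromosome lengths must be > 0")

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.names.index(chrom)]

    def items(self):
        return zip(self.names, self.lengths)


@dataclass(frozen=True)
class PopulationMap:
    """Sample -> population label.

    Exactly two labels take part in the scans; an optional third label
    (conventionally ``hybrid``) is carried through I/O but excluded from all
    statistics, mirroring a hybrid colony kept out of outlier detection.
    """

    assignments: dict[str, str]
    pop_a: str = "popA"
    pop_b: str = "popB"

    def __post_init__(self) -> None:
        for pop in (self.pop_a, self.pop_b):
            if len(self.samples(pop)) < 2:
                raise ValueError(f"population {pop!r} needs >=2 samples")

    def samples(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    @property
    def scan_samples(self) -> list[str]:
        return [s for s, p in self.assignments.items() if p in (self.pop_a, self.pop_b)]

    def population_of(self, sample: str) -> str:
        return self.assignments[sample]

    @classmethod
    def from_tsv(cls, path, pop_a: str = "popA", pop_b: str = "popB") -> "PopulationMap":
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sample, pop = line.split("\t")[:2]
                if sample in assignments:
                    raise ValueError(f"sample {sample!r} listed twice in popmap")
                assignments[sample] = pop
        return cls(assignments, pop_a=pop_a, pop_b=pop_b)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for one chromosome.

    ``haplotypes`` is an (n_haplotypes, n_sites) int8 matrix of {0, 1};
    haplotypes 2i and 2i+1 belong to ``samples[i]``.  ``ancestral_is_ref``
    marks sites where the reference allele is taken as ancestral (the
    default polarisation).
    """

    chrom: str
    positions: np.ndarray
    haplotypes: np.ndarray
    samples: tuple[str, ...]
    ancestral_is_ref: np.ndarray = field(default=None)  # type: ignore[assignment]
    ref_alleles: np.ndarray | None = None  # REF base per site (optional)
    alt_alleles: np.ndarray | None = None  # ALT base per site (optional)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ValueError("haplotype matrix and positions disagree")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("expected two haplotypes per diploid sample")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.ancestral_is_ref is None:
            self.ancestral_is_ref = np.ones(self.positions.size, dtype=bool)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.positions.size

    def alt_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per site."""
        return self.haplotypes.mean(axis=0)

    def derived_frequencies(self) -> np.ndarray:
        """Derived-allele frequency per site, given the polarisation."""
        p_alt = self.alt_frequencies()
        return np.where(self.ancestral_is_ref, p_alt, 1.0 - p_alt)

    def subset_samples(self, samples: list[str]) -> "HaplotypePanel":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = []
        for s in samples:
            i = index[s]
            rows.extend((2 * i, 2 * i + 1))
        return HaplotypePanel(
            self.chrom,
            self.positions,
            self.haplotypes[rows],
            tuple(samples),
            self.ancestral_is_ref,
            self.ref_alleles,
            self.alt_alleles,
        )

    def site_slice(self, start: int, end: int) -> slice:
        """Column slice of sites with position in [start, end)."""
        lo, hi = np.searchsorted(self.positions, [start, end])
        return slice(int(lo), int(hi))


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (allele indices, -1 = missing) for one chromosome."""

    chrom: str
    positions: np.ndarray
    genotypes: np.ndarray  # (n_samples, n_sites, 2) int8
    samples: tuple[str, ...]
    n_accessible: int | None = None  # genotyped positions incl. monomorphic

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), self.positions.size, 2):
            raise ValueError("genotype array shape mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in samples]
        return GenotypeMatrix(
            self.chrom, self.positions, self.genotypes[rows], tuple(samples), self.n_accessible
        )


@dataclass
class SvRecord:
    """One biallelic structural variant with diploid genotypes."""

    sv_id: str
    chrom: str
    start: int  # 0-based
    end: int
    svtype: str  # DEL | INS | DUP | INV
    length: int
    genotypes: np.ndarray  # (n_samples, 2) int8, -1 missing
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"SV {self.sv_id}: end < start")
        if self.length <= 0:
            raise ValueError(f"SV {self.sv_id}: length must be > 0")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


@dataclass
class StrRecord:
    """One short tandem repeat locus; alleles are integer repeat counts."""

    str_id: str
    chrom: str
    pos: int  # 0-based
    period: int  # repeat-unit length, 1..6
    genotypes: np.ndarray  # (n_samples, 2) int16 repeat counts, -1 missing
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.period <= 6:
            raise ValueError(f"STR {self.str_id}: period must be in [1, 6]")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)

    def alleles(self) -> np.ndarray:
        """Distinct observed repeat counts (missing excluded)."""
        g = self.genotypes[self.genotypes >= 0]
        return np.unique(g)


@dataclass
class GeneModel:
    """One protein-coding gene: span, strand, CDS segments with phase."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.cds = sorted(self.cds)
        self.exons = sorted(self.exons)
        for s, e, _ in self.cds:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.gene_id}: CDS outside gene span")
        for (s1, e1, _), (s2, _e2, _) in zip(self.cds, self.cds[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS segments")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds)


@dataclass(frozen=True)
class CandidateGeneList:
    """Curated candidate gene symbols, matched case-insensitively."""

    symbols: frozenset[str]

    @classmethod
    def from_iterable(cls, symbols) -> "CandidateGeneList":
        return cls(frozenset(s.casefold() for s in symbols))

    @classmethod
    def from_tsv(cls, path) -> "CandidateGeneList":
        with open(path) as fh:
            syms = [ln.split("\t")[0].strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls.from_iterable(syms)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self.symbols


@dataclass(frozen=True)
class Window:
    """One sliding-window interval with accessibility bookkeeping."""

    chrom: str
    start: int
    end: int
    n_accessible: int = 0
    n_variant: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.n_variant > self.n_accessible:
            raise ValueError("n_variant cannot exceed n_accessible")
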