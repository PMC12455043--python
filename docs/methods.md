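# Methods

`polyscan` implements a three-track divergence scan between two weakly
differentiated diploid populations — the study design used for comparing
two seabird subspecies sampled from one colony each — together with a
synthetic-data generator that reproduces the statistical structure the
scans consume. This note records the models, the defaults that matter,
the numerical choices, and what the synthetic data does and does not
emulate.

## Window statistics (SNP track)

All SNP statistics are computed on phased biallelic haplotype panels in
50 kb sliding windows with a 25 kb step (both configurable). Denominators
are *accessible-site* counts — genotyped positions including monomorphic
ones — supplied by a BED mask; this mirrors an all-sites genotyping panel
without materialising monomorphic VCF records. Windows whose accessible
fraction falls below 10% of the window length are nulled (NaN), never
zeroed; the threshold is configurable and deliberately permissive because
the synthetic mask covers the chromosomes completely.

Per window:

- **π** per population: Σ over sites of the unbiased per-site
  heterozygosity 2p̂(1−p̂)·n/(n−1), divided by accessible sites (n =
  haplotypes). Equal, by algebra, to the mean pairwise Hamming distance
  per accessible site — the test suite holds the two routes to 1e−12.
- **d_XY**: Σ [p_A(1−p_B) + p_B(1−p_A)] per accessible site.
- **window F_ST**: the Hudson-style 1 − π̄_within/d_XY, matching the
  popgenWindows lineage of window estimators; null when d_XY = 0.
- **Tajima's D**: standard coefficients (a1…e2), computed from the
  population-B panel by default — within-population statistics for the
  composite come from one population by design, with a config override
  (`tajima_pop`, `within_pop`).
- Per-locus F_ST (used for SVs and site-level checks) is the Weir &
  Cockerham (1984) θ from the a/b/c variance components, with
  pairwise-available handling of missing genotypes. Window-level and
  locus-level estimators are intentionally different and labelled.

## Haplotype statistics

EHH at distance x is the probability that two haplotypes carrying the
core allele are identical at every site from the core to x (the core
site included). iHH integrates the EHH decay curve over physical
distance by trapezoid, truncating with linear interpolation where the
curve first crosses the cutoff (default 0.05). Physical distance stands
in for genetic distance — no recombination map exists for the system.

- **iHS** = ln(iHH_ancestral/iHH_derived), standardised within 20
  equal-width derived-allele-frequency bins; cores with derived frequency
  outside [0.05, 0.95] are skipped. The ancestral allele is the reference
  allele by default (`ancestral: reference`), with a major-allele
  fallback — the synthetic VCF makes the reference allele ancestral by
  construction.
- **xpEHH** = ln(iHH_popA/iHH_popB) with pooled-allele EHH per population
  (Sabeti 2007 convention), standardised genome-wide. Negative values
  mean longer homozygosity in population B.
- Curves are abandoned (core nulled) when they hit an inter-site gap
  larger than 200 kb, and truncated at ±500 kb from the core; both guards
  are configurable and mirror the gap/extension guards of the standard
  EHH tools.
- |iHS| and |xpEHH| are averaged per 50 kb window for the composite.

The site-by-site decay loop is numba-compiled and operates on the carrier
subset of each allele class, so low-frequency classes with long
homozygosity tracts (common in founder-structured panels) stay cheap. A
second, curve-emitting kernel backs the public `ehh_curve` API; the two
are cross-checked against each other and against explicit pair
enumeration in the tests.

## DCMS composite

Each of the five statistics (π, Tajima's D, window F_ST, mean |iHS|,
mean |xpEHH|) becomes a one-tailed rank-based empirical p-value,
p = r/(n+1). Tail directions encode "selection-like" signal: lower for π
and Tajima's D, upper for the rest; they are config-exposed because the
direction convention is a design choice, not a published constant.

DCMS_j = Σ_i w_i ln((1−p_ij)/p_ij) with w_i = 1/Σ_k |r_ik|, where r is
the Pearson correlation matrix of the p-value columns over complete
windows ("decorrelation": duplicated signal is down-weighted, so a
duplicated column reproduces the single-column score exactly — an exact
test). Natural log is used; the base only rescales scores monotonically.
Windows with some null statistics are scored from the available columns
and rescaled by total/available weight (logged); fully null windows stay
null.

Significance: an intercept-only Huber M-estimate (tuning constant 1.345)
gives a robust location; scale is 1.4826·MAD of the residuals; p is the
upper normal tail of the standardised score. With ~10–15% of windows
carrying sweep signal, the robust fit holds the null location where a
plain mean would be dragged upward (verified by a contamination
experiment in the tests). Benjamini–Hochberg q-values follow (Storey's
procedure was considered and not needed; BH is the conventional reading
of "transformed to q-values"). Windows with q < 0.05 are merged when
overlapping or adjacent; regions are "supported" with ≥ 2 member windows.

## Per-locus scans

- **SVs**: Weir–Cockerham θ per biallelic SV; loci with > 20% missing
  genotypes are excluded, the rest use pairwise-available counts. Fixed
  differences (one population entirely homozygous reference, the other
  entirely homozygous alternate, no missing calls) are reported
  separately.
- **STRs**: loci must be called in every individual and exceed MAF 0.1,
  with the multi-allelic convention MAF = 1 − max allele frequency (the
  source procedure does not define MAF for > 2 alleles; this is the
  conservative literal reading). Differentiation is Jost's D with the
  Nei–Chesson bias corrections (mmod lineage); the uncorrected parametric
  variant backs the exactness tests and the two agree in the large-sample
  limit.
- Both statistic vectors are fitted to a normal distribution by maximum
  likelihood (sample mean, ML s.d.) and converted to one-tailed upper
  p-values, BH q-values, and outlier flags at q < 0.05 — the procedure
  applied literally even though both statistics are bounded. A
  skewness/kurtosis diagnostic is logged whenever the input is visibly
  non-normal. Under a *pure* null (no divergent loci) this literal
  procedure is mildly anti-conservative — a few per cent of loci flagged,
  driven by the right skew of the per-locus θ sampling distribution at
  weak differentiation — which is exactly the situation the diagnostic
  flags. On panels that do contain strongly divergent loci, those loci
  widen the fitted σ and the neutral flag rate drops well below 1%.

## Annotation and reporting

- **Gene proximity**: a hit is ≥ 1 bp overlap between the feature (DCMS
  regions as intervals, SV/STR outliers as points) and the gene span
  extended by 8 kb both sides — 8 kb being half the mean intergenic
  distance. Distance is measured from the gene span, not the CDS.
- **Permutation enrichment**: each permutation re-places every feature
  uniformly on its own chromosome, preserving length (overlaps allowed);
  statistic = features with ≥ 1 gene hit; two-sided p with add-one
  correction, so p ≥ 1/(n_perm+1). Type-I error calibration is tested
  against the exact binomial band over 200 null replicates.
- **Fixed SNP differences** are located against the gene models
  (CDS > intron > intergenic precedence) and CDS sites are classified
  synonymous/missense/nonsense by rebuilding the codon from the spliced
  CDS in transcript orientation (reverse-complemented on '−' strand,
  phase-aware). This is a minimal effect classifier, not a full effect
  ontology.
- **STR-to-CDS density**: signed, orientation-aware distance to the
  nearest CDS start (and separately end); Gaussian KDE per repeat period
  over ±50 kb, Silverman bandwidth by default, renormalised to integrate
  to one over the emitted range.
- **Summaries**: Pearson correlations among the window statistics
  (genome-wide and within outlier windows), Wilcoxon rank-sum
  (midranks, normal approximation with continuity correction) between
  outlier and non-outlier windows, and a Patterson-scaled genotype PCA
  per variant type as a population-structure check.

## Synthetic data

The generator plants known signal rather than simulating demography: the
inference layer, not the coalescent, is the target.

- **Sites** are a Poisson process with density θ/E[2p(1−p)] for ancestral
  frequencies p ~ Uniform(0.05, 0.95); θ defaults to 0.0036 per bp.
- **Frequencies** follow the Balding–Nichols model: each population draws
  Beta(p(1−F)/F, (1−p)(1−F)/F) around the ancestral frequency; background
  F defaults to 0.02, a stand-in for weak seabird-scale differentiation
  (the source reports no genome-wide F_ST for the pair) and a config knob.
- **Haplotypes**: 30 founders per population drawn site-wise from the
  population frequencies; 20 diploids per population are founder mosaics
  with switch probability 1e−6 per bp, giving long shared tracts and a
  realistic EHH substrate. Population B's per-site diversity is scaled to
  94% of population A's by monomorphising a corresponding fraction of its
  founder sites.
- Through this sampling chain the expected per-bp quantities are
  d_XY ≈ θ (independent of F), π_A ≈ θ(1−F)(1−1/30) and π_B ≈ 0.94·π_A,
  so θ = 0.0036 puts the window medians near 0.0035/0.0033/0.0035 with
  every target within a few per cent — this calibration was fixed
  analytically from the sampling chain, before any end-to-end run.
- **Sweeps**: ten non-overlapping 100 kb regions (five per chromosome);
  inside each, every population-B haplotype is replaced by a designated
  sweep founder with probability 0.8. This produces low π_B, elevated
  F_ST, negative Tajima's D and long-range homozygosity without forward
  simulation; `f_sweep` directly controls signal strength.
- **SVs**: 2,000 loci, type weights 0.7/0.1/0.1/0.1 (DEL/INS/DUP/INV),
  lengths log-uniform 50 bp–100 kb; 2% divergent with |Δp| ≥ 0.6 and
  frequencies clipped to [0.1, 0.9] so sampled fixed differences stay
  rare (none in the default dataset), matching the empty fixed-SV result
  the scan is expected to reproduce.
- **STRs**: 5,000 loci, period weighted toward 1–2 bp; allele
  distributions are discretised Gaussians over repeat counts (s.d. 1.5
  repeats) with a small neutral between-population mean jitter
  (s.d. 0.3, chosen so the parametric Jost's D of neutral loci stays
  below 0.1 for ≥ 95% of loci); 2% divergent with mean shifts of 2–4
  repeat units; 2% of loci carry one missing call to exercise the
  call-rate filter.
- **Annotation**: genes laid left-to-right with Exp(16 kb) intergenic
  gaps (so half the mean gap recovers the 8 kb proximity constant), 2–8
  CDS segments each with GFF3-consistent phases and total length
  divisible by three, on a random reference with start/stop codons
  written in frame. Genes overlapping sweeps are recorded in the truth
  files.
- An optional third "hybrid" population (mosaics over the pooled founder
  panels) is available behind `n_hybrids` and excluded from all scans,
  mirroring the study's design of carrying a hybrid colony through
  genotyping but not outlier detection.

**What the generator does not emulate**: coalescent linkage structure and
recombination-rate variation, sequencing error and genotyping artifacts,
SV-caller behaviour and discovery bias, STR mutation processes, and any
real gene content. Passing recovery tests therefore demonstrate that the
statistics and decision rules behave as intended on data with the assumed
frequency/haplotype structure — not that the pipeline is robust to
caller artifacts or demographic confounding in real data.

## Problem sizes and determinism

The default dataset is 2 chromosomes × 5 Mb, 20+20 diploids, ~100k SNPs,
2,000 SVs and 5,000 STRs — large enough that window medians are stable to
a few per cent and sweep recovery is reproducible, small enough for a
desk-scale run (full three-track scan ≈ 1 minute). Multi-seed checks in
the test suite use five seeds; sub-sampled configurations (single 1–2 Mb
chromosome, fewer loci) back the generator-law tests where genome scale
adds nothing. All randomness flows from a single integer seed through
`numpy.random.default_rng`; dataset emission is byte-reproducible.

## Known limitations

- The normal-fit outlier procedure is anti-conservative under a pure null
  (see above); it is retained deliberately as the faithful procedure,
  with a logged diagnostic.
- Empirical p-values are granular at 1/(n_windows+1); with ~400 windows
  the DCMS inputs are coarser than in a full-genome run (~44k windows).
- EHH integration treats the ±500 kb guard as a hard truncation rather
  than discarding non-converged cores; with the default site density the
  cutoff is reached far earlier for all but sweep cores.
- The STR repeat-count contract (RU/PERIOD INFO fields, alleles as exact
  unit multiples) is a minimal dialect; records violating it are dropped
  with a warning rather than repaired.
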