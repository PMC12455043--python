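"""Gene proximity, permutation enrichment, fixed differences, coding-effect
classification, STR density, candidate cross-referencing and summaries."""

import numpy as np
import pandas as pd
import pytest

from polyscan.annotate import (
    classify_coding_effect,
    crossref_candidates,
    fixed_differences,
    gene_proximity,
    genotype_pca,
    outlier_exclusivity,
    permutation_enrichment,
    str_cds_density,
    summary_compare,
)
from polyscan.model import (
    CandidateGeneList,
    GeneModel,
    GenomeLayout,
    GenotypeMatrix,
    StrRecord,
)


def _features(rows):
    return pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end", "kind"])


def _gene(gene_id="g1", start=10_000, end=20_000, strand="+", cds=None, chrom="chr1"):
    return GeneModel(gene_id, chrom, start, end, strand,
                     cds=cds or [(start, end, 0)],
                     exons=[(s, e) for s, e, _ in (cds or [(start, end, 0)])])


class TestGeneProximity:
    def test_half_open_boundary(self):
        gene = _gene()
        inside = _features([("p1", "chr1", 27_999, 28_000, "SNP")])
        outside = _features([("p2", "chr1", 28_000, 28_001, "SNP")])
        assert len(gene_proximity(inside, [gene])) == 1
        assert len(gene_proximity(outside, [gene])) == 0

    def test_overlap_distance_zero(self):
        gene = _gene()
        window = _features([("w1", "chr1", 0, 50_000, "SNP")])
        hits = gene_proximity(window, [gene])
        assert hits.iloc[0]["distance"] == 0
        assert hits.iloc[0]["relation"] == "overlaps_gene"

    def test_distance_zero_equals_plain_intersection(self):
        """With distance 0 the rule is exactly interval overlap (brute force)."""
        rng = np.random.default_rng(0)
        genes = []
        for i in range(50):
            s = int(rng.integers(0, 900_000))
            genes.append(_gene(f"g{i}", s, s + int(rng.integers(100, 5_000))))
        rows = []
        for i in range(1000):
            s = int(rng.integers(0, 900_000))
            rows.append((f"f{i}", "chr1", s, s + int(rng.integers(1, 3_000)), "SNP"))
        feats = _features(rows)
        hits = gene_proximity(feats, genes, distance=0)
        got = set(zip(hits["feature_id"], hits["gene_id"]))
        expected = set()
        for f in feats.itertuples(index=False):
            for g in genes:
                if f.start < g.end and g.start < f.end:
                    expected.add((f.feature_id, g.gene_id))
        assert got == expected

    def test_shared_gene_counted_once(self):
        gene = _gene()
        feats = _features([("a", "chr1", 12_000, 12_001, "SNP"),
                           ("b", "chr1", 13_000, 13_001, "SV"),
                           ("c", "chr1", 14_000, 14_001, "STR")])
        hits = gene_proximity(feats, [gene])
        sets = {k: set(hits.loc[hits["kind"] == k, "gene_id"]) for k in ("SNP", "SV", "STR")}
        excl = outlier_exclusivity(sets)
        assert len(excl) == 1
        assert not excl.iloc[0]["exclusive"]
        assert excl.iloc[0]["methods"] == "SNP, SV, STR"


class TestPermutation:
    LAYOUT = GenomeLayout(("chr1",), (1_000_000,))

    def test_observed_equals_null(self):
        # genes cover the whole chromosome: every placement hits
        gene = _gene("g1", 0, 1_000_000)
        feats = _features([(f"f{i}", "chr1", i * 1000, i * 1000 + 100, "SNP")
                           for i in range(5)])
        res = permutation_enrichment(feats, [gene], self.LAYOUT, n_perm=100, seed=1)
        assert res.observed == 5
        assert np.all(res.null_counts == 5)
        assert res.p == 1.0

    def test_add_one_bound(self):
        # a tiny gene island the observed features all hit but random
        # placement essentially never does
        gene = _gene("g1", 500_000, 500_050)
        feats = _features([(f"f{i}", "chr1", 500_000 + i, 500_001 + i, "SNP")
                           for i in range(10)])
        res = permutation_enrichment(feats, [gene], self.LAYOUT, n_perm=1000, seed=2)
        assert res.observed == 10
        assert res.p == pytest.approx(2 / 1001)

    def test_feature_longer_than_chromosome(self):
        feats = _features([("f0", "chr1", 0, 2_000_000, "SNP")])
        with pytest.raises(ValueError):
            permutation_enrichment(feats, [_gene()], self.LAYOUT, n_perm=10, seed=0)

    def test_type_one_error_calibration(self):
        """Null features placed uniformly: fraction of p < 0.05 over 200
        replicates sits in the exact binomial 95% interval around 0.05."""
        from scipy.stats import binom

        rng = np.random.default_rng(3)
        genes = []
        pos = 0
        while pos < 900_000:
            glen = int(rng.integers(1_000, 6_000))
            genes.append(_gene(f"g{pos}", pos, pos + glen))
            pos += glen + int(rng.integers(5_000, 40_000))
        n_rep = 200
        hits = 0
        for rep in range(n_rep):
            starts = rng.integers(0, 999_000, size=30)
            feats = _features([(f"f{i}", "chr1", int(s), int(s) + 500, "SNP")
                               for i, s in enumerate(starts)])
            res = permutation_enrichment(feats, genes, self.LAYOUT,
                                         n_perm=200, seed=1000 + rep)
            if res.p < 0.05:
                hits += 1
        lo, hi = binom.ppf([0.025, 0.975], n_rep, 0.05)
        assert lo <= hits <= hi


class TestFixedDifferences:
    def _gm(self, geno):
        geno = np.asarray(geno, dtype=np.int8)
        samples = tuple(f"s{i}" for i in range(geno.shape[0]))
        return GenotypeMatrix("chr1", np.arange(geno.shape[1]) * 10 + 5, geno, samples)

    def test_detected(self):
        geno = np.zeros((6, 1, 2), dtype=np.int8)
        geno[3:] = 1
        gm = self._gm(geno)
        out = fixed_differences(gm, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert len(out) == 1
        assert out.iloc[0]["alt_fixed_in"] == "popB"

    def test_heterozygote_disqualifies(self):
        geno = np.zeros((6, 1, 2), dtype=np.int8)
        geno[3:] = 1
        geno[0, 0] = [0, 1]
        out = fixed_differences(self._gm(geno), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert len(out) == 0

    def test_missing_disqualifies(self):
        geno = np.zeros((6, 1, 2), dtype=np.int8)
        geno[3:] = 1
        geno[4, 0] = [-1, -1]
        out = fixed_differences(self._gm(geno), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert len(out) == 0


def test_fixed_snp_sites_pipeline():
    """Panel-level fixed differences are found and classified in one pass."""
    from polyscan.model import HaplotypePanel, PopulationMap
    from polyscan.pipeline import fixed_snp_sites

    # site 0 fixed (A: ref, B: alt) inside a CDS; site 1 polymorphic
    haps = np.array([[0, 0], [0, 1], [0, 0], [0, 0],
                     [1, 0], [1, 1], [1, 0], [1, 1]], dtype=np.int8)
    panel = HaplotypePanel("chr1", np.array([12, 30]), haps,
                           ("a1", "a2", "b1", "b2"),
                           ref_alleles=np.array(["G", "C"], dtype=object),
                           alt_alleles=np.array(["A", "T"], dtype=object))
    popmap = PopulationMap({"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB"})
    seq = "N" * 10 + "ATGAAATAA" + "N" * 30
    gene = _gene("g1", 10, 19, cds=[(10, 19, 0)])
    out = fixed_snp_sites({"chr1": panel}, popmap, [gene], {"chr1": seq})
    assert len(out) == 1
    row = out.iloc[0]
    assert row["pos"] == 12 and row["alt_fixed_in"] == "popB"
    assert row["context"] == "CDS"
    assert row["effect"] == "missense"  # ATG -> ATA (Met -> Ile)


class TestCodingEffect:
    def _reference(self, seq):
        return {"chr1": seq}

    def test_synonymous_third_position(self):
        # gene [10, 22): codons ATG GGA TAA; GGA->GGG is synonymous
        seq = "N" * 10 + "ATGGGATAA" + "N" * 10
        gene = _gene("g1", 10, 19, cds=[(10, 19, 0)])
        out = classify_coding_effect("chr1", 15, "A", "G", [gene], self._reference(seq))
        assert out["effect"] == "synonymous"
        # GGA->GAA (position 2) is missense
        out = classify_coding_effect("chr1", 14, "G", "A", [gene], self._reference(seq))
        assert out["effect"] == "missense"

    def test_intergenic(self):
        seq = "A" * 100
        gene = _gene("g1", 10, 19, cds=[(10, 19, 0)])
        out = classify_coding_effect("chr1", 50, "A", "G", [gene], self._reference(seq))
        assert out["context"] == "intergenic"
        assert out["effect"] == "non_coding"

    def test_intron(self):
        seq = "A" * 100
        gene = _gene("g1", 10, 40, cds=[(10, 19, 0), (31, 40, 0)])
        out = classify_coding_effect("chr1", 25, "A", "G", [gene], self._reference(seq))
        assert out["context"] == "intron"

    def test_reference_mismatch(self):
        seq = "A" * 100
        gene = _gene("g1", 10, 19, cds=[(10, 19, 0)])
        with pytest.raises(ValueError, match="mismatch"):
            classify_coding_effect("chr1", 12, "C", "G", [gene], self._reference(seq))

    def test_minus_strand_two_codon_gene(self):
        """Manual reverse-complement construction on a 2-codon toy gene.

        Genomic [10, 16) = 'TTACAT'; minus-strand transcript is
        revcomp = 'ATGTAA' (ATG TAA).  A plus-strand A>C change at genomic
        position 12 edits transcript base index 3 (T>G): TAA -> GAA,
        replacing the stop with Glu (read through, classified missense).
        """
        seq = "N" * 10 + "TTACAT" + "N" * 10
        gene = _gene("g1", 10, 16, strand="-", cds=[(10, 16, 0)])
        out = classify_coding_effect("chr1", 12, "A", "C", [gene], self._reference(seq))
        assert out["context"] == "CDS"
        assert out["effect"] == "missense"
        # and a change creating a stop is nonsense: position 11 (transcript
        # codon 2 middle base): TAA -> TAA? choose pos 14 in codon 1:
        # transcript index 1: ATG -> A?G with ? = revcomp(alt)
        out = classify_coding_effect("chr1", 14, "A", "T", [gene], self._reference(seq))
        assert out["effect"] == "missense"


class TestStrCdsDensity:
    def _strs(self, positions, period=2):
        samples = ("s1", "s2")
        geno = np.full((2, 2), 10, dtype=np.int16)
        return [StrRecord(f"str_{i}", "chr1", int(p), period, geno.copy(), samples)
                for i, p in enumerate(positions)]

    def test_point_mass_at_zero(self):
        # STRs tightly clustered on the CDS start (a point mass up to the
        # KDE's ability to estimate it) put the density maximum at ~0
        gene = _gene("g1", 100_000, 103_000, cds=[(100_000, 103_000, 0)])
        strs = self._strs([100_000 + d for d in (-2, -1, 0, 0, 1, 2) * 4])
        df = str_cds_density(strs, [gene], bandwidth=0.1)
        starts = df[df["boundary"] == "start"]
        peak = starts.loc[starts["density"].idxmax(), "distance"]
        assert abs(peak) <= 200  # grid step resolution

    def test_uniform_is_flat(self):
        """Uniform STR placement on a gene-free flank gives a flat density."""
        rng = np.random.default_rng(4)
        gene = _gene("g1", 500_000, 503_000, cds=[(500_000, 503_000, 0)])
        positions = rng.integers(500_000 - 40_000, 500_000 + 40_000, size=4_000)
        strs = self._strs(positions)
        df = str_cds_density(strs, [gene], span=50_000)
        starts = df[df["boundary"] == "start"]
        mid = starts[np.abs(starts["distance"]) < 30_000]
        assert mid["density"].max() / mid["density"].min() < 1.35

    def test_normalisation(self):
        rng = np.random.default_rng(5)
        gene = _gene("g1", 100_000, 103_000, cds=[(100_000, 103_000, 0)])
        strs = self._strs(rng.integers(80_000, 120_000, size=200))
        df = str_cds_density(strs, [gene])
        for (_, _), grp in df.groupby(["period", "boundary"]):
            area = np.trapezoid(grp["density"], grp["distance"])
            assert area == pytest.approx(1.0, abs=1e-6)

    def test_requires_genes(self):
        with pytest.raises(ValueError):
            str_cds_density(self._strs([1, 2]), [])


class TestCrossref:
    def test_method_string(self):
        hits = pd.DataFrame({"feature_id": ["a", "b"], "kind": ["SV", "STR"],
                             "gene_id": ["CSMD3", "CSMD3"],
                             "distance": [0, 100], "relation": ["overlaps_gene"] * 2})
        candidates = CandidateGeneList.from_iterable(["csmd3", "OTHER"])
        full, matched = crossref_candidates(hits, candidates)
        assert matched.iloc[0]["method"] == "SV, STR"

    def test_non_candidate_kept_in_full_table(self):
        hits = pd.DataFrame({"feature_id": ["a"], "kind": ["SV"],
                             "gene_id": ["NOPE"], "distance": [0],
                             "relation": ["overlaps_gene"]})
        full, matched = crossref_candidates(hits, CandidateGeneList.from_iterable(["x"]))
        assert len(full) == 1 and len(matched) == 0

    def test_empty_candidate_list(self):
        hits = pd.DataFrame({"feature_id": ["a"], "kind": ["SV"],
                             "gene_id": ["NOPE"], "distance": [0],
                             "relation": ["overlaps_gene"]})
        _, matched = crossref_candidates(hits, CandidateGeneList.from_iterable([]))
        assert len(matched) == 0


def rank_sum_oracle(a, b):
    """Midrank Wilcoxon W and normal-approximation p (continuity corrected)."""
    combined = np.concatenate([a, b])
    order = np.argsort(combined)
    ranks = np.empty(combined.size)
    sorted_vals = combined[order]
    i = 0
    while i < combined.size:
        j = i
        while j + 1 < combined.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    n1, n2 = len(a), len(b)
    W = ranks[:n1].sum()
    U = W - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    # tie-corrected variance
    _, counts = np.unique(combined, return_counts=True)
    tie = (counts**3 - counts).sum()
    var = n1 * n2 / 12 * ((n1 + n2 + 1) - tie / ((n1 + n2) * (n1 + n2 - 1)))
    from scipy.stats import norm

    z = (abs(U - mu) - 0.5) / np.sqrt(var)
    return U, 2 * norm.sf(z)


class TestSummaryCompare:
    def _ws(self, n=20, rng=None):
        rng = rng or np.random.default_rng(6)
        pi_a = rng.uniform(0.002, 0.005, n)
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 100, "end": np.arange(n) * 100 + 100,
            "pi_A": pi_a, "pi_B": 2 * pi_a,
            "dxy": rng.uniform(0.002, 0.005, n),
            "fst_hudson": rng.uniform(0, 0.2, n),
        })

    def test_perfect_correlation(self):
        ws = self._ws()
        out = summary_compare(ws, np.zeros(len(ws), bool))
        assert out["pearson"]["genome"]["pi_A~pi_B"]["r"] == pytest.approx(1.0)

    def test_identical_groups_nonsignificant(self):
        rng = np.random.default_rng(7)
        base = self._ws(40, rng)
        # outlier half duplicates the non-outlier half exactly
        ws = pd.concat([base, base], ignore_index=True)
        mask = np.concatenate([np.ones(40, bool), np.zeros(40, bool)])
        out = summary_compare(ws, mask)
        for col in ("fst_hudson", "dxy", "pi_A", "pi_B"):
            assert out["wilcoxon"][col]["p"] > 0.9

    def test_vs_rank_and_covariance_oracle(self):
        rng = np.random.default_rng(8)
        ws = self._ws(20, rng)
        mask = np.zeros(20, bool)
        mask[:8] = True
        out = summary_compare(ws, mask)
        # Pearson against the closed-form covariance formula
        x, y = ws["fst_hudson"].to_numpy(), ws["dxy"].to_numpy()
        r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean())**2).sum() * ((y - y.mean())**2).sum()))
        assert out["pearson"]["genome"]["fst_hudson~dxy"]["r"] == pytest.approx(
            r_manual, abs=1e-9)
        # Wilcoxon against the midrank oracle
        a = ws.loc[mask, "fst_hudson"].to_numpy()
        b = ws.loc[~mask, "fst_hudson"].to_numpy()
        U, p = rank_sum_oracle(a, b)
        assert out["wilcoxon"]["fst_hudson"]["stat"] == pytest.approx(U, abs=1e-9)
        assert out["wilcoxon"]["fst_hudson"]["p"] == pytest.approx(p, abs=1e-9)


class TestPca:
    def test_block_structure_separates(self):
        rng = np.random.default_rng(9)
        a = rng.binomial(2, 0.05, size=(10, 200)).astype(float)
        b = rng.binomial(2, 0.95, size=(10, 200)).astype(float)
        X = np.concatenate([a, b])
        samples = [f"s{i}" for i in range(20)]
        df = genotype_pca(X, samples)
        pc1 = df["PC1"].to_numpy()
        assert max(pc1[:10]) < min(pc1[10:]) or max(pc1[10:]) < min(pc1[:10])

    def test_explained_variance_bounded(self):
        rng = np.random.default_rng(10)
        df = genotype_pca(rng.integers(0, 3, (12, 50)).astype(float),
                          [f"s{i}" for i in range(12)])
        ev = df.attrs["explained_variance_fraction"]
        assert sum(ev) <= 1 + 1e-9

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            genotype_pca(np.ones((5, 10)), [f"s{i}" for i in range(5)])

    def test_default_dataset_separation(self, full_scan):
        """SNP, SV and STR genotypes all recover the population structure."""
        for kind in ("snp", "sv", "str"):
            df = full_scan["pca"][kind]
            a = df[df["sample"].str.startswith("popA")]["PC1"]
            b = df[df["sample"].str.startswith("popB")]["PC1"]
            assert a.max() < b.min() or b.max() < a.min(), kind
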