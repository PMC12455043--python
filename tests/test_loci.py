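"""Per-locus scans: STR prefilter, Jost's D, normal-fit outlier calling."""

import numpy as np
import pytest

from polyscan.config import ScanConfig, SimConfig
from polyscan.loci import josts_d, normal_fit_outlier_scan, str_prefilter, sv_scan
from polyscan.model import GenomeLayout, StrRecord, SvRecord
from polyscan.sim import simulate_marker_loci


def jost_oracle(alleles_a: np.ndarray, alleles_b: np.ndarray) -> float:
    """Independent transcription of the Nei–Chesson-corrected Jost's D."""
    universe = sorted(set(alleles_a) | set(alleles_b))
    pa = np.array([np.mean(alleles_a == u) for u in universe])
    pb = np.array([np.mean(alleles_b == u) for u in universe])
    hs = ((1 - (pa**2).sum()) + (1 - (pb**2).sum())) / 2
    pm = (pa + pb) / 2
    ht = 1 - (pm**2).sum()
    n_a, n_b = len(alleles_a) / 2, len(alleles_b) / 2
    n_harm = 2 / (1 / n_a + 1 / n_b)
    hs_est = (2 * n_harm / (2 * n_harm - 1)) * hs
    ht_est = ht + hs_est / (2 * n_harm * 2)
    return ((ht_est - hs_est) / (1 - hs_est)) * 2


def _str(genotypes, samples=None, str_id="str_1", period=2):
    genotypes = np.asarray(genotypes, dtype=np.int16)
    samples = samples or tuple(f"s{i}" for i in range(genotypes.shape[0]))
    return StrRecord(str_id, "chr1", 100, period, genotypes, tuple(samples))


class TestStrPrefilter:
    def test_missing_call_dropped(self):
        rec = _str([[10, 10], [10, 12], [-1, -1], [12, 12]])
        assert str_prefilter([rec]) == []

    def test_low_maf_dropped(self):
        # frequencies {0.92, 0.08}: 23 of 25 alleles are allele 10
        geno = [[10, 10]] * 11 + [[10, 12], [12, 10]]
        geno[11] = [10, 12]
        g = np.array([[10, 10]] * 12 + [[12, 10]])  # 24:1 -> too simple; build 0.92
        g = np.array([[10, 10]] * 11 + [[10, 12]] + [[12, 10]])  # 24 vs 2 = 0.077
        rec = _str(g)
        assert str_prefilter([rec], maf_min=0.1) == []

    def test_multiallelic_maf_convention(self):
        # frequencies {0.6, 0.3, 0.1}: MAF = 1 - 0.6 = 0.4 -> kept
        alleles = [10] * 12 + [12] * 6 + [14] * 2
        g = np.array(alleles).reshape(10, 2)
        rec = _str(g)
        assert len(str_prefilter([rec], maf_min=0.1)) == 1


class TestJostsD:
    def test_complete_differentiation(self):
        ga = np.full((6, 2), 10, dtype=np.int16)
        gb = np.full((6, 2), 12, dtype=np.int16)
        comp = josts_d([ga, gb])
        assert comp.hs_est == pytest.approx(0.0)
        assert comp.ht_est == pytest.approx(0.5)
        assert comp.d == pytest.approx(1.0)

    def test_identical_frequencies(self):
        g = np.array([[10, 12]] * 3 + [[10, 10]] * 3, dtype=np.int16)
        comp = josts_d([g, g.copy()])
        assert comp.d_parametric == pytest.approx(0.0, abs=1e-12)

    def test_vs_independent_transcription(self):
        # popA counts {8 x a, 4 x b}, popB {4 x a, 8 x b}, 6 diploids each
        a = np.array([10] * 8 + [12] * 4, dtype=np.int16).reshape(6, 2)
        b = np.array([10] * 4 + [12] * 8, dtype=np.int16).reshape(6, 2)
        comp = josts_d([a, b])
        assert comp.d == pytest.approx(jost_oracle(a.ravel(), b.ravel()), abs=1e-10)

    def test_parametric_in_unit_interval(self):
        """Parametric D within [0, 1] on 10,000 random frequency pairs."""
        rng = np.random.default_rng(7)
        for _ in range(10_000):
            k = int(rng.integers(2, 6))
            pa = rng.dirichlet(np.ones(k))
            pb = rng.dirichlet(np.ones(k))
            hs = ((1 - (pa**2).sum()) + (1 - (pb**2).sum())) / 2
            ht = 1 - (((pa + pb) / 2) ** 2).sum()
            d = (ht - hs) / (1 - hs) * 2
            assert -1e-12 <= d <= 1 + 1e-12

    def test_estimator_converges_to_parametric(self):
        """Bias corrections vanish as the harmonic sample size grows."""
        n = 1_000_000
        # exact frequencies: popA {0.7 a, 0.3 b}, popB {0.4 a, 0.6 b}
        a = np.concatenate([np.full(int(2 * n * 0.7), 10), np.full(int(2 * n * 0.3), 12)])
        b = np.concatenate([np.full(int(2 * n * 0.4), 10), np.full(int(2 * n * 0.6), 12)])
        ga = a.astype(np.int16).reshape(n, 2)
        gb = b.astype(np.int16).reshape(n, 2)
        comp = josts_d([ga, gb])
        assert comp.d == pytest.approx(comp.d_parametric, abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        ga = rng.integers(10, 14, (8, 2)).astype(np.int16)
        gb = rng.integers(10, 14, (8, 2)).astype(np.int16)
        d1 = josts_d([ga, gb]).d
        d2 = josts_d([gb, ga]).d
        assert d1 == pytest.approx(d2, abs=1e-12)
        # allele relabeling (bijective map of repeat counts)
        remap = {10: 23, 11: 5, 12: 17, 13: 40}
        ra = np.vectorize(remap.get)(ga).astype(np.int16)
        rb = np.vectorize(remap.get)(gb).astype(np.int16)
        assert josts_d([ra, rb]).d == pytest.approx(d1, abs=1e-12)


class TestNormalFit:
    def test_planted_outlier(self):
        """One +10-sigma locus among 10,000 nulls is flagged; expected
        neutral flags <= 1 (5 seeds)."""
        neutral_flags = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = np.concatenate([rng.normal(size=10_000), [10.0]])
            df = normal_fit_outlier_scan(values)
            assert bool(df.iloc[-1]["outlier"])
            neutral_flags.append(int(df.iloc[:-1]["outlier"].sum()))
        assert np.mean(neutral_flags) <= 1

    def test_mean_value_p_half(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=100)
        values[0] = values[1:].mean()  # approximately mu
        df = normal_fit_outlier_scan(values)
        assert df.iloc[0]["p"] == pytest.approx(0.5, abs=0.02)

    def test_q_composition(self):
        from polyscan.dcms import bh_qvalues

        rng = np.random.default_rng(2)
        values = rng.normal(size=50)
        df = normal_fit_outlier_scan(values)
        assert np.allclose(df["q"], bh_qvalues(df["p"]), atol=1e-15)

    def test_minimum_loci(self):
        with pytest.raises(ValueError):
            normal_fit_outlier_scan(np.random.default_rng(0).normal(size=10))

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            normal_fit_outlier_scan(np.ones(40))


class TestSvScan:
    def test_recovery_on_default_dataset(self, full_scan, default_sim):
        sv = full_scan["sv"]
        div = set(default_sim.truth.divergent_svs)
        rec = sv[sv["locus_id"].isin(div)]["outlier"].mean()
        neu = sv[~sv["locus_id"].isin(div)]["outlier"].mean()
        assert rec >= 0.8
        assert neu <= 0.01

    def test_no_fixed_differences_in_default_dataset(self, full_scan):
        assert len(full_scan["sv_fixed"]) == 0

    def test_fixed_difference_detection(self):
        from polyscan.model import PopulationMap

        samples = tuple(f"s{i}" for i in range(8))
        popmap = PopulationMap({s: ("popA" if i < 4 else "popB")
                                for i, s in enumerate(samples)})
        fixed_geno = np.array([[0, 0]] * 4 + [[1, 1]] * 4, dtype=np.int8)
        rng = np.random.default_rng(0)
        svs = [SvRecord(f"sv_{j}", "chr1", 100 * j, 100 * j + 50, "DEL", 50,
                        fixed_geno if j == 0 else
                        rng.integers(0, 2, (8, 2)).astype(np.int8), samples)
               for j in range(40)]
        _, fixed = sv_scan(svs, popmap)
        assert set(fixed["locus_id"]) >= {"sv_0"}
        # a single heterozygote or missing call disqualifies a site
        het = fixed_geno.copy()
        het[0] = [0, 1]
        svs[1] = SvRecord("sv_1", "chr1", 100, 150, "DEL", 50, het, samples)
        miss = fixed_geno.copy()
        miss[5] = [-1, -1]
        svs[2] = SvRecord("sv_2", "chr1", 200, 250, "DEL", 50, miss, samples)
        _, fixed = sv_scan(svs, popmap)
        assert "sv_1" not in set(fixed["locus_id"])
        assert "sv_2" not in set(fixed["locus_id"])

    def test_too_few_loci(self):
        from polyscan.model import PopulationMap

        samples = tuple(f"s{i}" for i in range(4))
        popmap = PopulationMap({s: ("popA" if i < 2 else "popB")
                                for i, s in enumerate(samples)})
        geno = np.array([[0, 1]] * 4, dtype=np.int8)
        svs = [SvRecord(f"sv_{j}", "chr1", j * 10, j * 10 + 5, "DEL", 5, geno, samples)
               for j in range(10)]
        with pytest.raises(ValueError):
            sv_scan(svs, popmap)


class TestStrScan:
    def test_recovery_on_default_dataset(self, full_scan, default_sim):
        st = full_scan["str"]
        div = set(default_sim.truth.divergent_strs)
        scanned_div = st[st["locus_id"].isin(div)]
        rec = scanned_div["outlier"].mean()
        neu = st[~st["locus_id"].isin(div)]["outlier"].mean()
        assert rec >= 0.8
        assert neu <= 0.01


def test_scan_neutrality_diagnostic(caplog):
    """Under a pure null the heavy-tail diagnostic fires and the flag rate
    stays small.

    The per-locus WC FST sampling distribution at weak differentiation is
    right-skewed, so the literal normal-fit procedure is mildly
    anti-conservative under the pure null (a few % of loci flagged); the
    scan records this through the skewness/kurtosis warning instead of
    substituting a different null.  The <=1% neutral flag rate holds on the
    default dataset, where planted divergence widens the fitted sigma
    (checked in the recovery tests above).
    """
    import logging

    from polyscan.loci import str_scan
    from polyscan.model import PopulationMap

    rates = []
    with caplog.at_level(logging.WARNING, logger="polyscan"):
        for seed in range(5):
            cfg = SimConfig(seed=seed, sv_divergent_fraction=0.0,
                            str_divergent_fraction=0.0,
                            layout=GenomeLayout(("chr1",), (1_000_000,)),
                            n_sweeps=1, n_svs=1000, n_strs=1000).validate()
            svs, strs, _ = simulate_marker_loci(cfg, np.random.default_rng(seed))
            names = {}
            for s in svs[0].samples:
                names[s] = "popA" if s.startswith("popA") else (
                    "popB" if s.startswith("popB") else "hybrid")
            popmap = PopulationMap(names)
            sv_df, _ = sv_scan(svs, popmap)
            str_df = str_scan(strs, popmap)
            rates.append(sv_df["outlier"].mean())
            rates.append(str_df["outlier"].mean())
    assert np.mean(rates) <= 0.05
    assert any("non-normal" in rec.message for rec in caplog.records)
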