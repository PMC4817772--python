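"""ABBA-BABA machinery, jackknife, and the isolation-null test."""

import numpy as np
import pytest

from matpop import introgression as intro
from matpop import synthetic_data as sd
from matpop.coalescent_sim import MSCParams, simulate_isolation_pair
from matpop.io_formats import Region, SampleMeta, VariantTable, make_windows


def _table(pos, genotypes, chrom="c", names=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    names = names or [f"s{i}" for i in range(genotypes.shape[0])]
    samples = [SampleMeta(n) for n in names]
    return VariantTable([chrom] * len(pos), pos, ["A"] * len(pos),
                        ["G"] * len(pos), genotypes, samples)


class TestSitePatterns:
    def test_abba_site(self):
        # (P1,P2,P3,O) = (A,G,G,A): P1 ancestral, P2 & P3 derived
        c = intro.count_site_patterns([0], [1], [1], [0])
        assert (c.n_abba, c.n_baba) == (1.0, 0.0)

    def test_baba_site(self):
        c = intro.count_site_patterns([1], [0], [1], [0])
        assert (c.n_abba, c.n_baba) == (0.0, 1.0)

    def test_invariant_site_contributes_nothing(self):
        c = intro.count_site_patterns([0], [0], [0], [0])
        assert (c.n_abba, c.n_baba) == (0.0, 0.0)

    def test_missing_site_skipped(self):
        c = intro.count_site_patterns([-1], [1], [1], [0])
        assert (c.n_abba, c.n_baba) == (0.0, 0.0)

    def test_outgroup_polymorphic_site_skipped(self):
        g_out = np.array([[0], [1]])  # two outgroup genomes disagreeing
        abba, baba = intro.site_pattern_weights([0], [1], [1], g_out)
        assert abba[0] == 0.0 and baba[0] == 0.0

    def test_frequency_mode_products(self):
        p2 = np.array([[1], [0]])  # derived freq 0.5
        abba, baba = intro.site_pattern_weights([0], p2, [1], [0])
        assert abba[0] == pytest.approx(0.5)
        assert baba[0] == pytest.approx(0.0)


class TestDStatistic:
    def _quartet_table(self, abba_sites, baba_sites, spacing=1000):
        cols = []
        for _ in range(abba_sites):
            cols.append([0, 1, 1, 0])
        for _ in range(baba_sites):
            cols.append([1, 0, 1, 0])
        geno = np.array(cols, dtype=np.int8).T
        pos = np.arange(geno.shape[1]) * spacing
        return _table(pos, geno, names=["P1", "P2", "P3", "O"])

    def test_formula(self):
        t = self._quartet_table(30, 10)
        res = intro.d_statistic(t, "P1", "P2", "P3", "O")
        assert res.d == pytest.approx(0.5)
        assert (res.n_abba, res.n_baba) == (30.0, 10.0)

    def test_balanced_counts_give_zero(self):
        t = self._quartet_table(15, 15)
        assert intro.d_statistic(t, "P1", "P2", "P3", "O").d == \
            pytest.approx(0.0)

    def test_two_block_jackknife_closed_form(self):
        # block 1: (ABBA,BABA) = (3,1); block 2: (1,3) -> D = 0
        cols = [[0, 1, 1, 0]] * 3 + [[1, 0, 1, 0]] * 1
        cols += [[0, 1, 1, 0]] * 1 + [[1, 0, 1, 0]] * 3
        geno = np.array(cols, dtype=np.int8).T
        pos = np.array([0, 10, 20, 30, 250_000, 250_010, 250_020, 250_030])
        t = _table(pos, geno, names=["P1", "P2", "P3", "O"])
        res = intro.d_statistic(t, "P1", "P2", "P3", "O")
        assert res.d == pytest.approx(0.0)
        # delete-one estimates: drop block1 -> D=-0.5; drop block2 -> +0.5
        # SE = sqrt((m-1)/m * sum((Dj - mean)^2)) = sqrt(1/2 * 0.5) = 0.5
        assert res.n_blocks == 2
        assert res.se == pytest.approx(np.sqrt(0.5 * (0.25 + 0.25)))

    def test_antisymmetry_under_p1_p2_swap(self):
        t = self._quartet_table(25, 11)
        d12 = intro.d_statistic(t, "P1", "P2", "P3", "O").d
        d21 = intro.d_statistic(t, "P2", "P1", "P3", "O").d
        assert d12 == pytest.approx(-d21)

    def test_no_informative_sites_undefined(self):
        t = _table([0, 1], np.zeros((4, 2), dtype=np.int8),
                   names=["P1", "P2", "P3", "O"])
        res = intro.d_statistic(t, "P1", "P2", "P3", "O")
        assert np.isnan(res.d)

    def test_single_block_flags_se_unavailable(self):
        t = self._quartet_table(5, 2, spacing=10)
        res = intro.d_statistic(t, "P1", "P2", "P3", "O")
        assert res.n_blocks == 1
        assert np.isnan(res.se)


class TestWindowedMatFixed:
    def test_donor_tract_localized(self, introgressed_study):
        study = introgressed_study
        t = study.table
        tract = study.truth.introgressed_tracts[0]
        windows = make_windows("mat", study.config.chrom_lengths["mat"],
                               100_000, 20_000)
        rows = intro.windowed_abba_baba_matfixed(
            t, study.mat_class("A"), study.mat_class("a"),
            "donor", "outgroup", windows)
        inside = [r.d for r in rows if tract.start <= r.region.start
                  and r.region.end <= tract.end and np.isfinite(r.d)]
        sr = study.truth.sr_region
        outside = [r.d for r in rows
                   if (r.region.end <= tract.start - 100_000
                       or r.region.start >= tract.end + 100_000)
                   and sr.start <= r.region.start and r.region.end <= sr.end
                   and np.isfinite(r.d)]
        assert np.mean(inside) > 0.8          # ABBA excess inside the tract
        assert abs(np.mean(outside)) < 0.5    # background much weaker

    def test_window_without_fixed_sites_undefined(self):
        t = _table([0], [[0], [0], [1], [0]],
                   names=["A1", "a1", "P3", "O"])
        # matA and mata identical -> no mat-fixed site
        rows = intro.windowed_abba_baba_matfixed(
            t, ["A1"], ["a1"], "P3", "O", [Region("c", 0, 10)])
        assert np.isnan(rows[0].d)
        assert rows[0].n_fixed_sites == 0

    def test_unrelated_donor_centred_on_zero(self):
        # a donor with no affinity to either mat class: per-window D is
        # centred on 0 across seeds (a donor literally identical to the
        # outgroup yields no informative site at all, so the null is
        # phrased as exchangeability instead)
        rng = np.random.default_rng(21)
        ds = []
        for _ in range(30):
            m = 200
            a_allele = (rng.random(m) < 0.5).astype(np.int8)
            donor = (rng.random(m) < 0.5).astype(np.int8)
            out = np.zeros(m, dtype=np.int8)
            geno = np.stack([a_allele, 1 - a_allele, donor, out])
            t = _table(np.arange(m) * 50, geno,
                       names=["A1", "a1", "P3", "O"])
            rows = intro.windowed_abba_baba_matfixed(
                t, ["A1"], ["a1"], "P3", "O", [Region("c", 0, m * 50)])
            if np.isfinite(rows[0].d):
                ds.append(rows[0].d)
        assert len(ds) == 30
        assert abs(np.mean(ds)) < 0.15


class TestIsolationTest:
    MSC = MSCParams(theta_anc=0.018, tau_split=0.02)

    def test_median_observation_gives_half(self):
        sim = simulate_isolation_pair(self.MSC, 4000, seed=31)
        med = float(np.median(sim.jc_divergence))
        res = intro.isolation_divergence_test(med, self.MSC, n_loci=4000,
                                              seed=32)
        assert res.p == pytest.approx(0.5, abs=0.05)

    def test_value_below_all_simulations(self):
        res = intro.isolation_divergence_test(-1.0, self.MSC, n_loci=1000,
                                              seed=33)
        assert res.p == 0.0
        assert res.p_str == "<0.001"

    def test_upper_direction(self):
        res = intro.isolation_divergence_test(10.0, self.MSC, n_loci=1000,
                                              direction="upper", seed=34)
        assert res.p == 0.0

    def test_introgressed_divergence_significant(self):
        # donor-tract divergence far below 2*tau + theta_anc
        res = intro.isolation_divergence_test(0.002, self.MSC,
                                              n_loci=10_000, seed=35)
        assert res.p < 0.001

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            intro.isolation_divergence_test(0.01, self.MSC, n_loci=50)


class TestNullCalibrationSmoke:
    def test_quartet_null_z_moderate(self):
        zs = []
        for seed in range(8):
            t = sd.simulate_quartet_study(sd.QuartetConfig(seed=seed))
            zs.append(intro.d_statistic(t, "P1", "P2", "P3", "O").z)
        assert np.all(np.abs(zs) < 5)

    def test_power_with_half_genome_tract(self):
        t = sd.simulate_quartet_study(
            sd.QuartetConfig(introgressed_fraction=0.5, seed=5))
        assert intro.d_statistic(t, "P1", "P2", "P3", "O").z > 3
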