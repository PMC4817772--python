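"""The synthetic-study generator: determinism, truth-table consistency,
and agreement of emitted data with the configured expectations."""

import numpy as np
import pytest

from matpop import popgen_stats as ps
from matpop import synthetic_data as sd
from matpop.io_formats import read_regions_bed, read_vcf


SMALL = dict(chrom_lengths={"mat": 2_000_000, "chr2": 1_000_000,
                            "chr3": 1_000_000},
             sr_start=500_000, sr_end=1_500_000, mat_locus_pos=1_000_000)


class TestStudyConfig:
    def test_tract_outside_sr_rejected(self):
        with pytest.raises(ValueError, match="tract"):
            sd.StudyConfig(**SMALL, introgression=sd.IntrogressionSpec(
                start=100_000, end=400_000))

    def test_mat_locus_outside_sr_rejected(self):
        bad = dict(SMALL, mat_locus_pos=100_000)
        with pytest.raises(ValueError, match="locus"):
            sd.StudyConfig(**bad)

    def test_dict_specs_coerced(self):
        cfg = sd.StudyConfig(**SMALL, introgression=dict(
            start=600_000, end=900_000))
        assert isinstance(cfg.introgression, sd.IntrogressionSpec)


class TestSimulateStudy:
    def test_fixed_seed_identical_outputs(self, tmp_path):
        a = sd.simulate_study(sd.StudyConfig(**SMALL, seed=11))
        b = sd.simulate_study(sd.StudyConfig(**SMALL, seed=11))
        assert np.array_equal(a.table.pos, b.table.pos)
        assert np.array_equal(a.table.genotypes, b.table.genotypes)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        a.write(d1)
        b.write(d2)
        assert (d1 / "study.vcf").read_bytes() == \
            (d2 / "study.vcf").read_bytes()

    def test_different_seeds_differ(self):
        a = sd.simulate_study(sd.StudyConfig(**SMALL, seed=1))
        b = sd.simulate_study(sd.StudyConfig(**SMALL, seed=2))
        assert a.table.n_sites != b.table.n_sites or \
            not np.array_equal(a.table.pos, b.table.pos)

    def test_emitted_files_parse_losslessly(self, tmp_path):
        study = sd.simulate_study(sd.StudyConfig(**SMALL, seed=3))
        study.write(tmp_path)
        back = read_vcf(tmp_path / "study.vcf", tmp_path / "samples.tsv")
        assert np.array_equal(back.genotypes, study.table.genotypes)
        assert np.array_equal(back.pos, study.table.pos)
        assert [s.sample_id for s in back.samples] == \
            study.table.sample_ids
        truth_sr = read_regions_bed(tmp_path / "truth_sr.bed")[0]
        assert (truth_sr.start, truth_sr.end) == (500_000, 1_500_000)

    def test_sample_structure(self, small_study):
        t = small_study.table
        assert len(small_study.focal_samples) == 16
        assert len(small_study.mat_class("A")) == 8
        assert {s.sample_id for s in t.samples} >= {"donor", "outgroup"}
        # heterokaryon pairing invariant holds in the emitted sheet
        by_het = {}
        for s in t.samples:
            if s.heterokaryon_id:
                by_het.setdefault(s.heterokaryon_id, []).append(
                    s.mating_type)
        assert all(sorted(v) == ["A", "a"] for v in by_het.values())

    def test_autosomal_pi_matches_theta(self, small_study):
        cfg = small_study.config
        t = small_study.table
        one = ps.one_per_heterokaryon(
            [s for s in t.samples if s.lineage == cfg.lineage])
        rows = ps.nucleotide_diversity(t, one)
        vals = [r.value for r in rows
                if r.region.chrom != "mat" and r.defined]
        assert np.mean(vals) == pytest.approx(cfg.theta, rel=0.15)

    def test_sr_heterokaryon_divergence_matches_config(self, small_study):
        cfg = small_study.config
        rows = ps.pairwise_divergence(small_study.table, "L1H01A",
                                      "L1H01a", jc_correct=False)
        sr_vals = [r.value for r in rows
                   if r.region.chrom == "mat" and r.defined
                   and cfg.sr_start <= r.region.start
                   and r.region.end <= cfg.sr_end]
        assert np.mean(sr_vals) == pytest.approx(cfg.sr_divergence,
                                                 rel=0.15)

    def test_pair_identity_on_autosomes(self, small_study):
        rows = ps.pairwise_divergence(small_study.table, "L1H01A",
                                      "L1H01a", jc_correct=False)
        auto = [r.value for r in rows
                if r.region.chrom != "mat" and r.defined]
        assert np.mean(auto) < 1e-4  # near-clonal within heterokaryons


class TestSweepPlanting:
    def test_extreme_h_windows_cluster_at_planted_sweep(self):
        from matpop.io_formats import make_windows
        kw = dict(chrom_lengths={"mat": 6_000_000, "chr2": 3_000_000,
                                 "chr3": 3_000_000},
                  sr_start=1_500_000, sr_end=4_500_000,
                  mat_locus_pos=3_000_000,
                  sweep=sd.SweepSpec(start=4_600_000, end=4_900_000,
                                     chrom="mat", t_s=0.05))
        study = sd.simulate_study(sd.StudyConfig(**kw, seed=0))
        t = study.table
        one = ps.one_per_heterokaryon(
            [s for s in t.samples if s.lineage == "L1"])
        windows = []
        for c, L in sorted(kw["chrom_lengths"].items()):
            windows += make_windows(c, L, 100_000)
        h = ps.fay_wu_h_windows(t, one, "outgroup", windows=windows)
        flags = ps.extreme_window_flags(h, tail=0.05, direction="lower")
        sweep = study.truth.sweep_regions[0]
        overlapping = [r for r in flags if r.chrom == sweep.chrom
                       and r.end > sweep.start and r.start < sweep.end]
        assert len(overlapping) >= 1

    def test_sweep_reduces_local_diversity(self):
        kw = dict(chrom_lengths={"mat": 2_000_000, "chr2": 1_000_000,
                                 "chr3": 1_000_000},
                  sr_start=500_000, sr_end=1_200_000,
                  mat_locus_pos=800_000,
                  sweep=sd.SweepSpec(start=1_400_000, end=1_800_000,
                                     chrom="mat", t_s=0.05))
        study = sd.simulate_study(sd.StudyConfig(**kw, seed=2))
        one = ps.one_per_heterokaryon(
            [s for s in study.table.samples if s.lineage == "L1"])
        rows = ps.nucleotide_diversity(study.table, one)
        pi_sweep = np.nanmean([r.value for r in rows
                               if r.region.chrom == "mat"
                               and 1_400_000 <= r.region.start
                               and r.region.end <= 1_800_000])
        pi_bg = np.nanmean([r.value for r in rows
                            if r.region.chrom != "mat"])
        # escapee lineages keep some variation, so the reduction is
        # partial rather than total
        assert pi_sweep < 0.75 * pi_bg


class TestQuartetGenerator:
    def test_determinism(self):
        a = sd.simulate_quartet_study(sd.QuartetConfig(seed=5))
        b = sd.simulate_quartet_study(sd.QuartetConfig(seed=5))
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.genotypes, b.genotypes)

    def test_taxa_and_polarity(self):
        t = sd.simulate_quartet_study(sd.QuartetConfig(n_blocks=50, seed=6))
        assert t.sample_ids == ["P1", "P2", "P3", "O"]
        # a substantial fraction of sites have the outgroup ancestral
        assert (t.genotypes[3] == 0).mean() > 0.5

    def test_abba_baba_balanced_without_gene_flow(self):
        from matpop.introgression import count_site_patterns
        t = sd.simulate_quartet_study(sd.QuartetConfig(seed=7))
        g = t.genotypes
        c = count_site_patterns(g[0], g[1], g[2], g[3])
        total = c.n_abba + c.n_baba
        assert total > 200  # ILS produces informative sites
        assert abs(c.n_abba - c.n_baba) / total < 0.25


class TestCodonGeneGenerator:
    def test_zero_rates_zero_counts(self):
        cfg = sd.CodonGeneConfig(switch_counts={}, seed=1)
        alns, truth = sd.simulate_codon_genes(cfg)
        assert truth.total() == 0
        assert len(alns) == cfg.n_genes

    def test_determinism(self):
        a, _ = sd.simulate_codon_genes(sd.CodonGeneConfig(seed=2))
        b, _ = sd.simulate_codon_genes(sd.CodonGeneConfig(seed=2))
        assert all(np.array_equal(x.codons, y.codons)
                   for x, y in zip(a, b))

    def test_overfull_planting_rejected(self):
        cfg = sd.CodonGeneConfig(n_genes=1, n_codons=5, switch_counts={
            "mat_A": {"NOP->OP": 10}})
        with pytest.raises(ValueError, match="one change per codon"):
            sd.simulate_codon_genes(cfg)

    def test_alignments_in_frame_without_stops(self):
        alns, _ = sd.simulate_codon_genes(sd.CodonGeneConfig(n_genes=3,
                                                             seed=3))
        from matpop.io_formats import STOP_CODONS
        for aln in alns:
            assert not any(c in STOP_CODONS for c in aln.codons.ravel())
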