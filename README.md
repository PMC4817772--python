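# matpop

Population and comparative genomics of fungal mating-type chromosomes:
suppressed recombination, introgression, selective sweeps and mutational
load, from haploid SNP data.

## The problem

In pseudohomothallic fungi such as *Neurospora tetrasperma*, sexual spores
package nuclei of both mating types (*mat A* and *mat a*), making the
fungus self-fertile. This mating system suppresses crossing-over over a
large block of the mating-type (*mat*) chromosome, so the *mat A* and
*mat a* haplotypes of that block evolve like a young sex-chromosome pair:
they diverge from one another, stop purging deleterious variation
efficiently, lose nucleotide diversity, and can acquire large introgressed
tracts from heterothallic sister species. `matpop` implements the
population-genomic toolkit used to characterize this process from
resequenced single-mating-type homokaryons:

- **Suppressed-recombination (SR) demarcation** — mean pairwise
  r² = (p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B)) in 100-kb sliding
  windows (20-kb step); windows on the *mat* chromosome above the 95%
  quantile of the autosomal distribution are assigned to the SR, with an
  optional sub-window changepoint refinement of the two boundaries. A
  divergence-based variant uses windowed *mat A*/*mat a* heterokaryon
  divergence instead of LD.
- **Diversity and SFS scans** — π, θ_W = S/a₁, Tajima's
  D = (k − S/a₁)/√(e₁S + e₂S(S−1)), and Fay & Wu's H = π − θ_H with
  θ_H = Σ 2ξᵢi²/(n(n−1)) (normalized form optional), in sliding windows
  with the 10%-called-sites threshold; top-5% extreme-window flagging.
- **Divergence** — Jukes–Cantor-corrected pairwise distance
  d = −(3/4)ln(1 − 4p/3) and between-population D_xy in 25-kb windows.
- **Introgression** — Patterson's D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA)
  with a 250-kb block jackknife (Z = D/SE, two-sided normal p), windowed
  ABBA/BABA restricted to *mat*-fixed sites, and an empirical divergence
  test against a simulated two-species isolation (multispecies-coalescent)
  null: 50,000 independent 25-kb loci with pair coalescence at
  τ + Exp(θ_anc/2) and finite-site Jukes–Cantor mutation.
- **Sweep-model fitting** — the forced-coalescence hard-sweep model:
  a neutral coalescent truncated at time T_s, where all surviving lineages
  merge into one node; a (θ₀, T_s) grid is scored by the proportion of
  25,000 replicates whose simulated S and k fall within ±5% of the
  observed values (a rectangular-kernel ABC likelihood), using fourfold-
  degenerate sites as the neutral observation.
- **Mutational load in coding regions** — P_N/P_S with Nei–Gojobori
  expected-site denominators, the 70% CDS-coverage and within-lineage
  polymorphic-codon filters, and allele-specific optimal/nonoptimal
  (OP/NOP) codon-switch classification against an outgroup ancestral
  state, compared between the two *mat* genomes by Fisher's exact test.
- **A synthetic-study generator** that emulates the whole genomic
  structure (selfing heterokaryon pairs, SR block, donor introgression,
  sweeps, codon alignments with planted switches) with truth tables, so
  every stage is verifiable end to end without any external data.

## Worked example

Simulate a study with a planted SR (1.0–3.0 Mb on a 4-Mb *mat*
chromosome) and a donor tract introgressed into the *mat A* SR, then
recover all three signals:

```python
import numpy as np
from matpop import synthetic_data as sd, ld_sr, popgen_stats as ps, introgression as intro

cfg = sd.StudyConfig(
    chrom_lengths={"mat": 4_000_000, "chr2": 2_000_000, "chr3": 2_000_000},
    sr_start=1_000_000, sr_end=3_000_000, mat_locus_pos=2_000_000,
    introgression=sd.IntrogressionSpec(start=1_200_000, end=2_800_000),
    seed=7)
study = sd.simulate_study(cfg)
table = study.table

rows = ld_sr.window_mean_r2(table, study.focal_samples)
mat = [r for r in rows if r.region.chrom == "mat"]
auto = [r for r in rows if r.region.chrom != "mat"]
sr = ld_sr.detect_sr(mat, auto, cfg.mat_locus_pos,
                     table=table, samples=study.focal_samples)
print(f"SR: {sr.region.chrom}:{sr.region.start}-{sr.region.end} "
      f"(cutoff r2 = {sr.cutoff_value:.3f})")

one = ps.one_per_heterokaryon([s for s in table.samples if s.lineage == "L1"])
pi = ps.nucleotide_diversity(table, one)
pi_sr = np.nanmean([r.value for r in pi if r.region.chrom == "mat"
                    and sr.region.start <= r.region.start
                    and r.region.end <= sr.region.end])
pi_r = np.nanmean([r.value for r in pi if r.region.chrom != "mat"])
print(f"pi(SR) = {pi_sr:.2e}   pi(R) = {pi_r:.2e}   "
      f"reduction = {pi_r / pi_sr:.1f}-fold")

res = intro.d_statistic(table, study.mat_class("a")[0],
                        study.mat_class("A")[0], "donor", "outgroup")
print(f"Patterson's D = {res.d:.3f}   Z = {res.z:.1f}   p = {res.p:.3g}")
```

Output:

```
SR: mat:998198-2999995 (cutoff r2 = 0.368)
pi(SR) = 1.38e-04   pi(R) = 1.97e-03   reduction = 14.2-fold
Patterson's D = 0.957   Z = 155.8   p = 0
```

The detector places both SR boundaries within ~2 kb of the planted truth;
diversity inside the SR (one genome per mat class) is an order of
magnitude below the recombining background; and the ABBA/BABA quartet
(P1 = *mat a* strain, P2 = introgressed *mat A* strain, P3 = donor)
detects the donor tract overwhelmingly.

A `matpop` console script exposes each stage (`simulate-study`, `stats`,
`ld-sr`, `dstat`, `isolation-test`, `sweep-fit`, `codon-load`) plus an
orchestrating `run` command driven by a JSON config; every run writes a
manifest with its seed, config hash and output digests.

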