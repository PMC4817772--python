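# Methods

This note documents the statistical models implemented in `matpop`, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

The core container is a haploid biallelic SNP matrix (`VariantTable`):
samples × sites over {0, 1, missing}, with per-sample metadata (species,
lineage, mating type, heterokaryon pair). Coordinates are 0-based
half-open everywhere inside the package and in BED output; VCF I/O
converts at the boundary. Because the table is SNP-only, invariant sites
enter the analyses only through the callability mask, which defaults to
"every position callable" so that window thresholds degrade gracefully on
synthetic data. Diploid-encoded haploid calls (`0/0`, `1/1`) are accepted
silently; a true heterozygote in a homokaryon sample is an error by
default (all analyzed strains are single-mating-type homokaryons), with a
set-missing policy available.

Heterokaryon pairs matter for sampling: the two homokaryons of one
natural heterokaryon are nearly clonal on the autosomes of a selfing
lineage, so autosomal diversity statistics pick one homokaryon per
heterokaryon — deterministically (lowest sample id) unless a seed
requests a random draw.

## Windowed statistics

All scans use sliding windows (default 100 kb, 20-kb step; divergence and
D_xy use 25-kb non-overlapping windows). A window's value is undefined
when its called-site count falls below 10% of its span (10,000 sites for
a 100-kb window, 2,500 for a 25-kb window). The last partial window of a
chromosome keeps its true span, with the 10% threshold scaled
accordingly.

- **π** is computed per site from pairwise-complete observations
  (2c(n′−c)/(n′(n′−1)) with n′ the called samples at the site), summed
  over SNPs and divided by called sites. The called-sites denominator
  (rather than window length) is used whenever callability is partial.
- **Tajima's D** uses the 1989 normalization constants; complete-case
  sites within each window supply S and the mean pairwise difference
  count k. D is undefined at S = 0.
- **Fay & Wu's H** defaults to the unnormalized form H = π − θ_H; the
  variance-normalized form (with θ_L and the θ, θ² moment estimators) is
  available behind a flag, since published usage varies between the two.
  Polarization requires an outgroup sample; sites where the outgroup is
  missing, or any ingroup call is missing, are skipped, and fixed-derived
  sites are excluded (not segregating).
- **Jukes–Cantor divergence** d = −(3/4)ln(1 − 4p/3) is applied to
  two-genome window p-distances; p ≥ 0.75 yields an undefined value with
  an explicit domain-error flag.
- **D_xy** is the mean between-population per-site difference fraction
  over complete-case sites (sites with any missing call excluded from
  numerator and denominator), with no multiple-hit correction.
- **Extreme-window flagging** returns the windows in a stated tail
  (default 5%) of the genome-wide empirical distribution, including ties
  at the quantile boundary; a degenerate (all-equal) distribution flags
  everything with a warning.

## LD and SR demarcation

Pairwise linkage disequilibrium is r², the squared Pearson correlation of
haploid genotype vectors, computed after pairwise missing-data removal;
sites monomorphic in the analyzed subset are skipped. Window mean r²
averages all SNP pairs in the window (dense windows are deterministically
thinned to 300 SNPs before the all-pairs computation — a cost cap, with
the thinning even in position so both window halves stay represented).
LD decay reports, for each 1-kb distance increment up to 500 kb, the mean
r² over all pairs *within* that distance (cumulative, matching the
classical presentation); a per-bin variant is available.

The SR detector takes the empirical 95% quantile of defined autosomal
window values as a cutoff, flags mat-chromosome windows above it, merges
runs of flagged windows bridging gaps of at most 2 below-cutoff windows,
and reports the run containing (or nearest to) the mat locus. Gap
bridging and the mat-locus anchor are not part of the quantile rule
itself; they make the SR a single contiguous region, which is how a
suppressed-recombination block physically behaves. The same machinery
applied to windowed mat A/mat a heterokaryon divergence gives the
divergence-based variant for lineages with too few strains for
informative LD.

**Boundary refinement.** 100-kb windows smear a sharp boundary over up to
a full window, and gap bridging can extend a run past it, so window-level
demarcation alone is accurate only to ~100 kb. When genotypes are
supplied, each edge is therefore relocated by a least-squares single
changepoint on a per-SNP profile — mean r² of every mat-chromosome SNP
against a core SR SNP set (central half of the coarse run, capped at 200
SNPs) for the LD method, per-site difference indicators of the
heterokaryon pair for the divergence method — fitted separately on each
side of the coarse-run midpoint over the whole half-chromosome. Searching
the full half-chromosome (not a window around the coarse edge) keeps the
refinement robust when the coarse run over- or undershoots by several
windows. A flat profile (no informative changepoint) falls back to the
coarse edge. Raising the quantile can only shrink the detected region.

## Coalescent machinery

Time is measured in units of 2N generations (Hudson convention): with k
lineages the next coalescence is exponential with rate k(k−1)/2 between a
uniformly chosen pair, and mutations fall at rate θ/2 per unit of total
branch length with θ = 4Nμ per locus. Mutation dropping is infinite-sites
and supports two modes: Poisson(θ/2 · L) (theta mode) and exactly S
mutations multinomial on branch lengths (fixed-S mode). Besides the
single-tree API, a vectorized batch engine simulates tens of thousands of
replicates in numpy; all Monte-Carlo-heavy procedures use it, and every
simulator is bit-reproducible under a fixed seed.

**Hard-sweep genealogy.** The neutral coalescent runs backward until T_s,
when all surviving lineages merge instantaneously into a single
(multifurcating) node and the tree ends — no ancestral branch, no logistic
sweep trajectory. T_s = 0 gives a zero-length star (S = 0 under any θ);
T_s → large recovers the neutral model.

**Tajima's-D null.** The empirical p-value for an observed D simulates
neutral no-recombination genealogies conditioned on the observed S
(fixed-S mode; a theta-mode null is available behind a flag) and uses the
(1 + m)/(1 + reps) estimator so p is never exactly 0. Undefined
replicates are redrawn (only possible in theta mode).

**Isolation (MSC) divergence simulator.** For the two-species no-
migration null, each of n_loci independent loci draws a pair coalescence
time τ_split + Exp(mean θ_anc/2) in expected-substitutions-per-site
units, then evolves a finite-site locus (default 25 kb) under
Jukes–Cantor: each site differs with probability (3/4)(1 − e^{−4d/3}) for
path length d = 2t. Finite sites matter because cross-species divergences
of several percent make multiple hits non-negligible; the JC-corrected
per-locus divergence has mean 2τ_split + θ_anc. Parameters are user
inputs; the documented default θ_anc = 0.018 is a realistic ancestral
population mutation parameter for *Neurospora*-scale species pairs, and
locus lengths below 100 bp are rejected as numerically unstable.

## Introgression inference

Site patterns are polarized against the outgroup and weighted by derived
allele frequencies: ABBA = (1−f₁)f₂f₃, BABA = f₁(1−f₂)f₃. For
single-genome taxa these weights reduce exactly to binary pattern
counting, so one code path serves both the strain-level (default) and
population-frequency modes. Sites with a polymorphic or missing outgroup,
or an uncalled focal taxon, are skipped.

Patterson's D = (ΣABBA − ΣBABA)/(ΣABBA + ΣBABA) gets its standard error
from a delete-one block jackknife over contiguous 250-kb genomic tiles
(tiles without informative sites dropped, equal weights), Z = D/SE, and a
two-sided normal p. With fewer than two informative blocks the SE is
reported unavailable. The windowed variant restricts counting to sites
fixed between the mat A and mat a chromosomes of one lineage, with
P1 = mat a and P2 = mat A so that donor introgression into mat A yields
D > 0.

The isolation divergence test compares an observed median 25-kb window
divergence with the simulated null distribution; the tail direction is an
explicit argument (lower when the SR is less diverged from the
heterothallic species than the recombining region, upper otherwise), and
p = 0 is reported as "< 1/n_loci".

## Sweep-model fitting

The observation is (S, k) at fourfold-degenerate third positions (codons
whose amino acid is invariant to any third-position base, evaluated on
the reference row). Over a (θ₀, T_s) grid — default θ₀ log-spaced on
[0.1, 10·θ_W] × 25 and T_s linear on [0, 4] × 41, spanning star-tree to
effectively neutral regimes — each cell runs replicate sweep genealogies
(default 25,000) with mutations at θ₀, accepting replicates with
|S_sim − S_obs| ≤ 0.05·S_obs and |k_sim − k_obs| ≤ 0.05·k_obs (the k
condition is skipped when k_obs = 0, where a ±5% band is degenerate). The
acceptance proportion is a rectangular-kernel ABC likelihood; the
maximum-acceptance pair is the MLE (ties resolve to the lowest grid
indices) and all pairs with ≥1 acceptance form the compatible set. An
all-zero surface is flagged `model_incompatible` — a legitimate finding,
not an error. Cells use independent child seeds from a single
SeedSequence.

A note on parameter recovery: a single non-recombining locus carries
irreducible genealogical noise — at θ₀ = 10, T_s = 0.1 and n = 12 a
single draw has S anywhere in roughly 1–11 — so no estimator can place
the MLE near truth from one draw. The recovery experiment in the
acceptance suite therefore uses the ensemble-mean (S, k) under the true
parameters as the observation, which isolates the property actually at
stake: that the likelihood surface is peaked at the generating
parameters and the grid machinery finds that peak.

## Coding-region load

P_N/P_S counting applies the 70% CDS-coverage filter (inclusive) and
masks codon columns with within-lineage polymorphism before divergence
analyses. Each polymorphic codon position is classified synonymous or
nonsynonymous against the sample-major codon context; codons with two or
more polymorphic positions, or more than two alleles at one position, are
skipped. Site denominators L_N and L_S use Nei–Gojobori (1986) expected
site fractions (each position contributes the fraction of its three
possible changes that are synonymous; changes to stop codons count as
nonsynonymous), and both the raw P_N/P_S and the per-site
(P_N/L_N)/(P_S/L_S) ratios are exposed.

Codon switches assume the outgroup codon is ancestral: a column
contributes when exactly one of the two ingroup rows differs from the
outgroup, by a single nucleotide, synonymously; the switch is classified
OP/NOP→OP/NOP by the optimality of the ancestral and derived codons.
Multi-substitution codons are skipped rather than path-enumerated,
matching the single-change allele-specific logic. The OP/NOP table is a
required input (real lists come from codon-usage studies of highly
expressed genes); the package ships a synthetic stand-in for tests —
third-position C/G codons marked optimal — which guarantees both classes
exist within every synonymous family that permits it. The between-genome
comparison is a Fisher's exact test on (NOP→OP, OP→NOP) × genome; an
empty margin returns p = 1 with a warning.

## The synthetic-data generator

`simulate_study` builds a complete study — genotypes, sample sheet,
truth tables — with the structure the analyses assume:

- **Selfing autosomes.** Recombination is emulated by independent
  coalescent genealogies per 50-kb block over one founder haplotype per
  heterokaryon; both homokaryons of a pair share the founder, with rare
  within-pair mismatches (10⁻⁵ per site). Block length is the knob for
  selfing-like LD; 50 kb yields autosomal window mean r² far below the
  near-complete LD of the SR. Default per-site θ = 0.002 within the
  lineage.
- **The SR block.** One whole-span no-recombination genealogy per mat
  class (within-class θ = 10⁻⁴, a 20-fold reduction) plus class-fixed
  differences at density 0.02 — the mat A/mat a divergence. This
  construction (star phylogeny between classes, coalescent within)
  produces the near-complete LD, elevated heterokaryon divergence and
  reduced within-class diversity that the detectors target.
- **Heterothallic species.** Single haploid genomes hang off the focal
  lineage at configured split times (donor 0.015, outgroup 0.03
  substitutions/site), via explicit branch mutation classes (tip, stem,
  shared-internal). A low-density incomplete-lineage-sorting component
  (5 × 10⁻⁴/site) plants sites shared between the donor and part of the
  focal lineage — a founder subset on autosomes, one whole mat class in
  the SR, where the mat haplotypes are old enough to sort trans-species.
  This is what gives Patterson's D a finite, honest jackknife SE on
  study data.
- **Introgression.** A donor tract replaces the configured mat class's
  SR haplotype: inside the tract that class shares the donor's branch
  down to the introgression time (donor divergence default 0.002) and
  bypasses the focal stem, so the tract shows low divergence to the
  donor, high mat A/mat a divergence, and a strong ABBA excess.
- **Sweeps.** In a sweep region, per-block genealogies are replaced by a
  simplified hitchhiking genealogy: each founder escapes with probability
  0.25, non-escapees form a star at T_s, and the coalescent continues
  above. Mutations on the deep branch separating the swept group from
  escapees sit at high derived frequency, producing the negative Fay & Wu
  H signature. The default escape probability reflects a flanking region
  at the distance where that signature is strongest; with no escapees a
  block shows only the diversity reduction, so the H signal of a 2–3
  window sweep is strong but not certain in every block.
- **Codon genes.** `simulate_codon_genes` writes in-frame three-way
  (outgroup, mat A, mat a) alignments from random sense codons with
  exact planted switch counts, each on its own codon column, so
  classification recovers the truth identically.

A separate quartet generator (`simulate_quartet_study`) produces
(P1, P2, P3, outgroup) data from a vectorized four-taxon multispecies
coalescent over many short blocks (default 1,000 × 10 kb), with genuine
incomplete lineage sorting in the ancestral populations and optional
introgression rerouting P2 through P3's population. Blocks are short
deliberately: a fully linked 50-kb block turns one deep ILS branch into a
single huge cluster of correlated pattern sites, making per-jackknife-
block sums heavy-tailed and the normal conversion of Z anticonservative;
10-kb blocks put ~25 independent genealogies in each 250-kb jackknife
block, the regime a real multi-megabase genome is in.

**What the generator does not emulate:** real recombination gradients
(block boundaries are abrupt), gene conversion, mutation-rate or
callability heterogeneity, indels and genotyping error, overlapping gene
structure, and demography beyond a panmictic lineage. Passing tests
demonstrate that the estimators recover planted truth under the stated
model, not that they are robust to every artifact of real resequencing
data.

## Problem sizes

The test suite runs synthetic studies at 4-Mb mat chromosomes with two
2-Mb autosomes (the generator's documented defaults are 8 + 4 + 4 Mb),
20-seed replication for the SR and sweep-fit recovery experiments,
200 + 100 seeded quartet runs for D calibration and power, 1,000-trial
probability-integral-transform checks of both empirical nulls, and
reduced replicate counts (2,000/cell) for grid fits; `scripts/
acceptance.py` analyzes a 6 + 3 + 3 Mb study with the full 50,000-locus
isolation null and a 10,000-replicate Tajima null. These sizes were
chosen so a complete verification runs in minutes on one core while every
Monte-Carlo check retains enough replication for its stated tolerance.

## Known limitations

- The divergence-based SR rule is a quantile analogue of the LD rule, not
  a reimplementation of any specific published divergence procedure.
- Unnormalized per-window Fay & Wu H scales with S, so its genome-wide
  extreme tail is dominated by SNP-dense windows; on strongly linked
  (blocky) genomes the neutral extremes approach sweep-generated values,
  which is why the flagging example asserts clustering at the sweep
  rather than exclusive detection.
- The sweep fit's acceptance-proportion likelihood is a kernel-bandwidth
  choice; compatible sets (not the raw likelihood values) are the robust
  output.
- P_N/P_S assumes at most one polymorphic position per codon; heavily
  polymorphic genes lose codons to the multi-hit skip rule (logged).
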