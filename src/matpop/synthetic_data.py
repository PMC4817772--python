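"""Generate complete synthetic studies with the genomic structure the
pipeline assumes: highly selfing lineages of paired homokaryons, a mating-
type chromosome carrying a large suppressed-recombination (SR) block of
elevated mat A / mat a divergence and reduced within-class diversity,
heterothallic reference genomes, optional donor introgression confined to
one mating type's SR, optional recent hard sweeps, and three-way CDS
alignments with planted synonymous codon switches.  Truth tables record
everything needed to score the detection stages.

Recombination is emulated by independent coalescent genealogies per block
(default 50 kb) rather than an ancestral recombination graph; the block
length is the knob for selfing-like LD.  The SR region instead carries a
single genealogy per mat class over its whole span, plus fixed differences
between the classes at the configured density, which produces the
near-complete-LD, elevated-divergence signature the SR detector looks for.
All randomness flows from a single seed through numpy SeedSequence
spawning.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codon_load import OptimalCodonTable, SwitchCounts, SENSE_CODONS
from .io_formats import (
    CodonAlignment,
    GENETIC_CODE,
    Region,
    SampleMeta,
    VariantTable,
    write_cds_alignment,
    write_regions_bed,
    write_sample_sheet,
    write_vcf,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class IntrogressionSpec:
    """A donor tract replacing one mating type's SR haplotype."""

    start: int
    end: int
    mating_type: str = "A"
    donor: str = "donor"
    donor_divergence: float = 0.002  # tract haplotype vs donor genome


@dataclass
class SweepSpec:
    """A recent hard sweep planted in a recombining region."""

    start: int
    end: int
    chrom: str = "mat"
    t_s: float = 0.05           # time since sweep, 2N generations
    # per-founder probability of escaping the sweep via recombination; the
    # default reflects a flanking region at the distance where the
    # high-frequency-derived signature is strongest (escape common enough
    # that most blocks retain at least one pre-sweep lineage)
    escape_prob: float = 0.25


@dataclass
class StudyConfig:
    """Generating parameters for one synthetic study.

    theta/sr_theta are per-site population mutation parameters (within the
    lineage / within one SR mat class); sr_divergence is the density of
    fixed differences between the mat A and mat a SR haplotypes;
    species_divergence gives per-species split times in expected
    substitutions per site.
    """

    n_pairs: int = 8
    lineage: str = "L1"
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {
        "mat": 8_000_000, "chr2": 4_000_000, "chr3": 4_000_000})
    mat_chrom: str = "mat"
    sr_start: int = 2_000_000
    sr_end: int = 7_000_000
    mat_locus_pos: int = 4_500_000
    theta: float = 0.002
    sr_theta: float = 0.0001
    sr_divergence: float = 0.02
    block_length: int = 50_000
    pair_mismatch_rate: float = 1e-5
    species_divergence: dict[str, float] = field(default_factory=lambda: {
        "donor": 0.015, "outgroup": 0.03})
    # density of incomplete-lineage-sorting sites shared between the donor
    # and part of the focal lineage (a founder subset on autosomes, one
    # whole mat class in the SR, where the classes are old haplotypes)
    species_ils_density: float = 5e-4
    introgression: IntrogressionSpec | None = None
    sweep: SweepSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.introgression, dict):  # JSON config convenience
            self.introgression = IntrogressionSpec(**self.introgression)
        if isinstance(self.sweep, dict):
            self.sweep = SweepSpec(**self.sweep)
        L = self.chrom_lengths[self.mat_chrom]
        if not (0 <= self.sr_start < self.sr_end <= L):
            raise ValueError("SR span outside the mat chromosome")
        if not (self.sr_start <= self.mat_locus_pos < self.sr_end):
            raise ValueError("mat locus must lie inside the SR span")
        if self.introgression is not None:
            i = self.introgression
            if not (self.sr_start <= i.start < i.end <= self.sr_end):
                raise ValueError("introgression tract must lie inside the SR")
            if i.donor not in self.species_divergence:
                raise ValueError(f"unknown donor species {i.donor!r}")
        if self.sweep is not None:
            s = self.sweep
            if s.chrom not in self.chrom_lengths or not (
                    0 <= s.start < s.end <= self.chrom_lengths[s.chrom]):
                raise ValueError("sweep region outside chromosome bounds")
        if min(self.theta, self.sr_theta, self.sr_divergence,
               self.pair_mismatch_rate) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class TruthTables:
    """Ground truth for scoring detection operations."""

    sr_region: Region
    introgressed_tracts: list[Region]
    sweep_regions: list[Region]
    config: StudyConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_regions_bed([self.sr_region], outdir / "truth_sr.bed")
        write_regions_bed(self.introgressed_tracts,
                          outdir / "truth_introgression.bed")
        write_regions_bed(self.sweep_regions, outdir / "truth_sweeps.bed")
        with open(outdir / "truth_params.json", "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2,
                      default=str)


@dataclass
class StudyData:
    table: VariantTable
    truth: TruthTables
    config: StudyConfig

    @property
    def focal_samples(self) -> list[str]:
        return [s.sample_id for s in self.table.samples
                if s.lineage == self.config.lineage]

    def mat_class(self, mating_type: str) -> list[str]:
        return [s.sample_id for s in self.table.samples
                if s.lineage == self.config.lineage
                and s.mating_type == mating_type]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.table, outdir / "study.vcf", self.config.chrom_lengths)
        write_sample_sheet(self.table.samples, outdir / "samples.tsv")
        self.truth.write(outdir)


# ---------------------------------------------------------------------------
# mutation-group machinery
# ---------------------------------------------------------------------------

class _Groups:
    """Mutation groups: (positions, carrier sample indices) pairs.

    Groups are assembled into a genotype matrix at the end; when two groups
    claim the same position the earlier-added group wins (infinite-sites
    approximation on an integer grid)."""

    def __init__(self) -> None:
        self.items: list[tuple[np.ndarray, np.ndarray]] = []

    def add(self, positions: np.ndarray, carriers) -> None:
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size == 0:
            return
        self.items.append((positions, np.asarray(carriers, dtype=np.intp)))

    def add_poisson(self, rng, rate: float, start: int, end: int,
                    carriers) -> None:
        """Poisson(rate * span) mutations uniform over [start, end)."""
        if rate <= 0 or end <= start:
            return
        m = rng.poisson(rate * (end - start))
        if m:
            self.add(rng.integers(start, end, size=m), carriers)

    def assemble(self, n_samples: int, rng) -> tuple[np.ndarray, np.ndarray,
                                                     np.ndarray, np.ndarray]:
        """Returns (pos, ref, alt, genotypes) sorted by position."""
        if not self.items:
            pos = np.empty(0, dtype=np.int64)
            return (pos, np.empty(0, "U1"), np.empty(0, "U1"),
                    np.zeros((n_samples, 0), dtype=np.int8))
        all_pos = np.concatenate([p for p, _ in self.items])
        gid = np.concatenate([np.full(len(p), i, dtype=np.int64)
                              for i, (p, _) in enumerate(self.items)])
        order = np.lexsort((gid, all_pos))
        all_pos, gid = all_pos[order], gid[order]
        keep = np.ones(len(all_pos), dtype=bool)
        keep[1:] = all_pos[1:] != all_pos[:-1]
        pos_u, gid_u = all_pos[keep], gid[keep]
        geno = np.zeros((n_samples, len(pos_u)), dtype=np.int8)
        by_group = np.argsort(gid_u, kind="stable")
        bounds = np.searchsorted(gid_u[by_group],
                                 np.arange(len(self.items) + 1))
        for i, (_, carriers) in enumerate(self.items):
            cols = by_group[bounds[i]:bounds[i + 1]]
            if cols.size and carriers.size:
                geno[np.ix_(carriers, cols)] = 1
        ref_i = rng.integers(0, 4, size=len(pos_u))
        alt_i = (ref_i + rng.integers(1, 4, size=len(pos_u))) % 4
        return pos_u, _BASES[ref_i], _BASES[alt_i], geno


def _coalescent_tree_groups(rng, groups: _Groups, leaf_carriers,
                            theta_site: float, start: int, end: int,
                            t_s: float | None = None,
                            escape_prob: float = 0.0) -> None:
    """Drop branch-wise mutation groups for one genealogy over [start, end).

    leaf_carriers[i] is the array of table sample indices represented by
    leaf i.  With ``t_s`` set, a simplified hard sweep is emulated: each
    leaf escapes with probability ``escape_prob``; non-escapees merge into
    a star node at t_s, and the neutral coalescent then continues among
    the escapees and the star ancestor.
    """
    n = len(leaf_carriers)
    if n == 0 or theta_site <= 0:
        return
    if n == 1:
        return  # a single haplotype carries no within-group polymorphism
    # active lineages: (carrier index array, birth time)
    active = [(np.asarray(c, dtype=np.intp), 0.0) for c in leaf_carriers]
    t = 0.0
    if t_s is not None:
        escaped = rng.random(n) < escape_prob
        swept = [active[i] for i in range(n) if not escaped[i]]
        kept = [active[i] for i in range(n) if escaped[i]]
        if len(swept) >= 2:
            for carriers, birth in swept:
                _branch_mutations(rng, groups, carriers, t_s - birth,
                                  theta_site, start, end)
            star = (np.concatenate([c for c, _ in swept]), t_s)
            active = kept + [star]
        t = t_s
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        j += j >= i
        (ca, ba), (cb, bb) = active[i], active[j]
        _branch_mutations(rng, groups, ca, t - ba, theta_site, start, end)
        _branch_mutations(rng, groups, cb, t - bb, theta_site, start, end)
        merged = (np.concatenate([ca, cb]), t)
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(merged)


def _branch_mutations(rng, groups, carriers, length, theta_site,
                      start, end) -> None:
    if length <= 0:
        return
    groups.add_poisson(rng, 0.5 * theta_site * length, start, end, carriers)


# ---------------------------------------------------------------------------
# the study generator
# ---------------------------------------------------------------------------

def _make_samples(config: StudyConfig) -> list[SampleMeta]:
    samples = []
    for i in range(1, config.n_pairs + 1):
        het = f"{config.lineage}H{i:02d}"
        for mt in ("A", "a"):
            samples.append(SampleMeta(
                sample_id=f"{het}{mt}", species="focal",
                lineage=config.lineage, mating_type=mt,
                heterokaryon_id=het))
    for sp in sorted(config.species_divergence):
        samples.append(SampleMeta(sample_id=sp, species=sp))
    return samples


def simulate_study(config: StudyConfig) -> StudyData:
    """Simulate a full synthetic study (genotypes + truth tables).

    Autosomes and the recombining parts of the mat chromosome are built
    from independent per-block genealogies over one founder haplotype per
    heterokaryon (both homokaryons of a pair share the founder, emulating
    selfing).  The SR carries one whole-span genealogy per mat class plus
    class-fixed differences; heterothallic species are single haploid
    genomes hanging off the focal lineage at their configured divergence
    times.
    """
    ss = np.random.SeedSequence(config.seed)
    samples = _make_samples(config)
    id_index = {s.sample_id: i for i, s in enumerate(samples)}
    focal = [s for s in samples if s.lineage == config.lineage]
    focal_idx = np.array([id_index[s.sample_id] for s in focal])
    a_idx = np.array([id_index[s.sample_id] for s in focal
                      if s.mating_type == "A"])
    low_idx = np.array([id_index[s.sample_id] for s in focal
                        if s.mating_type == "a"])
    pair_carriers = [
        np.array([id_index[f"{config.lineage}H{i:02d}A"],
                  id_index[f"{config.lineage}H{i:02d}a"]])
        for i in range(1, config.n_pairs + 1)
    ]
    tau = config.species_divergence
    tau_out = max(tau.values())

    chrom_arrays = {}
    child_seeds = ss.spawn(len(config.chrom_lengths) + 1)
    for (chrom, length), cs in zip(sorted(config.chrom_lengths.items()),
                                   child_seeds):
        rng = np.random.default_rng(cs)
        groups = _Groups()
        is_mat = chrom == config.mat_chrom
        tract = None
        if is_mat and config.introgression is not None:
            tract = (config.introgression.start, config.introgression.end)

        _species_branch_groups(rng, groups, config, samples, id_index,
                               focal_idx, a_idx, low_idx, chrom, length,
                               tract)
        out_species = max(tau, key=tau.get)
        for sp in sorted(tau):
            if sp != out_species:
                _ils_groups(rng, groups, config, a_idx, low_idx,
                            pair_carriers, id_index[sp], chrom, length)

        # recombining segments: whole autosomes; mat chromosome outside SR
        segments = ([(0, config.sr_start), (config.sr_end, length)]
                    if is_mat else [(0, length)])
        for seg_start, seg_end in segments:
            for blk_start in range(seg_start, seg_end, config.block_length):
                blk_end = min(blk_start + config.block_length, seg_end)
                if blk_end <= blk_start:
                    continue
                sweep = config.sweep
                in_sweep = (sweep is not None and sweep.chrom == chrom
                            and blk_start < sweep.end
                            and blk_end > sweep.start)
                _coalescent_tree_groups(
                    rng, groups, pair_carriers, config.theta,
                    blk_start, blk_end,
                    t_s=sweep.t_s if in_sweep else None,
                    escape_prob=sweep.escape_prob if in_sweep else 0.0)

        if is_mat:
            _sr_groups(rng, groups, config, a_idx, low_idx, pair_carriers,
                       tract)

        # rare within-heterokaryon mismatches (selfing is near-clonal)
        for carriers in pair_carriers:
            m = rng.poisson(config.pair_mismatch_rate * length)
            for _ in range(m):
                which = carriers[int(rng.integers(2))]
                groups.add(rng.integers(0, length, size=1), [which])

        pos, ref, alt, geno = groups.assemble(len(samples), rng)
        chrom_arrays[chrom] = (pos, ref, alt, geno)

    chroms, poss, refs, alts, genos = [], [], [], [], []
    for chrom in sorted(config.chrom_lengths):
        pos, ref, alt, geno = chrom_arrays[chrom]
        chroms.extend([chrom] * len(pos))
        poss.append(pos)
        refs.append(ref)
        alts.append(alt)
        genos.append(geno)
    table = VariantTable(
        chroms, np.concatenate(poss), np.concatenate(refs),
        np.concatenate(alts), np.concatenate(genos, axis=1), samples)

    truth = TruthTables(
        sr_region=Region(config.mat_chrom, config.sr_start, config.sr_end,
                         "SR"),
        introgressed_tracts=(
            [Region(config.mat_chrom, config.introgression.start,
                    config.introgression.end, config.introgression.donor)]
            if config.introgression else []),
        sweep_regions=(
            [Region(config.sweep.chrom, config.sweep.start,
                    config.sweep.end, "sweep")] if config.sweep else []),
        config=config,
    )
    return StudyData(table=table, truth=truth, config=config)


def _species_branch_groups(rng, groups, config, samples, id_index,
                           focal_idx, a_idx, low_idx, chrom, length,
                           tract) -> None:
    """Fixed-difference groups from the species phylogeny.

    The focal lineage and each heterothallic species diverge at their
    configured times; inside an introgressed tract the introgressed mat
    class descends through the donor instead of the focal stem.
    """
    tau = config.species_divergence
    tau_out = max(tau.values())
    out_species = max(tau, key=tau.get)
    intro = config.introgression
    intro_idx = a_idx if (intro and intro.mating_type == "A") else low_idx
    other_idx = low_idx if (intro and intro.mating_type == "A") else a_idx

    # non-introgressed segments of this chromosome
    if tract is None:
        plain = [(0, length)]
    else:
        plain = [(0, tract[0]), (tract[1], length)]

    for sp in sorted(tau):
        sp_i = id_index[sp]
        t_sp = tau[sp]
        if sp == out_species:
            groups.add_poisson(rng, t_sp, 0, length, [sp_i])  # tip branch
            continue
        # internal branch: ancestor of focal + this species, up to outgroup
        groups.add_poisson(rng, tau_out - t_sp, 0, length,
                           np.concatenate([focal_idx, [sp_i]]))
        if tract is not None and intro is not None and sp == intro.donor:
            tau_i = 0.5 * intro.donor_divergence
            for s, e in plain:
                groups.add_poisson(rng, t_sp, s, e, [sp_i])
            # inside the tract: donor drift since introgression, the shared
            # donor+introgressed-class branch, and the class's own drift
            groups.add_poisson(rng, tau_i, tract[0], tract[1], [sp_i])
            groups.add_poisson(rng, t_sp - tau_i, tract[0], tract[1],
                               np.concatenate([intro_idx, [sp_i]]))
            groups.add_poisson(rng, tau_i, tract[0], tract[1], intro_idx)
        else:
            groups.add_poisson(rng, t_sp, 0, length, [sp_i])

    # focal stem (focal MRCA back to the nearest species split)
    t_stem = min(t for s, t in tau.items() if s != out_species) \
        if len(tau) > 1 else tau_out
    for s, e in plain:
        groups.add_poisson(rng, t_stem, s, e, focal_idx)
    if tract is not None:
        # in the tract the introgressed class bypasses the focal stem
        groups.add_poisson(rng, t_stem, tract[0], tract[1], other_idx)


def _ils_groups(rng, groups, config, a_idx, low_idx, pair_carriers,
                donor_i, chrom, length) -> None:
    """Ancestral-polymorphism (incomplete lineage sorting) sites shared
    between the donor and part of the focal lineage.

    On recombining sequence the shared partner is a random subset of
    founder pairs (sizes ~ 1/s, the neutral frequency spectrum); in the SR
    the partner is one whole mat class — the mat haplotypes are old enough
    to sort incompletely across the species split (trans-species
    polymorphism around the mating-type locus)."""
    dens = config.species_ils_density
    if dens <= 0:
        return
    is_mat = chrom == config.mat_chrom
    segments = ([(0, config.sr_start, False),
                 (config.sr_start, config.sr_end, True),
                 (config.sr_end, length, False)]
                if is_mat else [(0, length, False)])
    n_pairs = len(pair_carriers)
    sizes = np.arange(1, n_pairs)
    size_p = (1.0 / sizes) / (1.0 / sizes).sum()
    for s, e, in_sr in segments:
        if e <= s:
            continue
        m = rng.poisson(dens * (e - s))
        if m == 0:
            continue
        pos = rng.integers(s, e, size=m)
        if in_sr:
            side = rng.random(m) < 0.5
            groups.add(pos[side], np.concatenate([a_idx, [donor_i]]))
            groups.add(pos[~side], np.concatenate([low_idx, [donor_i]]))
        else:
            for p in pos:
                k = int(rng.choice(sizes, p=size_p))
                chosen = rng.choice(n_pairs, size=k, replace=False)
                carriers = np.concatenate(
                    [pair_carriers[c] for c in chosen] + [[donor_i]])
                groups.add(np.array([p]), carriers)


def _sr_groups(rng, groups, config, a_idx, low_idx, pair_carriers,
               tract) -> None:
    """SR region: one no-recombination genealogy per mat class over the
    whole SR span, plus class-fixed differences between the classes."""
    sr_start, sr_end = config.sr_start, config.sr_end
    for class_idx in (a_idx, low_idx):
        _coalescent_tree_groups(
            rng, groups, [np.array([i]) for i in class_idx],
            config.sr_theta, sr_start, sr_end)
    # class-fixed differences, skipping an introgressed tract (handled by
    # the species machinery there)
    if tract is None:
        spans = [(sr_start, sr_end)]
    else:
        spans = [(sr_start, tract[0]), (tract[1], sr_end)]
        intro = config.introgression
        keep_idx = low_idx if intro.mating_type == "A" else a_idx
        # the non-introgressed class still carries its own SR divergence
        groups.add_poisson(rng, 0.5 * config.sr_divergence,
                           tract[0], tract[1], keep_idx)
    for s, e in spans:
        if e <= s:
            continue
        m = rng.poisson(config.sr_divergence * (e - s))
        if m == 0:
            continue
        pos = rng.integers(s, e, size=m)
        side = rng.random(m) < 0.5
        groups.add(pos[side], a_idx)
        groups.add(pos[~side], low_idx)


# ---------------------------------------------------------------------------
# four-taxon quartet generator (multispecies coalescent with ILS)
# ---------------------------------------------------------------------------

@dataclass
class QuartetConfig:
    """Four-taxon (P1, P2, P3, outgroup) study on one chromosome, built
    from per-block multispecies-coalescent genealogies (times and thetas
    in expected substitutions per site).  Incomplete lineage sorting in
    the ancestral populations produces ABBA/BABA sites even without gene
    flow; an introgressed fraction reroutes P2 through P3's population at
    tau_intro for the leading blocks of the chromosome.

    Blocks are short (10 kb) so a single deep genealogy contributes a
    modest cluster of linked pattern sites rather than one huge one, and
    the default 10-Mb chromosome gives the 250-kb jackknife 40 blocks of
    ~25 independent genealogies each -- the regime where the normal
    conversion of the jackknife Z is trustworthy."""

    n_blocks: int = 1000
    block_length: int = 10_000
    tau1: float = 0.010      # P1-P2 split
    tau2: float = 0.012      # (P1,P2)-P3 split
    tau3: float = 0.020      # outgroup split
    theta_anc: float = 0.005
    introgressed_fraction: float = 0.0
    tau_intro: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.tau1 < self.tau2 < self.tau3):
            raise ValueError("need 0 < tau1 < tau2 < tau3")
        if not (0 <= self.tau_intro < self.tau2):
            raise ValueError("tau_intro must precede tau2")
        if not (0 <= self.introgressed_fraction <= 1):
            raise ValueError("introgressed_fraction in [0, 1]")


def _vec_coalesce_epoch(rng, t0, t_end, masks, births, alive, pool, theta,
                        records) -> None:
    """Coalesce pooled lineages in one population epoch, vectorized over
    blocks.

    masks/births/alive are (R, 4) slot arrays (bitmask over taxa, lineage
    birth time, liveness); ``pool`` flags the slots belonging to this
    epoch's population.  Pair coalescence waiting times are
    Exp(mean theta/2); by memorylessness, blocks whose next event falls
    beyond ``t_end`` simply redraw in the next epoch.  Branch segments of
    coalesced lineages are appended to ``records``.
    """
    R = masks.shape[0]
    t = np.full(R, float(t0))
    done = np.zeros(R, dtype=bool)
    while True:
        active = pool & alive
        k = active.sum(axis=1)
        can = (k >= 2) & ~done
        if not can.any():
            break
        w = np.full(R, np.inf)
        kk = k[can].astype(float)
        w[can] = rng.exponential(theta, size=int(can.sum())) / (kk * (kk - 1))
        t_new = t + w
        do = can & (t_new < t_end)
        done |= can & ~do
        idx = np.flatnonzero(do)
        if idx.size == 0:
            continue
        act = active[idx]
        order = np.cumsum(act, axis=1) - 1  # rank of each active slot
        r1 = rng.integers(0, k[idx])
        r2 = rng.integers(0, k[idx] - 1)
        r2 = r2 + (r2 >= r1)
        slot1 = np.argmax(act & (order == r1[:, None]), axis=1)
        slot2 = np.argmax(act & (order == r2[:, None]), axis=1)
        tb = t_new[idx]
        for slot in (slot1, slot2):
            records.append((idx, masks[idx, slot].copy(),
                            tb - births[idx, slot]))
        masks[idx, slot1] = masks[idx, slot1] | masks[idx, slot2]
        births[idx, slot1] = tb
        alive[idx, slot2] = False
        masks[idx, slot2] = 0
        t[idx] = tb


def _simulate_quartet_branches(cfg: QuartetConfig, rng,
                               intro: np.ndarray):
    """Branch records [(block idx, carrier bitmask, length)] for all
    blocks; taxon bits are P1=1, P2=2, P3=4, O=8."""
    R = cfg.n_blocks
    masks = np.tile(np.array([1, 2, 4, 8], dtype=np.uint8), (R, 1))
    births = np.zeros((R, 4))
    alive = np.ones((R, 4), dtype=bool)
    records: list = []
    th = cfg.theta_anc

    # [tau_intro, tau1): introgressed blocks: P2 sits in P3's population
    pool = np.zeros((R, 4), dtype=bool)
    pool[intro, 1] = pool[intro, 2] = True
    _vec_coalesce_epoch(rng, cfg.tau_intro, cfg.tau1, masks, births, alive,
                        pool, th, records)
    # [tau1, tau2): ancestral P1P2 population (P2+P3 pool persists for
    # introgressed blocks; their P1 stays isolated until tau2)
    pool = np.zeros((R, 4), dtype=bool)
    pool[~intro, 0] = pool[~intro, 1] = True
    pool[intro, 1] = pool[intro, 2] = True
    _vec_coalesce_epoch(rng, cfg.tau1, cfg.tau2, masks, births, alive,
                        pool, th, records)
    # [tau2, tau3): common ancestor of P1, P2, P3
    pool = np.ones((R, 4), dtype=bool)
    pool[:, 3] = False
    _vec_coalesce_epoch(rng, cfg.tau2, cfg.tau3, masks, births, alive,
                        pool, th, records)
    # [tau3, inf): root population
    pool = np.ones((R, 4), dtype=bool)
    _vec_coalesce_epoch(rng, cfg.tau3, np.inf, masks, births, alive,
                        pool, th, records)
    return records


def simulate_quartet_study(cfg: QuartetConfig) -> VariantTable:
    """Simulate a four-taxon VariantTable on one chromosome ("chr1")."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    n_intro = int(round(cfg.introgressed_fraction * cfg.n_blocks))
    intro = np.arange(cfg.n_blocks) < n_intro
    records = _simulate_quartet_branches(cfg, rng, intro)

    blocks = np.concatenate([r[0] for r in records])
    bmasks = np.concatenate([r[1] for r in records])
    lens = np.concatenate([r[2] for r in records])
    m = rng.poisson(lens * cfg.block_length)
    total = int(m.sum())
    rep_block = np.repeat(blocks, m)
    rep_mask = np.repeat(bmasks, m)
    pos = rep_block.astype(np.int64) * cfg.block_length \
        + rng.integers(0, cfg.block_length, size=total)
    order = np.argsort(pos, kind="stable")
    pos, rep_mask = pos[order], rep_mask[order]
    keep = np.ones(total, dtype=bool)
    keep[1:] = pos[1:] != pos[:-1]
    pos, rep_mask = pos[keep], rep_mask[keep]
    geno = ((rep_mask[None, :] >> np.arange(4)[:, None]) & 1).astype(np.int8)
    ref_i = rng.integers(0, 4, size=len(pos))
    alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
    samples = [
        SampleMeta("P1", species="sp1"), SampleMeta("P2", species="sp2"),
        SampleMeta("P3", species="sp3"), SampleMeta("O", species="out"),
    ]
    return VariantTable(["chr1"] * len(pos), pos, _BASES[ref_i],
                        _BASES[alt_i], geno, samples)


# ---------------------------------------------------------------------------
# codon-gene generator
# ---------------------------------------------------------------------------

def toy_optimal_codon_table() -> OptimalCodonTable:
    """A synthetic OP/NOP classification for tests and demonstrations:
    codons with a C or G third position are 'optimal'.  (Real optimality
    lists come from codon-usage studies of highly expressed genes; this
    stand-in merely guarantees every synonymous family has both classes
    where the family permits it.)"""
    classes = {c: ("OP" if c[2] in "CG" else "NOP") for c in SENSE_CODONS}
    return OptimalCodonTable(classes)


def _switch_options(table: OptimalCodonTable):
    """(anc, derived) codon pairs per category: single-base synonymous
    changes between the classes."""
    options: dict[str, list[tuple[str, str]]] = {
        "OP->OP": [], "OP->NOP": [], "NOP->OP": [], "NOP->NOP": []}
    for anc in SENSE_CODONS:
        for p in range(3):
            for b in "ACGT":
                if b == anc[p]:
                    continue
                der = anc[:p] + b + anc[p + 1:]
                if GENETIC_CODE.get(der) != GENETIC_CODE[anc] \
                        or GENETIC_CODE.get(der) == "*":
                    continue
                cat = f"{table[anc]}->{table[der]}"
                options[cat].append((anc, der))
    return options


@dataclass
class CodonGeneConfig:
    """Three-way CDS alignments with planted synonymous codon switches.

    switch_counts plants exactly the stated number of switches per genome
    and category, each on its own codon column."""

    n_genes: int = 20
    n_codons: int = 200
    switch_counts: dict[str, dict[str, int]] = field(default_factory=lambda: {
        "mat_A": {"NOP->OP": 30, "OP->NOP": 5},
        "mat_a": {"NOP->OP": 5, "OP->NOP": 30},
    })
    seed: int = 0


def simulate_codon_genes(cfg: CodonGeneConfig,
                         optimal_table: OptimalCodonTable | None = None
                         ) -> tuple[list[CodonAlignment], SwitchCounts]:
    """Generate in-frame (outgroup, mat_A, mat_a) codon alignments with
    planted switches; returns the alignments and the truth SwitchCounts."""
    optimal_table = optimal_table or toy_optimal_codon_table()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    options = _switch_options(optimal_table)
    total_cols = cfg.n_genes * cfg.n_codons
    planted: list[tuple[int, str, str, str]] = []  # (col, genome, anc, der)
    wanted = sum(n for cats in cfg.switch_counts.values()
                 for n in cats.values())
    if wanted > total_cols:
        raise ValueError("switch counts exceed available codon columns "
                         "(more than one change per codon)")
    cols = rng.choice(total_cols, size=wanted, replace=False)
    truth = SwitchCounts()
    ci = 0
    for genome in sorted(cfg.switch_counts):
        for cat in sorted(cfg.switch_counts[genome]):
            n = cfg.switch_counts[genome][cat]
            if n and not options[cat]:
                raise ValueError(f"no codon pair available for {cat}")
            for _ in range(n):
                anc, der = options[cat][int(rng.integers(len(options[cat])))]
                planted.append((int(cols[ci]), genome, anc, der))
                truth.add(genome, cat)
                ci += 1
    truth.genome("mat_A")
    truth.genome("mat_a")

    anc_codons = np.array(SENSE_CODONS)[
        rng.integers(0, len(SENSE_CODONS), size=total_cols)]
    rows = {"outgroup": anc_codons.copy(), "mat_A": anc_codons.copy(),
            "mat_a": anc_codons.copy()}
    for col, genome, anc, der in planted:
        for r in rows.values():
            r[col] = anc
        rows[genome][col] = der

    alignments = []
    for g in range(cfg.n_genes):
        sl = slice(g * cfg.n_codons, (g + 1) * cfg.n_codons)
        codons = np.stack([rows["outgroup"][sl], rows["mat_A"][sl],
                           rows["mat_a"][sl]])
        alignments.append(CodonAlignment(
            gene_id=f"gene{g + 1:03d}",
            names=["outgroup", "mat_A", "mat_a"],
            codons=codons,
            codon_mask=np.ones(cfg.n_codons, dtype=bool),
            full_length=3 * cfg.n_codons,
        ))
    return alignments, truth


def write_codon_genes(alignments, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for aln in alignments:
        write_cds_alignment(aln, outdir / f"{aln.gene_id}.fasta")
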