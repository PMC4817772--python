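"""Mutational-load analyses in coding regions.

Covers P_N/P_S polymorphism counting with the gene-coverage and
polymorphic-codon filters, Nei-Gojobori (1986) expected-site denominators,
allele-specific optimal/nonoptimal (OP/NOP) codon-switch classification
against an outgroup ancestral state, and the associated Fisher's-exact
contingency comparisons.

Codon optimality reflects translational selection: OP codons are the
synonymous variants preferred in highly expressed genes, so an excess of
OP->NOP switches on one chromosome signals relaxed selection on codon
usage (degeneration), while NOP->OP excess marks a haplotype that evolved
under stronger or longer-lasting translational selection (e.g. an
introgressed donor haplotype).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import GENETIC_CODE, STOP_CODONS, CodonAlignment

logger = logging.getLogger(__name__)

_BASES = "ACGT"
SWITCH_CATEGORIES = ("OP->OP", "OP->NOP", "NOP->OP", "NOP->NOP")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))


# ---------------------------------------------------------------------------
# OP/NOP table
# ---------------------------------------------------------------------------

class OptimalCodonTable:
    """codon -> {OP, NOP} classification over all sense codons.

    Stop codons are excluded; by default every sense codon must be
    classified (``strict=False`` relaxes this, leaving unlisted codons
    unclassifiable and their switches uncounted).
    """

    def __init__(self, classes: dict[str, str], strict: bool = True):
        self.classes = {}
        for codon, cls in classes.items():
            codon = codon.upper()
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} cannot be classified")
            if cls not in ("OP", "NOP"):
                raise ValueError(f"class for {codon} must be OP or NOP")
            self.classes[codon] = cls
        if strict:
            missing = set(SENSE_CODONS) - set(self.classes)
            if missing:
                raise ValueError(
                    f"unclassified sense codons: {sorted(missing)[:5]}..."
                )

    def __getitem__(self, codon: str) -> str | None:
        return self.classes.get(codon.upper())

    @classmethod
    def from_tsv(cls, path, strict: bool = True) -> "OptimalCodonTable":
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["codon", "class"], header=None, dtype=str)
        if df.iloc[0, 0].lower() == "codon":  # tolerate a header line
            df = df.iloc[1:]
        return cls(dict(zip(df["codon"], df["class"])), strict=strict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tclass\n")
            for codon in sorted(self.classes):
                fh.write(f"{codon}\t{self.classes[codon]}\n")


# ---------------------------------------------------------------------------
# gene filters
# ---------------------------------------------------------------------------

def filter_genes(alignments: Iterable[CodonAlignment],
                 min_frac: float = 0.70) -> list[CodonAlignment]:
    """Keep genes whose alignment covers at least ``min_frac`` (inclusive)
    of the declared full-length coding sequence; genes without a declared
    full length are kept."""
    kept, dropped = [], 0
    for aln in alignments:
        if aln.full_length:
            frac = (3 * aln.n_codons) / aln.full_length
            if frac < min_frac:
                dropped += 1
                continue
        kept.append(aln)
    if dropped:
        logger.info("filter_genes: removed %d genes below %.0f%% coverage",
                    dropped, 100 * min_frac)
    return kept


def remove_polymorphic_codons(alignment: CodonAlignment,
                              lineage_samples: Sequence[str]
                              ) -> CodonAlignment:
    """Mask codon columns with any polymorphism segregating within the
    lineage (rows named in ``lineage_samples``)."""
    rows = [alignment.names.index(s) for s in lineage_samples]
    mask = alignment.codon_mask.copy()
    n_masked = 0
    for j in np.flatnonzero(mask):
        if len(set(alignment.codons[rows, j])) > 1:
            mask[j] = False
            n_masked += 1
    if n_masked:
        logger.info("remove_polymorphic_codons: %s: masked %d codons",
                    alignment.gene_id, n_masked)
    if not mask.any():
        warnings.warn(f"{alignment.gene_id}: all codons polymorphic; "
                      "gene effectively dropped")
    return CodonAlignment(alignment.gene_id, list(alignment.names),
                          alignment.codons, mask, alignment.full_length)


# ---------------------------------------------------------------------------
# P_N / P_S
# ---------------------------------------------------------------------------

@dataclass
class PolymorphismCounts:
    """Counts of nonsynonymous/synonymous polymorphisms and NG86 expected
    site denominators, with per-site-class diversity."""

    p_n: int = 0
    p_s: int = 0
    l_n: float = 0.0
    l_s: float = 0.0
    pi_n: float = float("nan")
    pi_s: float = float("nan")

    @property
    def pn_ps_raw(self) -> float:
        return self.p_n / self.p_s if self.p_s else float("nan")

    @property
    def pn_ps_per_site(self) -> float:
        """(P_N / L_N) / (P_S / L_S), the expected-site-normalized ratio."""
        if not (self.p_s and self.l_n and self.l_s):
            return float("nan")
        return (self.p_n / self.l_n) / (self.p_s / self.l_s)


def ng86_site_fractions(codon: str) -> tuple[float, float]:
    """Nei-Gojobori expected (synonymous, nonsynonymous) site counts for
    one codon: at each position, the fraction of the three possible base
    changes that are synonymous (changes to stop codons count as
    nonsynonymous)."""
    aa = GENETIC_CODE.get(codon)
    if aa is None or aa == "*":
        return 0.0, 0.0
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE.get(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


_NG86_CACHE = {c: ng86_site_fractions(c) for c in SENSE_CODONS}


def count_pn_ps(alignment: CodonAlignment, samples: Sequence[str]
                ) -> PolymorphismCounts:
    """P_N, P_S, NG86 site totals and per-class diversity for one gene.

    Each polymorphic codon position is classified synonymous or
    nonsynonymous against the sample-major codon context.  Codons with two
    or more polymorphic positions, or more than two alleles at a position,
    are skipped (logged).  L_N and L_S sum the NG86 fractions of the major
    codon over usable columns.
    """
    rows = [alignment.names.index(s) for s in samples]
    n = len(rows)
    if n < 2:
        raise ValueError("P_N/P_S needs >= 2 samples")
    l_n = l_s = 0.0
    p_n = p_s = 0
    pi_n_sum = pi_s_sum = 0.0
    n_skipped = 0
    for j in np.flatnonzero(alignment.codon_mask):
        codons = [alignment.codons[r, j] for r in rows]
        if any("-" in c or "N" in c for c in codons):
            continue
        major = Counter(codons).most_common(1)[0][0]
        if major in STOP_CODONS:
            continue
        s_frac, n_frac = _NG86_CACHE.get(major, (0.0, 0.0))
        l_s += s_frac
        l_n += n_frac
        poly_pos = [p for p in range(3)
                    if len({c[p] for c in codons}) > 1]
        if not poly_pos:
            continue
        if len(poly_pos) > 1:
            n_skipped += 1
            continue
        p = poly_pos[0]
        bases = sorted({c[p] for c in codons})
        if len(bases) > 2:
            n_skipped += 1
            continue
        variants = [major[:p] + b + major[p + 1:] for b in bases]
        aas = {GENETIC_CODE.get(v) for v in variants}
        count = sum(c[p] == bases[1] for c in codons)
        site_pi = 2.0 * count * (n - count) / (n * (n - 1))
        if len(aas) == 1 and "*" not in aas:
            p_s += 1
            pi_s_sum += site_pi
        else:
            p_n += 1
            pi_n_sum += site_pi
    if n_skipped:
        logger.info("count_pn_ps: %s: skipped %d multi-hit codons",
                    alignment.gene_id, n_skipped)
    return PolymorphismCounts(
        p_n=p_n, p_s=p_s, l_n=l_n, l_s=l_s,
        pi_n=pi_n_sum / l_n if l_n else float("nan"),
        pi_s=pi_s_sum / l_s if l_s else float("nan"),
    )


def sum_counts(counts: Iterable[PolymorphismCounts]) -> PolymorphismCounts:
    """Pool per-gene counts; pooled pi_N/pi_S are re-derived from the
    pooled numerators."""
    counts = list(counts)
    p_n = sum(c.p_n for c in counts)
    p_s = sum(c.p_s for c in counts)
    l_n = sum(c.l_n for c in counts)
    l_s = sum(c.l_s for c in counts)
    num_n = sum(c.pi_n * c.l_n for c in counts if np.isfinite(c.pi_n))
    num_s = sum(c.pi_s * c.l_s for c in counts if np.isfinite(c.pi_s))
    return PolymorphismCounts(
        p_n=p_n, p_s=p_s, l_n=l_n, l_s=l_s,
        pi_n=num_n / l_n if l_n else float("nan"),
        pi_s=num_s / l_s if l_s else float("nan"),
    )


def pn_ps_fisher(a: PolymorphismCounts, b: PolymorphismCounts
                 ) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 (P_N, P_S) x (region) table;
    returns (odds ratio, two-sided p)."""
    odds, p = sps.fisher_exact([[a.p_n, a.p_s], [b.p_n, b.p_s]])
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# codon switches
# ---------------------------------------------------------------------------

@dataclass
class SwitchCounts:
    """OP/NOP switch counts per genome (e.g. mat A vs mat a)."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def genome(self, name: str) -> dict[str, int]:
        return self.counts.setdefault(
            name, {c: 0 for c in SWITCH_CATEGORIES})

    def add(self, genome: str, category: str, n: int = 1) -> None:
        if category not in SWITCH_CATEGORIES:
            raise ValueError(f"unknown switch category {category!r}")
        self.genome(genome)[category] += n

    def total(self, genome: str | None = None) -> int:
        genomes = [genome] if genome else list(self.counts)
        return sum(self.genome(g)[c] for g in genomes
                   for c in SWITCH_CATEGORIES)

    def __add__(self, other: "SwitchCounts") -> "SwitchCounts":
        out = SwitchCounts()
        for src in (self, other):
            for g, cats in src.counts.items():
                for c, n in cats.items():
                    out.add(g, c, n)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"genome": g, **cats} for g, cats in self.counts.items()]
        return pd.DataFrame(rows)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def classify_codon_switches(
    threeway: CodonAlignment,
    optimal_table: OptimalCodonTable,
    outgroup: str | None = None,
    mat_A: str | None = None,
    mat_a: str | None = None,
) -> SwitchCounts:
    """Classify allele-specific synonymous codon switches against the
    outgroup ancestral state.

    For each usable codon column of a three-way (outgroup, mat A, mat a)
    alignment: when exactly one ingroup row differs from the outgroup
    codon, the difference is a single nucleotide, and the change is
    synonymous, the switch is classified by the OP/NOP status of the
    outgroup codon -> the derived codon.  Columns where both ingroups
    differ, the change is nonsynonymous, or the codon is a multi-hit are
    skipped.  Row names default to the first three alignment rows in
    (outgroup, mat A, mat a) order.
    """
    names = threeway.names
    outgroup = outgroup or names[0]
    mat_A = mat_A or names[1]
    mat_a = mat_a or names[2]
    og = threeway.row(outgroup)
    rows = {mat_A: threeway.row(mat_A), mat_a: threeway.row(mat_a)}
    out = SwitchCounts()
    out.genome(mat_A)
    out.genome(mat_a)
    for j in np.flatnonzero(threeway.codon_mask):
        anc = og[j]
        if "-" in anc or anc in STOP_CODONS or "N" in anc:
            continue
        differing = [g for g, r in rows.items() if r[j] != anc]
        if len(differing) != 1:
            continue
        genome = differing[0]
        der = rows[genome][j]
        if "-" in der or "N" in der:
            continue
        if _hamming(anc, der) != 1:
            continue  # multi-substitution codon: path not enumerated
        if GENETIC_CODE.get(der) != GENETIC_CODE.get(anc) \
                or der in STOP_CODONS:
            continue  # nonsynonymous change
        cls_anc = optimal_table[anc]
        cls_der = optimal_table[der]
        if cls_anc is None or cls_der is None:
            continue
        out.add(genome, f"{cls_anc}->{cls_der}")
    return out


@dataclass
class SwitchComparison:
    odds_ratio: float
    p: float
    table: list[list[int]]


def compare_switches(counts: SwitchCounts, genome_a: str, genome_b: str
                     ) -> SwitchComparison:
    """Fisher's exact test on (NOP->OP, OP->NOP) x (genome) — does one mat
    chromosome show an excess of switches toward optimal codons?"""
    a = counts.genome(genome_a)
    b = counts.genome(genome_b)
    tab = [[a["NOP->OP"], a["OP->NOP"]], [b["NOP->OP"], b["OP->NOP"]]]
    if any(sum(row) == 0 for row in tab) or any(
            tab[0][i] + tab[1][i] == 0 for i in range(2)):
        warnings.warn("compare_switches: a table margin is empty; p = 1")
        return SwitchComparison(float("nan"), 1.0, tab)
    odds, p = sps.fisher_exact(tab)
    return SwitchComparison(float(odds), float(p), tab)
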