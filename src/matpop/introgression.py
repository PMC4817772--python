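"""Introgression inference: Patterson's D (ABBA-BABA) with a 250-kb block
jackknife, windowed ABBA/BABA restricted to mat-fixed sites, and the
empirical divergence test against a simulated isolation null.

Site patterns are computed from derived-allele frequencies polarized
against the outgroup; for single-genome taxa the frequency products reduce
exactly to binary ABBA/BABA counting, so one code path serves both the
strain-level (default) and population-frequency modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .coalescent_sim import MSCParams, as_rng, simulate_isolation_pair
from .io_formats import MISSING, Region, VariantTable

logger = logging.getLogger(__name__)

DEFAULT_BLOCK_SIZE = 250_000


# ---------------------------------------------------------------------------
# site patterns
# ---------------------------------------------------------------------------

@dataclass
class SitePatternCounts:
    """ABBA/BABA counts (real-valued to allow frequency weighting)."""

    n_abba: float
    n_baba: float
    block: str | None = None

    def __post_init__(self) -> None:
        if self.n_abba < 0 or self.n_baba < 0:
            raise ValueError("pattern counts must be non-negative")


def _derived_freq(g: np.ndarray, anc: np.ndarray) -> np.ndarray:
    """Per-site derived-allele frequency of a (samples x sites) or (sites,)
    genotype array, given the ancestral allele; NaN where no sample is
    called."""
    g = np.atleast_2d(np.asarray(g))
    called = g != MISSING
    n = called.sum(0)
    der = ((g != anc) & called).sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, der / n, np.nan)


def site_pattern_weights(g1, g2, g3, g_out):
    """Per-site ABBA and BABA weights for a taxon quartet.

    Inputs are genotype arrays over the same sites, 1D (single genome) or
    2D (samples x sites; frequency mode).  The outgroup defines the
    ancestral state; sites where the outgroup is polymorphic or entirely
    missing, or where any focal taxon has no called sample, are skipped.
    """
    go = np.atleast_2d(np.asarray(g_out))
    called = go != MISSING
    n_o = called.sum(0)
    ones = ((go == 1) & called).sum(0)
    anc = np.where(ones * 2 > n_o, 1, 0).astype(np.int8)
    poly = (ones > 0) & (ones < n_o)
    skip = (n_o == 0) | poly
    if poly.any():
        logger.info("site_pattern_weights: skipped %d outgroup-polymorphic "
                    "sites", int(poly.sum()))
    f1 = _derived_freq(g1, anc)
    f2 = _derived_freq(g2, anc)
    f3 = _derived_freq(g3, anc)
    ok = ~(skip | np.isnan(f1) | np.isnan(f2) | np.isnan(f3))
    abba = np.where(ok, (1 - f1) * f2 * f3, 0.0)
    baba = np.where(ok, f1 * (1 - f2) * f3, 0.0)
    return abba, baba


def count_site_patterns(g1, g2, g3, g_out, block: str | None = None
                        ) -> SitePatternCounts:
    """Total ABBA/BABA counts for a quartet of genotype arrays."""
    abba, baba = site_pattern_weights(g1, g2, g3, g_out)
    return SitePatternCounts(float(abba.sum()), float(baba.sum()), block)


# ---------------------------------------------------------------------------
# Patterson's D with block jackknife
# ---------------------------------------------------------------------------

@dataclass
class DStatResult:
    """Patterson's D with block-jackknife SE, Z score and two-sided p."""

    d: float
    se: float
    z: float
    p: float
    n_blocks: int
    block_size: int
    n_abba: float
    n_baba: float


def _jackknife(abba_b: np.ndarray, baba_b: np.ndarray) -> tuple[float, float]:
    """Delete-one-block jackknife SE of D from per-block pattern sums."""
    tot_a, tot_b = abba_b.sum(), baba_b.sum()
    m = len(abba_b)
    d_del = ((tot_a - abba_b) - (tot_b - baba_b)) \
        / ((tot_a - abba_b) + (tot_b - baba_b))
    se = float(np.sqrt((m - 1) / m * ((d_del - d_del.mean()) ** 2).sum()))
    return se, m


def d_statistic(
    table: VariantTable,
    p1: Sequence[str] | str,
    p2: Sequence[str] | str,
    p3: Sequence[str] | str,
    outgroup: Sequence[str] | str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> DStatResult:
    """Patterson's D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA) over
    the table, with a delete-one-block jackknife over contiguous genomic
    tiles of ``block_size`` bp (blocks without informative sites dropped,
    equal block weights).  Z = D/SE and p = 2*Phi(-|Z|).
    """
    def geno(ids):
        ids = [ids] if isinstance(ids, str) else list(ids)
        g = table.genotypes[table.sample_index(ids)]
        return g[0] if len(ids) == 1 else g

    abba, baba = site_pattern_weights(geno(p1), geno(p2), geno(p3),
                                      geno(outgroup))
    tot_a, tot_b = float(abba.sum()), float(baba.sum())
    if tot_a + tot_b == 0:
        return DStatResult(float("nan"), float("nan"), float("nan"),
                           float("nan"), 0, block_size, 0.0, 0.0)
    d = (tot_a - tot_b) / (tot_a + tot_b)

    # contiguous block tiles, keyed by chromosome and tile index
    _, chrom_code = np.unique(table.chrom.astype(str), return_inverse=True)
    block_keys = chrom_code.astype(np.int64) * (1 << 40) \
        + table.pos // block_size
    informative = (abba + baba) > 0
    keys, inverse = np.unique(block_keys[informative], return_inverse=True)
    m = len(keys)
    if m < 2:
        logger.warning("d_statistic: fewer than 2 informative blocks; "
                       "jackknife SE unavailable")
        return DStatResult(d, float("nan"), float("nan"), float("nan"),
                           m, block_size, tot_a, tot_b)
    abba_b = np.bincount(inverse, weights=abba[informative], minlength=m)
    baba_b = np.bincount(inverse, weights=baba[informative], minlength=m)
    se, m = _jackknife(abba_b, baba_b)
    z = d / se if se > 0 else float("nan")
    p = float(2.0 * sps.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return DStatResult(d, se, z, p, m, block_size, tot_a, tot_b)


# ---------------------------------------------------------------------------
# windowed ABBA/BABA over mat-fixed sites
# ---------------------------------------------------------------------------

@dataclass
class WindowPatternRow:
    """Per-window ABBA/BABA counts at mat-fixed sites; d is NaN when the
    window has no informative site."""

    region: Region
    n_abba: float
    n_baba: float
    d: float
    n_fixed_sites: int


def windowed_abba_baba_matfixed(
    table: VariantTable,
    mat_A_samples: Sequence[str],
    mat_a_samples: Sequence[str],
    donor: str,
    outgroup: str,
    windows: Sequence[Region],
) -> list[WindowPatternRow]:
    """Sliding-window ABBA/BABA restricted to sites fixed between the mat A
    and mat a chromosomes of one lineage.

    Only sites where every called mat A sample carries one allele and every
    called mat a sample the other enter pattern counting, with
    P1 = mat a, P2 = mat A, P3 = donor (so donor introgression into the
    mat A chromosome produces an ABBA excess, D > 0).
    """
    ia = table.sample_index(mat_A_samples)
    ib = table.sample_index(mat_a_samples)
    ga, gb = table.genotypes[ia], table.genotypes[ib]
    ca, cb = ga != MISSING, gb != MISSING
    na, nb = ca.sum(0), cb.sum(0)
    ones_a = ((ga == 1) & ca).sum(0)
    ones_b = ((gb == 1) & cb).sum(0)
    mono_a = (ones_a == 0) | (ones_a == na)
    mono_b = (ones_b == 0) | (ones_b == nb)
    allele_a = (ones_a > 0).astype(np.int8)
    allele_b = (ones_b > 0).astype(np.int8)
    fixed = (na > 0) & (nb > 0) & mono_a & mono_b & (allele_a != allele_b)

    g_donor = table.genotypes[table.sample_index(donor)[0]]
    g_out = table.genotypes[table.sample_index(outgroup)[0]]
    abba, baba = site_pattern_weights(allele_b, allele_a, g_donor, g_out)
    abba = np.where(fixed, abba, 0.0)
    baba = np.where(fixed, baba, 0.0)

    rows: list[WindowPatternRow] = []
    for w in windows:
        sl = table.sites_in(w.chrom, w.start, w.end)
        a, b = float(abba[sl].sum()), float(baba[sl].sum())
        n_fixed = int(fixed[sl].sum())
        d = (a - b) / (a + b) if a + b > 0 else float("nan")
        rows.append(WindowPatternRow(w, a, b, d, n_fixed))
    return rows


# ---------------------------------------------------------------------------
# isolation-null divergence test
# ---------------------------------------------------------------------------

@dataclass
class IsolationTestResult:
    p: float
    n_loci: int
    direction: str
    observed: float

    @property
    def p_str(self) -> str:
        return f"<{1.0 / self.n_loci:g}" if self.p == 0 else f"{self.p:g}"


def isolation_divergence_test(
    observed_median_d: float,
    msc: MSCParams,
    n_loci: int = 50_000,
    direction: str = "lower",
    seed=None,
) -> IsolationTestResult:
    """Empirical p for an observed median window divergence against the
    two-species isolation null.

    p is the proportion of simulated per-locus Jukes-Cantor divergences
    <= the observed value (``direction='lower'``, used when the SR is less
    diverged from the heterothallic species than the R region) or >= it
    (``'upper'``).  A result of 0 is reported as "< 1/n_loci".
    """
    if n_loci < 100:
        raise ValueError("n_loci must be >= 100")
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    sim = simulate_isolation_pair(msc, n_loci, seed=as_rng(seed))
    jc = sim.jc_divergence
    jc = jc[np.isfinite(jc)]
    if direction == "lower":
        p = float((jc <= observed_median_d).mean())
    else:
        p = float((jc >= observed_median_d).mean())
    return IsolationTestResult(p, n_loci, direction, observed_median_d)
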