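"""Linkage disequilibrium and demarcation of the suppressed-recombination
(SR) region on the mating-type chromosome.

The SR is identified by the autosomal-quantile rule: mean window r-squared
is computed in sliding windows genome-wide, the empirical 95% quantile of
the autosomal windows is taken as a cutoff, and the run of mat-chromosome
windows above that cutoff containing (or nearest to) the mat locus is
reported as the SR.  A divergence-based variant applies the same machinery
to windowed mat A / mat a divergence, for lineages with too few strains for
informative LD.

Because 100-kb windows smear a sharp boundary over a full window span, an
optional refinement pass relocates each SR edge at sub-window resolution
with a least-squares changepoint on per-SNP signal (r-squared against the
SR core for the LD method, per-site difference indicators for the
divergence method).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    CallabilityMask,
    Region,
    VariantTable,
    WindowStatRow,
)
from .popgen_stats import DEFAULT_STEP, DEFAULT_WINDOW, default_windows

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# r-squared
# ---------------------------------------------------------------------------

def _r2_matrix(g1: np.ndarray, g2: np.ndarray | None = None) -> np.ndarray:
    """Pairwise r^2 between rows of g1 and rows of g2 (or g1 with itself).

    Missing genotypes are removed pairwise; entries are NaN when either
    site is monomorphic among the shared non-missing samples or fewer than
    two shared samples remain.
    """
    if g2 is None:
        g2 = g1
    c1 = (g1 != MISSING).astype(np.float64)
    x1 = (g1 == 1).astype(np.float64)
    c2 = (g2 != MISSING).astype(np.float64)
    x2 = (g2 == 1).astype(np.float64)
    n_pair = c1 @ c2.T
    n_ab = x1 @ x2.T
    n_a = x1 @ c2.T
    n_b = c1 @ x2.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = n_a / n_pair
        p_b = n_b / n_pair
        p_ab = n_ab / n_pair
        d = p_ab - p_a * p_b
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = d * d / denom
    r2[(n_pair < 2) | ~(denom > 0)] = np.nan
    return r2


def r2_pair(g1: np.ndarray, g2: np.ndarray) -> float:
    """r^2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B)) between two
    biallelic haploid genotype vectors; NaN if either site is monomorphic
    after pairwise missing-data removal."""
    g1 = np.asarray(g1, dtype=np.int8).reshape(1, -1)
    g2 = np.asarray(g2, dtype=np.int8).reshape(1, -1)
    return float(_r2_matrix(g1, g2)[0, 0])


def _thin(idx_len: int, cap: int) -> np.ndarray:
    """Deterministic, evenly spaced thinning of range(idx_len) to <= cap."""
    if idx_len <= cap:
        return np.arange(idx_len)
    return np.unique(np.linspace(0, idx_len - 1, cap).round().astype(int))


@dataclass
class LDWindowRow:
    """One window with its mean pairwise r^2 and the number of SNP pairs."""

    region: Region
    mean_r2: float  # NaN when fewer than 2 usable SNPs
    n_pairs: int

    @property
    def value(self) -> float:
        return self.mean_r2

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.mean_r2))


def window_mean_r2(
    table: VariantTable,
    samples: Sequence[str],
    windows: Sequence[Region] | None = None,
    mask: CallabilityMask | None = None,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_snps_per_window: int = 300,
) -> list[LDWindowRow]:
    """Mean r^2 over all pairwise SNP combinations within sliding windows.

    Windows with fewer than two usable (polymorphic) SNPs are undefined.
    Windows denser than ``max_snps_per_window`` SNPs are deterministically
    thinned before the all-pairs computation.
    """
    idx = table.sample_index(samples)
    if windows is None:
        windows = default_windows(table, mask, window_size, step)
    geno = table.genotypes[idx]
    rows: list[LDWindowRow] = []
    for w in windows:
        sl = table.sites_in(w.chrom, w.start, w.end)
        g = geno[:, sl].T  # (m_snps, n_samples)
        keep = _usable_snps(g)
        g = g[keep]
        g = g[_thin(len(g), max_snps_per_window)]
        m = len(g)
        if m < 2:
            rows.append(LDWindowRow(w, float("nan"), 0))
            continue
        r2 = _r2_matrix(g)
        iu = np.triu_indices(m, k=1)
        vals = r2[iu]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append(LDWindowRow(w, float("nan"), 0))
        else:
            rows.append(LDWindowRow(w, float(vals.mean()), int(len(vals))))
    return rows


def _usable_snps(g: np.ndarray) -> np.ndarray:
    """SNPs polymorphic among the analyzed (non-missing) samples."""
    called = g != MISSING
    ones = ((g == 1) & called).sum(1)
    n = called.sum(1)
    return (ones > 0) & (ones < n)


def ld_decay(
    table: VariantTable,
    samples: Sequence[str],
    chroms: Sequence[str] | None = None,
    max_dist: int = 500_000,
    increment: int = 1_000,
    cumulative: bool = True,
    max_snps_per_chrom: int = 2_000,
) -> pd.DataFrame:
    """LD-decay curve: mean r^2 of SNP pairs within increasing distances.

    With ``cumulative=True`` (default) row d holds the mean r^2 over all
    pairs separated by <= d (1-kb increments up to 500 kb); with
    ``cumulative=False`` each row is the per-bin mean instead.  Rows with
    no qualifying pairs are NaN.
    """
    idx = table.sample_index(samples)
    geno = table.genotypes[idx]
    n_bins = max_dist // increment
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in (chroms if chroms is not None else table.chroms):
        sl = table.sites_in(chrom)
        g = geno[:, sl].T
        pos = table.pos[sl]
        keep = _usable_snps(g)
        g, pos = g[keep], pos[keep]
        t = _thin(len(g), max_snps_per_chrom)
        g, pos = g[t], pos[t]
        if len(g) < 2:
            continue
        r2 = _r2_matrix(g)
        iu = np.triu_indices(len(g), k=1)
        dist = np.abs(pos[iu[0]] - pos[iu[1]])
        vals = r2[iu]
        ok = np.isfinite(vals) & (dist > 0) & (dist <= max_dist)
        b = (dist[ok] - 1) // increment  # bin d covers ((d-1)inc, d*inc]
        np.add.at(sums, b, vals[ok])
        np.add.at(counts, b, 1)
    if cumulative:
        sums = np.cumsum(sums)
        counts = np.cumsum(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame({
        "dist": np.arange(1, n_bins + 1) * increment,
        "mean_r2": mean,
        "n_pairs": counts,
    })


# ---------------------------------------------------------------------------
# SR demarcation
# ---------------------------------------------------------------------------

@dataclass
class SRRegion:
    """A detected suppressed-recombination region on the mat chromosome."""

    region: Region | None
    method: str  # "ld_quantile" or "divergence_quantile"
    cutoff_value: float
    contains_mat_locus: bool = False

    @property
    def empty(self) -> bool:
        return self.region is None


def _row_value(row) -> float:
    return row.mean_r2 if isinstance(row, LDWindowRow) else row.value


def _flag_runs(flags: np.ndarray, gap_max: int) -> list[tuple[int, int]]:
    """Maximal runs of True, bridging gaps of <= gap_max consecutive False."""
    idx = np.flatnonzero(flags)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap_max + 1:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def _pick_run(rows, runs, mat_locus_pos):
    spans = [(rows[a].region.start, rows[b].region.end) for a, b in runs]
    containing = [i for i, (s, e) in enumerate(spans)
                  if s <= mat_locus_pos < e]
    if containing:
        return runs[containing[0]], True
    dists = [min(abs(s - mat_locus_pos), abs(e - mat_locus_pos))
             for s, e in spans]
    return runs[int(np.argmin(dists))], False


def _quantile_sr(mat_rows, autosome_rows, mat_locus_pos, q, gap_max, method):
    auto_vals = np.array([_row_value(r) for r in autosome_rows])
    auto_vals = auto_vals[np.isfinite(auto_vals)]
    if len(auto_vals) == 0:
        raise ValueError("no defined autosomal windows to set the cutoff")
    cutoff = float(np.quantile(auto_vals, q))
    rows = sorted(mat_rows, key=lambda r: r.region.start)
    vals = np.array([_row_value(r) for r in rows])
    flags = np.isfinite(vals) & (vals > cutoff)
    if not flags.any():
        warnings.warn(f"no mat-chromosome window above the {method} cutoff; "
                      "empty SR")
        return SRRegion(None, method, cutoff), rows, None
    runs = _flag_runs(flags, gap_max)
    (a, b), contains = _pick_run(rows, runs, mat_locus_pos)
    region = Region(rows[a].region.chrom, rows[a].region.start,
                    rows[b].region.end, "SR")
    return SRRegion(region, method, cutoff, contains), rows, (a, b)


def detect_sr(
    mat_rows: Sequence[LDWindowRow],
    autosome_rows: Sequence[LDWindowRow],
    mat_locus_pos: int,
    q: float = 0.95,
    gap_max: int = 2,
    table: VariantTable | None = None,
    samples: Sequence[str] | None = None,
    refine: bool = True,
) -> SRRegion:
    """Demarcate the SR region from windowed mean r^2.

    The cutoff is the empirical q-quantile of the defined autosomal window
    values; mat windows above it are flagged, runs are merged bridging gaps
    of <= ``gap_max`` below-cutoff windows, and the run containing (or
    nearest to) the mat locus is returned.  When ``table`` and ``samples``
    are supplied, each boundary is refined at sub-window resolution by a
    changepoint on per-SNP mean r^2 against the SR core.
    """
    sr, rows, run = _quantile_sr(mat_rows, autosome_rows, mat_locus_pos, q,
                                 gap_max, "ld_quantile")
    if sr.empty or table is None or samples is None or not refine:
        return sr
    window_size = rows[0].region.length if rows else DEFAULT_WINDOW
    region = _refine_ld_boundaries(sr.region, table, samples, window_size)
    return SRRegion(region, sr.method, sr.cutoff_value,
                    region.contains(mat_locus_pos))


def detect_sr_divergence(
    mat_rows: Sequence[WindowStatRow],
    autosome_rows: Sequence[WindowStatRow],
    mat_locus_pos: int,
    q: float = 0.95,
    gap_max: int = 2,
    table: VariantTable | None = None,
    pair: tuple[str, str] | None = None,
    refine: bool = True,
) -> SRRegion:
    """SR demarcation from windowed mat A / mat a heterokaryon divergence,
    using the same quantile/run machinery as the LD method.  Boundary
    refinement uses per-site difference indicators for the given sample
    pair."""
    sr, rows, run = _quantile_sr(mat_rows, autosome_rows, mat_locus_pos, q,
                                 gap_max, "divergence_quantile")
    if sr.empty or table is None or pair is None or not refine:
        return sr
    window_size = rows[0].region.length if rows else DEFAULT_WINDOW
    region = _refine_div_boundaries(sr.region, table, pair, window_size)
    return SRRegion(region, sr.method, sr.cutoff_value,
                    region.contains(mat_locus_pos))


# ---------------------------------------------------------------------------
# boundary refinement
# ---------------------------------------------------------------------------

def _ls_changepoint(pos: np.ndarray, values: np.ndarray) -> float | None:
    """Least-squares single changepoint over values ordered by position.

    Returns the midpoint between the two flanking observations, or None
    when no informative split exists (fewer than 4 points, or a flat
    profile)."""
    m = len(values)
    if m < 4:
        return None
    order = np.argsort(pos)
    pos, values = pos[order], values[order]
    csum = np.cumsum(values)
    csq = np.cumsum(values**2)
    total, total_sq = csum[-1], csq[-1]
    i = np.arange(1, m)  # split: left = [0, i), right = [i, m)
    left_n, right_n = i, m - i
    left_s = csum[i - 1]
    right_s = total - left_s
    sse = (csq[i - 1] - left_s**2 / left_n) \
        + ((total_sq - csq[i - 1]) - right_s**2 / right_n)
    base_sse = total_sq - total**2 / m
    if base_sse <= 1e-12:
        return None
    best = int(np.argmin(sse))
    split = best + 1
    return 0.5 * (pos[split - 1] + pos[split])


def _refine_boundaries_from_profile(region, pos, values,
                                    max_snps_per_side=4000) -> "Region":
    """Relocate both SR edges by a least-squares changepoint on a per-SNP
    signal profile, one changepoint per side of the region midpoint.

    Searching each whole half-chromosome (rather than a window around the
    coarse edge) makes the refinement robust to coarse runs that over- or
    undershoot by several windows."""
    mid = (region.start + region.end) // 2
    edges = []
    for side, coarse in ((pos < mid, region.start),
                         (pos >= mid, region.end)):
        p, v = pos[side], values[side]
        t = _thin(len(p), max_snps_per_side)
        cp = _ls_changepoint(p[t], v[t])
        edges.append(coarse if cp is None else int(round(cp)))
    start, end = edges
    if start >= end:  # refinement collapsed the span; keep the coarse call
        return region
    return Region(region.chrom, start, end, region.label)


def _refine_ld_boundaries(region, table, samples, window_size) -> Region:
    idx = table.sample_index(samples)
    sl = table.sites_in(region.chrom)
    if sl.stop == sl.start:
        return region
    # SR core: central half of the coarse span
    quarter = region.length // 4
    core_sl = table.sites_in(region.chrom, region.start + quarter,
                             region.end - quarter)
    g_core = table.genotypes[idx, core_sl].T
    keep = _usable_snps(g_core)
    g_core = g_core[keep]
    g_core = g_core[_thin(len(g_core), 200)]
    if len(g_core) < 5:
        return region
    g = table.genotypes[idx, sl].T
    pos = table.pos[sl]
    keep = _usable_snps(g)
    g, pos = g[keep], pos[keep]
    if len(g) < 16:
        return region
    g = g[_thin(len(g), 8000)]
    pos = pos[_thin(len(pos), 8000)]
    r2 = _r2_matrix(g, g_core)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        v = np.nanmean(r2, axis=1)
    ok = np.isfinite(v)
    return _refine_boundaries_from_profile(region, pos[ok], v[ok])


def _refine_div_boundaries(region, table, pair, window_size) -> Region:
    ia = table.sample_index(pair[0])[0]
    ib = table.sample_index(pair[1])[0]
    sl = table.sites_in(region.chrom)
    if sl.stop == sl.start:
        return region
    a = table.genotypes[ia, sl]
    b = table.genotypes[ib, sl]
    pos = table.pos[sl]
    both = (a != MISSING) & (b != MISSING)
    v = (a != b)[both].astype(float)
    p = pos[both]
    if len(v) < 16:
        return region
    return _refine_boundaries_from_profile(region, p, v)
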