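"""Site-frequency-spectrum and divergence statistics over genomic windows.

Implements nucleotide diversity (pi), Watterson's theta, Tajima's D,
Fay & Wu's H (unnormalized by default, normalized optional), raw and
Jukes-Cantor-corrected pairwise divergence, between-population D_xy, and
flagging of windows in the extreme tail of a genome-wide empirical
distribution.

Missing-data policy: pi uses pairwise-complete observations per site; D_xy
and unfolded-SFS statistics use complete-case sites (sites with any missing
call in the analyzed samples are excluded from numerator and denominator).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    MISSING,
    CallabilityMask,
    Region,
    SampleMeta,
    VariantTable,
    WindowStatRow,
    make_windows,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000
DEFAULT_STEP = 20_000
DEFAULT_MIN_CALLED_FRAC = 0.10  # windows below 10% called sites are undefined
DXY_WINDOW = 25_000


# ---------------------------------------------------------------------------
# SFS and scalar statistics
# ---------------------------------------------------------------------------

@dataclass
class SFS:
    """A site-frequency spectrum for n haploid samples.

    ``counts[i-1]`` is the number of segregating sites at derived-allele
    count i, i = 1..n-1 (unfolded) or minor-allele count i = 1..n//2
    (folded).  Unfolded spectra record the outgroup used for polarization.
    """

    n: int
    counts: np.ndarray
    folded: bool = False
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        expected = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != expected:
            raise ValueError(
                f"SFS for n={self.n} needs {expected} classes, "
                f"got {len(self.counts)}"
            )
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")
        if not self.folded and self.outgroup is None:
            # polarization source unknown; allowed for simulated data
            pass

    @property
    def S(self) -> int:
        return int(self.counts.sum())

    def pi_total(self) -> float:
        """Mean pairwise difference count (per locus) implied by the SFS."""
        if self.folded:
            raise ValueError("pi from a folded SFS not supported here")
        i = np.arange(1, self.n)
        return float((2.0 * self.counts * i * (self.n - i)).sum()
                     / (self.n * (self.n - 1)))


@dataclass
class DiversitySummary:
    """Per-locus diversity summary: pi (per site), S, theta_W, k, n."""

    pi: float
    S: int
    theta_w: float
    k: float
    n: int


def harmonic(n: int, power: int = 1) -> float:
    """a1 = sum 1/i (power=1) or a2 = sum 1/i^2 (power=2), i = 1..n."""
    i = np.arange(1, n + 1)
    return float((1.0 / i**power).sum())


def tajima_constants(n: int) -> dict[str, float]:
    """The Tajima (1989) normalization constants a1..e2 for sample size n."""
    a1 = harmonic(n - 1, 1)
    a2 = harmonic(n - 1, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S, pi_total, n: int, min_n: int = 4):
    """Tajima's D from segregating sites and the per-locus mean pairwise
    difference count.

    Accepts scalars or arrays for S and pi_total.  Returns NaN when S = 0
    (the statistic is undefined) or when n is below ``min_n``.
    """
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    S = np.asarray(S, dtype=float)
    pi_total = np.asarray(pi_total, dtype=float)
    if n < min_n:
        return np.full(S.shape, np.nan) if S.shape else float("nan")
    c = tajima_constants(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        d = np.where(S > 0, (pi_total - S / c["a1"]) / np.sqrt(var), np.nan)
    return float(d) if d.shape == () else d


def theta_h(sfs: SFS) -> float:
    """Fay & Wu's theta_H = sum 2 xi_i i^2 / (n(n-1)) over i = 1..n-1."""
    if sfs.folded:
        raise ValueError("theta_H requires an unfolded SFS (outgroup needed)")
    i = np.arange(1, sfs.n)
    return float((2.0 * sfs.counts * i**2).sum() / (sfs.n * (sfs.n - 1)))


def fay_wu_h(sfs: SFS, normalized: bool = False) -> float:
    """Fay & Wu's H from an unfolded SFS.

    Default is the unnormalized 2000 form H = pi - theta_H.  With
    ``normalized=True`` the Zeng et al. (2006) variance-normalized statistic
    (pi - theta_L) / sqrt(Var) is returned instead.  Sites fixed derived
    (i = n) are not part of the SFS (not segregating).
    """
    if sfs.folded:
        raise ValueError("Fay & Wu's H requires an unfolded SFS: supply an "
                         "outgroup for polarization")
    pi = sfs.pi_total()
    if not normalized:
        return pi - theta_h(sfs)
    n, S = sfs.n, sfs.S
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    theta_l = float((sfs.counts * i).sum() / (n - 1))
    a1 = harmonic(n - 1, 1)
    a2 = harmonic(n - 1, 2)
    bn1 = harmonic(n, 2)  # sum_{i=1}^{n} 1/i^2
    theta_w = S / a1
    theta_sq = S * (S - 1) / (a1**2 + a2)
    var = ((n - 2) / (6.0 * (n - 1))) * theta_w + (
        (18.0 * n**2 * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9.0 * n * (n - 1) ** 2)
    ) * theta_sq
    if var <= 0:
        return float("nan")
    return (pi - theta_l) / float(np.sqrt(var))


def diversity_summary(table: VariantTable, samples: Sequence[str],
                      n_called: int) -> DiversitySummary:
    """Per-locus pi, S, theta_W and k over all sites of the table."""
    idx = table.sample_index(samples)
    n = len(idx)
    if n < 2:
        raise ValueError("diversity requires >= 2 samples")
    g = table.genotypes[idx]
    called = g != MISSING
    n_i = called.sum(0)
    c = (g == 1).sum(0)
    ok = n_i >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = np.where(ok, 2.0 * c * (n_i - c) / (n_i * (n_i - 1.0)), 0.0)
    seg = ok & (c > 0) & (c < n_i)
    S = int(seg.sum())
    k = float(site_pi.sum())
    pi = k / n_called if n_called > 0 else float("nan")
    theta_w = S / harmonic(n - 1, 1) if n > 1 else float("nan")
    return DiversitySummary(pi=pi, S=S, theta_w=theta_w, k=k, n=n)


# ---------------------------------------------------------------------------
# per-sample selection
# ---------------------------------------------------------------------------

def one_per_heterokaryon(samples: Sequence[SampleMeta],
                         seed: int | None = None) -> list[str]:
    """Pick a single homokaryon per heterokaryon.

    Deterministic (lowest sample_id) unless a seed is given, in which case
    one member of each pair is drawn at random.  Samples without a
    heterokaryon id are kept as-is.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    by_het: dict[str, list[SampleMeta]] = {}
    singles: list[str] = []
    for s in samples:
        if s.heterokaryon_id:
            by_het.setdefault(s.heterokaryon_id, []).append(s)
        else:
            singles.append(s.sample_id)
    chosen = []
    for het in sorted(by_het):
        members = sorted(m.sample_id for m in by_het[het])
        if rng is None:
            chosen.append(members[0])
        else:
            chosen.append(members[int(rng.integers(len(members)))])
    return sorted(chosen + singles)


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def default_windows(table: VariantTable, mask: CallabilityMask | None,
                    size: int, step: int | None = None,
                    chroms: Sequence[str] | None = None) -> list[Region]:
    """Sliding windows over each chromosome, spanning the mask (if given)
    or the observed sites otherwise."""
    out: list[Region] = []
    for chrom in (chroms if chroms is not None else table.chroms):
        if mask is not None and chrom in mask.intervals \
                and mask.intervals[chrom].size:
            length = int(mask.intervals[chrom][:, 1].max())
        else:
            sl = table.sites_in(chrom)
            if sl.stop == sl.start:
                continue
            length = int(table.pos[sl.stop - 1]) + 1
        out.extend(make_windows(chrom, length, size, step))
    return out


def _resolve_mask(table: VariantTable, mask: CallabilityMask | None,
                  windows: Sequence[Region]) -> CallabilityMask:
    if mask is not None:
        return mask
    lengths: dict[str, int] = {}
    for w in windows:
        lengths[w.chrom] = max(lengths.get(w.chrom, 0), w.end)
    for chrom in table.chroms:
        sl = table.sites_in(chrom)
        if sl.stop > sl.start:
            lengths[chrom] = max(lengths.get(chrom, 0),
                                 int(table.pos[sl.stop - 1]) + 1)
    return CallabilityMask.all_callable(lengths)


def _window_rows(table, windows, mask, site_values, site_weight_excluded,
                 stat_name, min_called_frac, per_site=True, extra_fn=None):
    """Aggregate per-site values into window rows.

    site_values: per-site numerator contributions (NaN-free, 0 where the
    site does not contribute).  site_weight_excluded: per-site count to
    subtract from the callable denominator (complete-case exclusions).
    """
    rows: list[WindowStatRow] = []
    for w in windows:
        sl = table.sites_in(w.chrom, w.start, w.end)
        called = mask.called_in(w.chrom, w.start, w.end)
        excluded = int(site_weight_excluded[sl].sum())
        n_called = called - excluded
        n_snps = sl.stop - sl.start
        if n_called < min_called_frac * w.length or n_called <= 0:
            value = float("nan")
        else:
            total = float(site_values[sl].sum())
            value = total / n_called if per_site else total
        row = WindowStatRow(w, n_called, n_snps, stat_name, value)
        if extra_fn is not None and row.defined:
            row.extra.update(extra_fn(row, sl))
        rows.append(row)
    return rows


def nucleotide_diversity(
    table: VariantTable,
    samples: Sequence[str],
    windows: Sequence[Region] | None = None,
    mask: CallabilityMask | None = None,
    min_called_frac: float = DEFAULT_MIN_CALLED_FRAC,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowStatRow]:
    """Windowed per-site nucleotide diversity (pi), pairwise-complete."""
    idx = table.sample_index(samples)
    if len(idx) < 2:
        raise ValueError("pi requires >= 2 samples")
    if windows is None:
        windows = default_windows(table, mask, window_size, step)
    mask = _resolve_mask(table, mask, windows)
    g = table.genotypes[idx]
    called = g != MISSING
    n_i = called.sum(0)
    c = (g == 1).sum(0)
    ok = n_i >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = np.where(ok, 2.0 * c * (n_i - c) / (n_i * (n_i - 1.0)), 0.0)
    zeros = np.zeros(table.n_sites)
    return _window_rows(table, windows, mask, site_pi, zeros, "pi",
                        min_called_frac)


def tajimas_d_windows(
    table: VariantTable,
    samples: Sequence[str],
    windows: Sequence[Region] | None = None,
    mask: CallabilityMask | None = None,
    min_called_frac: float = DEFAULT_MIN_CALLED_FRAC,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowStatRow]:
    """Windowed Tajima's D (complete-case sites within each window)."""
    idx = table.sample_index(samples)
    n = len(idx)
    if windows is None:
        windows = default_windows(table, mask, window_size, step)
    mask = _resolve_mask(table, mask, windows)
    g = table.genotypes[idx]
    complete = (g != MISSING).all(0)
    c = np.where(complete, (g == 1).sum(0), 0)
    seg = complete & (c > 0) & (c < n)
    site_k = np.where(seg, 2.0 * c * (n - c) / (n * (n - 1.0)), 0.0)
    rows: list[WindowStatRow] = []
    for w in windows:
        sl = table.sites_in(w.chrom, w.start, w.end)
        n_called = mask.called_in(w.chrom, w.start, w.end) \
            - int((~complete[sl]).sum())
        S = int(seg[sl].sum())
        if n_called < min_called_frac * w.length or n_called <= 0:
            value = float("nan")
        else:
            value = tajimas_d(S, float(site_k[sl].sum()), n)
        rows.append(WindowStatRow(w, n_called, S, "tajimas_d", float(value)))
    return rows


def window_sfs(table: VariantTable, samples: Sequence[str], outgroup: str,
               region: Region) -> SFS:
    """Unfolded SFS for one window, polarized against an outgroup sample.

    Sites where the outgroup is missing, or where any ingroup call is
    missing, are skipped; fixed-derived sites (i = n) are excluded.
    """
    idx = table.sample_index(samples)
    og = table.sample_index(outgroup)[0]
    n = len(idx)
    sl = table.sites_in(region.chrom, region.start, region.end)
    g = table.genotypes[idx, sl]
    go = table.genotypes[og, sl]
    complete = (g != MISSING).all(0) & (go != MISSING)
    derived = np.where(go == 0, (g == 1).sum(0), (g == 0).sum(0))
    counts = np.zeros(n - 1, dtype=np.int64)
    use = complete & (derived > 0) & (derived < n)
    np.add.at(counts, derived[use] - 1, 1)
    return SFS(n=n, counts=counts, folded=False, outgroup=outgroup)


def fay_wu_h_windows(
    table: VariantTable,
    samples: Sequence[str],
    outgroup: str,
    windows: Sequence[Region] | None = None,
    mask: CallabilityMask | None = None,
    normalized: bool = False,
    min_called_frac: float = DEFAULT_MIN_CALLED_FRAC,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[WindowStatRow]:
    """Windowed Fay & Wu's H, polarized against an outgroup sample."""
    if windows is None:
        windows = default_windows(table, mask, window_size, step)
    mask = _resolve_mask(table, mask, windows)
    rows: list[WindowStatRow] = []
    for w in windows:
        n_called = mask.called_in(w.chrom, w.start, w.end)
        sfs = window_sfs(table, samples, outgroup, w)
        if n_called < min_called_frac * w.length or n_called <= 0:
            value = float("nan")
        else:
            value = fay_wu_h(sfs, normalized=normalized)
        rows.append(WindowStatRow(w, n_called, sfs.S, "fay_wu_h", float(value)))
    return rows


def jukes_cantor(p):
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3); NaN for p >= 0.75."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * p / 3.0), np.nan)
    return float(d) if d.shape == () else d


def pairwise_divergence(
    table: VariantTable,
    sample_a: str,
    sample_b: str,
    windows: Sequence[Region] | None = None,
    mask: CallabilityMask | None = None,
    jc_correct: bool = True,
    min_called_frac: float = DEFAULT_MIN_CALLED_FRAC,
    window_size: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    value_cap: float | None = None,
) -> list[WindowStatRow]:
    """Windowed pairwise divergence between two haploid genomes.

    Raw p is differing called sites / called sites; with ``jc_correct`` the
    Jukes-Cantor multiple-hit correction is applied.  p >= 0.75 yields an
    undefined value with a ``jc_domain_error`` flag; windows above
    ``value_cap`` (if set) carry a ``capped`` flag for plotting.
    """
    ia = table.sample_index(sample_a)[0]
    ib = table.sample_index(sample_b)[0]
    if windows is None:
        windows = default_windows(table, mask, window_size, step)
    mask = _resolve_mask(table, mask, windows)
    ga, gb = table.genotypes[ia], table.genotypes[ib]
    both = (ga != MISSING) & (gb != MISSING)
    diff = (both & (ga != gb)).astype(float)
    missing_either = (~both).astype(float)
    rows: list[WindowStatRow] = []
    for w in windows:
        sl = table.sites_in(w.chrom, w.start, w.end)
        n_called = mask.called_in(w.chrom, w.start, w.end) \
            - int(missing_either[sl].sum())
        n_snps = sl.stop - sl.start
        extra: dict = {}
        if n_called < min_called_frac * w.length or n_called <= 0:
            value = float("nan")
        else:
            p = float(diff[sl].sum()) / n_called
            extra["p_raw"] = p
            if jc_correct:
                if p >= 0.75:
                    value = float("nan")
                    extra["jc_domain_error"] = True
                else:
                    value = jukes_cantor(p)
            else:
                value = p
            if value_cap is not None and np.isfinite(value) \
                    and value > value_cap:
                extra["capped"] = True
        name = "jc_divergence" if jc_correct else "p_distance"
        rows.append(WindowStatRow(w, n_called, n_snps, name, value, extra))
    return rows


def dxy(
    table: VariantTable,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    windows: Sequence[Region] | None = None,
    mask: CallabilityMask | None = None,
    min_called_frac: float = DEFAULT_MIN_CALLED_FRAC,
    window_size: int = DXY_WINDOW,
    step: int | None = None,
) -> list[WindowStatRow]:
    """Windowed D_xy: mean between-population per-site difference fraction.

    Computed only at sites with no missing call in either population (sites
    with missing data are excluded from numerator and denominator); no
    multiple-hit correction is applied.  Default 25-kb non-overlapping
    windows with a 2,500-called-site (10%) threshold.
    """
    ia = table.sample_index(pop_a)
    ib = table.sample_index(pop_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both populations must be non-empty")
    if windows is None:
        windows = default_windows(table, mask, window_size, step)
    mask = _resolve_mask(table, mask, windows)
    ga, gb = table.genotypes[ia], table.genotypes[ib]
    complete = (ga != MISSING).all(0) & (gb != MISSING).all(0)
    fa = (ga == 1).mean(0)
    fb = (gb == 1).mean(0)
    site_dxy = np.where(complete, fa * (1 - fb) + fb * (1 - fa), 0.0)
    excluded = (~complete).astype(float)
    return _window_rows(table, windows, mask, site_dxy, excluded, "dxy",
                        min_called_frac)


def extreme_window_flags(
    rows: Sequence[WindowStatRow],
    tail: float = 0.05,
    direction: str = "lower",
) -> list[Region]:
    """Windows whose value falls in the stated tail of the empirical
    genome-wide distribution; ties at the quantile boundary are included."""
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    defined = [r for r in rows if r.defined]
    if not defined:
        raise ValueError("all window values are undefined")
    values = np.array([r.value for r in defined])
    if np.allclose(values, values[0]):
        warnings.warn("degenerate value distribution: all windows flagged")
        return [r.region for r in defined]
    if direction == "lower":
        thr = np.quantile(values, tail)
        flag = values <= thr
    else:
        thr = np.quantile(values, 1.0 - tail)
        flag = values >= thr
    return [r.region for r, f in zip(defined, flag) if f]
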