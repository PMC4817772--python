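"""Fit the forced-coalescence hard-sweep model to observed neutral
variation in a non-recombining region.

The model has two parameters: theta0, the per-locus neutral variation that
would be present without a sweep, and T_s, the time since the sweep (2N
generations).  Over a (theta0, T_s) grid, replicate sweep genealogies are
simulated and a replicate is accepted when its segregating-site count S is
within +-(tol * S_obs) of the observed S and its mean pairwise-difference
count k is within +-(tol * k_obs) of the observed k.  The per-pair
acceptance proportion is a rectangular-kernel ABC likelihood; parameter
pairs with any acceptance form the compatible set, and the
maximum-acceptance pair is reported as the MLE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coalescent_sim import batch_sweep_summary
from .io_formats import GENETIC_CODE, CodonAlignment, VariantTable
from .popgen_stats import harmonic

logger = logging.getLogger(__name__)

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# fourfold-degenerate sites
# ---------------------------------------------------------------------------

def _is_fourfold(codon: str) -> bool:
    aa = GENETIC_CODE.get(codon)
    if aa is None or aa == "*":
        return False
    return all(GENETIC_CODE.get(codon[:2] + b) == aa for b in _BASES)


#: third positions of these codon prefixes are fourfold degenerate
FOURFOLD_CODONS = frozenset(
    c for c in GENETIC_CODE if _is_fourfold(c)
)


def fourfold_degenerate_sites(alignment: CodonAlignment,
                              reference: str | int = 0) -> np.ndarray:
    """Alignment nucleotide columns (0-based) that are fourfold degenerate.

    A site qualifies when it is the third position of a codon whose amino
    acid is invariant to any third-position base, evaluated on the
    reference row; masked codons are skipped.
    """
    if isinstance(reference, str):
        ref_row = alignment.row(reference)
    else:
        ref_row = alignment.codons[reference]
    out = []
    for j in range(alignment.n_codons):
        if not alignment.codon_mask[j]:
            continue
        codon = ref_row[j]
        if len(codon) != 3 or "-" in codon:
            raise ValueError(f"frame violation in codon column {j}")
        if codon in FOURFOLD_CODONS:
            out.append(3 * j + 2)
    return np.array(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# observed neutral summary
# ---------------------------------------------------------------------------

@dataclass
class ObservedNeutralSummary:
    """Observed S and k at (fourfold-degenerate) neutral sites."""

    s_obs: int
    k_obs: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.s_obs < 0:
            raise ValueError("S must be non-negative")
        if not (0.0 <= self.k_obs <= self.s_obs + 1e-9):
            raise ValueError("k must satisfy 0 <= k <= S")
        if self.n < 2:
            raise ValueError("need n >= 2 samples")

    @property
    def theta_w(self) -> float:
        """Watterson's per-locus theta estimate S / a1."""
        return self.s_obs / harmonic(self.n - 1, 1)


def summary_from_genotypes(genotypes: np.ndarray, label: str = ""
                           ) -> ObservedNeutralSummary:
    """S and k from a (samples x sites) 0/1 genotype matrix."""
    g = np.asarray(genotypes)
    n = g.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    c = (g == 1).sum(0)
    seg = (c > 0) & (c < n)
    s = int(seg.sum())
    k = float((2.0 * c[seg] * (n - c[seg])).sum() / (n * (n - 1)))
    return ObservedNeutralSummary(s, k, n, label)


def observed_summary(table: VariantTable, samples: Sequence[str],
                     chrom: str, fourfold_sites: np.ndarray,
                     label: str = "") -> ObservedNeutralSummary:
    """Observed S and k over the given (genomic, 0-based) fourfold-site
    positions on one chromosome.  Positions absent from the SNP table are
    invariant and contribute nothing; zero callable sites is an error."""
    fourfold_sites = np.asarray(fourfold_sites, dtype=np.int64)
    if len(fourfold_sites) == 0:
        raise ValueError("no callable fourfold-degenerate sites")
    idx = table.sample_index(samples)
    sl = table.sites_in(chrom)
    pos = table.pos[sl]
    hit = np.isin(pos, fourfold_sites)
    g = table.genotypes[idx, sl][:, hit]
    if g.shape[1] == 0:
        return ObservedNeutralSummary(0, 0.0, len(idx), label)
    s = summary_from_genotypes(g)
    return ObservedNeutralSummary(s.s_obs, s.k_obs, len(idx), label)


# ---------------------------------------------------------------------------
# grid fit
# ---------------------------------------------------------------------------

@dataclass
class SweepGridResult:
    """Acceptance-proportion likelihood surface over (theta0, T_s)."""

    theta0_grid: np.ndarray
    ts_grid: np.ndarray
    accepted: np.ndarray      # (len(theta0_grid), len(ts_grid)) int
    reps: int
    tol: float
    obs: ObservedNeutralSummary
    metadata: dict = field(default_factory=dict)

    @property
    def likelihood(self) -> np.ndarray:
        return self.accepted / float(self.reps)

    @property
    def model_incompatible(self) -> bool:
        return not np.any(self.accepted > 0)

    @property
    def mle(self) -> tuple[float, float] | None:
        """(theta0, T_s) with the highest acceptance; None when nothing was
        accepted.  Ties resolve to the lowest (theta0, T_s) grid indices."""
        if self.model_incompatible:
            return None
        i, j = np.unravel_index(int(np.argmax(self.accepted)),
                                self.accepted.shape)
        return float(self.theta0_grid[i]), float(self.ts_grid[j])

    @property
    def compatible(self) -> list[tuple[float, float]]:
        """All (theta0, T_s) pairs with at least one accepted replicate."""
        ii, jj = np.nonzero(self.accepted > 0)
        return [(float(self.theta0_grid[i]), float(self.ts_grid[j]))
                for i, j in zip(ii, jj)]

    def to_frame(self):
        import pandas as pd
        t0, ts = np.meshgrid(self.theta0_grid, self.ts_grid, indexing="ij")
        return pd.DataFrame({
            "theta0": t0.ravel(), "t_s": ts.ravel(),
            "accepted": self.accepted.ravel(), "reps": self.reps,
            "likelihood": self.likelihood.ravel(),
        })


def default_grids(obs: ObservedNeutralSummary
                  ) -> tuple[np.ndarray, np.ndarray]:
    """theta0 log-spaced over [0.1, 10 * theta_W(obs)] x 25 (falling back
    to [0.1, 10] when S_obs = 0) and T_s linear over [0, 4] x 41, spanning
    star-tree to effectively neutral regimes."""
    hi = 10.0 * obs.theta_w if obs.s_obs > 0 else 10.0
    hi = max(hi, 1.0)
    theta0 = np.geomspace(0.1, hi, 25)
    ts = np.linspace(0.0, 4.0, 41)
    return theta0, ts


def fit_sweep_grid(
    obs: ObservedNeutralSummary,
    theta0_grid: Sequence[float] | None = None,
    ts_grid: Sequence[float] | None = None,
    reps: int = 25_000,
    tol: float = 0.05,
    seed=None,
) -> SweepGridResult:
    """Grid acceptance-sampling fit of the forced-coalescence sweep model.

    For each (theta0, T_s) pair, ``reps`` sweep genealogies with n = obs.n
    are simulated and mutations dropped at theta0; a replicate is accepted
    when |S_sim - S_obs| <= tol*S_obs and |k_sim - k_obs| <= tol*k_obs (the
    k condition is skipped when k_obs = 0, where a +-5% band is degenerate).
    An all-zero surface is a legitimate finding, flagged
    ``model_incompatible``.
    """
    if theta0_grid is None or ts_grid is None:
        d_theta, d_ts = default_grids(obs)
        theta0_grid = d_theta if theta0_grid is None else theta0_grid
        ts_grid = d_ts if ts_grid is None else ts_grid
    theta0_grid = np.asarray(theta0_grid, dtype=float)
    ts_grid = np.asarray(ts_grid, dtype=float)
    if theta0_grid.size == 0 or ts_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(theta0_grid.size * ts_grid.size)
    accepted = np.zeros((theta0_grid.size, ts_grid.size), dtype=np.int64)
    s_tol = tol * obs.s_obs
    k_tol = tol * obs.k_obs
    cell = 0
    for i, theta0 in enumerate(theta0_grid):
        for j, t_s in enumerate(ts_grid):
            rng = np.random.default_rng(children[cell])
            cell += 1
            S, k = batch_sweep_summary(obs.n, theta0, t_s, reps, seed=rng)
            ok = np.abs(S - obs.s_obs) <= s_tol
            if obs.k_obs > 0:
                ok &= np.abs(k - obs.k_obs) <= k_tol
            accepted[i, j] = int(ok.sum())
    result = SweepGridResult(
        theta0_grid, ts_grid, accepted, reps, tol, obs,
        metadata={"likelihood": "acceptance proportion (rectangular-kernel "
                                "ABC)"},
    )
    if result.model_incompatible:
        logger.warning("fit_sweep_grid: no parameter pair compatible with "
                       "the data (S=%d, k=%.3g, n=%d)",
                       obs.s_obs, obs.k_obs, obs.n)
    return result


def plot_sweep_surface(result: SweepGridResult, path: str) -> None:
    """Heat map of the acceptance-likelihood surface (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(result.ts_grid, result.theta0_grid,
                       result.likelihood, shading="nearest")
    ax.set_yscale("log")
    ax.set_xlabel("time since sweep $T_s$ (2N generations)")
    ax.set_ylabel(r"$\theta_0$ (per locus)")
    fig.colorbar(im, label="acceptance proportion")
    if result.mle is not None:
        ax.plot(result.mle[1], result.mle[0], "r*", ms=12)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
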