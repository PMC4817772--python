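"""Coalescent machinery: the neutral coalescent without recombination,
mutation dropping (theta mode and fixed-S mode), the forced-coalescence
hard-sweep genealogy, the two-species isolation (multispecies-coalescent)
divergence simulator, and the empirical Tajima's-D null.

Units follow the standard Hudson convention: time in units of 2N
generations, coalescence at rate k(k-1)/2 for k lineages, and mutations at
rate theta/2 per unit of total branch length with theta = 4*N*mu per locus.
The isolation simulator instead works directly in expected-substitutions-
per-site units (its theta and tau parameters are on that scale) and uses a
finite-site Jukes-Cantor mutation model, because cross-species divergences
of several percent make multiple hits non-negligible.

Besides the single-tree API, batch helpers simulate many replicates at once
with vectorized numpy operations; the Monte-Carlo-heavy procedures
(Tajima null, sweep-grid fitting, expectation checks) use those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .popgen_stats import SFS, tajimas_d

logger = logging.getLogger(__name__)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, Generator, or None to a numpy Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MSCParams:
    """Two-species isolation model parameters, in expected substitutions
    per site: within-species theta_a/theta_b, ancestral theta_anc, species
    divergence time tau_split, and the simulated locus length in bp."""

    theta_anc: float
    tau_split: float
    theta_a: float = 0.0
    theta_b: float = 0.0
    locus_length: int = 25_000

    def __post_init__(self) -> None:
        if min(self.theta_anc, self.tau_split, self.theta_a, self.theta_b) < 0:
            raise ValueError("MSC parameters must be non-negative")


@dataclass
class SweepParams:
    """Forced-coalescence sweep model: neutral per-locus theta0 absent a
    sweep, and the time T_s since the sweep in units of 2N generations."""

    theta0: float
    t_s: float
    n: int

    def __post_init__(self) -> None:
        if self.theta0 < 0 or self.t_s < 0:
            raise ValueError("theta0 and T_s must be non-negative")
        if self.n < 2:
            raise ValueError("sample size must be >= 2")


# ---------------------------------------------------------------------------
# single genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A coalescent tree: leaves 0..n-1 at time 0, internal nodes appended
    in coalescence order (a forced sweep node may be multifurcating)."""

    n: int
    parent: np.ndarray  # (n_nodes,), -1 at the root
    time: np.ndarray    # (n_nodes,), 0 at the leaves

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=float)
        if (self.parent == -1).sum() != 1:
            raise ValueError("genealogy must have exactly one root")
        child_ok = self.parent[: self.n_nodes]
        has_parent = child_ok >= 0
        if np.any(self.time[child_ok[has_parent]]
                  < self.time[has_parent] - 1e-12):
            raise ValueError("node times must be non-decreasing toward the root")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has = self.parent >= 0
        out[has] = self.time[self.parent[has]] - self.time[has]
        return out

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def leaf_counts(self) -> np.ndarray:
        """Number of sampled leaves below each node."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        counts[: self.n] = 1
        for i in range(self.n_nodes):  # parents always have larger index
            p = self.parent[i]
            if p >= 0:
                counts[p] += counts[i]
        return counts

    def leaf_sets(self) -> list[np.ndarray]:
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n):
            sets[i] = [i]
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                sets[p].extend(sets[i])
        return [np.array(sorted(s), dtype=np.int64) for s in sets]


def simulate_genealogy(n: int, seed=None) -> Genealogy:
    """Standard neutral coalescent genealogy for n lineages.

    With k lineages the next coalescence occurs after an Exp(k(k-1)/2)
    waiting time (in 2N-generation units) between a uniformly chosen pair.
    """
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    rng = as_rng(seed)
    return _simulate_tree(n, rng, t_stop=np.inf)


def simulate_sweep_genealogy(n: int, t_s: float, seed=None) -> Genealogy:
    """Hard-sweep genealogy: the neutral coalescent runs backward until time
    T_s, when all surviving lineages are forced to coalesce instantaneously
    into a single (possibly multifurcating) node; the tree ends there."""
    if n < 2:
        raise ValueError("need n >= 2 lineages")
    if t_s < 0:
        raise ValueError("T_s must be non-negative")
    rng = as_rng(seed)
    return _simulate_tree(n, rng, t_stop=float(t_s))


def _simulate_tree(n: int, rng: np.random.Generator, t_stop: float) -> Genealogy:
    parent = list(np.full(n, -1, dtype=np.int64))
    times = [0.0] * n
    active = list(range(n))
    t = 0.0
    while len(active) > 1:
        k = len(active)
        w = rng.exponential(2.0 / (k * (k - 1)))
        if t + w >= t_stop:
            # forced multifurcation at exactly t_stop
            node = len(parent)
            parent.append(-1)
            times.append(t_stop)
            for a in active:
                parent[a] = node
            active = [node]
            break
        t += w
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        j += j >= i
        node = len(parent)
        parent.append(-1)
        times.append(t)
        parent[active[i]] = node
        parent[active[j]] = node
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(node)
    return Genealogy(n=n, parent=np.array(parent), time=np.array(times))


@dataclass
class MutationDrop:
    """Mutations placed on a genealogy under the infinite-sites model."""

    genealogy: Genealogy
    node: np.ndarray  # branch (node below) carrying each mutation
    derived_count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = self.genealogy.leaf_counts()
        self.node = np.asarray(self.node, dtype=np.int64)
        self.derived_count = counts[self.node]

    @property
    def S(self) -> int:
        return len(self.node)

    def haplotypes(self) -> np.ndarray:
        """(n, S) binary matrix of derived-allele carriers."""
        n = self.genealogy.n
        sets = self.genealogy.leaf_sets()
        out = np.zeros((n, self.S), dtype=np.int8)
        for j, b in enumerate(self.node):
            out[sets[b], j] = 1
        return out

    def sfs(self) -> SFS:
        n = self.genealogy.n
        counts = np.zeros(n - 1, dtype=np.int64)
        seg = (self.derived_count > 0) & (self.derived_count < n)
        np.add.at(counts, self.derived_count[seg] - 1, 1)
        return SFS(n=n, counts=counts)

    def pi_total(self) -> float:
        n = self.genealogy.n
        i = self.derived_count
        return float((2.0 * i * (n - i)).sum() / (n * (n - 1)))


def drop_mutations(genealogy: Genealogy, theta: float | None = None,
                   fixed_s: int | None = None, seed=None) -> MutationDrop:
    """Place mutations on a genealogy.

    Exactly one of ``theta`` (Poisson(theta/2 * L) mutations, uniform on
    branches) or ``fixed_s`` (exactly S mutations, multinomial with
    probabilities proportional to branch lengths) must be given.
    """
    if (theta is None) == (fixed_s is None):
        raise ValueError("give exactly one of theta or fixed_s")
    rng = as_rng(seed)
    lengths = genealogy.branch_lengths()
    total = lengths.sum()
    if theta is not None:
        m = rng.poisson(0.5 * theta * total) if total > 0 else 0
    else:
        m = int(fixed_s)
        if m > 0 and total == 0:
            raise ValueError("cannot place mutations on a zero-length tree")
    if m == 0:
        return MutationDrop(genealogy, np.empty(0, dtype=np.int64))
    u = rng.random(m) * total
    nodes = np.searchsorted(np.cumsum(lengths), u, side="right")
    return MutationDrop(genealogy, nodes)


# ---------------------------------------------------------------------------
# vectorized batch engine
# ---------------------------------------------------------------------------

def _batch_intervals(n: int, reps: int, rng: np.random.Generator,
                     t_stop: float = np.inf):
    """Simulate `reps` coalescent genealogies at once.

    Returns (dur, sizes, tmrca): dur[:, idx] is the duration of the epoch
    with j = n - idx active lineages (truncated at t_stop for a sweep);
    sizes[idx] is a (reps, j) array of subtree leaf counts during that
    epoch.  With t_stop finite, the forced merge at t_stop is implicit
    (epochs beyond it have zero duration).
    """
    dur = np.empty((reps, n - 1))
    sizes: list[np.ndarray] = []
    sz = np.zeros((reps, n), dtype=np.int32)
    sz[:, :] = 1
    t = np.zeros(reps)
    rows = np.arange(reps)
    for idx, j in enumerate(range(n, 1, -1)):
        w = rng.exponential(2.0 / (j * (j - 1)), size=reps)
        t_new = t + w
        sizes.append(sz[:, :j].copy())
        if np.isinf(t_stop):
            dur[:, idx] = w
        else:
            dur[:, idx] = np.minimum(t_new, t_stop) - np.minimum(t, t_stop)
        t = t_new
        a = rng.integers(0, j, size=reps)
        b = rng.integers(0, j - 1, size=reps)
        b = b + (b >= a)
        sz[rows, a] += sz[rows, b]
        sz[rows, b] = sz[rows, j - 1]
        sz[rows, j - 1] = 0
    tmrca = np.minimum(t, t_stop)
    return dur, sizes, tmrca


def batch_tmrca(n: int, reps: int, seed=None, t_force: float = np.inf
                ) -> np.ndarray:
    """TMRCA of `reps` genealogies (forced to coalesce at t_force if set)."""
    rng = as_rng(seed)
    _, _, tmrca = _batch_intervals(n, reps, rng, t_stop=t_force)
    return tmrca


def batch_total_length(n: int, reps: int, seed=None,
                       t_force: float = np.inf) -> np.ndarray:
    rng = as_rng(seed)
    dur, _, _ = _batch_intervals(n, reps, rng, t_stop=t_force)
    j = np.arange(n, 1, -1)
    return (dur * j).sum(axis=1)


def _theta_mode_summary(n, dur, sizes, theta, rng, want_sfs=False):
    reps = dur.shape[0]
    S = np.zeros(reps, dtype=np.int64)
    k = np.zeros(reps)
    sfs = np.zeros((reps, n - 1), dtype=np.int64) if want_sfs else None
    pair_w = 2.0 / (n * (n - 1))
    for idx in range(n - 1):
        j = n - idx
        lam = 0.5 * theta * dur[:, idx]
        m = rng.poisson(lam[:, None] * np.ones((1, j)))
        S += m.sum(axis=1)
        s = sizes[idx]
        k += (m * (s * (n - s) * pair_w)).sum(axis=1)
        if want_sfs:
            flat_rep = np.repeat(np.arange(reps), j)
            np.add.at(sfs, (flat_rep, (s - 1).ravel()), m.ravel())
    return (S, k, sfs) if want_sfs else (S, k)


def batch_neutral_summary(n: int, theta: float, reps: int, seed=None,
                          want_sfs: bool = False):
    """(S, k[, sfs]) for `reps` neutral genealogies with per-locus theta."""
    rng = as_rng(seed)
    dur, sizes, _ = _batch_intervals(n, reps, rng)
    return _theta_mode_summary(n, dur, sizes, theta, rng, want_sfs)


def batch_sweep_summary(n: int, theta0: float, t_s: float, reps: int,
                        seed=None):
    """(S, k) for `reps` forced-coalescence sweep genealogies."""
    rng = as_rng(seed)
    dur, sizes, _ = _batch_intervals(n, reps, rng, t_stop=t_s)
    return _theta_mode_summary(n, dur, sizes, theta0, rng)


def batch_fixed_s_summary(n: int, fixed_s: int, reps: int, seed=None):
    """k (mean pairwise differences) for `reps` neutral genealogies each
    carrying exactly `fixed_s` mutations (multinomial on branch lengths)."""
    rng = as_rng(seed)
    dur, sizes, _ = _batch_intervals(n, reps, rng)
    # per-branch weights: every branch in epoch idx has length dur[:, idx]
    W = np.concatenate(
        [np.repeat(dur[:, idx:idx + 1], n - idx, axis=1)
         for idx in range(n - 1)], axis=1)
    SZ = np.concatenate(sizes, axis=1).astype(np.int64)
    cum = np.cumsum(W, axis=1)
    total = cum[:, -1]
    if np.any(total <= 0):
        raise ValueError("zero-length genealogy cannot carry mutations")
    u = rng.random((reps, fixed_s)) * total[:, None]
    branch = (u[:, :, None] >= cum[:, None, :]).sum(axis=2)
    s = SZ[np.arange(reps)[:, None], branch]
    k = (2.0 * s * (n - s)).sum(axis=1) / (n * (n - 1))
    return k


# ---------------------------------------------------------------------------
# Tajima's-D empirical null
# ---------------------------------------------------------------------------

def tajima_null_pvalue(n: int, s_obs: int, d_obs: float, reps: int = 10_000,
                       seed=None, tail: str = "lower",
                       conditioning: str = "fixed_s",
                       theta: float | None = None) -> float:
    """Empirical p-value for an observed Tajima's D under the neutral
    coalescent without recombination.

    Default conditions each replicate on the observed number of segregating
    sites (fixed-S mode); ``conditioning='theta'`` instead drops mutations
    at rate ``theta``.  p = (1 + #{D_sim <= D_obs}) / (reps + 1) for the
    lower tail (>= for the upper), which avoids p = 0.
    """
    if n < 4:
        raise ValueError("Tajima's D null requires n >= 4")
    if s_obs <= 0:
        raise ValueError("observed S must be positive")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    rng = as_rng(seed)
    if conditioning == "fixed_s":
        k = batch_fixed_s_summary(n, s_obs, reps, seed=rng)
        d_sim = tajimas_d(np.full(reps, s_obs), k, n)
    elif conditioning == "theta":
        if theta is None:
            raise ValueError("theta conditioning requires theta")
        S, k = batch_neutral_summary(n, theta, reps, seed=rng)
        d_sim = tajimas_d(S, k, n)
    else:
        raise ValueError("conditioning must be 'fixed_s' or 'theta'")
    bad = ~np.isfinite(d_sim)
    n_redrawn = 0
    while bad.any():  # redraw undefined replicates (theta mode, S = 0)
        n_redrawn += int(bad.sum())
        S2, k2 = batch_neutral_summary(n, theta, int(bad.sum()), seed=rng)
        d_sim[bad] = tajimas_d(S2, k2, n)
        bad = ~np.isfinite(d_sim)
    if n_redrawn:
        logger.info("tajima_null_pvalue: redrew %d undefined replicates",
                    n_redrawn)
    if tail == "lower":
        m = int((d_sim <= d_obs).sum())
    else:
        m = int((d_sim >= d_obs).sum())
    return (1.0 + m) / (reps + 1.0)


# ---------------------------------------------------------------------------
# two-species isolation divergence simulator
# ---------------------------------------------------------------------------

@dataclass
class IsolationResult:
    """Per-locus divergence draws from the isolation (no-migration) model."""

    t_coal: np.ndarray          # pairwise coalescence times (subst./site)
    raw_divergence: np.ndarray  # p-distance over the finite locus
    jc_divergence: np.ndarray   # Jukes-Cantor corrected
    params: MSCParams


def simulate_isolation_pair(msc: MSCParams, n_loci: int, seed=None
                            ) -> IsolationResult:
    """Simulate per-locus sequence divergence between two species under
    strict isolation.

    One lineage is sampled per species; their coalescence time is
    tau_split + Exp(mean theta_anc/2) in substitution units.  Sequences
    then evolve by finite-site Jukes-Cantor over ``locus_length`` bp: each
    site differs independently with probability (3/4)(1 - exp(-4d/3)) for
    total path length d = 2 t_coal.
    """
    if msc.locus_length < 100:
        raise ValueError("locus_length < 100 gives unstable divergence "
                         "estimates")
    rng = as_rng(seed)
    t_anc = (rng.exponential(0.5 * msc.theta_anc, size=n_loci)
             if msc.theta_anc > 0 else np.zeros(n_loci))
    t_coal = msc.tau_split + t_anc
    d = 2.0 * t_coal
    p_site = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    n_diff = rng.binomial(msc.locus_length, p_site)
    raw = n_diff / float(msc.locus_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        jc = np.where(raw < 0.75, -0.75 * np.log1p(-4.0 * raw / 3.0), np.nan)
    return IsolationResult(t_coal=t_coal, raw_divergence=raw,
                           jc_divergence=jc, params=msc)


def neutral_expectations(n: int, theta: float) -> dict[str, float]:
    """Closed-form neutral expectations E[S] = theta * a_{n-1}, E[k] = theta."""
    a1 = float((1.0 / np.arange(1, n)).sum())
    return {"S": theta * a1, "k": theta, "total_length":
            2.0 * a1, "tmrca": 2.0 * (1.0 - 1.0 / n)}


def ks_against_neutral(values: np.ndarray, n: int, reps: int, seed=None):
    """Two-sample KS test of a TMRCA sample against a fresh neutral sample."""
    ref = batch_tmrca(n, reps, seed=seed)
    return sps.ks_2samp(values, ref)
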