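"""Diversity and SFS statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matpop import popgen_stats as ps
from matpop.io_formats import CallabilityMask, Region, VariantTable, \
    SampleMeta


# ---------------------------------------------------------------------------
# independent oracles (pair enumeration + published formulas, written
# separately from the package implementation)
# ---------------------------------------------------------------------------

def oracle_pair_pi(haps: np.ndarray) -> float:
    """Mean pairwise difference count by explicit pair enumeration."""
    n = haps.shape[0]
    total = 0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((haps[i] != haps[j]).sum())
        pairs += 1
    return total / pairs


def oracle_tajimas_d(haps: np.ndarray) -> float:
    n, m = haps.shape
    counts = haps.sum(0)
    S = int(((counts > 0) & (counts < n)).sum())
    if S == 0:
        return float("nan")
    k = oracle_pair_pi(haps)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_fay_wu_h(haps: np.ndarray) -> float:
    """H = pi - theta_H with theta_H = sum 2 xi_i i^2 / (n(n-1)); the
    haplotype matrix is already polarized (1 = derived)."""
    n = haps.shape[0]
    counts = haps.sum(0)
    th = 0.0
    for i in counts:
        if 0 < i < n:
            th += 2.0 * i * i / (n * (n - 1))
    return oracle_pair_pi(haps) - th


def all_sfs_datasets(n_max=6, s_max=4):
    """Every dataset shape (n, multiset of derived counts) with n <= n_max
    and 1 <= S <= s_max, realized as a haplotype matrix."""
    for n in range(4, n_max + 1):
        for S in range(1, s_max + 1):
            for combo in itertools.combinations_with_replacement(
                    range(1, n), S):
                haps = np.zeros((n, S), dtype=np.int8)
                for j, c in enumerate(combo):
                    haps[:c, j] = 1
                yield n, haps


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

class TestTajimasD:
    def test_undefined_when_no_segregating_sites(self):
        assert np.isnan(ps.tajimas_d(0, 0.0, 8))

    def test_error_below_two_samples(self):
        with pytest.raises(ValueError):
            ps.tajimas_d(3, 1.0, 1)

    def test_three_singletons_match_textbook_oracle(self):
        haps = np.zeros((4, 3), dtype=np.int8)
        haps[0, 0] = haps[1, 1] = haps[2, 2] = 1
        k = oracle_pair_pi(haps)
        assert ps.tajimas_d(3, k, 4) == pytest.approx(
            oracle_tajimas_d(haps), rel=1e-12)

    def test_exhaustive_oracle_equivalence(self):
        for n, haps in all_sfs_datasets():
            counts = haps.sum(0)
            S = int(((counts > 0) & (counts < n)).sum())
            k = oracle_pair_pi(haps)
            assert ps.tajimas_d(S, k, n) == pytest.approx(
                oracle_tajimas_d(haps), rel=1e-12, abs=1e-12)

    def test_neutral_mean_near_zero(self):
        # D is normalized to variance ~1 but its neutral mean is known to
        # sit slightly below zero (about -0.07 at n=10, theta=5), so the
        # check brackets that small negative bias rather than exact zero
        from matpop.coalescent_sim import batch_neutral_summary
        S, k = batch_neutral_summary(10, 5.0, 10_000, seed=2024)
        d = ps.tajimas_d(S, k, 10)
        assert -0.15 < np.nanmean(d) < 0.05


class TestFayWuH:
    def test_n2_is_always_zero(self):
        for xi in ([0], [3], [7]):
            assert ps.fay_wu_h(ps.SFS(2, xi)) == pytest.approx(0.0)

    def test_single_high_frequency_site(self):
        # n=4, one site at derived count 3: pi = 0.5, theta_H = 1.5
        sfs = ps.SFS(4, [0, 0, 1])
        assert sfs.pi_total() == pytest.approx(0.5)
        assert ps.theta_h(sfs) == pytest.approx(1.5)
        assert ps.fay_wu_h(sfs) == pytest.approx(-1.0)

    def test_singletons_give_positive_h(self):
        assert ps.fay_wu_h(ps.SFS(4, [5, 0, 0])) > 0

    def test_folded_sfs_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            ps.fay_wu_h(ps.SFS(4, [1, 1], folded=True))

    def test_exhaustive_oracle_equivalence(self):
        for n, haps in all_sfs_datasets():
            counts = haps.sum(0)
            xi = np.zeros(n - 1, dtype=int)
            for c in counts:
                if 0 < c < n:
                    xi[c - 1] += 1
            assert ps.fay_wu_h(ps.SFS(n, xi)) == pytest.approx(
                oracle_fay_wu_h(haps), rel=1e-12, abs=1e-12)

    def test_normalized_form_is_finite_and_same_sign_tendency(self):
        sfs = ps.SFS(10, [4, 2, 1, 0, 0, 0, 0, 3, 5])
        h = ps.fay_wu_h(sfs)
        hn = ps.fay_wu_h(sfs, normalized=True)
        assert np.isfinite(hn)
        assert np.sign(hn) == np.sign(h)


# ---------------------------------------------------------------------------
# windowed statistics on small hand-built tables
# ---------------------------------------------------------------------------

def _table(pos, genotypes, n_samples=None, chrom="c"):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n = genotypes.shape[0]
    samples = [SampleMeta(f"s{i}") for i in range(n)]
    return VariantTable([chrom] * len(pos), pos, ["A"] * len(pos),
                        ["T"] * len(pos), genotypes, samples)


class TestNucleotideDiversity:
    def test_single_snp_derived_count_two_of_four(self):
        # 4 haplotypes, derived count 2: 4 of 6 pairs differ
        t = _table([0], [[0], [0], [1], [1]])
        mask = CallabilityMask({"c": [[0, 1]]})
        rows = ps.nucleotide_diversity(
            t, t.sample_ids, windows=[Region("c", 0, 1)], mask=mask,
            min_called_frac=0)
        assert rows[0].value == pytest.approx(4 / 6)

    def test_monomorphic_window_is_zero(self):
        t = _table([5], [[0], [0], [0]])
        rows = ps.nucleotide_diversity(
            t, t.sample_ids, windows=[Region("c", 100, 200)],
            mask=CallabilityMask({"c": [[0, 200]]}))
        assert rows[0].value == pytest.approx(0.0)

    def test_ten_percent_called_threshold(self):
        t = _table([0], [[0], [1]])
        windows = [Region("c", 0, 100_000)]
        below = CallabilityMask({"c": [[0, 9_999]]})
        at = CallabilityMask({"c": [[0, 10_000]]})
        assert not ps.nucleotide_diversity(t, t.sample_ids, windows,
                                           below)[0].defined
        assert ps.nucleotide_diversity(t, t.sample_ids, windows,
                                       at)[0].defined

    def test_pairwise_complete_missing_handling(self):
        t = _table([0], [[0], [1], [-1]])
        rows = ps.nucleotide_diversity(
            t, t.sample_ids, windows=[Region("c", 0, 1)],
            mask=CallabilityMask({"c": [[0, 1]]}), min_called_frac=0)
        assert rows[0].value == pytest.approx(1.0)  # one called pair differs

    def test_requires_two_samples(self):
        t = _table([0], [[0]])
        with pytest.raises(ValueError):
            ps.nucleotide_diversity(t, ["s0"])


class TestPairwiseDivergence:
    def test_identical_sequences_zero_everywhere(self):
        t = _table([10, 20], [[0, 1], [0, 1]])
        rows = ps.pairwise_divergence(
            t, "s0", "s1", windows=[Region("c", 0, 100)],
            mask=CallabilityMask({"c": [[0, 100]]}), min_called_frac=0)
        assert rows[0].value == pytest.approx(0.0)

    def test_jukes_cantor_value(self):
        assert ps.jukes_cantor(0.05) == pytest.approx(0.05174,  abs=1e-5)

    def test_jc_domain_error_flag(self):
        t = _table(list(range(3)), [[0, 0, 0], [1, 1, 1]])
        rows = ps.pairwise_divergence(
            t, "s0", "s1", windows=[Region("c", 0, 4)],
            mask=CallabilityMask({"c": [[0, 4]]}), min_called_frac=0)
        assert not rows[0].defined
        assert rows[0].extra.get("jc_domain_error")

    def test_jc_distance_exceeds_p(self):
        for p in (0.01, 0.1, 0.3, 0.6):
            assert ps.jukes_cantor(p) > p


class TestDxy:
    def test_fixed_difference_gives_one(self):
        t = _table(list(range(4)), [[0] * 4, [0] * 4, [1] * 4, [1] * 4])
        rows = ps.dxy(t, ["s0", "s1"], ["s2", "s3"],
                      windows=[Region("c", 0, 4)],
                      mask=CallabilityMask({"c": [[0, 4]]}),
                      min_called_frac=0)
        assert rows[0].value == pytest.approx(1.0)

    def test_identical_populations_zero(self):
        t = _table([0, 1], [[0, 1], [0, 1]])
        rows = ps.dxy(t, ["s0"], ["s1"], windows=[Region("c", 0, 2)],
                      mask=CallabilityMask({"c": [[0, 2]]}),
                      min_called_frac=0)
        assert rows[0].value == pytest.approx(0.0)

    def test_missing_site_excluded_from_both_sides(self):
        # site 1 has a missing call in pop A: excluded from numerator and
        # denominator, so dxy = 1/1 over the remaining called site
        t = _table([0, 1], [[0, -1], [1, 1]])
        rows = ps.dxy(t, ["s0"], ["s1"], windows=[Region("c", 0, 2)],
                      mask=CallabilityMask({"c": [[0, 2]]}),
                      min_called_frac=0)
        assert rows[0].n_called == 1
        assert rows[0].value == pytest.approx(1.0)

    def test_empty_population_rejected(self):
        t = _table([0], [[0], [1]])
        with pytest.raises(ValueError):
            ps.dxy(t, [], ["s1"])


class TestExtremeWindowFlags:
    def _rows(self, values):
        return [
            type("R", (), {"region": Region("c", i * 100, (i + 1) * 100),
                           "value": v,
                           "defined": bool(np.isfinite(v))})()
            for i, v in enumerate(values)
        ]

    def test_lower_tail_five_percent(self):
        rng = np.random.default_rng(5)
        vals = rng.permutation(100).astype(float)
        flags = ps.extreme_window_flags(self._rows(vals), 0.05, "lower")
        starts = {r.start // 100 for r in flags}
        assert starts == set(np.argsort(vals)[:5])

    def test_degenerate_distribution_flags_all(self):
        with pytest.warns(UserWarning, match="degenerate"):
            flags = ps.extreme_window_flags(self._rows([1.0] * 10))
        assert len(flags) == 10

    def test_all_undefined_is_error(self):
        with pytest.raises(ValueError):
            ps.extreme_window_flags(self._rows([float("nan")] * 3))


class TestSampleSelection:
    def test_one_per_heterokaryon_deterministic(self):
        metas = [SampleMeta(f"L1H0{i}{mt}", heterokaryon_id=f"h{i}",
                            mating_type=mt)
                 for i in (1, 2) for mt in ("A", "a")]
        assert ps.one_per_heterokaryon(metas) == ["L1H01A", "L1H02A"]

    def test_seeded_choice_is_reproducible(self):
        metas = [SampleMeta(f"H{i}{mt}", heterokaryon_id=f"h{i}",
                            mating_type=mt)
                 for i in range(6) for mt in ("A", "a")]
        assert ps.one_per_heterokaryon(metas, seed=3) == \
            ps.one_per_heterokaryon(metas, seed=3)


@settings(deadline=None, max_examples=25)
@given(st.integers(0, 2**31 - 1))
def test_windowed_stats_invariant_to_sample_order(seed):
    """pi rows are identical whichever order the samples are given in."""
    rng = np.random.default_rng(seed)
    n, m = 6, 30
    geno = (rng.random((n, m)) < 0.3).astype(np.int8)
    pos = np.sort(rng.choice(10_000, size=m, replace=False))
    t = _table(pos, geno)
    ids = list(t.sample_ids)
    shuffled = list(rng.permutation(ids))
    mask = CallabilityMask({"c": [[0, 10_000]]})
    w = [Region("c", 0, 10_000)]
    r1 = ps.nucleotide_diversity(t, ids, w, mask, min_called_frac=0)
    r2 = ps.nucleotide_diversity(t, shuffled, w, mask, min_called_frac=0)
    assert r1[0].value == pytest.approx(r2[0].value, rel=1e-12)
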