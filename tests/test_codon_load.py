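"""Codon-level load analyses: filters, P_N/P_S with an NG86 brute-force
oracle, switch classification, and exact-test comparisons."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from matpop import codon_load as cl
from matpop import synthetic_data as sd
from matpop.io_formats import GENETIC_CODE, CodonAlignment


def _aln(rows, names=None, full_length=None, mask=None):
    codons = np.array(rows)
    names = names or [f"t{i}" for i in range(codons.shape[0])]
    mask = np.ones(codons.shape[1], bool) if mask is None else mask
    return CodonAlignment("g", names, codons, mask, full_length)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_ng86_sites(codon: str) -> tuple[float, float]:
    """Per-codon expected synonymous/nonsynonymous sites, enumerated."""
    syn = nonsyn = 0.0
    aa = GENETIC_CODE[codon]
    for p in range(3):
        for b in "ACGT":
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if GENETIC_CODE.get(alt) == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


def oracle_fisher_2x2(a, b, c, d) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (sps.binom(row1, x) if False else None)

    from math import comb
    def hyper(x):
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = hyper(a)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    return sum(hyper(x) for x in range(lo, hi + 1)
               if hyper(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestFilterGenes:
    def test_below_seventy_percent_excluded(self):
        aln = _aln([["GCT"] * 13], full_length=60)  # 39/60 = 65%
        assert cl.filter_genes([aln]) == []

    def test_exactly_seventy_percent_retained(self):
        aln = _aln([["GCT"] * 14], full_length=60)  # 42/60 = 70%
        assert cl.filter_genes([aln]) == [aln]

    def test_empty_input(self):
        assert cl.filter_genes([]) == []


class TestRemovePolymorphicCodons:
    def test_segregating_codon_masked(self):
        aln = _aln([["GCT", "AAA"], ["GCC", "AAA"], ["GCT", "AAA"]])
        out = cl.remove_polymorphic_codons(aln, aln.names)
        assert list(out.codon_mask) == [False, True]

    def test_monomorphic_gene_unchanged(self):
        aln = _aln([["GCT", "AAA"], ["GCT", "AAA"]])
        out = cl.remove_polymorphic_codons(aln, aln.names)
        assert out.codon_mask.all()

    def test_fully_polymorphic_gene_warns(self):
        aln = _aln([["GCT"], ["GCA"]])
        with pytest.warns(UserWarning, match="dropped"):
            out = cl.remove_polymorphic_codons(aln, aln.names)
        assert not out.codon_mask.any()


# ---------------------------------------------------------------------------
# P_N / P_S
# ---------------------------------------------------------------------------

class TestCountPnPs:
    def test_one_syn_one_nonsyn(self):
        # GCT/GCC synonymous (Ala); AAA/GAA nonsynonymous (Lys/Glu)
        aln = _aln([["GCT", "AAA"], ["GCC", "GAA"]])
        c = cl.count_pn_ps(aln, aln.names)
        assert (c.p_n, c.p_s) == (1, 1)

    def test_no_polymorphism_all_zero(self):
        aln = _aln([["GCT", "AAA"], ["GCT", "AAA"]])
        c = cl.count_pn_ps(aln, aln.names)
        assert (c.p_n, c.p_s) == (0, 0)
        assert c.l_n + c.l_s == pytest.approx(6.0)

    def test_site_totals_match_ng86_oracle(self):
        rng = np.random.default_rng(51)
        codons = [cl.SENSE_CODONS[i]
                  for i in rng.integers(0, len(cl.SENSE_CODONS), 50)]
        aln = _aln([codons, codons])
        c = cl.count_pn_ps(aln, aln.names)
        exp_s = sum(oracle_ng86_sites(x)[0] for x in codons)
        exp_n = sum(oracle_ng86_sites(x)[1] for x in codons)
        assert c.l_s == pytest.approx(exp_s, rel=1e-9)
        assert c.l_n == pytest.approx(exp_n, rel=1e-9)

    def test_multi_hit_codon_skipped(self):
        aln = _aln([["GCT"], ["GGC"]])  # two positions differ
        c = cl.count_pn_ps(aln, aln.names)
        assert (c.p_n, c.p_s) == (0, 0)

    def test_fisher_helper_balanced_table(self):
        a = cl.PolymorphismCounts(p_n=10, p_s=10)
        b = cl.PolymorphismCounts(p_n=10, p_s=10)
        _, p = cl.pn_ps_fisher(a, b)
        assert p == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# codon switches
# ---------------------------------------------------------------------------

class TestClassifySwitches:
    TABLE = sd.toy_optimal_codon_table()

    def test_single_derived_synonymous_change(self):
        # outgroup GCT (NOP), matA GCT, mata GCC (OP): mata NOP->OP
        aln = _aln([["GCT"], ["GCT"], ["GCC"]],
                   names=["outgroup", "mat_A", "mat_a"])
        out = cl.classify_codon_switches(aln, self.TABLE)
        assert out.counts["mat_a"]["NOP->OP"] == 1
        assert out.total("mat_A") == 0

    def test_nonsynonymous_change_ignored(self):
        aln = _aln([["GCT"], ["GAT"], ["GCT"]],
                   names=["outgroup", "mat_A", "mat_a"])
        out = cl.classify_codon_switches(aln, self.TABLE)
        assert out.total() == 0

    def test_both_ingroups_differing_ignored(self):
        aln = _aln([["GCT"], ["GCC"], ["GCA"]],
                   names=["outgroup", "mat_A", "mat_a"])
        assert cl.classify_codon_switches(aln, self.TABLE).total() == 0

    def test_multi_substitution_codon_skipped(self):
        # CTA -> TTG is synonymous (Leu) but needs two changes
        aln = _aln([["CTA"], ["TTG"], ["CTA"]],
                   names=["outgroup", "mat_A", "mat_a"])
        assert cl.classify_codon_switches(aln, self.TABLE).total() == 0

    def test_planted_fixture_recovered_exactly(self):
        cfg = sd.CodonGeneConfig(seed=7)
        alns, truth = sd.simulate_codon_genes(cfg)
        total = cl.SwitchCounts()
        for aln in alns:
            total = total + cl.classify_codon_switches(aln, self.TABLE)
        assert total.counts == truth.counts

    def test_swapping_rows_swaps_counts(self):
        cfg = sd.CodonGeneConfig(n_genes=4, seed=8)
        alns, _ = sd.simulate_codon_genes(cfg)
        fwd = cl.SwitchCounts()
        rev = cl.SwitchCounts()
        for aln in alns:
            fwd = fwd + cl.classify_codon_switches(aln, self.TABLE)
            rev = rev + cl.classify_codon_switches(
                aln, self.TABLE, outgroup="outgroup", mat_A="mat_a",
                mat_a="mat_A")
        assert fwd.counts["mat_A"] == rev.counts["mat_A"]  # same genome
        assert fwd.counts["mat_a"] == rev.counts["mat_a"]

    def test_sum_of_categories_counts_qualifying_changes(self):
        cfg = sd.CodonGeneConfig(seed=9)
        alns, truth = sd.simulate_codon_genes(cfg)
        planted = sum(n for cats in cfg.switch_counts.values()
                      for n in cats.values())
        total = cl.SwitchCounts()
        for aln in alns:
            total = total + cl.classify_codon_switches(aln, self.TABLE)
        assert total.total() == planted


class TestCompareSwitches:
    def _counts(self, a_no, a_on, b_no, b_on):
        c = cl.SwitchCounts()
        c.add("mat_A", "NOP->OP", a_no)
        c.add("mat_A", "OP->NOP", a_on)
        c.add("mat_a", "NOP->OP", b_no)
        c.add("mat_a", "OP->NOP", b_on)
        return c

    def test_balanced_table_p_one(self):
        cmp = cl.compare_switches(self._counts(10, 10, 10, 10),
                                  "mat_A", "mat_a")
        assert cmp.p == pytest.approx(1.0)

    def test_matches_exact_hypergeometric_oracle(self):
        cmp = cl.compare_switches(self._counts(40, 5, 5, 40),
                                  "mat_A", "mat_a")
        assert cmp.p == pytest.approx(oracle_fisher_2x2(40, 5, 5, 40),
                                      rel=1e-9)

    def test_empty_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="margin"):
            cmp = cl.compare_switches(self._counts(0, 0, 3, 4),
                                      "mat_A", "mat_a")
        assert cmp.p == 1.0


class TestOptimalCodonTable:
    def test_strict_requires_full_coverage(self):
        with pytest.raises(ValueError, match="unclassified"):
            cl.OptimalCodonTable({"GCT": "OP"})

    def test_stop_codons_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            cl.OptimalCodonTable({"TAA": "OP"}, strict=False)

    def test_tsv_round_trip(self, tmp_path):
        t1 = sd.toy_optimal_codon_table()
        path = tmp_path / "opt.tsv"
        t1.to_tsv(path)
        t2 = cl.OptimalCodonTable.from_tsv(path)
        assert t1.classes == t2.classes
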