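"""Shared fixtures: tiny hand-written VCF/sheet inputs and reusable
synthetic studies (generated at test time; nothing is stored on disk)."""

from __future__ import annotations

import numpy as np
import pytest

from matpop import synthetic_data as sd

TINY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
##contig=<ID=chr2,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t11\t.\tA\tT\t.\tPASS\t.\tGT\t0\t1
chr1\t25\t.\tC\tG\t.\tPASS\t.\tGT\t1\t1
chr1\t40\t.\tG\tA\t.\tPASS\t.\tGT\t.\t0
chr1\t55\t.\tT\tC,G\t.\tPASS\t.\tGT\t0\t1
chr2\t7\t.\tA\tC\t.\tPASS\t.\tGT\t0/0\t1/1
"""

TINY_SHEET = """\
sample_id\tspecies\tlineage\tmating_type\theterokaryon_id
s1\tfocal\tL1\tA\th1
s2\tfocal\tL1\ta\th1
"""


@pytest.fixture
def tiny_vcf(tmp_path):
    vcf = tmp_path / "tiny.vcf"
    vcf.write_text(TINY_VCF)
    sheet = tmp_path / "sheet.tsv"
    sheet.write_text(TINY_SHEET)
    return vcf, sheet


SMALL_STUDY_KW = dict(
    chrom_lengths={"mat": 4_000_000, "chr2": 2_000_000, "chr3": 2_000_000},
    sr_start=1_000_000,
    sr_end=3_000_000,
    mat_locus_pos=2_000_000,
)


@pytest.fixture(scope="session")
def small_study():
    """A plain study (no introgression, no sweep) reused across tests."""
    return sd.simulate_study(sd.StudyConfig(**SMALL_STUDY_KW, seed=42))


@pytest.fixture(scope="session")
def introgressed_study():
    return sd.simulate_study(sd.StudyConfig(
        **SMALL_STUDY_KW,
        introgression=sd.IntrogressionSpec(start=1_200_000, end=2_800_000),
        seed=43))


def rng_for(name: str) -> np.random.Generator:
    """A derandomized per-test generator."""
    return np.random.default_rng(abs(hash(name)) % (2**31))
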