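"""Readers, writers and the in-memory variant/sequence model shared by all stages.

Coordinate conventions
----------------------
Positions are 0-based half-open everywhere inside the package (and in BED
output).  VCF input/output converts at the boundary (VCF is 1-based).

The variant model is SNP-only: invariant sites are representable only through
the :class:`CallabilityMask` denominator, matching SNP-only VCFs.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for a missing call

_STANDARD_TABLE = _BioCodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

#: codon -> one-letter amino acid, standard genetic code ('*' for stops)
GENETIC_CODE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
GENETIC_CODE.update({c: "*" for c in STOP_CODONS})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one haploid genome (a single-mating-type homokaryon)."""

    sample_id: str
    species: str = ""
    lineage: str = ""
    mating_type: str = "unknown"  # {"A", "a", "unknown"}
    heterokaryon_id: str | None = None


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class CallabilityMask:
    """Per-chromosome sets of callable positions, as sorted disjoint intervals.

    ``intervals`` maps chrom -> (m, 2) int array of 0-based half-open spans.
    A mask constructed with :meth:`all_callable` treats every position of the
    given chromosomes as called, so window called-site thresholds degrade
    gracefully when no mask is supplied.
    """

    def __init__(self, intervals: dict[str, np.ndarray]):
        self.intervals: dict[str, np.ndarray] = {}
        for chrom, arr in intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if arr.size:
                order = np.argsort(arr[:, 0])
                arr = arr[order]
                if np.any(arr[:, 1] <= arr[:, 0]):
                    raise ValueError(f"empty/inverted interval on {chrom}")
                if np.any(arr[1:, 0] < arr[:-1, 1]):
                    raise ValueError(f"overlapping intervals on {chrom}")
            self.intervals[chrom] = arr

    @classmethod
    def all_callable(cls, chrom_lengths: dict[str, int]) -> "CallabilityMask":
        return cls({c: np.array([[0, l]]) for c, l in chrom_lengths.items()})

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "CallabilityMask":
        by_chrom: dict[str, list[list[int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                by_chrom.setdefault(chrom, []).append([int(start), int(end)])
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    def called_in(self, chrom: str, start: int, end: int) -> int:
        """Number of callable base pairs inside [start, end)."""
        arr = self.intervals.get(chrom)
        if arr is None or arr.size == 0:
            return 0
        lo = np.clip(arr[:, 0], start, end)
        hi = np.clip(arr[:, 1], start, end)
        return int(np.maximum(hi - lo, 0).sum())

    def is_called(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean array: which of ``pos`` fall in a callable interval."""
        arr = self.intervals.get(chrom)
        pos = np.asarray(pos)
        if arr is None or arr.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < arr[idx[ok], 1]
        return out


class VariantTable:
    """Haploid biallelic SNP matrix with positions and sample metadata.

    genotypes is a (n_samples, n_sites) int8 matrix over {0, 1, MISSING};
    positions are 0-based and strictly increasing within each chromosome,
    and sites are grouped by chromosome in input order.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[str],
        genotypes: np.ndarray,
        samples: Sequence[SampleMeta],
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype="U1")
        self.alt = np.asarray(alt, dtype="U1")
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.samples = list(samples)
        self._validate()
        self._chrom_bounds: dict[str, tuple[int, int]] = {}
        if self.n_sites:
            breaks = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [self.n_sites]])
            for s, e in zip(starts, ends):
                self._chrom_bounds[str(self.chrom[s])] = (int(s), int(e))

    def _validate(self) -> None:
        n_sites = len(self.pos)
        if not (
            len(self.chrom) == len(self.ref) == len(self.alt) == n_sites
        ):
            raise ValueError("site arrays have inconsistent lengths")
        if self.genotypes.shape != (len(self.samples), n_sites):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {n_sites} sites"
            )
        bad = ~np.isin(self.genotypes, [0, 1, MISSING])
        if bad.any():
            raise ValueError("genotypes must be 0, 1 or missing")
        # strictly increasing positions per chromosome
        if n_sites > 1:
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(same & (np.diff(self.pos) <= 0)):
                raise ValueError(
                    "positions not strictly increasing within chromosome")
            firsts = self.chrom[np.concatenate(
                [[0], np.flatnonzero(~same) + 1])]
            if len(set(firsts)) != len(firsts):
                raise ValueError("sites are not grouped by chromosome")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_bounds)

    def sample_index(self, ids: Iterable[str] | str) -> np.ndarray:
        if isinstance(ids, str):
            ids = [ids]
        lookup = {s.sample_id: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in table") from None

    def sites_in(self, chrom: str, start: int | None = None,
                 end: int | None = None) -> slice:
        """Index slice of sites on ``chrom`` with start <= pos < end."""
        if chrom not in self._chrom_bounds:
            return slice(0, 0)
        lo, hi = self._chrom_bounds[chrom]
        p = self.pos[lo:hi]
        i = lo if start is None else lo + int(np.searchsorted(p, start, "left"))
        j = hi if end is None else lo + int(np.searchsorted(p, end, "left"))
        return slice(i, j)

    def select_samples(self, ids: Iterable[str]) -> "VariantTable":
        idx = self.sample_index(ids)
        return VariantTable(self.chrom, self.pos, self.ref, self.alt,
                            self.genotypes[idx], [self.samples[i] for i in idx])


@dataclass
class WindowStatRow:
    """One genomic window with its statistic value and called-site count."""

    region: Region
    n_called: int
    n_snps: int
    stat_name: str
    value: float  # NaN when undefined
    extra: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(chrom: str, length: int, size: int, step: int | None = None,
                 label: str = "") -> list[Region]:
    """Sliding windows over one chromosome (non-overlapping when step == size).

    The last partial window is emitted with its true, shorter span.
    """
    step = size if step is None else step
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    out = []
    start = 0
    while start < length:
        out.append(Region(chrom, start, min(start + size, length), label))
        if start + size >= length:
            break
        start += step
    return out


# ---------------------------------------------------------------------------
# sample sheet + VCF
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | os.PathLike) -> dict[str, SampleMeta]:
    """TSV with columns sample_id, species, lineage, mating_type, heterokaryon_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id"}
    if not required <= set(df.columns):
        raise ValueError(f"sample sheet must contain columns {sorted(required)}")
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        het = row.get("heterokaryon_id", "") or None
        metas[row["sample_id"]] = SampleMeta(
            sample_id=row["sample_id"],
            species=row.get("species", ""),
            lineage=row.get("lineage", ""),
            mating_type=row.get("mating_type", "") or "unknown",
            heterokaryon_id=het,
        )
    _check_heterokaryon_pairs(metas.values())
    return metas


def _check_heterokaryon_pairs(metas: Iterable[SampleMeta]) -> None:
    by_het: dict[str, list[SampleMeta]] = {}
    for m in metas:
        if m.heterokaryon_id:
            by_het.setdefault(m.heterokaryon_id, []).append(m)
    for het, members in by_het.items():
        if len(members) != 2 or {m.mating_type for m in members} != {"A", "a"}:
            raise ValueError(
                f"heterokaryon {het!r} must pair exactly two samples of "
                f"opposite mating type"
            )


def read_vcf(
    path: str | os.PathLike,
    sample_sheet_path: str | os.PathLike | None = None,
    on_heterozygote: str = "error",
) -> VariantTable:
    """Read haploid biallelic SNPs from a VCF into a :class:`VariantTable`.

    Multiallelic and non-SNP records are excluded (counts logged).  Missing
    genotypes ('.', './.') map to MISSING; '0/0' and '1/1' are accepted as
    haploid 0 and 1.  A truly heterozygous diploid GT for a homokaryon sample
    raises by default (``on_heterozygote='error'``) or is set missing
    (``'missing'``).
    """
    if on_heterozygote not in ("error", "missing"):
        raise ValueError("on_heterozygote must be 'error' or 'missing'")
    sheet = read_sample_sheet(sample_sheet_path) if sample_sheet_path else None

    vf = pysam.VariantFile(os.fspath(path))
    vcf_samples = list(vf.header.samples)
    if sheet is not None:
        for s in vcf_samples:
            if s not in sheet:
                raise ValueError(f"sample {s!r} in VCF absent from sample sheet")
        metas = [sheet[s] for s in vcf_samples]
    else:
        metas = [SampleMeta(sample_id=s) for s in vcf_samples]

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    gts: list[np.ndarray] = []
    n_skipped = 0
    for rec in vf:
        alleles = rec.alts or ()
        if len(alleles) != 1 or len(rec.ref) != 1 or len(alleles[0]) != 1 \
                or rec.ref.upper() not in "ACGT" or alleles[0].upper() not in "ACGT":
            n_skipped += 1
            continue
        row = np.full(len(vcf_samples), MISSING, dtype=np.int8)
        for i, s in enumerate(vcf_samples):
            gt = rec.samples[s].get("GT", (None,))
            calls = {a for a in gt if a is not None}
            if not calls:
                continue
            if len(calls) > 1:
                if on_heterozygote == "error":
                    raise ValueError(
                        f"heterozygous genotype for homokaryon sample {s!r} "
                        f"at {rec.chrom}:{rec.pos}"
                    )
                continue
            row[i] = calls.pop()
        chroms.append(rec.chrom)
        poss.append(rec.pos - 1)  # VCF 1-based -> internal 0-based
        refs.append(rec.ref.upper())
        alts.append(alleles[0].upper())
        gts.append(row)
    vf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    geno = (np.stack(gts, axis=1) if gts
            else np.zeros((len(vcf_samples), 0), dtype=np.int8))
    return VariantTable(chroms, poss, refs, alts, geno, metas)


def write_vcf(table: VariantTable, path: str | os.PathLike,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a VariantTable as an uncompressed VCF 4.2 with haploid GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=matpop\n")
        lengths = chrom_lengths or {}
        for c in table.chroms:
            ln = lengths.get(c, int(table.pos[table.sites_in(c)].max()) + 1
                             if table.sites_in(c).stop > table.sites_in(c).start else 1)
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.sample_ids) + "\n")
        geno = table.genotypes
        for j in range(table.n_sites):
            calls = "\t".join(
                "." if geno[i, j] == MISSING else str(int(geno[i, j]))
                for i in range(table.n_samples)
            )
            fh.write(f"{table.chrom[j]}\t{table.pos[j] + 1}\t.\t{table.ref[j]}"
                     f"\t{table.alt[j]}\t.\tPASS\t.\tGT\t{calls}\n")


def write_sample_sheet(samples: Sequence[SampleMeta],
                       path: str | os.PathLike) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "species": s.species,
            "lineage": s.lineage,
            "mating_type": s.mating_type,
            "heterokaryon_id": s.heterokaryon_id or "",
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def write_regions_bed(regions: Sequence[Region], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_regions_bed(path: str | os.PathLike) -> list[Region]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(Region(parts[0], int(parts[1]), int(parts[2]), label))
    return out


def write_stats_tsv(rows: Sequence[WindowStatRow], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "chrom": r.region.chrom,
                "start": r.region.start,
                "end": r.region.end,
                "n_called": r.n_called,
                "n_snps": r.n_snps,
                "stat": r.stat_name,
                "value": r.value,
            }
            for r in rows
        ],
        columns=["chrom", "start", "end", "n_called", "n_snps", "stat", "value"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_stats_tsv(path: str | os.PathLike) -> list[WindowStatRow]:
    df = pd.read_csv(path, sep="\t")
    return [
        WindowStatRow(
            region=Region(str(r.chrom), int(r.start), int(r.end)),
            n_called=int(r.n_called),
            n_snps=int(r.n_snps),
            stat_name=str(r.stat),
            value=float(r.value),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# CDS alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """An in-frame codon alignment: rows are taxa, columns are codons.

    ``codons[i, j]`` is the j-th codon (3-mer string) of taxon i; masked
    columns (gap fragments, internal stops) are excluded from all analyses.
    ``full_length`` is the declared full CDS length in nucleotides, used by
    the gene-coverage filter.
    """

    gene_id: str
    names: list[str]
    codons: np.ndarray  # (n_taxa, n_codons) dtype <U3
    codon_mask: np.ndarray  # (n_codons,) bool, True = usable
    full_length: int | None = None

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, name: str) -> np.ndarray:
        return self.codons[self.names.index(name)]

    @property
    def aligned_length(self) -> int:
        """Usable alignment length in nucleotides."""
        return 3 * int(self.codon_mask.sum())


def _parse_full_length(description: str) -> int | None:
    for tok in description.split():
        if tok.startswith("full_length="):
            return int(tok.split("=", 1)[1])
    return None


def read_cds_alignment(path: str | os.PathLike) -> CodonAlignment:
    records = list(SeqIO.parse(os.fspath(path), "fasta"))
    gene_id = Path(path).stem
    if not records:
        raise ValueError(f"{path}: empty alignment")
    length = len(records[0].seq)
    if length % 3 != 0:
        raise ValueError(f"{path}: alignment length {length} not divisible by 3")
    names = []
    rows = []
    full_length = None
    for rec in records:
        if len(rec.seq) != length:
            raise ValueError(f"{path}: ragged alignment")
        names.append(rec.id)
        rows.append(list(str(rec.seq).upper()))
        full_length = full_length or _parse_full_length(rec.description)
    arr = np.array(rows)  # (n_taxa, length)
    n_codons = length // 3
    codons = arr.reshape(len(names), n_codons, 3)
    codons = np.array(["".join(c) for row in codons for c in row]).reshape(
        len(names), n_codons
    )
    mask = np.ones(n_codons, dtype=bool)
    for j in range(n_codons):
        col = codons[:, j]
        has_gap = np.char.count(col, "-") > 0
        partial_gap = has_gap & (np.char.count(col, "-") < 3)
        if partial_gap.any():
            logger.warning("%s: codon %d has a partial-codon gap; masked",
                           gene_id, j)
            mask[j] = False
            continue
        if has_gap.any():
            mask[j] = False  # whole-codon gap: excluded from analyses
            continue
        internal = j < n_codons - 1
        if internal and any(c in STOP_CODONS for c in col):
            logger.warning("%s: internal stop codon at column %d; masked",
                           gene_id, j)
            mask[j] = False
    return CodonAlignment(gene_id, names, codons, mask, full_length)


def read_cds_alignments(dir_path: str | os.PathLike) -> list[CodonAlignment]:
    """Read every FASTA codon alignment in a directory (sorted by name)."""
    paths = sorted(
        p for p in Path(dir_path).iterdir()
        if p.suffix.lower() in (".fa", ".fasta", ".fna")
    )
    if not paths:
        warnings.warn(f"no FASTA alignments found in {dir_path}")
        return []
    return [read_cds_alignment(p) for p in paths]


def write_cds_alignment(aln: CodonAlignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(aln.names):
            seq = "".join(aln.codons[i])
            desc = f" full_length={aln.full_length}" if aln.full_length else ""
            fh.write(f">{name}{desc}\n{seq}\n")
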