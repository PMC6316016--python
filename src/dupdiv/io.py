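"""Readers and writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open intervals; VCF positions are
converted from 1-based on read and back on write.  Only biallelic SNPs are
retained from VCF input; multiallelic and non-SNP records are skipped with a
logged count.  Missing genotypes are kept as missing (coded -1) and excluded
site-wise from allele counts downstream — they are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import STOP_CODONS

logger = logging.getLogger(__name__)

MISSING = -1

DNA = set("ACGT")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for many samples with population labels.

    calls has shape (n_sites, n_samples) with entries in {0, 1, 2} counting
    alternate-allele copies per diploid, or -1 for missing.  positions are
    0-based and strictly increasing.
    """

    chrom: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    sample_ids: list[str]
    pop_map: dict[str, str]
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape != (len(self.positions), len(self.sample_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.positions)} sites x {len(self.sample_ids)} samples"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        missing = [s for s in self.sample_ids if s not in self.pop_map]
        if missing:
            raise ValueError(f"samples missing from population map: {missing}")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_map[s], None)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_map[s] == population],
            dtype=np.int64,
        )
        if idx.size == 0:
            raise ValueError(f"population {population!r} has no samples")
        return idx


@dataclass(frozen=True)
class GeneRegion:
    """A gene interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.name}: start {self.start} >= end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two aligned, gap-free coding sequences of equal codon length."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"alignment length {len(self.seq_a)} not divisible by 3")
        for name, seq in (("seq_a", self.seq_a), ("seq_b", self.seq_b)):
            bad = set(seq) - DNA
            if bad:
                raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in STOP_CODONS:
                    raise ValueError(f"internal stop codon {seq[i:i+3]} at position {i} in {name}")

    def __len__(self) -> int:
        return len(self.seq_a)

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codons(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class TraitTable:
    """Replicate-level cultivar trait and expression measurements.

    data holds one row per (cultivar, replicate) with a trait column, one
    expression column per gene (2^-ddCt scale, non-negative) and an optional
    promoter-genotype label column.
    """

    data: pd.DataFrame
    genes: list[str]
    trait: str = "trait"
    genotype: str | None = None

    def __post_init__(self) -> None:
        required = ["cultivar", "replicate", self.trait, *self.genes]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        if self.genotype is not None and self.genotype not in self.data.columns:
            raise ValueError(f"genotype column {self.genotype!r} not present")
        expr = self.data[self.genes].to_numpy(dtype=float)
        if (expr < 0).any():
            raise ValueError("expression values must be non-negative")
        dup = self.data.duplicated(subset=["cultivar", "replicate"])
        if dup.any():
            keys = self.data.loc[dup, ["cultivar", "replicate"]].to_records(index=False)
            raise ValueError(f"duplicated (cultivar, replicate) keys: {list(keys)[:5]}")

    @property
    def n_cultivars(self) -> int:
        return self.data["cultivar"].nunique()

    def cultivar_means(self) -> pd.DataFrame:
        """Average replicates to one row per cultivar (trait and expressions)."""
        cols = [self.trait, *self.genes]
        agg = self.data.groupby("cultivar", sort=True)[cols].mean()
        if self.genotype is not None:
            agg[self.genotype] = self.data.groupby("cultivar", sort=True)[self.genotype].first()
        return agg.reset_index()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, population), no header."""
    pop_map: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {ln}: expected two tab-separated columns")
            pop_map[parts[0]] = parts[1]
    return pop_map


def read_vcf(path: str | Path, pop_map_path: str | Path) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a GenotypeMatrix.

    Multiallelic and non-SNP records are skipped (count logged).  Every VCF
    sample must appear in the population map.  A multi-chromosome VCF is
    rejected; run per chromosome.
    """
    from cyvcf2 import VCF

    pop_map = read_pop_map(pop_map_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_map]
    if absent:
        raise ValueError(f"samples in VCF but not in population map: {absent}")

    positions: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    chrom: str | None = None
    chrom_length: int | None = None
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in DNA or v.ALT[0] not in DNA:
            n_skipped += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError(f"multiple chromosomes in {path} ({chrom}, {v.CHROM}); split input")
        row = np.empty(len(samples), dtype=np.int8)
        for j, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            row[j] = MISSING if (a < 0 or b < 0) else a + b
        positions.append(v.POS - 1)  # to 0-based
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(row)
    if chrom is not None:
        try:
            idx = vcf.seqnames.index(chrom)
            chrom_length = vcf.seqlens[idx]
        except (ValueError, AttributeError):
            chrom_length = None
    if n_skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", n_skipped)
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(
        chrom=chrom if chrom is not None else "NA",
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        calls=calls,
        sample_ids=samples,
        pop_map={s: pop_map[s] for s in samples},
        chrom_length=chrom_length,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as minimal VCF v4.2 (GT only, 1-based positions)."""
    length = matrix.chrom_length
    if length is None:
        length = int(matrix.positions[-1]) + 1 if matrix.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dupdiv\n")
        fh.write(f"##contig=<ID={matrix.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.sample_ids) + "\n")
        for i in range(matrix.n_sites):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[i])
            fh.write(
                f"{matrix.chrom}\t{matrix.positions[i] + 1}\t.\t{matrix.ref[i]}\t"
                f"{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_pop_map(pop_map: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_map.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# FASTA codon pairs
# ---------------------------------------------------------------------------

def read_fasta_pair(path: str | Path) -> CodonAlignmentPair:
    """Read a 2-record aligned FASTA into a CodonAlignmentPair.

    Alignment columns where either sequence carries a gap or an ambiguity
    character are removed in whole-codon units (a codon with any such column
    is dropped from both sequences; count logged).  A shared terminal stop
    codon is trimmed; a stop anywhere else is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 FASTA records, found {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ValueError(f"{path}: sequences have unequal lengths ({len(a)} vs {len(b)})")
    if len(a) % 3 != 0:
        raise ValueError(f"{path}: alignment length {len(a)} not divisible by 3")
    kept_a: list[str] = []
    kept_b: list[str] = []
    n_dropped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) <= DNA and set(cb) <= DNA:
            kept_a.append(ca)
            kept_b.append(cb)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("read_fasta_pair: dropped %d codons with gaps/ambiguities", n_dropped)
    if kept_a and kept_a[-1] in STOP_CODONS and kept_b[-1] in STOP_CODONS:
        kept_a.pop()
        kept_b.pop()
    return CodonAlignmentPair("".join(kept_a), "".join(kept_b))


def write_fasta_pair(pair: CodonAlignmentPair, path: str | Path,
                     names: Sequence[str] = ("seq_a", "seq_b")) -> None:
    with open(path, "w") as fh:
        for name, seq in zip(names, (pair.seq_a, pair.seq_b)):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# BED gene regions
# ---------------------------------------------------------------------------

def read_gene_regions(path: str | Path) -> list[GeneRegion]:
    """Read BED3+ intervals (0-based half-open); overlaps retained, no merging."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >=3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}: line {ln}: start {start} >= end {end}")
            name = parts[3] if len(parts) > 3 and parts[3] else f"region_{ln}"
            regions.append(GeneRegion(chrom, start, end, name))
    return regions


def write_gene_regions(regions: Sequence[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

def read_trait_table(
    path: str | Path,
    genes: Sequence[str],
    trait: str = "trait",
    genotype: str | None = None,
) -> TraitTable:
    """Read a TSV trait/expression table (header required).

    Rows with a missing trait or expression cell are dropped with a warning;
    a non-numeric value in a trait or expression column is an error naming
    the row; duplicated (cultivar, replicate) keys are an error.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["cultivar", "replicate", trait, *genes]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    for col in [trait, *genes]:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(f"{path}: non-numeric value {raw[row]!r} in column {col!r}, row {row}")
        df[col] = coerced
    incomplete = df[[trait, *genes]].isna().any(axis=1)
    if incomplete.any():
        logger.warning("read_trait_table: dropped %d rows with missing cells", int(incomplete.sum()))
        df = df.loc[~incomplete].reset_index(drop=True)
    return TraitTable(data=df, genes=list(genes), trait=trait, genotype=genotype)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
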