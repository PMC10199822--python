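"""Domain types, coordinate conventions and I/O for the analysis pipeline.

All internal coordinates are 0-based half-open ``[start, end)``.  GFF3 input
(1-based inclusive) is converted at the boundary; BED is taken as-is.  Strand
is one of ``+``, ``-`` or ``.``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeIndex",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "read_gff3",
    "write_gff3",
    "subgenome_of",
    "tpm_from_counts",
    "promoter_region",
    "nearest_gene",
    "overlaps_any",
    "read_matrix_tsv",
    "write_matrix_tsv",
]

SUBGENOME_PATTERN_DEFAULT = r"([ABD])$"


class BedParseError(ValueError):
    """Malformed BED record; message carries the 1-based line number."""


class Gff3ParseError(ValueError):
    """Malformed GFF3 gene record; message carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span.

    Parameters
    ----------
    chrom : str
        Chromosome identifier; must be non-empty.
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        0-based exclusive end, ``> start``.
    strand : str
        One of ``+``, ``-``, ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)`` (deterministic for even lengths)."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene with strand-aware TSS/TES.

    For ``+`` genes ``tss == interval.start`` and ``tes == interval.end - 1``;
    mirrored for ``-`` genes.  Both always lie inside the interval.
    """

    gene_id: str
    interval: GenomicInterval
    subgenome: str = "other"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.interval.strand!r}"
            )

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def tes(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


def subgenome_of(chrom: str, pattern: str = SUBGENOME_PATTERN_DEFAULT) -> str:
    """Infer the subgenome label from a chromosome name.

    The first group of ``pattern`` is the label (default: trailing A/B/D as in
    ``chr1A``).  Unmatched chromosomes get ``"other"`` and are excluded from
    subgenome-stratified analyses only.
    """
    m = re.search(pattern, chrom)
    return m.group(1) if m else "other"


@dataclass
class GenomeIndex:
    """Chromosome lengths, subgenome partition and an optional sequence accessor.

    ``sequences`` maps chrom -> object supporting ``str(seq[start:end])``
    (a plain string, or a ``pyfaidx.FastaRecord``).
    """

    chrom_lengths: dict[str, int]
    subgenomes: dict[str, str] = field(default_factory=dict)
    sequences: dict | None = None

    def __post_init__(self) -> None:
        for chrom in self.chrom_lengths:
            self.subgenomes.setdefault(chrom, subgenome_of(chrom))

    @classmethod
    def from_fasta(cls, path: str, pattern: str = SUBGENOME_PATTERN_DEFAULT) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        lengths = {name: len(fa[name]) for name in fa.keys()}
        subg = {name: subgenome_of(name, pattern) for name in lengths}
        return cls(lengths, subg, sequences=fa)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def fetch(self, interval: GenomicInterval) -> str:
        """Upper-case sequence of ``interval``; requires a sequence accessor."""
        if self.sequences is None:
            raise ValueError("GenomeIndex has no sequence accessor")
        seq = self.sequences[interval.chrom]
        return str(seq[interval.start : interval.end]).upper()

    def check_interval(self, interval: GenomicInterval) -> None:
        length = self.chrom_lengths.get(interval.chrom)
        if length is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > length:
            raise ValueError(
                f"interval [{interval.start}, {interval.end}) exceeds "
                f"{interval.chrom} length {length}"
            )


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals, in file order.

    Coordinates are 0-based half-open per the BED standard.  Column 4 -> name,
    column 5 -> score (``.`` allowed), column 6 -> strand.  Malformed lines
    raise :class:`BedParseError` naming the line.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if end <= start:
                raise BedParseError(
                    f"{path}:{lineno}: end ({end}) must exceed start ({start})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score {fields[4]!r}") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], header: str | None = None) -> None:
    """Write intervals as BED; emits exactly the columns that are populated."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            extra = [
                iv.name if iv.name is not None else ".",
                format(iv.score, "g") if iv.score is not None else ".",
                iv.strand,
            ]
            # trim trailing all-default columns
            if iv.strand == "." and iv.score is None and iv.name is None:
                pass
            elif iv.strand == "." and iv.score is None:
                cols.append(extra[0])
            else:
                cols.extend(extra)
            fh.write("\t".join(cols) + "\n")


_GFF_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff3(path, subgenome_pattern: str = SUBGENOME_PATTERN_DEFAULT) -> list[GeneModel]:
    """Read ``gene`` features from a GFF3 file into :class:`GeneModel` objects.

    GFF3 is 1-based inclusive; conversion to 0-based half-open happens here.
    Genes must carry an ``ID`` attribute and a ``+``/``-`` strand.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise Gff3ParseError(f"{path}:{lineno}: expected 9 columns")
            if fields[2] != "gene":
                continue
            chrom, _, _, start1, end1, _, strand, _, attrs = fields[:9]
            m = _GFF_ATTR_ID.search(attrs)
            if not m:
                raise Gff3ParseError(f"{path}:{lineno}: gene lacks ID attribute")
            if strand not in ("+", "-"):
                raise Gff3ParseError(
                    f"{path}:{lineno}: gene {m.group(1)} strand must be +/-, got {strand!r}"
                )
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise Gff3ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            genes.append(
                GeneModel(
                    gene_id=m.group(1),
                    interval=GenomicInterval(chrom, start, end, strand),
                    subgenome=subgenome_of(chrom, subgenome_pattern),
                )
            )
    return genes


def write_gff3(path, genes: Iterable[GeneModel], source: str = "hexatac") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        source,
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def tpm_from_counts(counts, gene_lengths) -> np.ndarray:
    """Transcripts-per-million from raw counts.

    ``tpm[g, s] = 1e6 * (counts[g, s] / length[g]) / sum_j (counts[j, s] / length[j])``

    Parameters
    ----------
    counts : array-like, genes x samples (a 1-D vector is one sample)
    gene_lengths : array-like, bp per gene, all ``> 0``

    An all-zero sample yields all-zero TPM with a warning.
    """
    c = np.asarray(counts, dtype=float)
    squeeze = c.ndim == 1
    if squeeze:
        c = c[:, None]
    lengths = np.asarray(gene_lengths, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rate = c / lengths[:, None]
    denom = rate.sum(axis=0)
    zero = denom == 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} all-zero sample(s); TPM set to 0", stacklevel=2)
        denom = np.where(zero, 1.0, denom)
    tpm = 1e6 * rate / denom
    return tpm[:, 0] if squeeze else tpm


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with derived TPM.

    ``counts`` and ``tpm`` are DataFrames indexed by gene_id with sample-ID
    columns; ``sample_tissues`` maps sample -> tissue.  TPM columns each sum to
    1e6 (within 1e-3 relative) unless the sample is all-zero.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_tissues: dict[str, str]
    tpm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_lengths.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            if self.gene_lengths.isna().any():
                raise ValueError("gene_lengths missing for some genes in counts")
        arr = tpm_from_counts(self.counts.to_numpy(), self.gene_lengths.to_numpy())
        self.tpm = pd.DataFrame(arr, index=self.counts.index, columns=self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_ids:
            t = self.sample_tissues[s]
            if t not in seen:
                seen.append(t)
        return seen

    def samples_of(self, tissue: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_tissues[s] == tissue]

    def tissue_mean_tpm(self) -> pd.DataFrame:
        """Mean TPM over replicates, genes x tissues."""
        cols = {t: self.tpm[self.samples_of(t)].mean(axis=1) for t in self.tissues}
        return pd.DataFrame(cols)


def read_matrix_tsv(path) -> pd.DataFrame:
    """TSV with header row = sample IDs and first column = gene IDs."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(path, df: pd.DataFrame, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"#{line}\n")
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Gene-relative geometry
# ---------------------------------------------------------------------------

def promoter_region(
    gene: GeneModel,
    upstream: int = 2000,
    downstream: int = 100,
    chrom_length: int | None = None,
) -> tuple[GenomicInterval, bool]:
    """Strand-aware promoter window around the TSS.

    ``+`` genes: ``[TSS - upstream, TSS + downstream)``; ``-`` genes the
    mirrored span ``[TSS - downstream, TSS + upstream + 1)``.  The window is
    clipped to ``[0, chrom_length)`` and the boolean return flags clipping.
    """
    tss = gene.tss
    if chrom_length is not None and not (0 <= tss < chrom_length):
        raise ValueError(f"gene {gene.gene_id}: TSS {tss} outside chromosome")
    if gene.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream + 1
    clipped = False
    if start < 0:
        start, clipped = 0, True
    if chrom_length is not None and end > chrom_length:
        end, clipped = chrom_length, True
    return GenomicInterval(gene.chrom, start, end, gene.strand, name=gene.gene_id), clipped


def nearest_gene(
    chrom: str, point: int, genes: Sequence[GeneModel]
) -> tuple[str | None, int | None]:
    """Nearest gene to a point, with signed distance.

    Distance is 0 inside a gene body; otherwise bp to the nearest gene edge,
    negative when the point lies left of the gene on the chromosome, positive
    when right.  Ties (equal |distance|) go to the lexicographically smaller
    gene_id.  A chromosome with no genes returns ``(None, None)``.
    """
    best: tuple[int, str] | None = None
    best_signed = 0
    for g in genes:
        if g.chrom != chrom:
            continue
        iv = g.interval
        if iv.start <= point < iv.end:
            signed = 0
        elif point < iv.start:
            signed = point - iv.start
        else:
            signed = point - (iv.end - 1)
        key = (abs(signed), g.gene_id)
        if best is None or key < best:
            best = key
            best_signed = signed
    if best is None:
        return None, None
    return best[1], best_signed


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean vector: does each query overlap (>=1 bp) any subject interval?"""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
    index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        arr = np.array(sorted(spans), dtype=np.int64)
        starts = arr[:, 0]
        ends_cummax = np.maximum.accumulate(arr[:, 1])
        index[chrom] = (starts, ends_cummax)
    out = np.zeros(len(queries), dtype=bool)
    for i, q in enumerate(queries):
        if q.chrom not in index:
            continue
        starts, ends_cummax = index[q.chrom]
        # candidates with start < q.end; overlap iff max end among them > q.start
        j = np.searchsorted(starts, q.end, side="left")
        out[i] = j > 0 and ends_cummax[j - 1] > q.start
    return out
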