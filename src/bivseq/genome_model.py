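"""Gene annotations and aligned-read intervals.

Conventions used by every downstream module:

* all internal coordinates are 0-based, half-open ``[start, end)``;
* a gene is reduced to a single transcription start site (TSS); when a GTF
  carries several features per ``gene_id`` the 5'-most TSS on the gene's
  strand is kept;
* a read contributes to all counting at exactly one genomic position, its
  midpoint ``(start + end) // 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "ParseError",
    "ValidationError",
    "GeneModel",
    "ReadInterval",
    "ReadSet",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_alignments",
    "write_reads_bed",
]

#: Comment/header prefixes tolerated (and skipped) by every text reader.
_SKIP_PREFIXES = ("#", "track", "browser")


class ParseError(ValueError):
    """A record in an input file could not be parsed."""

    def __init__(self, path: str | Path, line_number: int, message: str):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{self.path}:{line_number}: {message}")


class ValidationError(ValueError):
    """Parsed input violates a pipeline invariant."""


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, with optional functional-category labels."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True, slots=True)
class ReadInterval:
    """A single aligned read as a genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ReadSet:
    """A sequencing library: read intervals plus its total mapped-read count.

    ``library_size`` defaults to the number of reads retained and is the
    denominator of every reads-per-million (RPM) value computed downstream.
    Midpoints are cached per chromosome as sorted arrays so window and bin
    counting reduce to binary searches.
    """

    def __init__(self, reads: Sequence[ReadInterval], library_size: int | None = None):
        self.reads = list(reads)
        if library_size is None:
            library_size = len(self.reads)
        if library_size <= 0:
            raise ValidationError("library_size must be > 0")
        if library_size < len(self.reads):
            raise ValidationError(
                f"library_size {library_size} < number of reads {len(self.reads)}"
            )
        self.library_size = int(library_size)
        self._midpoints: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[ReadInterval]:
        return iter(self.reads)

    def _index(self) -> dict[str, np.ndarray]:
        if self._midpoints is None:
            by_chrom: dict[str, list[int]] = {}
            for r in self.reads:
                by_chrom.setdefault(r.chrom, []).append((r.start + r.end) // 2)
            self._midpoints = {
                c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()
            }
        return self._midpoints

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted read midpoints on ``chrom`` (empty array if none)."""
        return self._index().get(chrom, np.empty(0, dtype=np.int64))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._index())


def _records(path: str | Path) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, stripped line), skipping comments/blanks."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield i, line


def _parse_bed6_gene(path, lineno: int, line: str) -> GeneModel:
    fields = line.split()
    if len(fields) < 6:
        raise ParseError(path, lineno, f"expected >=6 BED fields, got {len(fields)}")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer coordinates {start_s!r}/{end_s!r}")
    if end <= start or start < 0:
        raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
    if strand not in ("+", "-"):
        raise ParseError(path, lineno, f"strand must be '+' or '-', got {strand!r}")
    tss = start if strand == "+" else end - 1
    return GeneModel(gene_id=name, chrom=chrom, tss=tss, strand=strand)


def _gtf_attribute(attrs: str, key: str) -> str | None:
    # GTF attributes: key "value"; key "value"; (unquoted values tolerated)
    for part in attrs.split(";"):
        part = part.strip()
        if not part:
            continue
        pieces = part.split(None, 1)
        if len(pieces) == 2 and pieces[0] == key:
            return pieces[1].strip().strip('"')
    return None


def read_gene_annotation(path: str | Path, format: str = "bed6") -> list[GeneModel]:
    """Read gene models from a BED6 or GTF file.

    BED6: the TSS is ``start`` on the + strand and ``end - 1`` on the -
    strand; gene names must be unique. GTF (1-based, inclusive) is converted
    to the internal 0-based half-open convention; ``gene`` features are used
    when present, otherwise ``transcript`` features, and the 5'-most TSS per
    ``gene_id`` is kept.
    """
    if format == "bed6":
        genes = [_parse_bed6_gene(path, n, line) for n, line in _records(path)]
        seen: dict[str, int] = {}
        dups = set()
        for g in genes:
            seen[g.gene_id] = seen.get(g.gene_id, 0) + 1
            if seen[g.gene_id] > 1:
                dups.add(g.gene_id)
        if dups:
            raise ValidationError(f"duplicate gene_id(s): {sorted(dups)}")
        return genes
    if format == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gtf(path: str | Path) -> list[GeneModel]:
    by_feature: dict[str, list[GeneModel]] = {"gene": [], "transcript": []}
    for lineno, line in _records(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(path, lineno, f"expected 9 GTF fields, got {len(fields)}")
        feature = fields[2]
        if feature not in by_feature:
            continue
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(path, lineno, "non-integer GTF coordinates")
        strand = fields[6]
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"strand must be '+' or '-', got {strand!r}")
        gene_id = _gtf_attribute(fields[8], "gene_id")
        if gene_id is None:
            raise ParseError(path, lineno, "missing gene_id attribute")
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        if end <= start or start < 0:
            raise ParseError(path, lineno, f"invalid interval [{start1}, {end1}]")
        tss = start if strand == "+" else end - 1
        by_feature[feature].append(
            GeneModel(gene_id=gene_id, chrom=fields[0], tss=tss, strand=strand)
        )
    pool = by_feature["gene"] or by_feature["transcript"]
    merged: dict[str, GeneModel] = {}
    for g in pool:
        prev = merged.get(g.gene_id)
        if prev is None:
            merged[g.gene_id] = g
            continue
        if (prev.chrom, prev.strand) != (g.chrom, g.strand):
            raise ValidationError(
                f"gene {g.gene_id}: inconsistent chrom/strand across features"
            )
        # keep the 5'-most TSS on the gene's strand
        if (g.strand == "+" and g.tss < prev.tss) or (
            g.strand == "-" and g.tss > prev.tss
        ):
            merged[g.gene_id] = g
    return list(merged.values())


def write_gene_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6, one 1-bp interval at the TSS per gene."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")


def read_alignments(
    path: str | Path, format: str = "bed", library_size: int | None = None
) -> ReadSet:
    """Read aligned reads from BED (>=3 columns) or SAM into a :class:`ReadSet`.

    Unmapped SAM records are skipped. ``library_size`` defaults to the number
    of reads retained. An empty file (or all-unmapped SAM) is an error.
    """
    reads: list[ReadInterval] = []
    if format == "bed":
        for lineno, line in _records(path):
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(
                    path, lineno, f"truncated BED record ({len(fields)} fields)"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates")
            if end <= start or start < 0:
                raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
            reads.append(ReadInterval(fields[0], start, end))
    elif format == "sam":
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for aln in sam.fetch(until_eof=True):
                if aln.is_unmapped:
                    continue
                start = aln.reference_start
                end = aln.reference_end
                if end is None:
                    end = start + max(1, aln.query_length)
                reads.append(ReadInterval(aln.reference_name, start, end))
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    if not reads:
        raise ValidationError(f"empty read set: {path}")
    return ReadSet(reads, library_size=library_size)


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    """Write read intervals as 3-column BED."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
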