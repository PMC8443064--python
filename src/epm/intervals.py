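"""Genomic interval primitives and standard-format I/O.

All coordinates are 0-based half-open (BED convention).  Every other module
builds on the types and predicates defined here, so there is exactly one
place where coordinate conventions live.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BedParseError",
    "SchemaError",
    "GenomicInterval",
    "GenomeTable",
    "TSSRecord",
    "Interaction",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_chrom_sizes",
    "overlaps",
    "distance",
    "bin_genome",
    "sort_intervals",
    "overlap_join",
]

BEDPE_COLUMNS = (
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "lnP", "FDR",
)


class BedParseError(ValueError):
    """A malformed record in a BED/BEDPE-like file."""


class SchemaError(ValueError):
    """A table is missing required columns or has mismatched samples."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``name``/``score``/``strand`` mirror BED columns 4-6; any further
    columns read from a file are preserved verbatim in ``extra``.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: str | None = None
    strand: str | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand is not None and self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.start}-{self.end}"


class GenomeTable(dict):
    """Mapping of chromosome name -> length in bp (all lengths > 0)."""

    def __init__(self, lengths: Mapping[str, int]):
        for name, length in lengths.items():
            if not name:
                raise ValueError("chromosome names must be non-empty")
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        super().__init__({str(k): int(v) for k, v in lengths.items()})


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: a width-1 interval plus gene id and strand."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "."

    def __post_init__(self) -> None:
        if self.interval.end != self.interval.start + 1:
            raise ValueError("TSS interval must have width 1")

    @property
    def position(self) -> int:
        return self.interval.start

    @classmethod
    def at(cls, gene_id: str, chrom: str, position: int, strand: str = ".") -> "TSSRecord":
        return cls(gene_id, GenomicInterval(chrom, position, position + 1), strand)


@dataclass(frozen=True)
class Interaction:
    """A significant chromatin contact between two anchors.

    ``ln_p`` is the natural log of the caller's interaction p-value
    (hence <= 0) and ``fdr`` its FDR estimate (>= 0).
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    name: str = "."
    ln_p: float = 0.0
    fdr: float = 0.0

    def __post_init__(self) -> None:
        if self.ln_p > 0:
            raise ValueError("ln_p must be <= 0 (natural log of a probability)")
        if self.fdr < 0:
            raise ValueError("fdr must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers


def _parse_coord(token: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise BedParseError(
            f"{path}:{lineno}: non-integer {what} {token!r}"
        ) from None


def read_bed(path: str | Path, min_cols: int = 3) -> list[GenomicInterval]:
    """Read a BED3+ file into a list of :class:`GenomicInterval`.

    Columns beyond the sixth are kept in ``extra``.  Lines must have at
    least ``min_cols`` tab-separated fields; comment/track lines and blank
    lines are skipped.
    """
    path = str(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < max(min_cols, 3):
                raise BedParseError(
                    f"{path}:{lineno}: expected >= {max(min_cols, 3)} columns, "
                    f"got {len(fields)}"
                )
            start = _parse_coord(fields[1], path, lineno, "start")
            end = _parse_coord(fields[2], path, lineno, "end")
            try:
                iv = GenomicInterval(
                    fields[0],
                    start,
                    end,
                    name=fields[3] if len(fields) > 3 else None,
                    score=fields[4] if len(fields) > 4 else None,
                    strand=fields[5] if len(fields) > 5 else None,
                    extra=tuple(fields[6:]),
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as tab-separated BED, emitting as many of the
    standard columns (name, score, strand) as are populated."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            tail = [iv.name, iv.score, iv.strand, *iv.extra]
            while tail and tail[-1] is None:
                tail.pop()
            fields.extend("." if f is None else f for f in tail)
            fh.write("\t".join(fields) + "\n")


def read_bedpe(path: str | Path) -> list[Interaction]:
    """Read a headered BEDPE dialect with columns
    ``chrom1 start1 end1 chrom2 start2 end2 name lnP FDR``."""
    path = str(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise SchemaError(f"{path}: empty file, expected a BEDPE header")
        header = header_line.split("\t")
        for required in ("lnP", "FDR"):
            if required not in header:
                raise SchemaError(f"{path}: missing required column {required!r}")
        for required in BEDPE_COLUMNS[:6]:
            if required not in header:
                raise SchemaError(f"{path}: missing coordinate column {required!r}")
        idx = {name: header.index(name) for name in header}
        out: list[Interaction] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise BedParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
                )
            try:
                a1 = GenomicInterval(
                    fields[idx["chrom1"]],
                    _parse_coord(fields[idx["start1"]], path, lineno, "start1"),
                    _parse_coord(fields[idx["end1"]], path, lineno, "end1"),
                )
                a2 = GenomicInterval(
                    fields[idx["chrom2"]],
                    _parse_coord(fields[idx["start2"]], path, lineno, "start2"),
                    _parse_coord(fields[idx["end2"]], path, lineno, "end2"),
                )
                inter = Interaction(
                    a1,
                    a2,
                    name=fields[idx["name"]] if "name" in idx else ".",
                    ln_p=float(fields[idx["lnP"]]),
                    fdr=float(fields[idx["FDR"]]),
                )
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            out.append(inter)
    return out


def write_bedpe(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BEDPE_COLUMNS) + "\n")
        for it in interactions:
            fh.write(
                "\t".join(
                    [
                        it.anchor1.chrom,
                        str(it.anchor1.start),
                        str(it.anchor1.end),
                        it.anchor2.chrom,
                        str(it.anchor2.start),
                        str(it.anchor2.end),
                        it.name,
                        repr(it.ln_p),
                        repr(it.fdr),
                    ]
                )
                + "\n"
            )


def read_chrom_sizes(path: str | Path) -> GenomeTable:
    """Read a two-column ``name<TAB>length`` chromosome-sizes file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
            if fields[0] in lengths:
                raise BedParseError(f"{path}:{lineno}: duplicate chromosome {fields[0]!r}")
            lengths[fields[0]] = _parse_coord(fields[1], str(path), lineno, "length")
    return GenomeTable(lengths)


# ---------------------------------------------------------------------------
# interval arithmetic


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share >= 1 bp (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Gap in bp between two intervals; 0 when they overlap, ``None``
    across chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.start < b.end and b.start < a.end:
        return 0
    if a.end <= b.start:
        return b.start - a.end
    return a.start - b.end


def bin_genome(genome: Mapping[str, int], width: int = 2000) -> list[GenomicInterval]:
    """Tile each chromosome with consecutive ``width``-bp bins.

    The terminal bin of a chromosome whose length is not a multiple of
    ``width`` is retained as a shorter, partial bin (identifiable by
    ``length < width``); downstream quantification is per-bp so partial
    bins do not bias signal.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins: list[GenomicInterval] = []
    for chrom in sorted(genome):
        length = genome[chrom]
        for start in range(0, length, width):
            end = min(start + width, length)
            bins.append(
                GenomicInterval(chrom, start, end, name=f"{chrom}:{start}-{end}")
            )
    return bins


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def overlap_join(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``overlaps(queries[i], subjects[j])``.

    Vectorized per chromosome; intended for the modest region counts this
    pipeline works at (thousands), not whole-genome read sets.
    """
    by_chrom_q: dict[str, list[int]] = {}
    for i, iv in enumerate(queries):
        by_chrom_q.setdefault(iv.chrom, []).append(i)
    by_chrom_s: dict[str, list[int]] = {}
    for j, iv in enumerate(subjects):
        by_chrom_s.setdefault(iv.chrom, []).append(j)

    pairs: list[tuple[int, int]] = []
    for chrom, qi in by_chrom_q.items():
        sj = by_chrom_s.get(chrom)
        if not sj:
            continue
        qs = np.array([[queries[i].start, queries[i].end] for i in qi])
        ss = np.array([[subjects[j].start, subjects[j].end] for j in sj])
        hit = (qs[:, None, 0] < ss[None, :, 1]) & (ss[None, :, 0] < qs[:, None, 1])
        for a, b in zip(*np.nonzero(hit)):
            pairs.append((qi[a], sj[b]))
    return pairs
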