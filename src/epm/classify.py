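"""Classification of candidate regions into the four regulatory classes.

A candidate region that overlaps (>= 1 bp) the window +/- 500 bp around any
transcription start site is a promoter: active promoter (AP) if the
candidate came from active states, bivalent promoter (BP) if from poised
states.  A candidate not classified as a promoter is an enhancer iff it
overlaps a p300 peak: active enhancer (AE) or poised enhancer (PE) by the
same group rule.  Promoter precedence is absolute, and no histone-content
filtering is applied at this stage (enhancers carrying H3K4me3 are kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GenomicInterval, TSSRecord, distance, overlap_join
from .states import CandidateRegion

__all__ = [
    "RegulatoryRegion",
    "CLASS_GROUP",
    "tss_window",
    "classify_promoters",
    "classify_enhancers",
    "classify_regions",
    "assign_genes_to_promoters",
    "tss_distance",
    "partition_intragenic",
    "write_regions",
    "read_regions",
    "read_tss_table",
    "write_tss_table",
]

#: class -> state group each class must carry
CLASS_GROUP = {"AP": "active", "BP": "poised", "AE": "active", "PE": "poised"}
_PROMOTER_CLASS = {"active": "AP", "poised": "BP"}
_ENHANCER_CLASS = {"active": "AE", "poised": "PE"}


@dataclass(frozen=True)
class RegulatoryRegion:
    interval: GenomicInterval
    region_class: str  # AP | BP | AE | PE
    id: str

    def __post_init__(self) -> None:
        if self.region_class not in CLASS_GROUP:
            raise ValueError(f"unknown region class {self.region_class!r}")

    @property
    def group(self) -> str:
        return CLASS_GROUP[self.region_class]


def tss_window(tss: TSSRecord, window: int = 500) -> GenomicInterval:
    """The interval spanned by TSS position t +/- ``window`` bp, i.e.
    ``[t - window, t + window + 1)`` clipped at 0 (2*window + 1 bp)."""
    t = tss.position
    return GenomicInterval(tss.interval.chrom, max(0, t - window), t + window + 1)


def _make_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:05d}" for i in range(1, n + 1)]


def classify_promoters(
    candidates: Sequence[CandidateRegion],
    tss: Sequence[TSSRecord],
    window: int = 500,
) -> list[RegulatoryRegion]:
    """Candidates overlapping any TSS window become AP/BP by their group."""
    windows = [tss_window(t, window) for t in tss]
    hit = {i for i, _ in overlap_join([c.interval for c in candidates], windows)}
    chosen = sorted(
        hit, key=lambda i: (candidates[i].interval.chrom, candidates[i].interval.start)
    )
    regions = []
    counters = {"AP": 0, "BP": 0}
    for i in chosen:
        cls = _PROMOTER_CLASS[candidates[i].group]
        counters[cls] += 1
        regions.append(
            RegulatoryRegion(candidates[i].interval, cls, f"{cls}_{counters[cls]:05d}")
        )
    return regions


def classify_enhancers(
    candidates: Sequence[CandidateRegion],
    promoters: Sequence[RegulatoryRegion],
    p300_peaks: Sequence[GenomicInterval],
) -> list[RegulatoryRegion]:
    """Non-promoter candidates overlapping a p300 peak become AE/PE.

    Promoter precedence is decided by coordinates: a candidate whose
    interval equals one already classified as a promoter is skipped.
    Candidates overlapping neither a TSS window nor a p300 peak are
    dropped.
    """
    promoter_keys = {
        (p.interval.chrom, p.interval.start, p.interval.end) for p in promoters
    }
    pool = [
        c
        for c in candidates
        if (c.interval.chrom, c.interval.start, c.interval.end) not in promoter_keys
    ]
    hit = {i for i, _ in overlap_join([c.interval for c in pool], list(p300_peaks))}
    chosen = sorted(hit, key=lambda i: (pool[i].interval.chrom, pool[i].interval.start))
    regions = []
    counters = {"AE": 0, "PE": 0}
    for i in chosen:
        cls = _ENHANCER_CLASS[pool[i].group]
        counters[cls] += 1
        regions.append(
            RegulatoryRegion(pool[i].interval, cls, f"{cls}_{counters[cls]:05d}")
        )
    return regions


def classify_regions(
    candidates: Sequence[CandidateRegion],
    tss: Sequence[TSSRecord],
    p300_peaks: Sequence[GenomicInterval],
    window: int = 500,
) -> list[RegulatoryRegion]:
    """Full classification: promoters first, then enhancers from the rest."""
    promoters = classify_promoters(candidates, tss, window)
    enhancers = classify_enhancers(candidates, promoters, p300_peaks)
    return promoters + enhancers


def assign_genes_to_promoters(
    promoters: Sequence[RegulatoryRegion],
    tss: Sequence[TSSRecord],
    window: int = 500,
) -> pd.DataFrame:
    """(promoter_id, gene_id) pairs for every gene with a TSS whose window
    overlaps the promoter; duplicates (multi-TSS genes) collapsed."""
    windows = [tss_window(t, window) for t in tss]
    pairs = {
        (promoters[i].id, tss[j].gene_id)
        for i, j in overlap_join([p.interval for p in promoters], windows)
    }
    frame = pd.DataFrame(sorted(pairs), columns=["promoter_id", "gene_id"])
    return frame


def tss_distance(
    region: GenomicInterval | RegulatoryRegion, tss: Sequence[TSSRecord]
) -> int | None:
    """Minimum distance in bp from ``region`` to any TSS on its chromosome,
    or ``None`` when the chromosome carries no TSS."""
    iv = region.interval if isinstance(region, RegulatoryRegion) else region
    best: int | None = None
    for t in tss:
        d = distance(iv, t.interval)
        if d is not None and (best is None or d < best):
            best = d
    return best


def is_distal(
    region: GenomicInterval | RegulatoryRegion,
    tss: Sequence[TSSRecord],
    threshold: int = 5000,
) -> bool | None:
    """Distal = strictly more than ``threshold`` bp from every TSS."""
    d = tss_distance(region, tss)
    return None if d is None else d > threshold


def partition_intragenic(
    enhancers: Sequence[RegulatoryRegion],
    gene_bodies: Sequence[GenomicInterval],
) -> tuple[list[RegulatoryRegion], list[RegulatoryRegion]]:
    """Split enhancers into (intragenic, intergenic) by >= 1 bp gene-body
    overlap; the two sets partition the input."""
    hit = {
        i for i, _ in overlap_join([e.interval for e in enhancers], list(gene_bodies))
    }
    intragenic = [e for i, e in enumerate(enhancers) if i in hit]
    intergenic = [e for i, e in enumerate(enhancers) if i not in hit]
    return intragenic, intergenic


# ---------------------------------------------------------------------------
# I/O


def write_regions(regions: Iterable[RegulatoryRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.id}|{r.region_class}\n"
            )


def read_regions(path: str | Path) -> list[RegulatoryRegion]:
    from .intervals import read_bed

    out = []
    for iv in read_bed(path, min_cols=4):
        rid, _, cls = (iv.name or "").partition("|")
        out.append(
            RegulatoryRegion(GenomicInterval(iv.chrom, iv.start, iv.end), cls, rid)
        )
    return out


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSV with columns gene_id, chrom, position, strand."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    for col in ("gene_id", "chrom", "position"):
        if col not in frame.columns:
            from .intervals import SchemaError

            raise SchemaError(f"{path}: missing TSS column {col!r}")
    strands = frame["strand"] if "strand" in frame.columns else "."
    return [
        TSSRecord.at(row.gene_id, row.chrom, int(row.position), getattr(row, "strand", "."))
        for row in frame.itertuples()
    ]


def write_tss_table(tss: Sequence[TSSRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in tss],
            "chrom": [t.interval.chrom for t in tss],
            "position": [t.position for t in tss],
            "strand": [t.strand for t in tss],
        }
    ).to_csv(path, sep="\t", index=False)
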