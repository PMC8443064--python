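"""Per-region sequencing-signal quantification.

The signal of a sample at a region is the number of reads overlapping the
region (>= 1 bp), scaled per million by the sample's library size and
averaged per bp of region length:

    value = 1e6 * overlapping_reads / library_size / region_length

This is the per-region quantity used as model predictor (before the log2
transform) and as the intensity fed to LOESS normalization.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, GenomeTable, SchemaError, bin_genome

__all__ = [
    "count_reads",
    "quantify",
    "quantify_bins",
    "build_signal_matrix",
    "write_signal_matrix",
    "read_signal_matrix",
    "write_library_sizes",
    "read_library_sizes",
]

SCALE = 1_000_000.0


def count_reads(
    reads: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    count_mode: str = "overlap",
) -> np.ndarray:
    """Number of reads assigned to each region.

    ``count_mode="overlap"`` counts any read sharing >= 1 bp with the
    region (a read straddling two regions counts in both);
    ``count_mode="midpoint"`` assigns each read to the region containing
    its midpoint.
    """
    if count_mode not in {"overlap", "midpoint"}:
        raise ValueError(f"count_mode must be overlap|midpoint, got {count_mode!r}")
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    mids: dict[str, list[int]] = {}
    for r in reads:
        starts.setdefault(r.chrom, []).append(r.start)
        ends.setdefault(r.chrom, []).append(r.end)
        mids.setdefault(r.chrom, []).append((r.start + r.end) // 2)
    for chrom in starts:
        starts[chrom].sort()
        ends[chrom].sort()
        mids[chrom].sort()

    counts = np.zeros(len(regions), dtype=np.int64)
    for i, region in enumerate(regions):
        if region.chrom not in starts:
            continue
        if count_mode == "overlap":
            s, e = starts[region.chrom], ends[region.chrom]
            # reads not overlapping: start >= region.end or end <= region.start
            n_right = len(s) - bisect_left(s, region.end)
            n_left = bisect_right(e, region.start)
            counts[i] = len(s) - n_right - n_left
        else:
            m = mids[region.chrom]
            counts[i] = bisect_left(m, region.end) - bisect_left(m, region.start)
    return counts


def quantify(
    reads: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    library_size: int,
    count_mode: str = "overlap",
) -> np.ndarray:
    """Library-size-normalized mean per-bp read count for each region."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    counts = count_reads(reads, regions, count_mode=count_mode)
    lengths = np.array([r.length for r in regions], dtype=float)
    return SCALE * counts / float(library_size) / lengths


def quantify_bins(
    reads: Sequence[GenomicInterval],
    genome: Mapping[str, int],
    library_size: int,
    width: int = 2000,
    count_mode: str = "overlap",
) -> pd.Series:
    """Quantify over a genome tiling of ``width``-bp bins; index is the
    stable bin id ``chrom:start-end``."""
    bins = bin_genome(GenomeTable(genome), width=width)
    values = quantify(reads, bins, library_size, count_mode=count_mode)
    return pd.Series(values, index=[b.name for b in bins], name="signal")


def build_signal_matrix(
    reads_by_sample: Mapping[str, Sequence[GenomicInterval]],
    regions: Sequence[GenomicInterval],
    library_sizes: Mapping[str, int],
    region_ids: Sequence[str] | None = None,
    count_mode: str = "overlap",
) -> pd.DataFrame:
    """Region x sample matrix of mean per-bp normalized counts."""
    if region_ids is None:
        region_ids = [r.name or str(r) for r in regions]
    data = {}
    for sample, reads in reads_by_sample.items():
        if sample not in library_sizes:
            raise SchemaError(f"no library size for sample {sample!r}")
        data[sample] = quantify(reads, regions, library_sizes[sample], count_mode)
    frame = pd.DataFrame(data, index=pd.Index(region_ids, name="region_id"))
    frame.insert(0, "chrom", [r.chrom for r in regions])
    frame.insert(1, "start", [r.start for r in regions])
    frame.insert(2, "end", [r.end for r in regions])
    return frame


COORD_COLUMNS = ["chrom", "start", "end"]


def write_signal_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=True)


def read_signal_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="region_id")
    return frame


def write_library_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: int(v) for k, v in sizes.items()}, fh, indent=2)


def read_library_sizes(path: str | Path) -> dict[str, int]:
    with open(path) as fh:
        return {k: int(v) for k, v in json.load(fh).items()}
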