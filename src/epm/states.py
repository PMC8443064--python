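"""Chromatin-state segmentation post-processing.

A segmentation assigns every genomic segment one of K integer state labels
(here the 9-state scheme learned from H3K4me3/H3K4me1/H3K27ac/H3K27me3).
This module turns such a track into candidate regulatory regions by merging
runs of same-group states, and computes the matrix of state-transition
enrichments along the linear genome, which is what reveals that the
"active" states (1-4) and the "poised" states (6-7) each mark single
functional regions rather than independent elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import BedParseError, GenomicInterval, read_bed

__all__ = [
    "Segment",
    "SegmentTrack",
    "DEFAULT_SCHEME",
    "CandidateRegion",
    "TransitionMatrix",
    "coalesce",
    "transition_matrix",
    "merge_state_groups",
    "read_segmentation",
    "write_candidates",
    "read_candidates",
]

GROUPS = ("active", "intermediate", "poised", "repressed_only", "unmarked")

#: Default mapping of the 9 segmentation states to functional groups:
#: 1-4 activation-associated, 5 H3K4me1-only (intermediate), 6-7 bivalent /
#: poised (H3K27me3 with H3K4me3 and/or H3K4me1), 8 H3K27me3-only,
#: 9 unmarked.
DEFAULT_SCHEME: Mapping[int, str] = {
    1: "active",
    2: "active",
    3: "active",
    4: "active",
    5: "intermediate",
    6: "poised",
    7: "poised",
    8: "repressed_only",
    9: "unmarked",
}


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    state: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=str(self.state))


@dataclass
class SegmentTrack:
    """Ordered, per-chromosome sorted, non-overlapping state-labelled segments."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.chrom, s.start, s.end)
        )
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and prev.chrom == seg.chrom and seg.start < prev.end:
                raise ValueError(
                    f"overlapping segments {prev.chrom}:{prev.start}-{prev.end} "
                    f"and {seg.chrom}:{seg.start}-{seg.end}"
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def by_chromosome(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for seg in self.segments:
            out.setdefault(seg.chrom, []).append(seg)
        return out

    @property
    def states(self) -> list[int]:
        return sorted({s.state for s in self.segments})


@dataclass(frozen=True)
class CandidateRegion:
    """A merged run of same-group segments, candidate regulatory region."""

    interval: GenomicInterval
    group: str  # "active" or "poised"
    states: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in {"active", "poised"}:
            raise ValueError(f"candidate group must be active/poised, got {self.group!r}")


@dataclass
class TransitionMatrix:
    """Observed / expected / enrichment of adjacent-segment state transitions.

    ``observed[x, y]`` counts ordered pairs where a segment of state ``x``
    is immediately followed (left to right, same chromosome) by a segment
    of state ``y``.  Expected counts assume independence of origin and
    destination marginals: ``E(x, y) = out(x) * in(y) / N``.  Enrichment is
    O/E, NaN where E = 0.
    """

    states: list[int]
    observed: np.ndarray
    expected: np.ndarray
    enrichment: np.ndarray
    n: int

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = pd.Index(self.states, name="from")
        cols = pd.Index(self.states, name="to")
        return {
            "observed": pd.DataFrame(self.observed, index=idx, columns=cols),
            "expected": pd.DataFrame(self.expected, index=idx, columns=cols),
            "enrichment": pd.DataFrame(self.enrichment, index=idx, columns=cols),
        }

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for block, frame in self.to_frames().items():
                fh.write(f"# {block} (N={self.n})\n")
                frame.to_csv(fh, sep="\t")


def coalesce(track: SegmentTrack) -> SegmentTrack:
    """Merge touching (0-bp gap) adjacent segments of identical state."""
    merged: list[Segment] = []
    for seg in track.segments:
        if (
            merged
            and merged[-1].chrom == seg.chrom
            and merged[-1].end == seg.start
            and merged[-1].state == seg.state
        ):
            prev = merged.pop()
            merged.append(Segment(prev.chrom, prev.start, seg.end, prev.state))
        else:
            merged.append(seg)
    return SegmentTrack(merged)


def transition_matrix(
    track: SegmentTrack, coalesce_first: bool = True
) -> TransitionMatrix:
    """Count state transitions between consecutive segments per chromosome.

    By default the track is coalesced first so that transitions are between
    distinct touching states; pass ``coalesce_first=False`` to count on the
    raw track.  Chromosome boundaries contribute no transitions.
    """
    if coalesce_first:
        track = coalesce(track)
    states = track.states
    k = len(states)
    pos = {s: i for i, s in enumerate(states)}
    observed = np.zeros((k, k), dtype=np.int64)
    for segs in track.by_chromosome().values():
        for a, b in zip(segs, segs[1:]):
            observed[pos[a.state], pos[b.state]] += 1
    n = int(observed.sum())
    if n == 0:
        empty = np.zeros((k, k))
        return TransitionMatrix(states, observed, empty, np.full((k, k), np.nan), 0)
    out = observed.sum(axis=1).astype(float)
    inn = observed.sum(axis=0).astype(float)
    expected = np.outer(out, inn) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(expected > 0, observed / expected, np.nan)
    return TransitionMatrix(states, observed, expected, enrichment, n)


def merge_state_groups(
    track: SegmentTrack,
    scheme: Mapping[int, str] = DEFAULT_SCHEME,
    min_length: int = 600,
) -> list[CandidateRegion]:
    """Merge touching same-group segments into candidate regions.

    Maximal runs of touching segments whose states all map to ``active``
    (or all to ``poised``) become one candidate spanning the run.  Runs
    shorter than ``min_length`` bp are discarded as background.  Finally,
    any surviving active region touching (0-bp gap) a surviving poised
    region is discarded together with its neighbour: such a boundary is
    ambiguous.  Intermediate, H3K27me3-only and unmarked segments break
    runs and are never emitted.
    """
    for state in track.states:
        if state not in scheme:
            raise ValueError(f"state {state} missing from scheme")

    regions: list[CandidateRegion] = []
    for chrom, segs in track.by_chromosome().items():
        run: list[Segment] = []
        run_group: str | None = None

        def flush() -> None:
            nonlocal run, run_group
            if run and run_group in {"active", "poised"}:
                regions.append(
                    CandidateRegion(
                        GenomicInterval(chrom, run[0].start, run[-1].end),
                        run_group,
                        tuple(s.state for s in run),
                    )
                )
            run, run_group = [], None

        for seg in segs:
            group = scheme[seg.state]
            if group not in {"active", "poised"}:
                flush()
                continue
            if run and (run_group != group or run[-1].end != seg.start):
                flush()
            run.append(seg)
            run_group = group
        flush()

    regions = [r for r in regions if r.interval.length >= min_length]

    # ambiguity rule: a surviving active region touching a surviving poised
    # region discards both
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    drop: set[int] = set()
    for i in range(len(regions) - 1):
        a, b = regions[i], regions[i + 1]
        if (
            a.interval.chrom == b.interval.chrom
            and a.interval.end == b.interval.start
            and a.group != b.group
        ):
            drop.update((i, i + 1))
    return [r for i, r in enumerate(regions) if i not in drop]


# ---------------------------------------------------------------------------
# I/O


def _parse_state_label(label: str, path: str) -> int:
    raw = label[1:] if label[:1] in {"E", "U"} else label
    try:
        return int(raw)
    except ValueError:
        raise BedParseError(f"{path}: unrecognized state label {label!r}") from None


def read_segmentation(path: str | Path) -> SegmentTrack:
    """Read a BED4 segmentation (``chrom start end state``), accepting
    ChromHMM-style labels ("E3") or bare integers."""
    intervals = read_bed(path, min_cols=4)
    return SegmentTrack(
        [
            Segment(iv.chrom, iv.start, iv.end, _parse_state_label(iv.name or "", str(path)))
            for iv in intervals
        ]
    )


def write_candidates(regions: Iterable[CandidateRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            states = ",".join(map(str, r.states))
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.group}|{states}\n"
            )


def read_candidates(path: str | Path) -> list[CandidateRegion]:
    out = []
    for iv in read_bed(path, min_cols=4):
        group, _, states = (iv.name or "").partition("|")
        out.append(
            CandidateRegion(
                GenomicInterval(iv.chrom, iv.start, iv.end),
                group,
                tuple(int(s) for s in states.split(",") if s),
            )
        )
    return out
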