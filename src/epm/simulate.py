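"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* a chromatin segmentation whose states alternate in runs, with
  within-group transitions enriched over chance;
* regulatory regions of the four classes (AP/BP/AE/PE) built to satisfy
  the classification rules exactly, together with contacts in which a
  poised enhancer touches a bivalent promoter with a plantable
  probability ``q`` against a known chance level;
* per-region mark signal and expression generated from a known linear
  model on log-signals, with housekeeping-like genes whose means are
  shared across cellular contexts and bivalent-like genes carrying
  planted monotone activation trends;
* multi-sample tables with smooth intensity-dependent biases for
  normalization stress-tests.

Everything is a pure function of its parameters and seed, so regenerated
fixtures are identical and every test runs without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import RegulatoryRegion, write_regions, write_tss_table
from .intervals import (
    GenomeTable,
    GenomicInterval,
    Interaction,
    TSSRecord,
    write_bed,
    write_bedpe,
)
from .states import CandidateRegion, Segment, SegmentTrack, write_candidates

__all__ = [
    "MARKS",
    "DEFAULT_BETA",
    "SyntheticTruth",
    "RegionWorld",
    "SimulatedContext",
    "gen_segmentation",
    "segmentation_from_candidates",
    "gen_regions_and_interactions",
    "gen_signal_expression",
    "gen_biased_samples",
    "smooth_bias",
    "gen_expression_trajectories",
    "gen_reads",
    "write_bundle",
]

#: the ten histone modifications used as predictors
MARKS = [
    "H3K4me3",
    "H3K4me1",
    "H3K27ac",
    "H3K27me3",
    "H3K36me3",
    "H2Bub",
    "H3K27me1",
    "H3K27me2",
    "H4K20me3",
    "H3K79me2",
]

#: default true coefficients: activation-associated marks positive, the
#: repressive H3K27me3 dominant and negative, broad repressive marks mildly
#: negative.
DEFAULT_BETA = {
    "H3K4me3": 0.5,
    "H3K4me1": 0.1,
    "H3K27ac": 0.6,
    "H3K27me3": -1.5,
    "H3K36me3": 0.6,
    "H2Bub": 0.4,
    "H3K27me1": 0.1,
    "H3K27me2": -0.3,
    "H4K20me3": -0.2,
    "H3K79me2": 0.3,
}

_SLOT = 20_000  # bp reserved per planted region; keeps 5-kb anchors unambiguous


def _default_genome() -> GenomeTable:
    return GenomeTable({"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000})


@dataclass
class SyntheticTruth:
    """Ground-truth parameters shared by the generators.

    ``beta``/``beta0`` define the expression model on log2 signals;
    ``sigma`` is the residual scale (when ``None`` it is derived per
    context so the theoretical evaluation correlation equals ``r_star``).
    ``q`` is the planted probability that a poised-enhancer contact hits a
    bivalent promoter, against chance level ``p0``.  ``mark_correlations``
    lists (mark_a, mark_b, rho) latent correlations; each mark may appear
    in at most one pair.
    """

    seed: int = 0
    genome: GenomeTable = field(default_factory=_default_genome)
    marks: list[str] = field(default_factory=lambda: list(MARKS))
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    beta0: float = 2.0
    sigma: float | None = None
    r_star: float = 0.8
    mark_mean: float = 2.0
    mark_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    bias_amplitude: float = 1.0
    q: float = 0.29
    q_active: float = 0.80
    p0: float = 0.24
    pe_fraction: float = 0.44
    housekeeping_frac: float = 0.30
    bivalent_frac: float = 0.17
    activated_frac: float = 0.5  # fraction of bivalent-like genes that activate
    trend_slope_range: tuple[float, float] = (0.5, 1.5)  # log2 per context step

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must be in (0, 1)")
        seen: set[str] = set()
        for a, b, rho in self.mark_correlations:
            if abs(rho) >= 1 or a in seen or b in seen or a == b:
                raise ValueError("mark_correlations must be disjoint pairs, |rho| < 1")
            seen.update((a, b))

    @property
    def beta_vector(self) -> np.ndarray:
        return np.array([self.beta[m] for m in self.marks])

    def covariance(self) -> np.ndarray:
        k = len(self.marks)
        cov = np.eye(k)
        idx = {m: i for i, m in enumerate(self.marks)}
        for a, b, rho in self.mark_correlations:
            cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = rho
        return cov

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "genome": dict(self.genome),
            "marks": self.marks,
            "beta": self.beta,
            "beta0": self.beta0,
            "sigma": self.sigma,
            "r_star": self.r_star,
            "mark_correlations": self.mark_correlations,
            "bias_amplitude": self.bias_amplitude,
            "q": self.q,
            "q_active": self.q_active,
            "p0": self.p0,
            "pe_fraction": self.pe_fraction,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# segmentation


def default_transition_probs() -> np.ndarray:
    """9x9 state-transition probabilities (zero diagonal) with within-group
    transitions enriched, mimicking the observed active (1-4) and poised
    (6-7) blocks, with the unmarked state as the common spacer."""
    p = np.full((9, 9), 0.01)
    groups = {0: range(0, 4), 1: (4,), 2: (5, 7), 3: (6,), 4: (8,)}
    for i in range(9):
        for j in range(9):
            if i == j:
                p[i, j] = 0.0
    # active block
    for i in range(4):
        for j in range(4):
            if i != j:
                p[i, j] = 0.12
        p[i, 8] = 0.35  # exit to unmarked
        p[i, 4] = 0.10  # flanking H3K4me1-only
    # intermediate
    p[4, 8] = 0.40
    for j in range(4):
        p[4, j] = 0.10
    # poised block (states 6,7 -> idx 5,6) with H3K27me3-only tails (8 -> idx 7)
    for i in (5, 6):
        for j in (5, 6):
            if i != j:
                p[i, j] = 0.25
        p[i, 7] = 0.20
        p[i, 8] = 0.30
    p[7, 5] = p[7, 6] = 0.15
    p[7, 8] = 0.45
    # unmarked returns anywhere, mostly to actives
    p[8, :4] = 0.15
    p[8, 4] = 0.08
    p[8, 5] = p[8, 6] = 0.08
    p[8, 7] = 0.08
    p /= p.sum(axis=1, keepdims=True)
    return p


def gen_segmentation(
    truth: SyntheticTruth,
    n_segments: int | None = None,
    mean_run_bp: int = 400,
    unit: int = 200,
    transition_probs: np.ndarray | None = None,
    seed: int | None = None,
) -> SegmentTrack:
    """Markov-style segmentation: states drawn from a zero-diagonal
    transition matrix, segment lengths ``unit * (1 + Geometric)`` with the
    stated mean, tiling each chromosome without gaps.  Deterministic given
    the seed; the resulting track is coalesced by construction."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    probs = default_transition_probs() if transition_probs is None else transition_probs
    mean_units = max(mean_run_bp / unit, 1.0)
    p_geom = 1.0 / mean_units

    genome = truth.genome
    if n_segments is not None:
        # synthesize chromosomes large enough to host the requested count
        per_chrom = 50_000
        total_bp = int(n_segments * mean_run_bp * 1.2)
        n_chroms = max(1, n_segments // per_chrom)
        genome = GenomeTable(
            {f"chr{i + 1}": total_bp // n_chroms for i in range(n_chroms)}
        )

    segments: list[Segment] = []
    count = 0
    for chrom in sorted(genome):
        length = genome[chrom]
        pos = 0
        state = int(rng.integers(9))
        while pos < length and (n_segments is None or count < n_segments):
            run = unit * int(rng.geometric(p_geom))
            end = min(pos + run, length)
            segments.append(Segment(chrom, pos, end, state + 1))
            count += 1
            pos = end
            state = int(rng.choice(9, p=probs[state]))
    return SegmentTrack(segments)


def segmentation_from_candidates(
    candidates: Sequence[CandidateRegion],
    genome: Mapping[str, int],
    filler_state: int = 9,
) -> SegmentTrack:
    """Build a genome-tiling segmentation whose group-merge recovers the
    given candidates exactly: each candidate is split into touching
    segments carrying its source states, and gaps are filled with the
    unmarked state."""
    segments: list[Segment] = []
    by_chrom: dict[str, list[CandidateRegion]] = {}
    for c in candidates:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for chrom in sorted(genome):
        length = genome[chrom]
        pos = 0
        for cand in sorted(by_chrom.get(chrom, []), key=lambda c: c.interval.start):
            if cand.interval.start > pos:
                segments.append(Segment(chrom, pos, cand.interval.start, filler_state))
            states = cand.states or (1,)
            bounds = np.linspace(
                cand.interval.start, cand.interval.end, len(states) + 1
            ).astype(int)
            for (s0, s1), st in zip(zip(bounds[:-1], bounds[1:]), states):
                if s1 > s0:
                    segments.append(Segment(chrom, int(s0), int(s1), st))
            pos = cand.interval.end
        if pos < length:
            segments.append(Segment(chrom, pos, length, filler_state))
    return SegmentTrack(segments)


# ---------------------------------------------------------------------------
# regions and interactions


@dataclass
class RegionWorld:
    """Planted regulatory regions plus the inputs that reproduce them."""

    genome: GenomeTable
    candidates: list[CandidateRegion]
    tss: list[TSSRecord]
    p300: list[GenomicInterval]
    gene_bodies: list[GenomicInterval]
    regions: list[RegulatoryRegion]
    gene_map: pd.DataFrame  # promoter_id, gene_id
    interactions: list[Interaction]
    associations: pd.DataFrame  # enhancer_id, promoter_id, gene_id, class_pair, provenance
    q: float
    p0: float

    def regions_of(self, *classes: str) -> list[RegulatoryRegion]:
        return [r for r in self.regions if r.region_class in classes]


_ACTIVE_STATES = (2, 3, 1)
_POISED_STATES = (6, 7)


def gen_regions_and_interactions(
    truth: SyntheticTruth,
    n_ap: int = 40,
    n_bp: int = 25,
    n_ae: int = 45,
    n_pe: int = 30,
    n_decoys: int = 10,
    n_interactions: int = 500,
    region_length: int = 1000,
    q: float | None = None,
    pe_fraction: float | None = None,
    top_fraction: float = 0.6,
    seed: int | None = None,
) -> RegionWorld:
    """Plant AP/BP/AE/PE regions and contacts with known class preference.

    Regions are laid out on a slot grid so that every 5-kb contact anchor
    covers exactly one region and no enhancer strays into a TSS window.
    Each contact is anchored on a poised enhancer with probability
    ``pe_fraction`` (else an active enhancer); the promoter side is the
    state-matched class with probability ``q`` for PEs (``truth.q_active``
    for AEs), otherwise the mismatched class.  Only matched draws yield
    ground-truth associations.  Decoy candidates overlap neither TSS
    windows nor p300 peaks and must be dropped by classification.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    q = truth.q if q is None else q
    pe_fraction = truth.pe_fraction if pe_fraction is None else pe_fraction

    slots: list[tuple[str, int]] = []
    for chrom in sorted(truth.genome):
        for start in range(0, truth.genome[chrom] - _SLOT + 1, _SLOT):
            slots.append((chrom, start))
    needed = n_ap + n_bp + n_ae + n_pe + n_decoys
    if needed > len(slots):
        raise ValueError(f"genome too small: {needed} regions, {len(slots)} slots")
    order = rng.permutation(len(slots))[:needed]

    labels = (
        ["AP"] * n_ap + ["BP"] * n_bp + ["AE"] * n_ae + ["PE"] * n_pe + ["decoy"] * n_decoys
    )
    candidates: list[CandidateRegion] = []
    tss: list[TSSRecord] = []
    p300: list[GenomicInterval] = []
    gene_bodies: list[GenomicInterval] = []
    planted: list[tuple[str, GenomicInterval]] = []

    gene_no = 0
    for label, slot_idx in zip(labels, order):
        chrom, slot_start = slots[slot_idx]
        start = slot_start + 5000
        iv = GenomicInterval(chrom, start, start + region_length)
        group = "poised" if label in {"BP", "PE"} else "active"
        states = _POISED_STATES if group == "poised" else _ACTIVE_STATES
        if label != "decoy":
            candidates.append(CandidateRegion(iv, group, tuple(states)))
            planted.append((label, iv))
        else:
            candidates.append(CandidateRegion(iv, "active", tuple(_ACTIVE_STATES)))
        if label in {"AP", "BP"}:
            gene_no += 1
            gene = f"G{gene_no:04d}"
            tss.append(TSSRecord.at(gene, chrom, start + region_length // 2, "+"))
            gene_bodies.append(
                GenomicInterval(chrom, start + region_length // 2, start + 7000, name=gene)
            )
        elif label in {"AE", "PE"}:
            mid = start + region_length // 2
            p300.append(GenomicInterval(chrom, mid - 100, mid + 100))

    # re-derive ids the classifier will assign (sorted by coordinates per class)
    regions: list[RegulatoryRegion] = []
    for cls in ("AP", "BP", "AE", "PE"):
        members = sorted(
            (iv for label, iv in planted if label == cls),
            key=lambda iv: (iv.chrom, iv.start),
        )
        for i, iv in enumerate(members, start=1):
            regions.append(RegulatoryRegion(iv, cls, f"{cls}_{i:05d}"))

    # every even-indexed enhancer becomes intragenic: a host gene body covers it
    enhancers = [r for r in regions if r.region_class in {"AE", "PE"}]
    for i, enh in enumerate(enhancers):
        if i % 2 == 0:
            gene_bodies.append(
                GenomicInterval(
                    enh.interval.chrom,
                    max(0, enh.interval.start - 2000),
                    enh.interval.end + 2000,
                    name=f"host_{enh.id}",
                )
            )

    # promoter -> gene map: the planted TSS sits inside its promoter
    promoters = [r for r in regions if r.region_class in {"AP", "BP"}]
    prom_rows = []
    for prom in promoters:
        for t in tss:
            if t.interval.chrom == prom.interval.chrom and (
                prom.interval.start <= t.position < prom.interval.end
            ):
                prom_rows.append((prom.id, t.gene_id))
    gene_map = pd.DataFrame(prom_rows, columns=["promoter_id", "gene_id"])

    def anchor_for(iv: GenomicInterval) -> GenomicInterval:
        center = (iv.start + iv.end) // 2
        start = (center // 5000) * 5000
        return GenomicInterval(iv.chrom, start, start + 5000)

    aps = [r for r in regions if r.region_class == "AP"]
    bps = [r for r in regions if r.region_class == "BP"]
    aes = [r for r in regions if r.region_class == "AE"]
    pes = [r for r in regions if r.region_class == "PE"]
    genes_of = gene_map.groupby("promoter_id")["gene_id"].agg(list).to_dict()

    interactions: list[Interaction] = []
    assoc_rows: set[tuple[str, str, str, str, str]] = set()
    for i in range(n_interactions):
        use_pe = rng.random() < pe_fraction
        enh = pes[int(rng.integers(len(pes)))] if use_pe else aes[int(rng.integers(len(aes)))]
        matched = rng.random() < (q if use_pe else truth.q_active)
        if enh.region_class == "PE":
            prom_pool = bps if matched else aps
        else:
            prom_pool = aps if matched else bps
        prom = prom_pool[int(rng.integers(len(prom_pool)))]
        if rng.random() < top_fraction:
            ln_p, fdr = float(rng.uniform(-300.0, -100.0)), 0.0
        else:
            ln_p, fdr = float(rng.uniform(-50.0, -7.0)), float(rng.uniform(1e-4, 0.05))
        interactions.append(
            Interaction(
                anchor_for(enh.interval),
                anchor_for(prom.interval),
                name=f"int_{i:05d}",
                ln_p=ln_p,
                fdr=fdr,
            )
        )
        if matched:
            pair = f"{enh.region_class}-{prom.region_class}"
            for gene in genes_of.get(prom.id, ()):
                assoc_rows.add((enh.id, prom.id, gene, pair, "hic"))

    associations = pd.DataFrame(
        sorted(assoc_rows),
        columns=["enhancer_id", "promoter_id", "gene_id", "class_pair", "provenance"],
    )
    return RegionWorld(
        genome=truth.genome,
        candidates=sorted(candidates, key=lambda c: (c.interval.chrom, c.interval.start)),
        tss=tss,
        p300=p300,
        gene_bodies=gene_bodies,
        regions=regions,
        gene_map=gene_map,
        interactions=interactions,
        associations=associations,
        q=q,
        p0=truth.p0,
    )


# ---------------------------------------------------------------------------
# signal and expression


@dataclass
class SimulatedContext:
    context: str
    signal: pd.DataFrame  # region x mark
    expression: pd.Series  # gene -> FPKM
    associations: pd.DataFrame  # gene_id, enhancer_id
    sigma: float
    gene_classes: pd.Series  # gene -> housekeeping | bivalent | background


def _gene_classes(n_genes: int, truth: SyntheticTruth, rng: np.random.Generator) -> pd.Series:
    genes = [f"g{i:05d}" for i in range(n_genes)]
    classes = np.full(n_genes, "background", dtype=object)
    n_hk = int(round(truth.housekeeping_frac * n_genes))
    n_biv = int(round(truth.bivalent_frac * n_genes))
    idx = rng.permutation(n_genes)
    classes[idx[:n_hk]] = "housekeeping"
    classes[idx[n_hk : n_hk + n_biv]] = "bivalent"
    return pd.Series(classes, index=genes)


def gen_signal_expression(
    truth: SyntheticTruth,
    n_genes: int = 2000,
    contexts: Sequence[str] = ("c0",),
    enhancers_per_gene: int | str = 1,
    context_sd: float = 0.5,
    seed: int | None = None,
) -> dict[str, SimulatedContext]:
    """Generate per-context region signal and expression from the true model.

    Per gene, a latent mark profile is drawn from a multivariate normal
    with the truth's mark covariance; housekeeping genes reuse it in every
    context, background genes add an independent per-context deviation,
    and bivalent-like genes add a planted monotone activation trend along
    the context order (gaining activating marks, losing H3K27me3).
    Expression follows ``y = b0 + x.beta + N(0, sigma)`` with
    ``FPKM = max(2^y - 0.1, 0)``; stored signal is ``max(2^x - 0.1, 0)``
    so the model-side log transform recovers x.  When ``sigma`` is unset
    it is chosen per context so the theoretical model-vs-truth correlation
    ``sqrt(Var(x.beta) / (Var(x.beta) + sigma^2))`` equals ``r_star``.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    k = len(truth.marks)
    beta = truth.beta_vector
    cov = truth.covariance()
    chol = np.linalg.cholesky(cov)
    classes = _gene_classes(n_genes, truth, rng)
    genes = list(classes.index)

    latent = truth.mark_mean + rng.standard_normal((n_genes, k)) @ chol.T
    # activation direction: gain activating marks, lose H3K27me3
    direction = np.zeros(k)
    for mark, w in (("H3K27ac", 0.6), ("H3K4me3", 0.4), ("H3K36me3", 0.5), ("H3K27me3", -0.7)):
        if mark in truth.marks:
            direction[truth.marks.index(mark)] = w
    slopes = rng.uniform(*truth.trend_slope_range, size=n_genes)
    activated = rng.random(n_genes) < truth.activated_frac
    is_biv = (classes == "bivalent").to_numpy()
    is_hk = (classes == "housekeeping").to_numpy()

    if enhancers_per_gene == "poisson":
        n_regions = 1 + rng.poisson(1.0, size=n_genes)
    else:
        n_regions = np.full(n_genes, int(enhancers_per_gene))

    out: dict[str, SimulatedContext] = {}
    for ci, context in enumerate(contexts):
        x = latent.copy()
        dev = rng.standard_normal((n_genes, k)) @ chol.T * context_sd
        x[~is_hk] += dev[~is_hk]
        trending = is_biv & activated
        x[trending] += np.outer(slopes[trending] * ci, direction)[: trending.sum()]
        sigma = truth.sigma
        signal_var = float(np.var(x @ beta))
        if sigma is None:
            sigma = float(np.sqrt(signal_var * (1.0 / truth.r_star**2 - 1.0)))
        y = truth.beta0 + x @ beta + rng.normal(0.0, sigma, size=n_genes)
        fpkm = np.clip(2.0**y - 0.1, 0.0, None)

        rows, row_ids, row_gene = [], [], []
        for g, gene in enumerate(genes):
            for e in range(n_regions[g]):
                rows.append(x[g])
                row_ids.append(f"E_{gene}_{e}")
                row_gene.append(gene)
        signal = pd.DataFrame(
            np.clip(2.0 ** np.array(rows) - 0.1, 0.0, None),
            index=pd.Index(row_ids, name="region_id"),
            columns=truth.marks,
        )
        associations = pd.DataFrame({"gene_id": row_gene, "enhancer_id": row_ids})
        out[context] = SimulatedContext(
            context=context,
            signal=signal,
            expression=pd.Series(fpkm, index=genes, name="FPKM"),
            associations=associations,
            sigma=float(sigma),
            gene_classes=classes,
        )
    return out


# ---------------------------------------------------------------------------
# biased multi-sample tables


def smooth_bias(amplitude: float, phase: float = 0.0, cycles: float = 1.0) -> Callable:
    """A smooth bounded bias g(A) = amplitude * sin(2*pi*cycles*u + phase)
    where u rescales A onto [0, 1] over the observed range."""

    def g(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a, dtype=float)
        lo, hi = a.min(), a.max()
        u = (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)
        return amplitude * np.sin(2 * np.pi * cycles * u + phase)

    return g


def gen_biased_samples(
    base: pd.Series | np.ndarray,
    bias_funcs: Sequence[Callable | float],
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Multi-sample table ``value_s = base * 2^(g_s(A)) * 2^(N(0, noise))``
    with A = log2(base).  ``bias_funcs`` entries are callables of A in
    log2 units, or constants."""
    rng = np.random.default_rng(seed)
    base = pd.Series(base)
    if np.any(base.to_numpy() <= 0):
        raise ValueError("base intensities must be strictly positive")
    a = np.log2(base.to_numpy(dtype=float))
    if sample_names is None:
        sample_names = [f"s{i + 1}" for i in range(len(bias_funcs))]
    data = {}
    for name, g in zip(sample_names, bias_funcs):
        shift = g(a) if callable(g) else float(g) * np.ones_like(a)
        noise = rng.normal(0.0, noise_sd, size=len(a)) if noise_sd > 0 else 0.0
        data[name] = base.to_numpy() * 2.0 ** (shift + noise)
    return pd.DataFrame(data, index=base.index)


def gen_expression_trajectories(
    n_genes: int = 3000,
    n_samples: int = 5,
    truth: SyntheticTruth | None = None,
    sample_bias: Sequence[float] | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-context expression with housekeeping-like and bivalent-like
    trajectories plus global per-sample biases.

    Housekeeping and background genes keep a constant true mean across
    samples; among bivalent-like genes, the activated fraction gains
    expression monotonically along the sample order with a planted per-gene
    slope (log2 per step).  Every sample is multiplied by a global bias
    ``2^b_s``.  Returns (table, info) where ``info`` holds per-gene class,
    activation flag and planted slope.
    """
    truth = truth or SyntheticTruth(seed=seed)
    rng = np.random.default_rng(seed)
    classes = _gene_classes(n_genes, truth, rng)
    genes = list(classes.index)
    base = rng.normal(3.0, 1.5, size=n_genes)  # log2 baseline expression
    is_biv = (classes == "bivalent").to_numpy()
    base[is_biv] -= 2.0  # bivalent genes start repressed
    activated = is_biv & (rng.random(n_genes) < truth.activated_frac)
    slopes = np.where(activated, rng.uniform(*truth.trend_slope_range, size=n_genes), 0.0)
    if sample_bias is None:
        sample_bias = truth.bias_amplitude * np.linspace(-0.5, 0.5, n_samples)
    data = {}
    for s in range(n_samples):
        logs = base + slopes * s + sample_bias[s] + rng.normal(0, noise_sd, n_genes)
        data[f"t{s}"] = 2.0**logs
    table = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    info = pd.DataFrame(
        {
            "gene_class": classes,
            "activated": activated,
            "slope": slopes,
            "bias_free_mean": base,
        }
    )
    return table, info


# ---------------------------------------------------------------------------
# read-level mode and bundle writing


def gen_reads(
    regions: Sequence[GenomicInterval],
    intensities: Sequence[float],
    library_size: int,
    genome: Mapping[str, int],
    read_length: int = 50,
    background_reads: int = 0,
    seed: int = 0,
) -> list[GenomicInterval]:
    """Poisson read counts per region at the expected mean-per-bp intensity
    (the inverse of the quantification formula), plus optional uniform
    background reads."""
    rng = np.random.default_rng(seed)
    reads: list[GenomicInterval] = []
    for region, value in zip(regions, intensities):
        lam = value * region.length * library_size / 1e6
        n = rng.poisson(lam)
        if n == 0:
            continue
        starts = rng.integers(region.start, max(region.start + 1, region.end - read_length), size=n)
        for s in starts:
            reads.append(GenomicInterval(region.chrom, int(s), int(s) + read_length))
    chroms = sorted(genome)
    for _ in range(background_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, genome[chrom] - read_length))
        reads.append(GenomicInterval(chrom, s, s + read_length))
    return sorted(reads, key=lambda r: (r.chrom, r.start))


PRESETS = {
    "small": {"contexts": ("ESC",)},
    "differentiation": {"contexts": ("ESC", "MES", "CP", "CM")},
    "loess-stress": {"contexts": ("ESC", "MES", "CM")},
}


def write_bundle(outdir: str | Path, preset: str = "small", seed: int = 0) -> dict:
    """Write a complete, internally consistent input bundle.

    The segmentation is constructed so group-merging recovers the planted
    candidate regions; TSS/p300/contacts reproduce the planted classes and
    associations; signal and expression follow the true linear model; a
    small read-level set exercises quantification.  Returns a manifest of
    written paths.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    contexts = PRESETS[preset]["contexts"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = SyntheticTruth(seed=seed)

    world = gen_regions_and_interactions(truth, seed=seed)
    track = segmentation_from_candidates(world.candidates, world.genome)

    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in sorted(world.genome):
            fh.write(f"{chrom}\t{world.genome[chrom]}\n")
    write_bed([s.interval for s in track], outdir / "segmentation.bed")
    write_tss_table(world.tss, outdir / "tss.tsv")
    write_bed(world.p300, outdir / "p300.bed")
    write_bed(world.gene_bodies, outdir / "gene_bodies.bed")
    write_bedpe(world.interactions, outdir / "interactions.bedpe")
    write_candidates(world.candidates, outdir / "candidates.bed")
    write_regions(world.regions, outdir / "regions_truth.bed")
    world.gene_map.to_csv(outdir / "gene_map.tsv", sep="\t", index=False)
    world.associations.to_csv(outdir / "associations_truth.tsv", sep="\t", index=False)

    # model-scale signal/expression per context on synthetic gene ids
    sims = gen_signal_expression(
        truth, n_genes=600, contexts=contexts, seed=seed + 1
    )
    (outdir / "expression").mkdir(exist_ok=True)
    (outdir / "signal").mkdir(exist_ok=True)
    for context, sim in sims.items():
        sim.expression.rename_axis("gene_id").to_csv(
            outdir / "expression" / f"{context}.tsv", sep="\t"
        )
        sim.signal.to_csv(outdir / "signal" / f"{context}.tsv", sep="\t")
    sims[contexts[0]].associations.to_csv(
        outdir / "gene_enhancer_links.tsv", sep="\t", index=False
    )

    # read-level samples for two marks over the planted regions
    (outdir / "reads").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed + 2)
    library_sizes = {}
    region_ivs = [r.interval for r in world.regions]
    for mark in ("H3K4me3", "H3K27me3"):
        library = 200_000
        intensities = rng.uniform(0.5, 5.0, size=len(region_ivs))
        reads = gen_reads(
            region_ivs,
            intensities,
            library,
            world.genome,
            background_reads=2000,
            seed=int(rng.integers(2**31)),
        )
        write_bed(reads, outdir / "reads" / f"{mark}.bed")
        library_sizes[mark] = library
    with open(outdir / "library_sizes.json", "w") as fh:
        json.dump(library_sizes, fh, indent=2)
    truth.to_json(outdir / "truth.json")

    return {"outdir": str(outdir), "preset": preset, "seed": seed, "contexts": list(contexts)}
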