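"""State-matched enhancer-promoter-gene association from chromatin contacts.

Enhancers are linked to genes through promoters of the *same* chromatin
category (active enhancer with active promoter, poised enhancer with
bivalent promoter) when the two regions fall on the two anchors of the
same significant contact, or — in the distance variant — when they lie
within a fixed genomic distance.  The module also provides the one-sided
exact binomial test used to show that poised enhancers contact bivalent
promoters more often than expected by chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .classify import RegulatoryRegion
from .intervals import Interaction, distance, overlap_join

__all__ = [
    "EnrichmentTest",
    "filter_interactions",
    "link_by_interactions",
    "link_by_distance",
    "binomial_enrichment",
    "count_enhancer_promoter_contacts",
    "marginal_null_probability",
]

ASSOCIATION_COLUMNS = ["enhancer_id", "promoter_id", "gene_id", "class_pair", "provenance"]

_MATCH = {"AE": "AP", "PE": "BP"}


@dataclass(frozen=True)
class EnrichmentTest:
    """One-sided exact binomial test of contact-class enrichment."""

    k: int
    n: int
    p0: float
    p_value: float

    @property
    def observed_prob(self) -> float:
        return self.k / self.n


def filter_interactions(
    interactions: Sequence[Interaction],
    mode: str = "top",
    fdr_max: float = 0.0,
    lnp_max: float = -100.0,
) -> list[Interaction]:
    """Keep the caller-significant set (``mode="all"``) or only the top
    contacts with ``fdr <= fdr_max`` and ``ln_p <= lnp_max`` (``mode="top"``)."""
    if mode == "all":
        return list(interactions)
    if mode != "top":
        raise ValueError(f"mode must be 'all' or 'top', got {mode!r}")
    return [it for it in interactions if it.fdr <= fdr_max and it.ln_p <= lnp_max]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=ASSOCIATION_COLUMNS)


def _finalize(rows: set[tuple[str, str, str, str, str]]) -> pd.DataFrame:
    if not rows:
        return _empty_table()
    frame = pd.DataFrame(sorted(rows), columns=ASSOCIATION_COLUMNS)
    return frame


def link_by_interactions(
    enhancers: Sequence[RegulatoryRegion],
    promoters: Sequence[RegulatoryRegion],
    gene_map: pd.DataFrame,
    interactions: Sequence[Interaction],
) -> pd.DataFrame:
    """Associate enhancers with promoters/genes through contact anchors.

    For every interaction, an association row (enhancer, promoter, gene) is
    emitted whenever an enhancer overlaps one anchor (>= 1 bp), a promoter
    of the matching category overlaps the other anchor, and the gene is a
    target of that promoter.  Both anchor orderings are tried; rows are
    deduplicated on (enhancer, promoter, gene).
    """
    genes_of = gene_map.groupby("promoter_id")["gene_id"].agg(list).to_dict()
    anchors1 = [it.anchor1 for it in interactions]
    anchors2 = [it.anchor2 for it in interactions]
    e_ivs = [e.interval for e in enhancers]
    p_ivs = [p.interval for p in promoters]

    # interaction index -> region indices overlapping each anchor
    e_on: list[dict[int, list[int]]] = [{}, {}]
    p_on: list[dict[int, list[int]]] = [{}, {}]
    for side, anchors in enumerate((anchors1, anchors2)):
        for ei, ii in overlap_join(e_ivs, anchors):
            e_on[side].setdefault(ii, []).append(ei)
        for pi, ii in overlap_join(p_ivs, anchors):
            p_on[side].setdefault(ii, []).append(pi)

    rows: set[tuple[str, str, str, str, str]] = set()
    for ii in range(len(interactions)):
        for e_side, p_side in ((0, 1), (1, 0)):
            for ei in e_on[e_side].get(ii, ()):
                enh = enhancers[ei]
                target = _MATCH[enh.region_class]
                for pi in p_on[p_side].get(ii, ()):
                    prom = promoters[pi]
                    if prom.region_class != target:
                        continue
                    pair = f"{enh.region_class}-{prom.region_class}"
                    for gene in genes_of.get(prom.id, ()):
                        rows.add((enh.id, prom.id, gene, pair, "hic"))
    return _finalize(rows)


def link_by_distance(
    enhancers: Sequence[RegulatoryRegion],
    promoters: Sequence[RegulatoryRegion],
    gene_map: pd.DataFrame,
    max_gap: int = 1_000_000,
) -> pd.DataFrame:
    """Associate same-category enhancer-promoter pairs closer than
    ``max_gap`` bp (strict) on the same chromosome."""
    genes_of = gene_map.groupby("promoter_id")["gene_id"].agg(list).to_dict()
    rows: set[tuple[str, str, str, str, str]] = set()
    for enh in enhancers:
        target = _MATCH[enh.region_class]
        for prom in promoters:
            if prom.region_class != target:
                continue
            d = distance(enh.interval, prom.interval)
            if d is None or d >= max_gap:
                continue
            pair = f"{enh.region_class}-{prom.region_class}"
            for gene in genes_of.get(prom.id, ()):
                rows.add((enh.id, prom.id, gene, pair, "distance"))
    return _finalize(rows)


def binomial_enrichment(k: int, n: int, p0: float) -> EnrichmentTest:
    """Exact one-sided (greater) binomial test.

    ``p_value = sum_{i=k..n} C(n, i) p0^i (1 - p0)^(n - i)``.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"require 0 <= k <= n, n >= 1; got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    p_value = float(stats.binom.sf(k - 1, n, p0))
    return EnrichmentTest(k=int(k), n=int(n), p0=float(p0), p_value=p_value)


def _contact_triples(
    enhancers: Sequence[RegulatoryRegion],
    promoters: Sequence[RegulatoryRegion],
    interactions: Sequence[Interaction],
) -> set[tuple[int, str, str]]:
    """Deduplicated (interaction index, enhancer id, promoter id) triples
    where the enhancer overlaps one anchor and the promoter the other."""
    anchors1 = [it.anchor1 for it in interactions]
    anchors2 = [it.anchor2 for it in interactions]
    e_ivs = [e.interval for e in enhancers]
    p_ivs = [p.interval for p in promoters]
    e_on: list[dict[int, list[int]]] = [{}, {}]
    p_on: list[dict[int, list[int]]] = [{}, {}]
    for side, anchors in enumerate((anchors1, anchors2)):
        for ei, ii in overlap_join(e_ivs, anchors):
            e_on[side].setdefault(ii, []).append(ei)
        for pi, ii in overlap_join(p_ivs, anchors):
            p_on[side].setdefault(ii, []).append(pi)
    triples: set[tuple[int, str, str]] = set()
    for ii in range(len(interactions)):
        for e_side, p_side in ((0, 1), (1, 0)):
            for ei in e_on[e_side].get(ii, ()):
                for pi in p_on[p_side].get(ii, ()):
                    triples.add((ii, enhancers[ei].id, promoters[pi].id))
    return triples


def count_enhancer_promoter_contacts(
    enhancers: Sequence[RegulatoryRegion],
    promoters: Sequence[RegulatoryRegion],
    interactions: Sequence[Interaction],
    target_class: str | None = None,
) -> tuple[int, int]:
    """(k, n) for the contact enrichment test of one enhancer class.

    ``n`` counts deduplicated (interaction, enhancer, promoter) triples in
    which an enhancer of the class under test overlaps one anchor and any
    promoter overlaps the other; ``k`` counts those whose promoter carries
    the target class (default: the state-matched partner, BP for PE).
    Returns ``(0, 0)`` when no such triple exists (test undefined).
    """
    classes = {e.region_class for e in enhancers}
    if len(classes) != 1:
        raise ValueError("enhancers must all carry the same class under test")
    if target_class is None:
        target_class = _MATCH[classes.pop()]
    prom_class = {p.id: p.region_class for p in promoters}
    triples = _contact_triples(enhancers, promoters, interactions)
    n = len(triples)
    k = sum(1 for _, _, pid in triples if prom_class[pid] == target_class)
    return k, n


def marginal_null_probability(
    enhancers: Sequence[RegulatoryRegion],
    promoters: Sequence[RegulatoryRegion],
    interactions: Sequence[Interaction],
    target_class: str,
) -> float:
    """Null probability for the enrichment test: the marginal frequency of
    the target promoter class among promoter-overlapping anchor instances
    across all enhancer-anchored contacts (both enhancer classes pooled).

    The choice of null is an explicit input to :func:`binomial_enrichment`,
    so alternatives can be substituted.
    """
    prom_class = {p.id: p.region_class for p in promoters}
    triples = _contact_triples(enhancers, promoters, interactions)
    if not triples:
        raise ValueError("no enhancer-promoter contacts; null probability undefined")
    k = sum(1 for _, _, pid in triples if prom_class[pid] == target_class)
    return k / len(triples)
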