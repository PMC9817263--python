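"""Marker-based bin quality: completeness, contamination, score, splitting.

Quality is computed per domain marker set with a simplified per-gene
model: completeness is the fraction of the set's markers present at
least once in the bin, contamination is the surplus copy count
normalized by the set size, and the bin score is
100 × (completeness − 3 × contamination). A bin is high quality when
score > 10, contamination < 15%, and completeness > 50% (all strict).
Bins that are both highly contaminated (≥ 50%) and reasonably complete
(≥ 70%) are split by re-estimating a sub-bin count and re-clustering
their rows of the combined feature matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ensemblebin.clustering import Binning, partial_seed_kmeans, select_bin_number
from ensemblebin.contig_io import MarkerHitTable
from ensemblebin.features import FeatureSet
from ensemblebin.markers import SeedPlan, candidate_bin_numbers, estimate_initial_bin_number

logger = logging.getLogger(__name__)

SCORE_THRESHOLD = 10.0
CONTAMINATION_THRESHOLD = 0.15
COMPLETENESS_THRESHOLD = 0.5
SPLIT_CONTAMINATION = 0.5
SPLIT_COMPLETENESS = 0.7


@dataclass(frozen=True)
class DomainMarkerSet:
    """A named set of single-copy marker genes expected once per genome."""

    name: str
    marker_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.marker_ids:
            raise ValueError("domain marker set must be non-empty")

    @property
    def size(self) -> int:
        return len(self.marker_ids)


@dataclass(frozen=True)
class BinQuality:
    completeness: float
    contamination: float
    score: float
    domain: str

    @classmethod
    def from_counts(cls, completeness: float, contamination: float, domain: str) -> "BinQuality":
        return cls(
            completeness=completeness,
            contamination=contamination,
            score=100.0 * (completeness - 3.0 * contamination),
            domain=domain,
        )


def default_domains(hits: MarkerHitTable) -> list[DomainMarkerSet]:
    """A single universal marker set covering every marker in the table."""
    markers = frozenset(hits.marker_ids)
    if not markers:
        raise ValueError("marker table has no markers")
    return [DomainMarkerSet(name=hits.domain or "universal", marker_ids=markers)]


def assess_bin(
    contig_ids: set[str],
    hits: MarkerHitTable,
    domains: list[DomainMarkerSet],
) -> BinQuality:
    """Best-scoring per-domain quality of one bin.

    Per domain: completeness = fraction of the set's markers present in
    the bin; contamination = sum over markers of surplus copies (total
    copies − 1, floored at 0) divided by the set size.
    """
    if not domains:
        raise ValueError("at least one domain marker set is required")
    best: BinQuality | None = None
    for domain in domains:
        present = 0
        surplus = 0
        for marker in domain.marker_ids:
            copies = sum(
                count
                for contig, count in hits.hits.get(marker, {}).items()
                if contig in contig_ids
            )
            if copies >= 1:
                present += 1
                surplus += copies - 1
        quality = BinQuality.from_counts(
            completeness=present / domain.size,
            contamination=surplus / domain.size,
            domain=domain.name,
        )
        if best is None or quality.score > best.score:
            best = quality
    return best


def is_high_quality(q: BinQuality) -> bool:
    """Strict thresholds: score > 10, contamination < 0.15, completeness > 0.5."""
    return (
        q.score > SCORE_THRESHOLD
        and q.contamination < CONTAMINATION_THRESHOLD
        and q.completeness > COMPLETENESS_THRESHOLD
    )


def _estimate_sub_bins(
    bin_contigs: set[str],
    features_sub: FeatureSet,
    hits_sub: MarkerHitTable,
    rng: np.random.Generator,
) -> int:
    k0 = estimate_initial_bin_number(hits_sub)
    n = len(features_sub.contig_ids)
    candidates = [k for k in candidate_bin_numbers(k0, n) if k < n]
    if not candidates:
        return min(max(2, k0), n - 1)
    if len(candidates) == 1:
        return candidates[0]
    plan = SeedPlan(
        k0=candidates[0],
        candidate_ks=candidates,
        seed_markers=("", "", ""),
        seed_contigs={},
    )
    return select_bin_number(features_sub, plan, rng)


def split_contaminated_bins(
    binning: Binning,
    features: FeatureSet,
    hits: MarkerHitTable,
    domains: list[DomainMarkerSet],
    rng: np.random.Generator,
) -> Binning:
    """Split every bin with contamination >= 50% and completeness >= 70%.

    The sub-bin count comes from the bin-number procedure restricted to
    the bin's contigs and marker hits; sub-bins are produced by plain
    weighted k-means++ on the bin's rows of X_combo. Other bins pass
    through untouched; membership is conserved.
    """
    row_of = features.row_index()
    assignment: dict[str, str] = {}
    for bin_id, members in sorted(binning.bins.items()):
        quality = assess_bin(members, hits, domains)
        do_split = (
            quality.contamination >= SPLIT_CONTAMINATION
            and quality.completeness >= SPLIT_COMPLETENESS
        )
        if not do_split:
            for contig in members:
                assignment[contig] = bin_id
            continue
        if len(members) < 2:
            logger.warning(
                "bin %s qualifies for splitting but has < 2 contigs; left as is",
                bin_id,
            )
            for contig in members:
                assignment[contig] = bin_id
            continue
        rows = np.array(sorted(row_of[c] for c in members))
        sub_features = features.subset(rows)
        hits_sub = hits.restricted_to(members)
        if hits_sub.is_empty():
            for contig in members:
                assignment[contig] = bin_id
            continue
        k_sub = _estimate_sub_bins(members, sub_features, hits_sub, rng)
        k_sub = max(2, min(k_sub, len(members)))
        sub = partial_seed_kmeans(
            sub_features.X_combo,
            sub_features.lengths,
            k_sub,
            [],
            rng,
            sub_features.contig_ids,
        )
        for contig, sub_bin in sub.assignment.items():
            assignment[contig] = f"{bin_id}.{sub_bin}"
        logger.info("split bin %s into %d sub-bins", bin_id, sub.n_bins)
    return Binning(assignment=assignment, provenance=dict(binning.provenance))
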