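"""Ground-truth assessment of a predicted binning.

Per-bin purity/completeness over base pairs, quality-tier counts at the
usual completeness/contamination thresholds, and a base-pair-weighted
adjusted Rand index over the assigned contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ensemblebin.clustering import Binning
from ensemblebin.synthetic import GroundTruth

#: (min completeness, max contamination) for the six reported tiers
QUALITY_TIERS = (
    (0.5, 0.10),
    (0.7, 0.10),
    (0.9, 0.10),
    (0.5, 0.05),
    (0.7, 0.05),
    (0.9, 0.05),
)


@dataclass(frozen=True)
class BinAssessment:
    bin_id: str
    mapped_genome: str
    purity: float
    completeness: float
    bin_bp: int

    @property
    def contamination(self) -> float:
        return 1.0 - self.purity


def assess_bins(
    pred: Binning,
    truth: GroundTruth,
    lengths: dict[str, int],
) -> list[BinAssessment]:
    """Map each bin to its dominant genome by bp overlap; compute purity
    (overlap / bin bp) and completeness (overlap / genome bp)."""
    assessments: list[BinAssessment] = []
    for bin_id in sorted(pred.bins):
        members = pred.bins[bin_id]
        overlap: dict[str, int] = {}
        bin_bp = 0
        for contig in members:
            if contig not in truth.contig_to_genome:
                raise ValueError(f"predicted contig {contig!r} missing from truth")
            genome = truth.contig_to_genome[contig]
            bp = lengths[contig]
            overlap[genome] = overlap.get(genome, 0) + bp
            bin_bp += bp
        mapped = min(overlap, key=lambda g: (-overlap[g], g))
        assessments.append(
            BinAssessment(
                bin_id=bin_id,
                mapped_genome=mapped,
                purity=overlap[mapped] / bin_bp,
                completeness=overlap[mapped] / truth.genome_bp[mapped],
                bin_bp=bin_bp,
            )
        )
    return assessments


def count_quality_tiers(assessments: list[BinAssessment]) -> dict[str, int]:
    """Bin counts per (completeness, contamination) tier; strict inequalities."""
    counts: dict[str, int] = {}
    for comp_min, cont_max in QUALITY_TIERS:
        key = f">{comp_min:.0%} comp <{cont_max:.0%} cont"
        counts[key] = sum(
            1
            for a in assessments
            if a.completeness > comp_min and a.contamination < cont_max
        )
    return counts


def _pair_sum(values) -> float:
    return sum(v * (v - 1) / 2.0 for v in values)


def adjusted_rand_index_bp(
    pred: Binning,
    truth: GroundTruth,
    lengths: dict[str, int],
) -> tuple[float, float]:
    """(ARI over bp-weighted contingency, fraction of assigned bp).

    Each assigned contig contributes its length in bp as multiplicity;
    unassigned contigs are excluded from the ARI but counted in the
    assigned-bp denominator.
    """
    assigned = sorted(pred.assignment)
    if not assigned:
        raise ValueError("no assigned contigs: ARI undefined")
    table: dict[tuple[str, str], int] = {}
    for contig in assigned:
        if contig not in truth.contig_to_genome:
            raise ValueError(f"predicted contig {contig!r} missing from truth")
        key = (pred.assignment[contig], truth.contig_to_genome[contig])
        table[key] = table.get(key, 0) + lengths[contig]
    row_sums: dict[str, int] = {}
    col_sums: dict[str, int] = {}
    for (bin_id, genome), bp in table.items():
        row_sums[bin_id] = row_sums.get(bin_id, 0) + bp
        col_sums[genome] = col_sums.get(genome, 0) + bp
    n = sum(table.values())
    sum_ij = _pair_sum(table.values())
    sum_a = _pair_sum(row_sums.values())
    sum_b = _pair_sum(col_sums.values())
    total_pairs = n * (n - 1) / 2.0
    expected = sum_a * sum_b / total_pairs if total_pairs else 0.0
    max_index = (sum_a + sum_b) / 2.0
    denom = max_index - expected
    ari = 1.0 if denom == 0 else (sum_ij - expected) / denom
    assigned_bp = sum(lengths[c] for c in assigned)
    total_bp = sum(lengths[c] for c in truth.contig_to_genome)
    return float(ari), assigned_bp / total_bp


def summarize(
    pred: Binning,
    truth: GroundTruth,
    lengths: dict[str, int],
) -> dict:
    """JSON-friendly evaluation summary (tiers, ARI, averages)."""
    assessments = assess_bins(pred, truth, lengths)
    out: dict = {"n_bins": len(assessments), "tiers": count_quality_tiers(assessments)}
    if pred.assignment:
        ari, frac = adjusted_rand_index_bp(pred, truth, lengths)
        out["ari_bp"] = ari
        out["assigned_bp_fraction"] = frac
    if assessments:
        out["mean_purity"] = float(np.mean([a.purity for a in assessments]))
        out["mean_completeness"] = float(
            np.mean([a.completeness for a in assessments])
        )
        bp = np.array([a.bin_bp for a in assessments], dtype=float)
        out["bp_weighted_mean_purity"] = float(
            np.average([a.purity for a in assessments], weights=bp)
        )
        out["bp_weighted_mean_completeness"] = float(
            np.average([a.completeness for a in assessments], weights=bp)
        )
    return out
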