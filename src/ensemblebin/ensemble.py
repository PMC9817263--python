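"""Two-stage ensemble integration of component binnings.

Stage 1 greedily dereplicates the four component binnings of each
feature track (select the highest-scoring high-quality bin, strip its
contigs from every remaining candidate, repeat). Stage 2 pools the three
stage-1 results with their pairwise and triple shared-contig refinements
and runs the same greedy selection over the pool. Also hosts the
end-to-end pipeline driver.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ensemblebin.bin_quality import (
    BinQuality,
    DomainMarkerSet,
    assess_bin,
    default_domains,
    is_high_quality,
    split_contaminated_bins,
)
from ensemblebin.clustering import (
    Binning,
    FEATURE_TRACKS,
    generate_component_binnings,
    select_bin_number,
    substream,
)
from ensemblebin.contig_io import (
    ContigRecord,
    MarkerHitTable,
    load_contigs,
    load_depth_table,
    load_marker_hits,
    write_binning,
)
from ensemblebin.features import build_feature_set
from ensemblebin.markers import build_seed_plan

logger = logging.getLogger(__name__)

#: Binning_refiner's published default minimum refined-bin size
DEFAULT_MIN_REFINED_BP = 524_288


@dataclass
class EnsembleConfig:
    min_refined_bp: int = DEFAULT_MIN_REFINED_BP
    hq_score: float = 10.0
    hq_cont: float = 0.15
    hq_comp: float = 0.5
    stage2_combinations: str = "pairs_and_triple"  # or "ab_only"
    min_contig_length: int = 1000
    length_weights: bool = True
    tie_break_bp: bool = True

    def __post_init__(self) -> None:
        if self.min_refined_bp < 0:
            raise ValueError("min_refined_bp must be >= 0")
        if self.stage2_combinations not in ("pairs_and_triple", "ab_only"):
            raise ValueError(
                f"unknown stage2_combinations {self.stage2_combinations!r}"
            )

    def passes(self, q: BinQuality) -> bool:
        return (
            q.score > self.hq_score
            and q.contamination < self.hq_cont
            and q.completeness > self.hq_comp
        )


@dataclass
class CandidateBin:
    contig_ids: set[str]
    source: str
    quality: BinQuality | None = None


def _total_bp(contigs: set[str], lengths: dict[str, int] | None) -> int:
    if lengths is None:
        return len(contigs)
    return sum(lengths.get(c, 0) for c in contigs)


def greedy_select(
    candidate_binnings: list[Binning],
    hits: MarkerHitTable,
    domains: list[DomainMarkerSet],
    cfg: EnsembleConfig,
    contig_lengths: dict[str, int] | None = None,
    selection_log: list | None = None,
) -> Binning:
    """Iteratively pick the best high-quality bin and strip its contigs.

    Ties break by larger total bp, then lexicographically smaller source
    string. Output bins are disjoint and each one passed the
    high-quality predicate at its moment of selection.
    """
    pool: list[CandidateBin] = []
    for b_idx, binning in enumerate(candidate_binnings):
        src_base = str(binning.provenance.get("source", b_idx))
        for bin_id in sorted(binning.bins):
            members = set(binning.bins[bin_id])
            pool.append(CandidateBin(contig_ids=members, source=f"{src_base}/{bin_id}"))
    for cand in pool:
        cand.quality = assess_bin(cand.contig_ids, hits, domains)

    assignment: dict[str, str] = {}
    rank = 0
    while True:
        best: CandidateBin | None = None
        best_key = None
        for cand in pool:
            if not cand.contig_ids or not cfg.passes(cand.quality):
                continue
            key = (
                -cand.quality.score,
                -_total_bp(cand.contig_ids, contig_lengths),
                cand.source,
            )
            if best is None or key < best_key:
                best, best_key = cand, key
        if best is None:
            break
        rank += 1
        bin_name = f"bin.{rank}"
        for contig in best.contig_ids:
            assignment[contig] = bin_name
        if selection_log is not None:
            selection_log.append(
                {
                    "bin": bin_name,
                    "source": best.source,
                    "score": best.quality.score,
                    "completeness": best.quality.completeness,
                    "contamination": best.quality.contamination,
                    "n_contigs": len(best.contig_ids),
                }
            )
        removed = set(best.contig_ids)
        best.contig_ids = set()
        for cand in pool:
            if cand.contig_ids and cand.contig_ids & removed:
                cand.contig_ids -= removed
                if cand.contig_ids:
                    cand.quality = assess_bin(cand.contig_ids, hits, domains)
    return Binning(assignment=assignment)


def refine_intersection(
    binnings: list[Binning],
    min_refined_bp: int,
    contig_lengths: dict[str, int] | None,
) -> Binning:
    """Group contigs by their joint label tuple across all input binnings.

    Only contigs assigned in every input survive; each distinct label
    tuple becomes a refined bin iff its total bp reaches
    ``min_refined_bp``.
    """
    if len(binnings) < 2:
        raise ValueError("refinement needs at least two binnings")
    groups: dict[tuple, set[str]] = {}
    common = set(binnings[0].assignment)
    for binning in binnings[1:]:
        common &= set(binning.assignment)
    for contig in common:
        key = tuple(binning.assignment[contig] for binning in binnings)
        groups.setdefault(key, set()).add(contig)
    assignment: dict[str, str] = {}
    for idx, key in enumerate(sorted(groups), start=1):
        members = groups[key]
        if _total_bp(members, contig_lengths) >= min_refined_bp:
            for contig in members:
                assignment[contig] = f"refined.{idx}"
    return Binning(assignment=assignment)


def stage1(
    component_binnings: list[Binning],
    hits: MarkerHitTable,
    domains: list[DomainMarkerSet],
    cfg: EnsembleConfig,
    contig_lengths: dict[str, int] | None = None,
    selection_log: list | None = None,
) -> Binning:
    """Greedy dereplication of one feature track's component binnings."""
    return greedy_select(
        component_binnings, hits, domains, cfg, contig_lengths, selection_log
    )


def stage2(
    metabin_a: Binning,
    metabin_b: Binning,
    metabin_c: Binning,
    hits: MarkerHitTable,
    domains: list[DomainMarkerSet],
    cfg: EnsembleConfig,
    contig_lengths: dict[str, int] | None = None,
    selection_log: list | None = None,
) -> Binning:
    """Pool the stage-1 results with their refinements; greedy-select.

    In ``pairs_and_triple`` mode the pool is {A, B, C} plus the three
    pairwise refinements and the triple refinement; ``ab_only`` drops C
    and everything derived from it.
    """
    def tagged(binning: Binning, tag: str) -> Binning:
        out = Binning(assignment=dict(binning.assignment), provenance=dict(binning.provenance))
        out.provenance["source"] = tag
        return out

    a, b, c = metabin_a, metabin_b, metabin_c
    pool = [tagged(a, "A"), tagged(b, "B")]
    pairs = [((a, b), "AB")]
    if cfg.stage2_combinations == "pairs_and_triple":
        pool.append(tagged(c, "C"))
        pairs += [((a, c), "AC"), ((b, c), "BC")]
    for (x, y), tag in pairs:
        if x.assignment and y.assignment:
            pool.append(
                tagged(refine_intersection([x, y], cfg.min_refined_bp, contig_lengths), tag)
            )
    if cfg.stage2_combinations == "pairs_and_triple" and all(
        m.assignment for m in (a, b, c)
    ):
        pool.append(
            tagged(refine_intersection([a, b, c], cfg.min_refined_bp, contig_lengths), "ABC")
        )
    return greedy_select(pool, hits, domains, cfg, contig_lengths, selection_log)


def run_pipeline(
    contigs_path,
    depth_path,
    markers_path,
    out_dir,
    cfg: EnsembleConfig | None = None,
    master_seed: int = 0,
    depth_dialect: str = "plain",
    gene_lengths_path=None,
    domains: list[DomainMarkerSet] | None = None,
) -> tuple[Binning, dict]:
    """End-to-end run: load → features → seeding → components → split →
    stage 1 × 3 → stage 2 → write. Returns the final binning and the
    JSON-serializable run report."""
    cfg = cfg or EnsembleConfig()
    contigs = load_contigs(contigs_path, cfg.min_contig_length)
    if not contigs:
        raise ValueError("no contigs survive the length filter")
    coverage = load_depth_table(depth_path, contigs, dialect=depth_dialect)
    hits = load_marker_hits(markers_path, contigs, gene_lengths_path)
    if hits.is_empty():
        raise ValueError("marker table is empty: cannot seed or score bins")
    return run_pipeline_from_objects(
        contigs, coverage, hits, out_dir, cfg, master_seed, domains
    )


def run_pipeline_from_objects(
    contigs: list[ContigRecord],
    coverage,
    hits: MarkerHitTable,
    out_dir,
    cfg: EnsembleConfig | None = None,
    master_seed: int = 0,
    domains: list[DomainMarkerSet] | None = None,
) -> tuple[Binning, dict]:
    """Pipeline core operating on already-loaded objects."""
    cfg = cfg or EnsembleConfig()
    if domains is None:
        domains = default_domains(hits)
    features = build_feature_set(contigs, coverage)
    lengths = {c.id: c.length for c in contigs}
    plan = build_seed_plan(hits, len(contigs))
    logger.info("k0=%d candidates=%s", plan.k0, plan.candidate_ks)
    K = select_bin_number(features, plan, substream(master_seed, "binnum"))
    logger.info("selected bin number K=%d", K)
    components = generate_component_binnings(
        features, plan, K, master_seed, length_weights=cfg.length_weights
    )
    split_components: list[Binning] = []
    for idx, component in enumerate(components):
        rng = substream(master_seed, f"split/{idx}")
        split_comp = split_contaminated_bins(component, features, hits, domains, rng)
        split_comp.provenance["source"] = "{feature}-{init}".format(
            feature=component.provenance.get("feature", "?"),
            init=component.provenance.get("init", "?"),
        )
        split_components.append(split_comp)

    report: dict = {
        "k0": plan.k0,
        "candidate_ks": plan.candidate_ks,
        "K": K,
        "seed_markers": list(plan.seed_markers),
        "n_contigs": len(contigs),
        "n_components": len(components),
        "component_bin_counts": [b.n_bins for b in split_components],
        "stage1": {},
        "stage2": [],
        "config": {
            "min_refined_bp": cfg.min_refined_bp,
            "stage2_combinations": cfg.stage2_combinations,
            "length_weights": cfg.length_weights,
            "min_contig_length": cfg.min_contig_length,
        },
        "master_seed": master_seed,
    }

    metabins: dict[str, Binning] = {}
    for track in FEATURE_TRACKS:
        track_components = [
            b for b in split_components
            if b.provenance.get("source", "").startswith(f"{track}-")
        ]
        log: list = []
        metabins[track] = stage1(track_components, hits, domains, cfg, lengths, log)
        report["stage1"][track] = {
            "n_bins": metabins[track].n_bins,
            "selections": log,
        }
        logger.info("stage1[%s]: %d bins", track, metabins[track].n_bins)

    final_log: list = []
    final = stage2(
        metabins["combo"], metabins["cov"], metabins["com"],
        hits, domains, cfg, lengths, final_log,
    )
    report["stage2"] = final_log
    report["n_final_bins"] = final.n_bins
    logger.info("final: %d bins over %d contigs", final.n_bins, len(final.assignment))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_binning(final, out_dir, contigs)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return final, report
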