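"""Bin-number estimation and seed-marker selection from marker hits.

The initial bin number is the ceiling of the third quartile (linear
interpolation) of the per-marker distinct-contig counts; candidate bin
numbers form a short arithmetic grid above it. Three seed markers — one
per quartile of the count distribution, ties broken toward the shortest
gene — provide fixed initial centers for the partial-seed runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ensemblebin.contig_io import MarkerHitTable


@dataclass
class SeedPlan:
    """Initial bin number, candidate grid, and the three quartile seed markers."""

    k0: int
    candidate_ks: list[int]
    seed_markers: tuple[str, str, str]  # Q1, Q2, Q3
    seed_contigs: dict[str, list[str]]

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if self.candidate_ks and self.candidate_ks[0] != self.k0:
            raise ValueError("candidate list must start at k0")
        if any(b <= a for a, b in zip(self.candidate_ks, self.candidate_ks[1:])):
            raise ValueError("candidate list must be strictly increasing")
        for marker, contigs in self.seed_contigs.items():
            if not contigs:
                raise ValueError(f"seed marker {marker!r} has no contigs")
            if len(set(contigs)) != len(contigs):
                raise ValueError(f"seed marker {marker!r} has duplicate contigs")


def estimate_initial_bin_number(hits: MarkerHitTable) -> int:
    """k0 = ceil of the third quartile of per-marker distinct-contig counts.

    Quartiles use linear interpolation over the ascending sorted counts
    (numpy's default / the R-7 convention).
    """
    counts = sorted(hits.contig_counts().values())
    if not counts:
        raise ValueError("cannot estimate bin number without marker hits")
    q3 = float(np.percentile(counts, 75, method="linear"))
    return max(1, math.ceil(q3))


def candidate_bin_numbers(k0: int, n_contigs: int) -> list[int]:
    """Arithmetic grid {k0 + i*s : i = 0..9}, s = max(1, ceil(k0/10)),
    truncated so every candidate <= n_contigs - 1."""
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    step = max(1, math.ceil(k0 / 10))
    grid = [k0 + i * step for i in range(10)]
    grid = [k for k in grid if k <= n_contigs - 1]
    return sorted(set(grid))


def choose_seed_markers(hits: MarkerHitTable) -> tuple[tuple[str, str, str], dict[str, list[str]]]:
    """Pick one seed marker per quartile of the distinct-contig counts.

    Each quartile target (linear interpolation, rounded to nearest
    integer) selects the marker whose count is closest to it; ties go to
    the smaller |count - target|, then the smaller gene_length, then the
    lexicographically smaller marker id. Returns the (Q1, Q2, Q3) marker
    ids and each winner's sorted distinct contig list.
    """
    counts = hits.contig_counts()
    if not counts:
        raise ValueError("no marker has any hit")
    values = sorted(counts.values())
    chosen: list[str] = []
    for pct in (25, 50, 75):
        target = round(float(np.percentile(values, pct, method="linear")))
        winner = min(
            counts,
            key=lambda m: (
                abs(counts[m] - target),
                hits.gene_length.get(m, 0),
                m,
            ),
        )
        chosen.append(winner)
    seed_contigs = {m: sorted(hits.hits[m]) for m in set(chosen)}
    return (chosen[0], chosen[1], chosen[2]), seed_contigs


def build_seed_plan(hits: MarkerHitTable, n_contigs: int) -> SeedPlan:
    """Full seeding plan: k0, candidate grid, and the quartile seed markers."""
    k0 = estimate_initial_bin_number(hits)
    candidates = candidate_bin_numbers(k0, n_contigs)
    if not candidates:
        candidates = [min(k0, max(1, n_contigs - 1))]
        candidates = sorted(set(candidates))
        k0 = candidates[0]
    markers_q, seed_contigs = choose_seed_markers(hits)
    return SeedPlan(
        k0=k0,
        candidate_ks=candidates,
        seed_markers=markers_q,
        seed_contigs=seed_contigs,
    )
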