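"""Desk-scale synthetic communities with known ground truth.

Each genome is an order-1 Markov chain whose transition rows are drawn
from a Dirichlet, giving a genome-specific tetramer signature. Genomes
are fragmented into lognormally sized contigs, per-sample abundances are
lognormal, and depth adds multiplicative lognormal noise. Exactly one
copy of each marker gene is planted per genome (optionally recorded on
two contigs to emulate fragmented genes). Everything is deterministic
under the spec's seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ensemblebin.clustering import Binning
from ensemblebin.contig_io import ContigRecord, CoverageTable, MarkerHitTable

_BASES = np.array(list("ACGT"))


@dataclass
class CommunitySpec:
    n_genomes: int = 20
    genome_length_bp: int = 200_000
    n_samples: int = 10
    contig_mean_bp: float = 8000.0
    contig_sigma: float = 0.5
    min_contig_length: int = 1000
    abundance_mu: float = 2.0
    abundance_sigma: float = 1.0
    dirichlet_alpha: float = 0.3
    n_markers: int = 40
    marker_fragmentation_prob: float = 0.0
    depth_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("need at least 2 genomes")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        for p in (self.marker_fragmentation_prob,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.genome_length_bp < self.min_contig_length:
            raise ValueError("genome shorter than the minimum contig length")


@dataclass
class GroundTruth:
    contig_to_genome: dict[str, str]
    genome_bp: dict[str, int]


@dataclass
class Community:
    """In-memory synthetic community: inputs plus ground truth."""

    contigs: list[ContigRecord]
    coverage: CoverageTable
    markers: MarkerHitTable
    truth: GroundTruth
    gene_lengths: dict[str, int] = field(default_factory=dict)


def _markov_genomes(spec: CommunitySpec, rng: np.random.Generator) -> list[str]:
    """All genomes advanced in lockstep — one uniform draw per genome per base."""
    g, length = spec.n_genomes, spec.genome_length_bp
    transitions = rng.dirichlet([spec.dirichlet_alpha] * 4, size=(g, 4))
    cumsum = np.cumsum(transitions, axis=2)
    states = rng.integers(0, 4, size=g)
    out = np.empty((g, length), dtype=np.int8)
    out[:, 0] = states
    uniforms = rng.random(size=(length - 1, g))
    rows = np.arange(g)
    for pos in range(1, length):
        cum = cumsum[rows, states]  # g x 4
        states = (uniforms[pos - 1][:, None] > cum).sum(axis=1)
        out[:, pos] = states
    return ["".join(_BASES[row]) for row in out]


def _fragment(genome_seq: str, spec: CommunitySpec, rng: np.random.Generator) -> list[str]:
    """Cut one genome into contigs with lognormal lengths; the remainder is
    merged into the last contig so nothing falls under the length filter."""
    sigma = spec.contig_sigma
    mu = np.log(spec.contig_mean_bp) - sigma**2 / 2
    pieces: list[str] = []
    pos = 0
    total = len(genome_seq)
    while pos < total:
        size = int(rng.lognormal(mu, sigma))
        size = max(size, spec.min_contig_length + 1)
        if total - (pos + size) <= spec.min_contig_length:
            size = total - pos
        pieces.append(genome_seq[pos : pos + size])
        pos += size
    return pieces


def generate_community(spec: CommunitySpec) -> Community:
    """Build the community in memory (contigs, depths, markers, truth)."""
    rng = np.random.default_rng(spec.seed)
    genomes = _markov_genomes(spec, rng)
    genome_ids = [f"g{g:03d}" for g in range(spec.n_genomes)]

    contigs: list[ContigRecord] = []
    contig_to_genome: dict[str, str] = {}
    genome_bp: dict[str, int] = {}
    contigs_of: dict[str, list[str]] = {}
    for gid, seq in zip(genome_ids, genomes):
        pieces = _fragment(seq, spec, rng)
        contigs_of[gid] = []
        genome_bp[gid] = 0
        for idx, piece in enumerate(pieces):
            cid = f"{gid}_c{idx:04d}"
            contigs.append(ContigRecord(id=cid, sequence=piece, length=len(piece)))
            contig_to_genome[cid] = gid
            contigs_of[gid].append(cid)
            genome_bp[gid] += len(piece)

    abundance = rng.lognormal(
        spec.abundance_mu, spec.abundance_sigma, size=(spec.n_genomes, spec.n_samples)
    )
    cv = spec.depth_noise_cv
    if cv > 0:
        noise_sigma = np.sqrt(np.log(1 + cv**2))
        noise = rng.lognormal(
            -noise_sigma**2 / 2, noise_sigma, size=(len(contigs), spec.n_samples)
        )
    else:
        noise = np.ones((len(contigs), spec.n_samples))
    genome_index = {gid: i for i, gid in enumerate(genome_ids)}
    depth = np.vstack(
        [abundance[genome_index[contig_to_genome[c.id]]] for c in contigs]
    ) * noise
    coverage = CoverageTable(
        contig_ids=[c.id for c in contigs],
        sample_ids=[f"s{j}" for j in range(spec.n_samples)],
        depth=depth,
    )

    marker_ids = [f"m{m:04d}" for m in range(spec.n_markers)]
    gene_lengths = {m: int(rng.integers(300, 3001)) for m in marker_ids}
    hits: dict[str, dict[str, int]] = {m: {} for m in marker_ids}
    for gid in genome_ids:
        pool = contigs_of[gid]
        for marker in marker_ids:
            host = pool[int(rng.integers(len(pool)))]
            hits[marker][host] = hits[marker].get(host, 0) + 1
            if spec.marker_fragmentation_prob > 0 and rng.random() < spec.marker_fragmentation_prob:
                if len(pool) > 1:
                    others = [c for c in pool if c != host]
                    second = others[int(rng.integers(len(others)))]
                    hits[marker][second] = hits[marker].get(second, 0) + 1
    markers = MarkerHitTable(
        marker_ids=marker_ids, gene_length=gene_lengths, hits=hits, domain="universal"
    )
    return Community(
        contigs=contigs,
        coverage=coverage,
        markers=markers,
        truth=GroundTruth(contig_to_genome=contig_to_genome, genome_bp=genome_bp),
        gene_lengths=gene_lengths,
    )


def simulate_community(spec: CommunitySpec, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the community as FASTA + TSVs; returns the file paths.

    Files: ``contigs.fa``, ``depth.tsv`` (plain dialect),
    ``markers.tsv``, ``gene_lengths.tsv``, ``truth.tsv``.
    """
    community = generate_community(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contigs": out_dir / "contigs.fa",
        "depth": out_dir / "depth.tsv",
        "markers": out_dir / "markers.tsv",
        "gene_lengths": out_dir / "gene_lengths.tsv",
        "truth": out_dir / "truth.tsv",
    }
    with open(paths["contigs"], "w", encoding="utf-8") as fh:
        for contig in community.contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, 80):
                fh.write(contig.sequence[i : i + 80] + "\n")
    with open(paths["depth"], "w", encoding="utf-8") as fh:
        fh.write("contig_id\t" + "\t".join(community.coverage.sample_ids) + "\n")
        for cid, row in zip(community.coverage.contig_ids, community.coverage.depth):
            fh.write(cid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(paths["markers"], "w", encoding="utf-8") as fh:
        fh.write("marker_id\tcontig_id\tcopy_count\n")
        for marker in community.markers.marker_ids:
            for contig, count in sorted(community.markers.hits[marker].items()):
                fh.write(f"{marker}\t{contig}\t{count}\n")
    with open(paths["gene_lengths"], "w", encoding="utf-8") as fh:
        fh.write("marker_id\tgene_length\n")
        for marker, length in sorted(community.gene_lengths.items()):
            fh.write(f"{marker}\t{length}\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("contig_id\tgenome_id\n")
        for contig in community.contigs:
            fh.write(f"{contig.id}\t{community.truth.contig_to_genome[contig.id]}\n")
    return paths


def make_merged_bin_fixture(spec: CommunitySpec) -> tuple[Binning, Community]:
    """Ground-truth binning whose first bin unites two genomes' contigs.

    Drives the contaminated-bin splitter: the merged bin has completeness
    1.0 and contamination 1.0 under the planted marker set.
    """
    community = generate_community(spec)
    genome_ids = sorted(community.truth.genome_bp)
    merged = set(genome_ids[:2])
    assignment: dict[str, str] = {}
    for contig in community.contigs:
        gid = community.truth.contig_to_genome[contig.id]
        assignment[contig.id] = "merged" if gid in merged else f"bin_{gid}"
    return Binning(assignment=assignment), community
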