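"""I/O for contigs, depth tables, marker-hit tables, and binning results.

All tabular formats are tab-delimited UTF-8 with a header row. The depth
table is accepted in two dialects: the ``jgi_summarize_bam_contig_depths``
layout (contigName/contigLen/totalAvgDepth plus alternating per-sample
depth and depth-var columns) and a plain matrix (contig_id column plus one
depth column per sample).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted in input sequences.
IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class ContigRecord:
    """A single assembled contig: the atomic unit of binning."""

    id: str
    sequence: str
    length: int

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if self.length != len(self.sequence):
            raise ValueError(
                f"contig {self.id!r}: length {self.length} != sequence length "
                f"{len(self.sequence)}"
            )
        if self.length < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")


@dataclass
class CoverageTable:
    """Per-contig mean read depth across samples, row-aligned to contigs."""

    contig_ids: list[str]
    sample_ids: list[str]
    depth: np.ndarray  # N x M, non-negative

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        n, m = self.depth.shape
        if n != len(self.contig_ids):
            raise ValueError("depth rows do not match contig_ids")
        if m != len(self.sample_ids):
            raise ValueError("depth columns do not match sample_ids")
        if m < 1:
            raise ValueError("coverage table needs at least one sample")
        if np.any(self.depth < 0):
            raise ValueError("negative depth values are not allowed")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class MarkerHitTable:
    """Which contigs carry which single-copy marker genes (with copy counts)."""

    marker_ids: list[str]
    gene_length: dict[str, int]
    hits: dict[str, dict[str, int]]
    domain: str = "universal"

    def __post_init__(self) -> None:
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        for marker, contigs in self.hits.items():
            for contig, count in contigs.items():
                if count < 1:
                    raise ValueError(
                        f"marker {marker!r} on contig {contig!r}: "
                        f"copy_count {count} < 1"
                    )

    def contig_counts(self) -> dict[str, int]:
        """Number of distinct contigs carrying each marker (only markers with hits)."""
        return {m: len(c) for m, c in self.hits.items() if c}

    def is_empty(self) -> bool:
        return not any(self.hits.values())

    def restricted_to(self, contig_ids: set[str]) -> "MarkerHitTable":
        """A copy whose hits only reference the given contigs."""
        hits = {
            m: {c: k for c, k in contigs.items() if c in contig_ids}
            for m, contigs in self.hits.items()
        }
        return MarkerHitTable(
            marker_ids=list(self.marker_ids),
            gene_length=dict(self.gene_length),
            hits=hits,
            domain=self.domain,
        )


def load_contigs(fasta_path: str | os.PathLike, min_contig_length: int = 1000) -> list[ContigRecord]:
    """Read contigs from FASTA, keeping records strictly longer than the cutoff.

    Sequences are uppercased; file order is preserved. Duplicate ids and
    non-IUPAC characters are hard errors; an empty file yields an empty
    list with a logged warning.
    """
    if min_contig_length < 0:
        raise ValueError("min_contig_length must be >= 0")
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"contig {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if len(seq) > min_contig_length:
            records.append(ContigRecord(id=rec.id, sequence=seq, length=len(seq)))
    if not seen:
        logger.warning("FASTA file %s contains no records", fasta_path)
    return records


def load_depth_table(
    path: str | os.PathLike,
    contigs: list[ContigRecord],
    dialect: str = "jgi",
) -> CoverageTable:
    """Read a depth table and align its rows to the given contig list.

    Rows for contigs absent from ``contigs`` (e.g. filtered short contigs)
    are dropped silently; a contig missing from the table is a hard error.
    """
    if dialect not in ("jgi", "plain"):
        raise ValueError(f"unknown depth-table dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=0)
    if dialect == "jgi":
        required = ["contigName", "contigLen", "totalAvgDepth"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"jgi depth table missing column {col!r}")
        value_cols = [c for c in df.columns if c not in required]
        # alternating <sample>.bam and <sample>.bam-var columns; keep depths
        sample_cols = [c for c in value_cols if not c.endswith("-var")]
        id_col = "contigName"
    else:
        id_col = df.columns[0]
        sample_cols = list(df.columns[1:])
    if not sample_cols:
        raise ValueError("depth table has no sample columns (M = 0)")
    df = df.set_index(id_col)
    wanted = [c.id for c in contigs]
    missing = [cid for cid in wanted if cid not in df.index]
    if missing:
        raise ValueError(
            f"depth table is missing {len(missing)} contig(s), "
            f"first: {missing[0]!r}"
        )
    depth = df.loc[wanted, sample_cols].to_numpy(dtype=float)
    if np.isnan(depth).any():
        raise ValueError("depth table contains NaN values")
    if np.any(depth < 0):
        raise ValueError("depth table contains negative values")
    return CoverageTable(contig_ids=wanted, sample_ids=sample_cols, depth=depth)


def load_marker_hits(
    path: str | os.PathLike,
    contigs: list[ContigRecord],
    gene_lengths_path: str | os.PathLike | None = None,
    domain: str = "universal",
) -> MarkerHitTable:
    """Read a marker-hit TSV (marker_id, contig_id, copy_count).

    Hits on contigs outside the universe (e.g. filtered short contigs) are
    ignored with a logged count. ``gene_lengths_path`` is an optional
    sidecar TSV (marker_id, gene_length); absent lengths default to 0 so
    tie-breaks fall through to the lexicographic marker id.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    for col in ("marker_id", "contig_id", "copy_count"):
        if col not in df.columns:
            raise ValueError(f"marker-hit table missing column {col!r}")
    if len(df) and (df["copy_count"] < 1).any():
        bad = df.loc[df["copy_count"] < 1].iloc[0]
        raise ValueError(
            f"copy_count < 1 for marker {bad['marker_id']!r} on contig "
            f"{bad['contig_id']!r}"
        )
    universe = {c.id for c in contigs}
    hits: dict[str, dict[str, int]] = {}
    dropped = 0
    for marker, contig, count in df[["marker_id", "contig_id", "copy_count"]].itertuples(index=False):
        marker, contig = str(marker), str(contig)
        if contig not in universe:
            dropped += 1
            continue
        hits.setdefault(marker, {})[contig] = hits.get(marker, {}).get(contig, 0) + int(count)
    if dropped:
        logger.info("ignored %d marker hit(s) on contigs outside the universe", dropped)
    gene_length: dict[str, int] = {}
    if gene_lengths_path is not None:
        gl = pd.read_csv(gene_lengths_path, sep="\t", header=0)
        gene_length = {
            str(m): int(v) for m, v in zip(gl.iloc[:, 0], gl.iloc[:, 1])
        }
    marker_ids = sorted(hits)
    return MarkerHitTable(
        marker_ids=marker_ids,
        gene_length={m: gene_length.get(m, 0) for m in marker_ids},
        hits=hits,
        domain=domain,
    )


def _check_disjoint(bins: Mapping[str, set[str]]) -> None:
    seen: dict[str, str] = {}
    for bin_id, members in bins.items():
        for contig in members:
            if contig in seen:
                raise ValueError(
                    f"contig {contig!r} appears in bins {seen[contig]!r} and {bin_id!r}"
                )
            seen[contig] = bin_id


def write_binning(binning, out_dir: str | os.PathLike, contigs: list[ContigRecord]) -> Path:
    """Write a binning as a 2-column TSV plus one FASTA per bin.

    Returns the path of the TSV. Bin ids containing path separators are
    rejected.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bins = binning.bins
    _check_disjoint(bins)
    for bin_id in bins:
        if "/" in bin_id or os.sep in bin_id:
            raise ValueError(f"bin id {bin_id!r} contains a path separator")
    seq_by_id = {c.id: c.sequence for c in contigs}
    tsv_path = out_dir / "binning.tsv"
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("contig_id\tbin_id\n")
        for bin_id in sorted(bins):
            for contig_id in sorted(bins[bin_id]):
                fh.write(f"{contig_id}\t{bin_id}\n")
    for bin_id in sorted(bins):
        with open(out_dir / f"{bin_id}.fa", "w", encoding="utf-8") as fh:
            for contig_id in sorted(bins[bin_id]):
                seq = seq_by_id.get(contig_id)
                if seq is None:
                    raise ValueError(f"binned contig {contig_id!r} has no sequence")
                fh.write(f">{contig_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    return tsv_path


def read_binning_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read a contig_id→bin_id mapping written by :func:`write_binning`."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if list(df.columns[:2]) != ["contig_id", "bin_id"]:
        raise ValueError("binning TSV must have columns contig_id, bin_id")
    return dict(zip(df["contig_id"], df["bin_id"]))
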