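"""Per-contig feature matrices: coverage, tetranucleotide composition, and both.

Coverage block: depth + 0.01 pseudocount, per-sample (column) library-size
normalization, then per-contig (row) L1 normalization. Composition block:
canonical (reverse-complement-folded) tetramer counts with a +1
pseudocount per class, row-L1 normalized. All three matrices are natural-
log transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ensemblebin.contig_io import ContigRecord, CoverageTable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: pseudocount added to every depth entry before normalization
COVERAGE_PSEUDOCOUNT = 0.01
#: pseudocount added to every canonical tetramer class count
COMPOSITION_PSEUDOCOUNT = 1.0


@dataclass
class FeatureSet:
    """The three row-aligned feature matrices over N contigs."""

    contig_ids: list[str]
    X_combo: np.ndarray  # N x (M + T)
    X_cov: np.ndarray  # N x M
    X_com: np.ndarray  # N x T
    lengths: np.ndarray  # N, bp
    T: int

    def __post_init__(self) -> None:
        n = len(self.contig_ids)
        for name in ("X_combo", "X_cov", "X_com"):
            mat = getattr(self, name)
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{name} contains non-finite entries")
        self.lengths = np.asarray(self.lengths, dtype=float)

    def matrix(self, track: str) -> np.ndarray:
        """Feature matrix for a named track (``combo``, ``cov``, or ``com``)."""
        try:
            return {"combo": self.X_combo, "cov": self.X_cov, "com": self.X_com}[track]
        except KeyError:
            raise ValueError(f"unknown feature track {track!r}") from None

    def row_index(self) -> dict[str, int]:
        return {cid: i for i, cid in enumerate(self.contig_ids)}

    def subset(self, rows: np.ndarray) -> "FeatureSet":
        """Row-subset FeatureSet (used when re-clustering one bin)."""
        rows = np.asarray(rows)
        return FeatureSet(
            contig_ids=[self.contig_ids[i] for i in rows],
            X_combo=self.X_combo[rows],
            X_cov=self.X_cov[rows],
            X_com=self.X_com[rows],
            lengths=self.lengths[rows],
            T=self.T,
        )


def _reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def canonical_tetramer_index() -> tuple[str, ...]:
    """The 136 canonical tetramers, lexicographically sorted.

    Each of the 256 tetramers maps to the lexicographic minimum of itself
    and its reverse complement; 16 palindromes map to themselves, leaving
    (256 - 16) / 2 + 16 = 136 classes.
    """
    bases = "ACGT"
    canon: set[str] = set()
    for a in bases:
        for b in bases:
            for c in bases:
                for d in bases:
                    kmer = a + b + c + d
                    canon.add(min(kmer, _reverse_complement(kmer)))
    return tuple(sorted(canon))


@lru_cache(maxsize=1)
def _tetramer_class_codes() -> np.ndarray:
    """Class index of each of the 256 tetramers, keyed by base-4 code."""
    index = {t: i for i, t in enumerate(canonical_tetramer_index())}
    codes = np.empty(256, dtype=np.int64)
    bases = "ACGT"
    for code in range(256):
        kmer = "".join(bases[(code >> shift) & 3] for shift in (6, 4, 2, 0))
        codes[code] = index[min(kmer, _reverse_complement(kmer))]
    return codes


@lru_cache(maxsize=1)
def _base_code_table() -> np.ndarray:
    table = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table


def composition_vector(sequence: str) -> np.ndarray:
    """Canonical tetramer frequency vector with a +1 pseudocount per class.

    Sliding 4-mer windows (step 1); windows containing any base outside
    A/C/G/T are skipped entirely. Entries sum to 1. Sequences with no
    valid window yield the uniform vector.
    """
    t = len(canonical_tetramer_index())
    counts = np.zeros(t, dtype=float)
    valid = 0
    seq = sequence.upper()
    if len(seq) >= 4:
        base = _base_code_table()[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        windows = (
            64 * base[:-3] + 16 * base[1:-2] + 4 * base[2:-1] + base[3:]
        )
        ok = (base[:-3] >= 0) & (base[1:-2] >= 0) & (base[2:-1] >= 0) & (base[3:] >= 0)
        codes = windows[ok]
        valid = int(codes.size)
        if valid:
            counts = np.bincount(
                _tetramer_class_codes()[codes], minlength=t
            ).astype(float)
    counts += COMPOSITION_PSEUDOCOUNT
    return counts / (valid + t * COMPOSITION_PSEUDOCOUNT)


def _coverage_block(depth: np.ndarray) -> np.ndarray:
    block = depth + COVERAGE_PSEUDOCOUNT
    block = block / block.sum(axis=0, keepdims=True)  # per-sample library size
    block = block / block.sum(axis=1, keepdims=True)  # per-contig L1
    return block


def build_feature_set(contigs: list[ContigRecord], coverage: CoverageTable) -> FeatureSet:
    """Assemble X_combo, X_cov, and X_com for the given contigs.

    The combined matrix is the log of the row-wise concatenation of the
    normalized coverage and composition blocks (each block keeps its own
    row-L1 normalization).
    """
    if [c.id for c in contigs] != coverage.contig_ids:
        raise ValueError("coverage rows are not aligned to the contig list")
    if np.isnan(coverage.depth).any():
        raise ValueError("coverage depth contains NaN")
    cov_block = _coverage_block(coverage.depth)
    com_block = np.vstack([composition_vector(c.sequence) for c in contigs])
    t = com_block.shape[1]
    return FeatureSet(
        contig_ids=list(coverage.contig_ids),
        X_combo=np.log(np.hstack([cov_block, com_block])),
        X_cov=np.log(cov_block),
        X_com=np.log(com_block),
        lengths=np.array([c.length for c in contigs], dtype=float),
        T=t,
    )


def export_matrix_tsv(features: FeatureSet, track: str, path) -> None:
    """Debug export of one feature matrix as TSV (9 significant digits)."""
    mat = features.matrix(track)
    with open(path, "w", encoding="utf-8") as fh:
        cols = "\t".join(f"f{i}" for i in range(mat.shape[1]))
        fh.write(f"contig_id\t{cols}\n")
        for cid, row in zip(features.contig_ids, mat):
            vals = "\t".join(f"{v:.9g}" for v in row)
            fh.write(f"{cid}\t{vals}\n")
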