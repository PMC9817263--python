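"""Shared fixtures: tiny on-disk inputs and small synthetic communities."""

from __future__ import annotations

import pytest

from ensemblebin.contig_io import ContigRecord, MarkerHitTable
from ensemblebin.synthetic import CommunitySpec, generate_community


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "contigs.fa"
    path.write_text(
        ">c_short\n" + "A" * 800 + "\n"
        ">c_edge\n" + "ACGT" * 250 + "\n"
        ">c_long\n" + "ACGT" * 300 + "\n"
    )
    return path


@pytest.fixture
def three_contigs():
    return [
        ContigRecord(id="c1", sequence="ACGT" * 300, length=1200),
        ContigRecord(id="c2", sequence="AAAC" * 300, length=1200),
        ContigRecord(id="c3", sequence="GGTC" * 500, length=2000),
    ]


@pytest.fixture
def example_hits():
    """Per-marker distinct-contig counts {2, 3, 3, 4, 10}."""
    def contigs(n):
        return {f"x{i}": 1 for i in range(n)}

    return MarkerHitTable(
        marker_ids=["m1", "m2", "m3", "m4", "m5"],
        gene_length={"m1": 900, "m2": 400, "m3": 700, "m4": 500, "m5": 600},
        hits={
            "m1": contigs(2),
            "m2": contigs(3),
            "m3": contigs(3),
            "m4": contigs(4),
            "m5": contigs(10),
        },
    )


@pytest.fixture(scope="session")
def small_community():
    """8 genomes, ~60 contigs; fast enough for any unit test."""
    spec = CommunitySpec(
        n_genomes=8,
        genome_length_bp=60_000,
        n_samples=6,
        n_markers=20,
        seed=3,
    )
    return generate_community(spec)


@pytest.fixture(scope="session")
def small_lengths(small_community):
    return {c.id: c.length for c in small_community.contigs}
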