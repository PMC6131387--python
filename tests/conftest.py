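"""Shared fixtures: tiny hand-built records and a seeded simulated data set."""

import pytest

from opvar.formats_io import AlignedReadRecord, GeneRecord, LibraryAlignments
from opvar.synthetic_data import SimConfig, simulate_genome, simulate_library


def make_read(read_id, start, end, strand="+", chrom="chr1"):
    return AlignedReadRecord(read_id, chrom, start, end, strand)


def make_library(spans, label="lib", chrom="chr1", total=None):
    """Build a library from (start, end, strand) tuples."""
    reads = [
        AlignedReadRecord(f"r{i}", chrom, s, e, st)
        for i, (s, e, st) in enumerate(spans)
    ]
    return LibraryAlignments(label=label, reads=reads, total_mappable=total or len(reads))


@pytest.fixture
def three_gene_annotation():
    return [
        GeneRecord("geneA", "chr1", 150, 400, "+"),
        GeneRecord("geneB", "chr1", 500, 900, "+"),
        GeneRecord("geneC", "chr1", 950, 1200, "+"),
    ]


@pytest.fixture(scope="session")
def sim_dataset():
    """One seeded simulation shared across recovery tests."""
    config = SimConfig(seed=7, n_operons=6, depth_per_tss=60, genome_length=80_000)
    genome, genes, specs = simulate_genome(config)
    enriched, truth = simulate_library(specs, config, "enriched")
    control, _ = simulate_library(specs, config, "control")
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "specs": specs,
        "enriched": enriched,
        "control": control,
        "truth": truth,
    }
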