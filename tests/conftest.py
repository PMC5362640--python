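"""Shared fixtures: small synthetic genomes with known truth."""

import pytest

from prokannot.cli import extract_db_fasta_from_truth
from prokannot.gene_model import consolidate
from prokannot.synthkit import make_genome


@pytest.fixture(scope="session")
def genome_truth():
    """A 12-kb genome with 10 planted genes (alternating strands)."""
    record, truth = make_genome(n_genes=10, genome_len=12000, seed=42)
    return record, consolidate(truth)


@pytest.fixture(scope="session")
def protein_db(genome_truth):
    record, truth = genome_truth
    db = extract_db_fasta_from_truth(record, truth)
    for i, entry in enumerate(db):
        entry.description = f"{entry.id} synthetic protein {i + 1} [Syntheticus exemplaris]"
    return db
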