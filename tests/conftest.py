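
import numpy as np
import pandas as pd
import pytest

from quantmeta import synthetic
from quantmeta.abundance import HIT_COLUMNS


def make_hits(records):
    return pd.DataFrame(records, columns=HIT_COLUMNS)


def paired_genome_hits(read_id, genome, start=0, span=200):
    """Two paired-match genome records for one read pair."""
    return [
        (read_id, 1, genome, "genome", start, start + 100, 1),
        (read_id, 2, genome, "genome", start + span - 100, start + span, 1),
    ]


@pytest.fixture
def two_genome_hits():
    """The worked unique/multi example: A (l=100, 4 unique), B (l=200, 2
    unique), 3 read pairs matching both."""
    records = []
    for i in range(4):
        records += paired_genome_hits(f"uA{i}", "A", span=100)
    for i in range(2):
        records += paired_genome_hits(f"uB{i}", "B", span=100)
    for i in range(3):
        records += paired_genome_hits(f"m{i}", "A", span=100)
        records += paired_genome_hits(f"m{i}", "B", span=100)
    return make_hits(records), pd.Series({"A": 100.0, "B": 200.0})


@pytest.fixture(scope="session")
def planted_blocks():
    """Low-dispersion cohort with planted co-abundance blocks spanning the
    MGS/CAG size classes, no disease effects, no dropout."""
    spec = synthetic.CohortSpec(
        n_cases=40, n_controls=40,
        cluster_sizes=(900, 400, 150, 100, 25),
        n_noise_genes=1000, effects={}, dispersion=0.05, dropout=0.0, seed=11,
    )
    matrix, labels, truth = synthetic.generate_cohort(spec)
    return matrix, labels, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """Discovery + validation cohorts with planted case/control effects."""
    spec = synthetic.CohortSpec(seed=5)
    return synthetic.generate_paired_cohorts(spec)


def true_labels(truth, genes):
    membership = truth.cluster_membership
    return [membership.get(g, "noise") for g in genes]
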