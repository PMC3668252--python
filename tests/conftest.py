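"""Shared fixtures: toy alignments and the default synthetic study."""

from __future__ import annotations

import pytest

from fernhybrid.pipeline import PipelineConfig, run_pipeline
from fernhybrid.seqio import Role, SampleRecord, SiteAlignment, Taxon
from fernhybrid.simulate import paper_config, simulate_dataset


def make_alignment(rows, locus="toy"):
    """rows: list of (sample_id, taxon, population, role, sequence[, prefix])"""
    samples = []
    matrix = []
    for row in rows:
        prefix = row[5] if len(row) > 5 else None
        samples.append(
            SampleRecord(row[0], row[1], row[2], row[3], readable_prefix=prefix)
        )
        matrix.append(row[4])
    return SiteAlignment(locus_name=locus, samples=tuple(samples),
                         matrix=tuple(matrix))


def hap_row(sid, seq, taxon=Taxon.SPECIES_A, pop="P1"):
    return (sid, taxon, pop, Role.HAPLOTYPE, seq)


def consensus_row(sid, seq, taxon=Taxon.HYBRID, pop="P1", prefix=None):
    return (sid, taxon, pop, Role.DIPLOID_CONSENSUS, seq, prefix)


@pytest.fixture(scope="session")
def study_dataset():
    """The default synthetic study (published design), fixed seed."""
    return simulate_dataset(paper_config(seed=1))


@pytest.fixture(scope="session")
def study_result():
    """Full pipeline run on the default synthetic study, fixed seed."""
    return run_pipeline(PipelineConfig(seed=1, simulate="paper"))
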