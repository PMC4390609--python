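import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mirconsensus import pipeline, sequence_space as seqspace, validated as val
from mirconsensus.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """One deterministic toy study: genome, annotation, miRNAs, validated pairs."""
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(seed=1), outdir)


@pytest.fixture(scope="session")
def utrs(fixture_set):
    return pipeline.build_utrs(fixture_set.gtf, fixture_set.genome_fasta)


@pytest.fixture(scope="session")
def mirnas(fixture_set):
    return seqspace.load_mirnas(fixture_set.mirna_fasta)


@pytest.fixture(scope="session")
def sites_by_engine(utrs, mirnas):
    return pipeline.predict_all(utrs, mirnas)


@pytest.fixture(scope="session")
def unique_pairs(fixture_set):
    return val.dedup_pairs(val.load_validated(fixture_set.validated_tsvs))


@pytest.fixture(scope="session")
def consensus_run(sites_by_engine, utrs, unique_pairs):
    """(ranked groups, calibration curves) from the full toy pipeline."""
    return pipeline.run_consensus(sites_by_engine, utrs, unique_pairs)
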