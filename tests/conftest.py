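import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import chipbias as cb
from chipbias.pipeline import simulate_samples

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

STUDY_N_FRAGMENTS = 200_000


@pytest.fixture(scope="session")
def genome():
    """The standard study genome: 200 genes, 20 divergent pairs."""
    return cb.build_toy_genome(n_genes=200, n_divergent_pairs=20, seed=1)


@pytest.fixture(scope="session")
def genes(genome):
    return genome.genes_frame()


@pytest.fixture(scope="session")
def sizes(genome):
    return genome.chrom_sizes


@pytest.fixture(scope="session")
def small_genome():
    """A cheap genome for structural tests."""
    return cb.build_toy_genome(n_genes=24, n_divergent_pairs=4, seed=7)


@pytest.fixture(scope="session")
def study_samples(genome):
    """One full sample grid at study depth, shared across read-only tests."""
    cfg = cb.SimConfig(seed=1, n_fragments=STUDY_N_FRAGMENTS)
    return simulate_samples(genome, cfg)


@pytest.fixture(scope="session")
def study_rpm(genome, study_samples):
    """Read-style RPM tracks for the control-condition samples."""
    sizes = genome.chrom_sizes
    return {
        kind: cb.normalize_rpm(
            cb.extend_and_count(study_samples[(kind, "control")].as_reads(), sizes)
        )
        for kind in ("input", "mock", "tf_chip", "rnapii_chip")
    }


@pytest.fixture(scope="session")
def study_occupancy(genome, study_samples):
    genes = genome.genes_frame()
    sizes = genome.chrom_sizes
    return {
        key: cb.gene_body_occupancy(
            cb.count_midpoints(fs, sizes), genes, sample_id=f"{key[0]}_{key[1]}"
        )
        for key, fs in study_samples.items()
    }


def make_fragments(rows, sample_id="toy", kind="unknown", condition="", **kw):
    """FragmentSet from a list of (chrom, start, end[, strand]) tuples."""
    recs = pd.DataFrame(
        [r if len(r) == 4 else (*r, "+") for r in rows],
        columns=["chrom", "start", "end", "strand"],
    )
    return cb.FragmentSet(
        sample_id=sample_id,
        sample_kind=kind,
        condition=condition,
        records=recs,
        **kw,
    ).sorted()


@pytest.fixture
def toy_fragments():
    return make_fragments
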