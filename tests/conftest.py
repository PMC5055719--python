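import warnings

import numpy as np
import pandas as pd
import pytest

from httscan import (CountMatrix, HitRecord, PipelineConfig, WorldSpec,
                     generate_world, load_family_catalog,
                     load_taxa17_scheme, load_ecology_scheme)


def make_hit(query="q1", subject="s1", organism="Danio rerio",
             lineage=("Eukaryota", "Metazoa", "Chordata", "Actinopterygii"),
             e_value=1e-30, bitscore=100.0, coverage=0.8,
             program="blastn", tag="nt"):
    return HitRecord(query_id=query, subject_id=subject,
                     subject_organism=organism,
                     subject_lineage=tuple(lineage), e_value=e_value,
                     bitscore=bitscore, query_coverage=coverage,
                     program=program, database_tag=tag, q_start=1, q_end=100)


@pytest.fixture(scope="session")
def catalog():
    return load_family_catalog()


@pytest.fixture(scope="session")
def taxa17():
    return load_taxa17_scheme()


@pytest.fixture(scope="session")
def ecology():
    return load_ecology_scheme()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared by read-only tests."""
    return generate_world(WorldSpec(n_transcripts=400, n_te=160, n_htt=64,
                                    n_decoys=15, n_mimics=10, seed=11))


@pytest.fixture
def toy_matrix():
    """Two groups x two replicates, six transcripts, fully deterministic."""
    counts = pd.DataFrame(
        {"s1": [10, 100, 0, 50, 5, 1000],
         "s2": [12, 110, 0, 55, 6, 1100],
         "s3": [40, 100, 7, 50, 5, 1000],
         "s4": [44, 95, 9, 45, 4, 900]},
        index=[f"t{i}" for i in range(1, 7)])
    groups = pd.Series({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
    return CountMatrix(counts=counts, groups=groups, project="toy")


@pytest.fixture(autouse=True)
def _silence_small_training_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="novelty training set has only")
        yield
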