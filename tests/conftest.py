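import numpy as np
import pandas as pd
import pytest

from cassex import CohortDesign, SampleManifest, generate_cohort
from cassex.io import Junction, JunctionCountTable


@pytest.fixture(scope="session")
def small_cohort():
    """Two cancer types, 8 pairs each, 40 events (6 altered), depth 50."""
    design = CohortDesign(
        cancer_types=("CT1", "CT2"),
        pairs_per_type=8,
        n_events=40,
        n_altered=6,
        seed=7,
    )
    return generate_cohort(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_manifest(rows):
    """rows: (sample_id, patient_id, condition, cancer_type) tuples."""
    return SampleManifest(entries=pd.DataFrame(rows, columns=list(SampleManifest.COLUMNS)))


def make_table(sample_id, triples):
    """triples: (Junction, count) pairs."""
    return JunctionCountTable(sample_id=sample_id, counts=dict(triples))


def cassette_junctions(chrom="chr1", strand="+", u=(100, 199), d=(300, 399)):
    """The three junctions of one cassette event."""
    uj = Junction(chrom, u[0], u[1], strand)
    dj = Junction(chrom, d[0], d[1], strand)
    sj = Junction(chrom, u[0], d[1], strand)
    return uj, dj, sj
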