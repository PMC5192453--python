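import numpy as np
import pytest

from nmrmet.preprocess import BucketTable, build_table, pqn_normalize
from nmrmet.synthetic import (
    MetaboliteSpec,
    default_design,
    default_library,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_axis():
    # 1.0-3.0 ppm at the default grid step: fast to render, covers acetate,
    # succinate and the glutamine/glutamate triplet
    step = 0.00025
    n = int(round(2.0 / step)) + 1
    return 1.0 + step * np.arange(n)


@pytest.fixture(scope="session")
def tiny_library():
    return [
        MetaboliteSpec("acetate", ((1.92, 1.0),)),
        MetaboliteSpec("succinate", ((2.41, 1.0),)),
        MetaboliteSpec("alanine", ((1.48, 1.0),)),
    ]


@pytest.fixture(scope="session")
def paper_like_cohort():
    """One seeded default cohort shared by read-only tests."""
    spectra, meta = generate_cohort(default_design(seed=7))
    return spectra, meta


@pytest.fixture(scope="session")
def paper_like_table(paper_like_cohort):
    spectra, meta = paper_like_cohort
    return pqn_normalize(build_table(spectra)), meta


def contrast_subset(table: BucketTable, meta, groups=("sham", "sepsis_survivor")):
    labels = [str(g) for g in meta["group"]]
    mask = np.array([l in groups for l in labels])
    sub = BucketTable(
        sample_ids=[s for s, m in zip(table.sample_ids, mask) if m],
        bucket_centers=table.bucket_centers,
        values=table.values[mask],
        normalization=table.normalization,
        excluded_regions=table.excluded_regions,
    )
    sub_labels = [l for l, m in zip(labels, mask) if m]
    return sub, sub_labels
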