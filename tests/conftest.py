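import numpy as np
import pytest

from residualphylo.io_formats import (
    Assay,
    Observation,
    RegionClass,
    SampleMeta,
    Timepoint,
    VariantRecord,
)
from residualphylo.simulate import SimConfig, simulate_dataset


def make_sample(sample_id, region, purity, assays=(Assay.WES,), patient="P1",
                timepoint=Timepoint.PRIMARY):
    return SampleMeta(sample_id, patient, region, timepoint, purity, frozenset(assays))


def make_variant(variant_id="chr1:100:A>T", observations=None):
    chrom, rest = variant_id.split(":", 1)
    pos, change = rest.split(":")
    ref, alt = change.split(">")
    v = VariantRecord(variant_id, chrom, int(pos), ref, alt)
    for (sample_id, assay), (depth, alt_count) in (observations or {}).items():
        v.add_observation(sample_id, assay, Observation(depth, alt_count))
    return v


@pytest.fixture(scope="session")
def ancestral_dataset():
    """One seeded ancestral-margin dataset shared across tests."""
    return simulate_dataset(SimConfig(ancestral_margin=True), seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
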