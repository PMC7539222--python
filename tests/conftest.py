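import numpy as np
import pytest

from rnasomatic.io_core import FunctionalClass, VariantRecord
from rnasomatic.simulate import SimulationParams, bundle_index, simulate_cohort


def make_variant(
    sample="S1", chrom="chr1", pos=100, ref="A", alt="G",
    vaf=0.3, depth=40, **kwargs,
):
    alt_depth = kwargs.pop("alt_depth", round(vaf * depth))
    return VariantRecord(
        sample_id=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        vaf=alt_depth / depth if depth else 0.0, depth=depth, alt_depth=alt_depth,
        **kwargs,
    )


def annotated_variant(annotations=frozenset(), pop_af=None, **kwargs):
    rec = make_variant(**kwargs)
    rec.annotations = set(annotations)
    rec.pop_af = dict(pop_af or {})
    if rec.homopolymer_len is None:
        rec.homopolymer_len = 1
    return rec


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_cohort(SimulationParams(seed=11, n_samples=12))


@pytest.fixture(scope="session")
def small_index(small_bundle):
    return bundle_index(small_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
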