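import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def two_sample_locus():
    """A small polymorphic locus with two temporal samples."""
    from cohortsel import GenotypeCounts, TemporalLocusData

    return TemporalLocusData(
        locus_id="L1",
        samples=(GenotypeCounts(10, 20, 10), GenotypeCounts(5, 18, 17)),
    )
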