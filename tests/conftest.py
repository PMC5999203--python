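import numpy as np
import pytest

from salmosim import ModelParams
from salmosim.lifecycle import Fishes
from salmosim import genetics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def weights():
    return genetics.build_locus_weights()


def make_fishes(
    n,
    sex=0,
    origin=0,
    fw_age=0,
    sea_age=0,
    length=60.0,
    allele=None,
    freq=None,
    rng=None,
):
    """Build a homogeneous test cohort.

    ``allele`` forces every allele to 0 or 1; ``freq`` draws genomes at that
    frequency (requires ``rng``); default is all-1 (pure wild) genomes.
    """
    if freq is not None:
        genomes = genetics.draw_genomes(n, freq, rng)
    else:
        fill = 1 if allele is None else allele
        genomes = np.full((n, *genetics.GENOME_SHAPE), fill, np.uint8)
    return Fishes(
        sex=np.full(n, sex, np.uint8),
        origin=np.full(n, origin, np.uint8),
        fw_age=np.full(n, fw_age, np.int32),
        sea_age=np.full(n, sea_age, np.int32),
        length=np.full(n, float(length)),
        genomes=genomes,
    )


try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass
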