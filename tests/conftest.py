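import numpy as np
import pytest

from pericentro import SignalTrack, SuppressionModel, ToyGenome, make_toy_genome


@pytest.fixture(scope="session")
def default_genome() -> ToyGenome:
    """The default 16 x 200 kb toy genome (markers every 500 bp)."""
    return make_toy_genome(seed=7)


@pytest.fixture(scope="session")
def small_genome() -> ToyGenome:
    """A 3-chromosome genome small enough for exhaustive checking."""
    return make_toy_genome(n_chrom=3, chrom_length=120_000, hotspot_rate=0.3, marker_spacing=500, seed=11)


@pytest.fixture
def default_model() -> SuppressionModel:
    return SuppressionModel()


@pytest.fixture
def flat_track(small_genome) -> SignalTrack:
    values = {c: np.full(small_genome.chrom_lengths[c], 2.0) for c in small_genome.chrom_names}
    return SignalTrack(values=values, total_mapped=sum(v.sum() for v in values.values()))
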