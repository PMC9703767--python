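import numpy as np
import pytest

from crossregulome.core import GenomeLayout, SignalTrack
from crossregulome.simulate import (SimConfig, simulate_all_samples,
                                    simulate_study)


@pytest.fixture(scope="session")
def small_config():
    """A reduced study that keeps every structural feature of the default
    design (planted mechanisms, spike-in, two conditions x two replicates)
    but runs in well under a second."""
    return SimConfig(n_chroms=2, chrom_length=6_000_000, n_genes=120,
                     n_pol3_peaks=60, depth=80.0, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_samples(small_study):
    return simulate_all_samples(small_study)


@pytest.fixture()
def tiny_layout():
    return GenomeLayout(("chr1", "chr2"), (100_000, 50_000))


def make_track(layout, bin_size=10, strand=".", **chrom_values):
    """Track with explicit per-chromosome bin values (zeros elsewhere)."""
    track = SignalTrack.zeros(layout, bin_size, strand=strand, dtype=np.float64)
    for chrom, values in chrom_values.items():
        arr = track.data[chrom]
        vals = np.asarray(values, dtype=float)
        arr[: len(vals)] = vals
    return track
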