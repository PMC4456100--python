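import numpy as np
import pytest

import tespread as ts


@pytest.fixture(scope="session")
def small_ds():
    """Hand-built ~50-kb miniature dataset (6 genes, 8 TEs, 2 stages)."""
    return ts.gen_small_fixture()


@pytest.fixture(scope="session")
def dataset():
    """Full synthetic study system under the default conditions."""
    return ts.simulate_dataset(ts.SynthConfig(seed=3))


@pytest.fixture(scope="session")
def clamped_tracks(dataset):
    return [ts.clamp_track(tr) for tr in dataset.tracks]


@pytest.fixture(scope="session")
def weighted_reads(dataset):
    return ts.assign_mapping_weights(dataset.reads)


@pytest.fixture(scope="session")
def gene_records(dataset, clamped_tracks, weighted_reads):
    return ts.build_gene_records(
        dataset.annotation,
        clamped_tracks,
        weighted_reads,
        dataset.te_frequency,
        dataset.recomb_map,
    )


def brute_force_interval_mean(edges, values, start, end):
    """Per-bp oracle for the length-weighted mean of a step function."""
    per_bp = np.repeat(values, np.diff(edges).astype(int))
    return float(per_bp[start:end].mean())
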