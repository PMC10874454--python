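import numpy as np
import pytest

from sigfate import synthgen


@pytest.fixture(scope="session")
def histories_500():
    """Default-regime signaling histories with ground truth (n=500)."""
    params = synthgen.HistoryGenParams(n_cells=500, seed=11)
    histories, truth = synthgen.gen_histories(params)
    return params, histories, truth


@pytest.fixture(scope="session")
def fates_500(histories_500):
    _, _, truth = histories_500
    return synthgen.gen_fates(truth, synthgen.FateGenParams(seed=12))


@pytest.fixture(scope="session")
def clean_histories():
    """Noiseless sigmoids with known parameters."""
    params = synthgen.HistoryGenParams(
        n_cells=20, noise_sd=0.0, high_sd=0.0, low_sd=0.0, duration_sd=4.0, seed=21
    )
    histories, truth = synthgen.gen_histories(params)
    return params, histories, truth


@pytest.fixture(scope="session")
def colony():
    params = synthgen.ColonyGenParams(seed=31)
    positions, histories, fates, truth = synthgen.gen_colony(params)
    return params, positions, histories, fates, truth


@pytest.fixture(scope="session")
def tracking_fixture():
    detections, truth = synthgen.gen_tracking_fixture(
        n_cells=100, n_frames=50, division_prob=0.002, seed=41
    )
    return detections, truth


@pytest.fixture(scope="session")
def counts():
    return synthgen.gen_counts(n_genes=1500, seed=51)
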