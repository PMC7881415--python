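import numpy as np
import pytest

from neoresp import breath_analysis as ba
from neoresp import synthetic_data as sd


@pytest.fixture(scope="session")
def clean_pleth():
    """Jitter-free, noiseless 60 s recording at 120 breaths/min."""
    spec = sd.PlethSpec(duration_s=60.0, base_freq_bpm=120.0,
                        freq_jitter_cv=0.0, amplitude_jitter_cv=0.0,
                        noise_sd=0.0, seed=1)
    trace, onsets, apneas = sd.gen_pleth_trace(spec)
    return spec, trace, onsets, apneas


@pytest.fixture(scope="session")
def clean_breaths(clean_pleth):
    _, trace, _, _ = clean_pleth
    return ba.segment_breaths(trace)


@pytest.fixture(scope="session")
def noiseless_burst_train():
    spec = sd.BurstTrainSpec(duration_s=60.0, mean_period_s=3.0,
                             period_jitter_cv=0.0, amplitude_jitter_cv=0.0,
                             baseline_noise_sd=0.0, burst_sigma_s=0.2, seed=2)
    return (spec,) + sd.gen_burst_train(spec)


@pytest.fixture(scope="session")
def nuclei_image():
    """150 well-separated nuclei, three channels keyed to label states."""
    cells = sd.gen_cellcycle_population(sd.CellCycleSpec(n_cells=400, seed=7))
    rules = {
        "dapi": sd.ChannelRule(positive_level=200.0, cv=0.05),
        "brdu": sd.ChannelRule("cldu_pos", 200.0, 20.0, cv=0.1),
        "edu": sd.ChannelRule("edu_pos", 200.0, 20.0, cv=0.1),
    }
    spec = sd.ImageSpec(shape_px=(700, 700), n_nuclei=150, channel_model=rules,
                        min_separation_px=18.0, seed=7)
    stack, truth = sd.gen_microscopy_image(spec, cells)
    return spec, stack, truth
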