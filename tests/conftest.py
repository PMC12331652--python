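import numpy as np
import pytest

import gaitrefine as gr


@pytest.fixture(scope="session")
def small_pairs():
    """3 subjects x 4 speeds, 20 channels, +2-sample shift, light noise."""
    spec = gr.DistortionSpec(
        temporal_shift=0.075, cycle_duration=0.75, noise_sd=0.02, seed=5
    )
    return gr.generate_dataset(3, 4, 1, spec, seed=11, measurement_noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_temporal_model(small_pairs):
    """A quickly trained One-Entire refiner shared across tests."""
    pat = gr.InputPattern("One-Entire", "m00")
    samples = [gr.build_pattern(p, pat) for p in small_pairs]
    std, rec = gr.standardize(samples)
    cfg = gr.ModelConfig(
        input_channels=1, sequence_length=20, hidden_units=24, epochs=40, seed=7
    )
    return gr.train(cfg, std, normalization=rec, pattern_name=pat.name), pat


@pytest.fixture(scope="session")
def flat_profile():
    """Single-channel subject with one centered burst and no randomness."""
    return gr.SubjectProfile(
        subject_id="S01",
        centers=[np.array([0.5])],
        widths=[np.array([0.08])],
        amplitudes=[np.array([0.8])],
        subject_offset=0.0,
        speed_scalings=(1.0, 1.0, 1.0, 1.0),
    )
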