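"""Shared fixtures: synthetic datasets and trained models.

Heavy fixtures (trained VAEs) are session-scoped so the expensive training
runs happen once; dataset sizes and epoch counts are chosen small enough
for single-CPU runs while still exercising the recovery properties.
"""

import numpy as np
import pytest

from vocalvae import spectrogram as sg
from vocalvae import synth, vae

SAMPLE_RATE = 32000


@pytest.fixture(scope="session")
def archetypes():
    """Four well-separated chirp archetypes."""
    return synth.example_archetypes(4)


@pytest.fixture(scope="session")
def clustered_data(archetypes):
    """Clustered repertoire: 200 syllables, 4 archetypes, 5% jitter."""
    spec = synth.RepertoireSpec(
        archetypes=archetypes,
        regime="clustered",
        n_syllables=200,
        jitter_scale=0.05,
        sample_rate=SAMPLE_RATE,
        seed=7,
    )
    ds = synth.generate_repertoire(spec)
    images, report = sg.batch_spectrograms(ds.audio, ds.segments, sg.SpectrogramConfig())
    return {"dataset": ds, "images": images, "config": report["config"]}


@pytest.fixture(scope="session")
def continuum_data(archetypes):
    """Continuum repertoire: same settings, archetype-interpolated shapes."""
    spec = synth.RepertoireSpec(
        archetypes=archetypes,
        regime="continuum",
        n_syllables=200,
        jitter_scale=0.05,
        sample_rate=SAMPLE_RATE,
        seed=7,
    )
    ds = synth.generate_repertoire(spec)
    images, report = sg.batch_spectrograms(ds.audio, ds.segments, sg.SpectrogramConfig())
    return {"dataset": ds, "images": images, "config": report["config"]}


@pytest.fixture(scope="session")
def default_model(clustered_data):
    """Reference-configuration VAE trained on the clustered repertoire."""
    return vae.train(clustered_data["images"], vae.ModelConfig(epochs=25, seed=11))


@pytest.fixture(scope="session")
def continuum_model(continuum_data):
    return vae.train(continuum_data["images"], vae.ModelConfig(epochs=25, seed=11))


@pytest.fixture(scope="session")
def tiny_model():
    """A very small trained VAE (16x16 images) for cheap interface tests."""
    rng = np.random.default_rng(0)
    images = rng.uniform(0, 1, (48, 16, 16))
    config = vae.ModelConfig(
        latent_dim=4, hidden=(32,), input_shape=(16, 16), epochs=3, batch_size=16,
        seed=2,
    )
    return vae.train(images, config), images
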