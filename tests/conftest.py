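"""Shared fixtures: the reference phantom and models trained on it.

The heavy artifacts (trained networks, denoised recordings) are
session-scoped so the whole suite pays the training cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

from tagspark.denoiser import NetworkConfig, TrainingConfig, build_network, denoise, train
from tagspark.synthetic import PhantomSpec, make_dataset

# Desk-scale training configuration used throughout the suite: 2 resolution
# levels, 16 base channels, 20 epochs on random (16, 32, 32) crops.
REF_NETWORK = NetworkConfig(levels=2, base_channels=16)
REF_TRAINING = TrainingConfig(epochs=20, seed=1, patch=(16, 32, 32))


@pytest.fixture(scope="session")
def reference_dataset():
    """The reference phantom: 16 volumes of 32x64x64, ~4 photons per voxel."""
    return make_dataset(PhantomSpec())


@pytest.fixture(scope="session")
def trained_model(reference_dataset):
    model = build_network(REF_NETWORK, seed=1)
    return train(model, reference_dataset.noisy, REF_TRAINING)


@pytest.fixture(scope="session")
def denoised_reference(trained_model, reference_dataset):
    return denoise(trained_model, reference_dataset.noisy)


@pytest.fixture(scope="session")
def temporal_baseline_model(reference_dataset):
    """Same network trained with adjacent-time-point pairing (baseline mode)."""
    import dataclasses

    model = build_network(REF_NETWORK, seed=1)
    tc = dataclasses.replace(REF_TRAINING, pairing="temporal")
    return train(model, reference_dataset.noisy, tc)


@pytest.fixture(scope="session")
def denoised_temporal(temporal_baseline_model, reference_dataset):
    return denoise(temporal_baseline_model, reference_dataset.noisy)


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast phantom for unit tests that only need valid structure."""
    return PhantomSpec(
        shape=(6, 16, 24, 24),
        dz_um=0.25,
        axial_psf_fwhm_um=4.0,
        n_dendrites=2,
        n_somas=2,
        soma_radius_um=1.0,
        dendrite_width_um=1.5,
        rest_frames=2,
        seed=3,
    )
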