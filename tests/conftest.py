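"""Shared fixtures: spectral constants, designs and small phantoms."""

import numpy as np
import pytest

from facmri.phantom_sim import make_oil_phantom, rasterize_phantom, simulate_echo_images
from facmri.recon import EchoImageSeries
from facmri.sequence_design import default_cardiac_design
from facmri.triglyceride_model import SpectralConstants, TriglycerideComposition


@pytest.fixture(scope="session")
def consts():
    return SpectralConstants()


@pytest.fixture(scope="session")
def design32():
    """Reference protocol scaled to a 32x32 matrix."""
    return default_cardiac_design(matrix_size=32, n_spokes_per_te=48)


@pytest.fixture(scope="session")
def te16(design32):
    return np.asarray(design32.te_list)


@pytest.fixture(scope="session")
def olive_comp():
    return TriglycerideComposition(cl=17.6, ndb=2.94, nmidb=0.39)


@pytest.fixture(scope="session")
def small_phantom_truth():
    """Rasterised 32x32 oil phantom with a uniform on-grid field map."""
    from dataclasses import replace

    defn = make_oil_phantom(32)
    defn = replace(defn, field_map_poly=np.array([[40.0]]))
    return rasterize_phantom(defn)


@pytest.fixture(scope="session")
def small_phantom_images(small_phantom_truth, design32, consts):
    """Noiseless echo images of the small phantom (inverse-crime free fit input)."""
    imgs = simulate_echo_images(small_phantom_truth, design32, consts)
    return EchoImageSeries(images=imgs, stage="denoised", design=design32)
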