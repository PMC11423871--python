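"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from spindlenematic.synthetic_data import (FluctParams, SpindleGroundTruth,
                                           default_voids,
                                           render_polscope_movie)

# canonical spindle geometry used throughout (um)
L0, R_BELT, R_CAP = 15.2, 8.0, 4.0


@pytest.fixture(scope="session")
def clean_truth():
    """Void-free, noise-free, fluctuation-free spindle."""
    return SpindleGroundTruth(n_frames=4, noise_sd=0.0,
                              fluct=FluctParams(amplitude=0.0), seed=0)


@pytest.fixture(scope="session")
def clean_movie(clean_truth):
    return render_polscope_movie(clean_truth)


@pytest.fixture(scope="session")
def voided_truth():
    """Spindle with a realistic 20-void population, no noise."""
    voids = default_voids(n_chr=20, beta=11.0, waist=1.0, plate_radius=6.5,
                          seed=3)
    return SpindleGroundTruth(n_frames=4, noise_sd=0.0, pixel_size=0.15,
                              fluct=FluctParams(amplitude=0.0), voids=voids,
                              seed=3)


@pytest.fixture(scope="session")
def voided_movie(voided_truth):
    return render_polscope_movie(voided_truth)
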