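"""Shared synthetic-video fixtures for the test suite."""

import numpy as np
import pytest

from stlapse import FixtureSpec, PreprocessConfig, ReferenceSpec, fixture_sequence
from stlapse import synthetic


@pytest.fixture
def preproc_config():
    """Pre-processing settings used across fixtures (sigma 1.5 px suits the
    radius-4..6 blobs the fixtures render)."""
    return PreprocessConfig(
        smooth_sigma=1.5, thresh_mask=0.08, thresh_trim=0.15
    )


@pytest.fixture
def linear_spec():
    """Small dark blob entering after 6 frames and leaving 6 before the end."""
    return FixtureSpec(
        size=(120, 160),
        fps=20,
        n_frames=100,
        trajectory=synthetic.linear(30, 40, 9.0, 4.0),
        blob_radius=4,
        lead_empty=6,
        tail_empty=6,
    )


@pytest.fixture
def linear_seq(linear_spec):
    return fixture_sequence(linear_spec)


@pytest.fixture
def first_ref():
    return ReferenceSpec(mode="first")
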