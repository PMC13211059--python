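"""Shared fixtures: default phantom geometry and small deterministic cohorts."""

import numpy as np
import pytest

from lgenoise import phantom


@pytest.fixture(scope="session")
def default_spec():
    return phantom.PhantomSpec(scar_angle_span=np.pi / 2)


@pytest.fixture(scope="session")
def default_mask(default_spec):
    return phantom.make_annulus_mask(default_spec)


@pytest.fixture(scope="session")
def clean_image(default_spec, default_mask):
    return phantom.render_clean_image(default_mask, default_spec.levels)


@pytest.fixture(scope="session")
def paired_sources_small():
    """12 patients x 3 slices of paired REAL / DM-like / GAN-like phantoms."""
    return phantom.make_paired_sources(12, 3, seed=42)
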