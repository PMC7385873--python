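import dataclasses
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from iclcentration import CohortParams, RenderConfig, render_eye, sample_cohort


@pytest.fixture(scope="session")
def clean_render_cfg() -> RenderConfig:
    """Noiseless, gradient-free render for exact-recovery checks."""
    return RenderConfig(noise_sigma=0.0, illumination_gradient=0.0)


@pytest.fixture(scope="session")
def sample_eye():
    """A representative right eye with moderate superonasal offsets."""
    eyes = sample_cohort(CohortParams(n_eyes=8, od_fraction=1.0), seed=42)
    return eyes[0]


@pytest.fixture(scope="session")
def clean_render(sample_eye, clean_render_cfg):
    """(image, ground-truth sidecar) of the sample eye, noiseless."""
    return render_eye(sample_eye, clean_render_cfg)


@pytest.fixture(scope="session")
def noisy_render(sample_eye):
    return render_eye(sample_eye, RenderConfig(seed=1))


def make_eye(**overrides):
    """Hand-built geometry with explicit offsets; kwargs override defaults."""
    from iclcentration import EyeGeometry

    defaults = dict(
        eye_id="eye_test",
        laterality="OD",
        wtw_mm=10.28,
        corneal_vertical_mm=9.69,
        pupil_center_mm=(0.28, 0.27),
        pupil_diameters_mm=(2.54, 2.43),
        hole_center_mm=(0.16, 0.30),
        kappa_offset_mm=(0.15, 0.0),
    )
    defaults.update(overrides)
    return EyeGeometry(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
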