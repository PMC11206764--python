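import numpy as np
import pytest

from mphsim.imaging_io import VoxelImage
from mphsim.synthetic import FixtureSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240620)


@pytest.fixture
def small_image():
    """A 6x5x4 ramp image with anisotropic spacing and offset origin."""
    vals = np.arange(120, dtype=float).reshape(6, 5, 4)
    return VoxelImage(vals, spacing=(1.0, 2.0, 0.5), origin=(-3.0, 1.0, 2.5))


@pytest.fixture
def clean_spec():
    """Noise-free coarse fixture spec used by deterministic round trips."""
    return FixtureSpec(
        seed=11,
        anat_shape=(26, 26, 20),
        anat_spacing_mm=(1.0, 1.0, 1.0),
        noise_gv=0.0,
        anat_noise=0.0,
        fiducial_gv=0.0,
    )


@pytest.fixture(scope="session")
def fast_case_dir(tmp_path_factory):
    """A small seeded synthetic case directory shared across pipeline tests."""
    from mphsim.synthetic import generate_case_dir

    spec = FixtureSpec(
        seed=7, anat_shape=(26, 26, 20), anat_spacing_mm=(1.0, 1.0, 1.0)
    )
    out = tmp_path_factory.mktemp("case") / "case7"
    generate_case_dir(spec, out, t_end=400.0)
    return out
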