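import numpy as np
import pytest

from wvtomo import AcquisitionPlan, OpticsConfig, PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def optics():
    return OpticsConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_plan():
    """Single-tile, two-section plan on a small camera crop."""
    return AcquisitionPlan(
        fov_pixels=(64, 64), pixel_size_um=0.325, overlap_um=3.25,
        z_planes_per_section=2, z_step_um=2.0, section_thickness_um=4.0,
        imaging_depth_um=1.5, n_sections=2,
    )


@pytest.fixture(scope="session")
def nucleus_phantom():
    """Nuclei-only phantom with generous separation for detection tests."""
    cfg = PhantomConfig(
        volume_shape_vox=(128, 128, 40), voxel_size_um=0.5,
        n_neurons=0, n_nuclei=20, nucleus_min_separation_um=8.0,
        soma_overlap_fraction=0.0, seed=7,
    )
    return generate_phantom(cfg)
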