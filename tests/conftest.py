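import numpy as np
import pytest

from swirtrack import (
    AcquisitionConfig,
    LaserChannel,
    OrganSpec,
    PhantomSpec,
    generate,
)


def four_channel_config(**kwargs) -> AcquisitionConfig:
    """The four-laser cycle at 7.8 ms per frame behind a 1150 nm long-pass."""
    defaults = dict(longpass_nm=1150.0)
    defaults.update(kwargs)
    return AcquisitionConfig(
        cycle=(
            LaserChannel("ICG", 785.0, 49.0, 7.8),
            LaserChannel("JuloChrom5", 892.0, 81.0, 7.8),
            LaserChannel("Chrom7", 968.0, 113.0, 7.8),
            LaserChannel("JuloFlav7", 1064.0, 165.0, 7.8),
        ),
        **defaults,
    )


def single_organ_spec(**kwargs) -> PhantomSpec:
    """Small single-channel, single-organ phantom for fast stage tests."""
    config = AcquisitionConfig(
        cycle=(LaserChannel("ICG", 785.0, 49.0, 7.8),),
        longpass_nm=1150.0,
        detector_width_px=64,
        detector_height_px=80,
    )
    defaults = dict(
        height=80,
        width=64,
        organs=(OrganSpec("liver", "ICG", (0.0, -6.0), (5.0, 5.0), 1200.0),),
        body_half_width=14.0,
        body_half_length=24.0,
        anterior_distance=20.0,
        config=config,
        duration_frames=30,
        seed=11,
    )
    defaults.update(kwargs)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noiseless, stationary single-organ phantom (shared, read-only)."""
    spec = single_organ_spec(
        poisson_noise=False,
        read_noise_sigma=0.0,
        step_sigma_px=0.0,
        turn_sigma_rad=0.0,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def moving_phantom():
    """Noiseless moving single-organ phantom with exact markers."""
    spec = single_organ_spec(
        poisson_noise=False,
        read_noise_sigma=0.0,
        step_sigma_px=1.0,
        turn_sigma_rad=0.08,
        duration_frames=40,
        seed=23,
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
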