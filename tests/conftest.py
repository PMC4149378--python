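import numpy as np
import pytest
from hypothesis import settings

import stainkinetics as sk

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=40, database=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> sk.ExactModelParams:
    return sk.ExactModelParams()


@pytest.fixture(scope="session")
def noiseless_config() -> sk.PhantomConfig:
    return sk.PhantomConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_config, default_params):
    return sk.simulate_stack(noiseless_config, default_params)


@pytest.fixture(scope="session")
def centre_ray(noiseless_stack):
    """Horizontal ray from the left image edge to the annulus centre."""
    ny, nx = noiseless_stack[0].pixels.shape
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    return (0.0, cy), (cx, cy)


@pytest.fixture(scope="session")
def small_edge_config() -> sk.PhantomConfig:
    """Thin-walled phantom kept small so many noisy renders stay cheap."""
    return sk.PhantomConfig(
        outer_radius=1.0, wall_thickness=0.7, noise_sd=0.0, beam_hardening_slope=0.0
    )


def true_boundary_offset_mm(cfg: sk.PhantomConfig, img) -> float:
    """Distance from the left image edge to the outer annulus boundary
    along the horizontal centre ray, mm."""
    nx = img.pixels.shape[1]
    cx = (nx - 1) / 2.0
    return cx * cfg.voxel_mm - cfg.outer_radius
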