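import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def oracle_phantom_geometry():
    """Phantom geometry for closed-form sharpness oracles.

    Finer grid and a flatter boundary than the acquisition-like default,
    so the linear-ramp edge is well resolved for all tested widths and the
    detected line is locally tangent to the boundary.
    """
    return dict(
        pixel_spacing_mm=0.75,
        shape=(256, 256),
        semi_axes_mm=(60.0, 45.0),
        tilt_deg=25.0,
        noise_sd=0.0,
    )
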