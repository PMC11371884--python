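import numpy as np
import pytest

from condyseat import (
    PhantomSpec,
    build_direction_set,
    rasterize_phantom,
)


@pytest.fixture(scope="session")
def ds198():
    return build_direction_set(198)


@pytest.fixture(scope="session")
def concentric_spec():
    """Concentric condyle/fossa spheres, full shell: every ray gap is 2 mm."""
    return PhantomSpec(fossa_coverage_deg=180.0)


@pytest.fixture(scope="session")
def concentric_volume(concentric_spec):
    return rasterize_phantom(concentric_spec)


@pytest.fixture(scope="session")
def capped_spec():
    """Concentric spheres with the default 80-degree fossa cap."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def capped_volume(capped_spec):
    return rasterize_phantom(capped_spec)


def random_shell_spec(rng, full_shell=True, spacing=0.4):
    """A random displaced-sphere phantom; full shells keep every ray on the
    line-sphere branch of the analytic oracle."""
    rc = 5.0 * rng.uniform(0.9, 1.1)
    ri = 7.0 * rng.uniform(0.9, 1.1)
    mag = rng.uniform(0.0, ri - rc - 0.4)
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return PhantomSpec(
        condyle_radius_mm=rc,
        fossa_inner_radius_mm=ri,
        fossa_coverage_deg=180.0 if full_shell else 80.0,
        displacement_mm=tuple(v * mag),
        spacing_mm=spacing,
    )
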