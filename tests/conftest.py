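import numpy as np
import pytest

from dermoct.phantom import (
    PhantomSpec,
    ScanGeometry,
    VesselSpec,
    WaveSpec,
    generate_octa_stack,
    generate_structural_volume,
)

SMALL_GEOMETRY = ScanGeometry(n_alines=128, n_bscans=32, n_repeats=5, n_depth=256)

OCE_GEOMETRY = ScanGeometry(n_alines=500, n_bscans=128, n_repeats=1, n_depth=64)

OCTA_GEOMETRY = ScanGeometry(n_alines=128, n_bscans=64, n_repeats=5, n_depth=256)


def oce_spec(frequency_hz=5000.0, n_pushes=1, c=2.5, noise=0.05, seed=0, **kw):
    return PhantomSpec(
        geometry=OCE_GEOMETRY,
        top_surface_um=40.0,
        bottom_surface_um=200.0,
        wave=WaveSpec(
            frequency_hz=frequency_hz, n_pushes=n_pushes, group_velocity_m_s=c
        ),
        phase_noise_rad=noise,
        seed=seed,
        **kw,
    )


def octa_spec(seed=0, diameters=(40.0, 80.0), decorrelation=1.0):
    g = OCTA_GEOMETRY
    xs = (400.0, 900.0)[: len(diameters)]
    vessels = tuple(
        VesselSpec.along_slow_axis(
            x_um=x, z_um=400.0, geometry=g, lumen_diameter_um=d, decorrelation=decorrelation
        )
        for x, d in zip(xs, diameters)
    )
    return PhantomSpec(geometry=g, vessels=vessels, seed=seed)


@pytest.fixture(scope="session")
def structural_default():
    """Default speckle phantom (flat surfaces 200/750 um) plus truth."""
    return generate_structural_volume(PhantomSpec(geometry=SMALL_GEOMETRY, seed=11))


@pytest.fixture(scope="session")
def octa_default():
    """Two-vessel OCTA stack (40 and 80 um lumens, full decorrelation)."""
    return generate_octa_stack(octa_spec(seed=4))
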