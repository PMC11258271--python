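"""Shared phantom fixtures. Everything is generated at test time from seeds."""

import numpy as np
import pytest

from cmrprecision.phantom import InfarctWedge, PhantomSpec, generate_cine_phantom, generate_lge_phantom

# endo_es/endo_ed ratio giving a 66% ejection fraction for a uniform cylinder:
# EF = 1 - (r_es/r_ed)^2
EF66_RATIO = float(np.sqrt(1.0 - 0.66))


@pytest.fixture(scope="session")
def cine_spec() -> PhantomSpec:
    """Small noiseless cine phantom with true EF 66% and papillary muscles."""
    return PhantomSpec(
        n_slices=6, rows=128, cols=128, pixel_spacing=(0.8, 0.8), n_phases=10,
        endo_radius_ed=18.0, endo_radius_es=18.0 * EF66_RATIO,
        wall_thickness_ed=9.0,
        papillary=[((6.0, 3.0), 2.5), ((-5.0, 4.0), 2.0)],
        seed=11,
    )


@pytest.fixture(scope="session")
def cine_phantom(cine_spec):
    return generate_cine_phantom(cine_spec)


@pytest.fixture(scope="session")
def lge_spec() -> PhantomSpec:
    """LGE phantom: 120° wedge, transmurality 0.6 -> exactly 20% infarct."""
    return PhantomSpec(
        n_slices=5, rows=160, cols=160, pixel_spacing=(0.6, 0.6),
        endo_radius_ed=18.0, endo_radius_es=11.0, wall_thickness_ed=9.0,
        infarct_wedge=InfarctWedge(angle_start_deg=-60.0, angle_end_deg=60.0,
                                   transmurality=0.6),
        seed=5,
    )


@pytest.fixture(scope="session")
def lge_phantom(lge_spec):
    return generate_lge_phantom(lge_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
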