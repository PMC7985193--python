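"""Shared fixtures: small phantoms and libraries, generated at test time."""

import numpy as np
import pytest

from murineecho.phantom import (
    BmodePhantomSpec,
    MmodePhantomSpec,
    make_bmode_phantom,
    make_library,
    make_mmode_phantom,
    phantom_seeds,
)


@pytest.fixture(scope="session")
def bmode_spec():
    # short loop (~2 cardiac cycles) keeps rendering cheap
    return BmodePhantomSpec(rng_seed=7, n_frames=42, tilt_deg=2.0)


@pytest.fixture(scope="session")
def bmode_phantom(bmode_spec):
    return make_bmode_phantom(bmode_spec)


@pytest.fixture(scope="session")
def small_library():
    return make_library(8, rng_seed=5)


@pytest.fixture(scope="session")
def mmode_spec():
    return MmodePhantomSpec(rng_seed=3)


@pytest.fixture(scope="session")
def mmode_phantom(mmode_spec):
    return make_mmode_phantom(mmode_spec)


@pytest.fixture(scope="session")
def mmode_seeds(mmode_spec):
    return phantom_seeds(mmode_spec)


def half_ellipse_contour(L=8.0, D=4.0, n_arc=512, origin=(2.0, 5.0)):
    """High-resolution half-ellipse test contour: base at x=origin[0]."""
    from murineecho.types import LvContour, Phase

    x0, y0 = origin
    phi = np.linspace(np.pi / 2, -np.pi / 2, n_arc)
    verts = np.column_stack(
        [x0 + L * np.cos(phi), y0 + (D / 2) * np.sin(phi)]
    )
    return LvContour(
        vertices=verts, basal_indices=(0, n_arc - 1), phase=Phase.ED
    ).validate()
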