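"""Shared fixtures: small synthetic samples reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from exmprofiler import (GroundTruth, LabelingGeometry, generate_curves,
                         load_geometry, make_fixture)

try:
    from hypothesis import settings
    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=25)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def igg_pre() -> LabelingGeometry:
    return load_geometry("igg_pre")


@pytest.fixture(scope="session")
def small_fixture(igg_pre):
    """A compact expanded-microtubule sample: image + table + manifest.

    Three filaments at 3.2x expansion in an 8 x 8 µm field, rendered at
    4 nm/px — large enough to trace, small enough for fast tests.
    """
    curves = generate_curves(3, field=(8000.0, 8000.0), curvature_scale=3e-5,
                             min_separation=1200.0, seed=11, margin=800.0)
    truth = GroundTruth(curves=curves, geometry=igg_pre, expansion=3.2,
                        density=400.0, background_density=0.3, seed=11,
                        field_size=(8000.0, 8000.0))
    image, table, manifest = make_fixture(truth, pixel_size=4.0)
    return image, table, manifest, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def long_fixture(igg_pre):
    """Two long filaments (16 x 16 µm field) for length-recovery checks.

    End erosion by the tracing blur costs a fixed few hundred nm per
    filament, so percentage-level length recovery needs filaments much
    longer than the blur.
    """
    curves = generate_curves(2, field=(16000.0, 16000.0),
                             curvature_scale=3e-5, min_separation=2000.0,
                             seed=21, margin=900.0)
    truth = GroundTruth(curves=curves, geometry=igg_pre, expansion=3.2,
                        density=400.0, background_density=0.3, seed=21,
                        field_size=(16000.0, 16000.0))
    image, table, manifest = make_fixture(truth, pixel_size=4.0)
    return image, table, manifest, truth
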