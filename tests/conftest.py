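from __future__ import annotations

import numpy as np
import pytest

from gonioagree import (
    ImageAnnotation,
    LayerLabel,
    PolygonAnnotation,
    SimConfig,
    simulate_panel,
)


def rect(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


@pytest.fixture
def square_annotation() -> ImageAnnotation:
    """One 10×10 image fully covered by a single IR rectangle."""
    return ImageAnnotation(
        image_id="img",
        image_size=(10, 10),
        annotator_id="a1",
        polygons=[PolygonAnnotation(LayerLabel.IR, rect(0, 0, 10, 10))],
    )


@pytest.fixture(scope="session")
def jittered_panel():
    """A small jittered panel reused by several test modules."""
    config = SimConfig(
        image_size=(96, 72),
        n_images=3,
        n_annotators=4,
        boundary_jitter_sigma=1.5,
        extent_fraction=0.9,
        omission_prob=0.0,
        seed=11,
    )
    return simulate_panel(config)


@pytest.fixture(scope="session")
def jittered_maps(jittered_panel):
    return jittered_panel.label_maps()


@pytest.fixture(scope="session")
def perfect_panel():
    """Zero jitter, zero bias, full extent, zero omission: every annotator
    reproduces the ground truth exactly."""
    config = SimConfig(
        image_size=(80, 60),
        n_images=2,
        n_annotators=5,
        boundary_jitter_sigma=0.0,
        boundary_bias=0.0,
        extent_fraction=1.0,
        omission_prob=0.0,
        seed=5,
    )
    return simulate_panel(config)
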