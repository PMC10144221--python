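"""Shared fixtures: rendered structures are expensive, so build them once."""

from __future__ import annotations

import numpy as np
import pytest

from printability.imaging import binarize, segment
from printability.metrics import CadTarget
from printability.synthetic import RenderSpec, render_structure


@pytest.fixture(scope="session")
def line_render():
    spec = RenderSpec(cad=CadTarget(kind="line"), seed=101, rotation=4.0)
    return render_structure(spec)


@pytest.fixture(scope="session")
def circle_render():
    spec = RenderSpec(cad=CadTarget(kind="circle"), seed=102, rotation=11.0)
    return render_structure(spec)


@pytest.fixture(scope="session")
def angle_render():
    spec = RenderSpec(cad=CadTarget(kind="angle"), seed=103, rotation=17.0)
    return render_structure(spec)


@pytest.fixture(scope="session")
def line_components(line_render):
    img, _ = line_render
    return segment(binarize(img))


@pytest.fixture(scope="session")
def circle_components(circle_render):
    img, _ = circle_render
    return segment(binarize(img))


@pytest.fixture(scope="session")
def angle_components(angle_render):
    img, _ = angle_render
    return segment(binarize(img))


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    """Boolean disc, for masks built without the renderer."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius_px**2
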