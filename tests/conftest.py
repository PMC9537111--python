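"""Shared fixtures: published anchor sets, fitted models, oracle circle fit."""

from __future__ import annotations

import numpy as np
import pytest

from arcequate import AnchorTriplet, fit_circle_arc

# Published anchor triplets of the four analysis blocks (nadir, midpoint,
# zenith), as (x1,y1),(x2,y2),(x3,y3).
PUBLISHED_ANCHORS = {
    "total": ((2, 1), (12, 8), (28, 25)),
    "high": ((2, 1), (16, 10), (27, 20)),
    "medium": ((2, 0), (16, 10), (23, 16)),
    "low": ((3, 1), (9, 5), (25, 15)),
}


def make_anchors(points) -> AnchorTriplet:
    (x1, y1), (x2, y2), (x3, y3) = points
    return AnchorTriplet(x1=x1, y1=y1, x2=x2, y2=y2, x3=x3, y3=y3)


@pytest.fixture(scope="session")
def total_anchors() -> AnchorTriplet:
    return make_anchors(PUBLISHED_ANCHORS["total"])


@pytest.fixture(scope="session")
def total_model():
    return fit_circle_arc(make_anchors(PUBLISHED_ANCHORS["total"]))


@pytest.fixture(scope="session")
def published_models():
    return {name: fit_circle_arc(make_anchors(pts))
            for name, pts in PUBLISHED_ANCHORS.items()}


def circle_through_points(p1, p2, p3):
    """Independent oracle: circle through three points by solving the
    general-equation linear system x^2 + y^2 + D x + E y + F = 0.

    Algebraically equivalent to intersecting perpendicular bisectors;
    shares no code with the closed-form fit under test.
    """
    pts = np.array([p1, p2, p3], dtype=float)
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(3)])
    b = -(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    D, E, F = np.linalg.solve(A, b)
    xc, yc = -D / 2.0, -E / 2.0
    r = float(np.sqrt(xc**2 + yc**2 - F))
    return float(xc), float(yc), r
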