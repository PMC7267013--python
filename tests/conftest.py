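"""Shared fixtures: analytic contours and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from leafqtl.geometry import Outline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_ellipse(a=2.0, b=1.0, n=2000, base_at_vertex=False, **meta) -> Outline:
    """Ellipse sampled uniformly in its angular parameter.

    With ``base_at_vertex`` the first point sits on the minor-axis vertex
    (0, -b), the blade-base convention.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    if base_at_vertex:
        pts = np.column_stack([a * np.sin(t), -b * np.cos(t)])
    else:
        pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    return Outline(points=pts, **meta)


def make_circle(r=1.0, n=1000, **meta) -> Outline:
    return make_ellipse(a=r, b=r, n=n, **meta)


def make_star_polygon(rng: np.random.Generator, n=200, wobble=0.15) -> Outline:
    """Random smooth star-shaped polygon (positive radial function)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = np.ones(n)
    for harm in range(1, 6):
        amp = wobble / harm * rng.uniform(0.2, 1.0)
        r += amp * np.cos(harm * theta + rng.uniform(0, 2 * np.pi))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Outline(points=pts)


def line_average_phenotypes(outlines, deme_of_line=None):
    """Per-line leaf-average phenotypes in the simulator's common frame.

    Simulated leaves already share location/rotation/scale, so unit tests
    can average without the GPA pass the full pipeline performs.
    """
    from leafqtl.scan import ShapePhenotype

    by_line: dict = {}
    for o in outlines:
        by_line.setdefault(o.line_id, []).append(o.points)
    phen = []
    for lid, pts in by_line.items():
        m = np.mean(pts, axis=0)
        phen.append(
            ShapePhenotype(
                line_id=lid,
                deme=(deme_of_line or {}).get(lid, "high"),
                z=np.concatenate([m[:, 0], m[:, 1]]),
            )
        )
    return phen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
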