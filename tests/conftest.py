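"""Shared fixtures and independent geometric oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def circle_points(n: int = 512, radius: float = 1.0, start_angle: float = 0.0) -> np.ndarray:
    t = start_angle + 2.0 * np.pi * np.arange(n) / n
    return radius * np.column_stack([np.cos(t), np.sin(t)])


def ellipse_points(a: float = 2.0, b: float = 1.0, n: int = 512) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


def random_blob(rng: np.random.Generator, n: int = 256) -> np.ndarray:
    """A random smooth simple contour: low-order radial Fourier profile."""
    t = 2.0 * np.pi * np.arange(n) / n
    r = np.ones(n)
    for k in range(2, 7):
        amp = rng.uniform(0.0, 0.12)
        r += amp * np.cos(k * t + rng.uniform(0.0, 2.0 * np.pi))
    r *= rng.uniform(20.0, 60.0)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def point_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to a closed polyline (exact, per segment)."""
    A = poly
    B = np.roll(poly, -1, axis=0)
    AB = B - A
    L2 = np.maximum((AB**2).sum(axis=1), 1e-300)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        tt = np.clip(((p - A) * AB).sum(axis=1) / L2, 0.0, 1.0)
        proj = A + tt[:, None] * AB
        out[i] = np.sqrt(((p - proj) ** 2).sum(axis=1)).min()
    return out


def symmetric_hausdorff(P: np.ndarray, Q: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two closed polygons."""
    return max(point_to_polyline(P, Q).max(), point_to_polyline(Q, P).max())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def default_head():
    from spermshape import HeadParams, make_head_contour

    return make_head_contour(HeadParams(), 256)
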