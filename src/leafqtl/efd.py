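"""Elliptic Fourier decomposition of closed contours.

A closed outline (x(t), y(t)) is expanded in a truncated Fourier series;
harmonic n contributes the quadruple (a_n, b_n, c_n, d_n) plus the DC terms
(A0, C0).  Coefficients are computed with the classical piecewise-linear
(Kuhl-Giardina) integrals.  Two parameterizations are supported:

``uniform``
    Landmarks are equally spaced in the curve parameter (the natural choice
    for equal-angle landmark sampling, and the default).  A pure ellipse
    sampled uniformly then decomposes exactly to its first harmonic, and a
    centred shape has A0 = C0 = 0.
``chord``
    Chord-length (approximate arc-length) parameterization with the total
    perimeter as the period.

"Shape information explained" by the first N harmonics is measured as
reconstruction R-squared (1 - SSE/SST) per shape, averaged over shapes;
a normalized Fourier power variant is exposed as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .geometry import Outline

logger = logging.getLogger(__name__)

__all__ = [
    "EFDescriptor",
    "efd_decompose",
    "efd_reconstruct",
    "fourier_basis",
    "fit_ef_curve",
    "variance_explained_profile",
    "select_order",
    "order_from_profile",
]


@dataclass
class EFDescriptor:
    """Elliptic Fourier coefficients of one closed contour up to order N.

    ``dc`` holds the centroid terms (A0, C0); ``coeffs`` is an (N, 4) array
    of per-harmonic quadruples (a_n, b_n, c_n, d_n) in aligned-shape units.
    """

    order: int
    dc: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.dc = np.asarray(self.dc, dtype=float)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.coeffs.shape != (self.order, 4):
            raise ValueError(
                f"coeffs must have shape ({self.order}, 4), got {self.coeffs.shape}"
            )
        if not (np.all(np.isfinite(self.dc)) and np.all(np.isfinite(self.coeffs))):
            raise ValueError("non-finite Fourier coefficients")


def _parameter(points: np.ndarray, parameterization: str) -> np.ndarray:
    k = len(points)
    if parameterization == "uniform":
        return np.arange(k + 1) / k
    if parameterization == "chord":
        d = np.diff(np.vstack([points, points[:1]]), axis=0)
        dt = np.hypot(d[:, 0], d[:, 1])
        t = np.concatenate([[0.0], np.cumsum(dt)])
        return t / t[-1]
    raise ValueError(f"unknown parameterization {parameterization!r}")


def efd_decompose(
    shape: Outline, order: int, parameterization: str = "uniform"
) -> EFDescriptor:
    """Closed-contour elliptic Fourier coefficients of a landmark polygon.

    Piecewise-linear closed-form integrals over the polygon edges with unit
    period; requires at least ``2*order + 1`` landmarks.
    """
    pts = shape.points
    if len(pts) < 2 * order + 1:
        raise ValueError(
            f"need at least 2*order+1 = {2 * order + 1} landmarks, got {len(pts)}"
        )
    t = _parameter(pts, parameterization)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("degenerate contour parameterization")
    closed = np.vstack([pts, pts[:1]])
    dxy = np.diff(closed, axis=0)
    slopes = dxy / dt[:, None]  # (K, 2)

    n = np.arange(1, order + 1)[:, None]  # (N, 1)
    phi = 2.0 * np.pi * t[None, :]  # (1, K+1)
    cosv = np.cos(n * phi)
    sinv = np.sin(n * phi)
    dcos = cosv[:, 1:] - cosv[:, :-1]
    dsin = sinv[:, 1:] - sinv[:, :-1]
    const = 1.0 / (2.0 * n.ravel() ** 2 * np.pi**2)
    a = const * (dcos @ slopes[:, 0])
    b = const * (dsin @ slopes[:, 0])
    c = const * (dcos @ slopes[:, 1])
    d = const * (dsin @ slopes[:, 1])
    # DC terms: exact integral of the piecewise-linear coordinate functions
    mid = 0.5 * (closed[1:] + closed[:-1])
    dc = (mid * dt[:, None]).sum(axis=0)
    return EFDescriptor(order=order, dc=dc, coeffs=np.column_stack([a, b, c, d]))


def efd_reconstruct(desc: EFDescriptor, k: int) -> Outline:
    """Evaluate the truncated series at ``k`` equally spaced parameter values."""
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    t = np.arange(k) / k
    n = np.arange(1, desc.order + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cosv, sinv = np.cos(phi), np.sin(phi)
    a, b, c, d = desc.coeffs.T
    x = desc.dc[0] + a @ cosv + b @ sinv
    y = desc.dc[1] + c @ cosv + d @ sinv
    # validation relaxed: an all-zero-harmonic descriptor legitimately
    # reconstructs to k coincident points
    return Outline(points=np.column_stack([x, y]), closed=True, validate=False)


@lru_cache(maxsize=32)
def fourier_basis(k: int, order: int) -> np.ndarray:
    """Uniform-parameter Fourier design matrix, shape (k, 2*order + 1)."""
    t = np.arange(k) / k
    cols = [np.ones(k)]
    for n in range(1, order + 1):
        cols.append(np.cos(2.0 * np.pi * n * t))
        cols.append(np.sin(2.0 * np.pi * n * t))
    return np.column_stack(cols)


@lru_cache(maxsize=32)
def _basis_projector(k: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    """(pinv, hat): least-squares coefficient extractor and projection matrix."""
    b = fourier_basis(k, order)
    pinv = np.linalg.solve(b.T @ b, b.T)
    return pinv, b @ pinv


def fit_ef_curve(points: np.ndarray, order: int) -> tuple[EFDescriptor, np.ndarray]:
    """Least-squares elliptic Fourier fit of a landmark polygon.

    Projects the x- and y-coordinate sequences onto the shared
    uniform-parameter Fourier basis; returns the descriptor and the fitted
    (K, 2) curve at the landmark positions.
    """
    pts = np.asarray(points, dtype=float)
    k = len(pts)
    if k < 2 * order + 1:
        raise ValueError(f"need at least {2 * order + 1} landmarks, got {k}")
    pinv, hat = _basis_projector(k, order)
    coef = pinv @ pts  # (2*order+1, 2)
    fitted = hat @ pts
    dc = coef[0]
    quads = np.empty((order, 4))
    quads[:, 0] = coef[1::2, 0]
    quads[:, 1] = coef[2::2, 0]
    quads[:, 2] = coef[1::2, 1]
    quads[:, 3] = coef[2::2, 1]
    return EFDescriptor(order=order, dc=dc, coeffs=quads), fitted


def variance_explained_profile(
    shapes: Sequence[Outline], max_order: int, method: str = "reconstruction"
) -> np.ndarray:
    """Cumulative fraction of shape information captured by harmonics 1..N.

    ``reconstruction`` (default): per shape, 1 - SSE(N)/SST where SSE(N) is
    the summed squared landmark distance to the order-N least-squares
    reconstruction and SST the summed squared distance from the shape
    centroid; fractions are averaged over shapes.  ``power``: cumulative
    normalized Fourier power of the harmonic quadruples.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if len(shapes) == 0:
        raise ValueError("need at least one shape")
    profiles = np.zeros((len(shapes), max_order))
    for i, s in enumerate(shapes):
        pts = s.points
        k = len(pts)
        centered = pts - pts.mean(axis=0)
        # spectral energy per harmonic via the real FFT of each coordinate;
        # Parseval gives the nested least-squares SSE without refitting
        nyq = k // 2
        energy = np.zeros(nyq + 1)
        for col in range(2):
            f = np.fft.rfft(centered[:, col])
            e = np.abs(f) ** 2 / k * 2.0
            e[0] = 0.0  # centred
            if k % 2 == 0:
                e[-1] /= 2.0
            energy[: len(e)] += e
        sst = float(np.sum(centered**2))
        if sst <= 0:
            profiles[i] = 1.0
            continue
        cum = np.cumsum(energy[1:])
        cum = np.concatenate([cum, np.full(max(0, max_order - len(cum)), cum[-1])])
        if method == "reconstruction":
            profiles[i] = cum[:max_order] / sst
        elif method == "power":
            total = cum[-1]
            profiles[i] = cum[:max_order] / (total if total > 0 else 1.0)
        else:
            raise ValueError(f"unknown method {method!r}")
    prof = profiles.mean(axis=0)
    return np.clip(np.maximum.accumulate(prof), 0.0, 1.0)


def order_from_profile(profile: Sequence[float], threshold: float = 0.95) -> int:
    """Smallest order whose cumulative explained fraction exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    prof = np.asarray(profile, dtype=float)
    above = np.nonzero(prof > threshold)[0]
    if above.size == 0:
        warnings.warn(
            f"no harmonic order reaches the {threshold:.0%} threshold "
            f"(max explained {prof[-1]:.3f}); returning the maximum order {len(prof)}",
            stacklevel=2,
        )
        return len(prof)
    return int(above[0]) + 1


def select_order(
    shapes: Sequence[Outline],
    max_order: int = 6,
    threshold: float = 0.95,
    method: str = "reconstruction",
) -> int:
    """Harmonic order selection by the explained-variation threshold rule."""
    profile = variance_explained_profile(shapes, max_order, method=method)
    return order_from_profile(profile, threshold)
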