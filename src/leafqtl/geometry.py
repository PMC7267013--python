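"""Leaf outline geometry: equal-angle landmarking, Procrustes alignment,
scalar shape traits.

An :class:`Outline` is an ordered closed sequence of planar points tracing a
leaf margin clockwise, with the first point anchored at the blade base
(petiole junction).  Equal-angle resampling about the area centroid turns a
raw margin into a fixed-length landmark configuration; generalized Procrustes
analysis (GPA) removes location, scale and rotation so that per-line average
shapes are comparable across clonal lines; scalar descriptors (length, width,
area, broadest-chord position) summarize each configuration along its
base-tip axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import DegenerateContourError, DegenerateShapeError, GeometryError

logger = logging.getLogger(__name__)

__all__ = [
    "Outline",
    "AlignedShapeSet",
    "resample_contour",
    "procrustes_align",
    "average_shape",
    "select_landmark_count",
    "trait_descriptors",
    "outline_from_image",
]


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple closed polygon (falls back to the vertex
    mean for near-zero-area polygons)."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return points.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class Outline:
    """Closed, ordered 2-D contour of one leaf.

    Parameters
    ----------
    points : (K, 2) array
        Margin points in arbitrary planar units.  Traversal direction is
        normalized to clockwise on construction (the first point stays
        first).  Point 0 is, by convention, the blade-base point.
    closed : bool
        Whether the last point connects back to the first (always true for
        leaf margins; kept explicit for partial traces).
    id, line_id : str
        Leaf and clonal-line identifiers.
    position : str
        Tree-crown section label (``upper`` / ``middle`` / ``lower``).
    block : str
        Nursery block label.

    Notes
    -----
    "Clockwise" refers to the image convention (y axis pointing down, as
    leaves are photographed and traced); in the mathematical frame used
    here (y up) that is the positive orientation, so ingest normalizes the
    signed polygon area to be positive.
    """

    points: np.ndarray
    closed: bool = True
    id: str = ""
    line_id: str = ""
    position: str = ""
    block: str = ""
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (K, 2) array")
        if len(pts) < 3:
            raise ValueError("an outline needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("outline contains non-finite coordinates")
        if self.validate:
            d = np.diff(np.vstack([pts, pts[:1]]) if self.closed else pts, axis=0)
            if np.any(np.hypot(d[:, 0], d[:, 1]) == 0.0):
                raise ValueError("outline has two identical consecutive points")
        if self.closed and _signed_area(pts) < 0:
            # wrong traversal direction: reverse, keeping point 0 first
            pts = np.roll(pts[::-1], 1, axis=0)
        self.points = pts

    @property
    def k(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray) -> "Outline":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass
class AlignedShapeSet:
    """Outlines superimposed by generalized Procrustes analysis.

    Every member is centred on the origin and scaled to unit centroid size
    (root-mean-square landmark distance from the centroid); ``reference`` is
    the consensus configuration the rotations were fitted against.
    """

    shapes: list
    reference: np.ndarray

    def __iter__(self):
        return iter(self.shapes)

    def __len__(self):
        return len(self.shapes)


def resample_contour(outline: Outline, k: int) -> Outline:
    """Resample an outline at ``k`` landmarks on equal-angle rays.

    Rays emanate from the polygon's area centroid at angles ``2*pi*j/k``
    (j = 0..k-1) measured clockwise from the direction of the outline's
    first point (the blade base), so landmark 0 stays on the base ray.
    Each landmark is the exact intersection of its ray with the linearly
    interpolated margin.

    The outline must be star-shaped about its centroid (every ray crosses
    the margin exactly once); otherwise :class:`DegenerateContourError` is
    raised naming the first offending angle.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    pts = outline.points
    c = _polygon_centroid(pts)
    rel = pts - c
    r = np.hypot(rel[:, 0], rel[:, 1])
    if np.any(r < 1e-12):
        raise DegenerateContourError("a margin point coincides with the centroid")
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    # the normalized traversal must sweep the angle monotonically (every ray
    # crossed exactly once); a backtracking step breaks star-shapedness.
    dtheta = np.diff(np.concatenate([theta, theta[:1]]))
    dtheta = (dtheta + np.pi) % (2.0 * np.pi) - np.pi  # map to (-pi, pi]
    bad = np.nonzero(dtheta < -1e-12)[0]
    if bad.size:
        ang = float(theta[bad[0]] % (2.0 * np.pi))
        raise DegenerateContourError(
            f"outline is not star-shaped about its centroid: margin backtracks "
            f"near angle {ang:.4f} rad (a ray there crosses the margin more than once)"
        )
    cum = theta[0] + np.concatenate([[0.0], np.cumsum(dtheta)])  # length K+1
    if not math.isclose(cum[-1], theta[0] + 2.0 * np.pi, abs_tol=1e-9):
        raise DegenerateContourError(
            "outline does not wind exactly once around its centroid"
        )
    closed = np.vstack([pts, pts[:1]])
    targets = theta[0] + 2.0 * np.pi * np.arange(k) / k
    # cum is increasing; locate bracketing segment for each target angle
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(pts) - 1)
    out = np.empty((k, 2))
    for j in range(k):
        i = idx[j]
        p1, p2 = closed[i], closed[i + 1]
        u = np.array([math.cos(targets[j]), math.sin(targets[j])])
        seg = p2 - p1
        mat = np.array([[seg[0], -u[0]], [seg[1], -u[1]]])
        det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
        if abs(det) < 1e-15:
            # segment parallel to the ray: take the nearer endpoint on the ray
            out[j] = p1 if abs(cum[i] - targets[j]) < abs(cum[i + 1] - targets[j]) else p2
            continue
        rhs = c - p1
        s = (rhs[0] * mat[1, 1] - rhs[1] * mat[0, 1]) / det
        s = min(max(s, 0.0), 1.0)
        out[j] = p1 + s * seg
    return replace(outline, points=out)


def _center_and_size(points: np.ndarray) -> tuple[np.ndarray, float]:
    centered = points - points.mean(axis=0)
    size = math.sqrt(float(np.mean(np.sum(centered**2, axis=1))))
    return centered, size


def _optimal_rotation(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Orthogonal (det +1, no reflection) rotation minimizing ||x R - ref||."""
    m = x.T @ ref
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def procrustes_align(
    shapes: Sequence[Outline], tol: float = 1e-11, max_iter: int = 100
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of equal-K outlines.

    Each shape is translated to centroid zero, scaled to unit centroid size
    (RMS landmark distance from the centroid = 1) and rotated — reflections
    are never applied, preserving leaf chirality — to minimize its summed
    squared distance to the running consensus.  The consensus is initialized
    to the first shape and iterated until its change drops below ``tol`` (or
    ``max_iter`` passes); the default tolerance is well below 1e-8 so that
    re-aligning an aligned set moves no landmark by more than 1e-8.
    """
    if len(shapes) == 0:
        raise ValueError("need at least one shape")
    ks = {s.k for s in shapes}
    if len(ks) != 1:
        raise ValueError(f"all shapes must share one landmark count, got {sorted(ks)}")
    normed = []
    for s in shapes:
        centered, size = _center_and_size(s.points)
        if size < 1e-12:
            raise DegenerateShapeError(f"shape {s.id!r} has zero centroid size")
        normed.append(centered / size)
    # consensus initialized to the normalized mean shape: an already-aligned
    # set is then an exact fixed point (GPA's global orientation is neutral,
    # so a first-shape initialization would drift on re-alignment)
    mean0, msize = _center_and_size(np.mean(normed, axis=0))
    ref = mean0 / msize if msize > 1e-6 else normed[0].copy()
    aligned = normed
    for _ in range(max_iter):
        aligned = [x @ _optimal_rotation(x, ref) for x in normed]
        new_ref = np.mean(aligned, axis=0)
        new_ref, size = _center_and_size(new_ref)
        if size < 1e-12:
            raise DegenerateShapeError("degenerate consensus shape during GPA")
        new_ref = new_ref / size
        if float(np.max(np.abs(new_ref - ref))) < tol:
            ref = new_ref
            break
        ref = new_ref
    # canonical orientation: the consensus base-tip axis (landmark 0 to
    # landmark K//2) points along +y, so the aligned frame does not depend
    # on the global orientation of the input
    axis = ref[len(ref) // 2] - ref[0]
    alpha = math.atan2(axis[0], axis[1])
    rot = np.array(
        [[math.cos(alpha), -math.sin(alpha)], [math.sin(alpha), math.cos(alpha)]]
    )
    ref = ref @ rot.T
    aligned = [x @ _optimal_rotation(x, ref) for x in normed]
    out = [s.with_points(a) for s, a in zip(shapes, aligned)]
    return AlignedShapeSet(shapes=out, reference=ref)


def average_shape(shapes: Sequence[Outline]) -> Outline:
    """Arithmetic per-landmark average of aligned outlines (one clonal line)."""
    if len(shapes) == 0:
        raise ValueError("cannot average an empty list of shapes")
    ks = {s.k for s in shapes}
    if len(ks) != 1:
        raise ValueError("all shapes must share one landmark count")
    mean_pts = np.mean([s.points for s in shapes], axis=0)
    first = shapes[0]
    return Outline(
        points=mean_pts,
        closed=True,
        id=f"{first.line_id or first.id}-mean",
        line_id=first.line_id,
    )


def select_landmark_count(
    shapes: Sequence[Outline],
    candidates: Sequence[int],
    ef_order: int,
    dense_k: int = 360,
) -> int:
    """Pick the landmark count minimizing AIC of the elliptic Fourier fit.

    For every candidate ``k`` each shape is resampled at ``k`` equal-angle
    landmarks, decomposed to order ``ef_order``, and the reconstruction is
    scored against the same shape resampled on a fixed dense grid of
    ``dense_k`` equal-angle points, so that residuals are comparable across
    candidates.  A pooled Gaussian residual variance gives the
    log-likelihood; AIC = 2p - 2 lnL with p = (4*ef_order + 2) coefficients
    per shape.  Ties break toward the smaller count.
    """
    from .efd import efd_decompose, efd_reconstruct  # local: avoid cycle

    if len(candidates) == 0:
        raise ValueError("need at least one candidate landmark count")
    min_k = 2 * ef_order + 1
    bad = [k for k in candidates if k < min_k]
    if bad:
        raise ValueError(
            f"candidates {bad} have fewer than 2*ef_order+1 = {min_k} landmarks; "
            "the elliptic Fourier fit would be underdetermined"
        )
    if len(shapes) == 0:
        raise ValueError("need at least one shape")

    n_shapes = len(shapes)
    sse = {}
    for k in sorted(set(int(c) for c in candidates)):
        total = 0.0
        for s in shapes:
            dense = resample_contour(s, dense_k)
            c0 = dense.points.mean(axis=0)
            scale = math.sqrt(float(np.mean(np.sum((dense.points - c0) ** 2, axis=1))))
            ref = (dense.points - c0) / scale
            coarse = resample_contour(s, k)
            coarse = coarse.with_points((coarse.points - c0) / scale)
            desc = efd_decompose(coarse, ef_order)
            # the truncated reconstruction may wiggle out of star-shapedness,
            # so sample it along the reference rays by nearest angle rather
            # than re-running the strict equal-angle resampler
            recon = efd_reconstruct(desc, 10 * dense_k)
            center = _polygon_centroid(ref)
            targets = np.arctan2(ref[:, 1] - center[1], ref[:, 0] - center[0])
            recon_d = _sample_rays(recon.points, center, targets)
            total += float(np.sum((recon_d - ref) ** 2))
        sse[k] = total
    m = n_shapes * dense_k * 2  # residual count
    aics = {}
    for k in sorted(sse):
        var = max(sse[k] / m, 1e-300)
        lnl = -0.5 * m * (math.log(2.0 * math.pi * var) + 1.0)
        aics[k] = 2.0 * n_shapes * (4 * ef_order + 2) - 2.0 * lnl
    return _select_min_aic(aics)


def _sample_rays(
    points: np.ndarray, center: np.ndarray, targets: np.ndarray
) -> np.ndarray:
    """Nearest-angle sample of a dense closed polyline along given rays.

    Robust to small angular backtracking (unlike exact ray intersection);
    with a densely evaluated curve the angular quantization error is far
    below the reconstruction residuals being scored.
    """
    rel = points - center
    th = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(th)
    ths = th[order]
    ths_ext = np.concatenate([ths - 2.0 * np.pi, ths, ths + 2.0 * np.pi])
    idx_ext = np.concatenate([order, order, order])
    pos = np.searchsorted(ths_ext, targets)
    left = np.clip(pos - 1, 0, len(ths_ext) - 1)
    right = np.clip(pos, 0, len(ths_ext) - 1)
    use_right = np.abs(ths_ext[right] - targets) < np.abs(targets - ths_ext[left])
    sel = np.where(use_right, idx_ext[right], idx_ext[left])
    return points[sel]


def _select_min_aic(aic_by_k: dict) -> int:
    """Candidate with minimal AIC; exact or numerical ties keep the smaller k."""
    best_k, best_aic = None, np.inf
    for k in sorted(aic_by_k):
        if aic_by_k[k] < best_aic - 1e-9:
            best_k, best_aic = k, aic_by_k[k]
    return best_k


def _axis_frame(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Base-tip axis frame: landmark 0 is the base, the landmark K//2 (the
    opposite equal-angle ray) is the tip; returns (axial, perp, unit axis)."""
    base = points[0]
    tip = points[len(points) // 2]
    axis = tip - base
    norm = np.hypot(axis[0], axis[1])
    if norm < 1e-12:
        raise GeometryError("base and tip landmarks coincide")
    u = axis / norm
    v = np.array([-u[1], u[0]])
    rel = points - base
    return rel @ u, rel @ v, u


def trait_descriptors(shape: Outline, check_simple: bool = True) -> dict:
    """Scalar shape traits of a closed outline.

    Returns ``length`` (extent along the base-tip axis), ``width`` (maximum
    extent perpendicular to it), ``area`` (absolute shoelace polygon area)
    and ``broadest_position`` (axial position of the maximum-width chord as
    a fraction of length from the blade base, in [0, 1]).
    """
    pts = shape.points
    if check_simple:
        from shapely.geometry import LinearRing

        try:
            ring_ok = LinearRing(pts).is_simple
        except Exception as exc:  # degenerate ring
            raise GeometryError(f"invalid polygon: {exc}") from exc
        if not ring_ok:
            raise GeometryError("self-intersecting outline")
    a, w, _ = _axis_frame(pts)
    length = float(a.max() - a.min())
    width = float(w.max() - w.min())
    area = abs(_signed_area(pts))

    # width profile along the axis from the two margin arcs between base and tip
    k = len(pts)
    half = k // 2
    arc1 = np.arange(0, half + 1)
    arc2 = np.concatenate([np.arange(half, k), [0]])
    grid = np.linspace(a.min(), a.max(), 256)
    prof = np.zeros_like(grid)
    sides = []
    for arc in (arc1, arc2):
        aa, ww = a[arc], w[arc]
        order = np.argsort(aa)
        sides.append(np.interp(grid, aa[order], ww[order]))
    prof = np.abs(sides[0] - sides[1])
    broadest = float((grid[int(np.argmax(prof))] - a.min()) / max(length, 1e-300))
    return {
        "length": length,
        "width": width,
        "area": area,
        "broadest_position": min(max(broadest, 0.0), 1.0),
    }


def outline_from_image(image, leaf_id: str = "", **meta) -> Outline:
    """Trace a binary leaf silhouette (white leaf on black background).

    Marching-squares boundary tracing at the 0.5 level; the longest closed
    boundary is taken and interior holes are ignored.  Image rows map to -y
    so the returned outline lives in conventional x/y coordinates.
    """
    from skimage import measure

    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / img.max()
    contours = measure.find_contours(img, 0.5)
    if not contours:
        raise GeometryError("no 0.5-level boundary found in image")
    longest = max(contours, key=len)
    # (row, col) -> (x, y) with y up
    pts = np.column_stack([longest[:, 1], -longest[:, 0]])
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    keep = np.ones(len(pts), dtype=bool)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    keep[np.hypot(d[:, 0], d[:, 1]) == 0.0] = False
    return Outline(points=pts[keep], id=leaf_id, **meta)
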