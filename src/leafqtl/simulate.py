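"""Synthetic two-altitude leaf-shape study generator with known truth.

Emulates the study design this package analyzes: two demes of clonal lines
(high / low altitude), each line genotyped at biallelic SNPs and phenotyped
by several leaves per tree-crown position.  Genotypes diverge between demes
under the Balding-Nichols model (per-deme allele frequencies Beta-distributed
around an ancestral frequency with divergence parameter F, a direct FST
dial).  Leaf contours are reconstructions of an order-4 elliptic Fourier
ovate base shape (broadest about 0.3 of the length from the blade base) plus
deme offset, planted genotype-dosed QTL effects of four pattern classes,
position (heterophylly) and block effects, a per-line polygenic size jitter,
and AR(1)-correlated landmark noise — i.e. the generator inverts the
analysis model, so every downstream stage has exact planted truth.

All randomness flows from the single config seed through named streams;
identical configs give identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .efd import EFDescriptor, efd_decompose, efd_reconstruct
from .geometry import Outline
from .popgen import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QTLSpec",
    "SimConfig",
    "default_base_shape",
    "simulate_genotypes",
    "simulate_shapes",
    "generate_dataset",
]

PATTERN_CLASSES = ("LENGTH", "WIDTH", "TIP", "BASE")

# neutrality class mix of non-QTL markers, matching a resequencing panel in
# which ~84% of retained SNPs are neutral (mostly intergenic, then intronic)
_NEUTRALITY_PROBS = {
    "intergenic": 0.648,
    "intron": 0.190,
    "synonymous": 0.003,
    "non-neutral": 0.159,
}


@dataclass
class QTLSpec:
    """One planted shape QTL."""

    marker_index: int
    pattern: str  # LENGTH | WIDTH | TIP | BASE
    effect: float  # fractional descriptor change between extreme genotypes
    deme_expression: str = "both"  # both | high_only | low_only
    seg_type: str = "intercross"  # intercross | testcross

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_CLASSES:
            raise ValueError(f"unknown pattern class {self.pattern!r}")
        if self.effect < 0:
            raise ValueError("effect sizes must be >= 0")
        if self.deme_expression not in ("both", "high_only", "low_only"):
            raise ValueError(f"unknown deme expression {self.deme_expression!r}")
        if self.seg_type not in ("intercross", "testcross"):
            raise ValueError(f"unknown segregation type {self.seg_type!r}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the emulated field design: 119 high- plus 141
    low-altitude clonal lines, six leaves per line (two per crown section),
    70 landmarks, order-4 ovate base shape, weak deme divergence
    (F = 0.0075) and a 2% cross-deme width offset (high-altitude leaves
    slender), AR(1) landmark noise.
    """

    n_lines: tuple = (119, 141)  # (high, low)
    leaves_per_line: int = 6
    k_landmarks: int = 70
    ef_order: int = 4
    base_coeffs: EFDescriptor | None = None
    qtl_specs: list = field(default_factory=list)
    n_markers: int = 500
    maf_range: tuple = (0.05, 0.5)
    fst: float = 0.0075
    noise_sd: float = 0.02
    noise_rho: float = 0.6
    deme_shape_offset: float = 0.02
    line_effect_sd: float = 0.01
    position_width_effects: dict = field(
        default_factory=lambda: {"upper": -0.02, "middle": 0.0, "lower": 0.02}
    )
    block_width_effects: dict = field(default_factory=lambda: {"B1": 0.0, "B2": 0.0})
    mean_depth: float = 20.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        for q in self.qtl_specs:
            if not 0 <= q.marker_index < self.n_markers:
                raise ValueError(f"QTL marker index {q.marker_index} out of range")


def _stream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG stream derived from the single config seed."""
    digest = hashlib.sha256(name.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([int(seed) % (2**31), sub])


def default_base_shape(k: int = 70, order: int = 4) -> EFDescriptor:
    """Order-``order`` descriptor of the default ovate leaf.

    Bilaterally symmetric parametric ovate with the blade base at the
    bottom (landmark 0), width/length ratio ~0.46 and the broadest chord
    about 0.28 of the length above the base.  The higher-harmonic terms
    (basal shoulders, acuminate tip) give the contour realistic non-
    elliptic content, so explained-variation order selection on simulated
    leaves lands at harmonic 4 rather than degenerating to the best-fit
    ellipse of an over-smooth shape.
    """
    t = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    y = (
        -np.cos(t) + 0.06 * np.cos(2.0 * t) - 0.10 * np.cos(3.0 * t)
        + 0.02 * np.cos(4.0 * t)
    )
    x = (
        0.48 * np.sin(t)
        * (1.0 + 0.50 * np.cos(t) + 0.17 * np.cos(2.0 * t) - 0.15 * np.cos(3.0 * t))
        + 0.04 * np.sin(3.0 * t)
        - 0.07 * np.sin(4.0 * t)
    )
    return efd_decompose(Outline(points=np.column_stack([x, y])), order)


def _line_table(config: SimConfig) -> pd.DataFrame:
    n_high, n_low = config.n_lines
    ids = [f"L{i + 1:04d}" for i in range(n_high + n_low)]
    demes = ["high"] * n_high + ["low"] * n_low
    return pd.DataFrame({"line_id": ids, "deme": demes})


def simulate_genotypes(config: SimConfig):
    """Genotypes of all lines under Balding-Nichols deme divergence.

    Returns (GenotypeMatrix, deme labels per line, truth dict).  Ancestral
    allele frequencies are uniform on ``maf_range``; per-deme frequencies
    are Beta(p(1-F)/F, (1-p)(1-F)/F) (identical when F = 0); genotypes are
    drawn under within-deme HWE.  QTL markers are forced to the segregation
    class their spec requires and share their frequency across demes, so
    planted shape effects — not drift — carry their association signal.
    """
    rng = _stream(config.seed, "genotypes")
    lines = _line_table(config)
    n = len(lines)
    deme_labels = lines["deme"].to_numpy()
    high = deme_labels == "high"
    m = config.n_markers
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    f = config.fst
    if f > 0:
        shape1 = p_anc * (1.0 - f) / f
        shape2 = (1.0 - p_anc) * (1.0 - f) / f
        p_high = rng.beta(shape1, shape2)
        p_low = rng.beta(shape1, shape2)
    else:
        p_high = p_anc.copy()
        p_low = p_anc.copy()
    p_line = np.where(high[:, None], p_high[None, :], p_low[None, :])
    calls = rng.binomial(2, p_line).astype(np.int8)

    qtl_by_marker = {q.marker_index: q for q in config.qtl_specs}
    for j, q in qtl_by_marker.items():
        for _ in range(50):
            if q.seg_type == "testcross":
                col = rng.binomial(1, 0.5, size=n).astype(np.int8)
                ok = len(np.unique(col)) == 2
            else:
                col = rng.binomial(2, 0.45, size=n).astype(np.int8)
                ok = len(np.unique(col)) == 3
            if ok:
                break
        calls[:, j] = col

    classes = list(_NEUTRALITY_PROBS)
    neut = rng.choice(classes, size=m, p=list(_NEUTRALITY_PROBS.values()))
    neut = neut.astype(object)
    for j in qtl_by_marker:
        neut[j] = "non-neutral"
    chrom = (np.arange(m) % 19 + 1).astype(str)
    pos = (np.arange(m) // 19 + 1) * 1000 + (np.arange(m) % 19)
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"M{j + 1:05d}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
            "neutrality": neut,
            "annotation": [
                f"QTL_{qtl_by_marker[j].pattern}" if j in qtl_by_marker else ""
                for j in range(m)
            ],
        }
    )
    depth_rng = _stream(config.seed, "depths")
    depths = depth_rng.poisson(config.mean_depth, size=calls.shape).astype(np.int16)
    if config.missing_rate > 0:
        miss_rng = _stream(config.seed, "missing")
        mask = miss_rng.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(-1), calls)
    gmatrix = GenotypeMatrix(lines["line_id"], calls, markers, depths)
    truth = {
        "seed": int(config.seed),
        "fst": float(config.fst),
        "n_lines": {"high": int(config.n_lines[0]), "low": int(config.n_lines[1])},
        "qtls": [
            {
                "marker_id": markers.iloc[q.marker_index]["id"],
                "marker_index": int(q.marker_index),
                "pattern": q.pattern,
                "effect": float(q.effect),
                "deme_expression": q.deme_expression,
                "seg_type": q.seg_type,
            }
            for q in config.qtl_specs
        ],
    }
    return gmatrix, deme_labels, truth


def _axial_fraction(points: np.ndarray) -> np.ndarray:
    y = points[:, 1]
    return (y - y.min()) / (y.max() - y.min())


def _region_bump(frac: np.ndarray, region: str) -> np.ndarray:
    """Margin-displacement weight confined to one axial third.

    BASE: a full sine period across the basal third (zero at both region
    edges, signed) — the margin is enlarged over one half of the region and
    drawn in over the other, and the inward lobe's amplitude is solved
    downstream so the planted redistribution is size-neutral.  The basal
    third is landmark-rich, so the compensation has support.

    TIP: a positive half-sine across the apical third, vanishing at the
    apex itself and at the region edge.
    """
    w = np.zeros_like(frac)
    if region == "BASE":
        inside = frac <= 1.0 / 3.0
        w[inside] = np.sin(6.0 * np.pi * frac[inside])
    else:  # TIP
        inside = frac >= 2.0 / 3.0
        w[inside] = np.sin(3.0 * np.pi * (1.0 - frac[inside]))
    return w


def _apply_region_bump(
    pts: np.ndarray, frac: np.ndarray, region: str, scale: float
) -> np.ndarray:
    """Apply a localized blade-region change.

    BASE: lateral margin enlargement of the basal third (with the inward
    lobe's amplitude solved so the equal-angle landmark centroid size — the
    metric Procrustes normalizes by — is unchanged; any residual coupling
    would leak into a uniform relative rescaling of the aligned shapes).

    TIP: apical displacement along the axis — the upper shoulders move
    toward the apex, a blunt versus acute blade tip at equal axis length
    and width.  The upper lateral margin runs nearly radially, so lateral
    displacement there is ill-conditioned for equal-angle landmarks; the
    axial form is the well-conditioned expression of a tip-contour QTL.
    Its unavoidable percent-level size coupling appears downstream as a
    uniform rescale of the aligned shapes, which the pattern classifier's
    robust similarity registration removes.
    """
    if scale == 0.0:
        return pts
    k = len(pts)
    w = _region_bump(frac, region)
    w_half = 0.5 * float(pts[:, 0].max() - pts[:, 0].min())
    if region == "TIP":
        # axial displacement scaled by the blade half-length (an axial
        # feature follows the axis, as the lateral ones follow the width)
        l_half = 0.5 * float(pts[:, 1].max() - pts[:, 1].min())
        out = pts.copy()
        out[:, 1] = pts[:, 1] + scale * w * l_half
        return out
    direction = np.tanh(pts[:, 0] / (0.3 * w_half))
    off_pos = np.where(w > 0, w, 0.0) * w_half * direction * scale
    # in-region compensating lobe (the basal third is landmark-rich)
    off_neg = np.where(w < 0, w, 0.0) * w_half * direction * scale
    target = _landmark_rms(pts, k)

    def shaped(lam):
        q = pts.copy()
        q[:, 0] = pts[:, 0] + off_pos + lam * off_neg
        return q

    lo, hi = 0.0, 2.5
    f_lo = _landmark_rms(shaped(lo), k) - target
    f_hi = _landmark_rms(shaped(hi), k) - target
    if f_lo * f_hi > 0:
        return shaped(1.0)  # not solvable in range: accept the tiny leak
    for _ in range(16):
        mid = 0.5 * (lo + hi)
        if (_landmark_rms(shaped(mid), k) - target) * f_lo <= 0:
            hi = mid
        else:
            lo, f_lo = mid, _landmark_rms(shaped(mid), k) - target
    return shaped(0.5 * (lo + hi))


def _landmark_rms(pts: np.ndarray, k: int) -> float:
    """Centroid size of the equal-angle landmark sampling of a contour.

    This is the exact metric Procrustes alignment normalizes by, so planted
    transforms solve their free parameter against it: any residual coupling
    would re-emerge after unit-size normalization as a uniform relative
    shrink of the whole margin between genotype groups.
    """
    from .geometry import resample_contour

    try:
        r = resample_contour(Outline(points=pts, validate=False), k).points
    except Exception:
        r = pts
    c = r - r.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


def _widen_preserve_length(pts: np.ndarray, fx: float) -> np.ndarray:
    """Widen a contour by ``fx`` at constant centroid size and y-extent.

    A plain x-scaling also changes centroid size, so after Procrustes unit-
    size normalization it reads as a length-vs-width trade-off rather than a
    width change.  Here the interior y-coordinates are warped (extent and
    blade tip/base fixed) to absorb the size change, so the aligned shapes
    differ in width at an equal axis length — the signature of a width QTL.
    """
    if fx == 1.0:
        return pts

    def area(p):
        # the angular mean of r^2 about the centroid is area/pi, so matching
        # the area keeps the equal-angle landmark size (and hence the
        # Procrustes-normalized axis length) unchanged
        xx, yy = p[:, 0], p[:, 1]
        return abs(0.5 * float(np.sum(xx * np.roll(yy, -1) - np.roll(xx, -1) * yy)))

    k = len(pts)
    target_area = area(pts)
    target_rms = _landmark_rms(pts, k)
    cur = pts.copy()
    cur[:, 0] = pts[:, 0] * fx
    # one quadratic interior squeeze has limited area-absorption capacity,
    # so compose up to four (each a monotone y-reparameterization that
    # fixes the blade base and tip); the cheap area criterion gets close
    for _ in range(4):
        if abs(area(cur) - target_area) <= 1e-4 * target_area:
            break
        y = cur[:, 1]
        ymid = 0.5 * (y.max() + y.min())
        u = 1.0 - ((y - ymid) / (0.5 * (y.max() - y.min()))) ** 2

        def warped(c):
            q = cur.copy()
            q[:, 1] = y - c * u * (y - ymid)
            return q

        lo, hi = (0.0, 0.8) if area(cur) > target_area else (-0.8, 0.0)
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            a_mid = area(warped(mid)) - target_area
            if a_mid * (area(warped(lo)) - target_area) <= 0:
                hi = mid
            else:
                lo = mid
        cur = warped(0.5 * (lo + hi))
    # corrective round in the exact landmark-RMS metric
    y = cur[:, 1]
    ymid = 0.5 * (y.max() + y.min())
    u = 1.0 - ((y - ymid) / (0.5 * (y.max() - y.min()))) ** 2

    def warped2(c):
        q = cur.copy()
        q[:, 1] = y - c * u * (y - ymid)
        return q

    lo, hi = -0.3, 0.3
    f_lo = _landmark_rms(warped2(lo), k) - target_rms
    f_hi = _landmark_rms(warped2(hi), k) - target_rms
    if f_lo * f_hi > 0:
        return cur
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        if (_landmark_rms(warped2(mid), k) - target_rms) * f_lo <= 0:
            hi = mid
        else:
            lo, f_lo = mid, _landmark_rms(warped2(mid), k) - target_rms
    return warped2(0.5 * (lo + hi))


def _ar1_noise(rng: np.random.Generator, k: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) sequence of length k with marginal sd."""
    e = np.empty(k)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(max(1.0 - rho**2, 1e-12))
    eps = rng.normal(0.0, innov_sd, size=k - 1)
    for i in range(1, k):
        e[i] = rho * e[i - 1] + eps[i - 1]
    return e


def _backtracking_steps(points: np.ndarray) -> np.ndarray:
    """Indices of contour steps that sweep backwards about the centroid."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if abs(a) < 1e-12:
        return np.arange(len(points))
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    rel = points - (cx, cy)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    d = np.diff(np.concatenate([theta, theta[:1]]))
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    if a < 0:
        return np.nonzero(d > 1e-9)[0]
    return np.nonzero(d < -1e-9)[0]


def _is_star_shaped(points: np.ndarray) -> bool:
    return _backtracking_steps(points).size == 0


def _damp_to_star(mean_pts: np.ndarray, noise: np.ndarray, max_iter: int = 80):
    """Locally shrink noise around backtracking landmarks until star-shaped.

    The noiseless mean contour is star-shaped, so repeatedly damping the
    offending landmarks' noise converges; only the rare violating landmarks
    are touched, leaving the AR(1) noise model intact elsewhere.
    """
    k = len(mean_pts)
    for _ in range(max_iter):
        pts = mean_pts + noise
        bad = _backtracking_steps(pts)
        if bad.size == 0:
            return pts
        idx = np.unique(np.concatenate([bad - 1, bad, bad + 1]) % k)
        noise[idx] *= 0.6
    return mean_pts  # fully damped fallback (noise erased for this leaf)


_POSITIONS = ("upper", "middle", "lower")


def simulate_shapes(gmatrix: GenotypeMatrix, config: SimConfig, deme_labels=None):
    """Per-leaf landmark outlines for every line in ``gmatrix``.

    Returns (list of Outline, line metadata DataFrame, per-line truth dict
    of planted genotype transforms).  Line mean contour = order-4 base
    reconstruction with deme width offset and multiplicative genotype-dosed
    QTL effects; each leaf adds position and block width effects, a per-line
    polygenic width/length jitter, and independent AR(1) landmark noise on
    the x- and y-blocks.  Rare leaves violating the star-shaped geometry
    precondition are redrawn (logged).
    """
    rng = _stream(config.seed, "shapes")
    lines = _line_table(config)
    if deme_labels is None:
        deme_labels = lines["deme"].to_numpy()
    if list(gmatrix.line_ids) != list(lines["line_id"]):
        lines = pd.DataFrame({"line_id": gmatrix.line_ids, "deme": deme_labels})
    base = config.base_coeffs or default_base_shape(config.k_landmarks, config.ef_order)
    # landmarks at equal angles about the centroid (the analysis convention);
    # even angular spacing also keeps noisy leaves star-shaped
    from .geometry import resample_contour

    base_pts = resample_contour(
        efd_reconstruct(base, 720), config.k_landmarks
    ).points
    frac = _axial_fraction(base_pts)
    k = config.k_landmarks
    dmax = {q.marker_index: float(np.max(gmatrix.calls[:, q.marker_index]))
            for q in config.qtl_specs}

    line_eff = rng.normal(0.0, config.line_effect_sd, size=(len(lines), 2))
    outlines: list[Outline] = []
    n_redrawn = 0
    for i, row in lines.iterrows():
        deme = deme_labels[i]
        wfac = 1.0 + (0.5 if deme == "low" else -0.5) * config.deme_shape_offset
        lfac = 1.0
        pts = base_pts.copy()
        bumps = []
        warped = False
        for q in config.qtl_specs:
            if q.deme_expression == "high_only" and deme != "high":
                continue
            if q.deme_expression == "low_only" and deme != "low":
                continue
            dose = gmatrix.calls[i, q.marker_index]
            if dose < 0:
                continue
            scale = q.effect * dose / max(dmax[q.marker_index], 1.0)
            if q.pattern == "WIDTH":
                pts = _widen_preserve_length(pts, 1.0 + scale)
                warped = True
            elif q.pattern == "LENGTH":
                lfac *= 1.0 + scale
                wfac /= 1.0 + 0.5 * scale  # long-narrow vs short-broad
            else:
                bumps.append((q.pattern, scale))
        if warped:
            # re-landmark the warped mean contour at equal angles: the width
            # warp redistributes vertex density, and sparse coverage near the
            # blade apex would otherwise bias the noisy resampled extent
            # dose-dependently
            pts = resample_contour(Outline(points=pts, validate=False), k).points
        for region, scale in bumps:
            # localized margin enlargement applied after any re-landmarking:
            # an extra equal-angle resampling pass would low-pass the narrow
            # displacement field away (it spans only a few landmarks).
            # Outward displacement of the affected third, sized as a fraction
            # of the leaf half-width (multiplicative widening would vanish
            # where the blade is narrow), landmark-size-neutralized
            pts = _apply_region_bump(pts, _axial_fraction(pts), region, scale)
        wfac_line = wfac * (1.0 + line_eff[i, 0])
        lfac_line = lfac * (1.0 + line_eff[i, 1])
        for leaf in range(config.leaves_per_line):
            position = _POSITIONS[(leaf * len(_POSITIONS)) // config.leaves_per_line]
            block = f"B{leaf % 2 + 1}"
            w = wfac_line * (1.0 + config.position_width_effects.get(position, 0.0))
            w *= 1.0 + config.block_width_effects.get(block, 0.0)
            mean_pts = pts * (w, lfac_line)
            for attempt in range(6):
                noise = np.column_stack(
                    [
                        _ar1_noise(rng, k, config.noise_sd, config.noise_rho),
                        _ar1_noise(rng, k, config.noise_sd, config.noise_rho),
                    ]
                )
                noisy = mean_pts + noise
                if config.noise_sd == 0.0 or _is_star_shaped(noisy):
                    break
                n_redrawn += 1
            else:
                # no valid full redraw at these noise settings: damp the noise
                # locally around the offending landmarks instead
                noisy = _damp_to_star(mean_pts, noise)
            outlines.append(
                Outline(
                    points=noisy,
                    id=f"{row['line_id']}-{leaf + 1}",
                    line_id=row["line_id"],
                    position=position,
                    block=block,
                )
            )
    if n_redrawn:
        logger.info("redrew %d leaves violating the star-shape precondition", n_redrawn)
    lines = lines.assign(n_leaves=config.leaves_per_line)
    return outlines, lines, {"n_redrawn": n_redrawn}


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(gmatrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT and per-sample DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN_CLASS,Number=1,Type=String,'
                 'Description="Site neutrality class">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,'
                 'Description="Gene annotation passthrough">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gmatrix.line_ids) + "\n")
        for j in range(gmatrix.n_markers):
            m = gmatrix.markers.iloc[j]
            info = f"ANN_CLASS={m['neutrality']}"
            if m.get("annotation"):
                info += f";GENE={m['annotation']}"
            samples = []
            for i in range(gmatrix.n_lines):
                dp = 0 if gmatrix.depths is None else int(gmatrix.depths[i, j])
                samples.append(f"{_GT_STR[int(gmatrix.calls[i, j])]}:{dp}")
            fh.write(
                f"{m['chrom']}\t{m['pos']}\t{m['id']}\t{m['ref']}\t{m['alt']}"
                f"\t.\tPASS\t{info}\tGT:DP\t" + "\t".join(samples) + "\n"
            )


def generate_dataset(config: SimConfig, outdir) -> dict:
    """Write a complete synthetic study bundle.

    Produces ``genotypes.vcf``, ``landmarks.csv`` (geometry-module dialect),
    ``lines.tsv`` and ``truth.json`` under ``outdir``; returns their paths.
    """
    from .io import write_landmark_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmatrix, deme_labels, truth = simulate_genotypes(config)
    outlines, lines, shape_truth = simulate_shapes(gmatrix, config, deme_labels)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "landmarks": outdir / "landmarks.csv",
        "lines": outdir / "lines.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(gmatrix, paths["vcf"])
    deme_of = dict(zip(lines["line_id"], lines["deme"]))
    write_landmark_csv(outlines, paths["landmarks"], deme_of_line=deme_of)
    lines.to_csv(paths["lines"], sep="\t", index=False)
    truth = dict(truth)
    truth.update(shape_truth)
    truth["config"] = {
        k: v for k, v in asdict(config).items() if k != "base_coeffs"
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}
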