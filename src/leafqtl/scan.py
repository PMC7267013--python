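"""Per-SNP likelihood-ratio association of whole-contour phenotypes.

Each clonal line contributes a phenotype vector z = (x_1..x_K, y_1..y_K) of
aligned landmark coordinates.  Under the null, one elliptic Fourier mean
curve describes all lines; under the alternative, each genotype class at the
tested SNP gets its own mean curve.  Residuals around the fitted means are
modeled as two independent AR(1) Gaussian blocks (x and y), sharing their
covariance across genotype groups, so the likelihood is O(K) via the
closed-form determinant and tridiagonal inverse of the AR(1) covariance.
The test statistic is LR = 2(lnL_H1 - lnL_H0); genome-wide significance
thresholds come from permutation of line phenotypes against genotype rows,
taking the maximal LR per permutation within each segregation type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .efd import EFDescriptor, _basis_projector, fit_ef_curve
from .errors import DegenerateDataError, LeafQTLError, PipelineError
from .popgen import GenotypeMatrix, classify_segregation

logger = logging.getLogger(__name__)

__all__ = [
    "ShapePhenotype",
    "ARCovParams",
    "ScanResult",
    "MarkerSkippedError",
    "ar1_loglik",
    "fit_group_model",
    "GroupModelFit",
    "lr_test",
    "genome_scan",
    "permutation_threshold",
    "snp_heritability",
]

_RHO_GRID = np.linspace(-0.99, 0.99, 100)


@dataclass
class ShapePhenotype:
    """Per-line average shape as a fixed-length coordinate vector.

    ``z`` stacks the K x-coordinates then the K y-coordinates of the aligned
    landmarks (length 2K), in aligned-shape units.
    """

    line_id: str
    deme: str
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.z.size % 2 != 0 or self.z.size < 4:
            raise ValueError("z must have even length 2K with K >= 2")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite phenotype entries")

    @property
    def k(self) -> int:
        return self.z.size // 2


@dataclass
class ARCovParams:
    """AR(1) residual covariance: independent x and y landmark blocks."""

    sigma2_x: float
    rho_x: float
    sigma2_y: float
    rho_y: float

    def __post_init__(self) -> None:
        for s in (self.sigma2_x, self.sigma2_y):
            if not s > 0:
                raise ValueError(f"variances must be > 0, got {s}")
        for r in (self.rho_x, self.rho_y):
            if not abs(r) < 1:
                raise ValueError(f"|rho| must be < 1, got {r}")


class MarkerSkippedError(LeafQTLError):
    """Marker cannot be tested (too few usable genotype groups)."""


def ar1_loglik(e: np.ndarray, sigma2: float, rho: float) -> float:
    """Gaussian log-density of one residual vector under AR(1) covariance.

    Sigma_ij = sigma2 * rho**|i-j|; uses ln|Sigma| = K ln sigma2 +
    (K-1) ln(1-rho^2) and the tridiagonal inverse quadratic form, O(K).
    """
    e = np.asarray(e, dtype=float).ravel()
    k = e.size
    if k < 2:
        raise ValueError("need a residual vector of length K >= 2")
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be > 0, got {sigma2}")
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    s_mid = float(np.sum(e[1:-1] ** 2))
    quad = (
        float(np.sum(e**2)) + rho**2 * s_mid - 2.0 * rho * float(np.sum(e[:-1] * e[1:]))
    ) / ((1.0 - rho**2) * sigma2)
    logdet = k * np.log(sigma2) + (k - 1) * np.log1p(-(rho**2))
    return float(-0.5 * (k * np.log(2.0 * np.pi) + logdet + quad))


def _suffstats(e_block: np.ndarray) -> tuple[float, float, float]:
    """(sum sq, interior sum sq, lag-1 cross sum) of a residual matrix (n, K)."""
    s_all = float(np.einsum("ij,ij->", e_block, e_block))
    s_mid = float(np.einsum("ij,ij->", e_block[:, 1:-1], e_block[:, 1:-1]))
    s_lag = float(np.einsum("ij,ij->", e_block[:, :-1], e_block[:, 1:]))
    return s_all, s_mid, s_lag


def _profile_block(
    s_all: float, s_mid: float, s_lag: float, n_rows: int, k: int
) -> tuple[float, float, float]:
    """Profile-ML AR(1) fit from sufficient statistics.

    Maximizes the profile log-likelihood over rho on a fixed grid in
    (-0.99, 0.99) with one parabolic refinement; sigma2 is closed-form given
    rho.  Returns (rho_hat, sigma2_hat, max log-likelihood).
    """
    if s_all <= 1e-20:  # numerically zero residual variation
        raise DegenerateDataError("residuals are identically zero")
    n_val = n_rows * k

    def _ll(rho):
        q = np.maximum(s_all + rho * rho * s_mid - 2.0 * rho * s_lag, 1e-300)
        sig = q / ((1.0 - rho * rho) * n_val)
        ll = (
            -0.5 * n_val * (np.log(2.0 * np.pi * sig) + 1.0)
            - 0.5 * n_rows * (k - 1) * np.log1p(-(rho * rho))
        )
        return ll, sig

    ll, _ = _ll(_RHO_GRID)
    i = int(np.argmax(ll))
    rho = _RHO_GRID[i]
    if 0 < i < len(_RHO_GRID) - 1:
        y0, y1, y2 = ll[i - 1], ll[i], ll[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < -1e-12:
            step = _RHO_GRID[1] - _RHO_GRID[0]
            rho = float(np.clip(rho + 0.5 * step * (y0 - y2) / denom, -0.99, 0.99))
    ll_r, sig_r = _ll(rho)
    return float(rho), float(sig_r), float(ll_r)


def _groups_loglik(
    z_mat: np.ndarray, groups: list[np.ndarray], hat: np.ndarray, k: int
) -> tuple[float, tuple, tuple]:
    """Maximized log-likelihood of the per-group EF-mean AR(1) model.

    ``groups`` are index arrays into ``z_mat`` rows; the AR(1) covariance is
    pooled (shared) across groups within each coordinate block.
    """
    sx = sy = mx = my = lx = ly = 0.0
    n_rows = 0
    for idx in groups:
        rows = z_mat[idx] if idx.size != z_mat.shape[0] else z_mat
        mean = rows.mean(axis=0)
        ex = rows[:, :k] - hat @ mean[:k]
        ey = rows[:, k:] - hat @ mean[k:]
        a, m, l = _suffstats(ex)
        sx += a; mx += m; lx += l
        a, m, l = _suffstats(ey)
        sy += a; my += m; ly += l
        n_rows += rows.shape[0]
    rho_x, sig_x, ll_x = _profile_block(sx, mx, lx, n_rows, k)
    rho_y, sig_y, ll_y = _profile_block(sy, my, ly, n_rows, k)
    return ll_x + ll_y, (rho_x, sig_x), (rho_y, sig_y)


@dataclass
class GroupModelFit:
    """Converged per-group elliptic Fourier mean model with AR(1) covariance."""

    means: dict
    fitted: dict
    cov: ARCovParams
    loglik: float
    n_iter: int
    converged: bool


def fit_group_model(
    phenotypes: list,
    grouping: dict,
    ef_order: int,
    min_group_size: int = 5,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> GroupModelFit:
    """Fit one elliptic Fourier mean curve per group, pooled AR(1) residuals.

    ``grouping`` maps line_id -> group label.  The group mean curve is the
    least-squares EF fit (given order) to the coordinate-wise mean of the
    group's z vectors; (sigma2, rho) per coordinate block are estimated by
    profile maximum likelihood on the pooled residuals.  Mean fit and
    covariance fit alternate until the log-likelihood change is below
    ``tol`` (at most ``max_iter`` passes).
    """
    labels = sorted({grouping[p.line_id] for p in phenotypes if p.line_id in grouping})
    if not labels:
        raise ValueError("grouping matches no phenotype line ids")
    k = phenotypes[0].k
    z_mat = np.vstack([p.z for p in phenotypes if p.line_id in grouping])
    line_ids = [p.line_id for p in phenotypes if p.line_id in grouping]
    groups, means, fitted, descs = [], {}, {}, {}
    for lab in labels:
        idx = np.array([i for i, lid in enumerate(line_ids) if grouping[lid] == lab])
        if idx.size < min_group_size:
            raise ValueError(
                f"group {lab!r} has {idx.size} lines < min_group_size={min_group_size}"
            )
        groups.append(idx)
    _, hat = _basis_projector(k, ef_order)
    last_ll = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        ll, (rho_x, sig_x), (rho_y, sig_y) = _groups_loglik(z_mat, groups, hat, k)
        if abs(ll - last_ll) < tol:
            converged = True
            break
        last_ll = ll
    if not converged:
        warnings.warn(
            "group-model fit did not converge; returning last iterate", stacklevel=2
        )
    for lab, idx in zip(labels, groups):
        mean = z_mat[idx].mean(axis=0)
        desc, curve = fit_ef_curve(np.column_stack([mean[:k], mean[k:]]), ef_order)
        descs[lab] = desc
        fitted[lab] = np.concatenate([curve[:, 0], curve[:, 1]])
    cov = ARCovParams(sigma2_x=sig_x, rho_x=rho_x, sigma2_y=sig_y, rho_y=rho_y)
    return GroupModelFit(
        means=descs, fitted=fitted, cov=cov, loglik=ll, n_iter=n_iter, converged=converged
    )


def _marker_group_indices(
    calls: np.ndarray, min_group_size: int
) -> tuple[list[np.ndarray], np.ndarray]:
    """Index arrays of usable genotype classes (>= min size, call != missing)."""
    groups = []
    used = []
    for g in (0, 1, 2):
        idx = np.nonzero(calls == g)[0]
        if idx.size >= min_group_size:
            groups.append(idx)
            used.append(idx)
    used_idx = np.concatenate(used) if used else np.empty(0, dtype=int)
    return groups, used_idx


def lr_test(
    phenotypes: list,
    genotypes: np.ndarray,
    ef_order: int,
    min_group_size: int = 5,
) -> tuple[float, GroupModelFit]:
    """Likelihood-ratio statistic for one SNP.

    ``genotypes`` holds one call per phenotype (0 hom_ref, 1 het, 2 hom_alt,
    -1 missing); lines with missing calls, or in genotype classes below
    ``min_group_size``, are dropped for this marker.  LR = 2(lnL_H1 -
    lnL_H0), covariance re-estimated under each hypothesis, clamped at 0.
    Raises :class:`MarkerSkippedError` if fewer than two usable groups
    remain.
    """
    calls = np.asarray(genotypes)
    if calls.size != len(phenotypes):
        raise ValueError("one genotype call per phenotype required")
    k = phenotypes[0].k
    z_mat = np.vstack([p.z for p in phenotypes])
    groups, used = _marker_group_indices(calls, min_group_size)
    if len(groups) < 2:
        raise MarkerSkippedError(
            f"only {len(groups)} genotype class(es) with >= {min_group_size} lines"
        )
    _, hat = _basis_projector(k, ef_order)
    l0, _, _ = _groups_loglik(z_mat, [used], hat, k)
    l1, covx, covy = _groups_loglik(z_mat, groups, hat, k)
    lr = max(0.0, 2.0 * (l1 - l0))
    sub = [phenotypes[i] for i in used]
    grouping = {phenotypes[i].line_id: int(calls[i]) for i in used}
    fit = fit_group_model(sub, grouping, ef_order, min_group_size=1)
    return lr, fit


@dataclass
class ScanResult:
    """Genome scan output: one row per marker, Manhattan-ready."""

    table: pd.DataFrame
    group_means: dict
    ef_order: int
    thresholds: dict = field(default_factory=dict)

    def apply_thresholds(self, thresholds: dict) -> "ScanResult":
        self.thresholds = dict(thresholds)
        thr = self.table["seg_type"].map(thresholds)
        self.table["threshold"] = thr
        self.table["significant"] = (~self.table["skipped"]) & (
            self.table["lr"] > thr.fillna(np.inf)
        )
        return self

    @property
    def significant(self) -> pd.DataFrame:
        if "significant" not in self.table:
            raise PipelineError("no thresholds applied yet")
        return self.table[self.table["significant"]]


def _phenotype_matrix(phenotypes: list, gmatrix: GenotypeMatrix) -> np.ndarray:
    by_line = {p.line_id: p for p in phenotypes}
    missing = [lid for lid in gmatrix.line_ids if lid not in by_line]
    if missing:
        raise ValueError(
            f"{len(missing)} genotyped lines have no phenotype (first: {missing[0]!r})"
        )
    return np.vstack([by_line[lid].z for lid in gmatrix.line_ids])


def genome_scan(
    phenotypes: list,
    gmatrix: GenotypeMatrix,
    ef_order: int,
    min_group_size: int = 5,
) -> ScanResult:
    """LR statistics for every marker; skipped markers are recorded, not lost."""
    z_mat = _phenotype_matrix(phenotypes, gmatrix)
    k = z_mat.shape[1] // 2
    _, hat = _basis_projector(k, ef_order)
    n = z_mat.shape[0]
    rows = []
    group_means: dict = {}
    n_tested = 0
    l0_all = None
    for j in range(gmatrix.n_markers):
        meta = gmatrix.markers.iloc[j]
        calls = gmatrix.calls[:, j]
        seg = classify_segregation(_counts(calls))
        rec = {
            "marker": meta["id"],
            "chrom": meta["chrom"],
            "pos": meta["pos"],
            "seg_type": seg,
            "lr": np.nan,
            "n_used": 0,
            "n_groups": 0,
            "skipped": True,
            "reason": "",
        }
        groups, used = _marker_group_indices(calls, min_group_size)
        if len(groups) < 2:
            rec["reason"] = f"{len(groups)} usable genotype group(s)"
            logger.info("marker %s skipped: %s", meta["id"], rec["reason"])
            rows.append(rec)
            continue
        if used.size == n:
            if l0_all is None:
                l0_all, _, _ = _groups_loglik(z_mat, [np.arange(n)], hat, k)
            l0 = l0_all
        else:
            l0, _, _ = _groups_loglik(z_mat, [used], hat, k)
        l1, _, _ = _groups_loglik(z_mat, groups, hat, k)
        rec.update(
            lr=max(0.0, 2.0 * (l1 - l0)),
            n_used=int(used.size),
            n_groups=len(groups),
            skipped=False,
        )
        means = {}
        for idx in groups:
            g = int(calls[idx[0]])
            mean = z_mat[idx].mean(axis=0)
            desc, _ = fit_ef_curve(np.column_stack([mean[:k], mean[k:]]), ef_order)
            means[g] = desc
        group_means[meta["id"]] = means
        n_tested += 1
        rows.append(rec)
    if n_tested == 0:
        raise PipelineError("genome scan: zero usable markers")
    table = pd.DataFrame(rows).sort_values(["chrom", "pos"], kind="stable")
    table = table.reset_index(drop=True)
    return ScanResult(table=table, group_means=group_means, ef_order=ef_order)


def _counts(calls: np.ndarray) -> dict:
    return {
        "hom_ref": int(np.sum(calls == 0)),
        "het": int(np.sum(calls == 1)),
        "hom_alt": int(np.sum(calls == 2)),
    }


def permutation_threshold(
    phenotypes: list,
    gmatrix: GenotypeMatrix,
    seg_type: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
    ef_order: int = 4,
    min_group_size: int = 5,
    per_marker: bool = False,
):
    """Genome-wide permutation threshold for one segregation type.

    Each permutation applies one shared shuffle of line phenotypes against
    genotype rows and records the maximal LR over all markers of
    ``seg_type``; the threshold is the empirical (1 - alpha) quantile
    (type-7 interpolation) of the ``n_perm`` maxima.  With
    ``per_marker=True`` the per-marker (1 - alpha) LR quantiles are returned
    instead of the genome-wide maximum rule.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    z_mat = _phenotype_matrix(phenotypes, gmatrix)
    n, k2 = z_mat.shape
    k = k2 // 2
    _, hat = _basis_projector(k, ef_order)
    seg_types = gmatrix.segregation_types()
    marker_idx = [j for j in range(gmatrix.n_markers) if seg_types[j] == seg_type]
    prepared = []
    for j in marker_idx:
        groups, used = _marker_group_indices(gmatrix.calls[:, j], min_group_size)
        if len(groups) >= 2:
            prepared.append((groups, used))
    if not prepared:
        raise ValueError(f"no testable marker of segregation type {seg_type!r}")
    rng = np.random.default_rng(seed)
    l0_all, _, _ = _groups_loglik(z_mat, [np.arange(n)], hat, k)
    stats = np.zeros((n_perm, len(prepared))) if per_marker else np.zeros(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(n)
        best = 0.0
        for m, (groups, used) in enumerate(prepared):
            if used.size == n:
                l0 = l0_all
            else:
                l0, _, _ = _groups_loglik(z_mat, [perm[used]], hat, k)
            l1, _, _ = _groups_loglik(z_mat, [perm[idx] for idx in groups], hat, k)
            lr = max(0.0, 2.0 * (l1 - l0))
            if per_marker:
                stats[p, m] = lr
            elif lr > best:
                best = lr
        if not per_marker:
            stats[p] = best
    if per_marker:
        return {
            gmatrix.markers.iloc[j]["id"]: float(np.quantile(stats[:, m], 1.0 - alpha))
            for m, (j, _) in enumerate(zip(marker_idx, prepared))
        }
    return float(np.quantile(stats, 1.0 - alpha))


def snp_heritability(trait: np.ndarray, genotypes: np.ndarray) -> float:
    """Fraction of trait variance explained by one SNP's genotype classes.

    h2 = 1 - SS_within / SS_total, the (count-weighted) between-genotype
    variance ratio, in [0, 1].  Cumulative heritability over a marker set is
    the sum of per-marker values (beware collinear markers: sums can
    overcount shared variance).
    """
    y = np.asarray(trait, dtype=float)
    calls = np.asarray(genotypes)
    keep = calls >= 0
    y, calls = y[keep], calls[keep]
    classes = np.unique(calls)
    if classes.size < 2:
        raise ValueError("need at least 2 genotype groups")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 1e-300:
        warnings.warn("constant trait: heritability undefined, returning 0", stacklevel=2)
        return 0.0
    ssw = 0.0
    for g in classes:
        yg = y[calls == g]
        ssw += float(np.sum((yg - yg.mean()) ** 2))
    return float(np.clip(1.0 - ssw / sst, 0.0, 1.0))
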