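"""SNP filtering, segregation typing, FST/QST and the shape-trait ANOVA.

Markers are biallelic SNP calls per clonal line (hom_ref / het / hom_alt /
missing) with per-line sequencing depth and a neutrality class.  Filtering
follows the study-style criteria (site depth > 12, HWE exact p > 0.05,
MAF > 5%, missing < 10%, heterozygote excess < 10%, all strict).  Deme
divergence at neutral markers is the multi-locus Weir-Cockerham theta; the
quantitative analog QST = s2_GB / (s2_GB + 2 s2_GW) comes from one-way
ANOVA variance components of per-line traits across demes, and
Nm = (1 - FST)/(4 FST) converts theta to an island-model migrant number.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .errors import AliasedTermError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerRecord",
    "GenotypeMatrix",
    "FilterConfig",
    "VarianceComponents",
    "classify_segregation",
    "hwe_exact_pvalue",
    "filter_markers",
    "weir_cockerham_fst",
    "nm_from_fst",
    "deme_variance_components",
    "qst",
    "shape_anova",
]

NEUTRAL_CLASSES = ("intergenic", "intron", "synonymous")


@dataclass
class MarkerRecord:
    """One biallelic SNP: per-line calls, depths and annotation."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    genotypes: np.ndarray  # int8 per line: 0 hom_ref, 1 het, 2 hom_alt, -1 missing
    depths: np.ndarray | None = None
    neutrality: str = "non-neutral"
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based (>= 1)")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


class GenotypeMatrix:
    """Biallelic SNP calls for a panel of clonal lines.

    ``calls`` is (n_lines, n_markers) int8 with 0/1/2 alt-allele dosage and
    -1 for missing; ``markers`` is a DataFrame with columns chrom, pos, id,
    ref, alt, neutrality, annotation.
    """

    def __init__(
        self,
        line_ids: Sequence[str],
        calls: np.ndarray,
        markers: pd.DataFrame,
        depths: np.ndarray | None = None,
    ):
        self.line_ids = list(line_ids)
        self.calls = np.asarray(calls, dtype=np.int8)
        self.markers = markers.reset_index(drop=True)
        self.depths = None if depths is None else np.asarray(depths)
        if self.calls.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError("calls shape must be (n_lines, n_markers)")
        if self.depths is not None and self.depths.shape != self.calls.shape:
            raise ValueError("depths shape must match calls")
        self._seg_types: np.ndarray | None = None

    # -- basic geometry -------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def segregation_types(self) -> np.ndarray:
        if self._seg_types is None:
            self._seg_types = np.array(
                [
                    classify_segregation(_counts_of(self.calls[:, j]))
                    for j in range(self.n_markers)
                ]
            )
        return self._seg_types

    @property
    def neutral_mask(self) -> np.ndarray:
        return self.markers["neutrality"].isin(NEUTRAL_CLASSES).to_numpy()

    # -- slicing --------------------------------------------------------
    def subset_markers(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return GenotypeMatrix(
            self.line_ids,
            self.calls[:, idx],
            self.markers.iloc[idx],
            None if self.depths is None else self.depths[:, idx],
        )

    def subset_lines(self, line_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {lid: i for i, lid in enumerate(self.line_ids)}
        idx = np.array([pos[lid] for lid in line_ids])
        return GenotypeMatrix(
            list(line_ids),
            self.calls[idx],
            self.markers,
            None if self.depths is None else self.depths[idx],
        )

    # -- record view ----------------------------------------------------
    def to_records(self) -> list:
        recs = []
        for j in range(self.n_markers):
            m = self.markers.iloc[j]
            recs.append(
                MarkerRecord(
                    chrom=str(m["chrom"]),
                    pos=int(m["pos"]),
                    id=str(m["id"]),
                    ref=str(m["ref"]),
                    alt=str(m["alt"]),
                    genotypes=self.calls[:, j],
                    depths=None if self.depths is None else self.depths[:, j],
                    neutrality=str(m["neutrality"]),
                    annotation=str(m.get("annotation", "")),
                )
            )
        return recs

    @classmethod
    def from_records(cls, records: Sequence[MarkerRecord], line_ids) -> "GenotypeMatrix":
        calls = np.column_stack([r.genotypes for r in records])
        depths = (
            None
            if any(r.depths is None for r in records)
            else np.column_stack([r.depths for r in records])
        )
        markers = pd.DataFrame(
            {
                "chrom": [r.chrom for r in records],
                "pos": [r.pos for r in records],
                "id": [r.id for r in records],
                "ref": [r.ref for r in records],
                "alt": [r.alt for r in records],
                "neutrality": [r.neutrality for r in records],
                "annotation": [r.annotation for r in records],
            }
        )
        return cls(line_ids, calls, markers, depths)


def _counts_of(calls: np.ndarray) -> dict:
    return {
        "hom_ref": int(np.sum(calls == 0)),
        "het": int(np.sum(calls == 1)),
        "hom_alt": int(np.sum(calls == 2)),
    }


def classify_segregation(counts: dict) -> str:
    """Segregation type from genotype-class counts at one marker.

    Three observed classes -> ``intercross``; one homozygote class plus
    heterozygotes -> ``testcross``; a single class -> ``monomorphic``; two
    homozygote classes with no heterozygote -> ``intercross`` (atypical for
    an outbred panel; logged).  Segregation ratios are deliberately not
    checked — this is a natural population, not a designed cross.
    """
    n_hom = int(counts.get("hom_ref", 0) > 0) + int(counts.get("hom_alt", 0) > 0)
    has_het = counts.get("het", 0) > 0
    n_classes = n_hom + int(has_het)
    if n_classes <= 1:
        return "monomorphic"
    if n_classes == 3:
        return "intercross"
    if n_hom == 1 and has_het:
        return "testcross"
    logger.info("marker with two homozygote classes and no heterozygote: "
                "classified intercross (atypical)")
    return "intercross"


def hwe_exact_pvalue(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts (same parity, fixed
    allele counts) that are no more probable than the observed one, under
    the exact hypergeometric-type distribution of heterozygotes given allele
    counts.  p is in (0, 1]; a monomorphic marker returns 1.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("counts must be nonnegative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_a = 2 * n_homalt + n_het  # minor-allele copies (choose smaller side)
    n_b = 2 * n_homref + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * math.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het]
    if obs.size == 0:  # parity mismatch cannot happen with consistent counts
        raise ValueError("inconsistent genotype counts")
    return float(np.sum(probs[probs <= obs[0] * (1.0 + 1e-12)]))


@dataclass
class FilterConfig:
    """Marker quality filters; all comparisons are strict, as printed.

    ``min_depth_exclusive`` applies to the site mean depth across lines by
    default (``depth_aggregation='site_mean'``); set ``'per_genotype'`` to
    require every individual call to exceed it instead, or None to disable.
    ``het_filter`` chooses between the heterozygote-excess rule (observed
    minus HWE-expected heterozygote frequency, default — a literal
    observed-heterozygosity cap would discard every intercross SNP) and the
    literal ``'observed'`` frequency cap.
    """

    min_depth_exclusive: float | None = 12.0
    min_hwe_p_exclusive: float = 0.05
    min_maf_exclusive: float = 0.05
    max_missing_exclusive: float = 0.10
    max_het_excess_exclusive: float = 0.10
    depth_aggregation: str = "site_mean"
    het_filter: str = "excess"

    def __post_init__(self) -> None:
        for name in ("min_hwe_p_exclusive", "min_maf_exclusive",
                     "max_missing_exclusive", "max_het_excess_exclusive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_aggregation not in ("site_mean", "per_genotype"):
            raise ValueError("depth_aggregation must be 'site_mean' or 'per_genotype'")
        if self.het_filter not in ("excess", "observed"):
            raise ValueError("het_filter must be 'excess' or 'observed'")


_FILTER_RULES = ("depth", "hwe", "maf", "missing", "heterozygosity")


def _first_failing_rule(rec: MarkerRecord, config: FilterConfig) -> str | None:
    calls = rec.genotypes
    n = calls.size
    ok = calls >= 0
    n_ok = int(ok.sum())
    if config.min_depth_exclusive is not None:
        if rec.depths is None:
            raise ValueError(
                f"marker {rec.id}: depth filter enabled but no depths available"
            )
        if config.depth_aggregation == "site_mean":
            if not float(np.mean(rec.depths)) > config.min_depth_exclusive:
                return "depth"
        else:
            if not np.all(rec.depths > config.min_depth_exclusive):
                return "depth"
    if n_ok == 0:
        return "missing"
    counts = _counts_of(calls)
    p_hwe = hwe_exact_pvalue(counts["hom_ref"], counts["het"], counts["hom_alt"])
    if not p_hwe > config.min_hwe_p_exclusive:
        return "hwe"
    p_alt = (2 * counts["hom_alt"] + counts["het"]) / (2.0 * n_ok)
    if not min(p_alt, 1.0 - p_alt) > config.min_maf_exclusive:
        return "maf"
    if not (n - n_ok) / n < config.max_missing_exclusive:
        return "missing"
    h_obs = counts["het"] / n_ok
    if config.het_filter == "excess":
        h_stat = h_obs - 2.0 * p_alt * (1.0 - p_alt)
    else:
        h_stat = h_obs
    if not h_stat < config.max_het_excess_exclusive:
        return "heterozygosity"
    return None


def filter_markers(records, config: FilterConfig | None = None):
    """Apply the marker quality filters; returns (retained, tally).

    ``records`` may be a list of :class:`MarkerRecord` or a
    :class:`GenotypeMatrix` (the return matches the input kind).  The tally
    maps each rule to the number of markers it rejected first (rules are
    checked in the fixed order depth, hwe, maf, missing, heterozygosity),
    plus ``retained``.
    """
    config = config or FilterConfig()
    matrix_input = isinstance(records, GenotypeMatrix)
    recs = records.to_records() if matrix_input else list(records)
    tally = {rule: 0 for rule in _FILTER_RULES}
    keep = []
    for i, rec in enumerate(recs):
        rule = _first_failing_rule(rec, config)
        if rule is None:
            keep.append(i)
        else:
            tally[rule] += 1
    tally["retained"] = len(keep)
    if matrix_input:
        return records.subset_markers(np.array(keep, dtype=int)), tally
    return [recs[i] for i in keep], tally


def _wc_components(calls: np.ndarray, deme_codes: np.ndarray, n_demes: int):
    """Weir-Cockerham (1984) per-locus a, b, c for one biallelic SNP."""
    ns, ps, hs = [], [], []
    for d in range(n_demes):
        sub = calls[(deme_codes == d) & (calls >= 0)]
        if sub.size == 0:
            return None
        ns.append(sub.size)
        ps.append(float(np.mean(sub)) / 2.0)
        hs.append(float(np.mean(sub == 1)))
    ns = np.asarray(ns, dtype=float)
    ps = np.asarray(ps)
    hs = np.asarray(hs)
    r = n_demes
    nbar = ns.mean()
    if nbar <= 1:
        return None
    nc = (r * nbar - float(np.sum(ns**2)) / (r * nbar)) / (r - 1)
    pbar = float(np.sum(ns * ps)) / (r * nbar)
    s2 = float(np.sum(ns * (ps - pbar) ** 2)) / ((r - 1) * nbar)
    hbar = float(np.sum(ns * hs)) / (r * nbar)
    if pbar <= 0.0 or pbar >= 1.0:
        return None  # monomorphic across demes
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst(records, demes, return_components: bool = False):
    """Multi-locus Weir-Cockerham theta across demes.

    Combines loci as a ratio of averages (sum of per-locus ``a`` numerators
    over sum of ``a + b + c`` denominators); monomorphic loci are skipped.
    ``records`` is a list of :class:`MarkerRecord` or a
    :class:`GenotypeMatrix`; ``demes`` gives one label per line.
    """
    if isinstance(records, GenotypeMatrix):
        calls_mat = records.calls
    else:
        calls_mat = np.column_stack([r.genotypes for r in records])
    demes = np.asarray(demes)
    labels = np.unique(demes)
    if labels.size < 2:
        raise ValueError("need at least 2 demes")
    codes = np.searchsorted(labels, demes)
    num = den = 0.0
    n_used = 0
    for j in range(calls_mat.shape[1]):
        comp = _wc_components(calls_mat[:, j], codes, labels.size)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
        n_used += 1
    if n_used == 0 or den == 0.0:
        raise UndefinedStatisticError(
            "FST undefined: no polymorphic locus across demes"
        )
    theta = num / den
    if return_components:
        return theta, {"sum_a": num, "sum_abc": den, "n_loci": n_used}
    return theta


def nm_from_fst(fst: float) -> float:
    """Island-model migrant number, Nm = (1 - Fst) / (4 Fst)."""
    if not 0.0 < fst < 1.0:
        raise ValueError(f"fst must be in (0, 1), got {fst}")
    return (1.0 - fst) / (4.0 * fst)


@dataclass
class VarianceComponents:
    """Between- and within-deme genetic variance of one trait."""

    sigma2_GB: float
    sigma2_GW: float

    def __post_init__(self) -> None:
        if self.sigma2_GW < 0 or self.sigma2_GB < 0:
            raise ValueError("variance components must be >= 0")


def deme_variance_components(trait, demes) -> VarianceComponents:
    """One-way ANOVA method-of-moments variance components across demes.

    sigma2_GW = MS_within, sigma2_GB = (MS_between - MS_within) / n0 with n0
    the standard unbalanced-design effective group size; negative
    between-deme estimates are truncated to 0 (with a warning).
    """
    y = np.asarray(trait, dtype=float)
    demes = np.asarray(demes)
    labels = np.unique(demes)
    if labels.size < 2:
        raise ValueError("need at least 2 demes")
    ns, ssw, means = [], 0.0, []
    for lab in labels:
        yg = y[demes == lab]
        if yg.size < 2:
            raise ValueError(f"deme {lab!r} has fewer than 2 lines")
        ns.append(yg.size)
        means.append(yg.mean())
        ssw += float(np.sum((yg - yg.mean()) ** 2))
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means)
    n_tot = ns.sum()
    grand = float(np.sum(ns * means)) / n_tot
    ssb = float(np.sum(ns * (means - grand) ** 2))
    r = labels.size
    ms_w = ssw / (n_tot - r)
    ms_b = ssb / (r - 1)
    n0 = (n_tot - float(np.sum(ns**2)) / n_tot) / (r - 1)
    s_gb = (ms_b - ms_w) / n0
    if s_gb < 0:
        warnings.warn(
            "negative between-deme variance estimate truncated to 0", stacklevel=2
        )
        s_gb = 0.0
    return VarianceComponents(sigma2_GB=s_gb, sigma2_GW=ms_w)


def qst(components: VarianceComponents) -> float:
    """QST = s2_GB / (s2_GB + 2 s2_GW)."""
    gb, gw = components.sigma2_GB, components.sigma2_GW
    if gb == 0.0 and gw == 0.0:
        raise UndefinedStatisticError("QST undefined: both variance components zero")
    return gb / (gb + 2.0 * gw)


# ---------------------------------------------------------------------------
# fixed-effects shape-trait ANOVA


def _dummies(levels: pd.Series) -> np.ndarray:
    return pd.get_dummies(levels.astype(str)).to_numpy(dtype=float)


def _interact(*blocks: np.ndarray) -> np.ndarray:
    out = blocks[0]
    for b in blocks[1:]:
        out = np.einsum("ij,ik->ijk", out, b).reshape(len(out), -1)
    return out


def shape_anova(
    data: pd.DataFrame,
    response: str,
    altitude: str = "altitude",
    genotype: str = "genotype",
    position: str = "position",
    block: str = "block",
) -> pd.DataFrame:
    """Sequential (type-I) fixed-effects ANOVA of a scalar shape trait.

    Model: y = mu + altitude + genotype(altitude) + position + block +
    altitude x position + genotype(altitude) x position + error, with sums
    of squares added in exactly that order and F = MS_term / MS_residual.
    The altitude x position interaction is fitted before the
    genotype-within-altitude x position interaction because the latter's
    column span contains the former — in the reverse order the altitude x
    position term would never have an estimable contrast.  Raises
    :class:`AliasedTermError` for a term completely confounded with its
    predecessors (beyond the declared nesting).
    """
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    alt = _dummies(data[altitude])
    gen = _dummies(data[genotype])
    pos = _dummies(data[position])
    blk = _dummies(data[block])
    for name, d in ((altitude, alt), (genotype, gen), (position, pos)):
        if d.shape[1] < 2:
            raise ValueError(f"factor {name!r} needs at least 2 levels")
    terms = [
        ("altitude", alt),
        ("genotype(altitude)", _interact(alt, gen)),
        ("position", pos),
        ("block", blk),
        ("altitude x position", _interact(alt, pos)),
        ("genotype(altitude) x position", _interact(alt, gen, pos)),
    ]
    design = np.ones((n, 1))
    rank_prev = 1
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss_prev = float(np.sum((y - design @ beta) ** 2))
    rows = []
    for name, cols in terms:
        design = np.hstack([design, cols])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        rank = int(np.linalg.matrix_rank(design))
        df_term = rank - rank_prev
        if df_term == 0:
            raise AliasedTermError(name)
        rss = float(np.sum((y - design @ beta) ** 2))
        rows.append((name, df_term, max(rss_prev - rss, 0.0)))
        rank_prev, rss_prev = rank, rss
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = rss_prev / df_res
    table = []
    for name, df_t, ss in rows:
        ms = ss / df_t
        with np.errstate(divide="ignore", invalid="ignore"):
            f_val = ms / ms_res if ms_res > 0 else (np.inf if ms > 0 else np.nan)
        p = float(sps.f.sf(f_val, df_t, df_res)) if np.isfinite(f_val) else 0.0
        table.append((name, df_t, ss, ms, f_val, p))
    table.append(("residual", df_res, rss_prev, ms_res, np.nan, np.nan))
    return pd.DataFrame(
        table, columns=["term", "df", "sum_sq", "mean_sq", "F", "p"]
    ).set_index("term")
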