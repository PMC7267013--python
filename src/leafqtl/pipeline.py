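"""End-to-end orchestration: outlines + VCF -> scans, patterns, popgen report.

Stage order (fixed, logged): read inputs -> landmark-count selection on
per-line average shapes -> phenotype construction (resample, generalized
Procrustes, per-line average, final superimposition) -> harmonic-order
selection -> marker filtering -> per-deme genome scans with per-segregation
permutation thresholds -> pattern classification -> cross-deme effect table
-> FST/QST/Nm and the shape-trait ANOVA.  Everything is deterministic given
the run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, io, patterns, popgen, scan
from .efd import variance_explained_profile, order_from_profile
from .errors import PipelineError
from .geometry import average_shape, procrustes_align, resample_contour
from .popgen import FilterConfig
from .scan import ShapePhenotype, genome_scan, permutation_threshold

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "build_phenotypes", "run_full",
           "read_landmark_csv", "read_vcf"]

# re-exported readers (this module owns the pipeline's external interfaces)
read_landmark_csv = io.read_landmark_csv
read_vcf = io.read_vcf


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    vcf: str
    landmarks: str
    lines: str
    outdir: str
    ef_order: int | None = None  # None: select by explained-variation threshold
    max_order: int = 6
    order_threshold: float = 0.95
    landmark_candidates: tuple = (30, 50, 70, 90)
    k_landmarks: int | None = None  # None: AIC selection over candidates
    n_perm: int = 1000
    alpha: float = 0.05
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    apply_filters: bool = True
    min_group_size: int = 5
    tau_rel: float = 0.02
    tau_ratio: float = 3.0
    seed: int = 0


def build_phenotypes(outlines, deme_of_line: dict, k: int):
    """Aligned per-line average-shape phenotypes from per-leaf outlines.

    All leaves are resampled at ``k`` equal-angle landmarks and jointly
    superimposed by GPA; leaves are averaged coordinate-wise per clonal
    line; the averages get a final GPA pass so line phenotypes share one
    frame.  Returns (phenotypes, aligned average Outlines by line).
    """
    if not outlines:
        raise ValueError("no outlines supplied")
    resampled = [resample_contour(o, k) for o in outlines]
    aligned = procrustes_align(resampled)
    by_line: dict = {}
    for shape in aligned:
        by_line.setdefault(shape.line_id, []).append(shape)
    averages = [average_shape(shapes) for shapes in by_line.values()]
    averages_aligned = procrustes_align(averages)
    phenos = []
    avg_by_line = {}
    for shape in averages_aligned:
        z = np.concatenate([shape.points[:, 0], shape.points[:, 1]])
        phenos.append(
            ShapePhenotype(
                line_id=shape.line_id,
                deme=deme_of_line.get(shape.line_id, ""),
                z=z,
            )
        )
        avg_by_line[shape.line_id] = shape
    return phenos, avg_by_line


def _stage(name):
    logger.info("pipeline stage: %s", name)
    return name


def run_full(config: RunConfig) -> dict:
    """Run the complete analysis; writes TSV/JSON outputs, returns a report.

    On any stage failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    report: dict = {"seed": config.seed}
    try:
        stage = _stage("read-inputs")
        lines_meta = io.read_line_metadata(config.lines)
        deme_of_line = dict(zip(lines_meta["line_id"], lines_meta["deme"]))
        outlines = io.read_landmark_csv(config.landmarks)
        if not outlines:
            raise PipelineError("no leaves in landmark file")
        gmatrix, vcf_tally = io.read_vcf(config.vcf)
        report["vcf_tally"] = vcf_tally

        stage = _stage("landmark-selection")
        if config.k_landmarks is None:
            dense = [resample_contour(o, 360) for o in outlines]
            dense_aligned = procrustes_align(dense)
            by_line: dict = {}
            for s in dense_aligned:
                by_line.setdefault(s.line_id, []).append(s)
            line_avgs = [average_shape(v) for v in by_line.values()]
            k_sel = geometry.select_landmark_count(
                line_avgs, config.landmark_candidates, ef_order=4
            )
        else:
            k_sel = config.k_landmarks
        report["k_landmarks"] = int(k_sel)

        stage = _stage("phenotypes")
        phenos, avg_by_line = build_phenotypes(outlines, deme_of_line, k_sel)

        stage = _stage("harmonic-selection")
        profile = variance_explained_profile(
            [avg_by_line[p.line_id] for p in phenos], config.max_order
        )
        order = (
            config.ef_order
            if config.ef_order is not None
            else order_from_profile(profile, config.order_threshold)
        )
        report["variance_profile"] = [float(v) for v in profile]
        report["ef_order"] = int(order)

        stage = _stage("marker-filtering")
        if config.apply_filters:
            gmatrix, tally = popgen.filter_markers(gmatrix, config.filter_config)
            report["filter_tally"] = tally
            tpath = outdir / "filter_tally.tsv"
            pd.Series(tally).to_csv(tpath, sep="\t", header=False)
            written.append(tpath)
        if gmatrix.n_markers == 0:
            raise PipelineError("no markers left after filtering")

        stage = _stage("scan")
        demes = sorted(set(deme_of_line.values()))
        scans: dict = {}
        thresholds_all: dict = {}
        for d_i, deme in enumerate(demes):
            line_ids = [p.line_id for p in phenos if p.deme == deme]
            sub_g = gmatrix.subset_lines(line_ids)
            sub_p = [p for p in phenos if p.deme == deme]
            result = genome_scan(sub_p, sub_g, order,
                                 min_group_size=config.min_group_size)
            thr = {}
            for s_i, seg in enumerate(("testcross", "intercross")):
                if not (result.table["seg_type"] == seg).any():
                    continue
                try:
                    thr[seg] = permutation_threshold(
                        sub_p, sub_g, seg,
                        n_perm=config.n_perm, alpha=config.alpha,
                        seed=(config.seed * 7919 + d_i * 101 + s_i) % (2**31),
                        ef_order=order, min_group_size=config.min_group_size,
                    )
                except ValueError:
                    continue  # seg type present but not testable
            result.apply_thresholds(thr)
            thresholds_all[deme] = thr
            scans[deme] = result
            spath = outdir / f"scan_{deme}.tsv"
            result.table.to_csv(spath, sep="\t", index=False)
            written.append(spath)
        report["thresholds"] = thresholds_all
        report["n_significant"] = {
            d: int(scans[d].table.get("significant", pd.Series(dtype=bool)).sum())
            for d in demes
        }

        stage = _stage("patterns")
        pat_rows = []
        for deme in demes:
            res = scans[deme]
            sub_p = [p for p in phenos if p.deme == deme]
            sub_g = gmatrix.subset_lines([p.line_id for p in sub_p])
            marker_col = {m: j for j, m in enumerate(gmatrix.markers["id"])}
            for mk in res.significant["marker"]:
                # classify on raw coordinate-wise genotype means: EF smoothing
                # would blur the localized divergence of tip/base QTLs
                means = patterns.genotype_mean_shapes(
                    sub_p, sub_g.calls[:, marker_col[mk]],
                    min_group_size=config.min_group_size,
                )
                if len(means) < 2:
                    continue
                pat = patterns.classify_pattern(
                    {g: m[0] for g, m in means.items()},
                    tau_rel=config.tau_rel, tau_ratio=config.tau_ratio,
                    marker=mk,
                )
                pat_rows.append(
                    {
                        "deme": deme, "marker": mk, "class": pat.label,
                        "delta_length": pat.delta_length,
                        "delta_width": pat.delta_width,
                        "d_base": pat.d_base, "d_mid": pat.d_mid,
                        "d_tip": pat.d_tip,
                    }
                )
        pat_df = pd.DataFrame(
            pat_rows, columns=["deme", "marker", "class", "delta_length",
                               "delta_width", "d_base", "d_mid", "d_tip"]
        )
        ppath = outdir / "patterns.tsv"
        pat_df.to_csv(ppath, sep="\t", index=False)
        written.append(ppath)
        report["patterns"] = pat_df.to_dict("records")

        stage = _stage("effect-table")
        if len(demes) == 2:
            eff = patterns.effect_table(scans)
            epath = outdir / "effect_table.tsv"
            eff.to_csv(epath, sep="\t", index=False)
            written.append(epath)

        stage = _stage("popgen")
        neutral = gmatrix.subset_markers(gmatrix.neutral_mask)
        deme_labels = np.array([deme_of_line[lid] for lid in gmatrix.line_ids])
        pg: dict = {}
        if neutral.n_markers and len(set(deme_labels)) >= 2:
            theta, comp = popgen.weir_cockerham_fst(
                neutral, deme_labels, return_components=True
            )
            pg["fst"] = theta
            pg["fst_components"] = comp
            pg["nm"] = popgen.nm_from_fst(theta) if 0 < theta < 1 else None
        trait_rows = {
            p.line_id: geometry.trait_descriptors(
                avg_by_line[p.line_id], check_simple=False
            )
            for p in phenos
        }
        pheno_demes = np.array([p.deme for p in phenos])
        pg["qst"] = {}
        for trait in ("width", "length", "area"):
            vals = np.array([trait_rows[p.line_id][trait] for p in phenos])
            comp = popgen.deme_variance_components(vals, pheno_demes)
            pg["qst"][trait] = {
                "sigma2_GB": comp.sigma2_GB,
                "sigma2_GW": comp.sigma2_GW,
                "qst": popgen.qst(comp),
            }
        # per-leaf trait ANOVA (altitude, genotype-within-altitude, position, block)
        leaf_rows = []
        k_cur = k_sel
        leaf_aligned = procrustes_align([resample_contour(o, k_cur) for o in outlines])
        for o_raw, o in zip(outlines, leaf_aligned):
            tr = geometry.trait_descriptors(o, check_simple=False)
            leaf_rows.append(
                {
                    "altitude": deme_of_line.get(o.line_id, ""),
                    "genotype": o.line_id,
                    "position": o.position,
                    "block": o.block,
                    **{t: tr[t] for t in ("width", "length", "area")},
                }
            )
        leaf_df = pd.DataFrame(leaf_rows)
        pg["anova"] = {}
        for trait in ("width", "length", "area"):
            try:
                tab = popgen.shape_anova(leaf_df, trait)
                pg["anova"][trait] = tab.reset_index().to_dict("records")
            except Exception as exc:
                pg["anova"][trait] = f"not estimable: {exc}"
        report["popgen"] = pg
        jpath = outdir / "popgen.json"
        with open(jpath, "w") as fh:
            json.dump(pg, fh, indent=1, default=float)
        written.append(jpath)

        stage = _stage("run-log")
        lpath = outdir / "run_log.json"
        log = {
            "config": {
                k: (v if not isinstance(v, FilterConfig) else vars(v))
                for k, v in vars(config).items()
            },
            "k_landmarks": report["k_landmarks"],
            "ef_order": report["ef_order"],
            "thresholds": thresholds_all,
            "vcf_tally": report["vcf_tally"],
            "filter_tally": report.get("filter_tally"),
            "n_significant": report["n_significant"],
        }
        with open(lpath, "w") as fh:
            json.dump(log, fh, indent=1, default=str)
        written.append(lpath)
        return report
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise PipelineError(f"stage {stage!r}: {exc}") from exc
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
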