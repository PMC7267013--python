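"""Readers and writers for the pipeline's external formats.

Landmark tables are plain CSV (one row per landmark: leaf_id, line_id,
deme, position, block, landmark_index, x, y); genotypes are VCF 4.x with
GT and per-sample DP, read through cyvcf2.  Line metadata is a TSV with
line_id and deme columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .geometry import Outline
from .popgen import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_landmark_csv",
    "write_landmark_csv",
    "read_line_metadata",
    "read_vcf",
]

_LANDMARK_COLUMNS = ("leaf_id", "line_id", "deme", "position", "block",
                     "landmark_index", "x", "y")


def write_landmark_csv(outlines, path, deme_of_line: dict | None = None) -> None:
    """Write outlines in the landmark CSV dialect (one row per landmark)."""
    deme_of_line = deme_of_line or {}
    frames = []
    for o in outlines:
        k = o.k
        frames.append(
            pd.DataFrame(
                {
                    "leaf_id": o.id,
                    "line_id": o.line_id,
                    "deme": deme_of_line.get(o.line_id, ""),
                    "position": o.position,
                    "block": o.block,
                    "landmark_index": np.arange(k),
                    "x": o.points[:, 0],
                    "y": o.points[:, 1],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_LANDMARK_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_landmark_csv(path) -> list:
    """Read a landmark CSV into a list of :class:`Outline`.

    Leaves are grouped by ``leaf_id`` (file order preserved) with landmarks
    ordered by ``landmark_index``; indices must run contiguously from 0.
    Raises :class:`ParseError` (with the offending row or leaf) for missing
    columns, non-numeric coordinates or index gaps.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file without header") from exc
    missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        return []
    for col in ("landmark_index", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric {col!r} at data row {bad[0] + 1}"
            )
        df[col] = vals
    outlines = []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        grp = grp.sort_values("landmark_index")
        idx = grp["landmark_index"].to_numpy(dtype=int)
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ParseError(
                f"{path}: leaf {leaf_id!r} has non-contiguous landmark indices"
            )
        outlines.append(
            Outline(
                points=grp[["x", "y"]].to_numpy(dtype=float),
                id=str(leaf_id),
                line_id=str(grp["line_id"].iloc[0]),
                position=str(grp["position"].iloc[0]),
                block=str(grp["block"].iloc[0]),
            )
        )
    return outlines


def read_line_metadata(path) -> pd.DataFrame:
    """Line metadata TSV with at least line_id and deme columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("line_id", "deme"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return df


# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN (incl. half calls), 3 HOM_ALT
_CYVCF2_MAP = np.array([0, 1, -1, 2], dtype=np.int8)


def read_vcf(path, ann_key: str = "ANN_CLASS", gene_key: str = "GENE"):
    """Read biallelic SNPs from a VCF 4.x into a :class:`GenotypeMatrix`.

    GT is required; DP is kept when present (all-zero/absent DP yields
    ``depths=None``, in which case the depth filter must be disabled).
    Multi-allelic records are skipped and tallied.  The neutrality class
    and gene annotation are read from the INFO keys ``ann_key`` /
    ``gene_key`` when present.  Returns (GenotypeMatrix, tally dict).
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise ParseError(f"{path}: no such file")
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc
    line_ids = list(vcf.samples)
    if not line_ids:
        raise ParseError(f"{path}: VCF has no sample columns")
    calls, depth_cols, meta = [], [], []
    tally = {"kept": 0, "multiallelic_skipped": 0, "non_snp_skipped": 0}
    have_depth = True
    for v in vcf:
        if len(v.ALT) != 1:
            tally["multiallelic_skipped"] += 1
            continue
        calls.append(_CYVCF2_MAP[np.asarray(v.gt_types)])
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            have_depth = False
            depth_cols.append(np.zeros(len(line_ids), dtype=np.int32))
        else:
            depth_cols.append(np.maximum(dp.reshape(-1), 0).astype(np.int32))
        meta.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "id": v.ID or f"{v.CHROM}:{v.POS}",
                "ref": v.REF,
                "alt": v.ALT[0],
                "neutrality": v.INFO.get(ann_key) or "non-neutral",
                "annotation": v.INFO.get(gene_key) or "",
            }
        )
        tally["kept"] += 1
    if not meta:
        raise ParseError(f"{path}: no usable biallelic records")
    gmatrix = GenotypeMatrix(
        line_ids,
        np.column_stack(calls),
        pd.DataFrame(meta),
        np.column_stack(depth_cols) if have_depth else None,
    )
    return gmatrix, tally
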