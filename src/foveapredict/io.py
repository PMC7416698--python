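"""On-disk formats.

* B-scans: TSV, first row lateral positions (deg), first column depth (um, 0
  at BrM after alignment, increasing toward vitreous), body reflectivity;
  ground truth (when present) in a sidecar ``<scan>.truth.tsv``.
* Cohorts: CSV with header ``subject_id,group,age,fs_db,va_decimal`` plus
  ground-truth scalar columns prefixed ``gt_``; non-detectable sensitivity is
  the literal string ``ND``.

Round-trips are lossless to 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .oct import BScan
from .synth import CohortRow, CohortTable, build_retina

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.8g"

ND_LITERAL = "ND"

_COHORT_COLUMNS = [
    "subject_id", "group", "age", "fs_db", "va_decimal",
    "gt_onl_fovea", "gt_is_fovea", "gt_cos_fovea", "gt_rpe_fovea",
    "gt_pit_center", "gt_gap_offset",
]


# ---------------------------------------------------------------------------
# B-scans
# ---------------------------------------------------------------------------

def write_bscan(scan: BScan, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("depth_um\t" + "\t".join(_FLOAT_FMT % x for x in scan.lateral_axis) + "\n")
        for i, d in enumerate(scan.depth_axis):
            row = "\t".join(_FLOAT_FMT % x for x in scan.reflectivity[i])
            fh.write(_FLOAT_FMT % d + "\t" + row + "\n")
    if scan.truth is not None:
        tpath = path.with_name(path.stem + ".truth.tsv")
        with tpath.open("w") as fh:
            fh.write("boundary\t" + "\t".join(_FLOAT_FMT % x for x in scan.lateral_axis) + "\n")
            for name, depths in scan.truth.items():
                fh.write(name + "\t" + "\t".join(_FLOAT_FMT % x for x in depths) + "\n")


def read_bscan(path: str | Path) -> BScan:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "depth_um":
            raise ParseError(f"{path}:1: expected header starting with 'depth_um'")
        try:
            lateral = np.array([float(x) for x in header[1:]])
        except ValueError as e:
            raise ParseError(f"{path}:1: non-numeric lateral position ({e})") from None
        depths, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != lateral.size + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {lateral.size + 1} columns, got {len(parts)}"
                )
            try:
                depths.append(float(parts[0]))
                rows.append([float(x) for x in parts[1:]])
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({e})") from None
    if not rows:
        raise ParseError(f"{path}: no data rows")
    depth = np.array(depths)
    refl = np.array(rows)

    # normalize axis orientation (canonical: both strictly increasing)
    if depth.size > 1 and np.all(np.diff(depth) < 0):
        logger.warning("%s: depth axis reversed; normalizing", path)
        depth, refl = depth[::-1], refl[::-1, :]
    if lateral.size > 1 and np.all(np.diff(lateral) < 0):
        logger.warning("%s: lateral axis reversed; normalizing", path)
        lateral, refl = lateral[::-1], refl[:, ::-1]
    if depth.size > 1 and not np.all(np.diff(depth) > 0):
        raise ParseError(f"{path}: depth axis not monotone")
    if lateral.size > 1 and not np.all(np.diff(lateral) > 0):
        raise ParseError(f"{path}: lateral axis not monotone")

    truth = None
    tpath = path.with_name(path.stem + ".truth.tsv")
    if tpath.exists():
        truth = {}
        with tpath.open() as fh:
            fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                truth[parts[0]] = np.array([float(x) for x in parts[1:]])
    return BScan(reflectivity=refl, depth_axis=depth, lateral_axis=lateral, truth=truth)


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for r in cohort:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "fs_db": ND_LITERAL if r.fs_db is None else r.fs_db,
                "va_decimal": r.va_decimal,
                "gt_onl_fovea": r.retina.onl_fovea,
                "gt_is_fovea": r.retina.is_fovea,
                "gt_cos_fovea": r.retina.cos_fovea,
                "gt_rpe_fovea": r.retina.rpe_fovea,
                "gt_pit_center": r.retina.pit_center,
                "gt_gap_offset": r.retina.gap_offset,
            }
        )
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype={"fs_db": str})
    missing = set(_COHORT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        fs = None if str(r["fs_db"]).strip() == ND_LITERAL else float(r["fs_db"])
        retina = build_retina(
            subject_id=str(r["subject_id"]),
            group=str(r["group"]),
            onl_fovea=float(r["gt_onl_fovea"]),
            is_fovea=float(r["gt_is_fovea"]),
            cos_fovea=float(r["gt_cos_fovea"]),
            rpe_fovea=float(r["gt_rpe_fovea"]),
            pit_center=float(r.get("gt_pit_center", 0.0)),
            gap_offset=float(r.get("gt_gap_offset", 0.0)),
        )
        rows.append(
            CohortRow(
                subject_id=str(r["subject_id"]),
                group=str(r["group"]),
                age=float(r["age"]),
                fs_db=fs,
                va_decimal=float(r["va_decimal"]),
                retina=retina,
            )
        )
    return CohortTable(rows=rows)
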