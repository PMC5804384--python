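"""Readers and writers for landmark tables and study reports.

The landmark interchange format is a long table (CSV or JSON records),
one row per landmark point:

    patient_id, joint_id, side, diagnosis, position, landmark,
    x_mm, y_mm, fh_dx, fh_dy, sup_dx, sup_dy, rater_id, session_id

Coordinates are millimetres in image space with y increasing superior
unless ``sup_dx/sup_dy`` override the superior direction; ``fh_dx/fh_dy``
optionally give the Frankfort-horizontal trace (defaults to the T→P
tangent at measurement time).  ``rater_id``/``session_id`` distinguish
replicate measurement sessions for reliability analysis.

Validation is strict and row-addressed: missing landmarks, duplicates and
unknown enum values are reported with the offending rows.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import LandmarkSet
from .kinematics import Cohort, DIAGNOSES, JointRecord, POSITIONS
from .report import StudyReport, render_markdown

__all__ = [
    "LANDMARK_COLUMNS",
    "read_landmarks",
    "read_replicates",
    "write_landmarks",
    "write_report",
]

LANDMARK_COLUMNS = [
    "patient_id", "joint_id", "side", "diagnosis", "position", "landmark",
    "x_mm", "y_mm", "fh_dx", "fh_dy", "sup_dx", "sup_dy",
    "rater_id", "session_id",
]
_REQUIRED = LANDMARK_COLUMNS[:8]
LANDMARK_NAMES = ("T", "P", "G", "C", "D")


def _load_frame(path, fmt: Optional[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark file not found: {path}")
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, dtype={"rater_id": "string", "session_id": "string"},
                         float_precision="round_trip")
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise ValidationError(f"{path}: JSON landmark file must be a list of rows")
        df = pd.DataFrame(rows)
    else:
        raise ValidationError(f"unknown landmark format {fmt!r}; use 'csv' or 'json'")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for c in LANDMARK_COLUMNS:
        if c not in df.columns:
            df[c] = pd.NA
    return df


def _fail_rows(df_index, msg: str):
    rows = ", ".join(str(i + 2) for i in list(df_index)[:10])  # 1-based + header
    raise ValidationError(f"{msg} (rows {rows})")


def _validate(df: pd.DataFrame, path) -> pd.DataFrame:
    bad = df[~df["landmark"].isin(LANDMARK_NAMES)]
    if len(bad):
        _fail_rows(bad.index, f"{path}: unknown landmark names {sorted(set(bad['landmark']))}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = df[~pos.isin(POSITIONS)]
    if len(bad):
        _fail_rows(bad.index, f"{path}: position must be one of {POSITIONS}")
    df = df.assign(position=pos.astype(int))
    bad = df[~df["diagnosis"].isin(DIAGNOSES)]
    if len(bad):
        _fail_rows(bad.index, f"{path}: unknown diagnosis values "
                              f"{sorted(set(bad['diagnosis']))}; expected {DIAGNOSES}")
    bad = df[~df["side"].isin(("left", "right"))]
    if len(bad):
        _fail_rows(bad.index, f"{path}: side must be 'left' or 'right'")
    for col in ("x_mm", "y_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[vals.isna()]
        if len(bad):
            _fail_rows(bad.index, f"{path}: non-numeric {col}")
        df = df.assign(**{col: vals.astype(float)})
    key = ["joint_id", "position", "landmark", "rater_id", "session_id"]
    dup = df[df.duplicated(subset=key, keep=False)]
    if len(dup):
        _fail_rows(dup.index, f"{path}: duplicate landmark rows for "
                              f"{sorted(set(map(tuple, dup[key[:3]].values)))[:5]}")
    return df


def _opt_vec(row, cx: str, cy: str) -> Optional[np.ndarray]:
    x, y = row[cx], row[cy]
    if pd.isna(x) and pd.isna(y):
        return None
    if pd.isna(x) or pd.isna(y):
        raise ValidationError(f"{cx}/{cy} must be given together (joint {row['joint_id']})")
    return np.array([float(x), float(y)])


def _build_cohort(df: pd.DataFrame, path) -> Cohort:
    cohort = Cohort()
    for joint_id, jdf in df.groupby("joint_id", sort=True):
        consts = {}
        for col in ("patient_id", "side", "diagnosis"):
            vals = set(jdf[col])
            if len(vals) != 1:
                _fail_rows(jdf.index, f"{path}: joint {joint_id} has conflicting {col} values {sorted(vals)}")
            consts[col] = vals.pop()
        rec = JointRecord(joint_id=str(joint_id), patient_id=str(consts["patient_id"]),
                          side=consts["side"], diagnosis=consts["diagnosis"])
        for pos, pdf in jdf.groupby("position"):
            present = dict(zip(pdf["landmark"], pdf.index))
            missing = [n for n in LANDMARK_NAMES if n not in present]
            if missing:
                raise ValidationError(
                    f"{path}: joint {joint_id} position {pos} is missing "
                    f"landmark(s) {missing}"
                )
            pts = {}
            for name in LANDMARK_NAMES:
                row = pdf.loc[present[name]]
                pts[name] = np.array([row["x_mm"], row["y_mm"]])
            any_row = pdf.loc[present["G"]]
            fh = _opt_vec(any_row, "fh_dx", "fh_dy")
            sup = _opt_vec(any_row, "sup_dx", "sup_dy")
            try:
                rec.landmarks[int(pos)] = LandmarkSet(
                    fh_dir=fh,
                    superior_dir=sup if sup is not None else np.array([0.0, 1.0]),
                    side=consts["side"], **pts,
                )
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: joint {joint_id} position {pos}: {exc}"
                ) from exc
        cohort.records.append(rec)
    return cohort


def read_landmarks(path, fmt: Optional[str] = None) -> Cohort:
    """Read a landmark table into a validated cohort.

    The file must contain a single measurement session; use
    :func:`read_replicates` when multiple ``rater_id``/``session_id``
    combinations are present."""
    df = _validate(_load_frame(path, fmt), path)
    combos = df[["rater_id", "session_id"]].fillna("").drop_duplicates()
    if len(combos) > 1:
        raise ValidationError(
            f"{path}: {len(combos)} rater/session combinations present; "
            "use read_replicates() for reliability data"
        )
    return _build_cohort(df, path)


def read_replicates(path, fmt: Optional[str] = None) -> Dict[Tuple[str, str], Cohort]:
    """Read a multi-session landmark table, one cohort per
    (rater_id, session_id) combination, keyed in sorted order."""
    df = _validate(_load_frame(path, fmt), path)
    out: Dict[Tuple[str, str], Cohort] = {}
    filled = df.assign(
        rater_id=df["rater_id"].fillna(""), session_id=df["session_id"].fillna("")
    )
    for (rater, session), sub in filled.groupby(["rater_id", "session_id"], sort=True):
        out[(str(rater), str(session))] = _build_cohort(sub, path)
    return out


def write_landmarks(
    cohort: Cohort, path, fmt: Optional[str] = None,
    rater_id: Optional[str] = None, session_id: Optional[str] = None,
) -> None:
    """Write a cohort's landmarks as a long CSV/JSON table."""
    rows = []
    # canonical row order (sorted by joint, position, landmark) so that
    # any accepted file re-serializes to an identical file
    for rec in sorted(cohort.records, key=lambda r: r.joint_id):
        for pos in sorted(rec.landmarks):
            lm = rec.landmarks[pos]
            for name in LANDMARK_NAMES:
                pt = getattr(lm, name)
                rows.append({
                    "patient_id": rec.patient_id,
                    "joint_id": rec.joint_id,
                    "side": rec.side,
                    "diagnosis": rec.diagnosis,
                    "position": pos,
                    "landmark": name,
                    "x_mm": float(pt[0]),
                    "y_mm": float(pt[1]),
                    "fh_dx": None if lm.fh_dir is None else float(lm.fh_dir[0]),
                    "fh_dy": None if lm.fh_dir is None else float(lm.fh_dir[1]),
                    "sup_dx": float(lm.superior_dir[0]),
                    "sup_dy": float(lm.superior_dir[1]),
                    "rater_id": rater_id,
                    "session_id": session_id,
                })
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    df = pd.DataFrame(rows, columns=LANDMARK_COLUMNS)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        clean = [
            {k: v for k, v in row.items() if v is not None and not
             (isinstance(v, float) and math.isnan(v))}
            for row in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(clean, indent=1), encoding="utf-8")
    else:
        raise ValidationError(f"unknown landmark format {fmt!r}")


def _write_table1(report: StudyReport, outdir: Path) -> None:
    rows = [
        {"group": g, "position": pos, "n": ds.n,
         "mean_deg": ds.mean, "sd_deg": ds.sd}
        for g, per_pos in report.table1.items()
        for pos, ds in sorted(per_pos.items())
    ]
    pd.DataFrame(rows, columns=["group", "position", "n", "mean_deg", "sd_deg"]
                 ).to_csv(outdir / "table1.csv", index=False)


def _write_table2(report: StudyReport, outdir: Path) -> None:
    rows = [
        {"group": g, "position": pos, "variable": var, "n": ds.n,
         "mean_mm": ds.mean, "sd_mm": ds.sd}
        for g, per_pos in report.table2.items()
        for pos, per_var in sorted(per_pos.items())
        for var, ds in per_var.items()
    ]
    pd.DataFrame(rows, columns=["group", "position", "variable", "n", "mean_mm", "sd_mm"]
                 ).to_csv(outdir / "table2.csv", index=False)


def _write_movements(report: StudyReport, outdir: Path) -> None:
    rows = []
    for g, per_struct in report.movements.items():
        for structure, spans in per_struct.items():
            for span, vec in spans.items():
                a, b = span.replace("P", "").split("->")
                rows.append({
                    "group": g, "structure": structure,
                    "from_pos": int(a), "to_pos": int(b),
                    "dx_mm": vec.dx, "dy_mm": vec.dy,
                    "anterior_mm": vec.anterior_mm, "posterior_mm": vec.posterior_mm,
                    "inferior_mm": vec.inferior_mm, "superior_mm": vec.superior_mm,
                })
    pd.DataFrame(rows, columns=[
        "group", "structure", "from_pos", "to_pos", "dx_mm", "dy_mm",
        "anterior_mm", "posterior_mm", "inferior_mm", "superior_mm",
    ]).to_csv(outdir / "movements.csv", index=False)


def _write_recapture(report: StudyReport, outdir: Path) -> None:
    rows = [
        {"treated_position": pos, "count": rr.count, "total": rr.total,
         "pct": rr.pct, "n_excluded": report.recapture_excluded}
        for pos, rr in sorted(report.recapture.items())
    ]
    pd.DataFrame(rows, columns=["treated_position", "count", "total", "pct", "n_excluded"]
                 ).to_csv(outdir / "recapture.csv", index=False)


def write_report(report: StudyReport, outdir, markdown: bool = False) -> List[Path]:
    """Write the study report as CSV tables plus a JSON document.

    Emits ``table1.csv``, ``table2.csv``, ``movements.csv``,
    ``recapture.csv`` and ``report.json`` (UTF-8, stable column order);
    optionally also ``report.md``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_table1(report, outdir)
    _write_table2(report, outdir)
    _write_movements(report, outdir)
    _write_recapture(report, outdir)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    written = [outdir / n for n in
               ("table1.csv", "table2.csv", "movements.csv", "recapture.csv", "report.json")]
    if markdown:
        (outdir / "report.md").write_text(render_markdown(report), encoding="utf-8")
        written.append(outdir / "report.md")
    return written
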