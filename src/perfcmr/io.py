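"""Readers and writers for the curve CSV and territory JSON exchange formats.

The analysis starts from ROI-averaged curves, so the interchange format is a
long-format CSV with one row per (patient, ROI, frame):

    patient_id, roi_id, roi_kind, slice_level, frame_index, time_s, si, n_baseline

``frame_index`` is 0-based; ``n_baseline`` is constant within an ROI.  The
per-patient metadata (group, adenosine heart rate, territory definitions and
LGE flags) travels in a JSON sidecar::

    {"patients": [{"patient_id": ..., "group": ..., "hr_adenosine": ...,
                   "lge": {"7": false, ...},
                   "territories": [{"territory_id": ..., "supply_kind": ...,
                                    "native_vessel": ..., "native_status": ...,
                                    "segment_ids": [..]}]}]}

Myocardial ROI ids follow the ``seg%02d`` convention so the AHA segment
number can be recovered from the id.  All floating-point output uses fixed
6-decimal formatting for reproducible diffs.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .curves import LV_BLOOD_POOL, MYOCARDIAL_SEGMENT, SignalTimeCurve
from .errors import CurveParseError
from .territories import TerritoryDef

__all__ = [
    "write_curves",
    "read_curves",
    "write_territories",
    "read_territories",
    "write_cohort",
    "read_cohort",
    "segment_id_of_roi",
]

CURVE_COLUMNS = [
    "patient_id",
    "roi_id",
    "roi_kind",
    "slice_level",
    "frame_index",
    "time_s",
    "si",
    "n_baseline",
]

_SEG_RE = re.compile(r"^seg(\d{1,2})$")
FLOAT_FMT = "%.6f"


def segment_id_of_roi(roi_id: str) -> int:
    m = _SEG_RE.match(roi_id)
    if not m:
        raise CurveParseError(f"myocardial roi id {roi_id!r} is not of the form 'segNN'")
    return int(m.group(1))


def write_curves(patients: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write all curves of a cohort to the long-format CSV."""
    rows = []
    for p in patients:
        curves = [p.lv_curve] + [p.segment_curves[s] for s in sorted(p.segment_curves)]
        for c in curves:
            for i in range(len(c)):
                rows.append(
                    (p.patient_id, c.roi_id, c.roi_kind, c.slice_level, i,
                     c.times[i], c.si[i], c.n_baseline)
                )
    df = pd.DataFrame(rows, columns=CURVE_COLUMNS)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_curves(path: Union[str, Path]) -> Dict[str, Dict[str, SignalTimeCurve]]:
    """Read a curve CSV into ``{patient_id: {roi_id: curve}}``.

    The result is independent of row order.  Structural problems raise
    :class:`CurveParseError` naming the offending patient/ROI/frame.
    """
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise CurveParseError(f"{path}: missing required columns {missing}")
    dup = df.duplicated(subset=["patient_id", "roi_id", "frame_index"])
    if dup.any():
        row = df[dup].iloc[0]
        raise CurveParseError(
            f"{path}: duplicate frame (patient {row.patient_id}, roi {row.roi_id}, "
            f"frame {row.frame_index})"
        )
    out: Dict[str, Dict[str, SignalTimeCurve]] = {}
    for (pid, roi), grp in df.groupby(["patient_id", "roi_id"], sort=True):
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise CurveParseError(
                f"{path}: non-contiguous frame indices for patient {pid}, roi {roi}"
            )
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise CurveParseError(
                f"{path}: non-monotone times for patient {pid}, roi {roi}"
            )
        nb = grp["n_baseline"].unique()
        if len(nb) != 1:
            raise CurveParseError(
                f"{path}: inconsistent n_baseline for patient {pid}, roi {roi}"
            )
        kind = grp["roi_kind"].iloc[0]
        if kind not in (LV_BLOOD_POOL, MYOCARDIAL_SEGMENT):
            raise CurveParseError(
                f"{path}: unknown roi_kind {kind!r} for patient {pid}, roi {roi}"
            )
        out.setdefault(str(pid), {})[str(roi)] = SignalTimeCurve(
            roi_id=str(roi),
            roi_kind=kind,
            times=times,
            si=grp["si"].to_numpy(dtype=float),
            n_baseline=int(nb[0]),
            slice_level=str(grp["slice_level"].iloc[0]),
        )
    return out


def write_territories(patients: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write per-patient metadata (group, HR, LGE flags, territories) as JSON."""
    doc = {
        "patients": [
            {
                "patient_id": p.patient_id,
                "group": p.group,
                "hr_adenosine": round(p.hr_adenosine, 6),
                "lge": {str(s): bool(v) for s, v in sorted(p.lge.items())},
                "territories": [
                    {
                        "territory_id": t.territory_id,
                        "supply_kind": t.supply_kind,
                        "native_vessel": t.native_vessel,
                        "native_status": t.native_status,
                        "segment_ids": sorted(t.segment_ids),
                    }
                    for t in p.territories
                ],
            }
            for p in patients
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_territories(path: Union[str, Path]) -> List[dict]:
    doc = json.loads(Path(path).read_text())
    if "patients" not in doc:
        raise CurveParseError(f"{path}: missing top-level 'patients' key")
    return doc["patients"]


def write_cohort(patients: Sequence[PatientRecord], out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Write a cohort as ``curves.csv`` + ``territories.json`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curves_path = out / "curves.csv"
    terr_path = out / "territories.json"
    write_curves(patients, curves_path)
    write_territories(patients, terr_path)
    return {"curves": curves_path, "territories": terr_path}


def read_cohort(
    curves_path: Union[str, Path], territories_path: Union[str, Path]
) -> List[PatientRecord]:
    """Assemble :class:`PatientRecord` objects from the two exchange files."""
    curve_map = read_curves(curves_path)
    meta = read_territories(territories_path)
    patients: List[PatientRecord] = []
    for m in meta:
        pid = m["patient_id"]
        if pid not in curve_map:
            raise CurveParseError(f"no curves found for patient {pid}")
        rois = curve_map[pid]
        lv = [c for c in rois.values() if c.roi_kind == LV_BLOOD_POOL]
        if len(lv) != 1:
            raise CurveParseError(
                f"patient {pid}: expected exactly 1 LV blood-pool curve, found {len(lv)}"
            )
        seg_curves = {
            segment_id_of_roi(rid): c
            for rid, c in rois.items()
            if c.roi_kind == MYOCARDIAL_SEGMENT
        }
        territories = [
            TerritoryDef(
                territory_id=t["territory_id"],
                supply_kind=t["supply_kind"],
                native_vessel=t["native_vessel"],
                native_status=t.get("native_status", "not_applicable"),
                segment_ids=frozenset(int(s) for s in t["segment_ids"]),
            )
            for t in m["territories"]
        ]
        patients.append(
            PatientRecord(
                patient_id=pid,
                group=m["group"],
                hr_adenosine=float(m["hr_adenosine"]),
                lv_curve=lv[0],
                segment_curves=seg_curves,
                lge={int(s): bool(v) for s, v in m["lge"].items()},
                territories=territories,
            )
        )
    return patients
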