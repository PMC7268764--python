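"""Reading and writing the package's file dialects.

Eye-level boundary input (JSON, or a long-format CSV), per-section metrics
CSV, and per-section grades CSV.  Coordinates are millimetres throughout.

Eye JSON schema::

    {"eye_id": str, "laterality": "OD"|"OS",
     "scans": [{"meridian_deg": float,
                "posterior_cornea": [[x, y], ...],      # full width
                "anterior_iris_left": [[x, y], ...],
                "anterior_iris_right": [[x, y], ...],
                "spur_left": [x, y], "spur_right": [x, y]}, ...]}

The CSV alternative is long format with columns eye_id, meridian_deg,
boundary (posterior_cornea | anterior_iris | spur), side (left | right |
full), idx, x_mm, y_mm (plus an optional laterality column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .geometry import (
    AngleMetrics,
    BScanSection,
    find_endothelial_apex,
    measure_section,
)
from .model import Grade

__all__ = [
    "Scan",
    "Eye",
    "load_eye_json",
    "load_eye_csv",
    "section_index",
    "eye_sections",
    "measure_eye",
    "write_metrics_csv",
    "read_metrics_csv",
    "metrics_from_frame",
]

METRIC_COLUMNS = ["aodss_mm", "aod750_mm", "tisa750_mm2", "lid_mm"]


@dataclass
class Scan:
    meridian_deg: float
    posterior_cornea: np.ndarray
    anterior_iris_left: np.ndarray
    anterior_iris_right: np.ndarray
    spur_left: np.ndarray
    spur_right: np.ndarray


@dataclass
class Eye:
    eye_id: str
    laterality: Literal["OD", "OS"]
    scans: list[Scan]


def load_eye_json(source) -> Eye:
    """Load one eye document (path, file object, or already-parsed dict)."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    scans = [Scan(meridian_deg=float(s["meridian_deg"]),
                  posterior_cornea=np.asarray(s["posterior_cornea"], float),
                  anterior_iris_left=np.asarray(s["anterior_iris_left"], float),
                  anterior_iris_right=np.asarray(s["anterior_iris_right"], float),
                  spur_left=np.asarray(s["spur_left"], float),
                  spur_right=np.asarray(s["spur_right"], float))
             for s in doc["scans"]]
    return Eye(eye_id=str(doc["eye_id"]), laterality=doc["laterality"],
               scans=scans)


def load_eye_csv(path) -> Eye:
    """Load one eye from the long-format CSV dialect."""
    df = pd.read_csv(path)
    eye_ids = df["eye_id"].unique()
    if len(eye_ids) != 1:
        raise ValueError("long-format CSV must contain exactly one eye")
    laterality = str(df["laterality"].iloc[0]) if "laterality" in df else "OD"
    scans = []
    for meridian, g in df.groupby("meridian_deg"):
        def pts(boundary, side):
            sel = g[(g["boundary"] == boundary) & (g["side"] == side)]
            sel = sel.sort_values("idx")
            return sel[["x_mm", "y_mm"]].to_numpy(float)

        spur_l = pts("spur", "left")
        spur_r = pts("spur", "right")
        scans.append(Scan(
            meridian_deg=float(meridian),
            posterior_cornea=pts("posterior_cornea", "full"),
            anterior_iris_left=pts("anterior_iris", "left"),
            anterior_iris_right=pts("anterior_iris", "right"),
            spur_left=spur_l.reshape(-1)[:2],
            spur_right=spur_r.reshape(-1)[:2]))
    return Eye(eye_id=str(eye_ids[0]), laterality=laterality, scans=scans)


def section_index(meridian_deg: float, side: Literal["left", "right"]) -> int:
    """Section index 0–31 of one side of a meridian.

    The right side of the scan at meridian θ is the section centred at θ;
    the left side is centred at θ+180°.
    """
    theta = float(meridian_deg) % 360.0
    if side == "left":
        theta = (theta + 180.0) % 360.0
    idx = int(round(theta / 11.25)) % 32
    return idx


def eye_sections(eye: Eye):
    """Yield ``(index, section, apex)`` for every angle section of an eye.

    Each scan's full-width posterior cornea is split at the detected
    endothelial apex into the two per-side wall polylines.
    """
    for scan in eye.scans:
        full = scan.posterior_cornea
        apex = find_endothelial_apex(full)
        cut = int(np.argmin(np.abs(full[:, 0] - apex[0])
                            + np.abs(full[:, 1] - apex[1])))
        cut = min(max(cut, 1), len(full) - 2)
        right_wall = full[cut:]
        left_wall = full[:cut + 1][::-1]
        m = scan.meridian_deg % 360.0
        for side, wall, iris, spur in (
                ("right", right_wall, scan.anterior_iris_right, scan.spur_right),
                ("left", left_wall, scan.anterior_iris_left, scan.spur_left)):
            sec = BScanSection(posterior_cornea=wall, anterior_iris=iris,
                               scleral_spur=spur, side=side, meridian_deg=m)
            yield section_index(scan.meridian_deg, side), sec, apex


def measure_eye(eye: Eye, lid_distance: str = "euclidean") -> pd.DataFrame:
    """Measure all sections of an eye into a metrics table.

    Columns: eye_id, meridian_deg, side, section_index, the four parameters
    and a status string ("ok" or per-metric failure reasons).
    """
    rows = []
    for idx, sec, apex in eye_sections(eye):
        m = measure_section(sec, apex, lid_distance=lid_distance)
        rows.append({
            "eye_id": eye.eye_id,
            "meridian_deg": sec.meridian_deg,
            "side": sec.side,
            "section_index": idx,
            "aodss_mm": m.aodss,
            "aod750_mm": m.aod750,
            "tisa750_mm2": m.tisa750,
            "lid_mm": m.lid,
            "status": m.status(),
        })
    return pd.DataFrame(rows).sort_values("section_index").reset_index(drop=True)


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def metrics_from_frame(df: pd.DataFrame, eye_id: str | None = None
                       ) -> list[AngleMetrics | None]:
    """Rebuild the 32-entry section metrics list from a metrics table."""
    if eye_id is not None:
        df = df[df["eye_id"] == eye_id]
    out: list[AngleMetrics | None] = [None] * 32
    for _, row in df.iterrows():
        idx = int(row["section_index"])
        m = AngleMetrics()
        for field_name, col in zip(("aodss", "aod750", "tisa750", "lid"),
                                   METRIC_COLUMNS):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                m.failures[field_name] = "missing"
            else:
                setattr(m, field_name, float(v))
        out[idx] = m
    return out


def grades_to_frame(eye_id: str, gmap) -> pd.DataFrame:
    """Flatten an :class:`~acangle.mapping.EyeGradeMap` into a grades table."""
    from .mapping import section_to_quadrant

    rows = []
    for i in range(32):
        p = gmap.section_probs[i]
        g = gmap.section_grades[i]
        rows.append({
            "eye_id": eye_id,
            "section_index": i,
            "quadrant": section_to_quadrant(i, gmap.laterality),
            "lid_mm": gmap.section_lids[i],
            "p_sa": p.p_sa if p else np.nan,
            "p_ma": p.p_ma if p else np.nan,
            "p_la": p.p_la if p else np.nan,
            "grade": g.name if g is not None else "",
        })
    return pd.DataFrame(rows)


def read_grades_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "grade" not in df.columns:
        raise ValueError("grades CSV must contain a 'grade' column")
    return df


def grades_column(df: pd.DataFrame) -> list[Grade]:
    return [Grade[str(g)] for g in df["grade"] if isinstance(g, str) and g]


def aligned_grade_pairs(actual: pd.DataFrame, predicted: pd.DataFrame
                        ) -> tuple[list[Grade], list[Grade]]:
    """Pair two grade tables for comparison.

    When both tables carry (eye_id, section_index) the rows are joined on
    those keys; otherwise they are paired by row order (requiring equal
    length).  Rows with an empty grade on either side are dropped.
    """
    keys = ["eye_id", "section_index"]
    if all(k in actual.columns for k in keys) and \
            all(k in predicted.columns for k in keys):
        merged = actual.merge(predicted, on=keys, suffixes=("_a", "_p"))
        ga, gp = merged["grade_a"], merged["grade_p"]
    else:
        if len(actual) != len(predicted):
            raise ValueError("grade tables differ in length and carry no "
                             "(eye_id, section_index) keys to join on")
        ga, gp = actual["grade"].reset_index(drop=True), \
            predicted["grade"].reset_index(drop=True)
    out_a, out_p = [], []
    for a, p in zip(ga, gp):
        if isinstance(a, str) and a and isinstance(p, str) and p:
            out_a.append(Grade[a])
            out_p.append(Grade[p])
    return out_a, out_p
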