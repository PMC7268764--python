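"""Circumferential mapping: 32 angle sections, quadrants and grade maps.

Sixteen radial B-scans at 11.25° intervals yield 32 angle sections per eye,
indexed 0–31 by the meridian angle of the section centre (index * 11.25°,
with 0° temporal for a right eye and 90° superior).  Each quadrant
(superior / inferior / nasal / temporal) comprises a contiguous block of 8
sections; for a left eye the nasal and temporal quadrants mirror.  The
quadrant-level grading unit is the quadrant mean of the predictor, matching
the per-quadrant modeling unit; majority vote over section grades is
available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .geometry import AngleMetrics
from .model import (
    Grade,
    GradeProbabilities,
    OrderedLogitParams,
    classify,
    predict_probabilities,
)

__all__ = [
    "QUADRANTS",
    "EyeGradeMap",
    "section_to_quadrant",
    "sections_of_quadrant",
    "quadrant_aggregate",
    "build_grade_map",
    "render_grade_map",
]

QUADRANTS = ("S", "I", "N", "T")

#: block order rotating counterclockwise from the temporal block of an OD
_BLOCK_ORDER = ("T", "S", "N", "I")

_METRIC_FIELDS = ("aodss", "aod750", "tisa750", "lid")


def section_to_quadrant(section_index: int,
                        laterality: Literal["OD", "OS"] = "OD") -> str:
    """Quadrant (S/I/N/T) owning a section index.

    Blocks of 8 sections start at the 45° boundary sections: for an OD,
    temporal is indices {28..31, 0..3}, superior {4..11}, nasal {12..19},
    inferior {20..27}.  An OS mirrors nasal and temporal.
    """
    idx = int(section_index)
    if not 0 <= idx <= 31:
        raise ValueError(f"section index out of range: {idx}")
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    q = _BLOCK_ORDER[((idx + 4) % 32) // 8]
    if laterality == "OS":
        q = {"N": "T", "T": "N"}.get(q, q)
    return q


def sections_of_quadrant(quadrant: str,
                         laterality: Literal["OD", "OS"] = "OD") -> list[int]:
    """The 8 section indices belonging to a quadrant."""
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    return [i for i in range(32)
            if section_to_quadrant(i, laterality) == quadrant]


def quadrant_aggregate(metrics: Sequence[AngleMetrics | None],
                       laterality: Literal["OD", "OS"] = "OD"
                       ) -> dict[str, tuple[AngleMetrics | None, int]]:
    """Per-quadrant arithmetic means of the section parameters.

    ``metrics`` holds 32 entries (None for unmeasured sections).  For each
    quadrant and each parameter, the mean is taken over the sections where
    that parameter is present; a parameter missing everywhere is None, and a
    quadrant with no measured section at all maps to ``(None, 0)``.  The
    second tuple element counts contributing sections.
    """
    if len(metrics) != 32:
        raise ValueError("expected 32 section metrics")
    out: dict[str, tuple[AngleMetrics | None, int]] = {}
    for q in QUADRANTS:
        idxs = sections_of_quadrant(q, laterality)
        present = [metrics[i] for i in idxs if metrics[i] is not None]
        if not present:
            out[q] = (None, 0)
            continue
        agg = AngleMetrics()
        for name in _METRIC_FIELDS:
            vals = [getattr(m, name) for m in present
                    if getattr(m, name) is not None]
            if vals:
                setattr(agg, name, float(np.mean(vals)))
            else:
                agg.failures[name] = "missing in all sections of the quadrant"
        out[q] = (agg, len(present))
    return out


@dataclass
class EyeGradeMap:
    """Per-section and per-quadrant grading of one eye."""

    laterality: Literal["OD", "OS"]
    section_grades: list[Grade | None]
    section_lids: np.ndarray
    section_probs: list[GradeProbabilities | None]
    quadrant_grades: dict[str, Grade | None]
    quadrant_values: dict[str, dict[str, float] | None]
    proportions: dict[Grade, float] = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return sum(g is not None for g in self.section_grades)


def _predictor_vector(m: AngleMetrics | None, names: Sequence[str]
                      ) -> dict[str, float] | None:
    if m is None:
        return None
    vec = {}
    for name in names:
        if name not in _METRIC_FIELDS:
            return None
        v = getattr(m, name)
        if v is None:
            return None
        vec[name] = float(v)
    return vec


def build_grade_map(metrics: Sequence[AngleMetrics | None],
                    params: OrderedLogitParams,
                    laterality: Literal["OD", "OS"] = "OD",
                    quadrant_method: Literal["mean", "majority"] = "mean"
                    ) -> EyeGradeMap:
    """Grade all 32 sections and the four quadrants of one eye.

    Section grades come from the model probabilities at the section's
    predictor values; quadrant grades from the quadrant-mean predictor
    (default) or by majority vote of section grades.  Grade proportions are
    taken over the non-missing sections.
    """
    if len(metrics) != 32:
        raise ValueError("expected 32 section metrics")
    names = params.predictors
    grades: list[Grade | None] = []
    probs: list[GradeProbabilities | None] = []
    lids = np.full(32, np.nan)
    for i, m in enumerate(metrics):
        if m is not None and m.lid is not None:
            lids[i] = m.lid
        vec = _predictor_vector(m, names)
        if vec is None:
            grades.append(None)
            probs.append(None)
            continue
        p = predict_probabilities(params, vec)
        probs.append(p)
        grades.append(classify(p))

    agg = quadrant_aggregate(metrics, laterality)
    q_grades: dict[str, Grade | None] = {}
    q_values: dict[str, dict[str, float] | None] = {}
    for q in QUADRANTS:
        qm, _count = agg[q]
        vec = _predictor_vector(qm, names)
        q_values[q] = vec
        if quadrant_method == "mean":
            q_grades[q] = classify(predict_probabilities(params, vec)) \
                if vec is not None else None
        elif quadrant_method == "majority":
            votes = [grades[i] for i in sections_of_quadrant(q, laterality)
                     if grades[i] is not None]
            if votes:
                counts = np.bincount([int(v) for v in votes], minlength=3)
                q_grades[q] = Grade(int(np.argmax(counts)))
            else:
                q_grades[q] = None
        else:
            raise ValueError("quadrant_method must be 'mean' or 'majority'")

    valid = [g for g in grades if g is not None]
    proportions = {g: (sum(1 for v in valid if v == g) / len(valid)
                       if valid else float("nan"))
                   for g in (Grade.SA, Grade.MA, Grade.LA)}
    return EyeGradeMap(laterality=laterality, section_grades=grades,
                       section_lids=lids, section_probs=probs,
                       quadrant_grades=q_grades, quadrant_values=q_values,
                       proportions=proportions)


def render_grade_map(gmap: EyeGradeMap, path, title: str | None = None) -> None:
    """Best-effort polar rendering: 32 sectors shaded black/gray/white."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {Grade.SA: "black", Grade.MA: "0.6", Grade.LA: "white",
              None: "red"}
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"},
                           figsize=(4, 4))
    width = np.deg2rad(11.25)
    for i, g in enumerate(gmap.section_grades):
        ax.bar(np.deg2rad(11.25 * i), 1.0, width=width, bottom=0.6,
               color=colors[g], edgecolor="0.3", linewidth=0.4)
    ax.set_xticks(np.deg2rad([0, 90, 180, 270]))
    t_lbl, n_lbl = ("T", "N") if gmap.laterality == "OD" else ("N", "T")
    ax.set_xticklabels([t_lbl, "S", n_lbl, "I"])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
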