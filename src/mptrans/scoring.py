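"""Defect grading, summed perfusion scores and ROC defect detection.

Grades follow the five printed bands of relative regional uptake --
normal 75-100 % -> 0, mild 65-74 -> 1, moderate 50-64 -> 2, severe
40-49 -> 3, complete < 40 -> 4 -- applied to segment values normalized so
the per-study maximum segment reads 100.  Summed stress/rest/difference
scores (SSS/SRS/SDS) and per-territory sums follow, with the standard AHA
coronary territory assignment (config-overridable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .segment17 import N_SEGMENTS, SegmentTable

#: printed lower bounds of the grade bands, closed on the bound
GRADE_BANDS = ((75.0, 0), (65.0, 1), (50.0, 2), (40.0, 3))
COMPLETE_DEFECT = 4

TERRITORIES = ("LAD", "RCA", "LCX")

#: standard AHA segment -> supplying coronary artery
DEFAULT_TERRITORY_MAP: dict[int, str] = {
    **{s: "LAD" for s in (1, 2, 7, 8, 13, 14, 17)},
    **{s: "RCA" for s in (3, 4, 9, 10, 15)},
    **{s: "LCX" for s in (5, 6, 11, 12, 16)},
}


def validate_territory_map(tmap: dict[int, str]) -> dict[int, str]:
    if sorted(tmap) != list(range(1, N_SEGMENTS + 1)):
        raise ValueError("territory map must assign all 17 segments")
    if any(t not in TERRITORIES for t in tmap.values()):
        raise ValueError(f"territories must be among {TERRITORIES}")
    return dict(tmap)


def grade_uptake(u: float) -> int:
    """0-4 defect grade for a relative uptake percentage in [0, 100]."""
    if not 0 <= u <= 100:
        raise ValueError(f"uptake {u} outside [0, 100]")
    for lower, grade in GRADE_BANDS:
        if u >= lower:
            return grade
    return COMPLETE_DEFECT


@dataclass
class ScoreTable:
    """Per-segment grades and derived sums for one case."""

    stress_scores: np.ndarray
    rest_scores: np.ndarray
    diff_scores: np.ndarray = field(init=False)
    floor_differences: bool = True

    def __post_init__(self) -> None:
        self.stress_scores = np.asarray(self.stress_scores, dtype=int)
        self.rest_scores = np.asarray(self.rest_scores, dtype=int)
        for arr in (self.stress_scores, self.rest_scores):
            if arr.shape != (N_SEGMENTS,):
                raise ValueError("17 scores per state required")
            if arr.min() < 0 or arr.max() > 4:
                raise ValueError("scores must lie in 0..4")
        d = self.stress_scores - self.rest_scores
        self.diff_scores = np.maximum(d, 0) if self.floor_differences else d

    @property
    def sss(self) -> int:
        return int(self.stress_scores.sum())

    @property
    def srs(self) -> int:
        return int(self.rest_scores.sum())

    @property
    def sds(self) -> int:
        return int(self.diff_scores.sum())

    def territory_scores(
        self, territory_map: dict[int, str] | None = None
    ) -> dict[str, dict[str, int]]:
        """Per-territory SSS/SRS/SDS sums."""
        tmap = validate_territory_map(territory_map or DEFAULT_TERRITORY_MAP)
        out = {t: {"sss": 0, "srs": 0, "sds": 0} for t in TERRITORIES}
        for seg in range(1, N_SEGMENTS + 1):
            t = tmap[seg]
            out[t]["sss"] += int(self.stress_scores[seg - 1])
            out[t]["srs"] += int(self.rest_scores[seg - 1])
            out[t]["sds"] += int(self.diff_scores[seg - 1])
        return out


def relative_uptake(table: SegmentTable) -> np.ndarray:
    """Normalize segment values so the per-study maximum segment reads 100."""
    m = table.values.max()
    if m <= 0:
        raise ValueError("degenerate all-zero segment table")
    return np.clip(table.values * (100.0 / m), 0.0, 100.0)


def grade_table(table: SegmentTable) -> np.ndarray:
    rel = relative_uptake(table)
    return np.array([grade_uptake(u) for u in rel], dtype=int)


def score_case(
    stress_table: SegmentTable,
    rest_table: SegmentTable,
    *,
    floor_differences: bool = True,
) -> ScoreTable:
    """Grade a case's stress and rest segment tables into a ScoreTable."""
    return ScoreTable(
        stress_scores=grade_table(stress_table),
        rest_scores=grade_table(rest_table),
        floor_differences=floor_differences,
    )


def defect_presence(
    score_table: ScoreTable,
    territory: str,
    territory_map: dict[int, str] | None = None,
) -> bool:
    """True iff the territory's summed stress, rest or difference score >= 1."""
    if territory not in TERRITORIES:
        raise ValueError(f"unknown territory {territory!r}")
    t = score_table.territory_scores(territory_map)[territory]
    return t["sss"] >= 1 or t["srs"] >= 1 or t["sds"] >= 1


@dataclass
class RocResult:
    auc: float
    sensitivity: float
    specificity: float
    threshold: float


def roc_defect_detection(
    truth_labels: np.ndarray, index_scores: np.ndarray
) -> RocResult:
    """ROC analysis of defect detection from summed scores.

    AUC via the rank (Mann-Whitney) formulation with ties mid-ranked;
    operating point at the Youden-optimal threshold, reported with the
    sensitivity/specificity achieved there (predict positive when
    score >= threshold).
    """
    y = np.asarray(truth_labels, dtype=bool)
    s = np.asarray(index_scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("labels and scores must be matching 1-D arrays")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = np.argsort(np.argsort(s, kind="mergesort"), kind="mergesort") + 1.0
    # mid-rank ties
    order = np.argsort(s, kind="mergesort")
    sorted_s = s[order]
    ranks_sorted = np.arange(1, len(s) + 1, dtype=float)
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks_sorted[i : j + 1] = (i + 1 + j + 1) / 2.0
        i = j + 1
    ranks = np.empty_like(ranks_sorted)
    ranks[order] = ranks_sorted
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    fpr, tpr, thresholds = roc_curve(y.astype(int), s)
    youden = tpr - fpr
    k = int(np.argmax(youden))
    return RocResult(
        auc=float(auc),
        sensitivity=float(tpr[k]),
        specificity=float(1.0 - fpr[k]),
        threshold=float(thresholds[k]),
    )
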