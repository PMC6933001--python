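"""Praxis score semantics for the BCoS screening tasks.

The three praxis tasks and their score grids:

* Gesture Production -- pantomime of 6 gestures, 2/1/0 points per item,
  total 0-12.
* Gesture Recognition -- multiple-choice recognition of 6 gestures,
  1/0 per item, total 0-6.
* Meaningless Gesture Imitation -- copying 4 meaningless gestures,
  3/2/1/0 per item, total 0-12.

Picture Naming (0-14) is a language control task.  Age-banded cut-off
scores classify per-task impairment; a patient is apraxic when impaired
on at least one praxis task.  The cut-off tie rule used throughout is
"impaired iff score <= cut-off", which on the integer score grid is
equivalent to the fractional (2 SD below control mean) thresholds
11.5 / 5.8 / 11.5 shipped as :data:`SD_CUTOFFS`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TASK_MAXIMA",
    "PRAXIS_TASKS",
    "CutoffTable",
    "TABLE_CUTOFFS",
    "SD_CUTOFFS",
    "PatientRecord",
    "score_item",
    "score_task",
    "classify_impairment",
    "composite_apraxia_score",
    "correlate",
    "cohort_summary",
    "read_patient_table",
    "write_patient_table",
]

TASK_MAXIMA = {
    "gesture_production": 12,
    "gesture_recognition": 6,
    "gesture_imitation": 12,
    "picture_naming": 14,
}

PRAXIS_TASKS = ("gesture_production", "gesture_recognition", "gesture_imitation")

#: enumerated per-item outcome codes -> points
ITEM_SCORES = {
    "gesture_production": {
        "correct": 2,
        "recognizable_inaccurate": 1,
        "unrecognizable": 0,
        "no_response": 0,
        "perseveration": 0,
    },
    "gesture_recognition": {"correct": 1, "incorrect": 0},
    "gesture_imitation": {
        "correct_first": 3,
        "correct_second": 2,
        "one_error_second": 1,
        "fail": 0,
    },
    "picture_naming": {"correct": 1, "incorrect": 0},
}

#: number of items per task (maxima above = items x max item points)
N_ITEMS = {
    "gesture_production": 6,
    "gesture_recognition": 6,
    "gesture_imitation": 4,
    "picture_naming": 14,
}

#: age-band upper edges for the cut-off tables: <=64 / 65-74 / >=75.
#: Non-integer ages fall in the band containing their floor.
AGE_BAND_EDGES = (65.0, 75.0)


def score_item(task: str, outcome: str) -> int:
    """Points for a single coded item outcome of one task."""
    try:
        table = ITEM_SCORES[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(ITEM_SCORES)}")
    try:
        return table[outcome]
    except KeyError:
        raise ValueError(
            f"unknown outcome {outcome!r} for task {task!r}; expected one of {sorted(table)}"
        )


def score_task(task: str, outcomes) -> int:
    """Task total: sum of item scores over the task's full item list."""
    outcomes = list(outcomes)
    if len(outcomes) != N_ITEMS[task]:
        raise ValueError(f"{task} has {N_ITEMS[task]} items, got {len(outcomes)}")
    return sum(score_item(task, o) for o in outcomes)


@dataclass(frozen=True)
class CutoffTable:
    """Per-task cut-off scores for the age bands <=64 / 65-74 / >=75."""

    cutoffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for task, vals in self.cutoffs.items():
            if task not in TASK_MAXIMA:
                raise ValueError(f"unknown task {task!r}")
            if len(vals) != len(AGE_BAND_EDGES) + 1:
                raise ValueError(f"{task}: need one cut-off per age band")
            for v in vals:
                if not 0 <= v <= TASK_MAXIMA[task]:
                    raise ValueError(f"{task}: cut-off {v} outside task range")

    @staticmethod
    def band_index(age: float) -> int:
        if age < 0:
            raise ValueError("age must be non-negative")
        for i, edge in enumerate(AGE_BAND_EDGES):
            if age < edge:
                return i
        return len(AGE_BAND_EDGES)

    def cutoff(self, task: str, age: float) -> float:
        return self.cutoffs[task][self.band_index(age)]


#: integer, age-banded cut-offs (5th percentile of age-matched controls)
TABLE_CUTOFFS = CutoffTable(
    {
        "gesture_production": (10, 9, 9),
        "gesture_recognition": (5, 5, 4),
        "gesture_imitation": (9, 9, 9),
    }
)

#: 2-SD-below-control-mean thresholds, identical across bands
SD_CUTOFFS = CutoffTable(
    {
        "gesture_production": (11.5, 11.5, 11.5),
        "gesture_recognition": (5.8, 5.8, 5.8),
        "gesture_imitation": (11.5, 11.5, 11.5),
    }
)


@dataclass
class PatientRecord:
    patient_id: str
    age_years: float
    handedness: str  # "R" | "L"
    hemisphere: str  # "L" | "R" | "B"
    gesture_production: float
    gesture_recognition: float
    gesture_imitation: float
    picture_naming: float | None = None
    orientation_score: float | None = None
    lesion_volume_mm3: float | None = None  # filled after delineation

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age must be non-negative")
        if self.handedness not in ("R", "L"):
            raise ValueError("handedness must be 'R' or 'L'")
        if self.hemisphere not in ("L", "R", "B"):
            raise ValueError("hemisphere must be 'L', 'R' or 'B'")
        for task in TASK_MAXIMA:
            val = getattr(self, task, None)
            if val is None:
                continue
            if not 0 <= val <= TASK_MAXIMA[task]:
                raise ValueError(f"{task}={val} outside [0, {TASK_MAXIMA[task]}]")


def classify_impairment(record: PatientRecord, cutoffs: CutoffTable = TABLE_CUTOFFS) -> dict:
    """Per-task impairment flags (score <= age-band cut-off) plus apraxia flag.

    Apraxia = impaired on at least one of the three praxis tasks.
    """
    flags = {}
    for task in cutoffs.cutoffs:
        score = getattr(record, task)
        if score is None:
            raise ValueError(f"record {record.patient_id}: missing {task}")
        flags[task] = bool(score <= cutoffs.cutoff(task, record.age_years))
    flags["apraxic"] = any(flags[t] for t in cutoffs.cutoffs)
    return flags


def composite_apraxia_score(record: PatientRecord) -> float:
    """Sum of the three praxis scores, each rescaled to [0, 1]; range [0, 3]."""
    total = 0.0
    for task in PRAXIS_TASKS:
        score = getattr(record, task)
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise ValueError(f"record {record.patient_id}: missing {task}")
        total += score / TASK_MAXIMA[task]
    return total


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p (Student t approximation, df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_summary(records, cutoffs: CutoffTable = TABLE_CUTOFFS) -> pd.DataFrame:
    """Per-task mean/SD/min/max plus impairment counts for a cohort.

    SD for a single-patient cohort is reported as missing (NaN), not 0.
    The overall apraxia count is stored in ``df.attrs['n_apraxic']``.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    rows = []
    flags = [classify_impairment(r, cutoffs) for r in records]
    for task in PRAXIS_TASKS:
        vals = np.array([getattr(r, task) for r in records], dtype=float)
        if len(vals) == 1:
            sd = float("nan")
            logger.info("single-patient cohort: SD reported as missing for %s", task)
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append(
            {
                "task": task,
                "mean": float(vals.mean()),
                "sd": sd,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "n_impaired": int(sum(f[task] for f in flags)),
            }
        )
    df = pd.DataFrame(rows).set_index("task")
    df.attrs["n_apraxic"] = int(sum(f["apraxic"] for f in flags))
    df.attrs["n_patients"] = len(records)
    return df


# ---- CSV I/O --------------------------------------------------------

TABLE_COLUMNS = [
    "patient_id",
    "age_years",
    "handedness",
    "hemisphere",
    "gesture_production",
    "gesture_recognition",
    "gesture_imitation",
    "picture_naming",
    "orientation_score",
]


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior table missing columns: {missing}")
    return df


def write_patient_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def records_from_table(df: pd.DataFrame) -> list[PatientRecord]:
    recs = []
    for _, row in df.iterrows():
        recs.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                age_years=float(row["age_years"]),
                handedness=str(row["handedness"]),
                hemisphere=str(row["hemisphere"]),
                gesture_production=float(row["gesture_production"]),
                gesture_recognition=float(row["gesture_recognition"]),
                gesture_imitation=float(row["gesture_imitation"]),
                picture_naming=float(row["picture_naming"]),
                orientation_score=float(row["orientation_score"]),
                lesion_volume_mm3=(
                    float(row["lesion_volume_mm3"]) if "lesion_volume_mm3" in row else None
                ),
            )
        )
    return recs
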