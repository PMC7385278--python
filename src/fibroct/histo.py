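"""Ashcroft-score analytics.

The Ashcroft system grades pulmonary fibrosis severity on an ordinal 0-8
scale per histological unit (here: per lobe). Grades decompose into three
severity classes — mild (0-3), moderate (4) and severe (5-8) — whose
frequency distribution weights each category's contribution to the total
score; the total Ashcroft score of an animal is the mean over its five
lobes.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LOBES
from . import stats as _stats

SEVERITY_CLASSES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class AshcroftRecord:
    animal_id: str
    day: int
    lobe: str
    grade: int

    def __post_init__(self) -> None:
        _check_grade(self.grade)
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}; expected one of {LOBES}")


@dataclass
class SeverityDistribution:
    freq_mild: float
    freq_moderate: float
    freq_severe: float
    n: int

    def __post_init__(self) -> None:
        total = self.freq_mild + self.freq_moderate + self.freq_severe
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"severity frequencies sum to {total}, not 1")

    @property
    def freq_moderate_severe(self) -> float:
        """Combined moderate+severe frequency, the histology readout
        correlated with the CT poorly-aerated fraction."""
        return self.freq_moderate + self.freq_severe


def _check_grade(grade: int) -> int:
    if not float(grade).is_integer():
        raise ValueError(f"Ashcroft grades are integers; got {grade!r}")
    grade = int(grade)
    if not 0 <= grade <= 8:
        raise ValueError(f"Ashcroft grade {grade} outside the 0-8 scale")
    return grade


def classify_severity(grade: int) -> str:
    """Map one grade to its severity class: 0-3 mild, 4 moderate, 5-8 severe."""
    grade = _check_grade(grade)
    if grade <= 3:
        return "mild"
    if grade == 4:
        return "moderate"
    return "severe"


def severity_distribution(grades: Iterable[int]) -> SeverityDistribution:
    """Class frequency distribution over a set of grades."""
    grades = [_check_grade(g) for g in grades]
    if not grades:
        raise ValueError("no grades supplied")
    classes = [classify_severity(g) for g in grades]
    n = len(classes)
    return SeverityDistribution(
        freq_mild=classes.count("mild") / n,
        freq_moderate=classes.count("moderate") / n,
        freq_severe=classes.count("severe") / n,
        n=n,
    )


def total_ashcroft(
    lobe_grades: Mapping[str, int] | Sequence[int],
    allow_missing: bool = False,
) -> float:
    """Total Ashcroft score of one animal: the mean over its lobes.

    All five lobes are required unless ``allow_missing`` is set (then the
    mean runs over the lobes present, with a warning).
    """
    if isinstance(lobe_grades, Mapping):
        present = {lobe: _check_grade(g) for lobe, g in lobe_grades.items()}
        missing = set(LOBES) - set(present)
        if missing and not allow_missing:
            raise ValueError(
                f"missing lobes {sorted(missing)}; pass allow_missing=True to average the rest"
            )
        if missing:
            import warnings

            warnings.warn(f"averaging over {len(present)} lobes; missing {sorted(missing)}", stacklevel=2)
        values = list(present.values())
    else:
        values = [_check_grade(g) for g in lobe_grades]
        if len(values) != len(LOBES) and not allow_missing:
            raise ValueError(f"expected {len(LOBES)} lobe grades, got {len(values)}")
    if not values:
        raise ValueError("no grades supplied")
    return float(np.mean(values))


@dataclass
class LobeHeterogeneity:
    """Per-lobe summaries plus the across-lobe omnibus comparison."""

    per_lobe: pd.DataFrame  # lobe, n, median, q1, q3
    comparison: "_stats.GroupComparisonResult"
    heterogeneity_index: float  # variance of the lobe medians


def lobe_heterogeneity(records: pd.DataFrame) -> LobeHeterogeneity:
    """Across-lobe heterogeneity of Ashcroft grades at one time point.

    Expects a table with ``lobe`` and ``grade`` columns (one row per
    animal-lobe). Reports per-lobe median and quartiles, the
    Kruskal-Wallis omnibus with Dunn's pairwise comparisons across lobes,
    and a scalar heterogeneity index: the variance of the lobe medians
    (0 when all lobes share one median — the uniform OA regime; large for
    the patchy IT regime).
    """
    if not {"lobe", "grade"} <= set(records.columns):
        raise ValueError("records need 'lobe' and 'grade' columns")
    groups = {
        lobe: sub["grade"].to_numpy(float)
        for lobe, sub in records.groupby("lobe", sort=False)
    }
    if len(groups) < 2:
        raise ValueError("need at least two lobes")
    if min(len(v) for v in groups.values()) < 2:
        raise ValueError("need at least two animals per lobe")
    per_lobe = (
        records.groupby("lobe")["grade"]
        .agg(
            n="count",
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    comparison = _stats.kruskal_dunn(groups)
    medians = per_lobe["median"].to_numpy(float)
    index = float(np.var(medians))
    return LobeHeterogeneity(
        per_lobe=per_lobe, comparison=comparison, heterogeneity_index=index
    )
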