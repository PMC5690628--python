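"""Spawn-level egg-quality classification and survival statistics.

Egg quality is operationalized on the percentage of incubated eggs
yielding *normal* embryos at 24 hours post spawning (hps): spawns above
90% are good quality, below 30% poor quality, anything between is
intermediate and excluded from good/poor contrasts.  Group differences
in survival are screened with Tukey's quick (Tukey-Duckworth) test,
whose statistic counts non-overlapping extreme values and is compared
with fixed critical values 7 / 10 / 13 for the 0.05 / 0.01 / 0.001
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import ValidationError, read_tsv

__all__ = [
    "SpawnSurvivalRecord",
    "load_survival_table",
    "packaged_survival_table",
    "classify_spawn",
    "group_survival_stats",
    "tukey_duckworth_test",
]

TIMEPOINTS = (8, 24, 48, 72)
QUICK_TEST_CRITICAL = {0.05: 7, 0.01: 10, 0.001: 13}


@dataclass
class SpawnSurvivalRecord:
    """One female's spawn: egg counts and the survival time course."""

    female_id: str
    eggs_total: int
    eggs_incubated: int
    pct_intact_2_3hps: float
    pct_survival: dict[int, float]
    pct_abnormal: dict[int, float] = field(default_factory=dict)
    experiment: str = "pooled"

    def __post_init__(self) -> None:
        for t, v in self.pct_survival.items():
            if not 0 <= v <= 100:
                raise ValidationError(
                    f"female {self.female_id}: survival {v} at {t} hps out of [0, 100]")
        times = sorted(self.pct_survival)
        vals = [self.pct_survival[t] for t in times]
        if any(b > a + 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                f"female {self.female_id}: survival increases over time")

    def normal_survival(self, timepoint: int) -> float:
        """Percent of eggs yielding normal embryos alive at ``timepoint``.

        When an abnormal percentage is recorded, abnormal embryos are
        excluded: normal survival = survival * (1 - abnormal/100).
        """
        if timepoint not in self.pct_survival:
            raise ValidationError(
                f"female {self.female_id}: no survival value at {timepoint} hps")
        surv = self.pct_survival[timepoint]
        abn = self.pct_abnormal.get(timepoint, 0.0)
        return surv * (1.0 - abn / 100.0)


def load_survival_table(path) -> list[SpawnSurvivalRecord]:
    frame = read_tsv(path)
    records = []
    for _, row in frame.iterrows():
        records.append(SpawnSurvivalRecord(
            female_id=str(row["female_id"]),
            eggs_total=int(row["eggs_total"]),
            eggs_incubated=int(row["eggs_incubated"]),
            pct_intact_2_3hps=float(row["pct_intact_2_3hps"]),
            pct_survival={t: float(row[f"surv_{t}"]) for t in TIMEPOINTS},
            pct_abnormal={t: float(row[f"abn_{t}"]) for t in TIMEPOINTS
                          if f"abn_{t}" in row},
            experiment=str(row.get("experiment", "pooled")),
        ))
    return records


def packaged_survival_table() -> list[SpawnSurvivalRecord]:
    """The packaged 16-female spawning-performance table."""
    ref = resources.files("ovoquant") / "data" / "spawn_survival.tsv"
    with resources.as_file(ref) as path:
        return load_survival_table(path)


def classify_spawn(record: SpawnSurvivalRecord, good_cut: float = 90.0,
                   poor_cut: float = 30.0, timepoint: int = 24) -> str:
    """good / poor / intermediate by normal-embryo survival at 24 hps."""
    value = record.normal_survival(timepoint)
    if value > good_cut:
        return "good"
    if value < poor_cut:
        return "poor"
    return "intermediate"


def group_survival_stats(records: Sequence[SpawnSurvivalRecord], timepoint: int,
                         labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-group n, mean, SEM, min, max of normal survival at a time point.

    SEM uses the sample standard deviation (n-1 denominator) over sqrt(n).
    """
    if labels is None:
        labels = [classify_spawn(r, timepoint=timepoint) for r in records]
    frame = pd.DataFrame({
        "label": list(labels),
        "value": [r.normal_survival(timepoint) for r in records],
    })
    rows = []
    for label, block in frame.groupby("label", sort=True):
        vals = block["value"].to_numpy(float)
        if len(vals) == 0:
            raise ValidationError(f"empty group {label!r}")
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        rows.append({"group": label, "n": len(vals), "mean": float(vals.mean()),
                     "sem": sem, "min": float(vals.min()), "max": float(vals.max())})
    return pd.DataFrame(rows).set_index("group")


def tukey_duckworth_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Tukey's quick test for a two-sample location shift.

    The statistic is the number of values in the higher-maximum sample
    exceeding the other sample's maximum, plus the number of values in
    the lower-minimum sample below the other sample's minimum.  Boundary
    ties count one half.  If one sample holds both pooled extremes the
    overlap count is undefined and the statistic is reported as 0.
    Significance: >=7 (0.05), >=10 (0.01), >=13 (0.001).
    """
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both samples must be nonempty")

    # which sample owns the pooled maximum / minimum (None on an exact tie)
    hi_side = "a" if a.max() > b.max() else "b" if b.max() > a.max() else None
    lo_side = "a" if a.min() < b.min() else "b" if b.min() < a.min() else None

    if hi_side is None and lo_side is None:
        statistic = 0.0  # both extremes tied across samples: test degenerate
    elif hi_side is not None and hi_side == lo_side:
        statistic = 0.0  # one sample spans the other: no two-tail pattern
    else:
        if hi_side is None:
            hi_side = "a" if lo_side == "b" else "b"
        if lo_side is None:
            lo_side = "a" if hi_side == "b" else "b"
        hi, hi_other = (a, b) if hi_side == "a" else (b, a)
        lo, lo_other = (a, b) if lo_side == "a" else (b, a)
        upper = float(np.sum(hi > hi_other.max())) + 0.5 * float(np.sum(hi == hi_other.max()))
        lower = float(np.sum(lo < lo_other.min())) + 0.5 * float(np.sum(lo == lo_other.min()))
        statistic = upper + lower

    significant_at = {alpha for alpha, crit in QUICK_TEST_CRITICAL.items()
                      if statistic >= crit}
    return {"statistic": statistic, "significant_at": significant_at}
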