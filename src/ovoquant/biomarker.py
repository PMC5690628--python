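"""Marker-panel summed-score classifier for egg quality.

A panel of marker proteins (each possibly a group of isoforms) yields a
per-sample score: the sum of N-SC values over all panel members, with
isoform values summed within a member.  Group separation is summarized
by mean, SEM, min-max range and the Student-t 95% confidence interval;
a midpoint threshold on the score then classifies samples into quality
groups, optionally with leave-one-out re-estimation of the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import SpectralCountTable, ValidationError

__all__ = [
    "GroupSummary",
    "MarkerPanelScore",
    "marker_sum_score",
    "group_separation_stats",
    "threshold_classify",
]

log = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    n: int
    mean: float
    sem: float
    min: float
    max: float
    ci95_low: float | None
    ci95_high: float | None


@dataclass
class MarkerPanelScore:
    scores: pd.Series                    # per-sample summed N-SC
    groups: dict[str, GroupSummary]
    range_overlap: bool
    ci_overlap: bool | None


def marker_sum_score(nsc: SpectralCountTable,
                     panel: list[list[str]] | list[str]) -> pd.Series:
    """Per-sample sum of N-SC over the panel (isoforms summed per member).

    Panel members absent from the table contribute zero and are logged.
    """
    if not panel:
        raise ValidationError("marker panel is empty")
    groups = [[m] if isinstance(m, str) else list(m) for m in panel]
    score = pd.Series(0.0, index=nsc.values.columns)
    for member in groups:
        for pid in member:
            if pid in nsc.values.index:
                score += nsc.values.loc[pid]
            else:
                log.warning("panel protein %s not in table; contributes 0", pid)
    score.name = "marker_score"
    return score


def summarize_group(values) -> GroupSummary:
    """Mean, SEM and two-sided Student-t 95% CI of one group's scores."""
    vals = np.asarray(list(values), float)
    n = len(vals)
    mean = float(vals.mean())
    if n >= 2:
        sem = float(np.std(vals, ddof=1) / np.sqrt(n))
        tq = float(stats.t.ppf(0.975, n - 1))
        lo, hi = mean - tq * sem, mean + tq * sem
    else:
        sem, lo, hi = float("nan"), None, None
    return GroupSummary(n=n, mean=mean, sem=sem,
                        min=float(vals.min()), max=float(vals.max()),
                        ci95_low=lo, ci95_high=hi)


def ci95_from_summary(mean: float, sem: float, n: int) -> tuple[float, float]:
    """Two-sided Student-t 95% CI reconstructed from (mean, SEM, n)."""
    if n < 2:
        raise ValidationError("confidence interval needs n >= 2")
    tq = float(stats.t.ppf(0.975, n - 1))
    return mean - tq * sem, mean + tq * sem


def _intervals_overlap(a_lo, a_hi, b_lo, b_hi) -> bool:
    return not (a_hi < b_lo or b_hi < a_lo)


def group_separation_stats(scores: pd.Series, design: pd.DataFrame) -> MarkerPanelScore:
    """Per-group summaries of the panel score, plus overlap flags."""
    labels = design.set_index("sample_id")["group"]
    groups: dict[str, GroupSummary] = {}
    for label in sorted(labels.unique()):
        members = labels.index[labels == label]
        vals = scores.loc[[s for s in members if s in scores.index]]
        if len(vals) == 0:
            raise ValidationError(f"no scores for group {label!r}")
        groups[label] = summarize_group(vals)
    names = list(groups)
    range_overlap = ci_overlap = None
    if len(names) == 2:
        a, b = groups[names[0]], groups[names[1]]
        range_overlap = _intervals_overlap(a.min, a.max, b.min, b.max)
        if a.ci95_low is not None and b.ci95_low is not None:
            ci_overlap = _intervals_overlap(a.ci95_low, a.ci95_high,
                                            b.ci95_low, b.ci95_high)
    return MarkerPanelScore(scores=scores, groups=groups,
                            range_overlap=bool(range_overlap),
                            ci_overlap=ci_overlap)


def _midpoint(scores: pd.Series, labels: pd.Series) -> tuple[float, str]:
    """Midpoint threshold between the two groups; returns (cut, upper group)."""
    means = scores.groupby(labels).mean().sort_values()
    lo_grp, hi_grp = means.index[0], means.index[-1]
    cut = (scores[labels == lo_grp].max() + scores[labels == hi_grp].min()) / 2.0
    return float(cut), str(hi_grp)


def threshold_classify(scores: pd.Series, labels: pd.Series,
                       threshold: float | str = "midpoint",
                       leave_one_out: bool = False) -> dict:
    """Classify samples by thresholding the panel score.

    The default threshold is the midpoint between the lower group's
    maximum and the upper group's minimum; with overlapping groups the
    midpoint is still computed and the resulting accuracy is below 1.
    With ``leave_one_out`` the threshold is re-estimated without each
    held-out sample before predicting it.
    """
    labels = labels.loc[scores.index]
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValidationError("threshold classification needs exactly two groups")

    def predict(cut: float, upper: str, value: float) -> str:
        lower = uniq[0] if upper == uniq[1] else uniq[1]
        return upper if value > cut else lower

    if leave_one_out:
        preds = {}
        for s in scores.index:
            rest = scores.drop(s)
            rest_labels = labels.drop(s)
            if rest_labels.nunique() < 2:
                raise ValidationError("leave-one-out leaves a single group")
            cut, upper = _midpoint(rest, rest_labels)
            preds[s] = predict(cut, upper, scores[s])
        predictions = pd.Series(preds)
        cut_reported, upper = _midpoint(scores, labels)
    else:
        if threshold == "midpoint":
            cut_reported, upper = _midpoint(scores, labels)
        else:
            cut_reported = float(threshold)
            upper = scores.groupby(labels).mean().idxmax()
        predictions = pd.Series(
            {s: predict(cut_reported, upper, scores[s]) for s in scores.index})
    accuracy = float((predictions == labels).mean())
    return {"threshold": cut_reported, "predictions": predictions,
            "accuracy": accuracy}
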