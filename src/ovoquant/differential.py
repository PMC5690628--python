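"""Differential-regulation classification and category distribution tests.

A protein is differentially regulated when its mean N-SC differs at
least 2-fold between egg-quality groups, or when it is unique to one
group.  A stricter tier ("highly up-regulated") uses a 5-fold cut in
the pooled design and a 4-fold cut in the replicated design.  In the
replicated design, per-protein two-sided independent t-tests (pooled
variance by default) are corrected with Benjamini-Hochberg within each
gel fraction; uniqueness there means the opposite group's values do not
differ significantly from zero.  The distribution of up-regulated
proteins across functional categories is compared between quality
groups with a chi-square test on the 2 x C contingency table, followed
by per-category 2 x 2 post-hoc chi-square tests, BH-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_data import Dataset, SpectralCountTable, ValidationError

__all__ = [
    "DifferentialRecord",
    "CategoryDistribution",
    "fold_change",
    "UNIQUE",
    "uniqueness_test",
    "bh_adjust",
    "protein_t_tests",
    "classify_regulation",
    "combine_fractions",
    "category_distribution_test",
]

log = logging.getLogger(__name__)

UNIQUE = float("inf")

TIERS = ("not_regulated", "up_good", "up_poor", "unique_good", "unique_poor",
         "highly_up_good", "highly_up_poor")

# fold cut defining the "highly up-regulated" tier, per experimental design
DEFAULT_HIGH_CUT = {"pooled": 5.0, "multiple": 4.0}


@dataclass
class DifferentialRecord:
    """Per-protein differential-regulation summary for one gel fraction."""

    protein_id: str
    fraction: str
    mean_nsc_good: float
    mean_nsc_poor: float
    fold_change: float          # >= 1, oriented; inf when unique
    direction: str              # "good" or "poor"
    tier: str
    p_value: float | None = None
    q_value: float | None = None
    marker_candidate: bool = False

    @property
    def is_unique(self) -> bool:
        return np.isinf(self.fold_change)

    @property
    def up_regulated(self) -> bool:
        return self.tier != "not_regulated"


@dataclass
class CategoryDistribution:
    """Category x quality-type counts of up-regulated proteins with tests."""

    counts: pd.DataFrame        # categories x {good, poor}
    chi2: float
    df: int
    p_value: float
    posthoc: pd.DataFrame       # per category: chi2, p_raw, q_bh


def regulated_fraction(n_common_2fold: int, n_unique_good: int,
                       n_unique_poor: int, n_total: int) -> float:
    """Fraction of detected proteins that are differentially regulated.

    Differential regulation unions proteins with a >=2-fold mean N-SC
    difference and proteins unique to either quality group.
    """
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    return (n_common_2fold + n_unique_good + n_unique_poor) / n_total


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Oriented fold change between two group means.

    Returns (fold, direction) with fold = max/min >= 1 and direction the
    group with the larger mean; a single zero mean gives (inf, nonzero
    group).  Both-zero input is undefined.
    """
    if mean_a == 0 and mean_b == 0:
        raise ValidationError("fold change undefined when both means are zero")
    if mean_b == 0:
        return UNIQUE, "a"
    if mean_a == 0:
        return UNIQUE, "b"
    if mean_a >= mean_b:
        return mean_a / mean_b, "a"
    return mean_b / mean_a, "b"


def uniqueness_test(values_in_absent_group, alpha: float = 0.05) -> bool:
    """Is a protein effectively absent from a group?

    True when every replicate value is zero, or when a one-sample t-test
    of the values against zero is not significant at ``alpha``.  With a
    single value (no replication) only the strict all-zero rule applies.
    """
    vals = np.asarray(list(values_in_absent_group), float)
    if np.all(vals == 0):
        return True
    if len(vals) < 2:
        return False
    if np.std(vals, ddof=1) == 0:
        return False  # constant nonzero: trivially differs from zero
    t, p = stats.ttest_1samp(vals, 0.0)
    return bool(p > alpha)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(list(p_values), float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def protein_t_tests(nsc: SpectralCountTable, design: pd.DataFrame,
                    welch: bool = False, pool_fractions: bool = False) -> pd.DataFrame:
    """Two-sided independent t-tests good vs poor, per protein.

    Student's pooled-variance t by default (``welch=True`` switches to
    Welch).  BH correction is applied within each fraction's protein set
    unless ``pool_fractions`` is set.  Proteins with zero variance in
    both groups and equal means get p = 1.  Returns a frame indexed by
    (protein_id, fraction) with columns t, p_value, q_value.
    """
    rows = []
    for (_, fraction), block in design.groupby(["experiment", "fraction"], sort=False):
        good = block.loc[block["group"] == "good", "sample_id"].tolist()
        poor = block.loc[block["group"] == "poor", "sample_id"].tolist()
        if len(good) < 2 or len(poor) < 2:
            continue
        sub = nsc.values[good + poor]
        sub = sub[sub.sum(axis=1) > 0]
        g = sub[good].to_numpy(float)
        p_ = sub[poor].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(g, p_, axis=1, equal_var=not welch)
        degenerate = np.isnan(p)
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
        for pid, ti, pi in zip(sub.index, t, p):
            rows.append({"protein_id": pid, "fraction": fraction,
                         "t": float(ti), "p_value": float(pi)})
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    if pool_fractions:
        frame["q_value"] = bh_adjust(frame["p_value"])
    else:
        frame["q_value"] = (frame.groupby("fraction")["p_value"]
                            .transform(lambda p: bh_adjust(p)))
    return frame.set_index(["protein_id", "fraction"])


def classify_regulation(nsc: SpectralCountTable, design: pd.DataFrame,
                        fold_cut: float = 2.0,
                        high_cut: float | None = None,
                        alpha: float = 0.05, q_cut: float = 0.1,
                        welch: bool = False,
                        marker_nsc_floor: float = 0.5) -> list[DifferentialRecord]:
    """Assign every detected protein a regulation tier, per fraction.

    Order of precedence: uniqueness first, then fold >= high_cut
    ("highly up-regulated"), then fold >= fold_cut ("up-regulated"),
    else not regulated.  ``marker_candidate`` flags proteins meeting
    the biomarker screen: common proteins at fold >= high_cut, or
    group-unique proteins whose mean N-SC in their group is >= 0.5;
    where replicated tests apply the t-test must also be significant
    (raw p < alpha and BH q < q_cut).
    """
    records: list[DifferentialRecord] = []
    tests = protein_t_tests(nsc, design, welch=welch)
    for (experiment, fraction), block in design.groupby(
            ["experiment", "fraction"], sort=False):
        cut_high = DEFAULT_HIGH_CUT.get(experiment, 5.0) if high_cut is None else high_cut
        good = block.loc[block["group"] == "good", "sample_id"].tolist()
        poor = block.loc[block["group"] == "poor", "sample_id"].tolist()
        if not good or not poor:
            raise ValidationError(
                f"stratum ({experiment}, {fraction}) lacks a good or poor group")
        replicated = len(good) >= 2 and len(poor) >= 2
        sub = nsc.values[good + poor]
        for pid, row in sub.iterrows():
            g = row[good].to_numpy(float)
            p_ = row[poor].to_numpy(float)
            mg, mp = float(g.mean()), float(p_.mean())
            if mg == 0 and mp == 0:
                log.info("protein %s undetected in (%s, %s); dropped",
                         pid, experiment, fraction)
                continue
            # uniqueness: favored group detected, other group consistent with 0
            if mg > 0 and uniqueness_test(p_, alpha):
                fold, direction, unique = UNIQUE, "good", True
            elif mp > 0 and uniqueness_test(g, alpha):
                fold, direction, unique = UNIQUE, "poor", True
            elif mg == 0 or mp == 0:
                # one mean zero but failed the t-test route cannot occur;
                # all-zero means are caught by uniqueness_test
                fold, direction, unique = UNIQUE, ("good" if mp == 0 else "poor"), True
            else:
                fold, ab = fold_change(mg, mp)
                direction = "good" if ab == "a" else "poor"
                unique = False

            if unique:
                tier = f"unique_{direction}"
            elif fold >= cut_high:
                tier = f"highly_up_{direction}"
            elif fold >= fold_cut:
                tier = f"up_{direction}"
            else:
                tier = "not_regulated"

            p_val = q_val = None
            if replicated and (pid, fraction) in tests.index:
                p_val = float(tests.loc[(pid, fraction), "p_value"])
                q_val = float(tests.loc[(pid, fraction), "q_value"])

            favored_mean = mg if direction == "good" else mp
            candidate = ((not unique and fold >= cut_high)
                         or (unique and favored_mean >= marker_nsc_floor))
            if candidate and p_val is not None:
                candidate = p_val < alpha and q_val < q_cut
            records.append(DifferentialRecord(
                protein_id=str(pid), fraction=fraction,
                mean_nsc_good=mg, mean_nsc_poor=mp,
                fold_change=fold, direction=direction, tier=tier,
                p_value=p_val, q_value=q_val,
                marker_candidate=bool(candidate)))
    return records


def combine_fractions(records: list[DifferentialRecord]) -> list[DifferentialRecord]:
    """Union of per-fraction records, deduplicated by protein.

    Fractions are analyzed separately for per-protein statistics but
    combined for category and enrichment analyses; a protein seen in
    several fractions keeps its record with the larger fold change
    (unique records, fold = inf, dominate).
    """
    best: dict[str, DifferentialRecord] = {}
    for rec in records:
        prev = best.get(rec.protein_id)
        if prev is None or rec.fold_change > prev.fold_change:
            best[rec.protein_id] = rec
    return list(best.values())


def category_distribution_test(records: list[DifferentialRecord],
                               meta: pd.DataFrame) -> CategoryDistribution:
    """Compare functional-category distributions of up-regulated proteins.

    Builds the 2 x C table of up-regulated protein counts (quality type
    x category), tests it with an uncorrected chi-square, then runs a
    2 x 2 post-hoc chi-square per category (this category vs all others)
    with BH adjustment across categories.  Zero-margin categories are
    dropped and logged.
    """
    up = [r for r in combine_fractions(records) if r.up_regulated]
    if not up:
        raise ValidationError("no up-regulated proteins to test")
    cats = meta["category"]
    frame = pd.DataFrame({
        "category": [cats.get(r.protein_id, "other") for r in up],
        "direction": [r.direction for r in up],
    })
    counts = (frame.groupby(["category", "direction"]).size()
              .unstack(fill_value=0)
              .reindex(columns=["good", "poor"], fill_value=0))
    zero_margin = counts.index[counts.sum(axis=1) == 0]
    if len(zero_margin):
        log.info("dropping zero-margin categories %s", list(zero_margin))
        counts = counts.drop(index=zero_margin)
    for direction in ("good", "poor"):
        if counts[direction].sum() == 0:
            raise ValidationError(f"no up-regulated proteins for the {direction} group")
    if len(counts) < 2:
        raise ValidationError("chi-square undefined with a single category (df = 0)")
    chi2, p, df, _ = stats.chi2_contingency(counts.T.values, correction=False)

    rows = []
    for cat in counts.index:
        this = counts.loc[cat].to_numpy(float)
        rest = counts.sum(axis=0).to_numpy(float) - this
        table = np.array([this, rest])
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            c2, praw = 0.0, 1.0
        else:
            c2, praw, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"category": cat, "chi2": float(c2), "p_raw": float(praw)})
    posthoc = pd.DataFrame(rows).set_index("category")
    posthoc["q_bh"] = bh_adjust(posthoc["p_raw"])
    return CategoryDistribution(counts=counts, chi2=float(chi2), df=int(df),
                                p_value=float(p), posthoc=posthoc)
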