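import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from ovoquant.core_data import SpectralCountTable, ValidationError
from ovoquant.differential import (
    bh_adjust,
    category_distribution_test,
    classify_regulation,
    combine_fractions,
    fold_change,
    protein_t_tests,
    regulated_fraction,
    uniqueness_test,
)


def bh_oracle(p):
    """Step-up procedure by direct enumeration of the defining minimum.

    q_i = min over all j with p_j >= p_i of p_(j) * m / rank_j, capped at 1.
    """
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = np.empty(m)
    for pos in range(m):
        candidates = [ranked[j] * m / (j + 1) for j in range(pos, m)]
        q[order[pos]] = min(1.0, min(candidates))
    return q


def nsc_table(values, samples):
    return SpectralCountTable(
        pd.DataFrame(values, index=pd.Index([f"P{i}" for i in range(len(values))],
                                            name="protein_id"),
                     columns=samples), stage="nsc")


def design_4v4(experiment="multiple", fraction="whole"):
    return pd.DataFrame({
        "sample_id": [f"g{i}" for i in range(1, 5)] + [f"p{i}" for i in range(1, 5)],
        "group": ["good"] * 4 + ["poor"] * 4,
        "experiment": experiment,
        "fraction": fraction,
        "replicate": list(range(1, 5)) * 2,
    })


SAMPLES_4V4 = design_4v4()["sample_id"].tolist()


class TestFoldChange:
    @pytest.mark.parametrize("a,b,fold,direction", [
        (4.0, 2.0, 2.0, "a"),
        (1.9, 1.0, 1.9, "a"),
        (1.0, 3.0, 3.0, "b"),
    ])
    def test_oriented_fold(self, a, b, fold, direction):
        f, d = fold_change(a, b)
        assert f == pytest.approx(fold) and d == direction

    def test_single_zero_gives_unique(self):
        f, d = fold_change(0.0, 1.2)
        assert np.isinf(f) and d == "b"

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            fold_change(0.0, 0.0)


class TestUniqueness:
    def test_all_zero_is_unique(self):
        assert uniqueness_test([0, 0, 0, 0])

    def test_trace_values_not_distinguishable_from_zero(self):
        # one-sample t of {0, 0.1, 0, 0.05} vs 0: t ~ 1.57, p ~ 0.21
        vals = [0, 0.1, 0, 0.05]
        t, p = sps.ttest_1samp(vals, 0.0)
        assert p > 0.05
        assert uniqueness_test(vals)

    def test_clearly_present_is_not_unique(self):
        t, p = sps.ttest_1samp([5, 6, 5, 6], 0.0)
        assert p < 0.001
        assert not uniqueness_test([5, 6, 5, 6])

    def test_single_nonzero_value_not_unique(self):
        # no replication: only the strict all-zero rule applies
        assert not uniqueness_test([3.0])


class TestProteinTTests:
    def test_pooled_variance_t_against_closed_form(self):
        g = np.array([4.0, 5.0, 6.0, 5.0])
        p = np.array([1.0, 2.0, 1.0, 2.0])
        sp2 = (g.var(ddof=1) * 3 + p.var(ddof=1) * 3) / 6
        t_manual = (g.mean() - p.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        p_manual = 2 * sps.t.sf(abs(t_manual), 6)
        assert t_manual == pytest.approx(7.0)
        assert p_manual == pytest.approx(4.2e-4, rel=0.05)

        table = nsc_table([[4, 5, 6, 5, 1, 2, 1, 2]], SAMPLES_4V4)
        out = protein_t_tests(table, design_4v4())
        assert out.loc[("P0", "whole"), "t"] == pytest.approx(t_manual)
        assert out.loc[("P0", "whole"), "p_value"] == pytest.approx(p_manual)

    def test_identical_groups_give_p_one(self):
        table = nsc_table([[3, 3, 3, 3, 3, 3, 3, 3]], SAMPLES_4V4)
        out = protein_t_tests(table, design_4v4())
        assert out.loc[("P0", "whole"), "t"] == 0.0
        assert out.loc[("P0", "whole"), "p_value"] == 1.0

    def test_bh_within_fraction(self):
        design = pd.concat([design_4v4(fraction="HMW"),
                            design_4v4(fraction="LMW")], ignore_index=True)
        design["sample_id"] = [f"{s}_{f}" for s, f in
                               zip(design["sample_id"], design["fraction"])]
        rng = np.random.default_rng(0)
        values = rng.poisson(20, size=(10, 16)).astype(float)
        table = nsc_table(values, design["sample_id"].tolist())
        out = protein_t_tests(table, design)
        for frac in ("HMW", "LMW"):
            block = out.xs(frac, level="fraction")
            np.testing.assert_allclose(block["q_value"],
                                       bh_oracle(block["p_value"].values))


class TestBenjaminiHochberg:
    def test_known_qlist(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_exhaustive_grids_up_to_length_four(self):
        grid = [0.001, 0.02, 0.3, 1.0]
        for m in range(1, 5):
            for p in itertools.product(grid, repeat=m):
                np.testing.assert_allclose(bh_adjust(p), bh_oracle(p),
                                           rtol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_on_random_lists(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-9,
                                   atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_raw_p(self, p):
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestClassifyRegulation:
    def test_tier_thresholds(self):
        table = nsc_table([
            [10, 10, 10, 10, 1.9, 1.9, 1.9, 1.9],   # fold 5.26 -> highly_up
            [4, 4, 4, 4, 1.9, 1.9, 1.9, 1.9],       # fold 2.1 -> up
            [3, 3, 3, 3, 2, 2, 2, 2],               # fold 1.5 -> not regulated
        ], SAMPLES_4V4)
        recs = {r.protein_id: r for r in classify_regulation(table, design_4v4())}
        assert recs["P0"].tier == "highly_up_good"
        assert recs["P1"].tier == "up_good"
        assert recs["P2"].tier == "not_regulated"

    def test_unique_below_nsc_floor_not_marker(self):
        table = nsc_table([[0.3, 0.3, 0.3, 0.3, 0, 0, 0, 0]], SAMPLES_4V4)
        rec = classify_regulation(table, design_4v4())[0]
        assert rec.tier == "unique_good"
        assert not rec.marker_candidate

    def test_unique_above_floor_with_significance_is_marker(self):
        table = nsc_table([[2.0, 2.2, 1.9, 2.1, 0, 0, 0, 0]], SAMPLES_4V4)
        rec = classify_regulation(table, design_4v4())[0]
        assert rec.tier == "unique_good"
        assert rec.marker_candidate

    def test_pooled_design_strict_zero_uniqueness(self):
        design = pd.DataFrame({
            "sample_id": ["g", "p"], "group": ["good", "poor"],
            "experiment": "pooled", "fraction": "whole", "replicate": [1, 1]})
        table = nsc_table([[5.0, 0.0], [5.0, 0.9]], ["g", "p"])
        recs = {r.protein_id: r for r in classify_regulation(table, design)}
        assert recs["P0"].tier == "unique_good"
        assert recs["P1"].tier == "highly_up_good"  # fold 5.6 >= pooled cut 5
        assert recs["P0"].p_value is None

    def test_scale_invariance_of_tiers(self):
        rng = np.random.default_rng(7)
        values = rng.poisson(15, size=(50, 8)).astype(float)
        table = nsc_table(values, SAMPLES_4V4)
        tiers1 = [r.tier for r in classify_regulation(table, design_4v4())]
        table2 = nsc_table(values * 37.5, SAMPLES_4V4)
        tiers2 = [r.tier for r in classify_regulation(table2, design_4v4())]
        assert tiers1 == tiers2

    def test_top_fraction_matches_planted_quantile(self):
        # build a fixture where 2.3% of common proteins exceed the 4-fold cut
        rng = np.random.default_rng(1)
        n = 1000
        folds = np.concatenate([np.full(977, 1.5), np.full(23, 6.0)])
        rng.shuffle(folds)
        base = np.full(n, 40.0)
        values = np.column_stack([np.tile(base * folds, (4, 1)).T,
                                  np.tile(base, (4, 1)).T])
        table = nsc_table(values, SAMPLES_4V4)
        recs = classify_regulation(table, design_4v4())
        common = [r for r in recs if not r.is_unique]
        frac = np.mean([r.fold_change >= 4.0 for r in common])
        assert frac == pytest.approx(0.023, abs=0.002)


class TestRegulatedFraction:
    def test_fraction_from_component_counts(self):
        assert regulated_fraction(545, 136, 211, 2535) * 100 == pytest.approx(
            35.2, abs=0.05)


class TestCategoryDistribution:
    @staticmethod
    def chi2_closed_form(table):
        table = np.asarray(table, float)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        return float(((table - exp) ** 2 / exp).sum())

    def test_2x2_closed_form(self):
        table = [[10, 5], [5, 10]]
        chi2 = self.chi2_closed_form(table)
        assert chi2 == pytest.approx(10 / 3)
        c2, p, _, _ = sps.chi2_contingency(table, correction=False)
        assert c2 == pytest.approx(chi2)
        assert p == pytest.approx(sps.chi2.sf(10 / 3, 1))
        assert p == pytest.approx(0.068, abs=0.001)

    def _records_from_counts(self, counts):
        """Synthesize differential records matching a category x type table."""
        from ovoquant.differential import DifferentialRecord
        meta_rows, recs = [], []
        i = 0
        for cat, (n_good, n_poor) in counts.items():
            for direction, n in (("good", n_good), ("poor", n_poor)):
                for _ in range(n):
                    pid = f"Q{i}"
                    meta_rows.append({"protein_id": pid, "length_aa": 100,
                                      "unique_peptide_count": 1, "category": cat})
                    recs.append(DifferentialRecord(
                        protein_id=pid, fraction="whole", mean_nsc_good=1,
                        mean_nsc_poor=1, fold_change=3.0, direction=direction,
                        tier=f"up_{direction}"))
                    i += 1
        meta = pd.DataFrame(meta_rows).set_index("protein_id", drop=False)
        return recs, meta

    def test_overall_chi2_on_2xC_table(self):
        recs, meta = self._records_from_counts(
            {"PS": (10, 5), "EM": (5, 10), "ZPs": (2, 8)})
        dist = category_distribution_test(recs, meta)
        expected = self.chi2_closed_form(dist.counts.T.values)
        assert dist.chi2 == pytest.approx(expected)
        assert dist.df == len(dist.counts) - 1
        assert (dist.posthoc["q_bh"].values
                == pytest.approx(bh_oracle(dist.posthoc["p_raw"].values)))

    def test_identical_distributions_give_p_one(self):
        recs, meta = self._records_from_counts({"PS": (5, 5), "EM": (3, 3)})
        dist = category_distribution_test(recs, meta)
        assert dist.p_value == pytest.approx(1.0)

    def test_single_category_is_an_error(self):
        recs, meta = self._records_from_counts({"PS": (5, 3)})
        with pytest.raises(ValidationError, match="single category"):
            category_distribution_test(recs, meta)


class TestCombineFractions:
    def test_larger_fold_wins_and_unique_dominates(self):
        from ovoquant.differential import DifferentialRecord
        a = DifferentialRecord("P1", "HMW", 4, 1, 4.0, "good", "up_good")
        b = DifferentialRecord("P1", "LMW", 8, 1, 8.0, "good", "highly_up_good")
        c = DifferentialRecord("P2", "HMW", 1, 0, float("inf"), "good", "unique_good")
        d = DifferentialRecord("P2", "LMW", 3, 1, 3.0, "good", "up_good")
        out = {r.protein_id: r for r in combine_fractions([a, b, c, d])}
        assert out["P1"].fraction == "LMW"
        assert out["P2"].tier == "unique_good"
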