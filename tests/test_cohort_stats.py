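"""Two-group tests and comparison tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pctrda.cohort_stats import (
    build_comparison_table,
    categorical_test,
    welch_t,
)


def welch_by_hand(a, b):
    """Textbook Welch statistic and Welch-Satterthwaite dof."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def fisher_enumeration_p(table):
    """Two-sided Fisher p by full hypergeometric enumeration: sum the
    probabilities of all tables (fixed margins) no more probable than the
    observed one."""
    (a, b), (c, d) = np.asarray(table)
    r1, n, c1 = a + b, a + b + c + d, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


class TestWelch:
    def test_identical_samples(self):
        t, _, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        a, b = [1, 2, 3], [1, 2, 3, 4, 5]
        t, df, p = welch_t(a, b)
        ht, hdf, hp = welch_by_hand(a, b)
        assert t == pytest.approx(ht)
        assert df == pytest.approx(hdf)
        assert p == pytest.approx(hp)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 2, 40)
        t1, df1, p1 = welch_t(a, b)
        t2, df2, p2 = welch_t(10 * a, 10 * b)
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1, 2, 3])
        with pytest.raises(ValueError):
            welch_t([2, 2, 2], [3, 3, 3])


class TestCategorical:
    def test_balanced_2x2_p_one(self):
        name, _, p = categorical_test([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_fisher_on_sparse_2x2(self):
        table = [[1, 9], [8, 2]]
        name, orr, p = categorical_test(table)
        assert name == "fisher_exact"
        assert p == pytest.approx(fisher_enumeration_p(table), abs=1e-12)

    def test_chi2_chosen_when_expected_large(self):
        name, stat, p = categorical_test([[50, 60], [55, 45]])
        assert name == "chi_squared"

    def test_equal_rows_2x3_stat_zero(self):
        name, stat, p = categorical_test([[30, 40, 30], [30, 40, 30]])
        assert name == "chi_squared"
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_chi2_invariant_to_permutation(self):
        t = np.array([[12, 30, 18], [25, 9, 31]])
        _, s1, p1 = categorical_test(t)
        _, s2, p2 = categorical_test(t[::-1])
        _, s3, p3 = categorical_test(t[:, [2, 0, 1]])
        assert s1 == pytest.approx(s2) == pytest.approx(s3)
        assert p1 == pytest.approx(p2) == pytest.approx(p3)

    def test_fisher_random_tables_match_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            name, _, p = categorical_test(t)
            if name == "fisher_exact":
                assert p == pytest.approx(fisher_enumeration_p(t), abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[0, 0], [3, 4]])


class TestComparisonTable:
    def make(self, rng, n=500, shift=0.0):
        g = np.repeat([0, 1], n)
        return pd.DataFrame(
            {
                "grp": g,
                "los_days": rng.lognormal(np.log(5), 0.5, 2 * n) + shift * g,
                "sex": rng.choice(["f", "m"], size=2 * n),
            }
        )

    def test_structure_and_recorded_tests(self):
        rng = np.random.default_rng(2)
        table = build_comparison_table(
            self.make(rng), "grp", continuous=["los_days"], categorical=["sex"]
        )
        f = table.frame
        assert list(f["variable"])[:2] == ["n", "los_days"]
        assert f.loc[f["variable"] == "los_days", "test"].item() == "welch_t"
        used = f.loc[f["variable"] == "sex = f", "test"].item()
        assert used in ("chi_squared", "fisher_exact")
        assert "(" in f.loc[f["variable"] == "los_days", "group1"].item()
        assert table.render()  # text rendering does not crash

    def test_null_pvalues_uniform(self):
        """Identical group distributions: the Welch p-value is uniform
        (KS test over 1000 replicates)."""
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(1000):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0, 1, 40)
            ps.append(welch_t(a, b)[2])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_los_detected(self):
        """A +4 day LOS shift at n=500/group is essentially always
        significant at p < 0.001."""
        rng = np.random.default_rng(4)
        hits = 0
        reps = 100
        for _ in range(reps):
            df = self.make(rng, n=500, shift=4.0)
            t = build_comparison_table(df, "grp", continuous=["los_days"])
            assert (
                t.frame.loc[t.frame["variable"] == "los_days", "p_value"].item()
                < 0.001
            )
            hits += 1
        assert hits / reps >= 0.99

    def test_near_identical_proportions_p_near_one(self):
        df = pd.DataFrame(
            {"grp": [0] * 200 + [1] * 200, "flag": (["y"] * 120 + ["n"] * 80) * 2}
        )
        t = build_comparison_table(df, "grp", categorical=["flag"])
        assert t.frame["p_value"].dropna().item() == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"grp": [0, 0, 0], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            build_comparison_table(df, "grp", continuous=["v"])
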