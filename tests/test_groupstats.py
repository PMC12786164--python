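"""Percent reductions, balanced ANOVA, Duncan's MRT, rate comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from shelfkin.errors import DomainError, UnbalancedDesignError
from shelfkin.groupstats import (
    balanced_anova,
    compare_fits,
    duncan_mrt,
    normality_diagnostics,
    percent_reduction,
    percent_retention,
    star_code,
    three_way_anova,
)
from shelfkin.kinetics import KineticFit
from shelfkin.synth import default_study_config, generate
from shelfkin.timeseries import MeasurementTable


class TestPercentReduction:
    @pytest.mark.parametrize(
        "kc,kp,expected",
        [(0.006, 0.003, 50), (0.064, 0.031, 52), (0.2, 0.2, 0)],
    )
    def test_worked_examples(self, kc, kp, expected):
        assert round(percent_reduction(kc, kp)) == expected

    def test_zero_control_rejected(self):
        with pytest.raises(DomainError):
            percent_reduction(0.0, 0.01)

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(1e-6, 1.0), st.floats(0.0, 1.0)
    )
    def test_reduction_plus_retention_is_100(self, kc, kp):
        total = percent_reduction(kc, kp) + percent_retention(kc, kp)
        assert total == pytest.approx(100.0, abs=1e-9)


def _anova_oracle_222(df):
    """Direct mean-contrast SS arithmetic for a 2x2x2 x r design."""
    f = ["A", "B", "C"]
    r = df.groupby(f).size().iloc[0]
    m = df["y"].mean()
    cell = df.groupby(f)["y"].mean()
    m1 = {x: df.groupby(x)["y"].mean() for x in f}
    m2 = {
        (a, b): df.groupby([a, b])["y"].mean()
        for a, b in itertools.combinations(f, 2)
    }
    ss = {}
    for x in f:
        others = [lv for lv in f if lv != x]
        n_per = r * df[others[0]].nunique() * df[others[1]].nunique()
        ss[x] = n_per * ((m1[x] - m) ** 2).sum()
    for a, b in itertools.combinations(f, 2):
        other = [lv for lv in f if lv not in (a, b)][0]
        n_per = r * df[other].nunique()
        dev = m2[(a, b)].copy()
        for (ai, bi) in dev.index:
            dev.loc[(ai, bi)] = (
                m2[(a, b)].loc[(ai, bi)] - m1[a].loc[ai] - m1[b].loc[bi] + m
            )
        ss[f"{a}:{b}"] = n_per * (dev**2).sum()
    dev3 = cell.copy()
    for (ai, bi, ci) in dev3.index:
        dev3.loc[(ai, bi, ci)] = (
            cell.loc[(ai, bi, ci)]
            - m2[("A", "B")].loc[(ai, bi)]
            - m2[("A", "C")].loc[(ai, ci)]
            - m2[("B", "C")].loc[(bi, ci)]
            + m1["A"].loc[ai]
            + m1["B"].loc[bi]
            + m1["C"].loc[ci]
            - m
        )
    ss["A:B:C"] = r * (dev3**2).sum()
    resid = df["y"] - df.set_index(f).index.map(cell)
    ss["residual"] = (resid**2).sum()
    return ss


class TestAnova:
    def _toy(self, seed=0, r=3):
        rng = np.random.default_rng(seed)
        rows = []
        for a, b, c in itertools.product([0, 1], repeat=3):
            for _ in range(r):
                rows.append((a, b, c, rng.normal(a * 0.5 + a * b * 0.3, 1.0)))
        return pd.DataFrame(rows, columns=["A", "B", "C", "y"])

    def test_matches_direct_ss_arithmetic(self):
        df = self._toy(seed=4)
        table = balanced_anova(df, "y", ["A", "B", "C"]).table
        oracle = _anova_oracle_222(df)
        for effect, ss in oracle.items():
            assert table.loc[effect, "sum_sq"] == pytest.approx(ss, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = self._toy(seed=9)
        mine = balanced_anova(df, "y", ["A", "B", "C"]).table
        # patsy's C() would be shadowed by a column named C; rename for the formula
        df_sm = df.rename(columns={"A": "f1", "B": "f2", "C": "f3"})
        model = ols("y ~ C(f1) * C(f2) * C(f3)", data=df_sm).fit()
        ref = sm.stats.anova_lm(model, typ=2)
        pairs = {
            "A": "C(f1)",
            "B": "C(f2)",
            "C": "C(f3)",
            "A:B": "C(f1):C(f2)",
            "A:B:C": "C(f1):C(f2):C(f3)",
            "residual": "Residual",
        }
        for eff, sm_eff in pairs.items():
            assert mine.loc[eff, "sum_sq"] == pytest.approx(
                ref.loc[sm_eff, "sum_sq"], rel=1e-9
            )

    def test_decomposition_is_exact(self):
        df = self._toy(seed=2, r=4)
        res = balanced_anova(df, "y", ["A", "B", "C"]).table
        parts = res.drop(index="total")["sum_sq"].sum()
        assert parts == pytest.approx(res.loc["total", "sum_sq"], rel=1e-12)
        assert res.drop(index="total")["df"].sum() == res.loc["total", "df"]

    def test_unbalanced_rejected(self):
        df = self._toy(seed=1).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            balanced_anova(df, "y", ["A", "B", "C"])

    def test_null_calibration(self):
        # pure-noise full factorial: treatment-effect p should be uniform
        rng = np.random.default_rng(77)
        n_sim = 400
        design = list(itertools.product([0, 1], range(6), range(3)))
        rej = 0
        for _ in range(n_sim):
            rows = [
                (a, b, c, rng.normal()) for a, b, c in design for _ in range(3)
            ]
            df = pd.DataFrame(rows, columns=["A", "B", "C", "y"])
            p = balanced_anova(df, "y", ["A", "B", "C"]).p_value("A")
            rej += p < 0.05
        rate = rej / n_sim
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_sim) + 0.005

    def test_strong_treatment_effect_detected(self):
        cfg = default_study_config(seed=3)
        table = generate(cfg)
        res = three_way_anova(table, "TA")
        assert res.p_value("treatment") < 0.001
        # three-way interaction was not built into the generator
        assert res.p_value("treatment:time_d:temperature_C") > 0.001

    def test_unknown_attribute_rejected(self):
        table = generate(default_study_config(seed=3))
        with pytest.raises(DomainError):
            three_way_anova(table, "colour")


def _duncan_oracle(groups, ms_error, df_error, alpha=0.05):
    """Exhaustive-stretch Duncan letters, written independently.

    Tests every ordered stretch explicitly; a pair shares a letter iff some
    stretch containing both has range <= its critical value.  Letters are the
    maximal such stretches.
    """
    labels = sorted(groups, key=lambda g: np.mean(groups[g]))
    means = [np.mean(groups[g]) for g in labels]
    r = len(next(iter(groups.values())))
    m = len(labels)

    def crit(p):
        q = stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_error)
        return q * math.sqrt(ms_error / r)

    nonsig = [
        (i, j)
        for i in range(m)
        for j in range(i, m)
        if means[j] - means[i] <= (crit(j - i + 1) if j > i else np.inf) or i == j
    ]
    maximal = [
        (i, j)
        for (i, j) in nonsig
        if not any(
            (a <= i and j <= b and (a, b) != (i, j)) for (a, b) in nonsig
        )
    ]
    letters = {lab: "" for lab in labels}
    for idx, (i, j) in enumerate(sorted(maximal)):
        ch = chr(ord("a") + idx)
        for pos in range(i, j + 1):
            letters[labels[pos]] += ch
    return letters


class TestDuncan:
    def test_identical_groups_share_letter(self):
        groups = {"g1": [5.0, 5.1, 4.9], "g2": [5.0, 5.1, 4.9]}
        disp = duncan_mrt(groups, ms_error=0.01, df_error=4)
        assert disp.letters == ["a", "a"]

    def test_distant_groups_get_distinct_letters(self):
        groups = {"lo": [0.0, 0.1, -0.1], "hi": [100.0, 100.1, 99.9]}
        disp = duncan_mrt(groups, ms_error=0.01, df_error=4)
        assert disp.letters == ["a", "b"]
        assert not disp.share_letter("lo", "hi")

    @pytest.mark.parametrize("n_groups", [2, 3, 4, 5, 6])
    def test_matches_exhaustive_stretch_oracle(self, n_groups):
        rng = np.random.default_rng(100 + n_groups)
        for trial in range(20):
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 3), 1.0, 3).tolist()
                for i in range(n_groups)
            }
            ms = float(rng.uniform(0.2, 2.0))
            df_err = n_groups * 2
            disp = duncan_mrt(groups, ms_error=ms, df_error=df_err)
            oracle = _duncan_oracle(groups, ms, df_err)
            mine = dict(zip(disp.labels, disp.letters))
            for la, lb in itertools.combinations(groups, 2):
                assert (set(mine[la]) & set(mine[lb]) != set()) == (
                    set(oracle[la]) & set(oracle[lb]) != set()
                ), (groups, mine, oracle)

    def test_two_groups_agree_with_t_test(self):
        # with 2 means the studentized range reduces to t: same reject/accept
        rng = np.random.default_rng(55)
        for trial in range(50):
            delta = rng.uniform(0, 2)
            g1 = rng.normal(0, 1, 3)
            g2 = rng.normal(delta, 1, 3)
            pooled = np.concatenate([g1 - g1.mean(), g2 - g2.mean()])
            ms = float(np.sum(pooled**2) / 4)
            disp = duncan_mrt({"a": g1, "b": g2}, ms_error=ms, df_error=4)
            duncan_reject = not disp.share_letter("a", "b")
            t = abs(g1.mean() - g2.mean()) / math.sqrt(ms * 2 / 3)
            t_reject = 2 * stats.t.sf(t, 4) < 0.05
            assert duncan_reject == t_reject

    def test_unequal_sizes_rejected(self):
        with pytest.raises(UnbalancedDesignError):
            duncan_mrt({"a": [1, 2, 3], "b": [1, 2]}, ms_error=1.0, df_error=3)


def _fit(k, k_se=0.0, k_sd=None, n_pts=6):
    return KineticFit(
        order=0, k=k, k_se=k_se, direction=-1, A0_hat=1.0, r2=0.95,
        rmse=0.01, residuals=np.zeros(n_pts), slope_p=0.01,
        times=np.arange(n_pts, dtype=float), k_sd_reps=k_sd,
    )


class TestCompareFits:
    def test_identical_fits(self):
        t, p, stars = compare_fits(_fit(0.01, k_se=0.001), _fit(0.01, k_se=0.001))
        assert p == 1.0
        assert stars == ""

    def test_published_ta_rows_highly_significant(self):
        t, p, stars = compare_fits(
            _fit(0.013, k_sd=0.0002), _fit(0.008, k_sd=0.0001), nA=3, nB=3
        )
        assert p < 0.001
        assert stars == "***"

    def test_no_uncertainty_rejected(self):
        with pytest.raises(DomainError):
            compare_fits(_fit(0.01), _fit(0.02))

    def test_null_simulation_type_one_error(self):
        rng = np.random.default_rng(31)
        n_sim = 1000
        rej = 0
        for _ in range(n_sim):
            a = rng.normal(0.02, 0.002, 3)
            b = rng.normal(0.02, 0.002, 3)
            _, p, _ = compare_fits(
                _fit(a.mean(), k_sd=a.std(ddof=1)),
                _fit(b.mean(), k_sd=b.std(ddof=1)),
                nA=3, nB=3,
            )
            rej += p < 0.05
        rate = rej / n_sim
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_sim) + 0.005

    def test_star_codes(self):
        assert star_code(0.0005) == "***"
        assert star_code(0.005) == "**"
        assert star_code(0.02) == "*"
        assert star_code(0.2) == ""


def test_normality_diagnostics_pass_through():
    rng = np.random.default_rng(12)
    groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
    diag = normality_diagnostics(groups)
    assert set(diag["shapiro_p"]) == {"a", "b"}
    assert 0 <= diag["levene_p"] <= 1
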