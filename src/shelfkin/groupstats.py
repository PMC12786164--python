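"""Treatment-effect statistics for balanced storage studies.

Covers the inferential layer of a shelf-life study: percent change of rate
constants between processing arms, classical balanced three-way factorial
ANOVA (processing method × storage time × storage temperature with all
interactions), Duncan's multiple range test with compact letter display, and
Welch comparisons of fitted rate constants with the conventional star codes
(* p<0.05, ** p<0.01, *** p<0.001).

The ANOVA engine is balanced-only: with equal cell counts the Type I/II/III
sums of squares coincide and the classical means decomposition is exact, so
it is computed directly from cell means (statsmodels reproduces it and is
used as a cross-check in the test suite).  Unbalanced data raise an error
rather than silently switching SS type.
"""

from __future__ import annotations

import functools
import itertools
import math
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, UnbalancedDesignError
from .kinetics import KineticFit
from .timeseries import MeasurementTable

__all__ = [
    "AnovaTable",
    "LetterDisplay",
    "percent_reduction",
    "percent_retention",
    "three_way_anova",
    "balanced_anova",
    "duncan_mrt",
    "compare_fits",
    "star_code",
    "normality_diagnostics",
]

DEFAULT_FACTORS = ("treatment", "time_d", "temperature_C")


@dataclass
class AnovaTable:
    """Fixed-effects factorial ANOVA decomposition.

    ``table`` has one row per effect (mains, interactions, residual) with
    columns ``sum_sq, df, mean_sq, F, p``.
    """

    table: pd.DataFrame
    grand_mean: float
    n_obs: int

    @property
    def residual_ms(self) -> float:
        return float(self.table.loc["residual", "mean_sq"])

    @property
    def residual_df(self) -> int:
        return int(self.table.loc["residual", "df"])

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def to_records(self) -> list[dict]:
        return self.table.reset_index(names="effect").to_dict("records")


@dataclass
class LetterDisplay:
    """Compact letter display from a multiple range test.

    Groups sharing any letter are not significantly different; means sorted
    ascending receive letters in order of first assignment.
    """

    labels: list
    means: np.ndarray
    letters: list[str]
    critical_ranges: dict[int, float]

    def as_dict(self) -> dict:
        return {
            lab: {"mean": float(m), "letters": lt}
            for lab, m, lt in zip(self.labels, self.means, self.letters)
        }

    def share_letter(self, lab_a, lab_b) -> bool:
        la = set(self.letters[self.labels.index(lab_a)])
        lb = set(self.letters[self.labels.index(lab_b)])
        return bool(la & lb)


def percent_reduction(k_control: float, k_prototype: float) -> float:
    """Percent reduction of the prototype rate constant relative to control.

    100 * (k_control - k_prototype) / k_control.  Negative when the
    prototype degrades faster.  Reporting convention is nearest-integer
    rounding, left to the caller.
    """
    if k_control == 0:
        raise DomainError("k_control must be nonzero")
    if k_control < 0 or k_prototype < 0:
        raise DomainError("rate constants must be nonnegative")
    return 100.0 * (k_control - k_prototype) / k_control


def percent_retention(k_control: float, k_prototype: float) -> float:
    """Complement of :func:`percent_reduction`: 100 * k_prototype/k_control."""
    if k_control == 0:
        raise DomainError("k_control must be nonzero")
    return 100.0 * k_prototype / k_control


def balanced_anova(
    df: pd.DataFrame, response: str, factors: Sequence[str]
) -> AnovaTable:
    """Classical fixed-effects ANOVA for a balanced complete factorial.

    Sums of squares come from the standard means decomposition: for a factor
    subset S, R(S) = n_S * sum of squared cell means over the cells of S, and
    SS(S) = R(S) - CF - sum of SS over proper subsets.  This is exact for
    balanced data (where all SS types coincide).
    """
    factors = list(factors)
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    counts = df.groupby(factors, sort=False)[response].count()
    if counts.nunique() != 1:
        raise UnbalancedDesignError(
            "cell counts are unequal; this engine handles balanced designs "
            "only — aggregate to cell means or rebalance the data"
        )
    n_rep = int(counts.iloc[0])
    if n_rep < 2:
        raise InsufficientDataError("need >= 2 replicates per cell for a residual")
    cf = n * y.mean() ** 2

    def r_term(subset: tuple[str, ...]) -> float:
        cell = df.groupby(list(subset), sort=False)[response]
        means = cell.mean().to_numpy()
        per_cell = n / means.size
        return float(per_cell * np.sum(means**2))

    ss: dict[tuple[str, ...], float] = {}
    dfs: dict[tuple[str, ...], int] = {}
    levels = {f: df[f].nunique() for f in factors}
    for size in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, size):
            ss_sub = r_term(subset) - cf
            df_sub = 1
            for f in subset:
                df_sub *= levels[f] - 1
            for smaller in ss:
                if set(smaller) < set(subset):
                    ss_sub -= ss[smaller]
            ss[subset] = ss_sub
            dfs[subset] = df_sub

    ss_total = float(np.sum(y**2) - cf)
    ss_model = sum(ss.values())
    ss_resid = ss_total - ss_model
    df_resid = n - int(np.prod([levels[f] for f in factors]))
    ms_resid = ss_resid / df_resid

    rows = {}
    for subset in ss:
        name = ":".join(subset)
        ms = ss[subset] / dfs[subset]
        f_stat = ms / ms_resid
        rows[name] = {
            "sum_sq": ss[subset],
            "df": dfs[subset],
            "mean_sq": ms,
            "F": f_stat,
            "p": float(stats.f.sf(f_stat, dfs[subset], df_resid)),
        }
    rows["residual"] = {
        "sum_sq": ss_resid,
        "df": df_resid,
        "mean_sq": ms_resid,
        "F": np.nan,
        "p": np.nan,
    }
    rows["total"] = {
        "sum_sq": ss_total,
        "df": n - 1,
        "mean_sq": np.nan,
        "F": np.nan,
        "p": np.nan,
    }
    table = pd.DataFrame(rows).T[["sum_sq", "df", "mean_sq", "F", "p"]]
    table["df"] = table["df"].astype(int)
    return AnovaTable(table=table, grand_mean=float(y.mean()), n_obs=n)


def three_way_anova(table: MeasurementTable, response: str) -> AnovaTable:
    """Three-way factorial ANOVA of one attribute's raw values.

    Factors are processing method (treatment), storage time and storage
    temperature, with all two- and three-way interactions, tested against
    the within-cell residual mean square.
    """
    sub = table.subset(attribute=response)
    if sub.empty:
        raise DomainError(f"attribute {response!r} not present in table")
    return balanced_anova(sub, "value", DEFAULT_FACTORS)


def duncan_mrt(
    group_values: Mapping[object, Sequence[float]],
    ms_error: float,
    df_error: int,
    alpha: float = 0.05,
) -> LetterDisplay:
    """Duncan's multiple range test with compact letter display.

    Means are sorted ascending.  For a stretch of p consecutive ordered
    means, the critical range is

        R_p = q(1 - alpha_p; p, df_error) * sqrt(ms_error / r)

    with protection level alpha_p = 1 - (1 - alpha)^(p-1) and q the
    studentized-range quantile.  A stretch whose range does not exceed R_p is
    declared homogeneous, and — per Duncan's shielding rule — so is every
    stretch inside it.  Letters mark the maximal homogeneous stretches.

    Equal replicate counts are required (the triplicate-design case); the
    harmonic-mean variant for unequal n is out of scope.
    """
    if len(group_values) < 2:
        raise InsufficientDataError("need >= 2 groups")
    if ms_error <= 0:
        raise DomainError("ms_error must be positive")
    ns = {len(v) for v in group_values.values()}
    if len(ns) != 1:
        raise UnbalancedDesignError("Duncan's test here requires equal group sizes")
    r = ns.pop()
    labels = list(group_values)
    means = np.array([np.mean(group_values[lab]) for lab in labels])
    order = np.argsort(means, kind="stable")
    labels = [labels[i] for i in order]
    means = means[order]
    m = len(means)

    crit = {
        p: _q_duncan(alpha, p, df_error) * math.sqrt(ms_error / r)
        for p in range(2, m + 1)
    }

    # direct homogeneity of each ordered stretch [i, j]
    homog = np.zeros((m, m), dtype=bool)
    for i in range(m):
        homog[i, i] = True
        for j in range(i + 1, m):
            homog[i, j] = (means[j] - means[i]) <= crit[j - i + 1]

    # maximal homogeneous stretches (shielding makes sub-stretches redundant)
    stretches = []
    for i in range(m):
        for j in range(i, m):
            if homog[i, j] and not _covered(i, j, homog, m):
                stretches.append((i, j))
    stretches.sort()

    letters = ["" for _ in range(m)]
    alphabet = _letter_stream()
    for i, j in stretches:
        letter = next(alphabet)
        for idx in range(i, j + 1):
            letters[idx] += letter
    return LetterDisplay(
        labels=labels, means=means, letters=letters, critical_ranges=crit
    )


@functools.lru_cache(maxsize=4096)
def _q_duncan(alpha: float, p: int, df_error: int) -> float:
    """Studentized-range quantile at Duncan's protection level (cached:
    the quantile is expensive and designs reuse a handful of (p, df))."""
    return float(stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_error))


def _covered(i: int, j: int, homog: np.ndarray, m: int) -> bool:
    """True if stretch [i, j] sits strictly inside a homogeneous stretch."""
    for a in range(i + 1):
        for b in range(j, m):
            if (a, b) != (i, j) and homog[a, b]:
                return True
    return False


def _letter_stream():
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_lowercase, repeat=size):
            yield "".join(combo)


def star_code(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_fits(
    fitA: KineticFit,
    fitB: KineticFit,
    nA: int = 3,
    nB: int = 3,
) -> tuple[float, float, str]:
    """Welch two-sided comparison of two rate constants.

    Uses across-replicate SDs (``k_sd_reps``) when both fits carry them,
    treating each k as a mean of ``nA``/``nB`` replicate fits; otherwise the
    regression standard errors with their residual degrees of freedom.

    Returns
    -------
    (t_statistic, p_value, stars)
    """
    if fitA.k_sd_reps is not None and fitB.k_sd_reps is not None:
        vA = fitA.k_sd_reps**2 / nA
        vB = fitB.k_sd_reps**2 / nB
        dfA, dfB = nA - 1, nB - 1
    elif fitA.k_se > 0 and fitB.k_se > 0:
        vA, vB = fitA.k_se**2, fitB.k_se**2
        dfA = len(fitA.residuals) - 2
        dfB = len(fitB.residuals) - 2
    else:
        raise DomainError(
            "no uncertainty available on k; supply per-replicate SDs or "
            "regression standard errors"
        )
    denom = math.sqrt(vA + vB)
    if denom == 0:
        return (0.0, 1.0, "") if fitA.k == fitB.k else (math.inf, 0.0, "***")
    t = (fitA.k - fitB.k) / denom
    df = (vA + vB) ** 2 / (vA**2 / dfA + vB**2 / dfB)
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), p, star_code(p)


def normality_diagnostics(
    group_values: Mapping[object, Sequence[float]]
) -> dict:
    """Optional Shapiro–Wilk and Levene pre-test diagnostics.

    Pass-through convenience: returns per-group Shapiro p-values and a
    single Levene p-value for homogeneity of variances.  These inform the
    analyst but never gate the pipeline.
    """
    shapiro = {
        lab: float(stats.shapiro(np.asarray(v)).pvalue)
        for lab, v in group_values.items()
        if len(v) >= 3
    }
    groups = [np.asarray(v) for v in group_values.values()]
    levene_p = float(stats.levene(*groups).pvalue) if len(groups) >= 2 else float("nan")
    return {"shapiro_p": shapiro, "levene_p": levene_p}
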