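"""Pseudo-zero- and first-order kinetic fitting with order selection.

Quality decay during storage is modelled on the normalized scale A(t)
(dimensionless, A(0) = 1) by one of two pseudo-order laws:

* zero order:   A = A0 - k t        (linear in t)
* first order:  ln A = ln A0 - k t  (exponential in t)

Both reduce to ordinary least squares on a working scale — the normalized
values themselves for zero order, their natural log for first order.  The
rate constant k (day^-1) is stored as a nonnegative magnitude plus a
``direction`` flag (+1 for attributes that increase during storage, such as
pH; -1 for those that decay), which keeps downstream percent-change
arithmetic free of sign ambiguity.

R-squared is reported on each model's working scale; RMSE is always reported
on the original normalized scale (first-order predictions are back-transformed
with exp before residuals are formed) so the two orders are directly
comparable.  Order selection follows three criteria — higher R², lower RMSE,
and no systematic residual pattern (Wald–Wolfowitz runs test) — with a
parsimony tie-break to zero order when the models are indistinguishable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DomainError,
    InsufficientDataError,
    SingularDesignError,
)
from .timeseries import MeasurementTable, NormalizedSeries, normalize

__all__ = [
    "KineticFit",
    "OrderChoice",
    "PerReplicateK",
    "RunsTestResult",
    "fit_zero_order",
    "fit_first_order",
    "fit_series",
    "residual_pattern_test",
    "select_order",
    "fit_per_replicate",
]


@dataclass
class KineticFit:
    """Result of fitting one pseudo-order kinetic model to one series."""

    order: int
    k: float                      # rate-constant magnitude, day^-1
    k_se: float                   # regression standard error of k, day^-1
    direction: int                # +1 attribute increases, -1 decreases
    A0_hat: float                 # fitted intercept on the working scale
    r2: float                     # R^2 on the working scale
    rmse: float                   # RMSE on the original normalized scale
    residuals: np.ndarray         # original-scale residuals, time-ordered
    slope_p: float                # two-sided p-value of the slope
    times: np.ndarray = field(repr=False, default=None)
    k_sd_reps: float | None = None  # across-replicate SD of k, if computed

    def to_record(self, series: NormalizedSeries | None = None) -> dict:
        """JSON-ready record mirroring a kinetic-parameter table row."""
        rec = {
            "order": self.order,
            "k": self.k,
            "k_se": self.k_se,
            "k_sd": self.k_sd_reps,
            "R2": self.r2,
            "RMSE": self.rmse,
        }
        if series is not None:
            rec = {
                "attribute": series.attribute,
                "treatment": series.treatment,
                "temperature_C": series.temperature_C,
                **rec,
            }
        return rec


@dataclass(frozen=True)
class RunsTestResult:
    """Wald–Wolfowitz runs test on residual signs."""

    n_runs: int
    n_pos: int
    n_neg: int
    p_value: float
    systematic: bool
    skipped: bool = False


@dataclass
class OrderChoice:
    """Outcome of zero- vs first-order model selection for one series."""

    chosen_order: int
    fit0: KineticFit
    fit1: KineticFit | None
    rationale: dict

    @property
    def chosen(self) -> KineticFit:
        return self.fit0 if self.chosen_order == 0 else self.fit1


@dataclass
class PerReplicateK:
    """Rate constant summarized across independently fitted replicates."""

    k_mean: float
    k_sd: float
    k_values: np.ndarray
    replicates: np.ndarray
    excluded: list


def _ols_line(t: np.ndarray, y: np.ndarray):
    """OLS of y on t; returns (slope, intercept, slope_se, r2, p, fitted)."""
    if len(t) < 3:
        raise InsufficientDataError("kinetic fit requires >= 3 points")
    if np.ptp(t) == 0:
        raise SingularDesignError("all time points identical")
    if np.allclose(y, y[0]):
        # flat series: slope exactly 0, R^2 defined as 0, p = 1
        return 0.0, float(y[0]), 0.0, 0.0, 1.0, np.full_like(y, y[0])
    res = stats.linregress(t, y)
    fitted = res.intercept + res.slope * t
    return (
        float(res.slope),
        float(res.intercept),
        float(res.stderr),
        float(res.rvalue**2),
        float(res.pvalue),
        fitted,
    )


def fit_zero_order(series: NormalizedSeries) -> KineticFit:
    """Fit A = A0 - k t by OLS of the normalized means on time."""
    t, y = series.times, series.mean_norm
    slope, intercept, se, r2, p, fitted = _ols_line(t, y)
    resid = y - fitted
    return KineticFit(
        order=0,
        k=abs(slope),
        k_se=se,
        direction=1 if slope > 0 else -1,
        A0_hat=intercept,
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid**2))),
        residuals=resid,
        slope_p=p,
        times=t.copy(),
    )


def fit_first_order(series: NormalizedSeries) -> KineticFit:
    """Fit ln A = ln A0 - k t by OLS of log normalized means on time.

    R² refers to the log working scale; RMSE and residuals are computed on
    the original scale from back-transformed predictions exp(fitted).
    """
    t, y = series.times, series.mean_norm
    if (y <= 0).any():
        bad = t[y <= 0]
        raise DomainError(
            f"first-order fit needs positive normalized values; "
            f"nonpositive at t = {bad.tolist()} d"
        )
    slope, intercept, se, r2, p, fitted = _ols_line(t, np.log(y))
    resid = y - np.exp(fitted)
    return KineticFit(
        order=1,
        k=abs(slope),
        k_se=se,
        direction=1 if slope > 0 else -1,
        A0_hat=intercept,
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid**2))),
        residuals=resid,
        slope_p=p,
        times=t.copy(),
    )


def _exact_runs_pvalue(n_pos: int, n_neg: int, r_obs: int) -> float:
    """P(R <= r_obs) under the exact null of exchangeable signs.

    Few runs indicate clustering (a systematic pattern), so the lower tail
    is the relevant one.  The null distribution of the number of runs R for
    n_pos pluses and n_neg minuses is the classical combinatorial one.
    """
    n = n_pos + n_neg
    total = math.comb(n, n_pos)
    cum = 0
    for r in range(2, r_obs + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(n_pos - 1, k - 1) * math.comb(n_neg - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = math.comb(n_pos - 1, k) * math.comb(n_neg - 1, k - 1) + math.comb(
                n_pos - 1, k - 1
            ) * math.comb(n_neg - 1, k)
        cum += ways
    return min(1.0, cum / total)


def residual_pattern_test(
    fit: KineticFit, alpha: float = 0.05, zero_tol: float = 1e-12
) -> RunsTestResult:
    """Test residual signs for non-randomness with a runs test.

    Residuals within ``zero_tol`` of zero are dropped before sign coding.
    The exact run-count null distribution is used for n <= 20; the normal
    approximation beyond that.  A one-sided lower-tail p-value below
    ``alpha`` flags a systematic pattern (residuals clustering on one side).

    An all-zero residual vector (perfect fit) skips the test without a flag.
    """
    resid = np.asarray(fit.residuals, dtype=float)
    keep = np.abs(resid) > zero_tol
    signs = np.sign(resid[keep]).astype(int)
    if signs.size == 0:
        return RunsTestResult(0, 0, 0, float("nan"), systematic=False, skipped=True)
    if signs.size < 4:
        raise InsufficientDataError(
            "runs test requires >= 4 nonzero residuals"
        )
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    runs = int(1 + np.count_nonzero(signs[1:] != signs[:-1]))
    if n_pos == 0 or n_neg == 0:
        # one-sided residuals: maximally systematic
        return RunsTestResult(runs, n_pos, n_neg, 0.0, systematic=True)
    n = n_pos + n_neg
    if n <= 20:
        p = _exact_runs_pvalue(n_pos, n_neg, runs)
    else:
        mu = 1 + 2 * n_pos * n_neg / n
        var = 2 * n_pos * n_neg * (2 * n_pos * n_neg - n) / (n**2 * (n - 1))
        p = float(stats.norm.cdf((runs + 0.5 - mu) / math.sqrt(var)))
    return RunsTestResult(runs, n_pos, n_neg, p, systematic=p < alpha)


def select_order(
    fit0: KineticFit, fit1: KineticFit, tol_r2: float = 0.01
) -> OrderChoice:
    """Choose between the zero- and first-order fits of the same series.

    First order is retained only when it dominates: R² higher by more than
    ``tol_r2``, RMSE no worse, and its residuals no more patterned than the
    zero-order fit's.  Any conflict among the criteria, or an R² difference
    within ``tol_r2``, falls back to zero order (parsimony tie-break) —
    justified because exp(-kt) ~ 1 - kt whenever the models are this close.
    """
    try:
        runs0 = residual_pattern_test(fit0)
    except InsufficientDataError:
        runs0 = RunsTestResult(0, 0, 0, float("nan"), False, skipped=True)
    try:
        runs1 = residual_pattern_test(fit1)
    except InsufficientDataError:
        runs1 = RunsTestResult(0, 0, 0, float("nan"), False, skipped=True)

    delta_r2 = fit1.r2 - fit0.r2
    delta_rmse = fit1.rmse - fit0.rmse
    tie = abs(delta_r2) <= tol_r2
    first_dominates = (
        not tie
        and delta_r2 > 0
        and delta_rmse <= 0
        and (not runs1.systematic or runs0.systematic)
    )
    chosen = 1 if first_dominates else 0
    rationale = {
        "delta_r2": delta_r2,
        "delta_rmse": delta_rmse,
        "residuals_systematic": {0: runs0.systematic, 1: runs1.systematic},
        "runs_p": {0: runs0.p_value, 1: runs1.p_value},
        "tie_break_zero_order": tie,
    }
    return OrderChoice(chosen_order=chosen, fit0=fit0, fit1=fit1, rationale=rationale)


def fit_series(series: NormalizedSeries, tol_r2: float = 0.01) -> OrderChoice:
    """Fit both pseudo-orders to a normalized series and select one."""
    return select_order(
        fit_zero_order(series), fit_first_order(series), tol_r2=tol_r2
    )


def fit_per_replicate(
    table: MeasurementTable,
    attribute: str,
    treatment: str,
    temperature_C: float,
    order: int,
) -> PerReplicateK:
    """Fit the chosen order separately to each replicate's trajectory.

    Every replicate series is normalized by the *condition* day-0 mean (the
    same single baseline the pooled fit uses), then fitted independently;
    the across-replicate mean and sample SD of k quantify between-replicate
    uncertainty.  Replicates with fewer than 3 time points are excluded with
    a note; if none survive, an error is raised.
    """
    sub = table.subset(attribute, treatment, temperature_C)
    pooled = normalize(table, attribute, treatment, temperature_C)
    baseline = pooled.baseline_raw
    ks, reps, excluded = [], [], []
    for rep, grp in sub.groupby("replicate"):
        grp = grp.sort_values("time_d")
        t = grp["time_d"].to_numpy(dtype=float)
        y = grp["value"].to_numpy(dtype=float) / baseline
        if len(np.unique(t)) < 3:
            excluded.append((rep, "fewer than 3 time points"))
            continue
        series = _replicate_series(pooled, t, y)
        fit = fit_zero_order(series) if order == 0 else fit_first_order(series)
        ks.append(fit.k)
        reps.append(rep)
    if not ks:
        raise InsufficientDataError(
            f"no replicate with >= 3 time points for ({attribute}, {treatment}, "
            f"{temperature_C} degC)"
        )
    if len(ks) < 2:
        raise InsufficientDataError("per-replicate SD requires >= 2 replicates")
    ks = np.asarray(ks)
    return PerReplicateK(
        k_mean=float(ks.mean()),
        k_sd=float(ks.std(ddof=1)),
        k_values=ks,
        replicates=np.asarray(reps),
        excluded=excluded,
    )


def _replicate_series(
    pooled: NormalizedSeries, t: np.ndarray, y: np.ndarray
) -> NormalizedSeries:
    """Build a single-replicate NormalizedSeries without re-validating t[0]=0.

    Replicate trajectories share the pooled condition baseline, so their
    first value need not be exactly 1; the container invariant (times start
    at 0) still holds for complete designs.
    """
    s = NormalizedSeries.__new__(NormalizedSeries)
    s.attribute = pooled.attribute
    s.treatment = pooled.treatment
    s.temperature_C = pooled.temperature_C
    s.times = np.asarray(t, dtype=float)
    s.mean_norm = np.asarray(y, dtype=float)
    s.sd_norm = np.zeros_like(s.times)
    s.n_rep = np.ones_like(s.times, dtype=int)
    s.baseline_raw = pooled.baseline_raw
    return s
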