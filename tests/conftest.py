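import numpy as np
import pytest

from shelfkin.reference import TIMES_D
from shelfkin.timeseries import NormalizedSeries

DESIGN_TIMES = np.asarray(TIMES_D)


def make_series(times, values, attribute="Q", treatment="control", temp_C=4.0):
    """Build a NormalizedSeries directly from mean values (test helper)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    return NormalizedSeries(
        attribute=attribute,
        treatment=treatment,
        temperature_C=temp_C,
        times=times,
        mean_norm=values,
        sd_norm=np.zeros_like(times),
        n_rep=np.full(times.shape, 3, dtype=int),
        baseline_raw=1.0,
    )


@pytest.fixture
def design_times():
    return DESIGN_TIMES.copy()


def ols_oracle(t, y):
    """Closed-form normal-equations solution for simple OLS.

    Independent of scipy's fitting path: slope = Sxy/Sxx, intercept from the
    means, slope SE from the residual variance.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * tbar
    resid = y - intercept - slope * t
    s2 = np.sum(resid**2) / (n - 2)
    slope_se = np.sqrt(s2 / sxx)
    return slope, intercept, slope_se
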