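"""Tidy quality-measurement tables, day-0 normalization, colour difference
and the modellability screen.

The central container is :class:`MeasurementTable`, a validated long-format
table of raw quality measurements keyed by
``(attribute, treatment, temperature_C, time_d, replicate)``.  Attributes are
quality indices such as pH, titratable acidity (TA), total polyphenol content
(TPC) or antioxidant capacity (AOC); treatments are the processing arms of a
storage study (e.g. ``control`` vs ``prototype``); temperatures are constant
storage temperatures in degrees Celsius; times are days since packaging.

Kinetic modelling operates on *normalized* series: each condition's replicate
means divided by the condition's day-0 mean, so every trajectory is
dimensionless and starts at 1.  Attributes without a monotone trend (typically
CIELAB colour coordinates) are excluded from kinetics by
:func:`screen_modellable`, which requires either a slope significantly
different from zero or a preliminary R-squared above a threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    IntegrityError,
    NormalizationError,
    SchemaError,
)

REQUIRED_COLUMNS = (
    "attribute",
    "treatment",
    "temperature_C",
    "time_d",
    "replicate",
    "value",
)

COLOUR_COLUMNS = ("treatment", "temperature_C", "time_d", "replicate", "L", "a", "b")

KEY_COLUMNS = ("attribute", "treatment", "temperature_C", "time_d", "replicate")


@dataclass(frozen=True)
class Measurement:
    """One raw quality measurement in its native units."""

    attribute: str
    treatment: str
    temperature_C: float
    time_d: float
    replicate: int
    value: float


@dataclass
class MeasurementTable:
    """Validated tidy table of raw quality measurements.

    Parameters
    ----------
    data
        Long-format frame with columns ``attribute, treatment, temperature_C,
        time_d, replicate, value``.
    rejections
        Rows dropped at ingest (non-finite value, negative time), indexed by
        the original CSV row with a ``reason`` column.  Empty for
        programmatically built tables.
    """

    data: pd.DataFrame
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        self.data = self.data.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        dup = self.data.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            first = self.data.loc[dup.idxmax(), list(KEY_COLUMNS)].tolist()
            raise IntegrityError(f"duplicate measurement key: {first}")
        bad_time = self.data["time_d"] < 0
        if bad_time.any():
            raise IntegrityError("negative time_d in table")
        for col in ("temperature_C", "value"):
            if not np.isfinite(self.data[col]).all():
                raise IntegrityError(f"non-finite {col} in table")

    def __len__(self) -> int:
        return len(self.data)

    def conditions(self) -> pd.DataFrame:
        """Distinct (attribute, treatment, temperature_C) combinations."""
        return (
            self.data[["attribute", "treatment", "temperature_C"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def subset(
        self,
        attribute: str | None = None,
        treatment: str | None = None,
        temperature_C: float | None = None,
    ) -> pd.DataFrame:
        sel = pd.Series(True, index=self.data.index)
        if attribute is not None:
            sel &= self.data["attribute"] == attribute
        if treatment is not None:
            sel &= self.data["treatment"] == treatment
        if temperature_C is not None:
            sel &= np.isclose(self.data["temperature_C"], temperature_C)
        return self.data.loc[sel]

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        """Write the table as UTF-8 CSV with the canonical header."""
        self.data.to_csv(path, index=False)


@dataclass
class NormalizedSeries:
    """Per-condition time series of day-0-normalized replicate means.

    ``mean_norm[0]`` is exactly 1 by construction; ``baseline_raw`` preserves
    the day-0 raw mean in the attribute's native units.
    """

    attribute: str
    treatment: str
    temperature_C: float
    times: np.ndarray
    mean_norm: np.ndarray
    sd_norm: np.ndarray
    n_rep: np.ndarray
    baseline_raw: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_norm = np.asarray(self.mean_norm, dtype=float)
        self.sd_norm = np.asarray(self.sd_norm, dtype=float)
        self.n_rep = np.asarray(self.n_rep, dtype=int)
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if (self.sd_norm < 0).any():
            raise ValueError("sd_norm must be nonnegative")


@dataclass(frozen=True)
class ColourRecord:
    """A CIELAB colour observation at one storage time."""

    L_star: float
    a_star: float
    b_star: float
    time_d: float = 0.0
    treatment: str = ""
    temperature_C: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.L_star <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L_star}")


@dataclass(frozen=True)
class ScreenVerdict:
    """Outcome of the kinetic-modellability screen for one series."""

    attribute: str
    treatment: str
    temperature_C: float
    slope_p: float
    r2_preliminary: float
    modellable: bool


def read_measurements(path: str | Path | io.TextIOBase) -> MeasurementTable:
    """Read a long-format quality-measurement CSV into a validated table.

    Rows whose ``value`` is non-finite (NaN/inf, including unparseable cells)
    are dropped and recorded in ``table.rejections`` with the original row
    index.

    Raises
    ------
    SchemaError
        If a required column is absent.
    IntegrityError
        On duplicate measurement keys.
    """
    raw = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    raw["value"] = pd.to_numeric(raw["value"], errors="coerce")
    bad = ~np.isfinite(raw["value"])
    rejections = pd.DataFrame(
        {"reason": ["non-finite value"] * int(bad.sum())},
        index=raw.index[bad],
    )
    return MeasurementTable(raw.loc[~bad], rejections=rejections)


def normalize(
    table: MeasurementTable,
    attribute: str,
    treatment: str,
    temperature_C: float,
) -> NormalizedSeries:
    """Normalize one condition's series to its day-0 replicate mean.

    The denominator is the *mean across replicates at time 0* — a single
    baseline per condition — so ``mean_norm(t) = mean_raw(t) / mean_raw(0)``
    and ``sd_norm(t) = sd_raw(t) / mean_raw(0)``.

    Raises
    ------
    NormalizationError
        If no day-0 measurement exists or its mean is zero.
    """
    sub = table.subset(attribute, treatment, temperature_C)
    if sub.empty:
        raise NormalizationError(
            f"no data for ({attribute}, {treatment}, {temperature_C} degC)"
        )
    grouped = sub.groupby("time_d")["value"]
    means = grouped.mean()
    sds = grouped.std(ddof=1).fillna(0.0)
    counts = grouped.count()
    if 0.0 not in means.index:
        raise NormalizationError("no day-0 measurement to normalize against")
    baseline = float(means.loc[0.0])
    if baseline == 0.0:
        raise NormalizationError("day-0 mean is zero")
    times = means.index.to_numpy(dtype=float)
    order = np.argsort(times)
    return NormalizedSeries(
        attribute=attribute,
        treatment=treatment,
        temperature_C=temperature_C,
        times=times[order],
        mean_norm=(means.to_numpy() / baseline)[order],
        sd_norm=(sds.to_numpy() / abs(baseline))[order],
        n_rep=counts.to_numpy()[order],
        baseline_raw=baseline,
    )


def normalize_all(table: MeasurementTable) -> list[NormalizedSeries]:
    """Normalize every condition present in the table."""
    return [
        normalize(table, row.attribute, row.treatment, row.temperature_C)
        for row in table.conditions().itertuples()
    ]


def compute_delta_e(ref: ColourRecord, obs: ColourRecord) -> float:
    """Total colour change ΔE: Euclidean distance in CIELAB space.

    ΔE = sqrt((ΔL*)² + (Δa*)² + (Δb*)²); symmetric in its arguments.
    """
    return float(
        np.sqrt(
            (ref.L_star - obs.L_star) ** 2
            + (ref.a_star - obs.a_star) ** 2
            + (ref.b_star - obs.b_star) ** 2
        )
    )


def read_colour_records(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read CIELAB colour observations from CSV.

    Expected header: ``treatment,temperature_C,time_d,replicate,L,a,b``.
    """
    raw = pd.read_csv(path)
    missing = [c for c in COLOUR_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return raw.loc[:, list(COLOUR_COLUMNS)]

def delta_e_trajectory(colour: pd.DataFrame) -> pd.DataFrame:
    """ΔE of each condition's cell mean against its own day-0 cell mean.

    Colour records are averaged over replicates per (treatment, temperature,
    time); ΔE is then the CIELAB distance from the day-0 mean of the same
    treatment × temperature, so the day-0 row is 0 by construction.
    """
    cells = (
        colour.groupby(["treatment", "temperature_C", "time_d"])[["L", "a", "b"]]
        .mean()
        .reset_index()
    )
    out = []
    for (trt, temp), grp in cells.groupby(["treatment", "temperature_C"]):
        grp = grp.sort_values("time_d")
        base = grp.iloc[0]
        if base["time_d"] != 0:
            raise NormalizationError(
                f"no day-0 colour record for ({trt}, {temp} degC)"
            )
        ref = ColourRecord(base["L"], base["a"], base["b"])
        for row in grp.itertuples():
            de = compute_delta_e(ref, ColourRecord(row.L, row.a, row.b))
            out.append(
                {
                    "treatment": trt,
                    "temperature_C": temp,
                    "time_d": row.time_d,
                    "delta_e": de,
                }
            )
    return pd.DataFrame(out)


def screen_modellable(
    series: NormalizedSeries,
    alpha: float = 0.05,
    r2_min: float = 0.30,
) -> ScreenVerdict:
    """Decide whether a normalized series carries enough trend for kinetics.

    Ordinary least squares of ``mean_norm`` on time gives a two-sided slope
    p-value and R².  The series is declared *not* modellable only when both
    indicators fail simultaneously: slope indistinguishable from zero
    (p > ``alpha``) *and* preliminary R² below ``r2_min``.  Either a
    significant slope or a reasonable R² keeps the attribute in play.

    A perfectly constant series is handled safely: slope 0, R² 0, p = 1,
    not modellable.
    """
    if len(np.unique(series.times)) < 3:
        raise InsufficientDataError("screen requires >= 3 distinct time points")
    y = series.mean_norm
    t = series.times
    if np.allclose(y, y[0]):
        return ScreenVerdict(
            series.attribute, series.treatment, series.temperature_C,
            slope_p=1.0, r2_preliminary=0.0, modellable=False,
        )
    res = stats.linregress(t, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    modellable = not (p > alpha and r2 < r2_min)
    return ScreenVerdict(
        series.attribute, series.treatment, series.temperature_C,
        slope_p=p, r2_preliminary=r2, modellable=modellable,
    )
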