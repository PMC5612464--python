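"""Emulated Australian melanoma incidence and mortality series, 1982-2028.

The model is calibrated against national registry rates (Australian
Institute of Health and Welfare annual incidence and mortality per 100,000,
1982-2013, and published projections to 2028).  Those extracts are not
redistributable, so this module reconstructs smooth stand-ins from a handful
of published summary anchors: the 1982 incidence and mortality levels, the
2013 mortality level, the calendar year at which diagnostic incidence
peaked, and the 32-year cumulative totals of both series.

Because the model is fitted to the least-squares smooth of the registry data
rather than to raw annual counts, the generator emits the smooth constrained
parabolas directly; a seeded Gaussian-noise option exists purely for
robustness testing and is never part of the calibration conditions.

The projection era (2014-2028) is flat at the 2013 level of each series,
matching published expectations of a stable age-standardised incidence rate
over the fifteen years after 2013.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Observation window, inclusive: 32 annual values.
OBS_YEARS = np.arange(1982, 2014)
#: Projection window, inclusive: 15 annual values after 2013.
PROJ_YEARS = np.arange(2014, 2029)

CSV_HEADER = ("year", "rate_per_100k")


class SeriesError(ValueError):
    """Raised for infeasible anchor systems or malformed series files."""


@dataclass(frozen=True)
class AnchorSet:
    """Published summary values the emulated series must reproduce.

    All rates are per 100,000 persons; cumulative totals are per 100,000
    summed over the 32 observed years.
    """

    inc_1982: float = 27.08
    mort_1982: float = 4.76
    mort_2013: float = 6.0
    inc_total_1982_2013: float = 1319.0
    mort_total_1982_2013: float = 171.0
    inc_peak_year: int = 2008
    prevalence_D1_1982: float = 3215.0
    projection_level_inc: float | None = None   # default: emulated 2013 value
    projection_level_mort: float | None = None

    def __post_init__(self):
        for name in ("inc_1982", "mort_1982", "mort_2013",
                     "inc_total_1982_2013", "mort_total_1982_2013",
                     "prevalence_D1_1982"):
            if getattr(self, name) <= 0:
                raise SeriesError(f"anchor {name} must be positive")
        if not OBS_YEARS[0] <= self.inc_peak_year <= OBS_YEARS[-1]:
            raise SeriesError(
                f"incidence peak year {self.inc_peak_year} outside 1982-2013")

    def replace(self, **kw) -> "AnchorSet":
        return replace(self, **kw)


def _series(years: np.ndarray, values: np.ndarray) -> pd.Series:
    return pd.Series(np.asarray(values, float),
                     index=pd.Index(years, name="year"),
                     name="rate_per_100k")


def build_observed_series(anchors: AnchorSet) -> tuple[pd.Series, pd.Series]:
    """Construct the 1982-2013 incidence and mortality series.

    Incidence is the unique parabola y(t) = a + b t + c t^2 on t = 0..31
    satisfying y(0) = the 1982 rate, y'(peak) = 0 at the peak year, and the
    32-year sum; mortality is the unique parabola through both endpoint
    rates with the stated 32-year sum.  Anchor systems implying negative
    rates anywhere in the window are rejected.
    """
    t = OBS_YEARS - OBS_YEARS[0]
    st, st2 = t.sum(), (t ** 2).sum()
    n = len(t)

    # Incidence: value at 0, zero slope at the peak, fixed sum.
    tp = anchors.inc_peak_year - OBS_YEARS[0]
    A = np.array([[1.0, 0.0, 0.0],
                  [0.0, 1.0, 2.0 * tp],
                  [float(n), st, st2]])
    abc = np.linalg.solve(A, [anchors.inc_1982, 0.0,
                              anchors.inc_total_1982_2013])
    inc = abc[0] + abc[1] * t + abc[2] * t ** 2

    # Mortality: both endpoints plus the sum.
    A = np.array([[1.0, 0.0, 0.0],
                  [1.0, float(t[-1]), float(t[-1] ** 2)],
                  [float(n), st, st2]])
    abc = np.linalg.solve(A, [anchors.mort_1982, anchors.mort_2013,
                              anchors.mort_total_1982_2013])
    mort = abc[0] + abc[1] * t + abc[2] * t ** 2

    for name, vals in (("incidence", inc), ("mortality", mort)):
        if np.any(vals <= 0):
            raise SeriesError(f"anchor system infeasible: emulated {name} "
                              "series goes non-positive")
    return _series(OBS_YEARS, inc), _series(OBS_YEARS, mort)


def build_projection_series(anchors: AnchorSet,
                            observed: tuple[pd.Series, pd.Series] | None = None
                            ) -> tuple[pd.Series, pd.Series]:
    """Flat 2014-2028 projections at the 2013 level of each emulated series
    (or at explicit ``projection_level_*`` overrides)."""
    if observed is None:
        observed = build_observed_series(anchors)
    inc_obs, mort_obs = observed
    inc_level = (anchors.projection_level_inc
                 if anchors.projection_level_inc is not None
                 else float(inc_obs.iloc[-1]))
    mort_level = (anchors.projection_level_mort
                  if anchors.projection_level_mort is not None
                  else float(mort_obs.iloc[-1]))
    return (_series(PROJ_YEARS, np.full(len(PROJ_YEARS), inc_level)),
            _series(PROJ_YEARS, np.full(len(PROJ_YEARS), mort_level)))


def add_noise(series: pd.Series, sd: float, seed: int) -> pd.Series:
    """Seeded Gaussian perturbation of an annual series, clipped at zero.

    For robustness experiments only; the calibration conditions use the
    smooth series.
    """
    rng = np.random.default_rng(seed)
    noisy = series + rng.normal(0.0, sd, size=len(series))
    return noisy.clip(lower=0.0).rename(series.name)


def write_series_csv(series: pd.Series, path) -> None:
    """Write an annual series as ``year,rate_per_100k`` (UTF-8, 6 d.p.)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_HEADER)
        for year, rate in series.items():
            w.writerow([int(year), f"{rate:.6f}"])


def read_series_csv(path) -> pd.Series:
    """Read an annual series; malformed rows name their line number."""
    years, rates = [], []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SeriesError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != CSV_HEADER:
            raise SeriesError(f"{path}: line 1: expected header "
                              f"{','.join(CSV_HEADER)!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise SeriesError(f"{path}: line {lineno}: expected 2 fields")
            try:
                year = int(row[0])
                rate = float(row[1])
            except ValueError as exc:
                raise SeriesError(f"{path}: line {lineno}: {exc}") from None
            if rate < 0:
                raise SeriesError(f"{path}: line {lineno}: negative rate")
            years.append(year)
            rates.append(rate)
    if not years:
        raise SeriesError(f"{path}: no data rows")
    if np.any(np.diff(years) != 1):
        raise SeriesError(f"{path}: years are not consecutive")
    return _series(np.asarray(years), np.asarray(rates))
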