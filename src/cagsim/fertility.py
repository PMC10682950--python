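"""Age-specific fertility schedules and the anticipation coefficient.

The anticipation coefficient (*antcoeff*) maps a carrier's age at onset (AO)
to the fraction of lifetime reproduction still available. The fertility
function over the reproductive window (12–50 years) is normalised so its area
is 1; the coefficient is the cumulative normalised area up to the AO, plus a
small additive correction for children born after parental onset, clamped to
[0, 1]. Onset before age 12 gives exactly 0 (reproduction fully prevented);
onset after age 50 gives exactly 1 (reproduction unaffected).

A deterministic synthetic schedule shaped like the EUROSTAT 2019 European
female fertility curve (unimodal, peak near age 30, near-zero at the window
edges) is packaged so no external data download is required; users may load a
real single-year schedule from a two-column ``age,rate`` CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "FertilitySchedule",
    "ScheduleError",
    "load_fertility_schedule",
    "load_fertility_csv",
    "make_synthetic_schedule",
    "cumulative_fraction",
    "anticipation_coefficient",
]

DEFAULT_WINDOW = (12.0, 50.0)


class ScheduleError(ValueError):
    """Raised for malformed fertility tables."""


@dataclass(frozen=True, eq=False)
class FertilitySchedule:
    """Tabulated age-specific fertility rates with a normalised cumulative form.

    Rates are interpreted as a piecewise-linear density over age; rates
    outside ``window`` contribute nothing to the normalised area. The
    cumulative form is the exact integral of the piecewise-linear density
    (trapezoidal between tabulated ages), rescaled so the area over the
    window equals 1.
    """

    ages: np.ndarray
    rates: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW
    # knots of the windowed density and its normalised cumulative, built in
    # __post_init__ and used by cumulative_fraction
    _knots: np.ndarray = field(init=False, repr=False, compare=False)
    _knot_rates: np.ndarray = field(init=False, repr=False, compare=False)
    _knot_cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        if ages.size < 2:
            raise ScheduleError(f"need at least 2 tabulated ages, got {ages.size}")
        if ages.ndim != 1 or rates.shape != ages.shape:
            raise ScheduleError("ages and rates must be 1-D arrays of equal length")
        if not np.all(np.isfinite(ages)) or not np.all(np.isfinite(rates)):
            raise ScheduleError("ages and rates must be finite")
        diffs = np.diff(ages)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ScheduleError(
                f"ages must be strictly increasing; violation at age {ages[i + 1]}"
            )
        neg = rates < 0
        if np.any(neg):
            i = int(np.argmax(neg))
            raise ScheduleError(f"negative fertility rate at age {ages[i]}: {rates[i]}")
        lo, hi = self.window
        if not lo < hi:
            raise ScheduleError(f"window must have min_age < max_age, got {self.window}")

        # Density over the window: linear interpolation of the table, zero
        # outside the tabulated range, restricted to [lo, hi].
        inner = ages[(ages > lo) & (ages < hi)]
        knots = np.concatenate(([lo], inner, [hi]))
        knot_rates = np.interp(knots, ages, rates, left=0.0, right=0.0)
        seg_area = np.diff(knots) * (knot_rates[:-1] + knot_rates[1:]) / 2.0
        total = float(seg_area.sum())
        if total <= 0:
            raise ScheduleError("total fertility area over the window must be > 0")
        cum = np.concatenate(([0.0], np.cumsum(seg_area))) / total
        cum[-1] = 1.0
        object.__setattr__(self, "_knots", knots)
        object.__setattr__(self, "_knot_rates", knot_rates / total)
        object.__setattr__(self, "_knot_cum", cum)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "rate": self.rates})


def load_fertility_schedule(
    table, window: tuple[float, float] = DEFAULT_WINDOW
) -> FertilitySchedule:
    """Build a schedule from two-column age/rate records.

    ``table`` may be a DataFrame with ``age``/``rate`` columns, a mapping, or
    any sequence of (age, rate) pairs. Ages must be strictly increasing and
    rates non-negative; rates outside ``window`` are kept in the table but
    contribute nothing to the normalised area.
    """
    if isinstance(table, pd.DataFrame):
        if not {"age", "rate"}.issubset(table.columns):
            raise ScheduleError("fertility table must have 'age' and 'rate' columns")
        ages = table["age"].to_numpy(dtype=float)
        rates = table["rate"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(table), dtype=float)
        if arr.size == 0:
            raise ScheduleError("empty fertility table")
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ScheduleError("fertility records must be (age, rate) pairs")
        ages, rates = arr[:, 0], arr[:, 1]
    if ages.size == 0:
        raise ScheduleError("empty fertility table")
    return FertilitySchedule(ages=ages, rates=rates, window=window)


def load_fertility_csv(
    path: Union[str, Path], window: tuple[float, float] = DEFAULT_WINDOW
) -> FertilitySchedule:
    """Load an ``age,rate`` CSV (one row per single year of age)."""
    df = pd.read_csv(path)
    return load_fertility_schedule(df, window=window)


def make_synthetic_schedule(
    peak_age: float = 30.0,
    spread: float = 6.0,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> FertilitySchedule:
    """Deterministic unimodal schedule on integer ages across the window.

    A Gaussian-shaped rate curve peaking at ``peak_age`` with standard
    deviation ``spread`` years, emulating the shape of the EUROSTAT 2019
    European female fertility curve. The packaged default is (30, 6).
    """
    lo, hi = window
    if not (lo < peak_age < hi):
        raise ScheduleError(f"peak_age must lie inside the window {window}, got {peak_age}")
    if not spread > 0:
        raise ScheduleError(f"spread must be > 0, got {spread}")
    ages = np.arange(np.floor(lo), np.floor(hi) + 1, dtype=float)
    rates = np.exp(-0.5 * ((ages - peak_age) / spread) ** 2)
    return FertilitySchedule(ages=ages, rates=rates, window=window)


def cumulative_fraction(s: FertilitySchedule, age: float) -> float:
    """Fraction of the normalised fertility area accumulated up to ``age``.

    Exact integral of the piecewise-linear density from the window start;
    ages clamp to the window, so the result is 0 at or below the window
    minimum and 1 at or above the maximum. Monotone non-decreasing in age.
    """
    lo, hi = s.window
    if age <= lo:
        return 0.0
    if age >= hi:
        return 1.0
    knots, r, cum = s._knots, s._knot_rates, s._knot_cum
    i = int(np.searchsorted(knots, age, side="right")) - 1
    x0, x1 = knots[i], knots[i + 1]
    r0, r1 = r[i], r[i + 1]
    ra = r0 + (r1 - r0) * (age - x0) / (x1 - x0)
    return float(cum[i] + (age - x0) * (r0 + ra) / 2.0)


def anticipation_coefficient(
    s: FertilitySchedule, ao: float, post_onset_birth_fraction: float = 0.0
) -> float:
    """Anticipation coefficient for a carrier with age at onset ``ao``.

    Exactly 0 when onset precedes the reproductive window, exactly 1 when it
    follows it; otherwise the cumulative fertility fraction up to the AO plus
    the post-onset birth fraction, capped at 1.
    """
    lo, hi = s.window
    if ao <= lo:
        return 0.0
    if ao >= hi:
        return 1.0
    return min(1.0, cumulative_fraction(s, ao) + post_onset_birth_fraction)
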