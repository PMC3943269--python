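"""Deterministic variable construction.

Three rules used throughout the analysis: rank-based quartile
categorization of continuous variables (so the four classes comprise a
similar number of participants), the 5-category coding of neighborhood
recreational walking time (category 1 reserved for exactly zero
minutes), and the 8-day weather-window average (recruitment day plus the
7 previous days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import (
    DegenerateOutcomeError,
    DegenerateVariableError,
    InvalidArgumentError,
    MissingWeatherError,
)

__all__ = [
    "QuartileCoding",
    "quartile_categorize",
    "code_ordinal_walking",
    "weather_window_average",
]


@dataclass(frozen=True)
class QuartileCoding:
    """Stored value cutoffs of a fitted quartile categorization.

    ``cutoffs`` are the largest training values falling in categories
    1..3; applying the coding assigns ``1 + sum(x > cutoff_k)``, which
    reproduces the training assignment exactly and extends it to new
    data.
    """

    cutoffs: tuple[float, float, float]

    def apply(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        cats = np.ones(x.shape, dtype=int)
        for c in self.cutoffs:
            cats += (x > c).astype(int)
        return cats

    def to_dict(self) -> dict:
        return {"cutoffs": [float(c) for c in self.cutoffs]}


def quartile_categorize(values) -> tuple[np.ndarray, QuartileCoding]:
    """Assign rank-based quartile categories 1-4.

    Average ranks are used so that tied values always share a category,
    with ties at a boundary going to the lower category; absent ties the
    four category sizes differ by at most one.

    Returns the integer category vector and a :class:`QuartileCoding`
    that can re-apply the training cutoffs to new data.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("expected a 1-d vector")
    if np.isnan(x).any():
        raise InvalidArgumentError("values contain NaN")
    if np.unique(x).size < 4:
        raise DegenerateVariableError(
            "fewer than 4 distinct values; quartile categorization is degenerate"
        )
    n = x.size
    r = rankdata(x, method="average")
    cats = np.ones(n, dtype=int)
    for q in (0.25, 0.5, 0.75):
        cats += (r > q * n).astype(int)
    # a tie block straddling a boundary can leave a lower category empty;
    # its cutoff then sits below the data so apply() reproduces training
    cutoffs = []
    for k in (1, 2, 3):
        members = x[cats <= k]
        cutoffs.append(float(members.max()) if members.size else float(x.min()) - 1.0)
    return cats, QuartileCoding(cutoffs=tuple(cutoffs))


def code_ordinal_walking(minutes) -> np.ndarray:
    """Code walking minutes as the 5-category ordinal outcome.

    Category 1 is exactly zero minutes; positive minutes are
    quartile-split into categories 2-5 so the four upper classes
    comprise a similar number of participants.
    """
    m = np.asarray(minutes, dtype=float)
    if np.isnan(m).any():
        raise InvalidArgumentError("minutes contain NaN")
    if (m < 0).any():
        raise InvalidArgumentError("walking minutes must be nonnegative")
    pos = m > 0
    if not pos.any():
        raise DegenerateOutcomeError("all walking minutes are zero")
    if np.unique(m[pos]).size < 4:
        raise DegenerateOutcomeError(
            "fewer than 4 distinct positive walking times; cannot form 4 upper categories"
        )
    out = np.ones(m.shape, dtype=int)
    cats_pos, _ = quartile_categorize(m[pos])
    out[pos] = cats_pos + 1
    return out


def weather_window_average(daily: pd.Series, recruitment_date) -> float:
    """Mean of a daily weather series over the recruitment day and the 7
    previous days (an 8-day window).

    ``daily`` must be indexed by date; any missing calendar day in the
    window raises :class:`MissingWeatherError`.
    """
    day = pd.Timestamp(recruitment_date).normalize()
    window = pd.date_range(day - pd.Timedelta(days=7), day, freq="D")
    idx = pd.DatetimeIndex(pd.to_datetime(daily.index)).normalize()
    s = pd.Series(daily.to_numpy(), index=idx)
    missing = window.difference(s.index)
    if len(missing) > 0:
        raise MissingWeatherError(
            f"weather series missing {len(missing)} day(s) in the 8-day window "
            f"ending {day.date()}: first missing {missing[0].date()}"
        )
    vals = s.loc[window].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise MissingWeatherError(f"NaN weather value inside the window ending {day.date()}")
    return float(vals.mean())
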