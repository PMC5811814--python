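"""Generation of the experimental salary time series.

The stimuli are monthly salary series (pounds sterling) built from a linear
deterministic component plus i.i.d. Gaussian noise:

* positive trend:  Y(t) = 3000 + 21.28 t + n
* negative trend:  Y(t) = 4000 - 21.28 t + n
* stationary:      Y(t) = 3500 + n

with t = 1..48 and n ~ N(0, variance 10) by default.  A *consistent* series
presents the 48 trend points; an *inconsistent* series appends a 49th point
equal to the grand mean 3,500 exactly (no noise), breaking the trend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "TrendDirection",
    "TrendConsistency",
    "TrendSpec",
    "SalarySeries",
    "MEAN_SALARY",
    "DEFAULT_NOISE_VARIANCE",
    "make_trend_spec",
    "deterministic_value",
    "generate_series",
    "series_mean",
]

#: Grand mean of the stationary generating equation and the appended
#: final value of every inconsistent series (pounds).
MEAN_SALARY = 3500.0

#: Variance of the Gaussian noise term n (pounds squared).
DEFAULT_NOISE_VARIANCE = 10.0


class TrendDirection(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    STATIONARY = "stationary"


class TrendConsistency(str, Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"


# (intercept, slope per month) of the deterministic component.
_TREND_PARAMS = {
    TrendDirection.POSITIVE: (3000.0, 21.28),
    TrendDirection.NEGATIVE: (4000.0, -21.28),
    TrendDirection.STATIONARY: (3500.0, 0.0),
}

_CONSISTENT_LENGTH = 48
_INCONSISTENT_LENGTH = 49


@dataclass(frozen=True)
class TrendSpec:
    """Parametric description of one generating equation.

    Attributes
    ----------
    direction, consistency
        Which trend and whether the final appended mean value is present.
    intercept, slope
        Deterministic component ``intercept + slope * t`` (pounds, pounds/month).
    noise_variance
        Variance of the additive Gaussian noise (pounds squared).
    length
        48 for consistent series, 49 for inconsistent ones.
    t_origin
        Index of the first month in the generating equation.  The default 1
        follows t = 1..48; 0 makes the trended deterministic means almost
        coincide with the stationary mean 3,500.
    """

    direction: TrendDirection
    consistency: TrendConsistency
    intercept: float
    slope: float
    noise_variance: float = DEFAULT_NOISE_VARIANCE
    length: int = _CONSISTENT_LENGTH
    t_origin: int = 1

    def __post_init__(self) -> None:
        if self.noise_variance < 0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")
        expected = (
            _INCONSISTENT_LENGTH
            if self.consistency is TrendConsistency.INCONSISTENT
            else _CONSISTENT_LENGTH
        )
        if self.length != expected:
            raise ValueError(
                f"{self.consistency.value} series must have length {expected}, got {self.length}"
            )


@dataclass(frozen=True)
class SalarySeries:
    """An ordered sequence of monetary values with a 1-based month index."""

    values: np.ndarray
    spec: TrendSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).reshape(-1)
        )

    def __len__(self) -> int:
        return self.values.size

    @property
    def month(self) -> np.ndarray:
        """1-based month index t = 1..length."""
        return np.arange(1, self.values.size + 1)

    @property
    def last(self) -> float:
        if self.values.size == 0:
            raise ValueError("empty series has no last element")
        return float(self.values[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.month, "value": self.values})


def make_trend_spec(
    direction: TrendDirection | str,
    consistency: TrendConsistency | str,
    noise_variance: float = DEFAULT_NOISE_VARIANCE,
    t_origin: int = 1,
) -> TrendSpec:
    """Build the spec for one of the six experimental series types."""
    direction = TrendDirection(direction)
    consistency = TrendConsistency(consistency)
    intercept, slope = _TREND_PARAMS[direction]
    length = (
        _INCONSISTENT_LENGTH
        if consistency is TrendConsistency.INCONSISTENT
        else _CONSISTENT_LENGTH
    )
    return TrendSpec(
        direction=direction,
        consistency=consistency,
        intercept=intercept,
        slope=slope,
        noise_variance=noise_variance,
        length=length,
        t_origin=t_origin,
    )


def deterministic_value(spec: TrendSpec, t: int) -> float:
    """Noise-free series value at month ``t`` (1-based).

    ``t = length + 1`` is allowed so the true next trend value can be read
    off directly.  The appended 49th point of an inconsistent series is the
    grand mean 3,500 exactly; beyond it, the trend equation resumes.
    """
    if not 1 <= t <= spec.length + 1:
        raise ValueError(f"month index {t} outside 1..{spec.length + 1}")
    if (
        spec.consistency is TrendConsistency.INCONSISTENT
        and t == _INCONSISTENT_LENGTH
    ):
        return MEAN_SALARY
    return spec.intercept + spec.slope * (spec.t_origin + t - 1)


def generate_series(spec: TrendSpec, rng: np.random.Generator) -> SalarySeries:
    """Draw one noisy realization of ``spec``.

    Every trend point receives an independent N(0, noise_variance) term;
    the appended inconsistent point is exactly 3,500 and carries no noise.
    Identical ``rng`` state yields identical series.
    """
    base = np.array([deterministic_value(spec, t) for t in range(1, spec.length + 1)])
    noise = rng.normal(0.0, np.sqrt(spec.noise_variance), spec.length)
    if spec.consistency is TrendConsistency.INCONSISTENT:
        noise[-1] = 0.0
    return SalarySeries(values=base + noise, spec=spec)


def series_mean(series: SalarySeries) -> float:
    """Arithmetic mean of all presented values (pounds)."""
    if len(series) == 0:
        raise ValueError("cannot take the mean of an empty series")
    return float(series.values.mean())
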