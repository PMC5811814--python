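"""The adaptive anchoring model (ADAM) of one-shot judgment and forecasting.

A simulated observer maps the experienced series onto an idealized stimulus
item S (what was experienced) and an idealized task item T (what is asked),
both on the unit interval, and responds

    BR = SW * EA * (1 + kp * x),    SW = exp(-(S - T)),

where EA is an experience-dependent anchor in pounds (the sequence mean for
static experience, the last presented value for dynamic experience), SW is
an exponential similarity weight on the *signed* stimulus-task distance, and
x is a standard normal draw modelling perceptual variability scaled by kp.

With kp = 0 the model is deterministic: it returns the last element for any
dynamic-mode forecast and the sequence mean 3,500 for any static judgment.
The two dynamic presentation modes (historic and momentary) are
indistinguishable to the model by construction: S, T and EA depend only on
the last element in both.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import exp, isclose

import numpy as np

from .series import SalarySeries, TrendSpec, generate_series

__all__ = [
    "PresentationMode",
    "TaskKind",
    "AdamParams",
    "IdealizedItems",
    "normalize",
    "stimulus_item",
    "task_item",
    "similarity_weight",
    "experience_anchor",
    "idealized_items",
    "expected_response",
    "behavioral_response",
    "simulate_condition",
]


class PresentationMode(str, Enum):
    """How the series was experienced."""

    STATIC = "static"
    HISTORIC_DYNAMIC = "historic_dynamic"
    MOMENTARY_DYNAMIC = "momentary_dynamic"


class TaskKind(str, Enum):
    """Which one-shot judgment is requested."""

    JUDGMENT = "judgment"
    FORECAST = "forecast"


_DYNAMIC = (PresentationMode.HISTORIC_DYNAMIC, PresentationMode.MOMENTARY_DYNAMIC)


@dataclass(frozen=True)
class AdamParams:
    """Model constants.

    kp is the dimensionless perceptual-noise coefficient (0.04 by default,
    imported from prior perceptual-scaling work).  The normalization
    constant (10,000 pounds) is the unique linear map sending the sequence
    mean 3,500 to the stated normalized value 0.35; static_stimulus and
    static_anchor are that mean on the unit-interval and pound scales.
    """

    kp: float = 0.04
    normalization_constant: float = 10_000.0
    static_stimulus: float = 0.35
    static_anchor: float = 3_500.0

    def __post_init__(self) -> None:
        if self.kp < 0:
            raise ValueError(f"kp must be >= 0, got {self.kp}")
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant must be positive")
        if not isclose(
            self.static_stimulus,
            self.static_anchor / self.normalization_constant,
            rel_tol=1e-9,
        ):
            raise ValueError(
                "static_stimulus must equal static_anchor / normalization_constant "
                f"({self.static_stimulus} != "
                f"{self.static_anchor / self.normalization_constant})"
            )


@dataclass(frozen=True)
class IdealizedItems:
    """The internal decision-space coordinates of one (mode, task, series)."""

    S: float
    T: float
    EA: float


def normalize(value: float, params: AdamParams = AdamParams()) -> float:
    """Map a pound value into the unit interval (3,500 -> 0.35)."""
    if not 0.0 <= value <= params.normalization_constant:
        raise ValueError(
            f"value {value} outside [0, {params.normalization_constant}] "
            "cannot be normalized into [0, 1]"
        )
    return value / params.normalization_constant


def stimulus_item(
    mode: PresentationMode,
    series: SalarySeries,
    params: AdamParams = AdamParams(),
) -> float:
    """Idealized stimulus item S: 0.35 for static experience, else the
    normalized last element."""
    mode = PresentationMode(mode)
    if mode is PresentationMode.STATIC:
        return params.static_stimulus
    return normalize(series.last, params)


def task_item(
    task: TaskKind,
    series: SalarySeries,
    params: AdamParams = AdamParams(),
) -> float:
    """Idealized task item T: 0.35 for average judgment, else the
    normalized last element (forecasting)."""
    task = TaskKind(task)
    if task is TaskKind.JUDGMENT:
        return params.static_stimulus
    return normalize(series.last, params)


def similarity_weight(S: float, T: float) -> float:
    """Exponential similarity on the signed distance: exp(-(S - T)).

    The sign is deliberate — it carries the trend direction; reciprocity
    similarity_weight(S, T) * similarity_weight(T, S) == 1 follows.
    """
    return exp(-(S - T))


def experience_anchor(
    mode: PresentationMode,
    series: SalarySeries,
    params: AdamParams = AdamParams(),
) -> float:
    """Experience-dependent anchor EA in pounds: the sequence mean 3,500 for
    static experience, the last presented value for either dynamic mode."""
    mode = PresentationMode(mode)
    if mode is PresentationMode.STATIC:
        return params.static_anchor
    return series.last


def idealized_items(
    mode: PresentationMode,
    task: TaskKind,
    series: SalarySeries,
    params: AdamParams = AdamParams(),
) -> IdealizedItems:
    return IdealizedItems(
        S=stimulus_item(mode, series, params),
        T=task_item(task, series, params),
        EA=experience_anchor(mode, series, params),
    )


def expected_response(
    mode: PresentationMode,
    task: TaskKind,
    series: SalarySeries,
    params: AdamParams = AdamParams(),
) -> float:
    """Deterministic part of the response, SW * EA (the mean of BR)."""
    items = idealized_items(mode, task, series, params)
    return similarity_weight(items.S, items.T) * items.EA


def behavioral_response(
    mode: PresentationMode,
    task: TaskKind,
    series: SalarySeries,
    params: AdamParams,
    rng: np.random.Generator,
) -> float:
    """One stochastic response BR = SW * EA * (1 + kp * x), x ~ N(0, 1).

    One draw of x per call: one simulated participant, one response.
    With kp = 0 the return is exactly the deterministic SW * EA.
    """
    mean = expected_response(mode, task, series, params)
    if params.kp == 0:
        return mean
    return mean * (1.0 + params.kp * rng.standard_normal())


def simulate_condition(
    mode: PresentationMode,
    task: TaskKind,
    spec: TrendSpec,
    params: AdamParams,
    n: int,
    rng: np.random.Generator,
    fixed_series: bool = False,
) -> np.ndarray:
    """Simulate ``n`` independent observers in one design cell.

    By default each replicate sees a freshly generated noisy series (fresh
    n_t) and draws a fresh perceptual noise term, so within-cell variability
    mixes both sources.  ``fixed_series=True`` freezes a single series for
    the whole cell, leaving perceptual noise as the only source.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    frozen = generate_series(spec, rng) if fixed_series else None
    out = np.empty(n)
    for i in range(n):
        series = frozen if frozen is not None else generate_series(spec, rng)
        out[i] = behavioral_response(mode, task, series, params, rng)
    return out
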