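"""The anchoring model: items, similarity weight, response distribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adamsim import (
    AdamParams,
    PresentationMode,
    TaskKind,
    behavioral_response,
    expected_response,
    experience_anchor,
    normalize,
    similarity_weight,
    simulate_condition,
    stimulus_item,
    task_item,
    make_trend_spec,
)

DYNAMIC = (PresentationMode.HISTORIC_DYNAMIC, PresentationMode.MOMENTARY_DYNAMIC)

# independently evaluated: exp(-(0.35 - 0.402144)) and its reciprocal
SW_STATIC_FORECAST_POS = 1.0535274395422107
SW_DYNAMIC_JUDGMENT_POS = 1.0 / SW_STATIC_FORECAST_POS


def test_params_invariant_enforced():
    with pytest.raises(ValueError):
        AdamParams(static_stimulus=0.5)  # 0.5 != 3500/10000
    with pytest.raises(ValueError):
        AdamParams(kp=-0.1)
    p = AdamParams(normalization_constant=7000.0, static_stimulus=0.5)
    assert p.static_anchor / p.normalization_constant == 0.5


@pytest.mark.parametrize(
    "value, expected",
    [(3500.0, 0.35), (0.0, 0.0), (4021.44, 0.402144), (10_000.0, 1.0)],
)
def test_normalize(value, expected):
    assert normalize(value) == pytest.approx(expected, abs=1e-12)


def test_normalize_range_error():
    for bad in (-1.0, 10_000.1):
        with pytest.raises(ValueError):
            normalize(bad)


def test_stimulus_and_task_items(zero_noise, params_kp0):
    _, pos = zero_noise("positive", "consistent")
    _, neg = zero_noise("negative", "consistent")
    _, stat = zero_noise("stationary", "consistent")
    _, pos_inc = zero_noise("positive", "inconsistent")

    assert stimulus_item(PresentationMode.STATIC, pos, params_kp0) == 0.35
    assert stimulus_item(
        PresentationMode.HISTORIC_DYNAMIC, pos, params_kp0
    ) == pytest.approx(0.402144)
    # last element of an inconsistent series is the appended mean
    assert stimulus_item(
        PresentationMode.MOMENTARY_DYNAMIC, pos_inc, params_kp0
    ) == pytest.approx(0.35)

    assert task_item(TaskKind.JUDGMENT, pos, params_kp0) == 0.35
    assert task_item(TaskKind.FORECAST, neg, params_kp0) == pytest.approx(0.297856)
    assert task_item(TaskKind.FORECAST, stat, params_kp0) == pytest.approx(0.35)


def test_similarity_weight_frozen_values():
    assert similarity_weight(0.4, 0.4) == 1.0
    assert similarity_weight(0.35, 0.402144) == pytest.approx(
        SW_STATIC_FORECAST_POS, abs=1e-12
    )
    # the signed distance carries direction: S above T shrinks the weight
    assert similarity_weight(0.402144, 0.35) < 1 < similarity_weight(0.35, 0.402144)


@settings(derandomize=True, max_examples=50)
@given(
    S=st.floats(0, 1, allow_nan=False),
    T=st.floats(0, 1, allow_nan=False),
)
def test_similarity_weight_reciprocity(S, T):
    assert similarity_weight(S, T) * similarity_weight(T, S) == pytest.approx(1.0)


def test_experience_anchor(zero_noise, params_kp0):
    _, pos = zero_noise("positive", "consistent")
    _, neg_inc = zero_noise("negative", "inconsistent")
    assert experience_anchor(PresentationMode.STATIC, pos, params_kp0) == 3500.0
    assert experience_anchor(
        PresentationMode.HISTORIC_DYNAMIC, pos, params_kp0
    ) == pytest.approx(4021.44)
    for mode in DYNAMIC:
        assert experience_anchor(mode, neg_inc, params_kp0) == 3500.0


def test_deterministic_responses_at_kp0(zero_noise, params_kp0, rng):
    """kp = 0: dynamic forecasts return the last element, static judgments
    the sequence mean, and the static forecast the frozen worked value."""
    _, pos = zero_noise("positive", "consistent")
    for mode in DYNAMIC:
        assert behavioral_response(
            mode, TaskKind.FORECAST, pos, params_kp0, rng
        ) == pytest.approx(4021.44)
    for series in (pos, zero_noise("stationary", "inconsistent")[1]):
        assert behavioral_response(
            PresentationMode.STATIC, TaskKind.JUDGMENT, series, params_kp0, rng
        ) == 3500.0
    assert behavioral_response(
        PresentationMode.STATIC, TaskKind.FORECAST, pos, params_kp0, rng
    ) == pytest.approx(SW_STATIC_FORECAST_POS * 3500.0)  # = 3687.346


def test_dynamic_modes_indistinguishable(params_default):
    """Historic- and momentary-dynamic yield identical response streams for
    identical noise: the model cannot separate them by construction."""
    spec = make_trend_spec("positive", "consistent")
    for task in TaskKind:
        a = simulate_condition(
            PresentationMode.HISTORIC_DYNAMIC, task, spec, params_default,
            50, np.random.default_rng(3),
        )
        b = simulate_condition(
            PresentationMode.MOMENTARY_DYNAMIC, task, spec, params_default,
            50, np.random.default_rng(3),
        )
        np.testing.assert_array_equal(a, b)


def test_trend_damping_reproduction(zero_noise, params_kp0, rng):
    """Static forecasts under-predict upward and over-predict downward
    trends, and by more than dynamic forecasts err."""
    for direction, sign in (("positive", -1), ("negative", +1)):
        spec, series = zero_noise(direction, "consistent")
        true_next = spec.intercept + spec.slope * (spec.length + 1)
        static = behavioral_response(
            PresentationMode.STATIC, TaskKind.FORECAST, series, params_kp0, rng
        )
        dynamic = behavioral_response(
            PresentationMode.HISTORIC_DYNAMIC, TaskKind.FORECAST, series, params_kp0, rng
        )
        assert sign * (static - true_next) > 0  # damping direction
        assert abs(dynamic - true_next) < abs(static - true_next)


def test_anchoring_reproduction(zero_noise, params_kp0, rng):
    """Dynamic judgments are dragged toward the last value; static judgments
    sit exactly on the mean."""
    _, pos = zero_noise("positive", "consistent")
    _, neg = zero_noise("negative", "consistent")
    assert behavioral_response(
        PresentationMode.MOMENTARY_DYNAMIC, TaskKind.JUDGMENT, pos, params_kp0, rng
    ) > 3500.0
    assert behavioral_response(
        PresentationMode.MOMENTARY_DYNAMIC, TaskKind.JUDGMENT, neg, params_kp0, rng
    ) < 3500.0
    assert behavioral_response(
        PresentationMode.STATIC, TaskKind.JUDGMENT, pos, params_kp0, rng
    ) == 3500.0


def test_inconsistent_trends_null_mode_effect(zero_noise, params_kp0, rng):
    """Every mode x task returns 3,500 on inconsistent series at kp = 0:
    the model predicts no presentation-mode effect there."""
    for direction in ("positive", "negative", "stationary"):
        _, series = zero_noise(direction, "inconsistent")
        for mode in PresentationMode:
            for task in TaskKind:
                assert behavioral_response(
                    mode, task, series, params_kp0, rng
                ) == pytest.approx(3500.0)


def test_response_moments_match_contract(params_default):
    """E[BR] = SW*EA and SD[BR] = SW*EA*kp on a frozen series."""
    from adamsim import generate_series

    spec = make_trend_spec("positive", "consistent")
    seed = 11
    # regenerate the frozen series exactly as simulate_condition will
    frozen = generate_series(spec, np.random.default_rng(seed))
    mean = expected_response(
        PresentationMode.STATIC, TaskKind.FORECAST, frozen, params_default
    )
    draws = simulate_condition(
        PresentationMode.STATIC, TaskKind.FORECAST, spec, params_default,
        10_000, np.random.default_rng(seed), fixed_series=True,
    )
    assert draws.mean() == pytest.approx(mean, rel=0.01)
    assert draws.std(ddof=1) == pytest.approx(mean * params_default.kp, rel=0.03)


def test_simulate_condition_contracts(params_kp0):
    spec = make_trend_spec("positive", "consistent", noise_variance=0.0)
    out = simulate_condition(
        PresentationMode.HISTORIC_DYNAMIC, TaskKind.FORECAST, spec, params_kp0,
        90, np.random.default_rng(5),
    )
    assert out.shape == (90,)
    assert np.unique(out).size == 1  # fully deterministic cell
    with pytest.raises(ValueError):
        simulate_condition(
            PresentationMode.STATIC, TaskKind.JUDGMENT, spec, params_kp0,
            0, np.random.default_rng(5),
        )
    a = simulate_condition(
        PresentationMode.STATIC, TaskKind.FORECAST,
        make_trend_spec("negative", "consistent"), AdamParams(),
        30, np.random.default_rng(6),
    )
    b = simulate_condition(
        PresentationMode.STATIC, TaskKind.FORECAST,
        make_trend_spec("negative", "consistent"), AdamParams(),
        30, np.random.default_rng(6),
    )
    np.testing.assert_array_equal(a, b)
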