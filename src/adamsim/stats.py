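"""Statistical machinery for comparing response distributions.

Unrelated (independent-samples, pooled-variance) t tests with the
correlation effect size r = sqrt(t^2 / (t^2 + df)), Levene's test for
equality of variances, SD-ratio diagnostics, balanced factorial ANOVA
reporting epsilon-squared effect sizes, and the split-half cross-validation
procedure (random 45 + 45 halves, 2 x 2 series-by-subsample ANOVA).

Student's pooled-variance t (not Welch) is used throughout: equality of
variances is the assumption Levene's test is run to license.  p values are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AnovaRow",
    "unrelated_t",
    "effect_size_r",
    "levene",
    "sd_ratio",
    "factorial_anova",
    "split_half_check",
]


@dataclass(frozen=True)
class TestResult:
    """t (or, for Levene's test, F) statistic with df, two-sided p and r."""

    t: float
    df: int
    p: float
    r: float


@dataclass(frozen=True)
class AnovaRow:
    source: str
    df: int
    F: float
    p: float
    epsilon_sq: float
    ss: float = float("nan")


def effect_size_r(t: float, df: int) -> float:
    """Correlation effect size r = sqrt(t^2/(t^2+df)); symmetric in the sign
    of t and strictly increasing in |t|."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(np.sqrt(t * t / (t * t + df)))


def _check_samples(a, b, min_n: int = 2) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size < min_n or b.size < min_n:
        raise ValueError(f"each sample needs at least {min_n} values")
    return a, b


def unrelated_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Student's two-sample t with pooled variance, df = n_a + n_b - 2."""
    a, b = _check_samples(a, b)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    t = float(t) if np.isfinite(t) else 0.0
    p = float(p) if np.isfinite(p) else 1.0
    return TestResult(t=t, df=df, p=p, r=effect_size_r(t, df))


def levene(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Levene's test (center = mean) for equality of variances.

    The statistic slot carries the Levene F on df = n_a + n_b - 2; r is the
    analogous sqrt(F/(F+df)) effect size.
    """
    a, b = _check_samples(a, b)
    F, p = sps.levene(a, b, center="mean")
    df = a.size + b.size - 2
    if not np.isfinite(F):  # identical spreads -> zero numerator and denominator
        F, p = 0.0, 1.0
    return TestResult(t=float(F), df=df, p=float(p), r=float(np.sqrt(F / (F + df))))


def sd_ratio(a: Sequence[float], b: Sequence[float]) -> float:
    """SD(a) / SD(b) (sample SDs, ddof = 1)."""
    a, b = _check_samples(a, b)
    sd_b = b.std(ddof=1)
    if sd_b == 0:
        raise ZeroDivisionError("SD of the denominator sample is zero")
    return float(a.std(ddof=1) / sd_b)


def _check_balanced(table: pd.DataFrame, factors: Sequence[str]) -> None:
    sizes = table.groupby(list(factors), observed=True).size()
    expected_cells = int(np.prod([table[f].nunique() for f in factors]))
    if len(sizes) != expected_cells or sizes.nunique() != 1:
        raise ValueError("factorial_anova requires a fully crossed balanced design")


def factorial_anova(
    table: pd.DataFrame,
    factors: Sequence[str],
    response: str,
) -> list[AnovaRow]:
    """Between-subjects factorial ANOVA on a balanced long-format table.

    All main effects and interactions up to the full order are fit; each
    effect is reported with epsilon-squared,
    eps^2 = (SS_effect - df_effect * MS_error) / SS_total, clipped below at
    0.  A response that is constant within machine precision reports F = 0,
    p = 1, eps^2 = 0 for every effect by convention.  The final row carries
    the residual (error) sum of squares, so SS_total = sum of all row SS.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if table.empty:
        raise ValueError("cannot run an ANOVA on an empty table")
    factors = list(factors)
    _check_balanced(table, factors)

    data = table[factors + [response]].copy()
    rename = {f: f"f{i}" for i, f in enumerate(factors)}
    data = data.rename(columns=rename | {response: "y"})
    formula = "y ~ " + " * ".join(f"C({rename[f]})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    anova = sm.stats.anova_lm(fit, typ=2)

    ss_total = float(anova["sum_sq"].sum())
    ms_error = float(anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"])
    degenerate = ss_total <= 1e-12 * max(1.0, float(np.abs(data["y"]).max()) ** 2)

    label_of = {rename[f]: f for f in factors}

    def pretty(term: str) -> str:
        parts = [p[2:-1] for p in term.split(":")]  # strip C( )
        return ":".join(label_of[p] for p in parts)

    rows = []
    for term in anova.index:
        df_eff = int(anova.loc[term, "df"])
        ss_eff = float(anova.loc[term, "sum_sq"])
        if term == "Residual":
            rows.append(
                AnovaRow(
                    source="Residual", df=df_eff, F=float("nan"), p=float("nan"),
                    epsilon_sq=0.0, ss=ss_eff,
                )
            )
            continue
        if degenerate:
            F, p, eps = 0.0, 1.0, 0.0
        else:
            F = float(anova.loc[term, "F"])
            p = float(anova.loc[term, "PR(>F)"])
            if not np.isfinite(F):
                F, p = 0.0, 1.0
            eps = max(0.0, (ss_eff - df_eff * ms_error) / ss_total)
        rows.append(
            AnovaRow(source=pretty(term), df=df_eff, F=F, p=p, epsilon_sq=eps, ss=ss_eff)
        )
    return rows


def split_half_check(
    responses: Sequence[float],
    predictions: Sequence[float],
    rng: np.random.Generator,
) -> tuple[AnovaRow, AnovaRow]:
    """Split-half cross-validation of model fit within one design cell.

    Randomly halves the response and prediction samples (e.g. 90 -> 45 + 45
    each) and runs the 2 x 2 ANOVA with factors series (data vs model) and
    subsample.  Returns the series main-effect row and the interaction row;
    a good, stable fit shows both non-significant.
    """
    responses = np.asarray(responses, dtype=float).reshape(-1)
    predictions = np.asarray(predictions, dtype=float).reshape(-1)
    if responses.size != predictions.size:
        raise ValueError("responses and predictions must be the same size")
    if responses.size < 4 or responses.size % 2:
        raise ValueError("need an even sample size of at least 4 to split")

    half = responses.size // 2
    frames = []
    for label, values in (("data", responses), ("model", predictions)):
        order = rng.permutation(values.size)
        frames.append(
            pd.DataFrame(
                {
                    "series": label,
                    "subsample": np.where(np.arange(values.size) < half, "A", "B"),
                    "y": values[order],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    rows = factorial_anova(table, ["series", "subsample"], "y")
    by_source = {row.source: row for row in rows}
    return by_source["series"], by_source["series:subsample"]
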