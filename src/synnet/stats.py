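"""Cross-level and cross-modality statistics on a metrics table.

The battery runs, for each panel metric, a per-modality proficiency-trend
OLS regression (level codes 1..4 for learners and 5 for the native
reference) and a cross-modality two-sample t-test restricted to the four
learner levels. The t-test variant per metric is configurable; the default
plan uses Welch for <k> and NC and pooled variance for L, C and ND.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from synnet.errors import ValidationError

TTestVariant = Literal["pooled", "welch"]

#: metric -> t-test variant used by the default battery plan
DEFAULT_TTEST_PLAN: dict[str, TTestVariant] = {
    "k_mean": "welch",
    "gamma_prime": "welch",
    "C": "pooled",
    "L": "pooled",
    "ND": "pooled",
    "NC": "welch",
}

BATTERY_METRICS = ("k_mean", "gamma_prime", "C", "L", "ND", "NC")

#: native reference level code used in trend regressions
NATIVE_LEVEL_CODE = 5


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    R2: float
    p_slope: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    variant: TTestVariant
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float

    @property
    def diff(self) -> float:
        return self.mean_a - self.mean_b


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def ols_simple(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple OLS y = a + b x with a two-sided slope test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 points for regression")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        R2=float(res.rvalue**2),
        p_slope=float(res.pvalue),
        n=int(x.size),
    )


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    variant: TTestVariant = "welch",
) -> TTestResult:
    """Two-sample two-sided t-test, pooled-variance or Welch."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValidationError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            raise ValidationError("zero variance and equal means: t undefined")
        t = math.inf if diff > 0 else -math.inf
        df = float(na + nb - 2)
        return TTestResult(variant, t, df, 0.0, float(a.mean()), float(b.mean()))
    if variant == "pooled":
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
    elif variant == "welch":
        sa, sb = va / na, vb / nb
        se = math.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    else:  # pragma: no cover
        raise ValueError(f"unknown variant {variant!r}")
    t = diff / se
    p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(variant, float(t), float(df), p, float(a.mean()), float(b.mean()))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a two-sided df = n-2 t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


# ---------------------------------------------------------------------------
# battery


def _level_code(level) -> int:
    if level in (1, 2, 3, 4):
        return int(level)
    if str(level) in {"1", "2", "3", "4"}:
        return int(level)
    if str(level).lower() in {"native", "n", "5"}:
        return NATIVE_LEVEL_CODE
    raise ValidationError(f"unrecognized level {level!r}")


def run_battery(
    table: pd.DataFrame,
    *,
    metrics: Sequence[str] = BATTERY_METRICS,
    ttest_plan: dict[str, TTestVariant] | None = None,
    include_native_in_regression: bool = True,
) -> dict:
    """Run trend regressions and cross-modality t-tests on a metrics table.

    ``table`` needs columns ``label``, ``modality``, ``level`` plus the
    requested metric columns; both modalities with levels 1-4 and a native
    row each must be present. Returns a JSON-ready nested report.
    """
    plan = dict(DEFAULT_TTEST_PLAN)
    if ttest_plan:
        plan.update(ttest_plan)
    required = {"label", "modality", "level"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValidationError(f"metrics table lacks columns {sorted(missing_cols)}")
    df = table.copy()
    df["level_code"] = df["level"].map(_level_code)

    wanted_codes = {1, 2, 3, 4} | (
        {NATIVE_LEVEL_CODE} if include_native_in_regression else set()
    )
    absent = [
        f"{mod}:{code}"
        for mod in ("written", "oral")
        for code in sorted(wanted_codes)
        if ((df["modality"] == mod) & (df["level_code"] == code)).sum() == 0
    ]
    if absent:
        raise ValidationError(f"metrics table missing rows: {absent}")

    report: dict = {"regressions": {}, "t_tests": {}, "plan": plan}
    for metric in metrics:
        if metric not in df.columns:
            raise ValidationError(f"metrics table lacks column {metric!r}")
        report["regressions"][metric] = {}
        for mod in ("written", "oral"):
            sub = df[
                (df["modality"] == mod) & (df["level_code"].isin(wanted_codes))
            ].sort_values("level_code")
            reg = ols_simple(sub["level_code"], sub[metric])
            report["regressions"][metric][mod] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "R2": reg.R2,
                "p": reg.p_slope,
                "n": reg.n,
            }
        learners = df[df["level_code"] <= 4]
        a = learners[learners["modality"] == "written"].sort_values("level_code")[metric]
        b = learners[learners["modality"] == "oral"].sort_values("level_code")[metric]
        variant = plan.get(metric, "welch")
        tt = t_test(a, b, variant)
        report["t_tests"][metric] = {
            "variant": tt.variant,
            "t": tt.t,
            "abs_t": abs(tt.t),
            "df": tt.df,
            "p": tt.p,
            "mean_written": tt.mean_a,
            "mean_oral": tt.mean_b,
            "diff": tt.diff,
        }
    return report
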