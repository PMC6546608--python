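"""Small-study / publication-bias diagnostics.

Egger's regression test: ordinary least squares of the standardized effect
z_i = d_i / se_i on precision x_i = 1/se_i. Under a symmetric funnel the
intercept is zero; it is tested with a two-tailed t on n - 2 df. The classic
unweighted OLS variant is used.

Begg's rank test: Kendall's tau (tau-b under ties) between the
variance-stabilized deviates u_i = (d_i - d_fixed) / sqrt(v_i - 1/sum(w)) and
the sampling variances v_i, with the normal-approximation p-value.

Funnel-plot data are emitted untransformed as (d, se) pairs.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats

from .data_model import EffectSize


class EggerResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    intercept: float
    intercept_se: float
    t: float
    df: int
    p: float
    slope: float


def egger_test(effects: Sequence[EffectSize]) -> EggerResult:
    """Egger's funnel-asymmetry regression on a set of effect sizes."""
    n = len(effects)
    if n < 3:
        raise ValueError(f"Egger's test requires at least 3 effects, got {n}")
    se = np.array([e.se for e in effects], dtype=float)
    d = np.array([e.d for e in effects], dtype=float)
    x = 1.0 / se  # precision
    y = d / se  # standardized effect
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError(
            "all standard errors are equal: precision is collinear with the intercept"
        )
    fit = stats.linregress(x, y)
    intercept = float(fit.intercept)
    se_int = float(fit.intercept_stderr)
    if not math.isfinite(se_int):
        # zero-variance y (all standardized effects equal): exact fit
        se_int = 0.0
    if se_int == 0.0:
        t = 0.0 if intercept == 0.0 else math.copysign(math.inf, intercept)
    else:
        t = intercept / se_int
    df = n - 2
    p = float(2.0 * stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return EggerResult(
        intercept=intercept, intercept_se=se_int, t=t, df=df, p=p, slope=float(fit.slope),
    )


def begg_statistic(effects: Sequence[EffectSize]) -> tuple[float, float]:
    """Begg-Mazumdar rank correlation between standardized deviates and variance."""
    n = len(effects)
    if n < 3:
        raise ValueError(f"Begg's test requires at least 3 effects, got {n}")
    d = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    w = 1.0 / v
    d_fixed = float(np.sum(w * d) / np.sum(w))
    v_star = v - 1.0 / np.sum(w)
    # v_i > 1/sum(w) always when n >= 2, but guard against rounding
    u = (d - d_fixed) / np.sqrt(np.maximum(v_star, np.finfo(float).tiny))
    res = stats.kendalltau(u, v, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def funnel_points(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Funnel-plot coordinates (d, se), one row per effect, in input order."""
    if not effects:
        raise ValueError("no effects")
    return pd.DataFrame({
        "study_id": [e.study_id for e in effects],
        "comparison_id": [e.comparison_id for e in effects],
        "category": [e.category for e in effects],
        "d": [e.d for e in effects],
        "se": [e.se for e in effects],
    })


class BiasReportRow(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    n: int
    egger_intercept: Optional[float] = None
    egger_t: Optional[float] = None
    egger_df: Optional[int] = None
    egger_p: Optional[float] = None
    begg_tau: Optional[float] = None
    begg_p: Optional[float] = None


def bias_report_row(label: str, effects: Sequence[EffectSize]) -> BiasReportRow:
    """Egger + Begg summary for one analysis; diagnostics are null when fewer
    than 3 effects (or a degenerate design) make the tests undefined."""
    kwargs: dict = {"label": label, "n": len(effects)}
    if len(effects) >= 3:
        try:
            egg = egger_test(effects)
            kwargs.update(egger_intercept=egg.intercept, egger_t=egg.t,
                          egger_df=egg.df, egger_p=egg.p)
        except np.linalg.LinAlgError:
            pass
        tau, p = begg_statistic(effects)
        kwargs.update(begg_tau=tau, begg_p=p)
    return BiasReportRow(**kwargs)
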