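"""Random-effects pooling with heterogeneity statistics.

Heterogeneity is quantified with Cochran's Q (fixed-effect weights w_i = 1/v_i)
and I^2 = 100 * max(0, (Q - df) / Q); the between-study variance tau^2 is
estimated by the DerSimonian-Laird method-of-moments,
tau^2 = max(0, (Q - df) / C) with C = sum(w) - sum(w^2)/sum(w). Pooling then
uses random-effects weights w*_i = 1/(v_i + tau^2) with normal (z) inference
and 95% confidence intervals.

The pooling unit is the study-comparison composite: one effect size per
(study, comparison, outcome category). Multi-arm studies contribute one unit
per comparison; the shared-arm dependency is documented, not modelled.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats

from .data_model import (
    ACTIVE_SUBTYPES,
    CATEGORIES,
    CONTROL_SUBTYPES,
    PASSIVE_SUBTYPES,
    Dataset,
    EffectSize,
)
from .effect_sizes import ESConfig, compute_comparison_composites

Z_95 = 1.959964  # two-sided 95% normal quantile

ALL_MEASURES_LABEL = "all_measures"

#: Named comparison filters over the control arm's subtype.
CONTROL_FILTERS: dict[str, Callable[[str], bool]] = {
    "all": lambda subtype: True,
    "active_only": lambda subtype: subtype in ACTIVE_SUBTYPES,
    "passive_only": lambda subtype: subtype in PASSIVE_SUBTYPES,
}


class PooledResult(BaseModel):
    """One row of a pooled-effects table (a category, subgroup, or overall)."""

    model_config = ConfigDict(frozen=True)

    label: str
    k_studies: int
    n_effects: int
    n_comparisons: int
    total_n: int
    d_pooled: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    Q: Optional[float] = None
    df: Optional[int] = None
    p_Q: Optional[float] = None
    i2: Optional[float] = None
    tau2: float = 0.0


def _arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    d = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    return d, v


def cochran_q(effects: Sequence[EffectSize]) -> tuple[float, int, float]:
    """Cochran's heterogeneity statistic, its df, and the chi-square upper-tail p."""
    if len(effects) < 2:
        raise ValueError("Q requires at least 2 effects")
    d, v = _arrays(effects)
    w = 1.0 / v
    d_bar = float(np.sum(w * d) / np.sum(w))
    q = float(np.sum(w * (d - d_bar) ** 2))
    df = len(effects) - 1
    return q, df, float(stats.chi2.sf(q, df))


def i_squared(Q: float, df: int) -> float:
    """I^2 heterogeneity percentage, truncated at zero."""
    if Q < 0 or df < 1:
        raise ValueError("require Q >= 0 and df >= 1")
    if Q == 0:
        return 0.0
    return 100.0 * max(0.0, (Q - df) / Q)


def dl_tau2(effects: Sequence[EffectSize]) -> float:
    """DerSimonian-Laird between-study variance estimate (truncated at 0)."""
    q, df, _ = cochran_q(effects)
    _, v = _arrays(effects)
    w = 1.0 / v
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if c == 0:
        raise ValueError("degenerate weights: C = 0")
    return max(0.0, (q - df) / c)


def pool_random_effects(
    effects: Sequence[EffectSize],
    tau2: float | None = None,
    label: str = "",
    k_studies: int | None = None,
    total_n: int | None = None,
) -> PooledResult:
    """Inverse-variance pooled estimate under a random-effects model.

    ``tau2=None`` estimates DerSimonian-Laird tau^2 when two or more effects
    are available (0 for a single effect); ``tau2=0`` reduces exactly to
    fixed-effect pooling. For a single effect Q/df/p_Q/I^2 are reported as
    null rather than the row being dropped.
    """
    if not effects:
        raise ValueError("no effects to pool")
    if tau2 is None:
        tau2 = dl_tau2(effects) if len(effects) >= 2 else 0.0
    d, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    d_pooled = float(np.sum(w * d) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    z = d_pooled / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    if len(effects) >= 2:
        q, df, p_q = cochran_q(effects)
        i2: Optional[float] = i_squared(q, df)
    else:
        q = df = p_q = i2 = None  # type: ignore[assignment]
    return PooledResult(
        label=label,
        k_studies=k_studies if k_studies is not None else len({e.study_id for e in effects}),
        n_effects=sum(e.n_measures_averaged for e in effects),
        n_comparisons=len({(e.study_id, e.comparison_id) for e in effects}),
        total_n=total_n if total_n is not None else sum(e.n_total for e in effects),
        d_pooled=d_pooled, se=se,
        ci_low=d_pooled - Z_95 * se, ci_high=d_pooled + Z_95 * se,
        z=z, p=p, Q=q, df=df, p_Q=p_q, i2=i2, tau2=float(tau2),
    )


def _unique_arm_n(dataset: Dataset, effects: Sequence[EffectSize]) -> int:
    """Total participants over the distinct arms behind a set of effects
    (shared arms of multi-arm studies are counted once)."""
    seen: set[tuple[str, str]] = set()
    total = 0
    for e in effects:
        mbi, ctl = dataset.comparison_arms(e.study_id, e.comparison_id)
        for arm in (mbi, ctl):
            key = (e.study_id, arm.arm_id)
            if key not in seen:
                seen.add(key)
                total += arm.n
    return total


def _filter_composites(
    dataset: Dataset,
    cfg: ESConfig | None,
    control_filter: str | Callable[[str], bool] | None,
) -> list[EffectSize]:
    pred = CONTROL_FILTERS["all"] if control_filter is None else control_filter
    if isinstance(pred, str):
        if pred in CONTROL_FILTERS:
            pred = CONTROL_FILTERS[pred]
        elif pred in CONTROL_SUBTYPES:
            subtype = pred
            pred = lambda s: s == subtype  # noqa: E731
        else:
            raise ValueError(f"unknown control filter {control_filter!r}")
    composites = compute_comparison_composites(dataset, cfg)
    return [e for e in composites
            if pred(dataset.control_subtype(e.study_id, e.comparison_id))]


def _pool_row(dataset: Dataset, label: str, effects: Sequence[EffectSize]) -> PooledResult:
    return pool_random_effects(
        effects, label=label, total_n=_unique_arm_n(dataset, effects),
    )


def pool_by_category(
    dataset: Dataset,
    cfg: ESConfig | None = None,
    control_filter: str | Callable[[str], bool] | None = None,
) -> list[PooledResult]:
    """Pooled results per outcome category plus an all-measures row.

    The all-measures row pools every comparison-level category composite;
    category rows pool the composites of that category. ``control_filter``
    restricts comparisons by their control arm's subtype ("all",
    "active_only", "passive_only", a specific subtype, or a predicate).
    """
    composites = _filter_composites(dataset, cfg, control_filter)
    if not composites:
        return []
    rows = [_pool_row(dataset, ALL_MEASURES_LABEL, composites)]
    for cat in CATEGORIES:
        cat_effects = [e for e in composites if e.category == cat]
        if cat_effects:
            rows.append(_pool_row(dataset, cat, cat_effects))
    return rows


def subgroup_by_control(
    dataset: Dataset, cfg: ESConfig | None = None
) -> list[PooledResult]:
    """All-measures pooling disaggregated by control-arm subtype.

    A multi-arm study with, say, a wait-list and an active-intervention arm
    contributes its comparisons to both corresponding rows.
    """
    rows: list[PooledResult] = []
    for subtype in CONTROL_SUBTYPES:
        effects = _filter_composites(dataset, cfg, subtype)
        if effects:
            rows.append(_pool_row(dataset, subtype, effects))
    return rows


def pool_effect_table(table: pd.DataFrame, tau2: float | None = None) -> PooledResult:
    """Pool an externally transcribed table of comparison-level effect sizes.

    Expects columns ``study_id``, ``comparison_id``, ``category``, ``d`` and
    either ``variance`` or ``se``. Intended for reproducing a published
    overall estimate from a deposited per-study effect-size listing.
    """
    required = {"study_id", "comparison_id", "category", "d"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"effect table missing column(s): {sorted(missing)}")
    if "variance" in table.columns:
        variance = table["variance"].astype(float)
    elif "se" in table.columns:
        variance = table["se"].astype(float) ** 2
    else:
        raise ValueError("effect table needs a 'variance' or 'se' column")
    effects = [
        EffectSize(
            study_id=str(r.study_id), comparison_id=str(r.comparison_id),
            category=str(r.category), d=float(r.d), variance=float(var),
            n_total=int(getattr(r, "n_total", 2) or 2), n_measures_averaged=1,
        )
        for r, var in zip(table.itertuples(index=False), variance)
    ]
    return pool_random_effects(effects, tau2=tau2, label=ALL_MEASURES_LABEL)


def results_to_frame(rows: Iterable[PooledResult]) -> pd.DataFrame:
    """Tabular (one row per PooledResult) view for reporting."""
    return pd.DataFrame([r.model_dump() for r in rows])
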