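"""Single-moderator random-effects meta-regression.

Model: d_i = beta0 + beta1 * x_i + u_i + e_i, with u_i ~ N(0, tau^2) between
studies and e_i ~ N(0, v_i) sampling error. The residual tau^2 is estimated by
the method of moments (the DerSimonian-Laird analogue for regression):

    tau^2 = max(0, (Q_E - (k - p)) / tr(P)),
    P = W - W X (X' W X)^{-1} X' W,  W = diag(1/v_i),

where Q_E is the weighted residual sum of squares of the fixed-effect fit.
The slope is then re-fit by weighted least squares with weights
1/(v_i + tau^2); the omnibus moderator statistic is Q_model = (beta1/se)^2
on one chi-square df. An REML tau^2 is available behind ``method="reml"``.

Moderators are study-level (age, total training hours, risk-of-bias score);
all comparisons of a study share its moderator value, and comparisons with a
missing moderator are dropped (the drop count is reported).
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy import optimize, stats

from .data_model import CATEGORIES, Dataset, EffectSize, rob_score
from .effect_sizes import ESConfig
from .pooling import _filter_composites

MODERATORS = ("age_mean", "total_hours", "rob_score")


class MetaRegResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    category: str
    moderator_name: str
    slope: float
    slope_se: float
    intercept: float
    Q_model: float
    p: float
    tau2_residual: float
    n_used: int
    n_dropped_missing: int = 0


class SkipRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    category: str
    moderator_name: str
    reason: str


def _mom_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    w = 1.0 / v
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ beta
    qe = float(np.sum(w * resid**2))
    p_mat = W - W @ X @ np.linalg.solve(xtwx, X.T @ W)
    trace_p = float(np.trace(p_mat))
    k, p = X.shape
    return max(0.0, (qe - (k - p)) / trace_p)


def _reml_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    def neg2_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        xtwx = X.T @ (X * wi[:, None])
        beta = np.linalg.solve(xtwx, X.T @ (wi * y))
        resid = y - X @ beta
        return (
            float(np.sum(np.log(v + tau2)))
            + float(np.linalg.slogdet(xtwx)[1])
            + float(np.sum(wi * resid**2))
        )

    upper = max(10.0 * float(np.var(y)), 1.0)
    res = optimize.minimize_scalar(
        neg2_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def meta_regress(
    effects: Sequence[EffectSize],
    moderator: Sequence[float],
    method: str = "mom",
    category: str = "",
    moderator_name: str = "",
) -> MetaRegResult:
    """Random-effects meta-regression of effect sizes on one moderator."""
    if len(effects) != len(moderator):
        raise ValueError("effects and moderator must be the same length")
    pairs = [(e, x) for e, x in zip(effects, moderator) if x is not None and not (
        isinstance(x, float) and math.isnan(x))]
    n_dropped = len(effects) - len(pairs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 comparisons with a non-missing moderator, got {len(pairs)}")
    y = np.array([e.d for e, _ in pairs], dtype=float)
    v = np.array([e.variance for e, _ in pairs], dtype=float)
    x = np.array([float(m) for _, m in pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("no moderator variance")
    X = np.column_stack([np.ones_like(x), x])
    if method == "mom":
        tau2 = _mom_tau2(y, v, X)
    elif method == "reml":
        tau2 = _reml_tau2(y, v, X)
    else:
        raise ValueError(f"unknown method {method!r}")
    wi = 1.0 / (v + tau2)
    xtwx = X.T @ (X * wi[:, None])
    cov = np.linalg.inv(xtwx)
    beta = cov @ (X.T @ (wi * y))
    slope = float(beta[1])
    slope_se = float(math.sqrt(cov[1, 1]))
    z = slope / slope_se
    q_model = z * z
    return MetaRegResult(
        category=category, moderator_name=moderator_name,
        slope=slope, slope_se=slope_se, intercept=float(beta[0]),
        Q_model=q_model, p=float(stats.chi2.sf(q_model, 1)),
        tau2_residual=tau2, n_used=len(pairs), n_dropped_missing=n_dropped,
    )


def intercept_only_fit(
    effects: Sequence[EffectSize], method: str = "mom"
) -> tuple[float, float, float]:
    """(estimate, se, tau2) of the moderator-free model — the nesting check
    against plain random-effects pooling."""
    y = np.array([e.d for e in effects], dtype=float)
    v = np.array([e.variance for e in effects], dtype=float)
    X = np.ones((len(y), 1))
    tau2 = _mom_tau2(y, v, X) if method == "mom" else _reml_tau2(y, v, X)
    wi = 1.0 / (v + tau2)
    est = float(np.sum(wi * y) / np.sum(wi))
    se = float(math.sqrt(1.0 / np.sum(wi)))
    return est, se, tau2


def _moderator_value(dataset: Dataset, study_id: str, name: str) -> Optional[float]:
    study = dataset.study(study_id)
    if name == "rob_score":
        return float(rob_score(study.rob))
    value = getattr(study, name)
    return None if value is None else float(value)


def run_moderator_suite(
    dataset: Dataset,
    cfg: ESConfig | None = None,
    control_filter: str | Callable[[str], bool] | None = None,
    method: str = "mom",
) -> tuple[list[MetaRegResult], list[SkipRecord]]:
    """One meta-regression per (present category) x (age, dose, risk-of-bias).

    Each moderator is tested separately. Categories where a regression is not
    estimable (k < 3 after missing-moderator drops, or a constant moderator)
    produce a skip record rather than an error.
    """
    composites = _filter_composites(dataset, cfg, control_filter)
    results: list[MetaRegResult] = []
    skips: list[SkipRecord] = []
    for cat in CATEGORIES:
        cat_effects = [e for e in composites if e.category == cat]
        if not cat_effects:
            continue
        for mod in MODERATORS:
            x = [_moderator_value(dataset, e.study_id, mod) for e in cat_effects]
            try:
                results.append(meta_regress(
                    cat_effects, x, method=method, category=cat, moderator_name=mod,
                ))
            except ValueError as exc:
                skips.append(SkipRecord(category=cat, moderator_name=mod, reason=str(exc)))
    return results, skips
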