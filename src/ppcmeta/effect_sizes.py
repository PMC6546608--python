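"""Pre/post-controlled standardized mean differences.

The effect size is the between-group difference in mean pre-to-post change,
standardized by the pooled *pretest* SD (so the intervention itself cannot
influence the denominator):

    d = [(post1 - pre1) - (post2 - pre2)] / S_pre,
    S_pre = sqrt(((n1-1) s1_pre^2 + (n2-1) s2_pre^2) / (n1 + n2 - 2)).

A positive d always means the intervention group benefitted more than the
control group; measures on which lower scores are better are sign-flipped.
The sampling variance uses the change-score form

    v = 2 (1 - rho) (1/n1 + 1/n2) + d^2 / (2 (n1 + n2)),

where rho is the assumed pre-post correlation within an arm (default 0.5).
When a study assesses one category with several instruments, the composite is
the unweighted mean of the instrument-level d's; its variance follows from the
full covariance double sum under an assumed between-measure correlation
(default 1.0, the conservative choice).
"""

from __future__ import annotations

import math
from typing import Sequence

from pydantic import BaseModel, ConfigDict, Field

from .data_model import Dataset, EffectSize, MeasureRecord


class DegenerateSampleError(ValueError):
    """Combined arm size too small to standardize a change score."""


class ESConfig(BaseModel):
    """Analyst-chosen constants of the effect-size computation.

    rho_prepost: assumed correlation between pre and post scores within an arm.
    rho_measures: assumed correlation between different instruments measuring
        the same category in the same study (1.0 gives the most conservative,
        i.e. largest, composite variance).
    hedges_correction: apply the small-sample factor J = 1 - 3/(4 df - 1);
        off by default (plain Cohen's d).
    """

    model_config = ConfigDict(frozen=True)

    rho_prepost: float = Field(default=0.5, gt=-1.0, lt=1.0)
    rho_measures: float = Field(default=1.0, ge=0.0, le=1.0)
    hedges_correction: bool = False


def variance_ppc_d(d: float, n1: int, n2: int, rho_prepost: float) -> float:
    """Sampling variance of the pre/post-controlled d."""
    if not (-1.0 < rho_prepost < 1.0):
        raise ValueError(f"rho_prepost must be in (-1, 1), got {rho_prepost}")
    if n1 < 2 or n2 < 2:
        raise DegenerateSampleError(f"need at least 2 per arm, got n1={n1}, n2={n2}")
    return 2.0 * (1.0 - rho_prepost) * (1.0 / n1 + 1.0 / n2) + d * d / (2.0 * (n1 + n2))


def compute_ppc_d(m: MeasureRecord, cfg: ESConfig | None = None) -> EffectSize:
    """Oriented pre/post-controlled d (with variance) for one measure."""
    cfg = cfg or ESConfig()
    n1, n2 = m.mbi_n, m.ctl_n
    if n1 + n2 < 3:
        raise DegenerateSampleError(
            f"combined n = {n1 + n2} < 3 for measure {m.measure_name!r}"
        )
    s_pre = math.sqrt(
        ((n1 - 1) * m.mbi_pre_sd**2 + (n2 - 1) * m.ctl_pre_sd**2) / (n1 + n2 - 2)
    )
    d = ((m.mbi_post_mean - m.mbi_pre_mean) - (m.ctl_post_mean - m.ctl_pre_mean)) / s_pre
    if m.direction == "lower_better":
        d = -d
    if cfg.hedges_correction:
        d *= 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    v = variance_ppc_d(d, n1, n2, cfg.rho_prepost)
    return EffectSize(
        study_id=m.study_id, comparison_id=m.comparison_id, category=m.category,
        d=d, variance=v, n_total=n1 + n2, n_measures_averaged=1,
    )


def aggregate_category(effects: Sequence[EffectSize], cfg: ESConfig | None = None) -> EffectSize:
    """Average several same-category effects of one comparison into a composite.

    Composite d is the unweighted mean; composite variance is
    (1/m^2) sum_ij rho_ij sqrt(v_i v_j) with rho_ii = 1 and rho_ij =
    ``cfg.rho_measures`` off the diagonal.
    """
    cfg = cfg or ESConfig()
    if not effects:
        raise ValueError("no effects to aggregate")
    keys = {(e.study_id, e.comparison_id, e.category) for e in effects}
    if len(keys) != 1:
        raise ValueError(f"cannot aggregate across different units/categories: {sorted(keys)}")
    m = len(effects)
    if m == 1:
        return effects[0]
    d_bar = sum(e.d for e in effects) / m
    var = 0.0
    for i, ei in enumerate(effects):
        for j, ej in enumerate(effects):
            rho = 1.0 if i == j else cfg.rho_measures
            var += rho * math.sqrt(ei.variance * ej.variance)
    var /= m * m
    return EffectSize(
        study_id=effects[0].study_id,
        comparison_id=effects[0].comparison_id,
        category=effects[0].category,
        d=d_bar,
        variance=var,
        n_total=max(e.n_total for e in effects),
        n_measures_averaged=sum(e.n_measures_averaged for e in effects),
    )


def compute_measure_effects(dataset: Dataset, cfg: ESConfig | None = None) -> list[EffectSize]:
    """One effect size per measure row, in row order."""
    cfg = cfg or ESConfig()
    return [compute_ppc_d(m, cfg) for m in dataset.measures]


def compute_comparison_composites(
    dataset: Dataset, cfg: ESConfig | None = None
) -> list[EffectSize]:
    """One composite per (study, comparison, category), averaging multi-measure
    categories; groups are emitted in first-appearance order."""
    cfg = cfg or ESConfig()
    groups: dict[tuple[str, str, str], list[EffectSize]] = {}
    for m in dataset.measures:
        key = (m.study_id, m.comparison_id, m.category)
        groups.setdefault(key, []).append(compute_ppc_d(m, cfg))
    return [aggregate_category(effs, cfg) for effs in groups.values()]
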