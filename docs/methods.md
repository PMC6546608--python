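# Methods

## Data model

A trial is a study with ≥2 arms (exactly one mindfulness-intervention arm per
comparison, one or more control arms); a *comparison* is one (intervention
arm, control arm) pair. Multi-arm trials are represented as multiple
comparisons sharing an arm, and each comparison is treated as an independent
unit of analysis. This matches the common reporting convention in which a
three-arm trial appears once per control type in subgroup tables; the
shared-arm dependency is documented here rather than modelled (no
multivariate or robust-variance pooling — see Limitations).

Control subtypes are `no_contact`, `wait_list` (together: passive controls)
and `attention_placebo`, `active_intervention` (together: active controls).
Outcome measures carry a category label (one of seven: mindfulness,
executive function, attention, depression, anxiety/stress, negative
behaviour, social behaviour) and a polarity flag (`higher_better` /
`lower_better`). Category assignment and polarity are input data, not
inferred.

## Effect size

For one measure with arm sizes `n₁` (intervention), `n₂` (control):

```
S_pre = sqrt(((n₁−1)·s₁,pre² + (n₂−1)·s₂,pre²) / (n₁+n₂−2))
d     = [(post₁ − pre₁) − (post₂ − pre₂)] / S_pre
```

Bessel-weighted pooling of the *pretest* SDs is used so the intervention
cannot influence the denominator. If the instrument's polarity is
`lower_better`, the sign of `d` is flipped; positive `d` always favours the
intervention. Plain Cohen's `d` is the default; the Hedges small-sample
factor `J = 1 − 3/(4(n₁+n₂−2) − 1)` is an opt-in flag.

Summary-statistic reports do not identify the pre/post correlation, so the
sampling variance uses the change-score (Morris-style) form

```
v = 2(1−ρ)(1/n₁ + 1/n₂) + d²/(2(n₁+n₂))
```

with ρ (`rho_prepost`, default 0.5) exposed in `ESConfig`. Some variance
assumption is unavoidable because pooling weights require one; 0.5 is the
conventional middle value, and sensitivity can be probed by re-running with
other values (the generator can likewise create data with a different true ρ
to stress this assumption).

When a trial measures one category with `m` instruments, the composite is the
unweighted mean of the `m` d's. Its variance is the full double sum
`(1/m²)·ΣᵢΣⱼ ρᵢⱼ·√(vᵢvⱼ)` with `ρᵢⱼ = rho_measures` off the diagonal.
The default `rho_measures = 1.0` is deliberately conservative (largest
composite variance); instrument-level correlations are essentially never
reported, and assuming 1.0 avoids overstating the precision of multi-measure
trials.

## Pooling and heterogeneity

Fixed-effect weights `wᵢ = 1/vᵢ` define Cochran's
`Q = Σwᵢ(dᵢ − d̄)²` on `df = k−1` (chi-square upper-tail p), and
`I² = 100·max(0, (Q−df)/Q)`. Between-study variance is the
DerSimonian–Laird moment estimator `τ² = max(0, (Q−df)/C)`,
`C = Σw − Σw²/Σw` — the default of the mainstream commercial meta-analysis
software, hence the natural choice when reproducing syntheses produced with
it. Pooling uses `w*ᵢ = 1/(vᵢ + τ²)`, z-based two-tailed p-values and
95% CIs (`±1.959964·se`); no Knapp–Hartung adjustment. Implementation is
cross-checked in the test suite against R's metafor (`method="DL"`) to 1e-8.

The pooling unit everywhere is the comparison-level category composite.
Category tables carry one row per category plus an `all_measures` row that
pools every composite; the control-type table pools composites within each of
the four subtypes (multi-arm trials appear in every applicable row). Row
bookkeeping: `k_studies` counts distinct studies, `n_effects` counts
measure-level effect sizes absorbed into the row's composites, `total_n`
sums participants over the distinct arms involved (a shared arm counts once
per row). A category with a single comparison is reported with null
`Q/df/p_Q/I²` rather than dropped. Verbal magnitude labels use the
conventional 0.2 / 0.5 / 0.8 thresholds.

## Publication bias

Egger's test is the classic unweighted OLS of `zᵢ = dᵢ/seᵢ` on
`xᵢ = 1/seᵢ`; the intercept is tested with a two-tailed t on `n−2` df.
(A weighted variant exists; the unweighted form is the near-universal
default.) All-equal standard errors make precision collinear with the
intercept and raise a singularity error. Begg's companion statistic is
Kendall's tau-b between the variance-stabilized deviates
`(dᵢ − d̄_fixed)/√(vᵢ − 1/Σw)` and `vᵢ`, with the normal-approximation
p-value. Reports compute both per analysis row when ≥3 effects are available,
at the comparison level for consistency with pooling.

## Moderator meta-regression

One moderator at a time (mean age in years, total training hours, composite
risk-of-bias score), never jointly, and with no multiple-testing correction —
matching how such syntheses are conventionally reported. Residual `τ²` is the
method-of-moments estimator `τ² = max(0, (Q_E − (k−p))/tr(P))` with
`P = W − WX(X′WX)⁻¹X′W` (the DL analogue for regression; REML behind
`method="reml"`), followed by WLS with weights `1/(vᵢ+τ²)`. The moderator
test is `Q_model = (β̂₁/se)²` against chi-square(1). Moderators are
study-level: all comparisons of a study share its value, and comparisons with
a missing value are dropped with the count reported. With no moderator the
estimator reduces exactly to DL pooling (asserted as a nesting test).

## Risk of bias

Five Cochrane domains (random sequencing, allocation concealment, blinding of
outcome assessment, incomplete outcome data, selective reporting), each rated
low / high / unclear. The composite moderator is `(#low) − (#high)`, range
−5…+5, lower = higher risk of bias. Per-domain count/percentage summaries are
emitted for charting.

## Synthetic-study generator

The generator emulates the *statistical* structure of an extracted evidence
base, on a standardized scale (pretest SD ≈ 1) so configured true effects map
directly to `d`; raw-scale realism (instrument units, floor effects) is
deliberately sacrificed for verifiability. Per study: a true category effect
`θ_s,c = δ_c + N(0, τ²)`; arm sizes uniform on `arm_n_range`; per measure,
pre-means `N(0, 0.1)`, SDs drawn as sample SDs of unit-variance data
(`√(χ²_{n−1}/(n−1))`), and observed mean changes
`N(±θ, √(2(1−ρ_true)/n))` — the exact sampling distribution of a mean change
score under pre/post correlation `ρ_true`. A `direction_prob` fraction of
measures is emitted on lower-is-better scales (changes negated, flag set), so
orientation logic is always exercised. Multi-arm trials (probability
`multi_arm_prob`) share the intervention arm's summary statistics across
comparisons. Moderators: age U(4, 18) years, training dose U(1.5, 18) hours,
occasional missingness; risk-of-bias ratings drawn per domain with low/high
rates typical of this literature. An optional selection rule suppresses a
study with probability π when its smallest measure-level p-value exceeds a
threshold, emulating p-value-driven publication. All draws flow from one
seeded generator; identical seeds give byte-identical CSVs.

Defaults are the study conditions of the evidence base the package is
designed around: 33 trials, per-category coverage probabilities matching an
11/10/11/13/20/15/8-of-33 category distribution, control-subtype mix
11:8:11:9, per-category true effects 0.16–0.30, `τ² = 0.05`, arm sizes
U(15, 90) (total enrolment ≈ 3,400–3,900, ≈ half the trials with active-type
controls). `paper_shape_preset(seed)` returns exactly this configuration.

What passing tests on generated data do show: the estimators recover the
generating `δ` and `τ²`, CIs attain near-nominal coverage, the Egger test
holds its size, and the pipeline produces no spurious category effects under
a true null. What they do not show: behaviour under real-data pathologies the
generator omits — non-normal outcomes, correlated categories within a study,
informative missingness, rounding of published summaries.

## Numerical and design choices

- CSV round-trips are lossless: floats are written with shortest-repr
  serialization and read with round-trip parsing.
- `I²` returns exactly 0 when `Q = 0` or `Q ≤ df`; `τ²` is truncated at 0.
- Egger with an exact fit (zero residual variance) reports `t = 0` when the
  intercept is 0 and `±inf` otherwise, rather than NaN.
- Pooled results are permutation-invariant in the input row order to 1e-12;
  grouping order follows first appearance for deterministic output files.
- The end-to-end null check averages each category's pooled `d` over 20
  seeds before applying the ±0.1 bound: with `τ² = 0.05` and per-category
  k ≈ 8–20, a *single-seed* pooled estimate has Monte-Carlo sd ≈ 0.07–0.11,
  so the bound is a statement about the expected estimate (bias), not about
  any one draw.
- Simulation sizes in the test suite (k = 200 recovery, 500 meta-analyses for
  coverage, 2000 Egger null replicates, 20 end-to-end seeds) were chosen so
  the Monte-Carlo error is comfortably inside each asserted band.
- A published per-study effect-size listing (e.g. a supplementary table of a
  synthesis to be reproduced) can be ingested via `pool_effect_table` from a
  TSV of `study_id, comparison_id, category, d, se|variance`; the test suite
  exercises this path with a synthetic stand-in listing.

## Limitations

- Shared-arm dependence in multi-arm trials is not modelled (no multivariate
  pooling, no robust variance estimation); subgroup k's can sum to more than
  the number of studies by design.
- The variance of `d` rests on an assumed pre/post correlation; results are
  mildly sensitive to it through the pooling weights.
- No trim-and-fill or selection-model adjustment; bias diagnostics are
  detection-only.
- Follow-up time points and missing-SD imputation (from SEs or CIs) are out
  of scope; only pre-to-post effects are synthesized.
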