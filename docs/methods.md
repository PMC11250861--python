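# Methods

## The model battery

Nine functions map age `t` (days, > 0) to expected body weight (g):

| model | form | p | asymptote |
|---|---|---|---|
| Bridges | `W0 + a(1 − e^{−k t^m})` | 4 | `W0 + a` |
| Janoschek | `a − (a − W0) e^{−k t^m}` | 4 | `a` |
| logistic | `a / (1 + b e^{−kt})` | 3 | `a` |
| Gompertz | `a e^{−b e^{−kt}}` | 3 | `a` |
| von Bertalanffy | `a (1 − b e^{−kt})³` | 3 | `a` |
| Richards | `a (1 − b e^{−kt})^{1/m}` | 4 | `a` |
| Schumacher | `a b² k (t + b)^{−2} e^{bkt/(t+b)}` | 3 | — |
| Morgan | `a b^k k t^{k−1} / (t^k + b^k)²` | 3 | — |
| sinusoidal | `y0 + a sin(2πt/b + c)` | 4 | `y0 + a` |

Notes on the less standard forms:

- **Bridges** is implemented with an explicit amplitude `a`. The form
  is sometimes typeset without it, but only the four-parameter version
  is consistent with published parameter tables that report `a` for
  Bridges and with information-criterion arithmetic that implies p = 4.
- **Schumacher** and **Morgan** are implemented in rate-style
  (derivative-like) forms. Both rise to a maximum and eventually decay
  as `t^{−2}` and `t^{−k−1}` respectively, so neither contains the
  mature weight as a parameter; `final_weight` returns an undefined
  marker for them. Under these readings the published parameter sets
  produce late-age predictions in line with the other models
  (≈ 1540–1560 g at day 70 for the Kuzi parameters), which is the
  internal evidence for choosing them over other possible groupings of
  the typeset expressions.
- **Sinusoidal**: `a` is the amplitude (g), `b` the period (days),
  `c` the phase (radians), `y0` the vertical offset (g). Over a
  quarter-period window the curve is a smooth sigmoid-like rise;
  initial weight is `y0 + a sin(c)` and the maximum over a period —
  reported as the final weight — is `y0 + a`. The representation is
  degenerate under `(a, c) → (−a, c + π)` and `(b, c) → (−b, −c)`;
  `canonical_sinusoidal_params` maps any fitted set to the canonical
  representative with `a > 0`, `b > 0`, `c ∈ [0, 2π)`, and all
  parameter comparisons (recovery experiments, final-weight
  cross-checks) are made in that chart.

"Initial weight" follows the `t = 0` convention: `W0` for
Bridges/Janoschek, `y0 + a sin(c)` for the sinusoid, and the functional
form at zero otherwise (logistic `a/(1+b)`, Gompertz `a e^{−b}`,
von Bertalanffy `a(1−b)³`, Richards `a(1−b)^{1/m}`, Schumacher `a·k`,
Morgan 0 for `k > 1`).

Derivatives are analytic for seven models; Schumacher and Morgan use
central finite differences with step 1e−4 day, which agrees with a
numeric derivative of the evaluator to better than 1e−5 relative
everywhere the tests probe.

Fractional powers of negative bases (Richards with `b e^{−kt} > 1` and
non-integer `1/m`) raise an explicit domain error naming the offending
age rather than silently returning NaN or a complex value. This is not
hypothetical: the published Kuzi Richards parameters have `b > 1`, so
that fitted curve is undefined for roughly the first four days of life.

## Fitting

Parameters are estimated by unweighted nonlinear least squares —
the implicit error model is additive i.i.d. Gaussian noise around the
mean curve — using Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`) with convergence tolerances of 1e−10 on both the
relative RSS change and the parameter step, and up to 1000 iterations.
These are stricter than necessary but essentially free at n ≤ 10.

Because several of the objectives are multimodal (the sinusoidal
likelihood especially, through its phase), each fit restarts from a
deterministic grid of heuristic initial values:

- asymptote `a ∈ {1.0, 1.2, 1.5} × max(weight)`; `W0 = first weight`;
- integration constants back-solved from the first observation
  (e.g. logistic `b = a/w₁ − 1`, Gompertz `b = ln(a/w₁)`);
- maturation rate `k ∈ {0.01, 0.05, 0.1, 0.5}` and shape
  `m ∈ {0.5, 1, 2}` grids;
- Morgan uses `k ∈ {1.5, 2.5, 3.5}` instead — its `k` is a Hill-type
  exponent near 2.5 in practice, not a rate — with `a` back-solved
  from the last observation (same for Schumacher);
- sinusoidal: `y0 = mean weight`, `a = half the weight range`,
  `b ∈ {2, 3, 4} ×` the age span, and `c` on an 8-point grid over
  `[0, 2π)`.

Eight additional starts jitter randomly chosen grid starts
(multiplicative log-normal, additive for the phase) under one seed, so
a fit is fully reproducible from its `FitConfig`. The lowest-RSS
*converged* start wins, ties going to the earlier start. During the
search, domain violations are clipped (Richards bases floored at
1e−12, non-finite predictions replaced by a large penalty) so the
optimiser can traverse bad regions; the winning parameter set is
re-scored with the strict evaluator, so a solution that only "works"
under clipping can never be returned.

Start-invariance holds in the operational sense: on noise-free
synthetic data the best-of-multistart optimum is invariant to the
jitter seed. Individual starts can and do land in local minima — that
is what the multi-start is for — so the property is asserted across
seeds of the whole procedure, not per start.

`grid_search_oracle` is a deliberately naive exhaustive minimiser over
a rectangular parameter box. It exists solely as an independent
cross-check: the optimiser must match or beat it on any shared box.

## Fit statistics

For n observations, p parameters, residual sum of squares RSS and
total sum of squares TSS about the mean:

- `R² = 1 − RSS/TSS`, `R²adj = 1 − [(n−1)/(n−p)](1 − R²)`;
- `RMSE = sqrt(RSS/(n−p))` by default. The alternative
  `sqrt(RSS/(n−p−1))` appears in some texts and is available via
  `rmse_denominator="n_minus_p_minus_1"`, but the `n−p` convention is
  the one under which the published (RMSE, AIC, BIC) triples for all
  27 breed × model cells are mutually consistent to within 0.01, so it
  is the default;
- Durbin–Watson on age-ordered residuals (statsmodels), range [0, 4],
  ≈ 2 for uncorrelated residuals;
- `AIC = n ln RSS + 2p` and `BIC = n ln(RSS/n) + p ln n`, natural
  logarithms. These RSS-based variants (no additive constants) are what
  the published tables use; they are valid for comparing models on the
  same data, not across datasets.

A perfect fit (RSS = 0) makes AIC/BIC/DW undefined; they are carried
as NaN, and the ranking treats RSS = 0 as AIC → −∞ (a perfect fit
ranks first). Ranking is by AIC, ties broken by smaller p then by
name; the comparison table also records the per-statistic winners
(min RMSE, min BIC, max R²adj).

## Absolute growth rate

The AGR is the first derivative of the fitted curve — expected daily
gain in g/day. It is reported on integer days (the observation
convention), with the age of maximum gain taken as the earliest grid
day attaining the maximum. For the sinusoid the continuous maximiser
is `b(2π − c + 2πj)/(2π)`; for the Kuzi parameters this is ≈ 30.7 d,
giving day 31 on the grid. For Polish Pekin and Peking the same
computation gives ≈ 26 and ≈ 29 d; published figure-based narratives
for those two breeds describe an earlier plateau (≈ 16 d) that the
analytic derivative of the published parameters does not produce, so
only the Kuzi feature is used as a quantitative check. As a
consistency property, the trapezoid integral of the AGR over a dense
grid reproduces the total weight gain between the endpoints to 0.1%.

## Synthetic data and fixtures

The generator draws `weight(t) = mean_curve(t) + Normal(0, noise_sd²)`
i.i.d. per age, truncated below at 1 g, under a single seed;
replicates differ only in their noise draws. It emulates the
*residual* structure that unweighted least squares assumes. It does
not emulate: heteroscedastic noise (real weight SDs grow with age),
serial correlation along a bird's trajectory, between-bird variance in
group means, or selection response across generations. Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to real
data pathologies.

The three breed fixtures carry the published per-model parameter
estimates and fit statistics. Observation designs: Kuzi
{1, 7, 14, 21, 28, 35, 42, 49, 56, 70} d (n = 10); Polish Pekin
{1, 7, 14, 21, 28, 35, 42, 49} d (n = 8); Peking: the true ages are
unpublished beyond "8 ages spanning day 1–42" (n = 8 is the only value
under which the published RMSE/AIC/BIC triples are consistent), so the
packaged grid {1, 3, 7, 14, 21, 28, 35, 42} is a synthetic stand-in
and is flagged as such. Three Richards entries (Kuzi `b`, Polish Pekin
`b`, Peking `m`) have sign-ambiguous transcriptions in the source
material; they are stored positive — the reading that yields plausible
weights — and annotated in the fixture CSVs.

Default experiment sizes (noise at the published residual SD, 200
seeded replicates for recovery and model-selection experiments; grid
oracles at ≤ 9 steps per dimension) keep the full test suite and the
acceptance script to a few minutes on one core while leaving the
Monte-Carlo margins wide: measured median offset/amplitude bias in the
noisy recovery experiment is below 1% against a 5% criterion, and the
generating model wins the AIC ranking in essentially all replicates
against a 60% criterion.

## Known limitations

- Single-group series only: no weighted least squares, no parameter
  standard errors or confidence intervals, no mixed-effects or
  multi-bird variance structure.
- The information criteria are the RSS-based small-sample variants
  without the AICc correction; with n = 8–10 and p = 3–4 they are
  comparative devices, not absolute evidence measures.
- The sinusoid is periodic: extrapolation beyond the fitted rise is
  biologically meaningless (weights would oscillate), so final-weight
  and AGR reporting is confined to the observed age window and the
  curve's first crest.
- Richards fits with `b > 1` are undefined at early ages; the fitting
  machinery handles this by restricting the domain, but comparisons of
  early-age predictions across models should exclude such fits.
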