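# Methods

## Model

The mixing model treats a consumer's biomarker vector as a noisy convex
combination of source signatures. For tracer *j* and diet proportions
*p* = (p₁…pₙ) on the simplex:

    u_j      = Σ_i p_i (m_{j,i} + f_{j,i})
    σ_j²     = Σ_i p_i² (s_{j,i}² + g_{j,i}²)
    x_j | p  ~ Normal(u_j, σ_j²),  independent across tracers

with library means/SDs (m, s) and fractionation mean/SD (f, g). Assumptions
worth stating plainly:

- **Tracer independence.** No cross-tracer covariance is modelled. For FA
  proportions this ignores the closure-induced correlation among tracers;
  it is the standard formulation for this model family and is what the
  validation experiments probe.
- **Gaussian likelihood on the raw scale.** FA values are modelled as
  percentages, not log-ratio transformed. The justification is the CLT
  argument: the mixture is a linear function of approximately normal source
  means, and the approximation improves with more tracers. The z-score
  diagnostic (`zscore_diagnostic`) lets a user check this on their own
  library: it pools within-group standardized values of every FA averaging
  > 5% of total FA. Note a structural detail: because each group-tracer
  column is standardized with the n−1 denominator, the pooled sample SD is
  √(Σ(n_g−1)/(N−1)) < 1 by construction (≈ 0.94–0.96 for feeding-trial-sized
  groups), so values near 0.95 indicate agreement with normality, not a
  deficit of spread.
- **Variance quirk of the p²-weighting.** σ² shrinks at interior p
  (Σp_i² < 1), so the likelihood is mildly overconfident for mixed diets.
  This is inherited from the model family on purpose; the sensitivity
  designs quantify its consequences.
- **Fractionation placement.** The model default applies g inside the
  per-source sum (Σ p_i² g²), i.e. the equation above. The *simulators*
  instead draw one fractionation realization per consumer per tracer
  (variance s-part + g²), which reproduces the composed spread
  √(2.3² + 1.3²) ≈ 2.64‰ observed for pure-diet pseudo-consumers. Both
  conventions are explicit in the code and documented where they differ.

### Priors

Default is Dirichlet(α = 1): uniform over compositions (each marginal is
Beta(1, n−1); for three sources the marginal median is 1 − √½ ≈ 0.293, not
1/3 — prior-recovery tests pin this). The alternative
`DIRICHLET_UNIFORM_HYPER` form places independent Uniform(0, 100)
hyperpriors on each αᵢ and samples (p, α) jointly; large sampled α
concentrate mass at the simplex center, so this prior is *less* vague than
it looks and is provided for sensitivity checks rather than as a default.

## Inference

Self-contained adaptive random-walk Metropolis on additive-log-ratio (ALR)
coordinates z = log(p₁..ₖ₋₁ / pₖ), with the log-Jacobian Σ log pᵢ in the
target. Choices:

- **Protocol**: 100 000 iterations, 50 000 burn-in, thinning 50, 2 chains
  (2000 retained draws per consumer). A `fast()` profile (10k/5k/5) keeps
  the same draw count for pipelines and passes the same oracle tolerance.
- **Adaptation**: per-walker step scale, multiplicative updates every 50
  iterations toward 30% acceptance, burn-in only (frozen afterwards, so the
  chain is a valid fixed-kernel Metropolis when draws are retained).
- **Reproducibility**: one RNG stream per (consumer index, chain), seeded
  `SeedSequence((seed, consumer, chain))`. `fit_many` runs all walkers as a
  single vectorized batch and is bit-identical to looping `fit_consumer`;
  the full protocol for 200 consumers takes ~10 s on one core.
- **Diagnostics**: split-chain R̂ and bulk ESS via ArviZ; R̂ > 1.05 flags
  (warning, not fatal), matching the per-consumer batch workflow where a
  rare sticky chain should be visible but not abort a 1000-consumer run.
- **Hyperprior form**: α is mapped through a scaled logistic transform and
  sampled jointly with p in the same walker.

### Validation oracle

`oracle_posterior` integrates likelihood × prior on a cell-centered
barycentric grid (default step 0.002; ~125 000 nodes for three sources) and
returns weighted marginal quantiles. It shares only the closed-form density
helpers with the sampler, none of the sampling machinery, and refuses more
than four sources. Acceptance tests require every marginal quantile
{2.5, 25, 50, 75, 97.5}% from the sampler to sit within 0.02 of quadrature
on all 2–3-source fixtures (measured worst gap ≈ 0.013–0.015 with 4 chains).

### Pooling

Replicate consumers are independent fits; the group posterior is the
equal-weight concatenation of their draws. This deliberately keeps pooled
dispersion from collapsing as consumer count grows (each consumer is a fixed
effect, not a draw from a shared diet), and a regression test checks the
pooled 95% width is non-shrinking from 10 to 100 consumers.

## Simulation machinery

- `simulate_pure_si` / `simulate_mixed_si`: per consumer, each source
  vector ~ Normal(m, s), mixed by the true weights, plus one Normal(f, g)
  fractionation draw per tracer. Closed-form check: mean Σw·m, SD
  √(Σw²s² + g²); moment tests run at n = 10 000.
- `simulate_mixed_fa`: resamples one raw feeding-trial profile per group
  (uniform with replacement) and sums with the true weights — consumers stay
  in the convex hull of the library and remain closed to 100%.
- `exact_mixture_consumer`: the zero-uncertainty mixture mean.
- **Known discrepancy, kept on purpose**: following the stated generation
  procedure, the mixed 80/10/10 SI pseudo-consumers have mean
  (−28.79‰, 7.15‰); the historically reported summary for this scenario
  (−28.7‰, 6.9‰) differs slightly on δ¹⁵N. The generator follows the
  procedure, not the printed summary, and the oracle regression test uses
  the printed observation only as a fixed input.

### Sensitivity designs

- **2×2 uncertainty matrix**: {resource SDs ×1 or ×0.01} × {consumers
  simulated with full noise or replaced by the exact mixture}. The
  fractionation SD is treated as model-side uncertainty and scaled together
  with the library SDs in the "minimized" cells: retaining g = (1.3, 1.0)‰
  unscaled while shrinking the library SDs leaves σ ≈ 1‰ and a diatom
  posterior SD of ~0.19 (interval ~40–100%), which contradicts the tight
  recovery this design is meant to exhibit; scaling g yields
  80.0% (79.2–80.8), the intended behaviour. Noisy consumers are always
  generated from the full-uncertainty library regardless of what the model
  assumes.
- **Fractionation grid**: resource and consumer uncertainty minimized,
  fractionation variance fixed to 0, and the *consumer's* true fractionation
  shifted by {0, ±1.96} SD per isotope while the model assumes the mean
  (`shift_model=True` flips the convention). Off-diagonal cells can push the
  consumer outside the mixing polygon; their boundary-piled posteriors are
  exploratory outputs, not pinned values.
- **Batching**: consumers are processed in groups (default 100) with
  per-batch summaries retained for dispersion checks.

## Synthetic FA library

The generator emulates the *structure* of a feeding-trial FA library — the
template values are synthetic, not measurements. Three default groups
(diatoms, green algae, cryptophytes; trial counts 10/8/8) over 26 tracers,
with group-diagnostic markers following the standard phyla contrasts and
near-zero values for foreign markers (e.g. diatom-fed animals carry almost
no green-algal C18 PUFAs — these "veto" tracers are what make monoculture
classification decisive). An optional fourth, deliberately degraded
cyanobacteria template mimics maternal-lipid carryover and is excluded from
defaults and acceptance checks.

Noise model: multiplicative logistic-normal — log-abundances are perturbed
and the profile re-closed to exactly 100%, keeping positivity and closure by
construction. The log-SD is per-tracer: 0.15 for a group's own markers
(diet-controlled FAs vary little within a trial), 0.60 for background
tracers. These two constants were pinned once by calibrating the observable
the generator is specified against — mean within-group profile-vs-group-mean
r² ≈ 0.88 (measured 0.886 on the default seed; band 0.80–0.95 across seeds)
— under the joint requirement that monoculture profiles remain decisively
classifiable (true-group posterior medians ≥ 0.96 on the default library).
A single uniform noise scale cannot satisfy both: spreading enough variance
over every tracer to reach r² ≈ 0.88 flattens the likelihood and caps
true-group medians near 0.90.

What passing FA-mode tests do **not** show about real data: real
within-group variation is correlated across tracers (lipid-allocation
shifts move whole blocks of FAs), real libraries mix Daphnia clones, diets
and labs, and real marker separations may be weaker; classification of
freshly drawn (held-out) synthetic profiles occasionally dips to median
≈ 0.93, so decisiveness on any particular real library must be checked on
that library.

## Numerical choices

- Variance floor 1e−12 on σ² (resources may not have exactly zero
  uncertainty; keeps exact matches finite).
- Quantiles: linear interpolation between order statistics everywhere.
- Sample SD (n−1) throughout library construction.
- FA closure tolerance 100 ± 5 by default; profiles are *not* renormalized
  unless asked (`renormalized()`).
- Tracer matching is by exact name after canonicalisation (ω→w, δ→d);
  library and consumer files must use the same tracer suite.
- Density curves: 1000 evenly spaced empirical quantiles histogrammed into
  40 equal-width bins on [0, 1], normalized to integrate to 1.

## Problem sizes

Desk-scale experiment sizes used by the tests and the acceptance script:
200 consumers for the full-uncertainty mixed SI scenario, 100 per group for
the pure-diet scenarios, 1000 for simulator moment checks, 26 monoculture
and 200 mixed consumers in FA mode — all with the full 100k-iteration
protocol (the vectorized batch sampler makes this cheap). Published-scale
runs (1000 consumers) reproduce the same pooled medians to within ~2 points
and can be run directly via the scenario API.

## Known limitations

- No cross-tracer covariance; no log-ratio (compositional) likelihood.
- No hierarchical (random-effects) sharing of diet across consumers.
- The underdetermined two-isotope/three-source case is faithfully bad:
  pooled medians land roughly midway between prior and truth. That is the
  phenomenon under study, not a defect of the implementation.
- The uniform-hyperprior form's exact historical parameterization is
  unverifiable; the per-component Uniform(0, 100) reading is implemented.
- The grid oracle is exact only up to its step (0.002) and refuses > 4
  sources.
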