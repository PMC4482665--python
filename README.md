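# fatracer

Bayesian biomarker mixing models for inferring the diet composition of
aquatic consumers, from either **fatty-acid (FA) signatures** (% of total FA,
typically 20+ tracers) or **stable-isotope (SI) δ-values** (usually just
δ¹³C and δ¹⁵N), plus the full Monte-Carlo simulation and sensitivity
machinery needed to know when such inferences can be trusted.

## Who this is for

Trophic ecologists with a *consumer-resource library* — biomarker signatures
(mean ± SD per tracer) of consumers experimentally fed each candidate
resource — who want posterior distributions of diet proportions for field
consumers, and methodologists who want to quantify how resource uncertainty,
consumer uncertainty, and the trophic-fractionation assumption propagate
into those posteriors. Because the library is measured on consumers fed
known diets, trophic modification of the biomarkers is built in: FA mode
needs no separate correction, while SI mode takes an explicit fractionation
spec (mean *f*, SD *g* per tracer).

## The model

A consumer's expected tracer value is a convex mixture of source signatures,

$$u_j = \sum_{i=1}^{n} p_i\,(m_{j,i} + f_{j,i}), \qquad
\sigma_j^2 = \sum_{i=1}^{n} p_i^2\,(s_{j,i}^2 + g_{j,i}^2),$$

where $p$ is the diet-proportion vector on the simplex, $m_{j,i}, s_{j,i}$
are the library mean and SD of tracer $j$ for source $i$, and $f, g$ the
fractionation mean and SD. Observations are independent Gaussians
$x_j \sim \mathcal N(u_j, \sigma_j^2)$; the prior on $p$ is Dirichlet
(α = 1 by default, uniform over compositions), optionally with
$\alpha_i \sim \mathrm{Uniform}(0, 100)$ hyperpriors. Posteriors are drawn
with an adaptive random-walk Metropolis sampler on additive-log-ratio
coordinates (100 000 iterations, 50 000 burn-in, thinning 50, two chains by
default; split-R̂/ESS diagnostics via ArviZ), validated against an exact
grid-quadrature oracle. Replicate consumers are fitted independently and
their posteriors pooled by concatenation, so pooled dispersion does not
shrink artificially with consumer count.

A packaged SI library ships with the code (phytoplankton δ¹³C/δ¹⁵N for
diatoms, chlorophytes and cyanobacteria, with fractionation SDs 1.3‰/1.0‰),
and a seedable synthetic FA library generator (3–4 phytoplankton groups ×
26 FAs with group-diagnostic markers) supports FA-mode experiments without
any external data.

## Worked example

```bash
python examples/fit_si_mixture.py
```

builds the exact 80% diatom / 10% chlorophyte / 10% cyanobacteria consumer
(δ¹³C = −28.79‰, δ¹⁵N = 7.15‰), minimizes library uncertainty (SDs ÷ 100),
and fits it:

```
Posterior diet proportions (median and 95% credible interval):
               median   q2.5  q97.5  mean     sd
group
Diatoms           0.8  0.792  0.808   0.8  0.004
Chlorophytes      0.1  0.093  0.107   0.1  0.004
Cyanobacteria     0.1  0.094  0.105   0.1  0.003
```

The true composition is recovered to two decimals. Re-running the same diet
under *full* uncertainty (`examples/si_uncertainty_scenarios.py`) instead
yields a pooled diatom median of ~0.47 with a 95% interval spanning
0.03–0.91: with two isotopes and three uncertain sources the answer is
pulled about halfway toward the generalist prior (1/3 each). The FA-mode
analogue (`examples/synthetic_fa_workflow.py`), with 26 tracers, recovers
0.79/0.10/0.10 with intervals a few points wide — the core argument for
many-tracer mixing models. `examples/fractionation_sensitivity.py` shows
that misjudging SI fractionation by ±1.96 SD swings medians by tens of
percentage points, and `examples/oracle_check.py` verifies the sampler
against exact quadrature (quantile gaps < 0.01).

A thin CLI wraps the same workflows (`fatracer fit | simulate | sensitivity
| validate-library | make-synthetic-library`); every run writes a JSON
manifest (options, seeds, library checksum) sufficient to reproduce its
outputs bit-for-bit.

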