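# Methods

## Model

A patient's nodal disease is the binary vector `X[t] = (X_v[t])` over the
`V = 6` ipsilateral lymph node levels I, II, III, IV, V, VII. At `t = 0`
(tumor formation) all levels are healthy. Per time-step, a healthy level
becomes involved with probability

```
P(X_v[t+1] = 1 | X_v[t] = 0) = 1 − (1 − b_v) ∏_{r ∈ pa(v), X_r[t] = 1} (1 − t_{r→v}),
```

and an involved level stays involved (no self-healing). `b_v` is direct
lymphatic seeding from the primary tumor, `t_{r→v}` cascade spread along a
drainage arc of the spread graph. The joint chain lives on the `2^V = 64`
binary states; the transition matrix is stored column-stochastically
(`A[i, j] = P(to i | from j)`, propagation `A @ pi`), states are ordered by
binary counting with the first listed level as the most significant bit, and
index 0 is all-healthy. These orientation/ordering conventions are arbitrary
but fixed for reproducibility.

The diagnose time `t_D` is unobserved; it carries a `Binom(t_max, p_T)`
prior with `t_max = 10` and one success probability per binarized T-category
(T0–T2 "early", T3–T4 "late"). `p_early` is fixed at 0.3 — with a single
free time-scale parameter per category the likelihood is invariant to the
prior's shape, so only the *relative* parameter `p_late` is identifiable and
is sampled. The diagnosis `Z` observes the hidden state at `t_D` through a
modality's sensitivity/specificity independently per level. The likelihood
vector over complete diagnoses is `ℓ = Σ_t P(t | T) · B^T A^t π`; a patient
with unreported levels contributes the exact sum of `ℓ` over all completions
(implemented as per-level observation factors of 1, not an explicit sum).
The cohort log-likelihood groups patients by (T-category, ternary pattern),
so its cost is independent of cohort size; it returns `−inf` (not an
exception) for zero-probability data so samplers can reject.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `b_v` | tumor → level v seeding probability per step | inferred, uniform prior on [0, 1] |
| `t_{r→v}` | spread along arc r → v per step, given r involved | inferred |
| `p_late` | binomial diagnose-time parameter, advanced T | inferred |
| `p_early` | same, early T | fixed 0.3 |
| `t_max` | time horizon (steps) | 10 |

Sampled dimensionality is `k = V + #arcs + 1`: 9 for the base graph, 11 for
the winning graph.

During fitting, the cohort's consensus involvement is treated as an
observation of the true hidden state (fitting modality with
`s_N = s_P = 1`). This is a deliberate modelling choice: literature
sensitivities/specificities near 0.8 are implausible given observed level II
involvement rates near 80%, which would force near-universal true
involvement. Imperfect modalities enter only (a) at consensus resolution
time and (b) at risk-prediction time. Both uses share one code path via a
per-call modality argument.

### Sensitivity/specificity convention for risk prediction

The shipped registry stores, in percent, CT 76/81, PET 86/79, MRI 63/81,
FNA 98/80, pathology 100/100 as (specificity, sensitivity). Risk
predictions for CT-based clinical staging therefore use **sensitivity 0.81,
specificity 0.76**. Quotations of these two numbers sometimes appear with
the labels exchanged; we verified numerically that the reference risk
values shipped with the package (e.g. 31.13% occult level II risk for an
early-T cN0 patient) are reproduced exactly by the registry assignment and
not by the swapped one, and the package consistently uses the registry.

## Inference

Uniform prior on `[0, 1]^k`, no reparameterization. Affine-invariant
ensemble MCMC (emcee) with the differential-evolution move mixture (80%
DE, 20% DE-snooker), `W = 20·k` walkers initialized uniformly in the cube,
1000 burn-in steps, then 200 steps of which every tenth is kept:
`S = 20·W` retained draws. A single master seed drives walker
initialization and proposals; runs are bit-reproducible. Acceptance
fractions and retained log-likelihoods are reported but deliberately not
used as stopping criteria — the schedule is fixed, not adaptive.
Burn-in for plain posterior runs is unified with the per-rung burn-in used
in thermodynamic integration (1000 steps) since nothing argues for a
different value.

## Model evidence

`ln E = ∫₀¹ E_β[ln L] dβ` over the power-posterior family
`L^β · prior`. The temperature ladder is the fifth-order power rule
`β_j = (j/R)^5`, default `R = 63`, dense near β = 0 where the integrand is
steepest. Chains are warm-started from the previous rung's final walker
positions, so retained sample `i` is defined at every rung and the
trapezoidal integral is evaluated per sample index; the estimate is the
mean of the S per-sample integrals and the error bar their standard
deviation. That error bar ignores the autocorrelation between matched
samples across rungs and is therefore somewhat optimistic — a known and
accepted simplification. Because the prior is proper on the unit cube, the
β = 0 endpoint needs no normalization correction. The β = 0 rung samples
the prior itself, so its warm-start-free initialization is already
stationary. `−BIC/2` is provided as the cheap large-N approximation to
`ln E`.

## Risk prediction

For a new diagnosis ζ, `P(ξ | ζ) ∝ P(ζ | ξ) P(ξ | θ)` with the prior from
the T-category's diagnose-time-marginalized state distribution; unknown
levels marginalize inside `P(ζ | ξ)`. "Occult risk in level v" means
`P(X_v = 1 | Z)` for a diagnosis with `Z_v = 0`. Point risks quoted in the
documentation are computed at the posterior-mean θ, accepting the small
Jensen gap versus averaging risks over draws; `risk_over_samples` (and
`Results.risk`) quantifies parameter uncertainty by re-evaluating the risk
over a seeded random tenth of the posterior draws. The shipped scenario
library (cN0, II, II+III, II+III+IV) covers the standard clinical
presentations. Observed prevalences are summarized as `Beta(n+1, N−n+1)`
posteriors (uniform prior), whose mode equals the raw frequency.

The 5%-threshold statements shipped as reference bounds attribute the
"level V above 4%" case to advanced T-category with clinical II+III+IV
involvement; where the source material for such statements is ambiguous
about T-category we use the advanced case, which is the binding one.

## Synthetic cohorts

`simulate_cohort` draws T-category (configurable late fraction, default
0.5), diagnose time from the matching binomial prior, evolves the hidden
state with per-level Bernoulli seeding (vectorized over patients), and
emits observations through a modality's confusion table. It emulates
exactly the generative process the likelihood integrates over — by design,
so simulator-vs-likelihood agreement is a meaningful consistency check
(chi-square on complete-diagnosis frequencies) and parameter recovery is a
meaningful self-consistency check. It does **not** emulate features of real
cohorts that the model itself ignores: inter-institutional heterogeneity,
HPV status, contralateral spread, correlated per-level diagnostic errors,
or the clinical-vs-pathological involvement discrepancy. Passing tests on
synthetic data therefore demonstrate internal correctness and
identifiability at realistic sample sizes, not clinical validity.

Default generator conditions used in the test suite: winning-graph
reference parameters, 50% advanced-T, perfect observation (consensus
treated as ground truth) — matching the fitting assumption.

## Numerical choices

- Dense 64×64 linear algebra; no sparsity (pointless at this size).
  State distributions use iterated mat-vec products, never matrix powers.
- Binomial pmfs from precomputed binomial coefficients (exact integers),
  not incomplete-beta evaluations.
- Likelihood evaluation caches per-pattern observation weights; one
  evaluation costs ~0.2 ms for the six-level model, which sets the MCMC
  budget.
- Consensus ties (possible with symmetric sensitivity/specificity) resolve
  to "involved" — clinically conservative.
- Degenerate inputs: empty cohorts have log-likelihood 0; all-unknown
  diagnoses probability 1; `p = 0` or `1` time priors are exact point
  masses; an impossible diagnosis under a perfect modality raises a
  `RiskError` naming the diagnosis.
- Problem sizes in the expensive self-consistency tests were chosen to keep
  the full suite in the few-minute range while leaving comfortable
  statistical margins: parameter recovery refits 5000 simulated patients
  with the full sampling schedule; graph comparison uses 2000 patients with
  an `R = 15` ladder and a reduced ensemble (10 walkers per dimension,
  100-step per-rung burn-in), which separates the compared graphs by ~2
  error bars on the evidence scale.

## Known limitations

- Ipsilateral disease only; contralateral spread, trinary involvement
  states (micro/macro) and time-inhomogeneous rates are out of scope.
- Sensitivity and specificity are fixed inputs, not inferred.
- One time-scale parameter carries the whole T-category dependence; levels
  whose involvement depends on T-category through other mechanisms (e.g.
  direct drainage changes as tumors grow) are described imperfectly.
- The TI error bar underestimates uncertainty when chains mix slowly
  between rungs (see above).
- The evidence ranking of graphs on small simulated cohorts is stochastic;
  only clearly separated alternatives should be distinguished at the
  reduced ladder settings.
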