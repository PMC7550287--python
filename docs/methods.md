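# Methods

## Dose-response model and ED50 estimation

Each drug's quantal response is modelled as

P(protected | dose d) = Φ(β₀ + β₁ · log₁₀ d),   β₁ > 0 for a protective drug,

and fitted by maximum likelihood as a binomial GLM with probit link
(statsmodels IRLS). The classical log-probit technique of the bioassay
literature is a graphical/nomographic approximation to this likelihood; ML
was chosen as the primary engine because it is reproducible, uses 0% and
100% groups (which are informative), and yields a parameter covariance from
the Fisher information. A Berkson-style minimum chi-square variant
(weighted least squares on empirical probits, weights n·φ(y)²/(p(1−p)),
0%/100% groups necessarily excluded) is available via
`FitConfig(engine="minchi2")` for comparison with older analyses, and
`drop_extreme_groups=True` reproduces the classical working rule of
discarding extreme groups before fitting.

Internally probits are centred at zero (probit 0 = 50%); the classical "+5"
offset is display-only and not used anywhere.

**ED50 and its SEM.** log₁₀ ED50 = −β₀/β₁; ED50 = 10^(−β₀/β₁). The SEM is
the delta method applied to −β₀/β₁ with the GLM covariance, transformed to
the dose scale by SEM(ED50) ≈ SEM(log₁₀ ED50) · ED50 · ln 10. The reference
analyses report "ED50 ± SEM" without defining the estimator; the delta
method is the standard choice with a likelihood fit and is validated here
by simulation (95% Wald CIs on log₁₀ ED50 achieve ≈93–96% empirical
coverage at the 4 × 8 design).

**Degenerate inputs.** Fewer than two distinct doses is an input error.
All groups at 0% (or all at 100%) response means the ED50 is not bracketed:
`Ed50NotIdentifiableError`. Complete separation — every group at 0% or
100% with the zeros entirely below the ones — leaves the likelihood without
a finite maximum; such fits are returned with `converged=False` (detected
structurally, not from optimiser diagnostics, because IRLS happily "converges"
to an arbitrary steep line there). Downstream operations refuse
non-converged fits.

**df.** Each fit stores residual df = (dose groups − 2), overridable in
`FitConfig`; it is bookkeeping only and never silently feeds the
interaction t-test (see below).

## Parallelism

H₀: β₁ᵃ = β₁ᵇ is tested with a two-sided z statistic
(β₁ᵃ − β₁ᵇ)/√(SEᵃ² + SEᵇ²) on the standard normal. The bioassay literature
names a "test of parallelism" without a formula; the z-test on the
asymptotic slope SEs is the natural companion of an ML fit. The classical
slope-function test is not implemented. At the reference design
(n = 200/group) simulations show ≥90% correct decisions both under equal
slopes and under a 3× slope ratio at α = 0.05.

Parallelism gates the fixed-ratio choice (`eligible_fixed_ratios`): if any
component pair is non-parallel, only the equi-effective ratio
(1:1, 1:1:1, …) is flagged eligible, because only equi-effective fractions
guarantee that the components exert the same quantal effect regardless of
slope. The pipeline warns and proceeds when a requested ratio is
ineligible, mirroring practice.

## Fixed-ratio additivity and the interaction test

"1:1:1" means equal fractions of each drug's **own ED50** (equi-effective
proportions), never equal mg/kg — the single most error-prone convention in
this analysis, pinned down by the worked example in the tests (component
doses 2.42 : 2.17 : 99.53 mg/kg are manifestly unequal).

- Additive prediction: ED50_add = Σ fᵢ·ED50ᵢ with per-component doses
  fᵢ·ED50ᵢ; SEM_add by independent-errors quadrature √(Σ fᵢ²·SEMᵢ²).
- Composition of any administered total dose keeps the proportions
  fᵢ·ED50ᵢ/Σⱼ fⱼ·ED50ⱼ and conserves the total exactly (the last component
  absorbs float round-off).
- Comparison: unpaired two-tailed Student t on the dose scale,
  t = (ED50_exp − ED50_add)/√(SEM_exp² + SEM_add²). The dose scale (not
  log) matches the reported point estimates of the reference analyses.
- df policy: an explicit df must be supplied, or `df_policy="animals"`
  uses (animals behind the experimental mixture) + (animals behind the
  single-drug fits) − 4. No default df exists because published df values
  in this literature are frequently not derivable from the stated designs.
- Classification at α (default 0.05): sub-additive iff p < α and
  interaction index ED50_exp/ED50_add > 1; supra-additive iff p < α and
  index < 1; additive otherwise. Both mixtures identical with zero SEM is
  classified additive with p = 1 by convention.

Isobologram projections (`isobologram_projections`) place the additive
point A and measured point M on each pairwise panel at their component
doses, apportioning each mixture's total SEM to components by the dose
proportions; M lies above A on every panel exactly when
ED50_exp > ED50_add.

## Synthetic data

`simulate_single_drug` draws protected counts Binomial(n, Φ(b·(log₁₀ d −
log₁₀ ED50))) per dose group. `simulate_mixture_experiment` draws the
mixture's total-dose groups the same way around a true total ED50 of
λ · Σ fᵢ·ED50ᵢ: λ = 1 is the additivity null, λ > 1 sub-additive truth,
λ < 1 supra-additive. The mixture's slope is a free parameter defaulting to
the fraction-weighted mean of the component slopes (real mixtures have an
empirical slope; no constraint is implied by the additivity model).

Defaults state the emulated world: groups of 8 animals, 4 dose levels per
single drug, 3 for the mixture, geometric dose spacing spanning the
predicted 10–90% response band (log₁₀ ED50 ± z₀.₉/slope) so the ED50 is
bracketed with high probability. Default true parameters in the tests use
component ED50s 7.26, 6.51 and 298.59 mg/kg (three times the worked
example's additive component doses) with probit slopes of 6, a typical
steepness for MES dose-response lines.

The generator reproduces exactly the structure the analysis assumes —
independent binomial groups on a true probit line. It does **not** emulate
litter effects, between-day variability, dose-measurement error, model
misspecification (non-probit links), or pharmacokinetic interaction between
components; a green simulation test therefore establishes internal
statistical correctness and calibration, not robustness to those
violations.

`recover_parameters` runs the full pipeline (fit singles → additive →
fit mixture → compare → classify) over seeded replicates, counting
unfittable draws as failures rather than crashing; at the 4 × 8 / 3 × 8
design under λ = 1 the observed pipeline type-I error is ≈4% at α = 0.05
(within the 3–7% acceptance band) and the null t distribution is centred
on zero.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; identical seed + scenario ⇒ byte-identical datasets.
- Likelihood comparisons against the brute-force grid oracle use a 1e-6
  log-likelihood tolerance; mixture dose conservation is enforced to 1e-9
  relative; fixed-ratio fractions must sum to 1 within 1e-12.
- Fit failure inside Monte Carlo sweeps is counted, not raised; in the
  one-shot pipeline it aborts the run with partial artifacts marked.

## Known limitations

- Type II isobolography (non-parallel lines analysed against an additivity
  *area*) is out of scope; non-parallel components restrict the ratio
  choice instead.
- The delta-method SEM and z/t tests are asymptotic; at 3 groups × 8
  animals the mixture ED50's SEM can be very large for unlucky draws
  (near-separated data), which the pipeline reports honestly rather than
  smoothing over.
- The t-test df is a policy decision, not an estimate; published df values
  in this literature often cannot be reconstructed, so the package refuses
  to invent one.
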