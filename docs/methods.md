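# Methods

## The model

`nanopbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model for gold nanoparticles (AuNPs) in the adult rat with seven
compartments — systemic blood, lung, liver, spleen, GI tract, kidney and
remaining tissues — connected in parallel by regional blood flows that
partition cardiac output.  Nanoparticle disposition differs from small
molecules in two ways the model makes explicit:

1. **Membrane-limited transcapillary transport.**  Each tissue is split into
   a capillary-blood sub-pool and an interstitial pool.  Blood exchanges with
   the capillary pool at the regional flow `Q_T (C_blood − C_cap)`; material
   crosses the capillary membrane at `PA_T · Q_T (C_cap − C_tis / P_T)`,
   where `PA_T` is the permeability–area coefficient (expressed as a fraction
   of tissue blood flow) and `P_T` the tissue:blood distribution coefficient.

2. **Saturable endocytic/phagocytic sequestration.**  Every tissue carries a
   phagocytic-cell (PC) sub-pool (Kupffer cells, alveolar and splenic
   macrophages, …) that takes up particles from the interstitium at
   `k_max,T · max(0, 1 − A_PC/A_cap,T) · A_tis` — linear in the available
   tissue amount, shutting off as the PC pool approaches its capacity
   `A_cap,T` (µg) — and releases them back at a first-order exocytosis rate
   `k_release,T`.  This capacity-limited linear-saturating form was chosen
   over a time-dependent Hill form because the parameterization is exactly
   {maximum uptake rate, capacity, release rate}.

First-order clearances complete the topology: biliary excretion drains liver
tissue into the GI lumen (tracked cumulatively as bile, a non-terminal
transfer), urinary elimination drains kidney tissue, the GI lumen loses to
feces and transfers to GI tissue (absorption `k_gi_abs` plus intestinal
reabsorption `k_reabs` — both lumen→tissue, so they add), and the lung lumen
clears by the mucociliary escalator into the GI lumen (`k_mucociliary`) and
translocates into lung tissue (`k_lung_trans`).

**Routes.**  IV bolus enters systemic blood; oral gavage enters the GI
lumen; intratracheal instillation enters the lung lumen; inhalation is a
zero-order deposition into the lung lumen over the exposure window, with the
deposited dose either given directly or computed as aerosol concentration ×
minute ventilation × duration × deposition fraction.  A single
`peripheral_fraction` (default 1.0) converts the deposited dose into the
%IPLD normalizer; the peripheral/tracheobronchial split is deliberately not
modeled further.

**Units.**  Amounts µg, volumes L (tissue density 1 kg/L), flows L/h, time
h.  Outputs are %ID (percent of administered dose) or %IPLD (inhalation).
Dissected-organ observables include residual capillary blood and, for GI and
lung, the lumen contents (whole-organ gamma counting counts them); tissue
AUC accumulators integrate the vascular+interstitial+PC concentration and
exclude lumen contents.

**Numerics.**  All transfer processes except PC uptake are linear, so the
right-hand side is a constant rate matrix plus the saturable-uptake
correction; the analytic Jacobian is supplied to LSODA (driven through
`scipy.integrate.odeint`; kernels are numba-compiled when available, with a
pure-numpy fallback).  Defaults rtol 1e-8 / atol 1e-10 — tight enough that
the closed-form oracles in the test suite hold to 1e-6 without per-call
overrides; the calibration forward model relaxes to rtol 1e-5 for speed.
Fluxes are computed from states clipped at zero, so integrator round-off
never feeds negative mass forward.  Mass balance (Σ compartments + urine +
feces = administered dose) is checked on every trajectory and violations
beyond 0.1% of the dose are logged; in practice the error is at round-off
level.  Inhalation trajectories are integrated piecewise so the
deposition-rate discontinuity falls on a segment boundary.

## Reference parameter values

The packaged physiology is a 0.25 kg female rat with standard reference
organ-weight fractions and allometric cardiac output (14 L/h/kg^0.75); the
lung receives a small systemic (bronchial-type) flow share so the six
perfused tissues partition cardiac output exactly.

The packaged nanoparticle kinetic sets are **synthetic reference values**
(the study-specific calibrated values live in external supplements): smooth,
monotone functions of hydrodynamic diameter (HD ≈ 1.18·core + 2.6 nm) chosen
to be physiologically plausible — liver/spleen uptake rates of order 10/h
growing mildly with size, urinary elimination falling off steeply with size
(glomerular filtration cut-off, `0.4·exp(−size/6) + 0.003` 1/h), µg-scale
uptake capacities comparable to the administered doses so that saturation is
active at study dose levels.  Route-specific multipliers on uptake/release
rates encode the route-divergent kinetics (different biomolecular coronas)
that the extrapolation experiment is designed to expose: e.g. lung uptake
×12 after intratracheal instillation, liver uptake ×0.5 and kidney ×2.5
after oral dosing.

## Synthetic-data generator

The generator emulates the multi-route rat study design: IV (1.4/5/18/80/200
nm, ~3–33 µg, samples at 1 and 24 h), oral (5–200 nm, 1/24 h), IT
(1.4–200 nm, 1/3/24 h), inhalation (23 nm, 20.1 µg deposited over 2 h,
samples to 672 h); tissues blood, lung, liver, spleen, GI, kidney, rest,
plus urine for the bolus routes; four replicates per design point.
Observations are the model prediction times multiplicative lognormal noise
with geometric SD 1.2 (not stated in the source studies; chosen once as a
realistic inter-animal scatter).  All randomness flows through one seeded
generator.

What the generator does *not* emulate: detection limits and censoring,
inter-study protocol differences, particle agglomeration, coating effects,
or model misspecification — synthetic data are generated by the same model
family that is fitted.  Passing recovery tests therefore demonstrate that
the inference machinery is correct and the design is informative, not that
the model is true for real rats.

## Hierarchical Bayesian calibration

Three stages: lognormal measurement error
`log y_ij ~ N(log f(D_i; t_ij; θ_i), σ²)`; multivariate-lognormal group level
`θ_tr,i ~ MVN(μ, Σ)`, `θ_i = exp(θ_tr,i)`; hyperpriors `μ ~ MVN(M, S²)`,
`Σ = diag(s)·C·diag(s)` with half-normal(1) priors on `s` and `σ` and an
LKJ(2) prior on the correlation matrix `C` (the LKJ shape is not fixed by
the source material; 2 gives mild regularization toward independence).
The monitored set is the nine parameters the data can inform across routes:
maximum uptake rates and release rates in liver, spleen, kidney and lung,
plus the urinary elimination constant; all other parameters are fixed at
their point values.  `M` defaults to the log of the packaged point set and
`S² = diag(1²)` on the log scale.  One `θ_i` per study group (route × size);
σ is shared across tissues and routes within a run.

**Sampler.**  A blocked Metropolis-within-Gibbs scheme authored here
(no gradient-based probabilistic-programming backend is used):

- `μ` — exact conjugate multivariate-normal draw given `θ_tr` and `Σ`.
- `θ_tr,i` — the only block touching the ODE model.  Before sampling, a
  maximum-a-posteriori pre-fit per group (Nelder–Mead on likelihood ×
  MVN(M, S²)) supplies both the chain initialization and, through the
  inverse of a finite-difference Hessian (eigenvalues floored at half the
  prior precision), a Laplace proposal covariance shared by all chains.
  Even sweeps take random-walk steps shaped by that covariance; odd sweeps
  take preconditioned Crank–Nicolson steps, which leave MVN(μ, Σ) invariant
  so their acceptance ratio is a pure likelihood ratio — this keeps weakly
  identified directions mixing at the population scale.
- joint translation moves — three per sweep, each shifting one random
  coordinate of `μ` and of every `θ_tr,i` by the same δ.  The population
  term is invariant under this shift, so it directly breaks the μ/θ
  lockstep (“funnel”) that otherwise throttles mixing of weakly identified
  coordinates.
- `σ` — random-walk MH on log σ using the cached residual sum of squares.
- `(s, C)` — `C` is parameterized by canonical partial correlations, under
  which LKJ(a) factorizes into independent shifted-Beta terms; updates mix
  independence proposals drawn from that prior (acceptance = population-MVN
  ratio) with random walks in the unconstrained tanh space; `log s` gets
  its own random-walk block.  Proposal scales adapt toward 30% acceptance
  during warmup only, preserving detailed balance afterwards.

Convergence is monitored with the split Gelman–Rubin potential scale
reduction factor on the population means (≤ 1.2 taken as acceptable;
the split variant is the stricter modern convention, and the classic
unsplit formula is available via `rhat(..., split=False)`).  Posterior
summaries report the population geometric mean `exp(mean μ_k)`, population
GSD `exp(mean s_k)`, and 2.5/50/97.5 percentiles of `exp(μ_k)`.

**Desk-scale problem sizes.**  The packaged recovery experiment uses one
group per route (all four routes; 23 nm for inhalation, 5 nm otherwise),
four replicates per design point (~360 observations), 4 chains × 400 warmup
+ 800 kept sweeps.  These sizes were chosen so a full calibration completes
in a few minutes on one core while keeping split R-hat ≤ 1.2; they are
smaller than one would use for a production analysis (where 4 × several
thousand sweeps is appropriate).

## Sensitivity analysis

Local one-at-a-time normalized sensitivity coefficients:
`NSC = [(AUC(1.01·p) − AUC(p))/AUC(p)] / 0.01`, a forward finite difference
at a +1% perturbation (central differences available as a cross-check).
Outputs are the AUCs of blood and the six tissues over [0, 24] h and
[0, 672] h, read from the integrated accumulator states; for the bolus
routes the 672 h window is pure simulation beyond the data horizon.
Parameters whose baseline value is zero (pathways inactive for the route)
are reported with NSC 0 rather than perturbed multiplicatively.  |NSC| ≥ 0.5
flags a parameter as highly sensitive.

## QSAR link

Route-specific biodistribution parameters are regressed on particle
physicochemistry.  Seven candidate predictors: HD, SA, ZP, log HD, log SA,
log |ZP| (all study particles are negatively charged, −47 to −37 mV, so the
magnitude carries the information) and log particle number.  "Stepwise"
selection is realized as an exhaustive, deterministic search over all
C(7,1)+C(7,2) = 28 one- and two-predictor subsets (three-predictor models
are excluded: with ≤ 5 size points they cannot reach significance); the
minimum-BIC subset among those with overall F-test p < 0.05 wins, ties
resolving toward fewer predictors.  BIC follows `n·log(RSS/n) + k·log(n)`
with k counting intercept and slopes — internally comparable, though offset
from other software by an additive constant.  Collinear subsets (design
condition number > 1e8) are skipped and logged.  Forward prediction is
`β₀ + Σβᵢxᵢ`, floored at zero for rate/capacity responses, with warnings
outside the training hull or the applicable 1.4–200 nm size domain.
Whether responses should be log-transformed before regression is an open
modeling choice; the default is the natural scale.

A packaged CSV transcribes the published IV-route regression coefficients;
the extraction lost which β-columns each printed coefficient occupied, so
predictor identity is recorded only where it is known (the liver
maximum-uptake row: HD and SA) and placeholder names elsewhere — those rows
support inspection, not forward prediction.

## Evaluation and the extrapolation experiment

Fold error is `max(obs/pred, pred/obs)`; "within k-fold" is inclusive at
the boundary (the factor-of-two adequacy convention).  RMSE and adjusted R²
(of the observed-vs-predicted regression) are computed on linear %ID scale
by default with a log10 option.  Pairs with a non-positive member are
excluded from ratio metrics and counted.

The traditional route-to-route extrapolation copies every particle-specific
parameter from an IV-calibrated set and takes only the route-entry
parameters (oral: `k_gi_abs`, `k_reabs`, `k_feces`; IT/IH: `k_mucociliary`,
`k_lung_trans`, `k_gi_abs`, `k_feces`) from the target route.  The packaged
discrimination experiment generates oral and IT data from the
route-divergent reference truth and scores both parameterizations on the
same observations.  Its RMSE is computed on the log10 scale: the error model
is multiplicative, and linear-scale RMSE is dominated by measurement noise
on the largest compartments (lung ≈ 50 %ID after IT) and carries almost no
information about systematic misfit.  Fold-error fractions discriminate on
either scale.

## Known limitations

- No lymphatic or tumor compartments, agglomeration kinetics, or
  protein-corona mechanism; rat only.
- The packaged kinetic values are synthetic reference values, not the
  calibrated values from the external rat datasets; loaders accept
  externally supplied observation tables in the documented tidy schema.
- The sampler is random-walk based; for much larger monitored sets or many
  more groups a gradient-based sampler would scale better.
- `σ` is shared across tissues; heteroscedastic extensions are out of scope.
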