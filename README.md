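# nanopbpk

Multi-route physiologically based pharmacokinetic (PBPK) modeling of gold
nanoparticles (AuNPs) in rats, for nanotoxicologists and nanomedicine
researchers who need target-organ dosimetry from particle properties and an
exposure scenario — without running a new animal study for every particle.

Nanoparticles do not behave like small molecules: they are sequestered by
endocytic/phagocytic cells (PCs) in the liver, spleen, lungs and kidneys,
and their kinetics differ by administration route (different biomolecular
coronas).  `nanopbpk` provides:

- **PBPK core** — a seven-compartment (blood, lung, liver, spleen, GI,
  kidney, rest) membrane-limited model with a saturable PC sub-pool per
  tissue, `uptake = k_max·max(0, 1 − A_PC/A_cap)·A_tissue`, first-order
  exocytic release and urinary/biliary/fecal clearances, and four routes:
  IV, oral gavage, intratracheal instillation (IT), inhalation (IH).
- **Hierarchical Bayesian calibration** — a three-stage model
  (`log y ~ N(log f(θ_i), σ²)`; `θ_tr,i ~ MVN(μ, Σ)`;
  `μ ~ MVN(M, S²)`, `Σ = diag(s)·C·diag(s)` with half-normal priors on `s`,
  `σ` and an LKJ prior on `C`) sampled by a blocked Metropolis-within-Gibbs
  scheme with a MAP/Laplace pre-fit, monitored by split Gelman–Rubin R̂
  (≤ 1.2 taken as converged) for the nine monitored uptake/release/excretion
  parameters.
- **Sensitivity analysis** — normalized sensitivity coefficients
  `NSC = (dAUC/AUC)/(dp/p)` of every tissue AUC (24 h and 672 h windows) at
  a +1% perturbation; |NSC| ≥ 0.5 flags highly sensitive parameters.
- **QSAR link** — deterministic best-subset (≤ 2 of 7 candidate
  descriptors: HD, SA, ZP and log transforms, log particle number)
  regression with BIC/adjusted-R²/F-test selection, and forward prediction
  of kinetic parameters for new particles.
- **Evaluation** — fold-error statistics (2-fold adequacy rule), RMSE,
  adjusted R², and the traditional-IV-extrapolation vs route-specific
  comparison experiment.
- **Synthetic data** — a seeded generator emulating the multi-route rat
  study design (sizes 1.4–200 nm, 23 nm for IH; µg doses; sampling 1–24 h,
  to 672 h for IH; lognormal measurement noise).

See `docs/methods.md` for the model equations, priors, sampler design and
limitations.

## Worked example

Simulate 5.3 µg of 5 nm AuNPs given IV to a 0.25 kg rat, using the packaged
reference parameter set:

```python
import nanopbpk as n

phys = n.default_physiology()
params = n.default_params(size_nm=5.0, route="iv")
scenario = n.make_scenario("iv", dose_ug=5.3, times=[1, 24])
traj = n.simulate(phys, params, scenario)
metrics = n.dose_metrics(traj, scenario, windows=(24.0,))
for tissue in ("blood", "liver", "spleen", "kidney", "lung", "urine"):
    print(f"{tissue:8s} %ID @1h = {metrics.pct_id[(tissue, 1.0)]:8.3f}"
          f"   %ID @24h = {metrics.pct_id[(tissue, 24.0)]:8.3f}")
print("liver AUC[0-24h] =", round(metrics.auc[("liver", 24.0)], 1), "ug*h/L")
```

prints

```
blood    %ID @1h =   46.222   %ID @24h =    5.442
liver    %ID @1h =   26.003   %ID @24h =   66.897
spleen   %ID @1h =    1.681   %ID @24h =    6.146
kidney   %ID @1h =    2.060   %ID @24h =    1.595
lung     %ID @1h =    1.337   %ID @24h =    0.501
urine    %ID @1h =    0.112   %ID @24h =    0.660
liver AUC[0-24h] = 8395.5 ug*h/L
```

— the classic AuNP picture: rapid clearance from blood into the
reticuloendothelial organs, with the liver holding two-thirds of the dose
by 24 h and only a small urinary fraction for a 5 nm particle.  Mass
balance (Σ compartments + excreta = dose) holds to round-off.

The same is available from the shell:

```bash
nanopbpk simulate --route iv --dose-ug 5.3 --size-nm 5 --times 1,24 --out traj.csv
nanopbpk synth --routes iv,oral,it --seed 1 --out obs.csv
nanopbpk calibrate --data obs.csv --chains 4 --seed 1 --out summary.csv
nanopbpk sensitivity --route oral --size-nm 5 --out nsc.csv
nanopbpk qsar fit --responses resp.csv --descriptors desc.csv --out models.json
nanopbpk evaluate --pairs pairs.csv --out report.json
nanopbpk compare-approaches --data obs.csv --out comparison.csv
```

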