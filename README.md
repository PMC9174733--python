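# pentrack

Personality, predictability and behavioural syndromes in group-housed
calves, quantified from high-frequency indoor-positioning (UWB) data.

Precision-livestock sensors can record the position of every calf in a pen
once per second for weeks. `pentrack` turns such streams into the
hierarchical statistics that behavioural ecologists use to describe
individual variation:

* **Personality (behavioural types).** For each movement or space-use
  behaviour `Y` measured per individual `j` in repeated four-day
  observational units `i`, a random-intercept mixed model

  ```
  Y_ij = β0 + x_ij'β + ind_j + e_ij,   ind_j ~ N(0, V_ind),  e_ij ~ N(0, V_e)
  ```

  is fitted by REML; the **adjusted repeatability**
  `R = V_ind / (V_ind + V_e)` is the fraction of phenotypic variance (after
  fixed effects for time unit, cohort, age, temperature, breed, sex,
  weaning stage and health status) due to consistent differences between
  individuals.

* **Predictability (rIIV).** A Bayesian double-hierarchical
  (location-scale) model gives every individual its own residual SD:

  ```
  mean:        Y = Xβ + Zα + ε,            α_j  ~ N(0, σ_α²)
  dispersion:  log σ_ε = X_d β_d + Z_d α_d,  α_d,j ~ N(0, ω²_ID)
  ```

  Individual residual SDs are lognormal, and the population-level
  **coefficient of variation in predictability** is
  `CVp = √(exp(ω²_ID) − 1)`.

* **Syndromes.** Multivariate fits with a full covariance across all
  individual random effects yield among-individual correlations between
  behavioural types (behavioural syndromes), between types and rIIV
  (is the bold individual also the erratic one?), and between the rIIV of
  different behaviours (predictability syndromes).

The behaviours themselves — total distance travelled, core (50%) and total
(95%) utilization-distribution areas, Hellinger-distance site fidelity, and
time in the feeder area — are computed from cleaned, smoothed trajectories
over four-day units. A synthetic-data module generates both raw
trajectories (bounded Ornstein–Uhlenbeck movement with feeder visits,
positional noise and data gaps) and behaviour tables with exactly known
hierarchical ground truth, so the entire pipeline is testable without any
sensor data.

MCMC for the location-scale models is an in-package Metropolis-within-Gibbs
sampler (conjugate mean-submodel and covariance updates, adaptive
Metropolis for dispersion parameters, interweaved recentering moves), with
split-R̂ / ESS / Raftery–Lewis convergence diagnostics.

## Worked example

```python
import pentrack as pt

# 60 calves x 12 four-day units; personality variance 0.8, mean residual
# variance 0.2, and individual differences in predictability (ω² = 0.2151)
sim = pt.simulate_metric_table(pt.MetricSimConfig(
    n_individuals=60, n_units=12, v_ind=0.8, v_res=0.2,
    omega2_id=0.2151, seed=1))

fit = pt.fit_lmm_reml(sim.table, pt.LMMSpec("trait", fixed_effects=()))
est = pt.bootstrap_repeatability_ci(sim.table, pt.LMMSpec("trait", ()),
                                    n_boot=1000, seed=1)
print(f"repeatability R = {est.r:.2f} [{est.ci_low:.2f}, {est.ci_high:.2f}]"
      f"  (V_ind = {fit.v_ind:.2f}, V_e = {fit.v_res:.2f})")

dfit = pt.fit_dhglm(sim.table, pt.DHGLMSpec(responses=("trait",)),
                    pt.MCMCSettings(n_chains=4, n_iter=3000, burn_in=1500,
                                    thin=3, seed=1))
cvp = pt.compute_cvp(dfit)
print(f"CVp = {cvp.cvp:.2f} [{cvp.cri_low:.2f}, {cvp.cri_high:.2f}]")
diag = pt.convergence_diagnostics(dfit)
print(f"max R-hat = {diag['rhat'].max():.3f}, min ESS = {diag['ess'].min():.0f}")
```

prints

```
repeatability R = 0.80 [0.73, 0.85]  (V_ind = 0.62, V_e = 0.16)
CVp = 0.39 [0.29, 0.50]
max R-hat = 1.005, min ESS = 909
```

Read: 80% of the variance in this behaviour is between-individual
(pronounced personality); the spread in individual residual SDs corresponds
to a CVp of 0.39 on this particular draw of 60 individuals (the generating
population value is 0.49; with 60 individuals the realized dispersion
variance of a single draw differs noticeably from its population value, and
the posterior tracks the realized one). All chains mix well.

A full raw-data-to-report run (`trajectories → cleaning → behaviour table →
repeatability / CVp / correlation tables + manifest`) is available both as
`pentrack.pipeline.run_pipeline(config)` and as a CLI:

```sh
pentrack run-all --config pipeline.yaml --seed 1 --out results/
```

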