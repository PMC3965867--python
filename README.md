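# pemjoint

Joint modeling of longitudinal IgG autoantibody titers and recurrent
pemphigus events through a shared random intercept.

Pemphigus is a chronic autoimmune blistering disease that relapses
repeatedly; serum IgG autoantibody titer is its standard activity biomarker.
Clinicians want to know whether a rising titer signals an elevated hazard of
the next recurrence. Analysing the two processes separately biases both
answers, so `pemjoint` fits them **jointly**: a linear mixed model for the
biomarker trajectory and a parametric proportional-hazards model for
recurrence gap times, linked by one subject-level random effect. The package
is aimed at biostatisticians running shared-parameter analyses of recurrent
events, and at simulation studies of that methodology.

## Model

For subject *i* at visit time *t<sub>ij</sub>* (months since disease onset),
with *y = ln(1 + IgG titer)*:

```
y_ij = x_ij' β + α_i + e_ij ,     α_i ~ N(0, σ_α²),  e_ij ~ N(0, σ_e²)
```

with design row *x = (1, age, male, single, lymphocyte, t)*. Gap times
*W<sub>ik</sub> = T<sub>ik</sub> − T<sub>ik−1</sub>* between successive
recurrences (onset is *T<sub>i0</sub> = 0*; the final gap is censored at the
end of follow-up) follow a proportional-hazards model sharing the same
random intercept:

```
h_i(w) = h0(w) · exp( z_i' η + γ α_i )
```

with *z = (age<sub>std</sub>, male, single, skin phenotype)* and a Weibull
(default) or piecewise-constant baseline hazard *h0*. Conditional on
*α<sub>i</sub>* the two processes are independent; the association parameter
**γ** measures how strongly the subject's underlying biomarker level drives
the recurrence hazard. Estimation maximizes the marginal likelihood obtained
by adaptive Gauss–Hermite quadrature over *α*; standard errors come from the
observed information, reported with Wald intervals, hazard ratios
*exp(η)*, and the per-month percent change *100·(e^{β_time} − 1)* of
*1 + IgG*. Because the clinical data were never deposited, a calibrated
synthetic-cohort generator reproduces the study design (112 subjects,
mean 39.1-month follow-up, monthly titers, up to ~8 recurrences) for
testing and simulation studies. See `docs/methods.md` for details.

## Worked example

```python
import pemjoint as pj

cohort = pj.simulate_cohort(pj.GeneratorConfig(n_subjects=112, seed=42))
model  = pj.JointModel(quad_order=9).fit(cohort)
print(model.result_.table2_text())
```

```
Covariate                       Estimate       SE       P    Lower    Upper   Transf
Longitudinal measures of IgG
  Age                              0.033    0.004   0.000    0.026    0.041
  Male                             1.499    0.106   0.000    1.291    1.707
  Single                           0.405    0.151   0.007    0.110    0.700
  Lymphocyte                       0.046    0.005   0.000    0.036    0.056
  Time                             0.024    0.001   0.000    0.022    0.025    2.401
Recurrent pemphigus event
  Age (per SD)                     0.196    0.091   0.030    0.019    0.374    1.217
  Male                             0.028    0.151   0.852   -0.268    0.325    1.029
  Single                          -0.034    0.214   0.873   -0.454    0.385    0.966
  Phenotype (skin vs mucosal)     -0.088    0.121   0.465   -0.325    0.148    0.916
Association
  Gamma                            0.852    0.129   0.000    0.599    1.105    2.345
```

The cohort was simulated with a true time trend of 0.024 and true γ = 0.876;
the fit recovers a 2.40 %/month IgG increase (`Transf` column of the Time
row) and γ̂ = 0.852 with 95% CI (0.60, 1.11): a strongly positive
biomarker–recurrence association, as built into the generator. `Transf`
shows hazard ratios for the recurrence rows.

The same pipeline is available from the shell:

```bash
pemjoint simulate --n 112 --seed 42 --out-dir cohort/
pemjoint fit --longitudinal cohort/longitudinal.csv --episodes cohort/episodes.csv --out fit.json
pemjoint report --fit fit.json
pemjoint recover --replicates 20 --n 112 --seed 0   # parameter-recovery study
```

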