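# mindsmci

Integrative subtyping of cognitively unimpaired (CU) adults from mixed
binary/continuous baseline data, subtype-specific risk of incident mild
cognitive impairment (MCI), and debiased estimation of cardiometabolic
medication effects on MCI-free time — implemented as a tested, reusable
pipeline exercised end-to-end on a synthetic multimodal cohort generator
with recoverable ground truth.

**Who it is for.** Biostatisticians and epidemiologists who want (a) a
working Pólya–Gamma Gibbs sampler for joint clustering + dimension
reduction of mixed-type data, (b) a reproducible subtype → risk → treatment
effect analysis scaffold, or (c) a seeded simulator of confounded, censored
EHR-style cohorts for methods evaluation.

## The models

**Subtyping (MINDS).** Subject *i* has latent construct
*u*ᵢ ∈ ℝ^q and cluster label *z*ᵢ:

    z_i ~ Cat(π),  u_i | z_i ~ N(μ_{z_i}, I_q)
    x_ij ~ Bern(σ(b_j + w_j·u_i))        binary block
    y_il ~ N(b_l + v_l·u_i, σ_l²)        continuous block

Pólya–Gamma augmentation makes every conditional conjugate; the cluster
count minimizes a BIC-style criterion on a Laplace-approximate
observed-data likelihood.

**Risk.** Kaplan–Meier curves and Cox proportional-hazards models
(HR = exp β, Efron ties) with a main-effects preset (subtype +
demographics + medication flags) and a subtype × medication interactions
preset.

**Treatment effects.** For each medication class, the average treatment
effect θ on log observed follow-up time via a cross-fitted interactive
regression model with the doubly-robust AIPW score, multiplied by inverse
probability-of-censoring weights under a fixed 48-month at-risk rule;
exp(θ) is a geometric-mean time ratio. Subtype GATEs are within-subtype
weighted score means.

See `docs/methods.md` for assumptions, priors, defaults and limitations.

## Worked example

```python
from mindsmci import (MindsConfig, MindsModel, TreatmentEffectModel,
                      cox_fit, generate_cohort, main_effects_spec)
from mindsmci.simulate import BINARY_COLUMNS, CONTINUOUS_COLUMNS, separated_config

cohort, truth = generate_cohort(separated_config(n_subjects=2000, seed=7))

fit = MindsModel(cohort[BINARY_COLUMNS], cohort[CONTINUOUS_COLUMNS],
                 MindsConfig(n_clusters=4, n_iter=1200, n_burnin=400, seed=7)).fit()
print(fit.summary())

print(cox_fit(cohort, main_effects_spec()).subtype_hazard_ratios()[["hr", "ci_low", "ci_high"]].round(2))

eff = TreatmentEffectModel(cohort, "antihypertensive", subtype_col="true_subtype").fit(seed=7)
print(f"time ratio {eff.time_ratio:.3f}  95% CI {eff.time_ratio_conf_int}")
```

Output (abridged):

```
MINDS fit summary
==================================================
subjects: 2000   clusters: 4   latent dim: 3
retained draws: 400 (of 1200 sweeps, burn-in 400, thin 2)
information criterion: 104581.8
cluster sizes (MAP): 1: 1103, 2: 502, 3: 133, 4: 262
mixing weights (posterior mean): [0.557 0.245 0.067 0.13 ]

             hr  ci_low  ci_high
subtype_2  1.17    0.95     1.45
subtype_3  3.68    3.17     4.27
subtype_4  1.98    1.71     2.30

time ratio 1.048  95% CI (0.877, 1.253)
```

Reading it: the sampler recovers four clusters whose mixing weights match
the generator (0.548/0.074/0.248/0.130 up to label order); the Cox fit
recovers the configured subtype hazard ratios (1.43, 3.69, 1.87) within
its intervals — at n=2,000 the subtype-2 interval is wide; the recovery
designs use n=20,000; and the antihypertensive time ratio estimate (truth
here is a mixture of subtype-level ratios 1.0–1.14) is 1.05 with an
honest, wide interval at this n.

The same stages run from the shell:

```bash
mindsmci run --seed 7 --out results/run7 --k-range 3:6
```

writing `cohort.csv`, `assignments.csv`, `ic_table.csv`,
`loading_matrix.csv`, `km_curves.csv`, `cox_table.csv`,
`effects_table.csv`, `report.json` and a hash manifest.

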