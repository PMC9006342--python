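# sbglm — surface-based spatial Bayesian GLM for task fMRI

Task-fMRI analyses that fit an independent linear model at every
cortical vertex ("massive univariate" GLM) ignore the strong spatial
dependence of activation amplitudes, produce noisy subject-level
estimates, and lose power to the massive multiple-comparisons
correction that follows. `sbglm` implements the spatial Bayesian
alternative for data on triangulated cortical surfaces, aimed at
researchers who want reliable *individual-subject* activation maps and
powerful small-sample group inference:

- **Spatial priors.** Each task's activation field `beta_k` (percent
  signal change) gets a Matérn Gaussian-field prior
  `cov(d) = sigma^2 (kappa d) K_1(kappa d)`, discretised by finite
  elements on the mesh into a Gaussian Markov random field with sparse
  precision `Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G)`.
- **Single- and multi-run models.** Runs share the per-task
  hyperparameters `(kappa_k, tau_k)` and noise variance while keeping
  run-specific fields; cross-run averages come from the exact joint
  Gaussian posterior. Hyperparameters are estimated by maximising the
  closed-form log marginal posterior (empirical Bayes).
- **Excursion sets.** Activated regions are the largest vertex set
  whose *joint* posterior probability of exceeding a threshold `gamma`
  is at least `1 - alpha` — no multiplicity correction needed, FWER
  controlled at `alpha` per hemisphere (whole-brain
  `1 - (1 - alpha)^2`).
- **Group contrasts.** `beta_G = (a' ⊗ I_N) beta` for any weight
  vector over (subject, run, task) blocks, with exact Gaussian
  combination of subject posteriors.
- **Classical benchmark.** Prewhitened per-vertex least squares,
  thresholded t-tests `(beta - gamma)/SE`, Bonferroni / FDR
  correction, and group averaging.
- **Preprocessing.** Percent-signal-change scaling, double-Gamma HRF
  designs, nuisance regression, Yule-Walker AR(6) estimation with
  cross-run averaging and 6 mm surface smoothing, banded
  innovations-filter prewhitening.
- **Reliability metrics.** Vertexwise two-visit ICC (truncated at 0),
  Dice overlap of activation maps, MSE/correlation against reference
  maps.
- **Synthetic studies.** A generator emulating an HCP-motor-style
  block design (12 s blocks, 3 s cues, TR 0.72 s, multiple
  runs/visits/subjects) with Matérn truth fields and spatially varying
  AR(6) noise, so everything is testable without data downloads.

See `docs/methods.md` for the model, estimation details and known
limitations.

## Worked example

Simulate a two-run subject on a 642-vertex sphere, preprocess, fit the
multi-run spatial Bayesian GLM, and extract an excursion set:

```python
import numpy as np
from sbglm import (SimulationSpec, simulate_study, fit_bayes_glm,
                   derive_field, LinearCombination, excursion_set)
from sbglm.pipeline import prepare_visit

spec = SimulationSpec(n_tasks=2, n_runs=2, n_subjects=1, n_visits=1,
                      n_timepoints=200, kappa=0.3, field_sd=1.0,
                      noise_sd=1.0, subject_sd=0.0, visit_sd=0.0, seed=42)
study = simulate_study(spec)
sessions = prepare_visit(study.runs[0][0], study.design, study.mesh)

post = fit_bayes_glm(sessions, study.ops)
print("kappa_hat:", np.round(post.theta_hat["kappa"], 3))

avg = derive_field(post, LinearCombination.run_average(2, 2, task=0))
exc = excursion_set(avg, gamma=0.5, alpha=0.01, n_samples=10_000, seed=0)
print("active vertices:", exc.n_active,
      "joint probability:", round(exc.joint_probability, 3))

truth = study.truth.visit_fields[0, 0][0][study.mesh.data_indices]
print("posterior-mean RMSE vs truth:",
      round(float(np.sqrt(np.mean((avg.mean - truth) ** 2))), 3))
```

Output:

```
kappa_hat: [0.309 0.309]
active vertices: 52 joint probability: 0.991
posterior-mean RMSE vs truth: 0.344
```

`kappa_hat` recovers the generating inverse range 0.3/mm within a few
percent; the 52 active vertices are those jointly above 0.5% signal
change with probability 0.991; the posterior-mean RMSE (0.34% signal
change) is below the classical GLM's RMSE on the same data (~0.40%).

A command-line surface wraps the same machinery:

```sh
sbglm init-config --out config.yaml   # editable defaults
sbglm simulate --config config.yaml --out study/ --seed 1
sbglm run --config config.yaml       # simulate -> fits -> excursions -> report
sbglm reliability map_visit1.func.gii map_visit2.func.gii
```

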