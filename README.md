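# pdmaxent

Accelerated primal–dual solvers for non-smooth, regularized
maximum-entropy (MaxEnt) density estimation over discrete site grids, as
used in presence-only occurrence modeling.

Given an `m × n` feature matrix Φ (features by sites), a strictly positive
prior distribution and an empirical distribution over sites, the package
solves

```
min_{p ∈ Δn}  KL(p ‖ prior) + t · H*((E_emp[Φ] − E_p[Φ]) / t)
```

for the elastic-net, non-overlapping group-lasso and ℓ∞ penalties, along a
141-point regularization path that starts at `t_max` (where the solution is
exactly the prior with a zero dual vector) and warm-starts each solve from
the previous one.

The primal–dual schemes replace the usual quadratic proximal step with a
Kullback–Leibler step, so the primal update is a closed-form Gibbs
distribution and the stepsize rule needs only the maximum feature-column
norm (one O(mn) pass) instead of the largest singular value. Two variants
are provided — an adaptive-stepsize scheme for any penalty and a
constant-stepsize linear-rate scheme for smooth potentials (elastic net
with α < 1) — plus an accelerated proximal-gradient (FISTA) baseline on
the dual for cross-validation.

## Layout

| Module | Contents |
| --- | --- |
| `pdmaxent.core` | `FeatureMatrix`, `MaxEntProblem`, Gibbs distributions, KL divergence, operator/spectral norms, primal and dual objectives |
| `pdmaxent.regularizers` | prox operators (soft threshold, elastic net, block shrinkage, ℓ1-ball projection, ℓ∞ via Moreau), penalty values, `t_max`, stopping-rule residuals |
| `pdmaxent.solvers` | `npdhg_solve_nonsmooth`, `npdhg_solve_smooth`, `stepsizes_linear`, `fbs_solve` |
| `pdmaxent.path` | 141-point schedule, warm-started `fit_path`, sparsity profiling |
| `pdmaxent.datagen` | region-weighted empirical distributions, prior imputation, min–max scaling, seeded synthetic datasets |
| `pdmaxent.reference` | dense SLSQP reference minimizer of the primal (oracle for tests) |
| `pdmaxent.io` / `pdmaxent.cli` | TSV readers/writers and the `pdmaxent` command |

## CLI

```bash
# seeded synthetic dataset (TSV files + manifest)
pdmaxent simulate --m 10 --n 200 --sparsity 3 --samples 10000 --seed 1 --out data/

# path-start hyperparameter
pdmaxent tmax --features data/features.tsv --prior data/prior.tsv \
    --empirical data/empirical.tsv --model elastic_net --alpha 0.95

# full regularization path (path_table.tsv, coefficients.tsv, config.yaml)
pdmaxent path --features data/features.tsv --prior data/prior.tsv \
    --empirical data/empirical.tsv --model elastic_net --alpha 0.95 \
    --solver npdhg --out runs/en095/
```

Models: `elastic_net` (requires `--alpha`), `group_lasso` (requires
`--groups`, a TSV of feature/group pairs) and `linf`. Exit codes: 0
success, 1 validation error, 2 some path point did not converge.

## Notes

- The group-lasso multiplier is `sqrt(m_g)` everywhere (penalty, prox
  threshold, `t_max`); pass `weighting="size"` to `group_lasso` for the
  literal group size.
- The stopping rule is the model's optimality-condition inequality with a
  relative slack of `1e-5` (configurable), checked after a minimum of 40
  iterations. It is a necessary condition, so for high-accuracy
  comparisons raise `min_iterations` rather than only lowering the
  tolerance.
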