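# fractional-ridge

Ridge regression whose regularization level is specified by what it does to
the solution, not by an opaque penalty.

## The problem

Ridge regression estimates linear-model coefficients as

    β̂(α) = (XᵀX + αI)⁻¹ Xᵀy,

trading a little bias for stability when predictors are correlated or noisy.
The catch is the hyperparameter α: its useful range depends on the scale of
the design matrix `X` and on predictor collinearity, so practitioners sweep
a heuristic log-spaced grid of α values and cross-validate. On such grids
many candidates are wasted — several α values yield solutions
indistinguishable from ordinary least squares (OLS), several shrink
everything to essentially zero — and the chosen α is not comparable across
targets, models, or datasets. This matters most in many-target settings
such as voxelwise encoding models, where one design is regressed against
tens of thousands of response vectors at once.

**Fractional ridge regression (FRR)** reparameterizes the problem by the
fraction

    γ = ‖β̂ᴿᴿ‖₂ / ‖β̂ᴼᴸˢ‖₂ ∈ [0, 1]

of the unregularized solution's L2-norm that the regularized solution
retains. Requesting γ on a linear grid from 0 to 1 guarantees that every
candidate solution is distinct and that the whole range from full shrinkage
to no shrinkage is covered; the γ selected by cross-validation is directly
interpretable and comparable across targets.

## The algorithm

With the SVD `X = U S Vᵀ` (singular values λ₁ ≥ … ≥ λ_r), rotating the
target by Uᵀ reduces ridge regression to independent scalar shrinkages:

    β̃ᴼᴸˢᵢ = ỹᵢ / λᵢ,      β̃ᴿᴿᵢ = λᵢ² / (λᵢ² + α) · β̃ᴼᴸˢᵢ.

The solver evaluates γ(α) on a log-spaced α grid spanning
`[10⁻³ λ_r², 10³ λ₁²]` (0.2 log₁₀ steps), interpolates to find the α
achieving each requested γ for each target, computes the shrunken
coefficients, and back-rotates everything with one multiplication by `V`.
One SVD serves all targets; the achieved fractions land within ~1% of the
requested ones. For d > p the singular values can be obtained from the
p×p matrix XᵀX, saving memory.

## Worked example

```python
import numpy as np
from fractional_ridge import frr

rng = np.random.default_rng(0)
X = rng.standard_normal((50, 10))
y = rng.standard_normal(50)
sol = frr(X, y, [0.3, 0.7, 1.0])
print(sol.alphas[:, 0])              # alpha achieving each fraction
print(sol.achieved_fractions[:, 0])  # realized ‖β‖/‖β_OLS‖
```

Or from the shell, on a simulated scenario (100 data points, 5 correlated
z-scored predictors, 3 targets, noise SD matched to each target's signal
SD):

```sh
frr simulate --d 100 --p 5 --t 3 --seed 7 --out-dir demo
frr fit --design demo/design.tsv --targets demo/targets.tsv \
        --fracs 0:1:0.25 --split 0.5 --seed 7 --out-dir demo/fit
```

`demo/fit/alphas.tsv` then holds, for target 0:

```
target  fraction  alpha
0       0         inf
0       0.25      116.94709001097084
0       0.5       18.84516873981687
0       0.75      1.3246576458863433
0       1         0
```

— the ridge penalty that shrinks this target's coefficient norm to each
requested fraction (γ=0 needs an infinite penalty, γ=1 none). The matching
`achieved_fractions.tsv` shows the realized fractions (0.2493, 0.5007,
0.7495 for the interior requests — within the ~1% interpolation accuracy),
and `best_fraction.tsv` reports the γ with the best held-out R² per target:

```
target  best_fraction  best_alpha
0       1              0
1       0.75           0.24994266632572637
2       0.75           2.7848177884778065
```

Targets 1 and 2 generalize best with a mildly shrunken solution; note how
different α values (0.25 vs 2.78) correspond to the *same* interpretable
fraction 0.75 on different targets.

`frr compare` fits FRR and a conventional log-spaced-α ridge sweep on the
same simulated problem and writes a tidy table of train/test R²,
fractional norm, and effective degrees of freedom per regularization level
(add `--plot` for a summary figure).

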