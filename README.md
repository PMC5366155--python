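# methdecon

Reference-free deconvolution of DNA methylation data into latent
methylation components.

## The problem

Bulk DNA methylation profiles (e.g. Infinium 450k/EPIC beta values) measure
composite tissue: each sample is a mixture of cell populations, each with
its own near-binary methylome.  Cell composition varies between samples and
is a major confounder in epigenome-wide association studies (EWAS).  When
reference methylomes of purified cell types are unavailable, the mixture
has to be unmixed from the data alone.

`methdecon` models the observed CpG-by-sample beta matrix as

    D = T A + E,      D ∈ [0,1]^{m×n}

where the columns of `T ∈ [0,1]^{m×k}` are **latent methylation components
(LMCs)** — prototype methylomes, typically cell types — and the columns of
`A ∈ Δ^{k×n}` are per-sample mixture proportions on the probability
simplex.  The factors are estimated by minimizing the regularized
least-squares criterion

    min_{T,A}  ‖D − TA‖²_F + λ Σ_{i,s} T_is (1 − T_is)
    s.t.       0 ≤ T_is ≤ 1,   A_sj ≥ 0,   Σ_s A_sj = 1,

where the penalty ω(x) = x(1−x) vanishes at 0 and 1 and pushes component
profiles towards biologically plausible binary methylation states.  This
matters because the unregularized problem is ill-posed whenever the data
contain only mixtures: many component simplices fit equally well, and
unpenalized fits place components on the data cloud instead of at the true
vertices.  Optimization alternates an exact simplex-constrained
least-squares update of `A` with a concave–convex procedure (CCP) for the
box-constrained, concave-penalized update of `T`; the objective descends
monotonically.  Both `k` and `λ` are chosen by column-leave-out
cross-validation with a two-stage λ grid search.

Also included: matching of estimated components to reference profiles
(Pearson correlation, mutual-maximum matching with an ε score, combined
average-linkage clustering), selection of component-specific CpGs,
reference-based proportion estimation, a simulation framework with ground
truth, and EWAS adjustment for component proportions with Q–Q/genomic
inflation diagnostics.

## Worked example

```python
import numpy as np
from methdecon import (SimulationScenario, simulate_scenario,
                       MethylationDeconvolution, evaluate_recovery)

# three cell types, 60 samples, moderately variable proportions, low noise
ds = simulate_scenario(SimulationScenario(m=2000, n=60, k_sim=3,
                                          v=10.0, noise_sd=0.05, seed=1))

est = MethylationDeconvolution(n_components=3, alpha=0.01,
                               n_restarts=5, random_state=0)
est.fit(ds.D.values.T)          # sklearn orientation: samples x CpGs

rec = evaluate_recovery((est.components_.T, est.proportions_.T),
                        ds.T_true, ds.A_true)
print(f"matched-profile RMSE: {rec.rmse_T:.3f}")
print(f"proportion MAE:       {rec.mae_A:.3f}")
```

Output:

```
matched-profile RMSE: 0.028
proportion MAE:       0.007
```

The RMSE is computed over the entries of the estimated component profiles
after one-to-one matching to the ground-truth profiles (mutual-maximum
correlation); the MAE is over the matched mixing proportions.  Values near
zero mean the three prototype methylomes and their per-sample fractions
were recovered almost exactly despite every sample being a noisy mixture.

The same pipeline is available from the shell:

```
methdecon simulate --m 2000 --n 60 --k 3 --seed 1 --out sim/
methdecon select --input sim/D.tsv --ks 2:5 --lambdas auto --folds 10 \
    --restarts 50 --seed 1 --out fit/
methdecon evaluate --estimated-t fit/T.tsv --true-t sim/T_true.tsv --out eval/
```

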