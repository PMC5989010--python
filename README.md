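# netlr

Linear-response theory for spike-count correlations in heterogeneous,
recurrently coupled, conductance-based integrate-and-fire networks — and
the machinery to ask when pairwise correlation *increases* with firing
rate, and when it decreases.

## The problem

In many cortical recordings the spike-count correlation of a cell pair
grows with the pair's firing rates; in others it shrinks.  For recurrent
networks of leaky integrate-and-fire neurons with conductance synapses and
heterogeneous spike thresholds, this package computes the pairwise
correlation structure *without simulating*, by linear response theory, and
reduces the correlation–rate question to the geometry of two functions on a
two-parameter plane.

The pipeline:

1. **Network model.** E/I populations (default 80/20), log-normal threshold
   heterogeneity at equally spaced quantiles, fixed in-degree random
   connectivity, second-order alpha synapses, additive background noise
   (`netlr.network_model`).
2. **Effective cells and self-consistent rates.** Poisson shot-noise
   formulas map rates to conductance mean/variance; each cell becomes a
   one-dimensional diffusion with effective leak g₀ and reversal E_rev,
   solved by Fokker–Planck threshold integration; a damped fixed-point
   iteration closes the loop (`netlr.fokker_planck`,
   `netlr.self_consistency`).
3. **Correlations by motif expansion.**  With the interaction matrix
   K̃_ij(ω) = Ã_X,i(ω)J̃_ij(ω) + Ã_{σ²_X},i(ω)L̃_ij(ω), the spike-train
   cross-spectrum is C̃ = (I−K̃)⁻¹C̃⁰(I−K̃)⁻ᴴ, and its geometric expansion
   splits pairwise covariance into chains and common-input motifs of each
   order (`netlr.linear_response`).
4. **Correlation susceptibility.**  Since inhibitory common input dominates,
   Ŝ = (∂F/∂g_I)²/F computed on the reduced rate surface F(⟨g_I⟩, θ)
   predicts how correlation co-varies with rate along any path through
   parameter space: dŜ/dF = (∇Ŝ·dx)/(∇F·dx), and the fraction of directions
   with dŜ/dF > 0 is (π − arccos cosθ)/π for the angle θ between the two
   gradients (`netlr.surface_analysis`).
5. **Validation and surveys.**  A numba Monte Carlo simulator of the full
   network provides ground truth (`netlr.mc_simulator`); `netlr.survey`
   sweeps families of networks over recurrent-excitation strengths and
   background-noise levels.

## Worked example

```python
import numpy as np, netlr

net = netlr.network_from_config(netlr.preset_config("asynchronous"), seed=1)
sol = netlr.solve_network_rates(net)
summ = netlr.population_summary(net, sol)
print(f"E rate {summ.rate*1e3:.2f} Hz  <g_I> {summ.mean_gI:.3f}  "
      f"sigma_gI {summ.sigma_gI:.4f}  E_rev {summ.E_rev:.4f}")

corr = netlr.network_correlations(net, sol)
tab = corr.pair_table(net, pairs="EE")
from netlr.surface_analysis import motif_regression
r2 = motif_regression(tab["rho"], {k: tab[f"R{k}"] for k in (1, 2, 3, 4)})
print(f"rho(K) {corr.spectral_radius:.3f}  mean EE corr "
      f"{np.mean(tab['rho']):.4f}  R^2 by motif order {{1: {r2[1]:.3f}, "
      f"2: {r2[2]:.3f}, 3: {r2[3]:.3f}, 4: {r2[4]:.3f}}}")
```

prints

```
E rate 10.77 Hz  <g_I> 1.928  sigma_gI 0.6768  E_rev -0.3162
rho(K) 0.394  mean EE corr 0.0067  R^2 by motif order {1: 0.001, 2: 0.970,
3: 0.000, 4: 0.123}
```

Reading: the asynchronous-regime network settles at ~11 Hz excitatory
rates with a mean inhibitory conductance of 1.93 (dimensionless); the
interaction matrix is comfortably stable (spectral radius 0.39 < 1); E–E
pairs are weakly positively correlated (mean 0.0067), and second-order
motifs — dominated by shared inhibitory input — explain 97 % of the
variance in total pairwise correlation, far more than any other order.

A shell interface wraps the same pipeline:

```bash
netlr solve --preset asynchronous --out rates.csv --summary
netlr correlate --preset asynchronous --out corr.h5 --csv pairs.csv
netlr surface --preset strong_asynchronous --out surface.h5
netlr sweep --preset representative-16 --out sweep.csv
```

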