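# Methods

## The model

`netlr` analyzes recurrent networks of leaky integrate-and-fire (LIF)
neurons with conductance-based synapses.  Each cell obeys, below its
threshold θ_i,

    τ_m dv_i/dt = −v_i − g_E,i(t)(v_i − E_E) − g_I,i(t)(v_i − E_I)
                  + σ_i √τ_m ξ_i(t),

with a spike and reset to v = 0 on reaching θ_i, followed by an absolute
refractory period τ_ref during which the voltage is clamped at reset while
the conductances keep evolving.  Conductances are second-order alpha
functions: each presynaptic spike increments an auxiliary variable g⁽¹⁾ by
α̂ = α_X W_YX / N_YX, and two first-order filters with rise/decay times
τ_r,X and τ_d,X shape the conductance.  Voltage, conductances and reversal
potentials are dimensionless (threshold of order 1); times are in ms and
rates internally in spikes/ms (displayed in Hz).

Heterogeneity enters through per-cell thresholds placed at equally spaced
quantiles (CDF 0.05–0.95) of a log-normal distribution with mean 1 and
variance e^{cv²} − 1 (cv = 0.2), separately for the E and I populations.
The default populations are N_E = 80, N_I = 20 with 40 % (E→E), 35 % (I→E),
20 % (E→I) and 40 % (I→I) connectivity.

### Connectivity model

By default each cell receives exactly round(p · N_X) inputs of each source
type, drawn uniformly without replacement ("fixed in-degree").  With the
per-synapse normalization α̂ = α W / N_YX, this keeps α̂ uniform across the
population, and the population-averaged conductance statistics then satisfy
the homogeneous shot-noise identity σ_g = √(⟨g⟩ · α̂/2 · τ_r/(τ_r+τ_d))
exactly — the regime in which the reference operating points for the two
packaged presets are internally consistent.  Independent-Bernoulli
(Erdős–Rényi) connectivity is available via `degree_model="bernoulli"`; its
realized in-degree spread adds a Jensen bias of order +10 % to the
population-averaged conductance-noise SD through E[1/N] > 1/E[N].

## Effective single-cell reduction

Assuming presynaptic trains are Poisson at the network's self-consistent
rates, the stationary conductance moments are

    ⟨g_X⟩ = α̂_X ν_X τ_r,X,
    Var[g_X] = (α̂_X² ν_X τ_r,X / 2) · τ_r,X/(τ_r,X + τ_d,X),

with ν_X the summed incoming type-X rate.  Splitting each conductance into
mean plus fluctuation and treating the fluctuations as white noise gives the
effective diffusion

    τ_m dv/dt = −g₀(v − E_rev) + σ_gE ξ_E (v − E_E) + σ_gI ξ_I (v − E_I)
                + σ√τ_m ξ,

with g₀ = 1 + ⟨g_E⟩ + ⟨g_I⟩ and E_rev = (⟨g_E⟩E_E + ⟨g_I⟩E_I)/g₀.  The
multiplicative terms are interpreted in the Itô sense, so the Fokker–Planck
flux carries the voltage-dependent diffusion coefficient

    D(v) = [σ²τ_m + σ_gE²(v−E_E)² + σ_gI²(v−E_I)²] / (2τ_m²).

## Threshold integration

Stationary rates, susceptibilities and spectra are computed by integrating
first-order ODEs in voltage backward from threshold:

* **Rate.** The flux-normalized density q = D·p̂ obeys dq/dv = (μ/D)q − j
  with j = 1 between reset and threshold; ν = 1/(∫p̂ dv + τ_ref).  The
  recurrence uses exact constant-coefficient exponential steps evaluated at
  segment midpoints, which stay stable in the small-noise (stiff) limit.
* **Susceptibilities.** For a perturbation X → X₀ + X₁e^{iωt} of any of the
  four channels (⟨g_E⟩, ⟨g_I⟩, σ_gE², σ_gI²), the linearized system in
  (J₁, D·P₁) is integrated twice (boundary-driven and source-driven); the
  re-injected flux carries e^{−iωτ_ref}.  At ω = 0 the response is computed
  from stationary perturbation theory instead and equals dν/dX exactly
  (verified against central finite differences to <10⁻⁵ relative).
* **Spectrum.** The uncoupled process is renewal, so
  C̃⁰(ω) = ν(1−|F̃|²)/|1−F̃|² with F̃ the Fourier transform of the ISI
  density (refractory delay times the first-passage transform, computed by
  the same backward integration).  At ω = 0 two additional scalar passes
  give the first two passage-time moments, so C̃⁰(0) = ν·CV²; this moment
  machinery reproduces the exact OU double-quadrature formulas to <0.5 %.

**Grid.** Uniform, 1024 points by default, from an adaptive lower bound —
five effective voltage SDs below E_rev (capped at E_I − 0.5) — up to each
cell's threshold.  At the preset noise magnitudes (σ√τ_m ≈ 4.7–6.3) the
stationary density has a substantial additive-noise tail below E_I; a fixed
shallow bound truncates probability mass and biases rates upward by tens of
percent.  Doubling the resolution changes rates by <0.1 %; deepening the
bound from −3 to −10 changes preset solutions by <0.5 %.

## Self-consistent rates

The network fixed point ν = Φ(ν) (moments → effective cell → threshold
integration) is solved by damped iteration ν ← (1−γ)ν + γΦ(ν) with γ = 0.5,
relative tolerance 10⁻⁶, at most 500 iterations, initialized at the
uncoupled rates.  The voltage grid is resolved once from the uncoupled cells
and frozen for the whole solve; re-resolving the adaptive bound each step
perturbs Φ at the discretization level and stalls the residual near 10⁻³.
Rates approaching 95 % of the refractory bound 1/τ_ref raise an instability
error: such states are far outside the asynchronous regime the theory
assumes.  Population summaries average over E cells; the additive-noise
amplitude is reported as σ√τ_m, the form in which it enters the effective
equation.

## Linear response and the motif expansion

Each synapse contributes K_ij(ω) = Ã_{⟨g_X⟩,i}J̃_ij + Ã_{σ²_gX,i}L̃_ij with
the synaptic filter J̃(ω) = α̂τ_r/[(1+iωτ_r)(1+iωτ_d)] and the variance
filter L̃ = J̃·(α̂/2)·τ_r/(τ_r+τ_d).  The cross-spectrum is
C̃ = (I−K̃)⁻¹C̃⁰(I−K̃)⁻ᴴ; long-time spike-count Pearson correlations are the
ω = 0 cross-spectrum normalized by its diagonal.  Expanding the inverses
yields motif orders R^k = Σ_l K̃^l C̃⁰ (K̃ᴴ)^{k−l} (k_max = 4 by default).
The order-2 term splits into excitatory and inhibitory common input (by
source type) and correlating/decorrelating chains.  The chain classes are
assigned by the sign of each individual length-2 path's real ω = 0
contribution — the only self-consistent reading of "correlating" vs
"decorrelating", since at ω = 0 a path's sign is determined by the product
of its two susceptibility-weighted filter gains.  Fourier convention:
f̃(ω) = ∫f(t)e^{−iωt}dt, ω in rad/ms; all headline statistics are taken at
ω = 0 and are convention independent.

## Monte Carlo simulator

Euler–Maruyama integration of the full network at dt = 0.01 ms (a tenth of
the fastest synaptic rise time), spikes detected at step boundaries,
voltage clamped at reset during the refractory period while conductances
evolve, per-spike jumps of α̂ on the auxiliary conductance variable.
Spike-count statistics use disjoint windows (default T = 200 ms) with
unbiased sample moments; pairs involving a zero-variance count are flagged
undefined rather than zero.  The test suite's independent single-cell
reference simulator additionally applies the standard continuity correction
for discretely monitored first passage (threshold lowered by
ζ(½)/√(2π)·σ_loc·√dt), which removes the leading O(√dt) rate bias.

## Correlation susceptibility surface

Freezing all effective parameters except (⟨g_I⟩, θ) at their E-population
averages defines F(g_I, θ); the correlation susceptibility is
Ŝ = (∂F/∂g_I)²/F (units Hz per dimensionless g_I²), computed by centered
differences on a 61×61 grid spanning the log-normal 1–99 % threshold
quantiles and [0.5, 1.5]×⟨g_I⟩, masked where F = 0.  Straight-line paths
(bilinear interpolation) yield dŜ/dF = (∇Ŝ·dx)/(∇F·dx), guarded against
vanishing denominators; the fraction of directions along which Ŝ rises with
F is (π − arccos cosθ_align)/π with cosθ_align the gradient alignment.
Path-family names follow the plane as conventionally drawn with θ on the
horizontal axis: *horizontal* paths vary θ (the trajectory threshold
heterogeneity traces through the plane), *vertical* paths vary g_I.

A network's own Ŝ–F curve is the horizontal path at its population-mean
g_I.  These curves are non-monotonic (rising to a peak near 6–10 Hz and
declining beyond), so two slope summaries are reported: the fit over the
full curve, which separates the noise families (negative for the
asynchronous-noise family, positive for the strong-asynchronous one), and
the fit over the low-rate half, which captures the "increasing at low F"
behavior of the strong-asynchronous family.

## Surveys

`run_sweep` re-solves the pipeline over grids of (W_EE, W_IE) and
(σ_E, σ_I).  One connectivity realization is shared across all grid points
by default so that differences between rows reflect parameters rather than
graph resampling (per-point resampling is available).  σ values are stored
exactly as configured; the preset sweep grids span W_EE ∈ [0.5, 12.6],
W_IE ∈ [5, 11.2] and σ_E ∈ [1.5, 2.5], σ_I ∈ [1.5, 3].  Per-row failures
are recorded in an error column and never abort a sweep.  Mean E–E
correlation excludes self-pairs and averages unordered pairs.

## What the synthetic conditions do and do not show

All validation runs use networks generated by the package itself — there is
no external data.  Passing tests show that the linear-response machinery is
internally consistent (finite-difference, closed-form and quadrature
oracles), that it agrees with Monte Carlo ground truth of the same
generative model (per-cell rates to <10 % relative, ISI moments to a few
percent, mean pair correlations at the sampling-noise level), and that the
qualitative mechanism structure (dominance of second-order motifs and of
inhibitory common input; noise-controlled sign of the Ŝ–F trend) is robust
across the surveyed families.  They do not show that real cortical
recordings obey this model: synaptic delays, plasticity, spatial structure,
non-Poisson presynaptic statistics and non-lognormal heterogeneity are all
outside the generative model.

A statistical caveat worth stating explicitly: per-pair spike-count
correlations of order 0.01 cannot be resolved from 500 disjoint 200-ms
windows (sampling SE ≈ 0.045), so per-pair scatter comparisons at a 100 s
simulation budget are noise dominated; rank agreement between theory and
simulation becomes visible only at ~10× longer recordings (measured rank
correlation 0.84 at 1000 s on the small fixture network).

## Numerical choices and limitations

* Regression R² (motif dominance) is ordinary least squares with intercept,
  equivalent to squared Pearson correlation for a single regressor;
  constant regressors return NaN.
* Division guards: dŜ/dF masked below 10⁻¹²·max|∇F|; rates below 10⁻¹⁵
  spikes/ms are treated as silent in the spectral normalization.
* The spectral (ω > 0) solver uses RK4 with analytic coefficients; it is
  accurate for the moderate-noise cells the pipeline produces but is not
  protected against the stiff small-noise limit, where only the stationary
  (exponential-step) solver is reliable.
* Only one interneuron class, no synaptic delays, no bifurcation tracking
  of multiple fixed points; the damped iteration finds one fixed point and
  reports non-convergence rather than searching for others.
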