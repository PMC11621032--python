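# Methods

## The model

`circvelo` estimates RNA velocity for processes that live on a known
low-dimensional manifold — primarily the cell cycle, a closed loop. Every
cell `c` carries a latent angular coordinate (phase) `φ_c ∈ [0, 2π)`. The
expected spliced expression of gene `g` is a log-linear Fourier series in
the phase,

    log s_g(φ) = Σ_f ν_gf ζ_f(φ),   ζ(φ) = (1, cos φ, sin φ, …, cos kφ, sin kφ),

with `k = 1` harmonic by default (typical cycling genes are well described
by a single harmonic). Cells progress around the circle at an angular speed
`ω(φ) = νω · ζ(φ)` (linear parametrization; constant by default, one
harmonic optionally). Combining the first-order splicing/degradation
kinetics `ds_g/dt = β_g u_g − γ_g s_g` with the chain rule
`ds_g/dt = ω(φ) ds_g/dφ` gives the expected unspliced expression

    u_g(φ) = s_g(φ)/β_g · relu( ω(φ) Σ_f ν_gf ∂_φζ_f(φ) + γ_g ),

where the relu (realized as a clamp at `1e-5`) keeps the negative-binomial
mean positive where the inner term would transiently dip below zero.
Counts are negative binomial: `S_cg ~ NB(s_g(φ_c), α_g^s)`,
`U_cg ~ NB(u_g(φ_c), α_g^u)`, with per-gene inverse-shape dispersions
(variance `μ + αμ²`; `α → 0` is Poisson).

Only the ratio of the speed to the kinetic rates is identifiable: scaling
`β, γ, ω` jointly by a constant is a change of time units that leaves the
likelihood invariant. Speeds are therefore reported in radians per mean
half-life (rpmh) and converted to hours only under an assumed average
half-life.

## Two-stage inference

**Manifold learning** maximizes the ELBO of the spliced model over cell
phases, gene harmonics, per-batch offsets `Δν` to the zeroth harmonic
(first batch pinned to zero — except under transfer learning, where the
gene harmonics are frozen from a reference fit and every target batch
learns its own offset), and spliced dispersions. The phase latent is
a 2-vector `φxy_c` with prior `N(ε·(cos Φ_c, sin Φ_c), I)` — a
projected-normal construction whose angle is the phase; the concentration
`ε = 5` encodes prior confidence in the empirical phase ordering. `Φ_c`
comes from the angle of the first two principal components of log1p
depth-normalized spliced counts (each component min-max rescaled to
[−0.5, 0.5]), with the global rotation/reflection chosen over a 360-point
grid to maximize the Pearson correlation between the prior angle and total
counts. Per-gene priors are empirical Bayes:
`μ_ν = [log mean(S), 0, 0]`, `σ_ν = [std(S+1)/2, std/4, std/4]`
(floored at 0.01). The guide is mean-field: `N(loc, 1)` for `φxy` (phase
point estimate = atan2 of the location), diagonal normals for `ν`, point
masses for `α` and `Δν`.

**Velocity learning** freezes `φ`, `ν`, `Δν` at their manifold posterior
means and maximizes the ELBO of the unspliced model over `log β_g`,
`log γ_g`, `α_g^u` and per-condition speed coefficients `νω_t` (gene-level
parameters shared across conditions). Priors:
`νω ~ N(0, diag(3, 0.05, 0.05)²)` (zero speed a priori, tight harmonics),
`log γ ~ N(0, 0.5²)` (degradation timescales of order an hour — the
biological constraint that pins the scale gauge), `log β ~ N(2, 3²)`,
`α ~ Gamma(1, 2)`.

Guides:

* **mean-field** — independent normals / point masses;
* **LRMN** — `x = [log γ_1…log γ_G, νω…]` gets a multivariate normal with
  covariance `F Fᵀ + diag(d)` (rank 5), and `log β_g | log γ_g` is the
  standard bivariate-normal conditional with a per-gene correlation
  `ρ_g ∈ [0,1]` (sigmoid-parametrized). This captures the
  degradation-speed coupling a joint sampler finds, and thus wider, more
  honest speed intervals. (The source description of this conditional
  scales both the shift and the sd by the *location* of `log β`, which can
  be negative; we use the dimensionally consistent textbook form.)
* **MCMC** — a No-U-Turn sampler over `(log β, log γ, νω, log α)`,
  initialized at the SVI posterior means with the SVI posterior scales as
  diagonal mass matrix; defaults 2,000 warm-up, 500 kept draws, 1 chain,
  divergences counted and warned above 5%.

## The SVI engine

No probabilistic-programming framework is available in this environment,
so the ELBO and its gradients are implemented directly in numpy
(`_engine.py`): single-sample reparametrized Monte Carlo for the
likelihood term, analytic KL terms for the normal and projected-normal
blocks, the closed-form NB gradient `∂loglik/∂log μ = Y − (Y+r)μ/(r+μ)`
(`r = 1/α`), and a per-gene histogram trick that evaluates the
`digamma(Y+r)` sums over distinct count values rather than all
cells × genes entries (exact, ~10× cheaper). The optimizer is Adam with
per-parameter gradient-norm clipping at 10 and a geometric learning-rate
decay from 0.03 to 0.005 across the run; 5,000 steps for manifold
learning and 10,000 for velocity learning by default. All hand-derived
gradients are validated against central finite differences and scipy's
`nbinom` in the test suite. An optional early-stopping rule (stop when the
mean loss over the last 100 iterations is within 5 units of the mean over
the last 10) is implemented but **off by default**: at ELBO magnitudes of
~10⁶ the rule fires long before the speed parameter has converged, so the
benchmarks use fixed step counts.

Large matrices are float32 with preallocated scratch buffers; parameters
and reductions that feed Adam are float64. The log-mean is clipped at ±25
as an overflow guard.

## The structured simulator

Per gene, `(ν0, ν1cos, ν1sin, log β, log γ)` are drawn from one
multivariate normal whose correlation matrix encodes r = 0.05 among the
three harmonic coefficients, r = 0.30 between `log β` and `ν0`, and
r = 0.30 between `log β` and `log γ` — without this structure, independent
draws routinely produce biologically implausible unspliced/spliced ratios.
Marginals: `ν0 ~ N(1, 1)` (log-count scale), `ν1 ~ N(0, 0.5)`,
`log β ~ N(0.7, 0.5)`, `log γ ~ N(0, 0.35)` (keeping `1/γ` mostly within
0.5–1.5 h); dispersions `α ~ Gamma(1, 2)`, mirroring the model prior.
Phases are i.i.d. uniform on `[0, 2π)`; counts are gamma-Poisson draws
from the model expectations. Zero-velocity contaminants ("noncycling"
cells) share the gene program but sit at a nuisance phase with `ω = 0`,
so their counts obey `u = s·γ/β`.

What the simulator does **not** emulate: per-cell sequencing-depth
variation (no size factors), ambient RNA, doublets, non-uniform phase
occupancy (real populations pile up in G1), gene-gene coexpression beyond
the phase, or phase-dependent kinetic rates. A green recovery test
therefore establishes correctness of the inference machinery under the
model's own assumptions, not robustness to these real-data violations
(contamination robustness is probed separately).

## Posterior analysis

* **Scaled speed**: each posterior draw of `νω` is multiplied by that
  draw's mean degradation timescale over genes. Default convention is the
  mean lifetime `mean_g(1/γ_g)` ("lifetime"); `mean_g(ln2/γ_g)`
  ("halflife") is available. The lifetime convention makes the simulator's
  nominal speed an rpmh value up to the lognormal correction
  `exp(sd²/2) ≈ 1.06`, keeping simulated truths and reported speeds on one
  scale; with the physical-half-life convention every reported speed
  would shift by ln 2.
* **Period**: per draw, the trapezoidal integral of `1/ω_scaled` over a
  20-point phase grid spanning `[0, 2π]` (exact for constant speed),
  converted to hours by the assumed mean half-life (default 1 h); mean and
  5–95% percentiles over 500 draws; draws with non-positive speed anywhere
  on the grid are excluded and counted.
* **Delays**: per-gene difference between the spliced and unspliced peak
  phases, wrapped to `(−π, π]`; closed form `atan2(b1, a1)` for one
  harmonic, dense-grid argmax otherwise; genes with first-harmonic
  amplitude below `1e-3` are flagged as having no defined peak. For weak
  single-harmonic genes with constant speed, `tan(delay) ≈ ω/γ`.
* **Point estimate**: the conditions × genes matrix of tan-delays is
  approximately rank-1 (`ω_c · τ_g`); the leading singular triple, oriented
  so the gene vector has positive mean, gives `ω*_c = u_c d v̄` in inverse
  mean lifetimes and `T*_c = 2π/ω*_c`.
* **Comparisons**: per-condition 5–95% intervals of the scaled speed, the
  interval of the per-draw difference (strict exclusion of zero =
  "significant"), and the overlapping coefficient of the two empirical
  distributions on a shared 50-bin histogram.

## Orientation and alignment

The circle has no preferred origin or direction. Against a known truth,
`align_to_truth` resolves both gauges in closed form (the rotation
maximizing circular correlation is `−arg mean e^{i(±φ̂−φ)}`), transforming
phases, phase locations and harmonics consistently; circular correlations
are only meaningful after this step. Without a truth, the pipeline
reflects the fitted manifold whenever the constant-speed posterior mean
is negative — an exact gauge transformation — so reported speeds are
positive.

## Interval model

For nonperiodic 1D processes the Fourier basis is replaced by cubic
B-splines (dimension 5) over a fixed pseudotime on `[0, 10]`, built by the
Cox–de Boor recursion on clamped uniform knots (base-case intervals
half-open, closed at the global right endpoint, preserving the partition
of unity; verified against scipy's design matrix). The speed is a scalar
with prior `N(0, 3²)`; spline coefficients get `N(0, 3²)`. Stage 1 (2,000
steps) fits the spline surface conditioned on pseudotime; stage 2 (6,000
steps) fits kinetics and the speed. Pseudotime is always an input — the
package never computes it.

**Limitation**: conditioning stage 2 on the stage-1 posterior mean makes
the slope `Σ w ∂B` an error-in-variables regressor; on small datasets
(≲1,000 cells) the estimation noise measurably attenuates the recovered
speed. The same mechanism exists in the periodic model but is negligible
at benchmark sizes because the harmonic posteriors are much tighter.

## Numerical choices

relu clamp `1e-5` (keeps `log u` finite with informative gradients);
log-mean clip ±25; `σ_ν` floor 0.01; guide scales initialized at 0.1 and
all guide locations at the prior means (zero speed start); LRMN factor
init `0.01·N(0,1)`, `ρ` init 0.5; alignment tie-breaks prefer the
unreflected orientation; posterior sample count 500 and credible
percentiles 5/95 throughout; every stochastic entry point takes an
explicit seed (default 0).

## Known limitations

Mean-field speed intervals understate uncertainty relative to LRMN/MCMC
(by design of the comparison); manifold uncertainty is not propagated into
velocity learning (conditioning is on posterior means); kinetic rates are
phase-independent; MCMC runs a single chain with only divergence counting
as a diagnostic; the bundled gene-set files are synthetic placeholders —
supply curated lists for real analyses.
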