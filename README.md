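# circvelo

**Manifold-constrained RNA velocity on a circular cell cycle coordinate.**

Classical RNA velocity treats every gene independently and struggles to
produce interpretable, quantitative rates. `circvelo` instead constrains
the dynamics to a known one-dimensional periodic manifold — the cell
cycle — and turns spliced/unspliced single-cell UMI counts into
biologically meaningful quantities with full posterior uncertainty:

* a cell cycle **phase** `φ_c ∈ [0, 2π)` for every cell,
* per-gene **Fourier harmonics** `ν_g` describing log expected spliced
  expression around the cycle,
* per-gene **splicing and degradation rates** (`β_g`, `γ_g`) and
  negative-binomial dispersions,
* the **angular speed** `ω(φ)` of progression around the cycle, hence the
  **cell cycle period**, and Bayesian comparisons of speed between
  conditions.

It is intended for computational biologists analyzing scRNA-seq data with
spliced/unspliced layers (velocyto/kallisto-style), and for methodologists
who want a fully generative, testable velocity model.

## The model in brief

With `ζ(φ) = (1, cos φ, sin φ, …)`:

    S_cg ~ NB(s_g(φ_c), α_g^s),            log s_g(φ) = ν_g · ζ(φ)
    U_cg ~ NB(u_g(φ_c), α_g^u),            u_g(φ) = s_g(φ)/β_g · relu(ω(φ) ν_g·∂_φζ(φ) + γ_g)

which follows from `ds_g/dt = β_g u_g − γ_g s_g` and the chain rule along
the manifold. Inference is two-stage stochastic variational inference
(implemented from scratch in numpy — no deep-learning framework needed):
**manifold learning** fits phases and harmonics from spliced counts;
**velocity learning** fits kinetics and speed from unspliced counts,
conditioned on the manifold. Guides: mean-field, a low-rank multivariate
normal (LRMN) that captures the degradation–speed posterior coupling, and
a NUTS sampler for exact joint posteriors. Because only the ratio of speed
to kinetic rates is identifiable, speeds are reported in **radians per
mean half-life (rpmh)** and converted to hours under an assumed average
half-life. A structured simulator (correlated gene programs, uniform
phases, gamma-Poisson noise) provides ground truth for every latent
variable, and a B-spline variant handles nonperiodic 1D trajectories.

## Worked example

```python
import circvelo as cv
from circvelo import manifold as mfl, velocity as vel, posterior as pst

data, truth = cv.sample_dataset(n_cells=1500, n_genes=200, omega_gt=0.4, seed=2)

priors = mfl.init_priors(data)                      # empirical-Bayes priors
man = mfl.fit_manifold(data, priors, seed=2)        # 5,000 SVI steps
man = mfl.align_to_truth(man, truth.phi)            # resolve rotation/reflection

fit = vel.fit_velocity(data, man, model="constant", seed=2)   # 10,000 steps
speed = pst.scaled_speed(fit.samples)               # rpmh draws
est = pst.period(fit.samples, mean_half_life_hours=1.0)
```

Running `python examples/03_velocity_and_period.py` (the script above)
prints:

```
posterior-mean angular speed: 0.477 (truth 0.4)
percent error: 19.3%
gamma/beta ratio recovery, Pearson r: 0.9963
scaled speed: 0.458 rpmh [0.455, 0.461]
cell cycle period: 13.7 h [13.6, 13.8] at an assumed 1 h mean half-life
statistical support for nonzero velocity: True
```

meaning: the constant angular speed is recovered within ~20% of the
simulated truth at this modest dataset size (errors shrink toward ~10% at
the 3,000 × 300 benchmark scale), the per-gene degradation/splicing
ratios are essentially exact, and a cycle traversed at ~0.46 radians per
mean half-life takes 2π/0.46 ≈ 14 hours if the average transcript
half-life is one hour. The
other scripts in `examples/` each demonstrate one capability: the
structured simulator, manifold learning and its credible-interval
calibration, mean-field vs LRMN uncertainty, unspliced–spliced delays and
the closed-form SVD period estimate, the B-spline interval model, and
two-condition speed comparison.

## Reading real data

`circvelo.io.read_dataset` accepts loom (layers `spliced`/`unspliced`),
AnnData `.h5ad`, or paired MatrixMarket files, plus gene-set text files
and the standard QC filters (mean-count thresholds, expectation-curve
correlation, delay floor). The bundled small/medium/large gene-set files
are synthetic placeholders with the conventional sizes — supply curated
lists for real analyses.

## Benchmarks

`scripts/acceptance.py` re-runs the package's simulation benchmarks from
scratch: it generates structured simulations, runs manifold and velocity
learning at the benchmark sizes, and measures phase recovery (circular
correlation), credible-interval calibration, harmonic and kinetic-ratio
recovery, speed errors at and across ground-truth velocities, and
robustness to small datasets and to noncycling-cell contamination:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The run takes roughly 15–20 minutes on one CPU and writes one JSON object
with a value per benchmark.
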