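# vergebayes

Bayesian modelling of absolute distance perception from ocular convergence.

Humans converging their eyes on an object receive, through the physical
orientation of the eyes, a signal that maps one-to-one onto the object's
absolute distance — yet behavioural studies consistently find that far
distances are *underestimated* even when convergence itself is accurate.
`vergebayes` implements a probabilistic observer model that explains this
bias without appeal to priors or response bias: the observer simply reports
the most likely distance to have caused a noisy (but unbiased) vergence
measurement.

## The model

For fixation on the median plane, the half-vergence angle is
`θ_F = atan(h / D_F)` with `h` half the interocular separation (default
6.5 / 2 = 3.25 cm) and `D_F` the fixation distance in cm. The measured angle
is an unbiased, truncated-Gaussian-corrupted reading of the true angle:

    θ̂ ~ N(θ_F, σ²)  restricted to  0 < θ̂ < π/2.

Because `D = h / tan θ` is nonlinear, the induced posterior over distance
(flat distance prior) is the change-of-variables push-forward

    p(D | θ̂) = TN(atan(h/D); centre, σ) · h / (h² + D²),

which is positively skewed: a symmetric angular error produces a larger
overestimation than underestimation error in centimetres. The estimate then
depends on the loss function — quadratic loss → posterior mean
(overestimates), absolute loss → median (nearly unbiased at near
distances), zero-one loss (ε → 0) → posterior peak / MAP, which
*underestimates progressively* with distance and noise, matching the
behavioural literature.

The package covers, module by module:

* `geometry` — vergence angles, distance inversion, retinal disparity,
  disparity scaling and scaling distance;
* `likelihood` — the truncated-normal measurement model, its inverse-CDF
  sampler, the distance posterior (pdf/cdf/quantiles) and the
  over/underestimation asymmetry;
* `estimators` — mean / median / peak estimators, their risks, and the
  MAP-versus-distance curve;
* `response_sim` — trial-level Monte-Carlo response distributions and their
  fitted-density peaks over a noise-by-distance grid;
* `noise_inference` — the ordinary-least-squares quadratic peak surface and
  the positioning of a behavioural dataset along its noise axis (the
  inferred vergence noise σ̂);
* `priors` — vergence-prior transforms, the distance density implied by a
  flat vergence prior, the "internalised" prior, and a synthetic
  sphere-scene sampler of binocularly visible world distances;
* `synthetic_data` — seeded generators and packaged fixtures emulating a
  manual distance-matching experiment.

## Worked example

```python
import numpy as np
from vergebayes import (
    DEFAULT_GEOMETRY, DistancePosterior, VergenceNoiseModel,
    half_vergence_from_distance, posterior_mean, posterior_median,
    posterior_peak, peak_grid, fit_surface, infer_sigma, fixture,
)

noise = VergenceNoiseModel.from_degrees(1.0)
for D in (30, 50, 100):
    post = DistancePosterior(
        half_vergence_from_distance(DEFAULT_GEOMETRY, D), noise)
    print(f"D={D:>3} cm  peak={posterior_peak(post):6.2f}  "
          f"median={posterior_median(post):6.2f}  mean={posterior_mean(post):6.2f}")

grid = peak_grid(np.arange(0.25, 1.76, 0.25), np.arange(20, 101, 10),
                 n_trials=10_000, seed=1)
surface = fit_surface(grid)
print(f"surface R^2 = {surface.r_squared:.4f}")
res = infer_sigma(surface, fixture("viguier_like_sigma079"))
print(f"sigma_hat = {res.sigma_hat_deg:.3f} deg  (data R^2 = {res.r_squared_data:.3f})")
```

prints

```
D= 30 cm  peak= 28.57  median= 30.00  mean= 30.86
D= 50 cm  peak= 44.31  median= 50.00  mean= 54.86
D=100 cm  peak= 70.93  median= 97.93  mean=123.43
surface R^2 = 0.9948
sigma_hat = 0.764 deg  (data R^2 = 0.996)
```

At one degree of vergence noise the posterior peak underestimates 100 cm by
nearly 30 cm while the mean overestimates it; the simulated peak grid is
described almost perfectly by a quadratic surface; and a packaged synthetic
dataset generated at σ = 0.79° is positioned on that surface at
σ̂ ≈ 0.76° — parameter recovery through two independent code paths.

The same operations are available from the shell, e.g.

```
vergebayes estimate --sigma-deg 1.0 --distance-cm 50 --loss peak
vergebayes simulate --n-trials 10000 --seed 1 --out peaks.csv
vergebayes infer-noise --grid peaks.csv --data my_estimates.csv
```

Behavioural data files are plain CSV with header
`distance_cm,estimate_cm,sd_cm` (`sd_cm` optional, `#` comments allowed).

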