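# Methods

## Measurement model and posterior

The observer's proximal signal is the half-vergence angle
`θ_F = atan(h / D_F)`; the measured angle `θ̂` is modelled as
`N(θ_F, σ²)` truncated to the physically possible range `(0, π/2)`. The
truncated normal is implemented through the CDF-ratio construction (normal
pdf divided by the support mass), which is the distribution the definition
`θ̂ ~ N(θ_F, σ²)` on a bounded domain forces; no closed erf expression is
transcribed. Sampling is by inverse CDF, which is robust across the whole
σ range, and every sampler takes an explicit seed — there is no hidden
global RNG state.

The posterior over distance under a flat distance prior is the
change-of-variables push-forward through `D = h / tan θ`, with Jacobian
`h / (h² + D²)`. One notational subtlety is resolved explicitly: the
truncation constant of the truncated normal can be anchored either at the
distribution's **centre** (giving the exact push-forward density of
`h / tan θ̂`, with closed-form CDF and quantiles) or at the **candidate**
angle being scanned (the form that arises when the per-trial posterior
formula is read with the candidate's own angle inside the constants). Both
parameterisations are implemented (`truncation="measured" | "candidate"`);
they coincide wherever the support boundary is many σ away from the centre,
which holds for near-to-intermediate distances, and diverge mildly at far
distances where a few percent of Gaussian mass would fall at negative
angles. Estimators default to the measured anchor (closed-form CDF);
the trial-level simulator defaults to the candidate anchor, the per-trial
reading.

Quadrature over distance is always performed by substituting back to the
angle domain, turning a half-infinite integral into a smooth bump on a
finite interval; adaptive quadrature with absolute tolerance ~1e-11 then
reaches the 1e-6…1e-8 normalisation accuracy the tests assert.

## Estimators

* **Mean** (quadratic loss): conditional expectation over a configurable
  distance range, default 10–600 cm — roughly the nearest comfortable
  fixation through to the distance beyond which vergence carries almost no
  signal. The range matters and is therefore exposed: widening it only ever
  increases the mean (the skewed far tail), never produces underestimation.
* **Median** (absolute loss): medians are invariant under the monotone
  transform, so the median is `h / tan` of the truncated-normal median —
  closed form, no search. Note that once the zero-angle boundary is within
  ~2σ of the centre (beyond ~1 m at σ = 1°), the truncated-normal median
  shifts above the true angle and the distance median falls measurably
  below the true distance (−2% at 100 cm, −8% at 140 cm at σ = 1°): "the
  median is nearly unbiased" is a near-to-intermediate-distance statement.
* **Peak / MAP** (zero-one loss, ε → 0): in the angle domain the log
  posterior is `−(θ−θ̂)²/(2σ²) + 2 log sin θ (− log Z(θ))` and its
  stationarity condition is monotone for the measured anchor, so the peak
  is found by vectorised bisection on the derivative (~90 iterations,
  exact to machine precision); candidate-anchor correction terms join the
  same bracketing search. Peaks outside the distance bounds are returned at
  the bound. A dense-grid argmax serves as the test oracle. With ε > 0 the
  estimator maximises the posterior mass of the ±ε interval and reports the
  interval midpoint.

Ties on flat plateaus cannot arise for σ > 0 (the derivative condition is
strictly monotone); degenerate inputs (non-positive distances, angles
outside the support, ε < 0) raise rather than clip.

## Response distributions

One simulated trial draws `θ̂ᵢ`, builds the posterior centred on it, and
records its peak; the across-trials distribution of these per-trial peaks
is the response distribution, which is *not* the same object as any single
posterior. It is summarised by a smooth density whose mode ("peak") is the
most likely estimate an observer would give across trials. Default
smoother: Gaussian KDE with Silverman bandwidth; alternative: maximum
likelihood over {log-normal, gamma, skew-normal} selected by BIC. The two
agree to within a few percent — smoothing bias on strongly skewed
far-distance batches reaches ~3–4%, so the parametric family is a
description of the data, not part of the model. Default 10⁴ trials per
condition keeps the full 7 × 9 grid under ten seconds while the fitted
peaks are stable to well under a centimetre (their scatter shrinks as
n^(−1/2)); 10⁵ reproduces the higher-precision setting. Grids derive one
child seed stream per cell from a single root seed, so results are
independent of evaluation order; per-cell trial files can be cached to
delimited text.

## Noise inference

Simulated peaks over the canonical grid (σ = 0.25…1.75° in 0.25° steps,
D = 20…100 cm in 10 cm steps) are summarised by an OLS quadratic surface in
(σ, D) — terms 1, s, d, s², d², sd — a deliberately simple *description*
(R² ≈ 0.995 at 10⁴ trials/cell), fixed by design rather than selected. A
behavioural dataset is positioned along the σ axis by minimising the
unweighted sum of squared differences between its reported estimates and
the surface at the data's own distances (per-datapoint interpolation; σ is
continuous, not restricted to simulated grid values). A 1/sd² weighting is
available behind a flag, off by default. Minima at the edge of the
simulated σ span are flagged as boundary solutions. Single-prediction 95%
intervals come from the standard OLS prediction-variance formula and widen
toward grid edges.

One structural property deserves emphasis: the surface predicts the
response distribution's *peak*, while behavioural tables usually report
per-distance *means*. Because per-trial reports are positively skewed, mean
rows sit above peak rows, and σ inferred from mean-summarised data is
systematically lower (by ~0.25–0.35° in the 0.5–1.5° range) than the
generating noise. The synthetic generator therefore exposes both summaries
(`summary="mean"`, the published data form and the default;
`summary="peak"`, the quantity the surface predicts). Parameter recovery is
essentially unbiased with peak summaries (mean error ≤ 0.035°, every one of
20 replicates per condition within ±0.25° at σ* ∈ {0.5°, 1.0°, 1.5°}) and
carries the documented downward bias with mean summaries; the bias
direction is itself asserted by a test. Any σ inferred from real mean±SD
data should be read with this in mind.

## Priors

The distance density implied by a flat vergence prior on `(a, b)` is
`h / ((b−a)(h² + D²))` on the image of the interval (the sign convention is
fixed so the density is positive; normalisation forces it). For `a = 0,
b = π/2` it integrates to one exactly and decreases strictly with distance.
Sampling inverts the transform (uniform angles mapped through
`h / tan θ`), and a χ² test of uniformity of the mapped-back angles is part
of the acceptance checks.

The "internalised" prior pushes world distances through the
physical-to-perceived mapping; the default mapping is the noise-free MAP
curve at the requested σ (the response-peak slice of the fitted surface can
be passed as a custom callable instead). Because the MAP underestimates far
distances, the mapped sample's mean and upper quantiles contract toward
near space, and some physically present far distances disappear from the
internalised distribution.

## Synthetic scenes and data

The scene sampler is a deliberately simplified, fully synthetic stand-in
for a corpus of scanned natural objects: spheres with radii drawn from
1.5–4 cm (bounding radii typical of hand-scale produce, and feasible for
sequential non-overlap placement of 14 objects on a 35 cm square plane)
rest on the floor plane; a scene in which placement fails is discarded and
redrawn. Points are sampled uniformly on each sphere; a point contributes
its cyclopean radial distance only if the open segment to *each* eye
(interocular 6.5 cm, observer 8 cm above and 60 cm back from the plane
centre) is unobstructed by every sphere, its own included. The sampler's
contract is statistical (an empirical world-distance sample with occlusion
structure), not mesh fidelity; per-sphere sampling density is a parameter.

The behavioural-data generator emulates a manual distance-matching design:
distances 20–100 cm in 10 cm steps, many trials per distance, per-distance
summary rows. Defaults: σ = 0.79° (the noise level such data imply under
this model), 1000 trials per distance (per-distance summary sampling error
well below the effects under study), no report noise. Optional additive
report noise (zero-mean Gaussian in cm, truncated so responses stay
positive) exists purely to stress-test inference robustness and is not part
of the estimation model. The generator finds per-trial peaks by a dense
grid scan with parabolic refinement — intentionally a different route from
the estimation pipeline's bisection optimiser, so that parameter recovery
exercises two independent implementations that share only the geometry and
measurement model. What passing recovery shows is that the pipeline
recovers the noise of data generated *by this model*; real data add report
noise, memory demands, cue conflicts and per-observer heterogeneity that
the generator deliberately omits.

## Known limitations

* Vergence noise is a single fixed σ; distance-dependent or non-Gaussian
  noise is out of scope.
* The posterior always uses a flat distance prior; the priors module
  analyses transforms of priors but never feeds them into estimation.
* Version ≠ 0, vertical disparity, torsion, and nodal-point eye geometry
  are not modelled; the general off-median vergence case is provided but
  all downstream analyses use the median-plane case.
* The quadratic surface is descriptive; extrapolating it outside the
  simulated (σ, D) grid is refused (distances) or flagged (σ at the span
  edge).
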