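# Methods

`tipcast` predicts where a forced dynamical system will tip — the value of a
slowly ramped forcing parameter μ at which the system abruptly leaves its
current attractor — from two observed channels: one state variable sampled
(possibly irregularly) in time, and the forcing parameter at the same
instants. This note records the model conventions, the numerical choices,
and what the synthetic experiments do and do not establish.

## The tipping observable

For a system dx/dt = f(x, μ) drifting along a quasi-static attractor x*(μ),
the recovery rate is

    λ = max Re eigvals( ∂f/∂x ),

evaluated **along the simulated trajectory** (not on the static equilibrium
branch). λ < 0 on a stable attractor; the tipping point μ_c is the parameter
value at the first negative-to-positive crossing of λ, located by linear
interpolation between consecutive evaluations. Because the trajectory lags a
moving equilibrium, this crossing overshoots the static bifurcation value —
rate-delayed tipping. For a ramped fold normal form ẋ = αΔμ + βΔx², Δμ̇ = r,
the crossing overshoot has the closed form 1.0188·(αβ)^(−1/3)·r^(2/3) (the
1.0188 is the first zero of Ai′; the better-known 2.338, the first zero of
Ai, governs the later blow-up instead). The package reproduces this law to
four digits (see the fold-delay tests), which pins down both the labeling
convention and the ramp-rate convention below.

## Training-system library (`syslib`)

Training data come from random planar cubic vector fields

    dx/dt = Σ aᵢ pᵢ(x,y),  dy/dt = Σ bᵢ pᵢ(x,y),
    p = (1, x, y, x², xy, y², x³, x²y, xy², y³),

with standard-normal coefficients, exactly half of the twenty zeroed at
random, and the eight cubic coefficients forced nonpositive (bounded
trajectories). A system is kept if forward Euler (dt = 0.01, 10⁴ steps)
settles — final ten states within 10⁻⁸ — after which the equilibrium is
Newton-polished.

Bifurcations are found by pseudo-arclength continuation with Newton
correction (replacing a dedicated continuation package; adequate for planar
cubics): every nonzero coefficient is continued in both directions; the
first sign change of λ along the branch is classified as

* **hopf** if |Im| of the crossing eigenvalues exceeds 10⁻⁶,
* **fold** if the branch's μ-progression reverses inside the bracket,
* **transcritical** otherwise (degenerate ties are discarded).

μ_static is refined by bisection along the branch (Hopf, transcritical) or
by Newton on the extended system (f = 0, det J = 0) (fold; bisection in μ is
impossible where the branch folds back). On the three analytic normal forms
the classifier is exact and |μ_static| < 10⁻⁸. All bifurcations of a system
may enter the library, with provenance, until each type's quota is met; the
record keeps the starting equilibrium of its branch so that ramps later
start on the correct attractor of a multistable system.

## Ramped simulations and labels (`simulate`)

Noisy paths use Euler–Maruyama (dt = 0.01); per step the state gains
σ√dt·ξ (white) or an AR(1) stream η with lag-1 coefficient φ and per-step
innovation sd = sd_red·√(1−φ²)·√dt (red; the source specifications give
φ ∈ (−1,1) but no red amplitude, so sd_red defaults to 0.01 matching the
white scale). Training draws σ from triangular(0.0075, 0.01, 0.0125), φ from
U(−1,1), and mixes white and red instances evenly. A 100-time-unit burn-in
at fixed μ precedes every ramp and is discarded.

The label of a noisy path is the λ-crossing of its **noise-free twin** —
never the noisy path's own (stochastic, premature) escape point. Paths whose
twin never crosses before the terminal μ are discarded.

**Ramp geometry.** Each (system, bifurcation) pair gets a base rate that
spans the distance from the original coefficient value to the static
bifurcation (plus a 50% overshoot margin) in 200 time units; five distinct
integer multipliers from {1..10} scale it per simulation. 200 time units
(2·10⁴ steps) mirrors the pre-tipping segment lengths implied by the
benchmark systems' ramp rates (about 10³–10⁴ steps), so training and test
series share their sampling-correlation regime; it also keeps a
10,000-instance corpus tractable on one CPU.

**Irregular sampling.** ls ~ U{505..1000} indices are drawn uniformly
without replacement from the pre-tipping segment, sorted, and truncated to
the first 500; the draw is repeated until the relative distance
(μ_c − μ_end)/(μ_end − μ_0) lands in [0.01, 2]. The distribution of μ_end
consequently follows the 500th-order-statistic law of the ls uniforms
(property-tested against direct simulation of that law).

## Preprocessing (`preprocess`)

Order: Lowess detrend → zero-pad → normalize.

* Detrending: locally weighted linear regression, span 0.2, one robustness
  iteration, with the *index position* as abscissa (the architecture treats
  samples as a sequence; sampling times are not an input).
* Padding: a prefix of length U{0..250} is zeroed in both channels
  (training-time length augmentation); records shorter than 500 are
  right-aligned the same way. Padded entries stay exact zeros — a "missing"
  token — and are excluded from all normalizations.
* Residual channel: divided by the mean |residual| of the live part.
  Parameter channel: affinely mapped so the live part runs 0 → 1 regardless
  of ramp direction. Label: label_norm = 1 + (μ_c − μ_end)/(μ_end − μ_0eff),
  constrained to [1.01, 3] by redrawing the pad length (the pad shortens the
  visible ramp and so raises the label).
* The relative error of a prediction is ε = |μ̂_c − μ_c| / |μ_end − μ_c|.

## Predictor (`predictor`)

A two-row convolution kernel of width d (default 10) scans both channels
jointly — d plays the role of the delay-embedding dimension, so d > 2m is
needed for an m-dimensional system — then ReLU, local max pooling, an LSTM
over the pooled feature sequence, and a dense scalar head. The ablation
feeds the raw 2×500 sequence straight into the LSTM. Training minimizes MSE
on label_norm with Adam (gradient-norm clipping at 5); predictions are
ensemble-averaged, clipped to [1.01, 3], and denormalized through the exact
inverse of the label rule, so a prediction always lies beyond the observed
ramp.

The reference hyperparameter table of the source work is not available;
defaults (50 filters, pool 2, 64 LSTM units, lr 5·10⁻⁴, batch 64, 200
epochs, ensemble 10, split 0.95/0.04/0.01) are exposed in `ModelConfig`, and
`DESK_CONFIG` (24 filters, pool 4, 24 units, lr 2·10⁻³, batch 256, 20
epochs, ensemble 3) sizes a single-CPU run. The network itself is
implemented in NumPy (im2col convolution, BPTT, float32), which keeps the
package dependency-light and fully deterministic given a seed.

**What desk-scale training shows — and does not.** At the reference scale
(300,000 instances, 200 epochs, ten networks) the source work reports mean ε
near 9% (23% for the ablation). At desk scale (3,000 instances, 20 epochs,
ensemble of 3) our held-out mean ε is far higher (order 1), and extensive
probing — gradient-boosting on envelope/autocorrelation features, parametric
fits of the critical-slowing-down variance law v(μ) ∝ (μ_c − μ)^(−p), and
capacity/epoch sweeps — plateaus at the same level. Under the stated noise
conditions the per-instance signal that survives detrending and amplitude
normalization appears to cap desk-scale accuracy near that level, most
severely for instances whose series end close to the tipping point (the ε
denominator → 0.01 of the window). The suite keeps a regression test
asserting mean ε < 0.25 at desk scale as an honest record of this gap; it
currently fails, while the architecture contrast (CNN-LSTM below the
ablation) holds. The deterministic pipeline (labels, delays, benchmark
ground truths) is validated independently of predictor skill.

## Early-warning baselines (`baselines`)

All three operate on sliding windows (default: half the series, step 1;
windows are linearly detrended) of regularly sampled records; irregular
records are first linearly interpolated onto a uniform grid.

* **Degenerate fingerprinting**: lag-1 autocorrelation of the leading
  principal component (the series itself when univariate); critical value 1.
* **BB estimator**: with AR(1) driving noise, the observed series is AR(2):
  x_{t+1} = (a+φ)x_t − aφ x_{t−1} + ε. Yule–Walker gives both roots; the
  larger is the system multiplier a (the mode that slows down), and
  λ = ln(a)/dt with critical value 0. When sampling noise merges the roots
  (negative discriminant) the repeated root φ₁/2 is used. This removes the
  upward bias of the naive ln(r₁)/dt under red noise.
* **DEV**: locally weighted linear one-step maps in a delay embedding
  (S-map weighting exp(−θ·dist/d̄), θ = 0 → one global map per window);
  indicator is the dominant-eigenvalue modulus of the fitted companion
  matrix; critical value 1.

Indicator series are extrapolated to their critical value by linear and
quadratic least squares in μ; the nearest real crossing beyond the observed
range in the ramp direction is taken from the fit with the larger in-sample
R² ("better performance" is not defined in the source; both candidates are
always reported). Crossings farther than 20 observed ranges are treated as
non-predictions.

## Benchmark systems (`benchmark`)

Eight named systems with published constants and tipping locations; λ uses
each model's analytic Jacobian (verified against finite differences).

**Rate conventions.** The five-rate systems (harvesting, food chain,
consumer–resource, ocean, glacial-cycle, vegetation) only reproduce their
published tipping intervals when the quoted "changing rate" is read as the
parameter increment **per Euler step**; the two hysteresis systems
(arousal, Sprott B) require the literal per-unit-time reading. Both
conventions were confirmed numerically to 3–4 digits (harvesting
0.2713/0.2922 vs 0.2713/0.2926; arousal 1.153/0.883 and Sprott
1.461π/1.539π exactly) and are stored as effective per-unit-time rates.

**Reconstructions.** Two models' published constants do not close:

* The ocean energy-balance model has no equilibrium with the printed
  I₀ = 7.1944·10⁷; with I₀ = 7.1944·10⁸ (a dropped digit; also the value
  demanded by the underlying radiative balance) a fold appears at
  u ≈ 0.968 vs the published [0.9596, 0.9631] (~0.6% off). It is kept as a
  calibration case only.
* The vegetation (TRIFFID) model's published negative-productivity
  crossing [−0.0061, −0.0046] is reproduced (to [−0.0061, −0.0047]) by
  evaluating λ with the *unfloored* Jacobian P(1−2V) − G along the
  floored-field trajectory: with the per-step rate reading the ramp outruns
  the slow relaxation near P ≈ G, V stays near its upper branch, and λ
  crosses at P ≈ −G/(2V−1). The floored variant sits behind a switch.

**Protocol.** Test sets follow the 11-initial-values × 5-rates ×
10-replicates grid; instance lengths are drawn from [250, 500] (first-L of
ls ~ U{505..1000} index draws, relative distance constrained to [0.01, 2]);
each instance carries the noise-free μ_c of its own (initial value, rate).
Starting states are carried adiabatically along the experiment's branch
from the direction's base initial value — settling directly at a later
initial value can land on the wrong attractor of a hysteretic system.
Aggregation reports mean ε and the 5th–95th percentile band per
(model, initial value, method); baseline non-predictions are recorded as
missing.

## Known limitations

* The generator emulates additive stationary noise on planar polynomial
  systems; multiplicative noise, measurement noise, missing data and
  non-autonomous forcing beyond a linear ramp are out of scope, so green
  tests here say nothing about such data.
* Trajectory-evaluated λ can cross marginally *before* the static value for
  Hopf systems (the state spirals around, not on, the equilibrium); the
  delay-positivity checks allow a 2% early margin for that reason.
* Desk-scale predictor skill is limited as discussed above; conclusions
  about the architecture contrast (CNN-LSTM vs LSTM) at reference scale
  cannot be drawn from desk-scale runs.
* The continuation handles codimension-one local bifurcations of planar
  systems only; period-doubling, global bifurcations and higher dimensions
  are out of scope.
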