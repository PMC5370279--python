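# Methods

This note documents the model, the numerical choices, and the synthetic
data conditions used throughout `statewell`, including the places where a
design question was genuinely open and how it was resolved.

## Model

The behavioral observable x(t) (rescaled active-sensing rate, unitless;
inactive median 0, active median 1) follows an overdamped Langevin
equation in a quartic double-well landscape

    U(x,t) = a(t)(x-1/2) + b(t)(x-1/2)^2 + c(t)(x-1/2)^4 .

The symmetric part is parameterized by the well depth h (< 0, measured
from the barrier) and separation d between the barrier and either
minimum: b = 2h/d^2, c = -h/d^4, which places the minima at 1/2 +/- d
with depth exactly h. Tilt a(t) and separation d(t) are affine images of
a slow latent variable s(t); the map is anchored at the observed extrema
of s(t), so the y-intercept of any prescribed latent profile is
irrelevant. Latent values outside the anchored range are clipped rather
than extrapolated (the anchors *are* the observed extrema, so
out-of-range queries only arise from user-supplied trajectories). Depth
h is stored signed exactly as in the shipped parameter tables.

Two shipped parameter sets (unitless; D in 1/s-scaled units, dt in s):

| parameter | Fish A | Fish B | meaning |
|-----------|--------|--------|---------|
| h         | -0.08  | -0.32  | well depth below barrier |
| d1, d2    | 0.3, 0.6 | 0.5, 0.5 | separation at latent extrema |
| a1, a2    | 0.12, -0.1 | 0.07, -0.1 | tilt at latent extrema |
| D         | 0.02   | 0.1    | noise intensity |
| dt        | 0.01   | 0.01   | integration step |

With Fish A values the landscape is bistable over the entire latent
range (the saddle-node tilt at d = 0.3 is ~0.41, well above |a| = 0.12),
so deterministic trajectories never switch; all switching is
noise-activated. The Kramers estimate for the symmetric Fish A well,
tau = 2 pi / sqrt(U''_min |U''_max|) * exp(-h/D) ≈ 68 s, serves as a
closed-form oracle for the simulator.

## Fixed points

Stationary points solve the depressed cubic U'(x) = 0 in closed form
(trigonometric branch for three real roots, Cardano for one), with an
absolute tolerance of 1e-10 on the discriminant so the root count is
deterministic at saddle-nodes. A vectorized variant classifies whole
coefficient time series at once; monostable instants carry a NaN
unstable point.

## Langevin integration

Euler–Maruyama with dt = 0.01 s:
x_{n+1} = x_n - U'(x_n, t_n) dt + sqrt(2 D dt) z_n. The latent is
sampled by nearest-time lookup (it varies on ~1000 s scales, so sub-step
interpolation is irrelevant and lookup keeps runs bitwise reproducible).
The state is never clamped — the quartic confines it, and a non-finite
state raises an error naming the step, because silent clamping would
bias residence-time statistics. Ensembles use consecutive seeds
(seed, seed+1, ...). A separate joint-evolution routine advances many
states under one RNG stream and records only snapshot marginals; it is
the memory-light route to distributional comparisons, not to per-member
paths.

Crossing alignment (for event-locked analyses of simulations) accepts a
downward crossing of the instantaneous unstable point only after the
state has spent 5 s continuously in the active basin, yielding one stamp
per realization even when noise recrosses; detection is suspended while
the landscape is monostable. Exactly at D = 0 no crossing ever occurs in
a tilting scenario: critical slowing keeps the lagging state above the
merging stable/unstable pair until the pair vanishes. The deterministic
limit is therefore exercised at vanishing noise, where the stamp
concentrates at the saddle-node time.

## Fokker–Planck solver

Conservative finite volumes on a uniform grid (reference configuration:
1000 cells of width 0.004 on [-2, 2]), fully implicit Euler at the same
dt = 0.01 s, advective face flux upwinded by the sign of -U', diffusive
flux from a linear profile between cell centers, tridiagonal solves
(LAPACK `dgtsv`). Landscape coefficients are evaluated at the current
step (explicit in coefficients, implicit in the density): they vary on
the slow latent timescale, so the lag is O(dt) and the system stays
tridiagonal. Boundaries are zero-flux; the column sums of the implicit
operator are identically one, so mass is conserved to solver roundoff at
every step, and the operator is an M-matrix, so nonnegative data stays
nonnegative. The initial condition "all mass at x = 1" is realized as a
single-cell discrete delta; smoothing choices wash out within a few
steps.

Donor-cell upwinding is first-order accurate: its numerical diffusion
biases the *steady state* by about Pe/2 = |U'| dx / (2D) in relative
terms, an L1 deviation from exp(-U/D)/Z of 2.3e-2 at dx = 0.004 for the
symmetric Fish A well (halving dx halves it). This is immaterial for the
transient tilting scenarios the solver exists for, but for applications
that need the equilibrium density exactly, `scheme="exponential"`
switches the face flux to exponential fitting (Chang–Cooper /
Scharfetter–Gummel weights), which reproduces the Boltzmann steady state
to ~1e-4 on the same grid. The default remains upwind.

## Segmentation

Thresholds derive from the raw signal histogram: 100 equal-width bins,
counts smoothed with a 5-bin moving average, the two most populated
local maxima and the minimum between them located; the Schmitt-trigger
thresholds are the halfway points between the minimum and each maximum
(binning is a free choice; the smoothing makes extremum search robust).
Crossings are evaluated on a *centered* 1 s moving average of the signal
(a causal filter would lag every stamp by half the window) with
sub-sample linear interpolation of crossing times. Hysteresis makes
detected events strictly alternate by construction; incomplete leading/
trailing states are discarded. Detection is invariant under affine
rescaling of the signal since the thresholds are histogram-derived.

When the rescaling anchors themselves must be estimated, a provisional
segmentation of the movement channel supplies the active/inactive labels
whose medians map to 1 and 0; segmentation may then be re-run on the
rescaled signal. This resolves the circular dependence between
rescaling and state labels.

## Per-state features

For each active state [onset, offset): f1 amplitude (mean over the 30 s
after onset minus baseline), f2 duration, f3 mean, f4 variance of the
least-squares-detrended signal, f5 time to first return to baseline
after offset (capped at the next onset and flagged). The baseline is the
mean over [onset-30 s, onset-5 s]; the last 5 s are excluded because of
the short preparatory rise that precedes transitions. Two windowing
guards keep f1 a valid amplitude when states crowd together, as they do
under the Fish B parameters (median active duration ~20 s): the
post-onset window is capped at the offset (otherwise the following
inactive period dilutes f1 for any state shorter than 30 s, mechanically
coupling f1 to f2), and the baseline window is clipped at the previous
offset (otherwise the preceding active state inflates the baseline
whenever the inactive gap is shorter than the window, producing spurious
negative amplitudes). States whose inactive gap is under 5 s carry no
usable baseline and are skipped. Correlation analyses between f1 and f2
are reported over states with f2 >= 30 s, where the full window applies
uniformly; shorter states carry a fixed ~0.5 s transition-edge bite
whose 1/f2 relative effect is a property of the detector, not of the
latent coupling under study.

PCA standardizes the five features first (they carry wildly different
units, and only the correlation-based decomposition yields comparable
loadings across features); PC1 is oriented so its loading sum is
positive. Shape groups of 20 states each sample the PC1 axis: the top
20, the bottom 20, and the 20 lowest-scoring states at or above 4/5,
3/5 and 1/6 of the maximum score (topped up from just below a threshold
when fewer than 20 qualify, so the boundary case of exactly 20 states is
well defined). The within-state slope is deliberately not a feature.

## Latent estimation

The estimated latent is a centered moving average of the signal with
window W = 4 (<T_act> + <T_inact>); edges use shrinking windows so the
endpoint extrema (which anchor the latent map) are not biased. The
filter is linear, hence affine-equivariant. When a model run is driven
by a latent estimated from the same data, agreement at timescales beyond
W is guaranteed by construction and is excluded from any validation
claim.

## RTD fitting

The empirical density is a Gaussian KDE of log-durations (Silverman
bandwidth w) mapped back with the 1/t Jacobian — the standard
positive-support construction. Two exact corrections are applied during
fitting. First, a log-scale Gaussian kernel is a lognormal kernel on the
linear scale and inflates the first moment by exactly exp(w^2/2); the
mean <t> is the KDE integral divided by that factor (the uncorrected
integral is biased +10–15% at a few hundred samples). Second, the
1-D grid search for the stretch exponent (alpha in 0.05…2.0, step 0.005,
bracketing every empirically relevant value with margin) minimizes the
integrated squared difference only over t >= the smallest observed
duration: the log-scale KDE vanishes at the origin by construction while
every alpha < 1 candidate has its maximum there, so including the
unsupported near-zero region drags the fitted exponent upward (measured:
0.5 -> ~0.6 at n = 500). With both corrections, 500 draws at alpha = 0.5
are recovered within +-0.1 and the mean within a few percent.

Goodness of fit is a two-sample Kolmogorov–Smirnov test against an
equal-size seeded sample from the fitted law, drawn exactly as
t = (<t>/b) G^{1/alpha} with G gamma-distributed (shape 1/alpha) — a
change of variables shows these are exact draws from the fitted density.
Near-exponential data leaves a +-0.06 single-fit scatter in the
exponent even at n = 2000, so summary exponents are averaged over a few
independent sessions or draws where a single number is reported.
Bootstrap bands are percentile bands over KDEs of resampled duration
sets. Sessions are always fitted separately, never pooled.

## Transition-triggered densities

Aligned segments (half-window 250 s by default; a 300 s figure-style
window is a parameter away) are cut into 5 s bins; each bin pools all
samples from all traces (10,000 values per bin at 20 traces and 0.01 s
sampling) and carries a Gaussian KDE over the signal axis, without a
positive-support transform since the signal can be negative. The
event sample sits exactly at relative time 0. This conditioned density
is intentionally never compared with the Fokker–Planck solution of the
same scenario: the two are conditioned on different events (a transition
at t = 0 versus the initial state).

## Synthetic data

The generator defines the study conditions for every pipeline test:

- **Latent**: an Ornstein–Uhlenbeck process with correlation time tau
  (default 2000 s, well separated from both the within-well ~1 s and the
  switching ~10–100 s timescales), exact discrete update, mapped onto
  its bounds through its own Gaussian CDF. The copula map gives a
  uniform marginal — the latent actually visits the range endpoints that
  anchor the affine shape map — and attenuates autocorrelation by only
  (6/pi) asin(rho/2) vs rho, about 4%. sigma = 0 yields the
  constant-latent (stationary) control at the midpoint.
- **Sessions**: the signal is a Langevin run under the chosen parameter
  set; ground-truth transitions are defined *before* any detector is
  judged, as changes of the noise-free basin membership (which side of
  the instantaneous unstable point; the surviving basin during
  monostable phases) debounced with a 1 s refractory. The movement
  channel is the debounced membership indicator, smoothed over 1 s, plus
  Gaussian observation noise of sd 0.05 — cleanly bimodal yet
  non-trivial for the Schmitt trigger. Typical session lengths are
  2x10^4–2.4x10^5 s, chosen to yield from a few hundred to ~1300
  analyzable states depending on the check.
- **Templates**: piecewise-linear states whose extracted features equal
  their targets exactly (a variance target is realized by a seeded,
  state-demeaned perturbation), used for feature-extraction closure.
- **Stretched-exponential sampler**: the exact gamma-transform draw
  described above, the oracle for the fitting machinery.

What the generator does *not* emulate: the elevated within-state
fluctuation variance of real recordings (f4 is noise-driven and
homogeneous here), the 1–4 s preparatory rise before movement onset, and
the slow asymmetric decay shapes that would require a second dynamical
variable. Pipeline tests passing on synthetic sessions therefore
demonstrate correctness of the machinery under the model's own
assumptions, not fidelity of the model to any particular recording.

## Known limitations

- The default upwind Fokker–Planck steady state carries the O(Pe/2) bias
  quantified above; use the exponential-fitting scheme when equilibrium
  accuracy matters.
- The stretch-exponent estimator inherits KDE smoothing bias; exponents
  from single small sessions scatter by ~+-0.08 near alpha = 1.
- Amplitude (f1) is not meaningful for states much shorter than its
  30 s averaging window; analyses here filter such states rather than
  redefine the window.
- The 1-D model cannot produce different approach/departure paths for a
  state (that requires two dimensions); offset-locked and onset-locked
  analyses are therefore treated independently.
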