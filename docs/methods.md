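# Methods

## Data model and conventions

A trial is one stimulus sweep condition: 1 s blank, 1 s static grating,
3 s of grating motion, with spike times stored relative to the trial's
blank onset and the epoch schedule stored explicitly per trial. Stimulus
speed is always derived as temporal frequency / spatial frequency and
bucketed to the nearest nominal protocol speed in log2 (the stimulus
grids only approximate the printed speeds, e.g. 16 Hz / 0.0155 cpd =
1,032.3 °/s is the nominal 1,024 °/s condition). All rate windows are
half-open `[start, end)`. Directions are stored in the analysis frame
where 0° is temporal-to-nasal motion; an optional per-dataset angular
offset (default 0°, settable to 20° for recordings made in a pitched
stereotaxic frame) is applied at read time.

The spontaneous rate is the mean rate in the 500–1,000 ms window of the
static epoch over all trials — late enough that the stimulus-onset
transient (≤ 200 ms) has decayed. Tuning metrics default to the full
0–3,000 ms motion window; a config switch (`motion_window=(0.04, 3.0)`)
restricts them to 40–3,000 ms for consistency with the temporal analyses,
since the texts defining the mean-rate metrics say only "over the motion
epoch".

Suppressed (negative) spontaneous-subtracted rates are floored at zero
inside PD, SI and AP/PD: the vector-sum formulas presuppose nonnegative
rates, and suppression is infrequent in this preparation. Signed rates
are preserved for the normalized directional response.

## Tuning-curve fit and peak counting

The 8-point tuning curve is periodized by tripling the data over
[−360°, 720°) and fitting a natural cubic regression spline with 7 or 8
degrees of freedom per period (so df = 8 on 8 distinct directions
near-interpolates). Peaks are circular local maxima of the dense (1°)
curve with prominence ≥ 10% of the curve range; a constant curve has
zero peaks. Both the prominence threshold and df are configurable, since
the original procedure names the peak-finding function but not its
parameters.

## Two-stage classification

Stage 1 assigns one of three shapes. The canonical deterministic rule is:

- **directional** — SI > 0.2 with ≤ 1 prominent peak, or with 2 peaks
  whose height ratio exceeds 2;
- **bidirectional** — exactly 2 peaks, SI ≤ 0.2, and inverse CV < 3;
- **omnidirectional** — everything else (including flat curves flagged
  with infinite inverse CV).

The inverse-CV condition in the bidirectional branch exists because a
near-flat curve's spline fit can carry exactly two noise-ripple peaks
while its prominence still clears 10% of a small range; a genuinely
bidirectional curve has large between-direction variance (inverse CV
≲ 1), whereas flat-but-responsive curves sit far above 3. This is the
same reasoning that makes inverse CV the informative feature for
omnidirectionality in the boosted model.

The boosted classifier (XGBoost, small grid over learning rate, depth,
rounds and subsampling, repeated 5×5-fold CV, fixed seed) is trained on
rule-labeled most-active responses plus 100 random modulated responses,
mirroring a manual-labeling workflow; the rule classifier remains the
test oracle, and both labels are recorded for audit. On the default
population the two agree on ~95% of responses.

Stage 2 reclassifies a response as unmodulated iff (1) fewer than six
directions have per-sweep motion rates significantly different from the
per-trial spontaneous-window rates (two-sided Wilcoxon rank-sum, α =
0.05, uncorrected — a nonparametric choice appropriate for ≤ 10 sweeps;
test family and α are config), and (2) SI ≤ 0.29, boundary inclusive
(the worked boundary case with SI exactly 0.29 is reclassified). Where
the narrative appears to allow either "fewer than six significant" or
"not significant in more than six", the cutoff consistent with the
worked examples (< 6 significant) is the default and the cutoff is a
config parameter. Stage 2 only ever moves labels *toward* unmodulated.

**Known limitation.** The SI ≤ 0.29 bound cannot recover *pure-noise*
responses: after flooring, the SI of zero-mean noise on 8 directions is
scale-invariant and concentrates near 0.45–0.5, so only ~24% of truly
unresponsive conditions pass condition (2). Unmodulated responses in
real recordings are typically weak-but-positive omnidirectional
elevations (for which SI is small), not pure noise; for the synthetic
unmodulated archetype (zero motion gain) recovery is therefore ~18% and
is reported but not asserted. Misclassified noise responses land almost
entirely in the omnidirectional class.

## Synthetic population

Each cell is an inhomogeneous Poisson process with intensity

    r(t, θ, v) = spont + G_dir(θ; pd, κ(v)) · G_speed(v)
                        · [A_IT(v)·α(t) + sustained_gain·σ(t)]

- `G_dir` — von Mises bump normalized to peak 1 (equal-weight mixture of
  two opposite bumps for bidirectional cells; weight configurable);
- `κ(v) = κ₀ · decay^{max(0, log₂(v / v_c))}` — concentration decays
  multiplicatively per octave *above* the center speed only. Applying
  the decay below the center would sharpen tuning without bound toward
  slow speeds (κ ≈ 256 at 4 °/s for decay 0.25), making off-grid
  preferred directions invisible to the 45°-spaced protocol; physiological
  tuning widths are roughly stable at slow-to-intermediate speeds and
  broaden toward fast ones, which the capped form reproduces;
- `G_speed(v) = peak_gain · exp(−log₂²(v/v_c) / 2σ_v²)` — log-Gaussian
  speed tuning;
- `α(t)` — alpha-function transient peaking at
  `latency(v) = latency_base − latency_slope·log₂ v` (floored at 10 ms),
  with speed-dependent amplitude `A_IT(v) = it_gain · (v/v_c)^{slope}`;
- `σ(t) = 1 − e^{−t/150 ms}` — saturating sustained envelope.

Spikes are drawn by thinning against a per-trial intensity ceiling
(exact for bounded intensities; no binning artifacts); blank and static
epochs fire at the spontaneous rate. Per-cell random streams derive from
(master seed, cell index), so populations extend without disturbing
existing cells. Trial order is randomized within each sweep.

Ground-truth per-speed labels come from the noiseless rate model: a
condition whose best-direction mean modulation is below 5 spikes/s (the
inclusion bound) is truly unmodulated; otherwise the deterministic rule
applied to the noiseless tuning curve defines the label. With the
default parameters this reproduces the archetype rules exactly (e.g. the
directional-to-omnidirectional archetype is directional at ≤ 64 °/s and
omnidirectional above).

Defaults (versioned in `population_defaults.yaml`): 114 cells, 48 on the
wide six-speed protocol and 66 on the dense ten-speed protocol, 10
sweeps; archetype counts 36 dir→omni / 32 directional / 24
omnidirectional / 12 bidirectional / 10 unmodulated, matching the
across-speed category counts reported for this preparation (the
bidirectional/unmodulated split within the 22-cell "variable" group is
our choice); spontaneous rate 4–8 spikes/s, peak gain 10× spontaneous
(a high-SNR regime), κ₀ ≈ 4, speed centers mostly 32 °/s (population
speed tuning peaks at 32–64 °/s), speed σ 2.5–3.5 octaves, dir→omni
decay 0.25/octave (transition between 64 and 128 °/s), latency ≈ 180 −
14·log₂v ms and transient-gain slope ≈ 0.3/octave (time to peak falls
monotonically with speed; the initial-transient phase peaks at a faster
speed than the steady state). About 65% of directional-family cells
prefer temporal-to-nasal motion (0° ± 22.5°), yielding a TN-directional
cohort near the reported 44/114.

What the generator does *not* emulate: adaptation and biophysics, eye
movements, correlated noise across trials or cells, stimulus-onset
transients outside the motion epoch, and suppression below baseline.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under Poisson variability at realistic rates — not robustness to
every property of real recordings.

## Population analyses

`Rₙ` divides each cell's signed, spontaneous-subtracted rates by its
maximum absolute response over all speeds and directions (idempotent;
all-zero cells are flagged). Across-speed categories over the four
common speeds (4, 32, 256, 1,024 °/s) use precedence rules —
(1) dir→omni: directional at 32 and omnidirectional at 256;
(2) mostly-directional: directional at 32 and at 4 or 256;
(3) mostly-omni: omnidirectional at 32 and at ≥ 2 of the other three;
(4) variable: remainder — which partition every fully-labeled cell.
Precedence (1) > (2) resolves the overlap for cells directional at both
4 and 32 that become omnidirectional at 256. The temporal-to-nasal
cohort is defined by circular PD distance from 0° ≤ 22.5° (half the
sampling step); the PD-stability zone is ±22.5°, boundary inclusive.
These predicates are narrative in origin and are exposed in config.

## Temporal dynamics

Responses are binned at 10 ms aligned to motion onset (final bin
[2,990, 3,000) ms), spontaneous-subtracted, and normalized per cell by
the maximum absolute bin rate over all speeds, directions and bins. Time
to peak is the center of the first maximal bin within 40–3,000 ms (ties
to the earliest bin; flat traces flagged), computed without smoothing —
a boxcar option exists but is off by default. Phase activities are bin
maxima within IT/TR/SS, which partition the full-time window exactly.
Two scopes are computed throughout: the across-direction mean trace and
the trace at the tested direction nearest the PD at that speed.

## Additive-model comparison

Three candidate families describe speed trends in `Rₙ`, `log₂ timeₚ`
and `activityₚ` (the latter two in both scopes, excluding unmodulated
responses). Smooths are cubic B-splines (basis dimension 10, second-order
difference penalty, sum-to-zero constrained), random intercepts are
ridge-penalized per-cell dummies, and smooth-by-factor terms are
per-level smooths sharing one penalty. Two numerical choices matter and
were made after the obvious alternative failed a designed validation:

1. **Shrinkage (double-penalty) smooths.** The difference penalty leaves
   a linear null space, so a spurious smooth retains one unpenalized
   degree of freedom and wins against the simpler model in ~16% of
   null replicates. A second ridge penalty on the null space lets a
   spurious smooth vanish entirely.
2. **Marginal-likelihood smoothing selection with marginal AIC.** With
   GCV-chosen penalties and conditional (edf-based) AIC, a spurious
   random-intercept term absorbs noise (edf 12–20) and *lowers* AIC on a
   large fraction of replicates — the standard double-use problem of
   selecting λ and comparing models with the same conditional criterion.
   Penalties are instead chosen by maximizing the profiled Gaussian
   marginal likelihood (penalized blocks treated as random effects with
   variance σ²/λ), and candidates are compared by marginal AIC
   (−2 log ML + 2·[unpenalized coefficients + variance parameters + 1]),
   with the standard ΔAIC < 2 parsimony convention (among candidates
   within 2 AIC units of the minimum, the simplest is selected).

Under this scheme, data simulated from each candidate's own generative
form select that candidate in ≥ 49/50 seeded replicates at n = 500 in
every family. Absolute AIC values are backend-specific; candidate
*ranks* are the meaningful output, and reports also carry R², RMSE and
residual SD (all recomputable from stored residuals). Degenerate fits
are flagged, never silently dropped; factor levels with < 3 observations
warn. Predictions set random intercepts to zero (population level) and
carry pointwise 95% intervals; grid points outside the fitted speed
range are flagged as extrapolation.

## Problem sizes

The default study is 114 cells × (6 or 10 speeds) × 8 directions × 10
sweeps ≈ 73,000 trials (≈ 4 million spikes), which runs end to end in
well under a minute plus ~15 s for boosted-model training. The
selection-sanity experiment fits all candidates of all three families on
50 replicates of n = 500 per generating form (~2,000 fits, a few
minutes). These sizes were chosen to match the study's own scale while
keeping a full run interactive.
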