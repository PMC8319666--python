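# Methods

## The behavioral model

A single adult *C. elegans*, recorded alone at 1 frame/s for 30 minutes,
is described by a hidden state S_t ∈ {quiescence Q, dwelling D, roaming
R} evolving as a first-order Markov chain, observed through the animal's
centroid speed. The observation model is Gaussian on
y_t = log(speed_t + ε): each state has a log-speed mean μ_s and sd σ_s,
and the states are identified purely by speed, labeled by ascending
emission mean (μ_Q < μ_D < μ_R). ε (default 0.01 px/s) keeps the
transform finite for perfectly still frames and is stored with the
fitted parameters.

Speed-only emissions are the minimal identifiable choice. Roaming is
also distinguished by path straightness in the field's descriptions; a
heading-based feature would be a natural extension, and the emission
interface is the single place it would plug in. Until then, roaming
detection leans entirely on its speed separation from dwelling.

Transition **rates** are first-order hazards, analogous to rate
constants of first-order chemical kinetics: r_ij is the per-second
tendency to switch from state i to state j. Rates convert to per-frame
probabilities linearly, p_ij = r_ij/f with f the frame rate. At f = 1 Hz
and the rate scale of this assay (2×10⁻⁴ … 5×10⁻² s⁻¹) the linear and
matrix-exponential conversions differ by less than the estimators can
resolve, and linearity makes the count-based estimator
(below) the exact maximum-likelihood inverse of the generator.

## Fitting and decoding

Baum–Welch (EM) pools expected counts across all sequences of an
experiment; sequences of equal length run as one vectorized recursion.
All recursions are scaled per step, so 10⁵-frame sequences pose no
underflow risk. Initialization is deterministic ("quantile"): pooled
observations are split at terciles, each tercile's mean/sd seeds one
emission component; A starts at 0.95 self-transition, π uniform. Optional
seeded random restarts perturb the initial means. Iteration stops at a
relative log-likelihood improvement below 1e-6 (default) or 500
iterations; σ is floored at 1e-3 to prevent variance collapse; the
iteration trace is returned so EM's monotonicity guarantee can be checked
(tests allow 1e-8 numerical slack). After convergence states are
relabeled by ascending mean. Viterbi decoding breaks ties toward the
lowest state index; posteriors come from forward–backward smoothing.

The screen protocol fits **one model per experiment on the concurrent
control group**, freezes it, and decodes both control and treated
animals with it. This guarantees treated/control comparability — a
treated group with distorted behavior never distorts the model that
scores it. Per-animal fitting is available behind a flag but is not the
default: a 30-minute session frequently contains no roaming at all, and
a 3-state fit on two-state data degenerates (the spare component splits
one of the occupied states — the usual degenerate-mixture behavior of
EM). The same failure mode appears rarely (~2% of replicate fits) even
for pooled control groups when roaming frames are very scarce; the
screen layer flags the resulting near-zero control means as "unstable"
rather than reporting extreme ratios.

## Per-animal readouts

* **Percent time**: per-state frame counts over valid frames; sums to 1
  by construction and is invariant to how the session is cut into
  segments.
* **Transition rates**: rate[i][j] = (# decoded i→j steps) / (time in
  state i counting only frames with a decoded successor). Excluding each
  segment's last frame from the denominator makes this the exact MLE of
  the discrete chain; multiplied by occupancy it reproduces the integer
  transition counts. Rates are reported in s⁻¹ (per-frame probability ×
  frame rate); a state never occupied yields missing (not zero) rates,
  and the diagonal is zero by convention. No transition is ever counted
  across a tracking gap.
* **Bouts**: maximal single-state runs; duration = run length / frame
  rate. Runs truncated by the session ends or a gap are flagged censored
  and excluded from mean-duration summaries by default. For a Markov
  chain, mean uncensored bout duration equals 1/(summed exit rates) —
  the geometric holding-time identity the tests verify to 10% on
  10⁵-frame simulations.

## Screen statistics

Normalized values are ratios of arithmetic group means
(treated / concurrent control), per metric. Controls spend ~1% of time
roaming, so roaming ratios divide by near-zero means; metrics whose
control mean falls below a floor (0.5 percentage points for percent
times, 1e-4 s⁻¹ for rates) are flagged "unstable" with the value
withheld. The significance test is the classical pooled-variance
two-sided Student's t on per-animal percent-time values (df = n₁+n₂−2);
the Bonferroni family defaults to 2 × (number of genes) — one dwelling
and one quiescence comparison per gene — with the per-comparison
threshold α/m kept exact internally and displayed to 4 decimals (0.05/56
→ 0.0009). Raw p-values are reported alongside the threshold rather than
adjusted. Two ratio rules classify the normalized quiescence value: a
symmetric ±20% band (reduced < 0.8, enhanced > 1.2) and an asymmetric
0.6/1.7 cutoff pair. Ratio class and t-test significance are reported as
separate columns; no fusion rule is imposed. Whether normalized rates
should be ratios of group means or means of per-animal ratios is
genuinely open; ratio-of-means is implemented for consistency with the
percent-time normalization.

## The synthetic generator

The generator is the model run forward, plus kinematics and rendering:

* **Chain**: initial state drawn from the stationary distribution (no
  burn-in artifacts in short sessions); default control rates
  r(D→Q) = r(Q→D) = 0.02 s⁻¹ (balanced dwelling/quiescence switching,
  ~50 s mean bouts), r(D→R) = 0.001, r(Q→R) = 0.0002 (the control
  regime's printed values), r(R→D) = 0.05, r(R→Q) = 0.005 (chosen to
  keep roaming rare, ~1% occupancy, with ~16 s bouts). All overridable.
* **Kinematics**: per frame the displacement to the next frame depends
  on the current state. Roaming moves at exp(N(μ_R, σ_R)) px/s along a
  persistent heading with 0.15 rad/frame angular diffusion; dwelling
  moves at exp(N(μ_D, σ_D)) and reverses heading with probability ½ per
  frame (back-and-forth movement — cosmetic, since the HMM sees only
  speed); quiescence displaces by isotropic Gaussian jitter of sd
  0.15 px (centroid noise, not locomotion). Positions reflect at the
  arena walls, inset by the worm radius.
* **Emissions**: defaults μ_Q = −1.9 (the jitter floor, ~0.15 px/s),
  μ_D = log 2 ≈ 0.69, μ_R = log 10 ≈ 2.30, σ = 0.5/0.35/0.30 — chosen
  for identifiability (>3 pooled sd between neighbors), not calibrated
  to any particular imaging rig. No published speed thresholds separate
  the states, so these are explicit, overridable choices.
* **Rendering**: one bright filled disk per frame at the true centroid
  on a dark background, uint8, optional additive Gaussian pixel noise,
  written losslessly (multi-page TIFF or numbered PNG).
* **Screens**: per gene, an independent concurrent control group and a
  treated group whose rates are the control rates multiplied elementwise
  by an effect matrix; default group sizes 8 controls vs 16 treated,
  inside the assay's reported ranges (6–9 and 15–18). All animals draw
  from seeds spawned deterministically off one master seed.

What the generator does **not** emulate: worm posture and body-shape
changes, pharyngeal pumping, multi-animal arenas, illumination drift,
tracking failures from coiling or edge contact, and any systematic
speed-distribution mismatch with real rigs. Passing tests therefore
demonstrate the inference machinery is correct under the stated model,
not that the model captures every property of real recordings.

## Tracking

Frames are binarized (Otsu by default; fixed threshold for synthetic
noiseless frames), the largest connected component above 5 px is kept,
and its intensity-weighted centroid is returned in (x = column,
y = row), 0-based, origin at the top-left pixel center. Speeds are
Euclidean displacements between consecutive valid frames divided by
elapsed time. Dropouts of ≤5 frames are bridged by linear position
interpolation (the bridged speed is exactly displacement/duration, so
bridging can never fabricate fast movement); longer dropouts split the
track into segments that are decoded and counted independently —
interpolating a long gap would fabricate quiescence.

A centered moving-average speed smoother is available but **off by
default**. With dwelling↔quiescence switching every ~50 s, a 10 s window
places roughly one frame in five within half a window of a state
boundary; the averaged speeds there belong to no single state, and EM
reliably spends its third component on this mixture band instead of on
rare roaming (group-level decode accuracy drops from 0.999 to ~0.5 at
any window ≥2 s under the default regime). The quiescence emission
component models the centroid jitter floor directly, which is the job
smoothing would otherwise have done.

## Problem sizes and numerics

The replicate studies use 200 null families (28 genes, 8 vs 16 animals,
1800 frames each) for calibration and 50 replicate screens for power;
rate-estimator and bout checks use single 10⁵-frame chains; the
recursion-vs-enumeration oracle uses 100 random instances of ≤6 frames
(3⁶ paths). Calibration of the screen statistics operates on
ground-truth state sequences — the quantities under test are the
group-level statistics, and state inference is validated separately —
while the power study runs the full chain (fit on controls, freeze,
decode all). Forward/backward use per-step scaling; Viterbi runs in log
space with probabilities floored at 1e-300 before the log; CSV readers
parse floats in round-trip mode so write→read→recompute pipelines are
bit-reproducible.

## Known limitations

* Speed-only emissions cannot separate a slow, straight "roam" from
  fast dwelling; with the default separations this is negligible on
  synthetic data but will matter on rigs where the speed distributions
  of dwelling and roaming overlap.
* The 3-state model degenerates when a fitted group contains (almost) no
  roaming; the unstable-ratio floor catches the symptom, but a 2-state
  fallback would be a better cure.
* Bout-duration summaries treat censoring by exclusion rather than by
  survival-analysis estimators; for sessions much shorter than typical
  bouts this biases means downward.
* Transition-rate units assume the linear rate↔probability conversion;
  at frame intervals approaching typical bout durations a matrix-
  exponential treatment would be required.
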