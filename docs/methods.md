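# Methods

This note documents the models, algorithms and design choices behind
`apneadbn`: what each stage computes, which knobs matter, what the
synthetic generator does and does not emulate, and the numerical decisions
a maintainer would need to know.

## 1. Signal model and markers

The raw input is a single-lead ECG sampled at a known rate (rat recordings
are typically acquired at 1250 Hz). Preprocessing resamples to 10 kHz —
rat heart rates of 300–500 bpm need sub-millisecond R-peak resolution —
then corrects baseline drift with a cubic spline through one isoelectric
knot per beat (the median of a 10-ms segment ending 25 ms before each R
peak, the rat PQ zone), and finally applies a zero-phase fourth-order
Butterworth low-pass at 45 Hz. Note the 45-Hz fourth-order design
suppresses 50-Hz mains by only ~10 dB in the zero-phase configuration;
its main role is high-frequency noise reduction for stable QRS candidate
detection. QRS complexes are detected on the filtered signal and each R
peak is refined to the local maximum of the *nonfiltered*
(baseline-corrected only) signal within ±10 ms, on which all markers are
measured so amplitudes and slopes are not attenuated by the low-pass.

Per beat: `RR` (preceding inter-beat interval), `Ra` (amplitude at the R
index, relative to the spline baseline), `Sa` (minimum within 20 ms after
R), `RSd = Ra − Sa` (exact by construction), and the upstroke/downstroke
slopes `US`/`DS` from least-squares straight-line fits over 4-ms windows
centered on the steepest point of the ascending limb in [R−12 ms, R] and
the descending limb in [R, R+12 ms]. A straight QRS limb makes the first
difference plateau, so the fit centers on the midpoint of the
maximal-slope run; the least-squares line (rather than a finite
difference) keeps the slopes noise-robust. All window lengths are
rat-scale defaults exposed in `MarkerWindows`; human-scale analysis would
use roughly 80/50/8 ms. `QRSpca` projects the five standardized morphology
series onto the first eigenvector of their correlation matrix, computed
per recording (absolute amplitudes vary too much across recordings for
pooling), with the sign fixed so the Ra loading is non-negative.

## 2. Preprocessing of marker series

Each marker series is detrended by removing a least-squares polynomial of
order 20 fitted on beat index, then z-scored per recording. The fit uses a
Legendre basis on the index rescaled to [−1, 1]; a raw monomial basis at
order 20 is numerically unusable (condition numbers overflow double
precision), while the orthogonal basis gives residuals identical to the
exact monomial least-squares solution to ~1e−6. Order 20 over a 15-min
recording removes drifts slower than roughly 45 s, i.e. anesthesia-depth
and electrode drifts, while leaving the 15-s apnea transients intact. The
z-score after detrending (order: detrend → normalize) makes recordings
comparable regardless of gain; the composition order is a package choice —
the two operations nearly commute on these data, and normalizing last
guarantees unit variance of what the network actually sees.

Per-beat labels derive from half-open annotation intervals
`[onset_s, offset_s)`: a beat is apneic iff its R-peak time falls inside an
interval.

## 3. The CLG dynamic Bayesian network

Variables per time slice (one slice per heartbeat): the binary apnea
indicator `Ap` and the chosen continuous markers. The network is
time-homogeneous with Markov order L: arcs run only from lags 0…L into
lag 0, parameters are tied across slices, and no arc runs from the present
into the past. Discrete nodes have multinomial CPTs and only discrete
parents; continuous nodes are conditional linear Gaussians — mean linear
in continuous parents, all parameters switched by the discrete-parent
configuration. For a fixed discrete path the continuous block is exactly
multivariate normal (verified in tests by comparing ancestral-sampling
moments with the closed form).

**Likelihood.** Transition likelihood conditional on the first L slices;
no initial-slice model is learned. Zero-probability discrete events under
a zero-pseudocount CPT yield −inf (logged), not an exception.

**Parameter estimation.** Maximum likelihood throughout: per
discrete-configuration OLS for continuous nodes with the residual SD taken
with divisor n (the ML variant, not n−p), and empirical frequencies for
CPTs. Two guards: a configuration with fewer than (#continuous parents +
2) rows falls back to the pooled regression that ignores the discrete
split (otherwise short recordings produce singular fits), and CPTs use a
Laplace-style pseudocount ε = 0.5 by default — ε = 0 reproduces raw
frequencies but lets a single unseen transition zero out the filtering
recursion. Residual SDs are floored at 1e−9.

**Scoring.** BIC = loglik − (k/2)·log n with k counting regression
coefficients, intercepts, SDs and free CPT entries; larger is better; the
score decomposes node-wise, which is what makes greedy search cheap.

## 4. Structure learning

Dynamic max–min hill-climbing in two phases. Phase 1 learns the
intra-slice ("static") arcs: a max–min parents-children screen restricts
candidates, then greedy add/delete/reverse moves optimize BIC. Phase 2
learns the transition arcs — parents at lags 1…L for each lag-0 node —
with the intra-slice arcs frozen and no reversals (inter-slice direction
is forced by time). Conditional-independence tests: Fisher-z partial
correlation (continuous–continuous), a likelihood-ratio test on the
discrete dummy in a nested regression (mixed), stratified chi-square
(discrete–discrete); α = 0.05, conditioning sets capped at 3. Self-lags
(X@k → X@0) are always admitted as candidates — autoregression is the
central temporal mechanism and screening it out on a technicality would be
self-defeating. The apnea node's own history is learned, not forced; a
`force_self_chain` flag adds Ap@1 → Ap@0 unconditionally for users who
want the hidden chain guaranteed. Everything is deterministic given the
data: single best improving move per iteration, gain threshold 1e−6,
lexicographic tie-breaks. Structures are validated on output: acyclic, no
continuous→discrete arc, no future→past arc.

## 5. Inference

At detection time the apnea indicator is hidden and the markers are
observed. Because every continuous parent is itself a measured marker,
emissions factor per beat and the filtering density
`p(Ap_t | y_{1:t})` is exact by a forward recursion over the 2^L
*history states* (the apnea values of the most recent L slices), encoded
as L-bit integers. The recursion is normalized every step and emission
products are accumulated in log space, so arbitrarily long recordings are
numerically safe. Exactness is feasible to L = 15 (32,768 states); larger
orders raise a capability error — no silent approximation. The initial
state distribution takes the training-data apnea marginal independently
per slot (the package's choice; the first L beats are flagged as carrying
the prior). Prediction pushes the filtered state through the transition
CPT with no new evidence; fixed-lag smoothing reads the lagged bit
directly off the forward state when τ < L and otherwise runs a normalized
backward recursion over the intervening slices. A brute-force enumerator
over all 2^T hidden sequences (T ≤ 16) serves as the independent oracle:
in filter mode it uses, for beat t, only the factors available at time t,
which is exactly what the forward recursion computes; agreement is
at machine precision (< 1e−9) across a randomized model battery.

Training fit is summarized by the RMSE between the filtered posterior and
the 0/1 labels over evidence-bearing beats (prior-flagged beats excluded);
this probability-vs-label definition is the package's named choice.

## 6. Detection and evaluation

The posterior is smoothed by a centered moving average of 40 beats —
widened to 41 so the filter is symmetric (zero phase); the difference is
negligible and the symmetric form avoids a systematic half-beat delay. At
the edges the window truncates symmetrically, keeping output in [0, 1].
Epochs of 15 s tile the recording from its start; each epoch's RMS of the
smoothed posterior is compared against δ (apneic iff rms ≥ δ, the
inclusive convention made explicit because the δ grid 0.1…0.9 makes the
boundary visible). Ground truth marks an epoch apneic when ≥ 50% of it
overlaps an annotated episode — episodes and epochs are both 15 s, so
alignment ambiguity is real and the overlap fraction is config-exposed.
Se/Sp/Acc come from the confusion counts; AUC is the rank statistic
(probability a random apneic epoch out-scores a random normal one, ties ½)
— exact and grid-free, and equal to trapezoidal ROC integration.
Protocols: ideal record-specific (train = test recording) and
record-specific (train on recording 1, test on 2–3); metrics average per
rat then across rats, unweighted, with undefined per-recording metrics
dropped rather than imputed as 0 or 100.

## 7. The synthetic generator

The generator emulates the anesthetized-rat protocol: 5 rats × 3
recordings of 900 s at F ∈ {20, 40, 60} events/hour (order randomized per
rat, each F once per rat), episodes of exactly 15 s placed periodically
with period 3600/F and a seeded onset jitter. Totals are exact: 150
episodes, 30 per rat, 15 recordings, 60 epochs per recording.

Beat series: RR is the rat-scale mean (drawn per rat from the 350–450 bpm
range) plus an AR(1) fluctuation, the apnea effect, a slow seeded
polynomial drift (Legendre, order ≤ 5), and white measurement noise.
Morphology markers add a shared latent "effort" factor inducing
cross-marker correlation; `RSd` is derived exactly as `Ra − Sa`. The
apnea response is an additive shift with exponential onset/offset
kinetics: gating g(t) rises with time constant τ_on inside an episode and
decays with τ_off after release. Raw ECG, when requested, renders
piecewise-Gaussian Q/R/S lobes at the generated beat times with per-beat
amplitudes following the ground-truth markers, plus optional sinusoidal
baseline wander and white noise.

**Default calibration.** The real study published no quantitative effect
sizes (figures only), so defaults are calibrated for test usefulness, not
fidelity: effects (in units of each marker's baseline fluctuation SD)
RR +4.0, Ra +2.5, Sa −2.2, US +1.9, DS −3.2; τ_on = τ_off = 0.3 s;
AR(1) coefficient 0.7; latent loading 0.3; noise SD 0.6; drift amplitude
1.5 SD; onset jitter uniform on [0, 0.5] s. The kinetics are deliberately
sharp — an abrupt mechanical obstruction with fast autonomic response and
sub-second valve-trigger variability — because the epoch decision rule is
unforgiving near boundaries: the 40-beat smoothing alone spreads a
detected episode about 3 s past its end, and any additional posterior
spill (slow marker recovery, or an episode straddling the 15-s grid by
more than ~1 s) lands genuine high-probability beats in a truth-negative
epoch, which at δ = 0.2 becomes a false positive no matter how good the
detector. With the defaults the record-specific RR+DS benchmark at L = 5,
δ = 0.2 sits at ~0.90 accuracy and ~0.99 AUC — solved well but not
trivially (sensitivity and specificity both still miss). The jitter bound
of 10 s remains available in `generate_protocol` for emulating less
regular event timing, at a known cost in epoch-boundary contamination.

**What passing tests do and do not show.** The generator's marker
dynamics are linear-Gaussian with a binary switch — exactly the model
family the network assumes. Passing recovery and benchmark tests
therefore demonstrates the correctness of the estimator, the search and
the inference machinery, not robustness to real-ECG pathologies:
arrhythmia, electrode artifacts, non-Gaussian noise, nonstationary
response amplitudes and event-duration variability are all absent by
design.

## 8. Problem sizes

Test and acceptance workloads are scaled for a single CPU: the oracle
battery uses 51 random models at 10 beats; parameter recovery samples
5,000 slices; structure recovery uses 10 seeds at 4,000 slices and order
3; the order-response check fits univariate models at L = 1 and 5 on ten
15-minute recordings; the end-to-end benchmark runs the full five-rat
protocol (15 recordings of roughly 6,000 beats). These sizes were chosen
so each check is statistically decisive for its tolerance.

## 9. Known limitations

* Inference is exact but exponential in L (hard cap 15); no approximate
  fallback is provided.
* Missing marker values are not supported at inference time; beats with
  non-finite markers are dropped at extraction.
* The QRS slope windows are rat-calibrated defaults; the source
  literature's human windows are not restated for rats, so these are
  exposed in configuration rather than claimed as measured values.
* File formats are CSV/JSON only; binary waveform containers are out of
  scope.
* Only one event type (complete obstruction, fixed 15-s duration) is
  modeled; hypopneas and variable-duration events are not.
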