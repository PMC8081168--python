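# Methods

`clipcontext` analyses drinking situations whose ambiance — brightness,
loudness, and attendance (number of people present) — is measured three
ways: by the participant in situ, by a panel of five external annotators
watching a 10-second clip, and by signal-processing algorithms run on the
clip. Because the original study media cannot be redistributed, the package
ships a synthetic-study generator that emulates the full data structure, so
every stage of the analysis runs end to end from a single seed. This note
documents the models, the measurement algorithms, the generator's stated
world, and the numerical choices.

## The synthetic study

### Structure

A study consists of `n_participants` (default 210) young adults, each
contributing a heavy-tailed number of drinking situations: 1 plus a negative
binomial draw (size 1.05, mean 10.2), giving ≈2,400 situations in total with
roughly half of them contributed by the top 20% of participants — the
imbalance typical of event-level EMA data. Each situation is assigned one of
seven location types (bars/pubs, nightclubs, restaurants, events,
streets/parks, travelling, private places) with probabilities matching the
observed frequencies of such studies (private places dominate, ~55%).
Locations map deterministically onto three coarse classes: commercial,
public, private.

### Ground-truth ambiance

Each location type carries a ground-truth distribution for physical
luminance (normal on a 0–100 scale, truncated), calibrated sound level
(normal in dB, truncated to [20, 87]), and attendance (negative binomial
head count). Defaults are calibrated so the per-location means of the
*algorithmic* ratings reproduce the orderings reported for real nightlife
data: nightclubs darkest and loudest, restaurants/travelling brightest,
private places quietest and least attended. The 87 dB ceiling exists because
the default calibration (RMS 1.0 ≡ 94 dB) leaves no headroom above ~88 dB
for the rendered tone-plus-noise mixture without clipping the waveform; the
ceiling still lies inside the top loudness bin (≥85 dB).

### Alcohol choice

The alcohol flag is drawn from a random-intercept logistic model on the
*true* context, expressed on the scales the sources rate:

    logit P(alcohol_ij) = α_loc + β_b·brightness_bin + β_l·loudness_bin
                          + β_a·attendance + β_p·prior_drinks + u_j,
    u_j ~ N(0, σ_u²),  σ_u = 1.

Coefficients vary by coarse location (e.g. in private places louder and more
attended situations are more alcoholic, brighter ones less), with magnitudes
in the range reported for real data (loudness OR ≈ 2.6 in private places,
brightness OR ≈ 0.6 in commercial venues). Intercepts vary by *fine*
location: a single commercial intercept cannot reproduce both the ~94%
alcohol rate of nightclubs and the ~50% rate of restaurants, since their
context profiles do not differ enough under any plausible coefficient
vector. The seven intercepts are calibrated to the observed per-location
alcohol percentages. Prior drinks are Poisson (mean 2 standard drinks of
10 g pure alcohol).

### Rating channels

Participant ratings are the algorithmic bin of the true ambiance plus a
bias and Gaussian noise, rounded and clamped to {0..4}; attendance is the
true head count under multiplicative noise. Annotators rate the same way
but with smaller bias and SD — the generator's stance is that in-situ raters
are noisier and slightly anchored upward, while clip annotators are more
uniform, which is an *assumption*, exposed in `RatingNoise`, not a measured
fact. With all noise and bias at zero both channels reproduce the
algorithmic bins exactly, which is the identity the unit tests exploit.
Music and chatter loudness are generated so each rater's maximum tracks the
true dB bin (music at the bin, chatter one step below). Annotator attendance
is reported as the category containing the (noisily perceived) rendered head
count among {0, 1, 2–4, 5–10, >10}.

### Rendered media

Clips are rendered for a per-location fraction of situations (30–56%,
higher in nightclubs and while travelling). Frames are a constant 8-bit
background plus one moving elliptical blob per rendered person; each blob
occupies its own horizontal lane and reflects off the lane ends, so
identities never overlap and a deterministic tracker can recover the exact
count. The background value is solved so the stack's mean luminance equals
the target (within 8-bit quantisation, well inside the ±1.0 contract), and
blob/background contrast is floored at 60 intensity steps so blobs stay
detectable even on black backgrounds. Audio is a 1 kHz sine (A-weighting
≈ 0 dB there) plus pink noise at −10 dB relative power, with pink
excursions clipped at 2.5×RMS to preserve headroom; the mixture is scaled
so the measured calibrated level equals the target exactly, and an
unreachable target raises rather than clipping silently. People beyond
`max_render_people` (default 10) are treated as off-camera: the participant
rates the full head count, while annotators and the algorithm see only the
rendered people — mirroring the real difference between being in a crowd
and watching a 10-second pan of it.

What the generator does **not** emulate: real scene content, camera
auto-exposure, microphone frequency response, annotator fatigue or drift,
and GPS/location misreporting. A green end-to-end test therefore
establishes that the *pipeline arithmetic* is right under the stated world,
not that the stated world matches any particular field study.

## Measurement algorithms

* **Brightness** — mean pixel intensity over all pixels and frames
  (Rec.601 luma for RGB), rescaled to 0–100, transformed to perceived
  lightness with the cube-root law L = 25.29·Y^(1/3) − 18.38 (clamped to
  [0, 100]), binned in 20-point increments. The cube-root constants are the
  classical lightness-scale values on a 0–100 luminance domain; they are
  exposed as module constants because sources citing "the" formula differ
  in domain conventions.
* **Loudness** — A-weighting applied in the frequency domain (analog
  IEC 61672 magnitude response normalised to exactly 0 dB at 1 kHz),
  instantaneous power = squared weighted samples, exponential moving
  average with a 125 ms time constant (the "fast" sound-level-meter
  convention; the smoother is initialised at the signal's mean power so
  stationary signals measure without warm-up bias), mean power converted to
  10·log₁₀(power) + C with C = 94 dB (RMS 1.0 ≡ 94 dB — an arbitrary
  reference for uncalibrated phone microphones; only bin positions relative
  to C matter). Digital silence (power < 1e−12) returns a 0 dB floor. Bins:
  <40 / 40–50 / 50–70 / 70–85 / ≥85 dB, half-open.
* **Attendance** — a deterministic surrogate for a trained
  detector-plus-tracker: per-pixel temporal median background, foreground =
  |frame − background| > k·(robust spread, floored at one 8-bit step),
  connected components ≥ `min_area` as detections, greedy nearest-centroid
  association under a displacement gate, and the count is the number of
  tracks covering at least half the frames. The surrogate preserves the
  contract of counting identity clusters across frames and is exactly
  testable against the generator's ground truth; it is not a person
  detector and will count any coherent moving object.

## Annotator fusion and agreement

Per-item fusion is majority-then-mean: a value held by ≥3 of 5 raters wins,
otherwise the mean is rounded (half away from zero; with five integer
ratings exact .5 ties cannot occur). Overall loudness takes each rater's
max of music and chatter *before* fusing — the max is a per-rating
operation, so applying it per rater is the natural reading; the opposite
order is a one-line change if wanted. Attendance categories are recoded to
{0, 1, 3, 7.5, 15} and averaged. Agreement is the Shrout–Fleiss ICC(2,k)
(two-way random effects, absolute agreement, average of k raters), computed
from the two-way ANOVA mean squares; degenerate inputs return a value ≤ 0
rather than raising. Qualitative labels for coefficients follow the
conventional bands (<.40 poor, .40–.59 fair, .60–.74 good, ≥.75 excellent)
and are for report annotation only.

## Descriptive comparison

Cross-source agreement is shown as 5×5 correspondence matrices (attendance
first binned into the five annotator categories) and summarised by Pearson
correlations and paired mean differences. Point estimates are ordinary;
*inference* is adjusted for the nesting of situations within participants
via cluster-robust (sandwich) standard errors from an auxiliary OLS
regression, clustered on participant. Alcohol-vs-no-alcohol contrasts per
location and source are Cohen's d with the pooled-(n−1)-weighted SD and the
Hedges–Olkin large-sample CI, variance (n1+n2)/(n1·n2) + d²/(2(n1+n2)).
Effect-size point estimates are deliberately *not* cluster-adjusted — the
adjustment lives in the uncertainty statements.

## Mixed models and fit indices

The random-intercept logistic likelihood is maximised by adaptive
Gauss–Hermite quadrature: per cluster, an inner Newton iteration finds the
posterior mode of u_j and its curvature, quadrature nodes (15 by default)
are recentred and rescaled there, and the log integrand is combined by
log-sum-exp. The outer optimiser is L-BFGS-B started from the ordinary
logistic fit with σ_u bounded at 0; a stalled line search is retried once
with a coarser finite-difference step. σ_u → 0 reproduces the ordinary
logistic estimates (verified to ~1e-8), and estimates match lme4's
`glmer(nAGQ=15)` to four decimals on test fixtures. Standard errors are
cluster-level sandwich estimates (numerical per-cluster scores and Hessian)
— the "maximum likelihood robust" convention; when σ̂_u sits on the
boundary the sandwich is computed over the interior parameters only.
Separation is flagged when any |β̂| exceeds 15.

Fit indices use the fixed part only, the flavour appropriate for asking how
the model would fare in a new sample:

* **McKelvey & Zavoina R²** = Var(Xβ̂) / (Var(Xβ̂) + σ̂_u² + π²/3): the
  fixed-effects variance share of the latent outcome, with the random
  intercept kept in the denominator. A flag drops σ̂_u² entirely for the
  alternative reading.
* **Hosmer–Lemeshow** on the fixed-part probabilities: decile groups (ties
  to the lower group; degenerate groups merged with df reduced),
  χ² = Σ (O−E)²/(E(1−E/n)), referred to χ² with g−2 df. Null simulations
  put the rejection rate at ≈5% at α = .05.

The full model report fits 3 sources × 3 coarse locations; a stratum whose
model cannot be fitted (constant outcome, too few clusters) is flagged and
skipped without aborting the report, and a stratum too small for the
Hosmer–Lemeshow group count reports NaN fit statistics alongside its ORs.

## Inference task

Random forests (300 trees by default, inside the conventional 200–500
range) predict the alcohol flag from one source's three context ratings
plus prior drinks, per coarse location. Class imbalance is handled by
duplicating minority rows to balance; accuracy is stratified 10-fold CV
repeated 10 times. The default protocol (`leakage_safe`) oversamples inside
each training fold only; `paper_mode` oversamples the full dataset before
splitting, which replicates a common ordering in the literature but lets
duplicated rows straddle the train/test boundary and inflates accuracy —
the package exposes both so the difference can be measured rather than
argued about.

## Determinism

All randomness descends from one root seed through a spawned `SeedSequence`
tree; media and annotator randomness are keyed on (root seed, situation id)
so streaming and materialised generation agree. Two runs with the same
config produce byte-identical report CSVs.

## Known limitations

* The blob tracker is exact only while identities never merge; the default
  generator guarantees that by lane placement, and the `max_render_people`
  cap (10 on the default 120-px frame) truncates what the camera "sees" in
  very crowded scenes.
* The rating-noise defaults are assumptions; conclusions about *which
  source predicts best* under the defaults reflect those assumptions.
* The sandwich covariance uses numerical derivatives; with very small
  strata (<10 clusters) the model refuses to fit rather than returning
  unstable output.
* Cohen's d on 0–4 ordinal scales inherits the usual caveats of treating
  ordinal ratings as interval data; it is reported because it is the
  field's convention for these contrasts.
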