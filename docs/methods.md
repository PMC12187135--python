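# Methods

## The decision model

A trial of the 3-AFC task requires the observer to report the second
target (T2) as clockwise (CW), counterclockwise (CCW), or absent.  The
model represents the trial's evidence as a bivariate decision variable
`psi = (psi_dis, psi_det)`: the horizontal component carries orientation
evidence, the vertical component presence evidence.  Across trials `psi`
is Gaussian with identity covariance (the variance is not separately
identifiable from the sensitivities, so it is fixed at 1, the standard
SDT convention).  Its mean is the origin on T2-absent trials and
`(+d'_dis, d'_det)` / `(-d'_dis, d'_det)` on CW / CCW trials at the
relevant contrast, so `d'_det` is detection sensitivity and `d'_dis` is
each signal mean's offset from the detection axis (the CW-CCW mean
separation is `2 d'_dis`; a documented convention — the alternative
"full-separation" reading is a factor-of-2 reparametrization and changes
no inference).

Responses follow an inverted-Y decision surface with junction at
`(c_dis, t_det)`: the stem is the upward vertical ray, and the two arms
descend symmetrically at `±beta/2` from the downward vertical.  CW is
reported when `psi` falls right of the stem and above the right arm,
CCW symmetrically on the left, and "absent" inside the lower wedge of
angle `beta`.  Boundary hits (measure zero) resolve by the fixed
precedence CW > CCW > none.  Each zone is the intersection of two
half-planes through the junction, so its probability under any condition
mean has the closed form `Phi2(u1, u2; rho)` with `u_i` the signed
margins along the inward unit normals and `rho` their inner product; we
evaluate `Phi2` with Owen's T function (vectorized, accurate to
~1e-14, cross-checked against scipy's bivariate normal CDF and a
10^7-sample Monte-Carlo classifier).

The derived detection criterion is `c_det = t_det - d'_det / 2`
(threshold relative to the noise/signal midpoint), and the
likelihood-ratio bias is `LR = exp(-d'_det * c_det)`.

## Fitting and model comparison

Responses are tallied per lag into two present-condition 2x3 tables (one
per contrast) plus one absent-condition row stored once per lag — false
alarms and correct rejections cannot depend on the contrast of a
stimulus that was never shown, and duplicating the row per contrast
would double-count those trials.  The likelihood is multinomial with
cell probabilities from the closed-form zone measures (floored at 1e-12
before the log).

Five variants tie parameters progressively: I (free: 35 parameters), II
(beta shared across lags: 31), III (II + `d'_dis` tied across contrasts
and `c_dis` shared across lags: 22), IV (II + `d'_det` tied across
contrasts and `t_det` shared across lags: 22), V (all ties: 13).  (A
variant description in terms of a lag-shared `c_det` is equivalent in
parameter count; we tie `t_det`, the actual free surface parameter.)
Each variant is fit with bounded L-BFGS-B (`d' in [0, 6]`,
`t_det in [-4, 6]`, `c_dis in [-4, 4]`, `beta in [0.1, pi]`) from one
fixed mid-range start plus seeded random restarts (default 10); the
angle parameter makes the objective multimodal, hence the restarts.
Variants are compared with `AIC = 2k - 2 logL` and
`BIC = k ln n - 2 logL` (n = total trials).

Absolute fit is assessed by a chi-squared randomization test: expected
cells below 5 are pooled with their nearest within-row neighbour, and
the observed chi-squared is ranked within replicates simulated from the
fitted model at the observed row totals, evaluated at the fitted
parameters without refitting (a per-replicate refit is available behind
a flag but is not the default in the randomization-test lineage this
follows).  p-values include the observed statistic
(floor `1/(n_boot+1)`).

### Identifiability

The model has a structural blind spot worth knowing about.  With a
mirror-symmetric design and a single signal level (sensitivities equal
across lags and contrasts), the data fix only three independent response
proportions — P(none|absent), P(CW|signal), P(none|signal) — while
(d'_det, d'_dis, t_det, beta) are four effective unknowns: an exact
one-parameter ridge of indistinguishable models results (verified: a far
start on expected counts reaches a parameter set several SD units away
with a log-likelihood equal to the truth's to 1e-10).  Lag-varying
sensitivities with shared (t_det, beta) — the actual blink scenario —
break the exact ridge, but a soft ridge remains: at 20,000 trials per
lag, sensitivities and `c_dis` recover with SD ~0.03 and negligible
bias, while single-run `t_det`/`beta` estimates scatter with SD
~0.2.  Consequently recovery checks should be read per parameter:
sensitivity and criterion estimates are trustworthy; `t_det` and `beta`
are jointly weakly constrained, though their lag *differences* (tied
here anyway) are not what the blink conclusions rest on.  With real
multi-contrast data under Models I-III (contrast-specific `d'_det`,
per-lag `t_det`), the per-lag constraint count exceeds the unknowns and
the surface parameters are better pinned.

Fitted short-minus-long deficits at single-session size (~900 trials)
are noticeably inflated relative to the generating values (sampling
noise stretches the fitted lag profile); cohort means of per-lag
estimates remain centered.

## Behavioral quantities

Detection accuracy at a lag is the trial-pooled proportion
`(n_hit + n_misid + n_cr) / n_total` (misidentifications count as
correct detections); a condition-averaged variant is available behind a
flag.  Discrimination accuracy is `n_hit / n_present`.  Blink deficits
are short-lag (100+300 ms) minus long-lag (700+900 ms) pooled values —
the sign convention under which sensitivity deficits are negative — and
modulation indices are `(LL - SL) / (LL + SL)`.  Trial-weighted pooling
is used for count-based metrics and simple lag means for fitted
parameters.

## The synthetic study

The trial generator emits 3 blocks x 312 trials (936 per session), a 2/3
T2-present fraction, 50/50 contrasts with orientation x contrast
counterbalanced within each block's lag cells, and a truncated-geometric
lag schedule with ratio 0.85 (matching the decaying per-lag trial counts
of the task; the exact schedule parameter is configurable).  T1 accuracy
is a Bernoulli flag with rate 0.875 (the staircase target); T1 behavior
is not modeled mechanistically.

The default generating parameters follow Model III structure and were
chosen once to emulate the magnitude of the reported blink effects:
`d'_det` (low contrast) = [1.0, 1.1, 1.5, 1.9, 2.0] and (high) = that
+0.6; `d'_dis` = [0.9, 1.0, 1.3, 1.5, 1.6] (both contrasts);
`t_det` = [0.9, 1.0, 1.25, 1.5, 1.6]; `c_dis` = 0.1; `beta` = 2.2 rad.
Pooled short-minus-long deficits of this truth: `d'_det` -0.90, `d'_dis`
-0.60, `t_det` -0.60, `c_det` -0.15 (i.e. criteria nearly flat across
lags while sensitivities carry the blink).  Cohorts add per-participant
Gaussian jitter (SD 0.15) to these values.

### Synthetic EEG

Epochs are trials x channels x time at 250 Hz, -300 to +700 ms around T2
onset, on a named 10-10-style montage (41 channels) containing a
documented 33-channel occipito-parietal subset.  Each trial sums:

* a common stimulus-evoked template on every trial — it cancels exactly
  under correct-rejection subtraction;
* Gaussian-windowed ERP components on present trials: P1 (P7/P8, 90 ms,
  lag-invariant), N2p (occipito-parietal set, 225 ms, negative), P2
  (frontocentral, 225 ms), P3 (P3/P4/Pz, 425 ms), the late three
  attenuated at short lags;
* class-dependent spatial patterns over the 33-channel subset in a
  300-600 ms Hann window: CW trials get `eta_det + eta_dis/2`, CCW
  `eta_det - eta_dis/2`, with per-lag magnitudes (fixed random
  orthogonal unit directions);
* 24 Hz oscillations in frontal and parietal channels, phase-locked
  within trial up to a von Mises offset with per-lag concentration
  `kappa` on present trials (uniform offset on absent trials) — a
  monotone `kappa` -> coherence mapping;
* AR(1) noise (coefficient 0.9, SD 3 µV) with optional uniform
  inter-channel correlation (0.2).

The 10 Hz stream-evoked steady-state component is not injected by
default (data are emitted as if already removed by a bandstop filter);
a flag adds it back for robustness checks.  What the generator does
*not* emulate: realistic scalp topographies from volume conduction,
artifacts (blinks, line noise), non-stationary background rhythms, or
any trial-by-trial link between the EEG and the simulated behavioral
response.  Passing tests therefore demonstrate correctness of the
analysis chain under the assumed statistical structure, not robustness
to real-EEG nuisance structure.

## Neural analyses

ERPs are computed T2-locked over an electrode mean, baseline-corrected
on -300-0 ms, with the matched-lag correct-rejection average subtracted
before pooling a lag group (trial-count weighted).  Component amplitudes
are window extrema: P1 40-140 ms, N1 90-160 ms (P7/P8), N2p 150-300 ms
(O1, O2, Oz, P3, P4, Pz plus PO3, PO4, POz, PO7, PO8 — the "surrounding
PO" set resolved to a fixed documented list), P2 150-300 ms
(C3, C4, Cz, F3, F4, Fz), P3 300-550 ms (P3, P4, Pz).  N-components are
reported as signed minima (negative values).

Coherence uses DPSS multitapers (time-half-bandwidth 3, 5 tapers) in
300 ms windows with 50 ms stride; cross/auto spectra are averaged over
tapers and trials, `C = |G_xy|^2 / (G_xx G_yy)` per window and
frequency, then averaged over the pair set (bilateral = the 9
{F3,F4,Fz} x {P3,P4,Pz} pairs; left = F3-P3, right = F4-P4 — midline
electrodes are excluded from the lateralized sets since the 9-pair set
is explicitly bilateral).  Window centers are those whose full window
fits inside the epoch (-150 to +550 ms at the defaults).  Optional
divisive normalization divides each pair's coherogram frequency-wise by
that pair's coherence in the -300-0 ms baseline window (the ensemble
reading of a per-trial normalization: single-trial coherence is
undefined for an ensemble estimator); optional CR subtraction removes
the matched-lag correct-rejection coherogram.  Band summaries average a
time x frequency rectangle (low beta 13-19 Hz, high beta 20-30 Hz,
0-300 ms).  Caveat: with a single pair and a few dozen trials the
baseline coherence can be arbitrarily close to zero at single
frequencies, making the divisively normalized values heavy-tailed; the
pipeline's per-lag scalar metric therefore uses raw CR-subtracted band
coherence, which is stable at desk scale and identical in expectation
up to the baseline scale (the generator plants no baseline-window
coupling).

Neural dimensions: per time point, the 33-channel class means (CW, CCW)
relative to the correct-rejection mean give `eta_det` (their mean) and
`eta_dis` (their difference); norms are inter-class distances.  Distance
summaries resample each lag's trials with replacement down to the
per-class minimum count across lags (10 bootstrap draws), average the
per-timepoint norms over 300-600 ms, and divide by the 900 ms lag value.
The positive norm bias of noisy mean vectors is deliberately *not*
subtracted — trial-count equalization is the only bias control — so
normalized distances at low signal-to-noise are compressed toward 1;
ratio-recovery checks are run at noise levels where the bias is
second-order.

## Inference layer

Metric series (participant x 5 lags) are normalized by dividing each
participant's row by its own across-lag sum (rows with near-zero sums
are excluded); note this maps consistently negative metrics (N2p) to
positive normalized profiles, which is why reported N2p-sensitivity
partial correlations are positive.  The partial correlation of two
pooled series controlling a third uses the first-order formula on
pooled (participant, lag) points; the null permutes lag labels within
participant, independently for each of the three measures, 1000
permutations by default, one-sided p with the observed statistic
included (floor `1/(n_perm+1)`).  Families of p-values are adjusted
with step-down Holm per reported family.

The percentage-bend correlation (bend constant 0.2, the robust-
correlation toolbox default) is implemented from its definition and
cross-checked against an independent implementation in tests.  The
cluster-based permutation test thresholds a pointwise paired t-map at
two-sided alpha = 0.05 (configurable to Wilcoxon), joins supra-threshold
points by 8-connectivity, sums t-values per cluster, and compares
against the max-|cluster| distribution under per-participant sign flips.
Wilcoxon signed-rank comparisons drop zero differences, use midranks
with the standard tie correction, and report the normal-approximation z
without continuity correction.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and the acceptance script —
chosen as desk-scale versions of the study design: 936-trial sessions,
cohorts of 6-12 synthetic participants, 300 EEG trials per participant,
10 bootstrap draws for distances, 500-1000 permutations/replicates for
the calibration suites, 10^7 Monte-Carlo samples for the quadrature
oracle.  Optimizer convergence uses `ftol = 1e-10`; probability
normalization is asserted at 1e-6; degenerate inputs (all-"none" data,
empty classes, missing correct rejections) raise named errors rather
than returning silent NaNs, except where the contract calls for a
flagged-missing value (undefined modulation indices, all-zero signed-
rank differences).
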