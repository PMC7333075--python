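# Methods

## Problem setting

A virtual driving test (VDT) records multichannel telemetry — pedal
fractions, signed steering rotation, lane offset, vehicle pose, speed,
turn-signal and scan-button state, posted limit — at ~10 Hz while a license
applicant drives a planned route through one of ten simulated environments.
Each applicant later takes the state on-road examination (ORE), scored as an
integer accumulation of examiner-cited infractions: 0 is perfect, a score of
26 or more fails, and scores between 20 and 35 form a "gray zone" of drivers
who barely pass or barely fail.  The screening question is whether the VDT
telemetry predicts ORE failure well enough to flag underprepared applicants
before they occupy an examiner's seat.

`zonescreen` implements two featurizations of a drive and the evaluation
harness that compares them:

* **variables** — 67 engineered per-drive summaries (global and per-zone-type
  speed and speed-ratio statistics, limit-adherence percentages, control-input
  statistics, signal/scan usage, rule-based infraction counts);
* **time-series clustering** — the drive is partitioned into *event zones*
  (route segments between entry/exit waypoints designed to elicit a specific
  behaviour), per-zone behaviour sequences are compared with dynamic time
  warping (DTW), clustered with k-medoids, and each drive is represented by
  its dissimilarity to every elected medoid: a soft-clustering feature vector
  of width k per zone, with k blanks for unvisited zones.  With k = 8 and 166
  zones this is 1328 features.

## Preprocessing

Replays are stored as JSONL frames.  Capture-rate recordings are subsampled
(every 6th frame by default, preserving true timestamps — never resampled or
averaged) and truncated to begin at the first frame whose simulated speed
exceeds 0.5 m/s, aligning drives on a common in-motion start.  A recording
whose speed never exceeds the threshold is excluded.  Cohort records carry
workflow-completion flags; a record enters the analyzable sample only if the
practice drive, comprehension test and assessment drive were completed and
the replay uploaded, with each exclusion tallied under the first failing
check in workflow order.

## Zone partitioning

Frame positions are projected onto the route centreline (nearest point on
the polyline, candidates bounded by a KD-tree over vertices) to give a
per-frame arc length, clamped monotone so brief reversals cannot create
duplicate traversals.  A zone's subinterval is the half-open frame range
`entry <= s < exit` — a frame on a shared boundary belongs to exactly one
zone — and only the first traversal exists by construction.  Intervals with
fewer than two frames count as unvisited.  Clustering uses four channels per
frame: lane offset, throttle, brake, steering.

## DTW dissimilarity

Classic dynamic program with steps (i−1,j), (i,j−1), (i−1,j−1), Euclidean
local cost across the four channels, no warping window.  Channels are
z-scored per zone with statistics pooled over that zone's subintervals;
without this, lane offset (metres) dominates the unit-interval pedals.  The
optimal warp cost is divided by the warping path length by default (`raw`
available as a switch) so that transit duration — already driven by speed,
which is not a clustered channel — does not dominate the dissimilarity.
Ties in optimal cost break toward the shorter path, making the normalized
value well defined.  DTW is not a metric; nothing downstream assumes the
triangle inequality.  Equality with an exhaustive enumeration of all
monotone warping paths is checked on short sequences in the test suite.

## k-medoids and membership features

Given a zone's dissimilarity matrix, alternating k-medoids (k = 8 by
default) assigns each subinterval to its nearest medoid and then elects,
within each cluster, the member minimising the sum of squared
dissimilarities to the other members.  The objective (*inertia*) is the sum
of squared dissimilarities to assigned medoids; iteration stops when it
fails to decrease, with a 100-round cap.  Election by *squared*
dissimilarity makes each round exact coordinate descent on the inertia, so
the stopping rule terminates with a strictly decreasing inertia history
(electing by unsquared sums — another defensible reading of "aggregate
dissimilarity" — can let the squared objective oscillate).  Twenty random
initialisations (uniform k-subsets) are run per zone and the minimum-inertia
model kept; a master seed fans out per-zone, per-restart substreams so each
zone is independently reproducible.  Assignment ties break toward the lowest
medoid position, election ties toward the lowest subinterval index.

The feature vector concatenates, over zones in ascending id, the
(unsquared) dissimilarities from a drive's subinterval to the zone's k
medoids; unvisited zones contribute k missing values.  Per-cluster summaries
(member count, collision rate from the zone event rules, ORE score mean/SD)
are attached for inspection.

## Screening evaluation

Outcomes are labelled fail iff score >= 26.  The logistic screen is
evaluated with stratified 10-fold cross-validation: out-of-fold fail
probabilities are pooled and a decision threshold swept over 0.00–1.00 in
steps of 0.01 (predict fail iff P(fail) >= tau).  Each threshold yields a
2x2 confusion matrix (FF/FP/PF/PP; first letter = screen, second = exam) and
the metric suite: accuracy (FF+PP)/N, fail rate (FF+FP)/N, false-alarm rate
FP/N, ratio of false alarms FP/(FF+FP), TPR FF/(FF+PF), FPR FP/(FP+PP), and
the risk ratio [FF/(FF+FP)]/[PF/(PF+PP)] with a Katz log-normal 95% CI,
`exp(ln RR ± 1.96·sqrt(1/FF − 1/(FF+FP) + 1/PF − 1/(PF+PP)))`.  The Katz
choice is validated by reproducing both published CIs from the
reconstructed worked-example matrices.  The ROC is the threshold sweep's
(FPR, TPR) points with (0,0) and (1,1) endpoints and trapezoidal AUC.  The
RBF-SVM harness grids gamma dyadically over 2^-10..2^6 (17 values) and cost
over 2^-5..2^15 (21 values), tabulating out-of-fold hard predictions per
cell.  (The source material prints the cost range as "2^-5 to 2^-15 by
doubling", which is self-inconsistent; an increasing dyadic range is used.)

Missing membership entries are mean-imputed per column with training-fold
means, then standardized; the logistic fit carries a small ridge penalty
(1e-8 by default) for stability on many correlated columns.

Two clustering scopes are provided.  `all` clusters every subinterval once
and is how published deployments most plausibly operated, but leaks test
information into the medoids.  `trainfold` (the default) re-elects medoids
per CV fold from the training-fold submatrix only; features for all drives
are then read off the precomputed full DTW matrix.  The per-zone channel
standardization behind that matrix is pooled over all subintervals — making
the scaling strictly fold-local would require recomputing the entire DTW
stage per fold at 10x cost for a second-order effect.

## Worked-example reconstruction

Published screening tables print rounded percentages.  Because the cohort
size and outcome margin are known (N = 4308, 1096 failing), the integer
confusion matrix behind a row can be recovered by exhaustive search over
(FF, FP): compute each constrained metric exactly, round half away from zero
to the printed precision, and keep matrices matching every constraint.  The
search either returns the unique solution or raises with the candidate list;
under-determined constraint sets are reported as such rather than guessed.
The clustering+logistic row is pinned by {TPR 10.0, FPR 1.3, ratio of false
alarms 27.2}; the variables+logistic row needs {TPR 15.9, FPR 3.4, fail rate
6.6, ratio 38.5} — with the ratio omitted, two matrices (FP = 109, 110)
survive.  (That row's printed false-alarm rate of 2.6 is inconsistent by one
rounding unit with every matrix satisfying the other constraints — 109/4308
rounds to 2.5 — and is treated as a typographical artifact, not used.)

## Synthetic cohort

The study cohort is not public, so a simulator provides data with the same
shape.  What it emulates:

* a bank of 10 routes (~5.2 km) carrying 166 zones of eight types
  (crosswalk, school/construction/playground zones, banking curve,
  stop-sign and traffic-light intersections, a rear-end conflict), 16–17
  per route, with per-type lengths and posted limits (25–35 mph converted
  at 1 mph = 0.44704 m/s);
* drives at 10 Hz averaging roughly eight minutes: a standing start, cruise
  at 90% of the base limit between zones, and inside each zone one
  *archetype* — a parametric template over normalised zone progress for
  speed, brake, throttle, steering and lane offset.  Each zone type ships
  at least three archetypes (e.g. crosswalk: full stop / slow yield / speed
  through without yielding), exactly the zero-weight ones compliant;
* unequal lengths by construction: each execution's duration is scaled by a
  Uniform(0.8, 1.25) time-warp jitter, stop archetypes dwell for a random
  time, and compliant templates keep peak speed <= 0.78 of the limit so
  jitter cannot push them over;
* per-frame Gaussian channel noise with sigma = 0.05 of each channel's
  range (range 1 for pedals, 2 for steering, 4 m for lane offset);
* a latent skill theta ~ Uniform(0, 1) per driver: in each zone the driver
  draws a risky (positive-weight) archetype with probability 1 − theta,
  otherwise a compliant one, so risky execution frequency is linear and
  decreasing in skill and a theta = 1 driver is always compliant;
* ORE scores `round(max(0, a(1−theta) + eps) + b·Sum(w))` with eps ~
  N(0, sigma_e), where Sum(w) is the total infraction weight of the
  archetypes actually executed.  Defaults a = 34, sigma_e = 8, b = 0.01 were
  calibrated once by Monte Carlo so that failure prevalence lands near the
  ~25% observed in deployment (the a/sigma_e pair alone gives ~26.6%;
  b = 0.01 keeps the infraction coupling alive at ~27.2%).  The *null*
  condition for falsification tests sets a = b = 0 with sigma_e raised to
  40, keeping prevalence comparable while the score is independent of
  behaviour (at sigma_e = 8 essentially nobody would reach 26 and the
  null AUC would be undefined).

What it does **not** emulate: ambient-traffic dynamics (traffic interactions
are folded into the archetype templates), vehicle physics, render-level
artifacts, demographic covariates, examiner variability beyond the score
noise, and any correlation structure among zones beyond the shared theta.
Passing tests therefore demonstrate that the pipeline recovers planted
behavioural structure and calibrated outcome links — not that the real
cohort's effect sizes are reproduced.

## Problem sizes used in checks

Structural checks (feature width 1328) run the full 10-route/166-zone bank
with 12 drivers per route and 2 restarts.  The end-to-end signal/null study
simulates n = 2000 drivers on a reduced bank — 2 routes, 12 zones at 0.4
zone scale, ~650 m routes (~80 s drives) — chosen so the all-pairs DTW
stage (~10^6 pairs per zone) stays tractable on a single CPU while each
driver still traverses six behavioural zones.  On this study the
training-fold-clustered logistic screen reaches AUC ≈ 0.8 under the default
skill-coupled outcome model and ≈ 0.5 under the matched-prevalence null;
these are recomputed, not asserted, by `scripts/acceptance.py` and the test
suite.

## Numerical choices and degenerate inputs

* Rounding for printed-value comparison is half-away-from-zero (1 decimal on
  the percent scale, 3 for risk ratios).
* Risk-ratio edge cases: no predicted failures raises (or NaN in sweep
  mode); PF = 0 yields an infinite RR with NaN CI, flagged rather than
  fabricated.
* Zero-variance channels are left unscaled during z-scoring.
* k-medoids requires n >= k; training folds with fewer subintervals than k
  use as many medoids as available.
* Off-route frames (beyond an 8 m corridor) warn and keep their nearest
  projection; route progress is clamped monotone.
* Drives visiting no zone at all are dropped from the feature matrix with a
  warning.

## Known limitations

The archetype library is stylised: real drivers mix behaviours within a
zone and produce within-cluster variance the templates lack.  The 67
engineered variables follow the documented families (global/per-zone speed
statistics, limit-adherence percentages, infraction counts) but the full
original catalog was never published; the remainder of this catalog is this
package's own fixed choice.  Cluster-count selection (silhouette) and
ANOVA-based cluster refinement are out of scope.
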