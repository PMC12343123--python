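# Methods

## The inference problem

A pop-up satellite archival tag on a released skate records depth,
temperature and acceleration at 1 Hz but transmits only summaries: depth
every 150 s, quantized by splitting each 2 h window's depth range into 16
equal bins; the per-window mean of the tag-mobility metric (the mean
standard deviation of summed three-axis acceleration over 3 s, a unit-less
5–63 scale); and the fraction of each window the tag floated upright.  The
question is whether the animal survived release.  Three complications make
this non-trivial: the depth sensor's error grows with depth (±1% of
reading, so ±13–18 m at the 1300–1800 m depths involved), which can mask
the movements of a sluggish but living animal; bottom currents push a tag
on a dead animal around, producing mobility and tilt signals without any
animal activity; and roughly 20% of summary windows never arrive.

## Observation model

`sensor_accuracy(d) = 0.01·d` is the half-width of the accuracy band.
Window binning divides the observed range into 16 half-open bins (closed at
the top; the window maximum joins the top bin) and decodes to bin centres,
which minimizes the worst-case decode error at `bin_width/2`.  Whether real
tags anchor bins at the window minimum or a rounded value is not
documented; we bin against the window minimum and state so here (the
choice moves decoded values by less than one bin).  A zero-range window has
bin width 0.  Summarizing a 1 Hz archive reproduces the transmitted
products exactly; this identity is the generator's consistency invariant
and is tested.

Orientation: a free-floating tethered tag stands vertical and reads
A_z ≈ −1 g, so *upright* means A_z ≤ −0.75 g and *tilted* means
A_z > −0.75 g.  (Source descriptions of the threshold's direction are
inconsistent; the physical convention above is the one consistent with the
statement that a 0.5 m/s current tilts a tag to −0.5 g.)

## Synthetic deployments

The generator produces a latent 1 Hz record per tag, then applies the
observation model and drops whole windows uniformly at random at rate 0.2.
Per-window latent states (still/active) drive a hierarchical mobility
model: window level ~ truncated normal (still: mean 7, sd 0.3; active:
mean 30, sd 8 for survivors, 18/4 for the sluggish regime), 1 Hz values ~
truncated normal around the level (sd 2) plus the tidal boost, all on
[5, 63].  The still-state window-level sd is small because a dead animal's
only window-to-window variation is exogenous; the 1 Hz sd of 2 matches the
non-zero mobility baseline of real tags.

Tidal forcing is deterministic: current = peak × |sin(π t / 24.5 h)| ×
envelope, with a spring–neap envelope of period 14.77 d ranging from 0.1
to 1, at spring maximum at release.  The sine argument uses π (not 2π) so
the forcing period equals the diurnal period of 24.5 h, matching the ~24 h
periodicity a dead tag under tidal forcing should show.  Current maps to
tilt at 1 g per m/s (0.5 m/s ⇒ A_z = −0.5 g) and to a mobility boost of 16
units per m/s — a free scale anchored only by that single tilt point, since
no quantitative current-to-mobility link is documented.  Deployments start
at a spring tide; the phase is a config, and fixing it guarantees every
≥13-day deployment contains a neap (hence a long still bout on dead tags).

Regime defaults (the study conditions, fixed once):

| regime | bottom depth | tidal peak | depth behaviour | detachment |
|---|---|---|---|---|
| survivor_active | 1300 m | 0.10 m/s | 3 excursions/day of 120–300 m, window-level wander | scheduled (30 d) |
| dead_plateau | 1500 m | 0.08 m/s | flat within noise | early (13–27 d) w.p. 0.4 |
| dead_canyon | 1400 m | 0.35 m/s | flat | always early |
| control_dead | 1500 m | 0.1507 m/s | flat | scheduled |
| ambiguous_sluggish | 1400 m | 0.30 m/s (boost 8/m·s⁻¹) | one downward step of ~33 m | always early |

The control peak current is calibrated (scripts/calibrate_control.py)
against the deterministic forcing quantile so the expected not-still
fraction is 12%, emulating a control tag still 88% of the time.  The
canyon peak (0.35 m/s) keeps dead canyon tags ≥40% still while producing
diurnal mobility peaks, ≥2 h of tilt around springs, and multi-day still
runs near neaps.  The sluggish regime's single ~33 m downward step inside
an otherwise flat trace reproduces a depth record confined to a 35–40 m
band with no resolvable vertical movement.

What the generator does *not* emulate: realistic current fields or
bathymetry (slope is a scalar), burst-structured transmission loss,
predator ingestion signatures, or behavioural nonstationarity beyond the
window-level state process.  Passing tests therefore demonstrate that the
pipeline recovers fates when the regime phenomenology holds, not that the
phenomenology itself is correct for any particular animal.

## Activity metrics

A window is *still* when its mean mobility is below 9 (the value consistent
with gravity alone); a window at exactly 9 counts as not-still,
conservative toward activity.  Stillness percentages are over received
windows only.  Still-bout durations bridge transmission gaps of up to 6 h
between received still windows (a dropped window inside a continuous still
period does not interrupt the behaviour; without bridging, a >40 h bout
would survive 20% dropout with probability 0.8²¹ ≈ 1%); a received
not-still window always ends a bout, and bout durations run from the first
window's start to the last window's end.

The Lomb–Scargle periodogram is computed on the irregular window grid over
periods 6 h–10 d with 5× frequency oversampling, normalized by the centered
sum of squares so power is scale- and offset-invariant in [0, 1].
Significance of the peak is a seeded permutation test
(p = (1 + #{permuted max ≥ observed}) / (n_perm + 1)); a Bonferroni-style
analytic false-alarm bound is reported for reference only.  A constant
series is flagged "no variance" with p = 1.

## Mobility HMM

One two-state Gaussian HMM is fitted to the pooled cohort by Baum–Welch:
emissions and transitions shared across tags, each tag an independent
chain.  A per-tag two-state fit would split pure noise into two states on
an always-inactive tag; the pooled fit is identified by the cohort's
between-tag contrast, and a per-tag mode remains available for sensitivity.
Initialization is deterministic (state means at the pooled 25th/75th
percentiles, sds at the pooled sd, self-transitions 0.95), the total
log-likelihood is asserted non-decreasing at every step, emission sds are
floored at 0.5 (the sensor's resolution scale) to prevent collapse, and
states are relabelled so the lower mean is "non-mobile".  Tags are labelled
by the majority state of their Viterbi path; an exact 50/50 path breaks
toward "mobile" (conservative for a mortality claim) with a logged warning,
and a dominant fraction below 0.95 is logged as unusual.  Identical
observations everywhere raise a degenerate-emissions error rather than a
meaningless fit.

## Fate calls

The benthic span of a transmitted depth record starts at the first
stationary summary window — one whose within-window depth range is at most
twice the accuracy band at its median — after trimming the first hour
(descent) and trailing surface records.  Movement is flagged when the
maximum deviation from the benthic median exceeds the accuracy half-width
at that median (this reproduces the ±13–18 m criterion at 1300–1800 m).  A
deviation pattern fully explained by a single *downward* level shift (two
flat segments, optionally with one transition window whose median lies
between the levels) is recorded as a shift, not movement — a carcass can
slide deeper once, and a one-bin shift is a known artefact; an upward step
is movement.  Less than 6 h of benthic data yields insufficient evidence.

Rules, ordered and total: R1 movement → survivor; R2 no movement and
non-mobile → mortality; R3 no movement but mobile → ambiguous; R0
insufficient evidence → ambiguous.  Early detachment is carried in the
evidence and the report but is not itself a deciding rule.  Ambiguous tags
enter the survival estimate per the `ambiguous_as` config, default
mortality.

The NMDS ordination (Bray–Curtis on range-scaled mean mobility, tilt
hours, stillness fraction, and early-detachment coding; tags detaching with
the pin intact count as scheduled) is a diagnostic of cluster structure,
not a deciding rule.  Range scaling precedes Bray–Curtis because the raw
features mix hours with unit-free fractions.  Non-metric stress admits
degenerate zero-stress embeddings that collapse tied ranks onto coincident
points; restarts therefore start once from the classical
(principal-coordinates) configuration and otherwise from seeded random
ones, and the lowest-Kruskal-stress-1 non-degenerate restart is returned.

## Survival estimation

The Wilson score interval is the default (it is well behaved at n = 23 and
reproduces the reported 13–46% for 6/23; Clopper–Pearson is wider);
`exact` and `normal` are selectable.  The control tag is excluded from n.
The planning curve holds p̂ fixed and evaluates the Wilson width over n;
with p̂ = 6/23 the smallest n that halves the width relative to n = 23 is
101.  (A published figure for the same question is 105; the exact
procedure behind it — CI method, rounding, target definition — is
unstated, so we report our closed-form value and note the discrepancy
rather than matching it.)

The survival GLM is a binomial logit on capture depth (metres), total
length, sex, time out of water and soak time; capture area is excluded by
default because it confounds with depth.  The depth effect is reported as
exp(−100·β) — the odds ratio per 100 m shallower — with its Wald CI.
Quasi-separation (fitted probabilities within 1e−8 of 0 or 1) is flagged;
on the 23-tag cohort the model frequently cannot be fitted at all, which
the pipeline reports rather than hides, and the estimable-scale analysis
(analysis/05_depth_effect.py) demonstrates recovery at n = 200.

## Problem sizes and determinism

Test and driver problem sizes are the study's: 24 tags × 30 days at 1 Hz,
360 two-hour windows per full deployment.  The end-to-end recovery check
runs 20 cohort replicates; periodogram and GLM calibrations use 100 seeded
replicates with 99–199 permutations.  Every stochastic step takes an
explicit seed; per-tag seeds are spawned from the cohort master seed, and
identical configurations reproduce byte-identical outputs.  A 12-character
SHA-256 prefix of the canonical YAML configuration is written to the run
log, report and JSON outputs to tie results to settings.

## Known limitations

The classifier cannot distinguish an extremely sluggish animal from a dead
one when no vertical movement survives the sensor error band — exactly the
ambiguity class; the estimate's treatment of that class is a reporting
choice, not evidence.  The transmitted high-activity count metric is
carried through I/O but nothing is built on it.  Temperature is carried but
not analyzed (no predation inference).  Geolocation/drift evidence is out
of scope; tag trajectories do not enter the fate rules.
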