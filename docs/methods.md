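# Methods

`seqdecode` analyses spike-train recordings from a delayed non-match-to-position
(DNMP) operant task: a rat presses a sample lever (left or right), holds the
side in memory across a 1, 5 or 10 s delay spent mostly at a nose port, then
earns reward by pressing the *opposite* lever.  The package quantifies three
population phenomena and their dissociation: sequential delay activity, early
transient stimulus encoding, and choice-related activity — plus controls that
separate genuine memory coding from positional confounds.  Because the analyses
are validated on simulated sessions with planted structure, this note states
both the models and what the simulations do and do not establish.

## Peri-event rate estimation

Rates are spike counts binned relative to a task event, divided by
(trials x bin width).  Defaults follow the analysis conventions used
throughout: 50 ms bins smoothed by a Gaussian kernel with sigma = 1/6 s
(truncated at +/-4 sigma and renormalized at edges, so constants are
preserved; spike mass is conserved to better than 1e-6 when the signal sits
more than 4 sigma from the array edge).  Pooled PSTHs are the average of the
left-trial and right-trial PSTHs, so unequal side counts weigh equally.
Z-scoring uses the mean and SD over a +/-50 s window around the event; the
window is truncated at session edges and zero-variance rows map to zeros.
Peak times are bin centers of the row maximum, earliest bin on ties.

Port-masked rate maps keep only time the head spent within 2.5 in of the nose
port (port located as the median head position at nose pokes).  Each bin's
rate is total in-port spikes over total in-port seconds (an occupancy-weighted
estimator — the plain trial average would be biased when port coverage varies
across trials), and bins with fewer than 25 contributing left trials and fewer
than 25 contributing right trials are masked invalid.

Occupancy maps histogram head positions on a 0.5 in grid (19 x 24 tiles over
the 9.5 x 12 in chamber, half-open tiles assigning edge points to the
lower-index tile) and normalize to proportions; multi-session maps average
per-session-normalized maps.

## Sequence statistics

The ridge-to-background ratio of a unit is the mean rate of the 11 bins
(0.1 s bins, a 1.1 s window) centered at its peak, divided by the mean rate of
all other bins in a +/-50 s background window.  Peak search windows are named
profiles: `delay` = [-1, delay + 1] s, `event` = [-5, +15] s, `delay_only` =
[0, delay].  Significance uses circular-shift surrogates: spike times rotated
by an offset drawn uniformly over the session (a 1 s minimum shift avoids
near-identity surrogates), which preserves the firing rate and inter-spike
statistics while destroying event alignment.  One-tailed p-values use the
add-one rule, p = (1 + #{null >= observed}) / (1 + n_shifts), so they are
never zero and are exactly (discretely) uniform under the null.  The
population statistic is the across-unit mean ratio compared against the
across-unit mean of the per-shift null ratios; shifts are drawn independently
per unit.  Default 1000 shifts.

Peak-order agreement between delay conditions uses Spearman rank correlation
with mid-ranks for ties; below 30 pairs the p-value comes from a seeded
permutation test rather than the t approximation.  Peak-time distribution
shifts use the two-sided Wilcoxon rank-sum test.

## Stimulus information

Within a 500 ms window split into k = 10 bins of 50 ms, counts are modeled as
independent Poisson with side-conditional rates given by the smoothed
condition PSTHs.  The pointwise mutual information of a count sequence s with
its side x is log2[P(s|x) / (P(s|left)/2 + P(s|right)/2)]; its expectation
over the fitted model is the model's mutual information, at most 1 bit for the
binary equiprobable stimulus.  The estimator simulates 500 count sequences
from the fitted model and averages the pointwise information; we average over
the posterior P(x|s) of each simulated sequence (conditional Monte Carlo),
which leaves the expectation unchanged and shrinks the variance enough that a
50 000-sample estimate matches brute-force summation to a few thousandths of
a bit.  A batch-of-50 standard error is reported with every estimate.

A 0.01 Hz rate floor enters every Poisson likelihood (here and in the
decoder) so a spike under a fitted rate of exactly zero keeps finite
log-probability; the floor only matters for near-silent units and leaves
estimates for ordinary rates untouched.

Significance of an information peak: trial side labels are permuted globally
(preserving side counts), the condition rates are refitted with the identical
smoothing pipeline, the sliding-window trace is recomputed, and its maximum
over the delay period recorded; 200 shuffles give the null peak distribution.
A unit is significant when its observed peak exceeds the 99th percentile of
the null peaks, taken as the order statistic (numpy `method="higher"`) —
linear interpolation between order statistics would make the nominal 1% level
closer to 1.5%.  Lever-press information uses the same machinery on a single
500 ms window centered at the press, and the press-context dispersion test
compares the across-unit variance of (sample-press minus choice-press
information) against its press-type-shuffled counterpart with a two-sided
F-test.

The estimate is the fitted model's information, not a debiased plug-in: with
few trials the fitted PSTHs differ between sides by chance, so raw traces sit
slightly above zero even for untuned units.  The shuffle test is built to be
exchangeable against exactly that bias.

## Population decoding

A maximum-likelihood Poisson decoder scores an N x k count matrix under each
side's rate models (trained on correct trials only) and picks the larger
log-likelihood; exact ties are broken by a seeded fair coin.  Because units
are not recorded simultaneously across sessions, evaluation uses 500
pseudo-trials per condition: each unit contributes the counts of one real
trial drawn with replacement from the fixed (side x outcome) condition.
Correct-trial accuracy uses leave-one-out cross-validation — the held-out
source trial of each unit is removed from that unit's training PSTH, which is
done algebraically (smoothing is linear, so the LOO PSTH is the smoothed
total minus the smoothed held-out trial, over n-1).  The SEM upper bound is
sqrt(p(1-p)/n_min) with n_min the minimum per-condition trial count across
units — the SEM the accuracy would have if trials were drawn without
replacement.

Error-trial generalization trains on all correct trials and scores error-trial
pseudo-trials against the *sample* label; sustained below-chance accuracy
around the choice press means the population reflects the upcoming (matching)
choice rather than the remembered sample.  Error-trial pseudo-trial count
defaults to 500 as well, and "below chance" claims are assessed against the
binomial at n_min — the dataset's own trial resolution.  Port-aligned decoding
aligns trials at the first detected port arrival, excludes trials where the
rat left the port within 1.5 s, and evaluates only windows inside that first
1.5 s, when every included trial is still at the port; this equalizes head
position across sides, so selectivity of positional origin collapses to
chance while genuine stimulus coding survives.

## GLM confound tests

Spike counts in 10 ms bins between each trial's sample press and choice press
are fit with Poisson GLMs (log link, statsmodels IRLS, parameter tolerance
1e-8).  Predictors: 9 position tiles (3 x 3 grid), 8 head-direction sectors
(45 degrees, half-open), velocity (vx, vy, speed from boxcar-smoothed finite
differences), 10 one-second delay-time indicators active only inside each
trial's own delay, a sample-side indicator, and the 10 time x sample
interactions — 41 predictors.  One active level per categorical group is
dropped as the reference; never-active indicators are dropped from both
models of a nested pair.  Time coding is tested by the likelihood-ratio
statistic for adding the 10 time indicators to the position/direction/velocity
model (10 df); sample-memory coding adds time + sample + interactions (21 df).
Full fits warm-start from the reduced fit's coefficients, and any fit with a
non-finite or positive log-likelihood is flagged non-converged and excluded
with a logged reason.  Null simulations on 40-trial sessions put both tests'
type-I error at the nominal level; substantially smaller sessions start to
strain the chi-square asymptotics for the 21-df test.

## The synthetic session model

`synthetic.make_preset_session` generates complete sessions so every stage
can be tested against ground truth:

* **Behavior** — a state machine with the task's timing rules: 30 s to press
  the sample lever (else a sample omission), delay of 1/5/10 s drawn
  equiprobably, 5 s to poke the lit port (else an abort), 5 s to press a
  choice lever, 5 s timeout after errors, 10 s inter-trial interval.  Outcomes
  are imposed, not emergent: correct probability defaults to 0.9/0.8/0.7 for
  1/5/10 s delays (the delay-dependent accuracy regime of a trained animal),
  omission and abort rates default to 3% and 2% — plausible lapse rates; the
  task defines their timing but not their frequency, so these are documented
  choices.  Latencies are log-normal with medians 2.5 s (sample press), 0.4 s
  (poke) and 1.2 s (choice press).  Default 300 trials/session (recording
  sessions run 200–520 trials), 30 Hz tracking.
* **Trajectory** — waypoint motion between the sample lever, the nose port
  (where the rat dwells from ~press + 1.4 s until the poke), the choice lever
  and the reward receptacle, with 0.12 in Gaussian jitter.  This is
  deliberately minimal: analyses consume only position/direction/speed
  summaries, not gait realism.
* **Spiking** — inhomogeneous Poisson by thinning against
  rate(t) = [baseline + delay-aligned Gaussian bump] x sample gain x choice
  gain + 2-D Gaussian position field, floored at zero.  Thinning ceilings are
  running block maxima (256-frame blocks widened to neighbors), a finer
  partition than per-trial ceilings with the same correctness argument.
  Baselines are uniform on 0.5–2.5 Hz so population means stay well under
  6 Hz.  One RNG stream drives behavior and one each unit, spawned from the
  session seed: adding units never perturbs behavior, and fixed seeds are
  bit-reproducible.

Presets plant the dynamics the analyses are meant to find: `sequences_only`
(bumps of 8–15 Hz, widths 0.4–0.8 s, tiling 0–10 s), `early_encoding` (the
same tiling plus x2.5–3.5 side gains on envelopes starting within 0.7 s of
delay onset and ending near 2 s — outlasting the run to the port, as required
for encoding that genuinely persists at the port — with envelope centers
independent of bump peaks by construction), `choice_encoding` (early sample
gains plus x2.5–3.5 choice-side gains in +/-0.5 s around the choice press),
`position_confound` (tuning only through position fields near the sample
levers, so early-delay "selectivity" is an artifact of the travel path), and
`null` (homogeneous Poisson).

What passing tests on these sessions do *not* show: robustness to
non-Poisson spiking (bursting, refractoriness), drifting baselines, spike
sorting errors, correlated noise across units, or behavioral strategies that
correlate position with memory beyond the planted travel paths.  The
simulator realizes exactly the probabilistic model the analyses assume, so
the tests validate correctness and calibration of the inference machinery,
not the model's adequacy for any particular dataset.

## Numerical and design choices

* Timestamps are float64 seconds from session start; absent events are NaN
  (nullable), never sentinels.  Camera rate is a config knob (30 Hz default;
  not dictated by the task).
* Chamber origin is the left corner of the nose-port wall, x across the
  9.5 in width.
* Circular shifts are drawn per unit independently (whether simultaneously
  recorded units should share shifts is moot for pseudo-populations).
* The sliding information window strides 50 ms by default; coarser strides
  (0.25 s) are used in calibration runs where only the peak's null rank
  matters.
* Analysis problem sizes in the test suite (session, unit and shuffle counts)
  are chosen so the full suite validates every property on a single CPU in
  minutes; all statistical checks state their sampling error explicitly.

## Known limitations

* The GLM's chi-square reference requires enough data per predictor; with
  very short sessions (<~20 trials) the 21-df test can be anticonservative
  and fits may fail to converge (such units are flagged, not silently kept).
* Port-masked maps need the animal at the port: bins before the typical
  arrival time are usually masked, so early-delay selectivity can only be
  assessed at the port from the arrival onward.
* The information estimate is model-based; it inherits any misfit of the
  smoothed Poisson rate model.
* NWB reading is not implemented; bundles are plain CSV/YAML directories.
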