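# seqdecode

Spike-train analysis for delayed non-match-to-position (DNMP) working-memory
sessions: event-aligned rate maps and sequence statistics, time-varying
mutual information between spiking and the sample stimulus, maximum-likelihood
population decoding with pseudo-trials, and Poisson-GLM confound tests — plus
a generative session simulator that plants known dynamics so every analysis
can be validated end to end.

## Who it is for

Systems neuroscientists analysing operant working-memory recordings in which a
rat presses a sample lever (left/right), waits out a 1/5/10 s delay at a nose
port, and is rewarded for choosing the opposite lever.  The central scientific
question the toolkit addresses: are stimulus memory and elapsed time carried
by the same population dynamics?  Typical findings it can quantify are
delay-spanning firing-rate sequences, transient stimulus encoding near delay
onset, choice-related activity at the response, and the dissociation between
them.

## The models at the core

* **Sequences.** Per unit, the ridge-to-background ratio: mean rate in the
  11-bin (1.1 s) window at the unit's peak over the mean rate of all other
  0.1 s bins in ±50 s.  Significance from circular-shift surrogates
  (spike times rotated modulo the session; one-tailed add-one p-values).

* **Stimulus information.** In a sliding 500 ms window of k = 10 bins, counts
  are independent Poisson with side-conditional rates λ_left(t), λ_right(t)
  (smoothed condition PSTHs).  The pointwise mutual information of a count
  sequence s with its side x is

      log₂ [ P(s | x) / (½ P(s | left) + ½ P(s | right)) ],
      P(s | x) = ∏ᵢ Poisson(sᵢ ; λ_x(binᵢ) · 0.05 s)

  and its Monte-Carlo average over model-simulated sequences is the fitted
  model's mutual information (≤ 1 bit).  Peaks are tested against a
  trial-label-shuffle null (99th percentile of 200 shuffled peaks).

* **Decoding.** A maximum-likelihood Poisson decoder picks
  argmax_x Σᵢⱼ log Poisson(Sᵢⱼ ; λ_x,i(binⱼ)·0.05 s) on pseudo-trials (one
  real trial per unit, drawn with replacement within a condition), with
  leave-one-out cross-validation on correct trials and error-trial
  generalization to separate sample from choice coding.

* **GLM tests.** Nested likelihood-ratio tests on 10 ms-bin Poisson GLMs ask
  whether delay time (10 df) or the task block time + sample + interaction
  (21 df) predicts spiking beyond head position, head direction and velocity.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import seqdecode as sq

# a session with planted sequences tiling the delay and stimulus
# selectivity confined to its first ~2 s
session, truth = sq.make_preset_session("early_encoding", seed=7,
                                        n_units=12, n_trials=300)
rng = np.random.default_rng(0)

rm = sq.smooth_rates(sq.estimate_rates(session, delays=(10.0,),
                                       window=(-1, 11), bin_width_s=0.1))
peaks = sq.peak_times(rm, (-1, 11))
print("rate peaks (s):", np.round(peaks, 2))

mean_ratio, p_pop, _ = sq.population_ridge_test(session, delays=(10.0,),
                                                n_shifts=1000, rng=rng)
print(f"population ridge-to-background: {mean_ratio:.2f}, p = {p_pop:.4g}")

tr = sq.shuffle_significance(session, "u000", n_shuffles=200, rng=rng,
                             delays=(10.0,), stride_s=0.25)
print(f"u000 info peak: {tr.peak_bits:.3f} bits at {tr.peak_time_s:.2f} s, "
      f"null99 = {tr.null_peak_99:.3f}, significant = {tr.significant}")

dec = sq.loo_accuracy_trace(session, delays=(10.0,), stride_s=1.0, rng=rng)
print("LOO decode accuracy:", np.round(dec.accuracy, 2))
```

Output:

```
rate peaks (s): [0.85 1.15 1.85 3.05 3.95 4.55 5.45 6.25 7.15 7.85 8.75 9.65]
population ridge-to-background: 6.33, p = 0.000999
u000 info peak: 0.820 bits at 1.00 s, null99 = 0.192, significant = True
LOO decode accuracy: [0.86 1.   0.94 0.45 0.55 0.55 0.38 0.46 0.42 0.62]
```

Reading the numbers: the twelve units' rate peaks tile the 10 s delay (the
planted sequence, recovered in order); the population ridge-to-background
ratio of 6.3 is larger than every one of 1000 circular-shift surrogates
(p ≈ 0.001, the add-one floor); unit `u000` carries 0.82 bits about the
sample side at 1.0 s into the delay, far above its shuffle threshold of
0.19 bits; and population decoding is nearly perfect in the first two seconds
of the delay but falls to chance (≈0.5) afterwards — stimulus encoding is
transient even though the sequence spans the whole delay.

## Command line

Bundles are plain directories (`trials.csv`, `units/unit_*.csv`,
`tracking.csv`, `session.yaml`):

```bash
seqdecode simulate --preset early_encoding --seed 7 --out sess/
seqdecode validate sess/
seqdecode ratemaps sess/ --delays 10 --out maps.csv
seqdecode sequences sess/ --shifts 1000 --seed 3 --out ridge.csv
seqdecode info sess/ --shuffles 200 --mc 500 --seed 11 --out info.csv
seqdecode decode sess/ --eval loo --pseudo 500 --seed 5 --out decode.csv
seqdecode glm sess/ --test both --out glm.csv
seqdecode run sess/ --seed 0 --out results/
```

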