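# whiskattn

Analysis pipeline for history-cued focal attention in a Go/NoGo
whisker-detection task, with a synthetic-data generator that provides
ground truth for every stage.

## The scientific problem

Head-fixed mice detect a brief deflection of one of nine whiskers
(arranged in a 3×3 row × arc grid) and report it by licking. Go trials
deflect one randomly chosen whisker; NoGo trials deflect none. Because
whisker identity is unpredictable, the recent history of
stimulus–reward association acts as an attentional cue: after one or
more rewarded detections (Hits) of a whisker, detection of *that*
whisker improves on the next trials, while detection of *other*
whiskers degrades. The same history boosts sensory responses of
layer-2/3 pyramidal cells in the corresponding barrel column of primary
somatosensory cortex.

`whiskattn` implements the full analysis chain for this paradigm:

- **Trial-history classification** — every current trial is labeled by
  the outcome and stimulus of the immediately preceding trials
  (prior NoGo / prior Miss same–different / prior 1 Hit same–different /
  prior >1 Hit same–different, with run length, somatotopic offset
  class, inter-Go interval and prior reward size).
- **History-conditioned signal detection** — sensitivity
  d′ = Z(HR) − Z(FA) and criterion c = −(Z(HR) + Z(FA))/2 per history
  category, with the false-alarm rate drawn from NoGo trials carrying
  the matched history; engagement-window trimming by a 50-trial sliding
  d′ cutoff; spatial gradients over somatotopic offset and temporal
  profiles over inter-Go intervals.
- **Neural metrics** — ΔF/F with neuropil subtraction and a
  20th-percentile baseline, evoked responses in fixed post-stimulus
  windows, a permutation responsiveness test with FDR correction,
  attention modulation indices AMI = (A − B)/|A + B| between history
  conditions, linear baseline detrending for VIP-like interneurons, the
  somatotopic profile of attentional boosting, and spike PSTHs.
- **Receptive-field shifts** — 9-whisker receptive fields per history
  condition, center-of-mass shifts projected on the attention axis from
  the columnar whisker to the attended whisker, and CW/SW response
  modulation indices.
- **Population decoding** — per-session L2-regularized logistic
  regression detecting stimulus presence from single-trial population
  activity, with outcome-class balancing, cross-validated ridge
  strength, and history-conditioned evaluation.
- **Synthetic sessions** — a generator that works in effective-d′
  space (somatotopic kernel × temporal decay × hit-streak scaling,
  mapped through an equal-variance Gaussian observer) and emits neural
  populations with known multiplicative attentional gain, so every
  estimator can be validated against stored ground truth.

## Worked example

```python
import numpy as np
from whiskattn import behavior, simulate
from whiskattn.grid import generate_whisker_grid

grid = generate_whisker_grid()                      # 3x3, 300 µm pitch
cfg = simulate.BehaviorGenConfig(p_same_repeat=0.4, n_trials=600)

counts = []
for seed in range(20):
    session = simulate.generate_session(cfg, grid, seed=seed)
    labels = behavior.classify_trial_history(session)
    window = behavior.engagement_window(session)
    counts.append(behavior.history_counts(session, labels, window))

pooled = behavior.pooled_history_sdt(counts)
for cat in ("priorGT1HitSame", "priorNoGo", "priorGT1HitDiff"):
    m = pooled[cat]["metrics"]
    print(f"{cat:18s} d' = {m.d_prime:5.2f}  (n_go = {m.n_go})")
```

Output:

```
priorGT1HitSame    d' =  2.66  (n_go = 319)
priorNoGo          d' =  1.22  (n_go = 2925)
priorGT1HitDiff    d' =  0.59  (n_go = 376)
```

Detection sensitivity after two or more consecutive rewarded hits to
the same whisker (≈2.7) is roughly double the prior-NoGo baseline
(≈1.2), while multi-hit streaks to a *different* whisker suppress it
(≈0.6) — the attend-toward / attend-away signature the analysis is
built to quantify. (The generator enriches same-whisker repeats,
mirroring the task variant used to populate multi-hit histories.)

The same pipeline runs from the shell:

```bash
whiskattn all --seed 7 --out runs/demo        # simulate → ... → report
```

which writes the trial/cell tables, per-stage JSON metric tables, and a
manifest with the seeds needed to reproduce every output byte-for-byte.

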