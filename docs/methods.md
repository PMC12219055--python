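# Methods

This note documents the models implemented in `whiskattn`, the
parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical conventions used throughout.

## Signal-detection model

Behavioral sensitivity and bias follow the standard equal-variance
Gaussian model: d′ = Z(HR) − Z(FA) and c = −(Z(HR) + Z(FA))/2, where Z
is the standard-normal quantile, HR the hit rate and FA the false-alarm
rate. The sign convention for c makes liberal responding (high HR and
FA) negative, which matches how criterion shifts after rewarded trials
are conventionally reported; the occasionally seen opposite-sign form
c = +(Z_HR + Z_FA)/2 differs only by sign.

Rates of exactly 0 or 1 make Z infinite. The default correction is
log-linear — (k + 0.5)/(n + 1), applied only when the raw rate is
exactly 0 or 1 — with `correction="none"` available for callers who
prefer an error. At small per-category trial counts this correction
caps attainable |Z| and biases per-session d′ toward zero, which is why
the multi-session functions (`history_counts` → `pooled_history_sdt`)
pool 2×2 outcome counts across sessions *before* the inverse-normal
transform, with bootstrap-over-sessions confidence intervals
(`bootstrap_pooled_dprime`).

## Engagement window

A session's analyzable span is bounded by the first and last trial
whose 50-trial sliding-window d′ (centered, clipped at the session
edges) reaches a cutoff of 0.5 (1.2 is the conventional stricter value
for spike-recording sessions). Trials outside the window are dropped
from every rate computation; aborted trials never contribute to rates
but keep their place in time.

## Trial-history taxonomy

Each current Go trial is classified by the immediately preceding
trials: prior NoGo; prior Miss to the same/different whisker; prior
single Hit to the same/different whisker; or two or more consecutive
Hits to one consistent whisker (same/different). Current NoGo trials
use the matched categories (prior NoGo / Miss / 1 Hit / >1 Hit, whisker
identity collapsed), and supply the false-alarm rate for the
corresponding Go categories — the same- and different-whisker variants
share one NoGo pool because NoGo trials have no whisker.

Two walking modes are provided: `consecutive` (history is literally the
previous trials) and `ignore-nogo` (NoGo trials are skipped, so history
is defined Go-to-Go — required when profiling effects against the
inter-Go interval). Aborted trials are skipped as history sources and,
by default, do not break a hit streak (configurable). Hits whose reward
is below a configurable fraction of the session maximum (4% mirrors the
reward-size control analysis) can be treated as non-boosting, i.e. like
misses, when building streaks.

## Synthetic behavioral sessions

The generator works in effective-d′ space. On each Go trial,

    d′_eff = d0 + exp(−Δt/τ) · f(run) · [B·k(offset) − S·(1 − k(offset))]

where d0 = 1.13 is baseline sensitivity, k is the somatotopic kernel of
the offset between the prior-hit-streak whisker and the current whisker
(same = 1, same-row adjacent = 0.8, same-arc adjacent = 0.45, diagonal
adjacent = 0.05, further = 0), Δt is the time since the last rewarded
Go, τ (default 10 s) the temporal decay constant, and f(run) = 1.75 for
streaks of two or more hits. B is the attend-toward boost and S an
attend-away suppression; a non-negative-kernel boost alone cannot
reproduce the empirical finding that sensitivity *drops* below baseline
after hits to a distant whisker, so suppression scales with (1 − k).

Calibration: B is set so d′_eff after a >1-hit same-whisker streak at
the mean one-ITI lag equals 2.45; S is set so the *category average*
over uniformly drawn different whiskers (kernel averaged over the 3×3
pair geometry) equals 0.82. Both are the point estimates this paradigm
reports under its standard conditions and serve as fixed calibration
constants, not tuned values.

Outcomes come from an equal-variance Gaussian observer with an absolute
decision criterion λ = d0/2 + c: P(hit) = Φ(d′_eff − λ),
P(FA) = Φ(−λ). Because λ is shared between Go trials and their
history-matched NoGo trials, the d′ recovered from a category converges
to the mixture-implied generating value Z(E[P(hit)]) − Z(E[P(FA)]) —
exposed as `truth_category_dprime` — rather than to the arithmetic mean
of per-trial d′_eff, which differs whenever a category mixes
heterogeneous offsets or lags (Jensen's inequality through Φ). Recovery
tests therefore always compare estimates against this stored-truth
quantity, never against hard-coded numbers.

The criterion shifts by −0.3 (liberal) on trials following any hit.
Go/NoGo draws are i.i.d. (P(Go) = 0.55), ITIs uniform on 3 ± 2 s,
whisker identity uniform over the nine whiskers, with an optional
`p_same_repeat` probability of repeating the previous Go whisker — the
task variant that enriches same-whisker histories. Desk-scale analyses
use `p_same_repeat = 0.4`: under pure equal-probability sampling,
multi-hit-same histories need three consecutive same-whisker Go trials
(probability (1/9)² per Go pair) and are far too rare at 20 × 600
trials, which is precisely why the original paradigm includes a
repeat-enriched variant. Hit streaks survive intervening NoGo trials
(subject to the temporal decay), so a small attentional residue
contaminates the prior-NoGo baseline category — in truth and estimate
alike, as in the real task.

## Synthetic neural populations

Cells are placed uniformly over the barrel map (300 µm pitch; the mean
barrel width equals the pitch). Tuning is a Gaussian bump of the
cortical distance between the cell and the stimulated whisker's column
center (width 0.6 column widths, peak 0.5 ΔF/F). Per-trial responses
are gain × tuning + Gaussian noise; NoGo trials evoke zero mean.

Pyramidal-like mode applies a multiplicative gain (default 2) on Go
trials whose hit streak matches the current whisker, to cells within
`gain_space_halfwidth` (default 0.75 column widths) of that whisker's
column center and in a gain-bearing layer — a hard-edged spotlight
whose half-width the somatotopic profile analysis should recover.
VIP-like mode applies the gain after any qualifying streak regardless
of whisker or position, and adds an exponentially declining post-reward
baseline to frame traces. Spike mode emits Poisson trains with five
evoked rate bumps at 100-ms spacing over a 4-Hz baseline, binned
analyses at 10 ms. Generating gains are stored per trial × cell.

The generator emulates the *statistical structure* the analyses assume:
multiplicative whisker-specific gain, somatotopic falloff, non-specific
arousal gain, post-reward baseline decay. It does not model calcium
indicator dynamics beyond a fixed exponential kernel, correlated noise
across cells, adaptation, or behavioral covariates (whisking, pupil);
passing recovery tests on it validates the estimators, not the
biological fidelity of any particular dataset.

## Neural metrics

ΔF/F is (F_t − F0)/F0 with F0 the 20th percentile of the (optionally
neuropil-corrected, scale 0.3) series. Evoked responses are
mean(post-stimulus window) − mean(pre-stimulus baseline window); the
calcium windows are specified in frames (7 post, 2 baseline at 7.5 Hz —
window durations in seconds are derived from the frame counts), spikes
use a 0.5-s window. z-scoring divides by the baseline-epoch standard
deviation pooled across the session's trials.

Responsiveness is a one-sided (Go > NoGo) two-sample permutation test
per whisker, FDR-corrected across the nine whiskers; a cell is
responsive iff some whisker has adjusted p < 0.05 *and* a positive mean
evoked difference. AMI denominators below 1e-6 (response units) mark
the index invalid rather than clipping. Single-cell AMI requires at
least 3 trials per condition. VIP detrending fits a line to the
per-condition median pre-stimulus trace (8 frames ≈ 1.07 s) and
subtracts its extrapolation from every trial of that condition — exact
for linear trends, step-amplitude preserving by construction.

The somatotopic profile bins cells by normalized distance to a
reference whisker's column center (0.25-column bins), averages evoked
responses per history condition and reference whisker, then averages
over the nine references. The attentional footprint is the
condition-minus-prior-NoGo profile; `profile_half_max_distance`
interpolates the distance at which it falls to half its near-column
value. Because the profile difference is (g − 1) × tuning inside the
spotlight, the tuning falloff slightly advances the half-max point
relative to the hard spotlight edge; with the default widths the
discrepancy is within a bin.

## Receptive fields and the attention axis

Receptive fields live on a columnar-whisker-centered offset grid, x
rostral-positive along arcs, y up-positive along rows. The center of
mass is the response-weighted mean offset with negative weights clipped
at zero (a signed field has no well-defined CoM; clipping is logged by
the flag in the call). Shifts are computed only on the intersection of
the two conditions' sampling masks, require at least 6 of 9 positions,
and are projected on the unit vector toward the attended whisker and
normalized by the CW-to-target distance; per-cell shifts average over
available targets with equal weight. Population CoMs are unweighted
across cells. At desk scale the per-target attend fields pool single-
and multi-hit streak trials so that enough of the 9 positions are
sampled; the condition set is a parameter.

## Decoder

Features are per-trial evoked scalars of whisker-responsive cells.
Each balanced-resampling iteration undersamples Hit/Miss/CR/FA to the
minority count (asserted equal each iteration), assigns 10 folds,
selects the ridge strength by internal 10-fold cross-validated log-loss
over a 30-point grid spanning six decades, and collects
stimulus-present calls (threshold 0.5 on the logistic output) from
held-out folds only (fold disjointness asserted). Balancing happens
once per iteration before folding. Performance is the fraction of
trials called stimulus-present per (trial filter × history category),
averaged over iterations (default 25); the shuffled control refits with
permuted training labels. Tests and the acceptance script use reduced
settings (4–5 iterations, 5 folds, 8–10 grid points) that preserve the
procedure at desk scale.

## Statistics

Permutation tests use the add-one convention
p = (1 + #{null ≥ observed}) / (1 + iterations), so p is never zero and
is bounded below by 1/(iterations + 1); the default is 10,000
iterations, two-sided on |Δmean| (one-sided variants available). The
two-sample null is generated in a canonical form (sorted pool,
minority-size split) so p-values are bit-identical under group-order
swap and under adding a constant. FDR adjustment is Benjamini–Hochberg
step-up. The binomial exact test is two-sided by the minimum-likelihood
method. Every stochastic call takes an explicit seed; a master seed
fans out through a SeedSequence-based counter scheme (`spawn_seeds`).

## Pipeline and formats

Trial and cell tables are tab-delimited text with fixed schemas
(0-based trial indices); responses are HDF5 (`/evoked`, optional
`/traces`, window metadata as attributes) with a delimited fallback;
configuration is TOML; the generator writes a ground-truth JSON
sidecar. `run_pipeline` executes simulate → behavior → neural → rf →
decode → report and writes a manifest with the version, config hash,
per-stage seeds and filter counts; identical config + seed reproduces
every metric table byte-for-byte (floats are rounded to 9 decimals in
JSON reports, full precision in the TSV tables).

## Known limitations

- The generator's observer is stationary within a trial class; slow
  motivational drifts (which the engagement window exists to trim in
  real data) are not simulated beyond the window's ability to pass
  through.
- Suppression of different-whisker detection is modeled as a single
  (1 − k)-scaled term; real attend-away costs may have their own
  spatial structure.
- The hard-edged spotlight makes half-width recovery well-posed but is
  a simplification of any real cortical gain field.
- Per-session d′ at small counts is bias-prone under extreme-rate
  correction; use the pooled-count estimators for quantitative
  comparisons.
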