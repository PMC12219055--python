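"""Evoked-response extraction and attentional modulation of neural data.

Covers ΔF/F computation with neuropil subtraction, evoked-response
windows, the permutation responsiveness test with FDR correction,
attention modulation indices (AMI), linear baseline detrending for
VIP-like cells, the somatotopic profile of attentional modulation, and
spike PSTHs.

The attention modulation index between two history conditions with
condition-mean evoked responses a and b is AMI = (a - b) / |a + b|;
under a pure multiplicative gain g (a = g*b) this equals (g-1)/(g+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from whiskattn import stats

__all__ = [
    "FluorescenceTrace",
    "AMIRecord",
    "ResponsivenessResult",
    "dff_from_fluorescence",
    "evoked_response",
    "evoked_from_table",
    "responsiveness_test",
    "compute_ami",
    "ami_per_cell",
    "detrend_baseline",
    "somatotopic_profile",
    "profile_half_max_distance",
    "psth",
]

NEUROPIL_SCALE = 0.3
POST_WINDOW_FRAMES = 7           # 0.933 s at 7.5 Hz
BASELINE_WINDOW_FRAMES = 2
AMI_DENOM_EPS = 1e-6
MIN_TRIALS_PER_CONDITION = 3


@dataclass(frozen=True)
class FluorescenceTrace:
    """A fluorescence time series with its fractional-change transform."""

    frames: np.ndarray
    frame_rate: float
    f0: float
    dff: np.ndarray


@dataclass(frozen=True)
class AMIRecord:
    """Attention modulation indices for one cell.

    ami_same_vs_nogo / ami_diff_vs_nogo compare multi-hit same/different
    histories against the prior-NoGo baseline; ami_same_vs_diff compares
    the two multi-hit histories directly. Indices are None when the
    denominator magnitude falls below AMI_DENOM_EPS.
    """

    ami_same_vs_nogo: float | None
    ami_diff_vs_nogo: float | None
    ami_same_vs_diff: float | None
    n_trials: dict
    valid: bool


@dataclass(frozen=True)
class ResponsivenessResult:
    """Per-whisker permutation p-values and the responsiveness call."""

    p_values: dict
    p_adjusted: dict
    evoked_means: dict
    responsive: bool
    best_whisker: str | None


def dff_from_fluorescence(raw, neuropil=None, scale: float = NEUROPIL_SCALE,
                          frame_rate: float = 7.5) -> FluorescenceTrace:
    """ΔF/F from a raw somatic fluorescence series.

    When a neuropil series is given it is scaled by ``scale`` and
    subtracted first (pyramidal-cell imaging); VIP-cell imaging passes
    no neuropil. F0 is the 20th percentile of the corrected series and
    ΔF/F = (F_t - F0) / F0 framewise.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty fluorescence series")
    if neuropil is not None:
        neuropil = np.asarray(neuropil, dtype=float)
        if neuropil.shape != raw.shape:
            raise ValueError("neuropil series must match raw series length")
        corrected = raw - scale * neuropil
    else:
        corrected = raw
    f0 = float(np.percentile(corrected, 20))
    if f0 <= 0:
        raise ValueError(f"degenerate baseline: 20th percentile F0 = {f0}")
    return FluorescenceTrace(frames=corrected, frame_rate=frame_rate,
                             f0=f0, dff=(corrected - f0) / f0)


def evoked_response(trace, onset: int, post_window: int = POST_WINDOW_FRAMES,
                    baseline_window: int = BASELINE_WINDOW_FRAMES,
                    baseline_sd: float | None = None) -> float:
    """Scalar evoked magnitude of one trial trace.

    mean(post-stimulus window) - mean(pre-stimulus baseline window),
    with the post window starting at ``onset`` (frame index) and the
    baseline window ending there. Passing ``baseline_sd`` (pooled
    across trials) z-scores the result.
    """
    trace = np.asarray(trace, dtype=float)
    if onset - baseline_window < 0 or onset + post_window > trace.size:
        raise ValueError(
            f"windows out of bounds: onset {onset}, trace length {trace.size}")
    post = trace[onset:onset + post_window].mean()
    base = trace[onset - baseline_window:onset].mean()
    value = float(post - base)
    if baseline_sd is not None:
        if baseline_sd <= 0:
            raise ValueError("baseline_sd must be positive")
        value /= baseline_sd
    return value


def evoked_from_table(traces: np.ndarray, onset: int,
                      post_window: int = POST_WINDOW_FRAMES,
                      baseline_window: int = BASELINE_WINDOW_FRAMES,
                      normalize: str = "raw") -> np.ndarray:
    """Evoked scalars for a (trials, cells, frames) trace block.

    normalize="zscore-baseline" divides each cell's evoked values by the
    standard deviation of its pre-stimulus baseline frames pooled across
    all trials.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 3:
        raise ValueError("traces must be (trials, cells, frames)")
    if onset - baseline_window < 0 or onset + post_window > traces.shape[2]:
        raise ValueError("windows out of bounds")
    post = traces[:, :, onset:onset + post_window].mean(axis=2)
    base = traces[:, :, onset - baseline_window:onset].mean(axis=2)
    evoked = post - base
    if normalize == "zscore-baseline":
        pooled_sd = traces[:, :, onset - baseline_window:onset].std(axis=(0, 2))
        pooled_sd = np.where(pooled_sd > 0, pooled_sd, np.nan)
        evoked = evoked / pooled_sd[None, :]
    elif normalize != "raw":
        raise ValueError(f"unknown normalize mode {normalize!r}")
    return evoked


def responsiveness_test(go_responses: dict, nogo_responses,
                        n_iterations: int = stats.DEFAULT_N_ITERATIONS,
                        seed: int = 0, alpha: float = 0.05,
                        min_trials: int = MIN_TRIALS_PER_CONDITION,
                        ) -> ResponsivenessResult:
    """Whisker-responsiveness of one cell by permutation test.

    For each whisker the Go evoked-response distribution is compared to
    the NoGo distribution with a one-sided (Go > NoGo) two-sample
    permutation test; the per-whisker p-values are FDR-adjusted. The
    cell is responsive iff at least one whisker has adjusted p < alpha
    with a positive mean evoked difference.
    """
    nogo = np.asarray(nogo_responses, dtype=float)
    if nogo.size < min_trials:
        raise ValueError("insufficient NoGo trials to classify cell")
    whiskers = [w for w, r in go_responses.items()
                if np.asarray(r).size >= min_trials]
    if not whiskers:
        raise ValueError("no whisker has enough Go trials to classify cell")
    seeds = stats.spawn_seeds(seed, len(whiskers))
    p_values, means = {}, {}
    for w, s in zip(whiskers, seeds):
        go = np.asarray(go_responses[w], dtype=float)
        res = stats.permutation_test_two_sample(
            go, nogo, n_iterations=n_iterations, seed=s, sided="greater")
        p_values[w] = res.p_value
        means[w] = float(go.mean() - nogo.mean())
    adjusted = dict(zip(whiskers, stats.fdr_adjust(
        [p_values[w] for w in whiskers])))
    significant = [w for w in whiskers
                   if adjusted[w] < alpha and means[w] > 0]
    best = (max(significant, key=lambda w: means[w]) if significant
            else None)
    return ResponsivenessResult(p_values=p_values, p_adjusted=adjusted,
                                evoked_means=means,
                                responsive=bool(significant),
                                best_whisker=best)


def compute_ami(condition_means: dict,
                n_trials: dict | None = None,
                min_trials: int = MIN_TRIALS_PER_CONDITION) -> AMIRecord:
    """Attention modulation indices from condition-mean evoked responses.

    ``condition_means`` must contain "priorGT1HitSame", "priorGT1HitDiff"
    and "priorNoGo" (mean evoked response of current-Go trials with that
    history). ``n_trials`` gives per-condition trial counts for the
    validity flag.
    """
    n_trials = n_trials or {}

    def index(a_key: str, b_key: str) -> float | None:
        a = condition_means.get(a_key)
        b = condition_means.get(b_key)
        if a is None or b is None:
            return None
        denom = abs(a + b)
        if denom < AMI_DENOM_EPS:
            return None
        return float((a - b) / denom)

    valid = all(n_trials.get(c, 0) >= min_trials
                for c in ("priorGT1HitSame", "priorGT1HitDiff", "priorNoGo"))
    return AMIRecord(
        ami_same_vs_nogo=index("priorGT1HitSame", "priorNoGo"),
        ami_diff_vs_nogo=index("priorGT1HitDiff", "priorNoGo"),
        ami_same_vs_diff=index("priorGT1HitSame", "priorGT1HitDiff"),
        n_trials=dict(n_trials),
        valid=valid,
    )


def ami_per_cell(evoked: np.ndarray, session, labels,
                 min_trials: int = MIN_TRIALS_PER_CONDITION) -> list[AMIRecord]:
    """AMI for every cell from a (trials, cells) evoked matrix.

    Condition means pool current-Go trials (any whisker) by history
    category, as the index definitions require.
    """
    evoked = np.asarray(evoked, dtype=float)
    cats = ("priorGT1HitSame", "priorGT1HitDiff", "priorNoGo")
    masks = {}
    for cat in cats:
        masks[cat] = np.array(
            [t.kind == "Go" and not t.aborted and lab.category == cat
             for t, lab in zip(session.trials, labels)])
    records = []
    for c in range(evoked.shape[1]):
        means = {}
        counts = {}
        for cat in cats:
            vals = evoked[masks[cat], c]
            vals = vals[~np.isnan(vals)]
            counts[cat] = int(vals.size)
            if vals.size:
                means[cat] = float(vals.mean())
        records.append(compute_ami(means, counts, min_trials))
    return records


def detrend_baseline(traces_by_condition: dict, onset: int,
                     baseline_window: int = 8, frame_rate: float = 7.5,
                     ) -> tuple[dict, dict]:
    """Remove per-condition linear baseline trends from trial traces.

    For each history condition, the median pre-stimulus trace over its
    trials (the ``baseline_window`` frames before ``onset``; 8 frames is
    1.07 s at 7.5 Hz) is fit with a line, which is extrapolated over the
    full trace length and subtracted from every trial of that condition.
    Conditions with fewer than 2 trials are skipped (returned
    untouched, listed under the "skipped" key of the second return
    value).

    Returns (detrended: dict condition -> (trials, frames) array,
    info: {"slopes": {condition: slope per frame}, "skipped": [...]}).
    """
    detrended = {}
    slopes = {}
    skipped = []
    for cond, arr in traces_by_condition.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError("each condition needs a (trials, frames) array")
        if arr.shape[0] < 2:
            detrended[cond] = arr.copy()
            skipped.append(cond)
            continue
        if onset - baseline_window < 0:
            raise ValueError("baseline window precedes trace start")
        frames = np.arange(arr.shape[1], dtype=float)
        base_frames = frames[onset - baseline_window:onset]
        median_base = np.median(arr[:, onset - baseline_window:onset], axis=0)
        slope, intercept = np.polyfit(base_frames, median_base, 1)
        line = slope * frames + intercept
        detrended[cond] = arr - line[None, :]
        slopes[cond] = float(slope)
    return detrended, {"slopes": slopes, "skipped": skipped}


def somatotopic_profile(cells, evoked: np.ndarray, session, labels,
                        bin_width: float = 0.25, max_distance: float = 2.0,
                        conditions=("priorNoGo", "priorGT1HitSame",
                                    "priorGT1HitDiff"),
                        min_trials: int = 1) -> dict:
    """Mean evoked response vs cortical distance to the reference column.

    For each reference whisker, cells are binned by their distance to
    that whisker's column center (normalized by the mean barrel width);
    the mean response of each bin to reference-whisker Go trials is
    computed per history condition, then averaged over all reference
    whiskers. For the same/different conditions the reference whisker is
    the attended (prior-hit streak) whisker, so the profile reads out
    the spatial footprint of attentional boosting.

    Returns {"bin_centers": array, condition: mean-profile array (NaN
    for empty bins)}.
    """
    grid = session.grid
    evoked = np.asarray(evoked, dtype=float)
    xy = np.asarray(cells.xy_um, dtype=float)
    edges = np.arange(0.0, max_distance + bin_width / 2, bin_width)
    centers = edges[:-1] + bin_width / 2
    n_bins = centers.size

    sums = {c: np.zeros(n_bins) for c in conditions}
    counts = {c: np.zeros(n_bins) for c in conditions}

    for ref in grid.whiskers:
        dist = (np.linalg.norm(xy - grid.centroid(ref), axis=1)
                / grid.mean_barrel_width)
        bin_idx = np.digitize(dist, edges) - 1
        in_range = (bin_idx >= 0) & (bin_idx < n_bins)
        for cond in conditions:
            if cond == "priorNoGo":
                mask = [t.kind == "Go" and not t.aborted
                        and t.whisker == ref and lab.category == cond
                        for t, lab in zip(session.trials, labels)]
            else:
                # attended whisker = reference; current whisker = reference
                # for "same", any other for "diff"
                want_same = cond == "priorGT1HitSame"
                mask = [t.kind == "Go" and not t.aborted
                        and lab.category == cond
                        and (lab.prior_whisker == ref if want_same
                             else t.whisker == ref)
                        for t, lab in zip(session.trials, labels)]
            mask = np.asarray(mask)
            if mask.sum() < min_trials:
                continue
            cell_means = evoked[mask].mean(axis=0)
            for b in range(n_bins):
                sel = in_range & (bin_idx == b)
                if sel.any():
                    sums[cond][b] += cell_means[sel].sum()
                    counts[cond][b] += sel.sum()

    out = {"bin_centers": centers}
    for cond in conditions:
        with np.errstate(invalid="ignore"):
            out[cond] = np.where(counts[cond] > 0,
                                 sums[cond] / np.maximum(counts[cond], 1),
                                 np.nan)
    return out


def profile_half_max_distance(profile: dict, condition: str = "priorGT1HitSame",
                              baseline: str = "priorNoGo") -> float:
    """Distance (column widths) at which the attentional profile
    difference (condition - baseline) first falls to half its value at
    the nearest bin, by linear interpolation."""
    centers = profile["bin_centers"]
    diff = profile[condition] - profile[baseline]
    valid = ~np.isnan(diff)
    centers, diff = centers[valid], diff[valid]
    if centers.size < 2 or diff[0] <= 0:
        raise ValueError("no positive attentional profile to measure")
    half = diff[0] / 2.0
    below = np.nonzero(diff <= half)[0]
    if below.size == 0:
        return float(centers[-1])
    j = below[0]
    if j == 0:
        return float(centers[0])
    x0, x1 = centers[j - 1], centers[j]
    y0, y1 = diff[j - 1], diff[j]
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


def psth(spike_times_per_trial, bin_width: float = 0.010,
         t_start: float = -0.5, t_stop: float = 1.0) -> dict:
    """Peristimulus time histogram: trial-averaged rate in Hz.

    ``spike_times_per_trial`` is a sequence of arrays of spike times in
    seconds relative to stimulus onset. Returns {"bin_centers", "rate"}.
    """
    edges = np.arange(t_start, t_stop + 1e-9, bin_width)
    centers = edges[:-1] + bin_width / 2
    n_trials = len(spike_times_per_trial)
    if n_trials == 0:
        return {"bin_centers": centers, "rate": np.zeros(centers.size)}
    counts = np.zeros(centers.size)
    for times in spike_times_per_trial:
        hist, _ = np.histogram(np.asarray(times, dtype=float), bins=edges)
        counts += hist
    return {"bin_centers": centers,
            "rate": counts / (n_trials * bin_width)}


def spike_evoked_rate(spike_times, window: float = 0.5,
                      baseline_window: float = 0.5) -> float:
    """Evoked firing-rate change (Hz): post-stimulus window rate minus
    the rate in an equal pre-stimulus baseline window."""
    t = np.asarray(spike_times, dtype=float)
    post = np.sum((t >= 0) & (t < window)) / window
    base = np.sum((t >= -baseline_window) & (t < 0)) / baseline_window
    return float(post - base)
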