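"""Trial-history classification and history-conditioned signal detection.

The behavioral analysis proceeds in three steps: (1) restrict each
session to its task-engaged phase using a sliding-window d' cutoff,
(2) label every trial by the stimulus/outcome/reward history of the
immediately preceding trials, and (3) compute hit and false-alarm rates,
d' and criterion per history category, with false-alarm rates drawn from
NoGo trials carrying the matched history.

Sensitivity is d' = Z(HR) - Z(FA). Criterion is reported as
c = -(Z(HR) + Z(FA)) / 2, the convention in which liberal responding
(high hit and false-alarm rates) gives negative c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from whiskattn.grid import WhiskerGrid

__all__ = [
    "Trial",
    "Session",
    "HistoryLabel",
    "SDTMetrics",
    "GO_CATEGORIES",
    "NOGO_CATEGORIES",
    "GO_TO_NOGO_CATEGORY",
    "engagement_window",
    "classify_trial_history",
    "compute_sdt",
    "history_conditioned_sdt",
    "history_counts",
    "pooled_history_sdt",
    "pooled_spatial_gradient",
    "pooled_temporal_profile",
    "bootstrap_pooled_dprime",
    "spatial_gradient",
    "temporal_profile",
    "fit_temporal_decay",
]

#: History categories assigned to current Go trials.
GO_CATEGORIES = (
    "priorNoGo",
    "prior1HitSame",
    "priorGT1HitSame",
    "prior1HitDiff",
    "priorGT1HitDiff",
    "priorMissSame",
    "priorMissDiff",
)

#: History categories assigned to current NoGo trials.
NOGO_CATEGORIES = ("priorNoGo", "prior1Hit", "priorGT1Hit", "priorMiss")

#: NoGo pool supplying the false-alarm rate for each Go category. Same-
#: and different-whisker Go categories share one NoGo pool, since whisker
#: identity is undefined on NoGo trials.
GO_TO_NOGO_CATEGORY = {
    "priorNoGo": "priorNoGo",
    "prior1HitSame": "prior1Hit",
    "prior1HitDiff": "prior1Hit",
    "priorGT1HitSame": "priorGT1Hit",
    "priorGT1HitDiff": "priorGT1Hit",
    "priorMissSame": "priorMiss",
    "priorMissDiff": "priorMiss",
}

DEFAULT_MIN_GO = 5
DEFAULT_MIN_NOGO = 5


@dataclass(frozen=True)
class Trial:
    """One behavioral trial.

    Go trials carry a whisker label and end in Hit or Miss; NoGo trials
    have no whisker and end in FA or CR. Aborted trials (early licks)
    are excluded from rate computations but keep their place in time.
    """

    index: int
    onset_time: float
    kind: str                      # "Go" | "NoGo"
    whisker: str | None
    amplitude: float
    outcome: str                   # "Hit" | "Miss" | "FA" | "CR"
    reward_volume: float = 0.0
    first_lick_latency: float | None = None
    aborted: bool = False

    def __post_init__(self):
        if self.kind == "Go":
            if self.whisker is None:
                raise ValueError(f"trial {self.index}: Go trial without whisker")
            if not self.aborted and self.outcome not in ("Hit", "Miss"):
                raise ValueError(
                    f"trial {self.index}: Go outcome must be Hit or Miss")
        elif self.kind == "NoGo":
            if self.whisker is not None:
                raise ValueError(f"trial {self.index}: NoGo trial with whisker")
            if not self.aborted and self.outcome not in ("FA", "CR"):
                raise ValueError(
                    f"trial {self.index}: NoGo outcome must be FA or CR")
        else:
            raise ValueError(f"trial {self.index}: kind must be Go or NoGo")


@dataclass
class Session:
    """An ordered sequence of trials with task metadata."""

    trials: list[Trial]
    grid: WhiskerGrid
    subject_id: str = "synthetic"
    task_variant: str = "EqP"
    delay_period: float = 0.5
    #: optional per-trial generating effective d' (ground truth)
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        onsets = [t.onset_time for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onset times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class HistoryLabel:
    """Per-trial categorization of recent stimulus-reward history."""

    category: str | None
    run_length: int = 0
    prior_whisker: str | None = None
    offset_class: str = "n/a"
    inter_go_interval: float | None = None
    prior_reward_fraction: float | None = None
    low_reward: bool = False


@dataclass(frozen=True)
class SDTMetrics:
    """Hit/false-alarm rates and the derived sensitivity and criterion."""

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    n_go: int
    n_nogo: int
    correction_applied: bool = False


# ---------------------------------------------------------------------------
# core SDT


def _rate(k: int, n: int, correction: str) -> tuple[float, bool]:
    """Proportion k/n, with the log-linear (k+0.5)/(n+1) correction
    applied only when the raw rate is exactly 0 or 1."""
    if n == 0:
        raise ValueError("zero trials in a response class")
    raw = k / n
    if raw in (0.0, 1.0):
        if correction == "none":
            raise ValueError(
                "extreme rate (0 or 1) with no correction selected")
        return (k + 0.5) / (n + 1), True
    return raw, False


def compute_sdt(n_hit: int, n_miss: int, n_fa: int, n_cr: int,
                correction: str = "log-linear") -> SDTMetrics:
    """Signal-detection metrics from a 2x2 outcome table.

    d' = Z(HR) - Z(FA) and c = -(Z(HR) + Z(FA))/2 where Z is the
    standard-normal quantile function. ``correction`` is "log-linear"
    (default) or "none"; the correction only touches rates that are
    exactly 0 or 1.
    """
    if correction not in ("none", "log-linear"):
        raise ValueError(f"unknown correction {correction!r}")
    n_go = n_hit + n_miss
    n_nogo = n_fa + n_cr
    hr, c1 = _rate(n_hit, n_go, correction)
    fa, c2 = _rate(n_fa, n_nogo, correction)
    z_hr = norm.ppf(hr)
    z_fa = norm.ppf(fa)
    return SDTMetrics(
        hit_rate=hr, fa_rate=fa,
        d_prime=float(z_hr - z_fa),
        criterion=float(-0.5 * (z_hr + z_fa)),
        n_go=n_go, n_nogo=n_nogo,
        correction_applied=c1 or c2,
    )


# ---------------------------------------------------------------------------
# engagement window


def _window_dprime(trials: list[Trial]) -> float:
    n_hit = sum(t.outcome == "Hit" for t in trials)
    n_miss = sum(t.outcome == "Miss" for t in trials)
    n_fa = sum(t.outcome == "FA" for t in trials)
    n_cr = sum(t.outcome == "CR" for t in trials)
    if n_hit + n_miss == 0 or n_fa + n_cr == 0:
        return -math.inf
    return compute_sdt(n_hit, n_miss, n_fa, n_cr, "log-linear").d_prime


def engagement_window(session: Session, window: int = 50,
                      cutoff: float = 0.5) -> tuple[int, int]:
    """Trim low-performance epochs at session start and end.

    Computes d' in a ``window``-trial sliding window (centered, clipped
    at session edges) over non-aborted trials, and returns indices into
    ``session.trials`` of the first and last trial whose window d'
    meets ``cutoff``. Raises ValueError when no window does.
    """
    active = [t for t in session.trials if not t.aborted]
    if len(active) < window:
        raise ValueError(
            f"session has {len(active)} non-aborted trials; need >= {window}")
    half = window // 2
    n = len(active)
    meets = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        meets[i] = _window_dprime(active[lo:lo + window]) >= cutoff
    if not meets.any():
        raise ValueError(
            f"no {window}-trial window reaches sliding d' cutoff {cutoff}")
    first = int(np.argmax(meets))
    last = int(n - 1 - np.argmax(meets[::-1]))
    return active[first].index, active[last].index


# ---------------------------------------------------------------------------
# trial-history classification


def classify_trial_history(
    session: Session,
    mode: str = "consecutive",
    reward_threshold_fraction: float = 0.0,
    low_reward_breaks: bool = False,
    abort_breaks: bool = False,
) -> list[HistoryLabel]:
    """Label every trial by the outcome history of its predecessors.

    ``mode`` "consecutive" looks at literally preceding trials;
    "ignore-nogo" skips NoGo trials when walking backwards, so history
    is defined over Go trials only. Aborted trials never serve as
    history sources; whether they break a hit streak is controlled by
    ``abort_breaks`` (default: they do not).

    Hits whose reward is below ``reward_threshold_fraction`` x the
    session's maximum reward are flagged low_reward; with
    ``low_reward_breaks`` they are treated as non-boosting (like a Miss)
    when building hit streaks.

    Returns one HistoryLabel per trial, aligned with ``session.trials``;
    the first trial (and any trial with no usable history) gets
    category None.
    """
    if mode not in ("consecutive", "ignore-nogo"):
        raise ValueError(f"unknown history mode {mode!r}")
    trials = session.trials
    max_reward = max((t.reward_volume for t in trials), default=0.0)
    threshold = reward_threshold_fraction * max_reward

    def boosting_hit(t: Trial) -> bool:
        if t.aborted or t.outcome != "Hit":
            return False
        return not (low_reward_breaks and t.reward_volume < threshold)

    # precompute last-Go onset time before each trial (for inter-Go interval)
    last_go_onset: list[float | None] = []
    prev_go = None
    for t in trials:
        last_go_onset.append(prev_go)
        if t.kind == "Go" and not t.aborted:
            prev_go = t.onset_time

    labels: list[HistoryLabel] = []
    for i, t in enumerate(trials):
        igi = (t.onset_time - last_go_onset[i]
               if last_go_onset[i] is not None else None)

        # walk backwards to collect the relevant history trials
        hist: list[Trial] = []
        j = i - 1
        while j >= 0:
            prev = trials[j]
            j -= 1
            if prev.aborted:
                if abort_breaks:
                    break
                continue
            if mode == "ignore-nogo" and prev.kind == "NoGo":
                continue
            hist.append(prev)
            if len(hist) > len(trials):  # pragma: no cover - safety
                break
            # only need enough to resolve the streak; keep walking while hits
            if not boosting_hit(prev):
                break

        if not hist:
            labels.append(HistoryLabel(category=None,
                                       inter_go_interval=igi))
            continue

        prior = hist[0]
        prior_frac = (prior.reward_volume / max_reward
                      if (prior.outcome == "Hit" and max_reward > 0) else None)
        low = (prior.outcome == "Hit" and max_reward > 0
               and prior.reward_volume < threshold)

        if not boosting_hit(prior):
            # prior trial is NoGo, Miss, or a non-boosting low-reward hit
            if prior.kind == "NoGo":
                cat = "priorNoGo"
                prior_w = None
            else:
                effective_miss = prior.outcome == "Miss" or low
                if not effective_miss:  # pragma: no cover - exhaustive above
                    effective_miss = True
                prior_w = prior.whisker
                if t.kind == "Go":
                    cat = ("priorMissSame" if prior_w == t.whisker
                           else "priorMissDiff")
                else:
                    cat = "priorMiss"
            offset = (session.grid.offset_class(prior_w, t.whisker)
                      if (t.kind == "Go" and prior_w is not None) else "n/a")
            labels.append(HistoryLabel(
                category=cat, run_length=0, prior_whisker=prior_w,
                offset_class=offset, inter_go_interval=igi,
                prior_reward_fraction=prior_frac, low_reward=low))
            continue

        # prior trial is a boosting hit: measure the streak to one
        # consistent whisker
        streak_w = prior.whisker
        run = 0
        for prev in hist:
            if boosting_hit(prev) and prev.whisker == streak_w:
                run += 1
            else:
                break

        if t.kind == "Go":
            same = streak_w == t.whisker
            if run >= 2:
                cat = "priorGT1HitSame" if same else "priorGT1HitDiff"
            else:
                cat = "prior1HitSame" if same else "prior1HitDiff"
            offset = session.grid.offset_class(streak_w, t.whisker)
        else:
            cat = "priorGT1Hit" if run >= 2 else "prior1Hit"
            offset = "n/a"
        labels.append(HistoryLabel(
            category=cat, run_length=run, prior_whisker=streak_w,
            offset_class=offset, inter_go_interval=igi,
            prior_reward_fraction=prior_frac, low_reward=low))
    return labels


# ---------------------------------------------------------------------------
# history-conditioned SDT


def _select(session, labels, first, last):
    """(trial, label) pairs inside the engagement window, non-aborted."""
    out = []
    for t, lab in zip(session.trials, labels):
        if t.aborted or not (first <= t.index <= last):
            continue
        out.append((t, lab))
    return out


def history_conditioned_sdt(
    session: Session,
    labels: list[HistoryLabel],
    window: tuple[int, int] | None = None,
    group_by: str | None = None,
    min_go: int = DEFAULT_MIN_GO,
    min_nogo: int = DEFAULT_MIN_NOGO,
    correction: str = "log-linear",
) -> dict:
    """Signal-detection metrics per trial-history category.

    For each Go-history category the hit rate comes from matching Go
    trials and the false-alarm rate from the matched NoGo-history pool
    (GO_TO_NOGO_CATEGORY). Results include delta_d and delta_c relative
    to the priorNoGo baseline, and the median first-lick latency per
    category. ``group_by`` in {"offset_class", "interval-bin", "row",
    "arc", "amplitude-bin"} further splits Go trials (NoGo pools are
    shared within a history category). Categories below the minimum
    trial counts are omitted.

    Returns {"baseline": SDTMetrics | None, "conditions": {key: dict}},
    where key is the category (or (category, group) when grouping).
    """
    if window is None:
        window = (session.trials[0].index, session.trials[-1].index)
    first, last = window
    pairs = _select(session, labels, first, last)

    def go_group(t: Trial, lab: HistoryLabel):
        if group_by is None:
            return None
        if group_by == "offset_class":
            return lab.offset_class
        if group_by == "row":
            return t.whisker[0]
        if group_by == "arc":
            return t.whisker[1:]
        if group_by == "amplitude-bin":
            return float(t.amplitude)
        raise ValueError(f"unsupported group_by {group_by!r}")

    nogo_counts: dict[str, list[int]] = {c: [0, 0] for c in NOGO_CATEGORIES}
    go_data: dict = {}
    latencies: dict = {}
    for t, lab in pairs:
        if lab.category is None:
            continue
        if t.kind == "NoGo":
            cnt = nogo_counts[lab.category]
            cnt[0] += t.outcome == "FA"
            cnt[1] += 1
        else:
            key = (lab.category if group_by is None
                   else (lab.category, go_group(t, lab)))
            hit, n = go_data.get(key, (0, 0))
            go_data[key] = (hit + (t.outcome == "Hit"), n + 1)
            if t.first_lick_latency is not None:
                latencies.setdefault(key, []).append(t.first_lick_latency)

    def metrics_for(key):
        cat = key if group_by is None else key[0]
        n_hit, n_go = go_data[key]
        n_fa, n_nogo = nogo_counts[GO_TO_NOGO_CATEGORY[cat]]
        if n_go < min_go or n_nogo < min_nogo:
            return None
        return compute_sdt(n_hit, n_go - n_hit, n_fa, n_nogo - n_fa,
                           correction)

    baseline_key = "priorNoGo" if group_by is None else None
    baseline = None
    if group_by is None and "priorNoGo" in go_data:
        baseline = metrics_for("priorNoGo")
    else:
        # grouped runs still need an ungrouped baseline for deltas
        b_hit = sum(t.outcome == "Hit" for t, lab in pairs
                    if t.kind == "Go" and lab.category == "priorNoGo")
        b_n = sum(1 for t, lab in pairs
                  if t.kind == "Go" and lab.category == "priorNoGo")
        n_fa, n_nogo = nogo_counts["priorNoGo"]
        if b_n >= min_go and n_nogo >= min_nogo:
            baseline = compute_sdt(b_hit, b_n - b_hit, n_fa, n_nogo - n_fa,
                                   correction)

    conditions = {}
    for key in sorted(go_data, key=str):
        m = metrics_for(key)
        if m is None:
            continue
        lat = latencies.get(key, [])
        entry = {
            "metrics": m,
            "delta_d": (m.d_prime - baseline.d_prime
                        if baseline is not None else None),
            "delta_c": (m.criterion - baseline.criterion
                        if baseline is not None else None),
            "median_first_lick_latency": (float(np.median(lat))
                                          if lat else None),
        }
        conditions[key] = entry
    return {"baseline": baseline, "conditions": conditions,
            "baseline_key": baseline_key}


def history_counts(session: Session, labels: list[HistoryLabel],
                   window: tuple[int, int] | None = None,
                   go_key=None) -> dict:
    """Outcome counts per history category for one session.

    ``go_key(trial, label)`` may remap Go trials onto custom keys (e.g.
    offset classes); returning None drops the trial. Returns
    {"go": {key: [n_hit, n_go]}, "nogo": {category: [n_fa, n_nogo]}}.
    """
    if window is None:
        window = (session.trials[0].index, session.trials[-1].index)
    first, last = window
    go: dict = {}
    nogo: dict = {c: [0, 0] for c in NOGO_CATEGORIES}
    for t, lab in zip(session.trials, labels):
        if t.aborted or not (first <= t.index <= last):
            continue
        if lab.category is None:
            continue
        if t.kind == "NoGo":
            nogo[lab.category][0] += t.outcome == "FA"
            nogo[lab.category][1] += 1
        else:
            key = go_key(t, lab) if go_key is not None else lab.category
            if key is None:
                continue
            cnt = go.setdefault(key, [0, 0])
            cnt[0] += t.outcome == "Hit"
            cnt[1] += 1
    return {"go": go, "nogo": nogo}


def pooled_history_sdt(counts_list, key_to_nogo=None,
                       min_go: int = DEFAULT_MIN_GO,
                       min_nogo: int = DEFAULT_MIN_NOGO,
                       correction: str = "log-linear") -> dict:
    """SDT metrics from outcome counts pooled across sessions.

    Pooling counts before the inverse-normal transform avoids the
    small-sample bias that per-session extreme-rate corrections
    introduce. ``key_to_nogo`` maps each Go key to its NoGo pool
    (default GO_TO_NOGO_CATEGORY). Returns {key: {"metrics", "delta_d",
    "delta_c"}} with deltas relative to the pooled priorNoGo baseline
    when present.
    """
    key_to_nogo = key_to_nogo or GO_TO_NOGO_CATEGORY
    go_tot: dict = {}
    nogo_tot: dict = {c: [0, 0] for c in NOGO_CATEGORIES}
    for counts in counts_list:
        for key, (h, n) in counts["go"].items():
            cnt = go_tot.setdefault(key, [0, 0])
            cnt[0] += h
            cnt[1] += n
        for cat, (f, n) in counts["nogo"].items():
            nogo_tot[cat][0] += f
            nogo_tot[cat][1] += n

    def metrics(key):
        h, n = go_tot[key]
        nogo_cat = (key_to_nogo(key) if callable(key_to_nogo)
                    else key_to_nogo[key])
        cats = (nogo_cat,) if isinstance(nogo_cat, str) else tuple(nogo_cat)
        f = sum(nogo_tot[c][0] for c in cats)
        m = sum(nogo_tot[c][1] for c in cats)
        if n < min_go or m < min_nogo:
            return None
        return compute_sdt(h, n - h, f, m - f, correction)

    baseline = metrics("priorNoGo") if "priorNoGo" in go_tot else None
    out = {}
    for key in sorted(go_tot, key=str):
        m = metrics(key)
        if m is None:
            continue
        out[key] = {
            "metrics": m,
            "delta_d": (m.d_prime - baseline.d_prime
                        if baseline is not None else None),
            "delta_c": (m.criterion - baseline.criterion
                        if baseline is not None else None),
        }
    return out


_HIT_CATS_SAME = frozenset({"prior1HitSame", "priorGT1HitSame"})
_HIT_CATS_DIFF = frozenset({"prior1HitDiff", "priorGT1HitDiff"})
_HIT_NOGO_POOL = ("prior1Hit", "priorGT1Hit")


def pooled_spatial_gradient(session_label_pairs,
                            min_go: int = DEFAULT_MIN_GO,
                            min_nogo: int = DEFAULT_MIN_NOGO) -> dict:
    """Δd' per somatotopic offset class, pooled across sessions.

    Prior-hit Go trials are keyed by the offset class between the
    prior-hit whisker and the current whisker; the shared false-alarm
    pool is all prior-hit NoGo trials. Δd' is relative to the pooled
    priorNoGo baseline. Returns {offset_class: {"metrics", "delta_d"}}.
    """
    hit_cats = _HIT_CATS_SAME | _HIT_CATS_DIFF

    def key(t, lab):
        if lab.category in hit_cats:
            return lab.offset_class
        if lab.category == "priorNoGo":
            return "priorNoGo"
        return None

    counts = [history_counts(s, labs, go_key=key)
              for s, labs in session_label_pairs]

    def to_nogo(k):
        return "priorNoGo" if k == "priorNoGo" else _HIT_NOGO_POOL

    pooled = pooled_history_sdt(counts, key_to_nogo=to_nogo,
                                min_go=min_go, min_nogo=min_nogo)
    return {k: v for k, v in pooled.items() if k != "priorNoGo"}


def pooled_temporal_profile(session_label_pairs,
                            interval_bins=(1, 3, 5, 7, 9, 12),
                            min_go: int = DEFAULT_MIN_GO,
                            min_nogo: int = DEFAULT_MIN_NOGO) -> dict:
    """Whisker-specific Δd' per inter-Go-interval bin, pooled.

    Labels should be computed in "ignore-nogo" mode so prior-hit
    histories at long Go-to-Go intervals (spanning intervening NoGo
    trials) are represented. Returns {(lo, hi): {"d_same", "d_diff",
    "delta"}} for bins populated in both groups; feed to
    fit_temporal_decay to recover the decay constant.
    """
    edges = list(interval_bins)
    bins = list(zip(edges, edges[1:]))

    def key(t, lab):
        if lab.category in _HIT_CATS_SAME:
            grp = "same"
        elif lab.category in _HIT_CATS_DIFF:
            grp = "diff"
        else:
            return None
        igi = lab.inter_go_interval
        if igi is None:
            return None
        for lo, hi in bins:
            if lo <= igi < hi:
                return (grp, (lo, hi))
        return None

    counts = [history_counts(s, labs, go_key=key)
              for s, labs in session_label_pairs]
    pooled = pooled_history_sdt(counts,
                                key_to_nogo=lambda k: _HIT_NOGO_POOL,
                                min_go=min_go, min_nogo=min_nogo)
    out = {}
    for b in bins:
        ks, kd = ("same", b), ("diff", b)
        if ks in pooled and kd in pooled:
            d_s = pooled[ks]["metrics"].d_prime
            d_d = pooled[kd]["metrics"].d_prime
            out[b] = {"d_same": d_s, "d_diff": d_d, "delta": d_s - d_d}
    return out


def bootstrap_pooled_dprime(counts_list, key, key_to_nogo=None,
                            n_boot: int = 500, seed: int = 0,
                            correction: str = "log-linear") -> np.ndarray:
    """Bootstrap (resampling sessions) of a pooled-count d' estimate."""
    key_to_nogo = key_to_nogo or GO_TO_NOGO_CATEGORY
    rng = np.random.default_rng(seed)
    n = len(counts_list)
    values = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        pooled = pooled_history_sdt([counts_list[i] for i in idx],
                                    key_to_nogo=key_to_nogo,
                                    min_go=1, min_nogo=1,
                                    correction=correction)
        values[b] = (pooled[key]["metrics"].d_prime
                     if key in pooled else np.nan)
    return values


def spatial_gradient(session: Session, labels: list[HistoryLabel],
                     window: tuple[int, int] | None = None,
                     min_go: int = DEFAULT_MIN_GO,
                     min_nogo: int = DEFAULT_MIN_NOGO) -> dict:
    """Δd' as a function of somatotopic offset between the prior-hit
    whisker and the current whisker.

    Pools all prior-hit Go trials (single and multi-hit streaks) by
    offset class; the false-alarm pool is all prior-hit NoGo trials.
    Returns {offset_class: {"delta_d": float, "metrics": SDTMetrics}}.
    """
    if window is None:
        window = (session.trials[0].index, session.trials[-1].index)
    pairs = _select(session, labels, *window)

    hit_cats = {"prior1HitSame", "priorGT1HitSame",
                "prior1HitDiff", "priorGT1HitDiff"}
    nogo_fa = sum(t.outcome == "FA" for t, lab in pairs
                  if t.kind == "NoGo" and lab.category in ("prior1Hit",
                                                           "priorGT1Hit"))
    nogo_n = sum(1 for t, lab in pairs
                 if t.kind == "NoGo" and lab.category in ("prior1Hit",
                                                          "priorGT1Hit"))
    base = history_conditioned_sdt(session, labels, window,
                                   min_go=min_go, min_nogo=min_nogo)
    baseline = base["baseline"]

    out = {}
    for cls in ("same", "same-row adjacent", "same-arc adjacent",
                "diagonal adjacent", "further"):
        n_hit = sum(t.outcome == "Hit" for t, lab in pairs
                    if t.kind == "Go" and lab.category in hit_cats
                    and lab.offset_class == cls)
        n_go = sum(1 for t, lab in pairs
                   if t.kind == "Go" and lab.category in hit_cats
                   and lab.offset_class == cls)
        if n_go < min_go or nogo_n < min_nogo:
            continue
        m = compute_sdt(n_hit, n_go - n_hit, nogo_fa, nogo_n - nogo_fa)
        out[cls] = {
            "metrics": m,
            "delta_d": (m.d_prime - baseline.d_prime
                        if baseline is not None else None),
        }
    return out


def temporal_profile(session: Session, labels: list[HistoryLabel],
                     interval_bins=(0, 3, 5, 7, 9, 11, 20),
                     window: tuple[int, int] | None = None,
                     min_go: int = DEFAULT_MIN_GO,
                     min_nogo: int = DEFAULT_MIN_NOGO) -> dict:
    """Whisker-specific Δd' versus time since the last Go trial.

    Go trials with a prior hit are split into same- vs different-whisker
    pools per inter-Go-interval bin; each pool's d' uses the shared
    prior-hit NoGo pool. The whisker-specific effect per bin is
    d'(same) - d'(different). Empty bins are absent from the output.

    Returns {(lo, hi): {"d_same", "d_diff", "delta", "n_same", "n_diff"}}.
    """
    if window is None:
        window = (session.trials[0].index, session.trials[-1].index)
    pairs = _select(session, labels, *window)
    edges = list(interval_bins)

    nogo_fa = sum(t.outcome == "FA" for t, lab in pairs
                  if t.kind == "NoGo" and lab.category in ("prior1Hit",
                                                           "priorGT1Hit"))
    nogo_n = sum(1 for t, lab in pairs
                 if t.kind == "NoGo" and lab.category in ("prior1Hit",
                                                          "priorGT1Hit"))
    same_cats = {"prior1HitSame", "priorGT1HitSame"}
    diff_cats = {"prior1HitDiff", "priorGT1HitDiff"}

    out = {}
    for lo, hi in zip(edges, edges[1:]):
        def in_bin(lab):
            return (lab.inter_go_interval is not None
                    and lo <= lab.inter_go_interval < hi)
        counts = {}
        for name, cats in (("same", same_cats), ("diff", diff_cats)):
            n_hit = sum(t.outcome == "Hit" for t, lab in pairs
                        if t.kind == "Go" and lab.category in cats
                        and in_bin(lab))
            n_go = sum(1 for t, lab in pairs
                       if t.kind == "Go" and lab.category in cats
                       and in_bin(lab))
            counts[name] = (n_hit, n_go)
        if (counts["same"][1] < min_go or counts["diff"][1] < min_go
                or nogo_n < min_nogo):
            continue
        d = {}
        for name in ("same", "diff"):
            n_hit, n_go = counts[name]
            d[name] = compute_sdt(n_hit, n_go - n_hit,
                                  nogo_fa, nogo_n - nogo_fa).d_prime
        out[(lo, hi)] = {
            "d_same": d["same"], "d_diff": d["diff"],
            "delta": d["same"] - d["diff"],
            "n_same": counts["same"][1], "n_diff": counts["diff"][1],
        }
    return out


def fit_temporal_decay(profile: dict) -> float:
    """Exponential time constant (s) of the whisker-specific effect.

    Fits delta(t) = A * exp(-t / tau) to the per-bin same-vs-different
    d' differences at bin centers by least squares and returns tau.
    """
    from scipy.optimize import curve_fit

    centers = np.array([(lo + hi) / 2 for lo, hi in profile])
    deltas = np.array([v["delta"] for v in profile.values()])
    if centers.size < 3:
        raise ValueError("need >= 3 populated bins to fit a decay constant")

    def model(t, a, tau):
        return a * np.exp(-t / tau)

    a0 = max(deltas.max(), 0.1)
    popt, _ = curve_fit(model, centers, deltas, p0=[a0, 3.0],
                        bounds=([0, 0.1], [10, 100]), maxfev=10_000)
    return float(popt[1])
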