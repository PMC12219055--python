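"""Synthetic Go/NoGo sessions and neural populations with known ground truth.

The behavioral generator works in effective-d' space: each Go trial's
hit probability derives from

    d'_eff = d0 + decay(dt) * f(run) * [B * k(offset) - S * (1 - k(offset))]

where d0 is baseline sensitivity, k is a somatotopic kernel of the
offset between the prior-hit whisker and the current whisker (1 at zero
offset, falling to 0 for distant whiskers), decay(dt) = exp(-dt/tau)
with dt the time since the prior-hit Go trial, and f(run) scales
multi-hit streaks above single hits. B is the attend-toward boost and S
the attend-away suppression, so prior hits to the same whisker raise
sensitivity while prior hits to a distant whisker lower it. A hit
streak survives intervening NoGo trials (subject to the temporal
decay), as the behavioral data require.

Hit and false-alarm probabilities follow the equal-variance Gaussian
observer with an absolute decision criterion lambda = d0/2 + c:
HR = Phi(d'_eff - lambda), FA = Phi(-lambda). Because lambda is shared
between Go trials and their history-matched NoGo trials, the d'
recovered from a history category equals the mean generating d'_eff of
its trials. The criterion shifts liberally after any hit. Boost and
suppression defaults are calibrated so d'_eff at the mean one-ITI lag
equals the study conditions (2.45 after >1 same-whisker hits, 0.82
after >1 different-whisker hits, against a 1.13 baseline).

The neural generator emits per-trial evoked responses as
gain x tuning + noise, where tuning is a Gaussian bump over cortical
distance between the cell and the stimulated whisker's column, and gain
implements either a whisker-specific, spatially localized attentional
spotlight (pyramidal-like mode) or a non-specific arousal gain
(VIP-like mode). Generating gains are stored per trial x cell so every
recovery test can compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from whiskattn.behavior import Session, Trial, classify_trial_history
from whiskattn.grid import WhiskerGrid, generate_whisker_grid

__all__ = [
    "BehaviorGenConfig",
    "NeuralGenConfig",
    "CellTable",
    "NeuralData",
    "generate_session",
    "generate_neural_population",
    "DEFAULT_SPATIAL_KERNEL",
]

#: Relative attentional gain by somatotopic offset class of the prior-hit
#: whisker; qualitative shape of the behavioral spatial gradient.
DEFAULT_SPATIAL_KERNEL = {
    "same": 1.0,
    "same-row adjacent": 0.8,
    "same-arc adjacent": 0.45,
    "diagonal adjacent": 0.05,
    "further": 0.0,
}

#: Multi-hit streaks boost d' by this factor relative to a single hit.
RUN_LENGTH_FACTOR = 1.75

#: Ordered-pair counts of somatotopic classes among the 72 (prior,
#: current) whisker pairs with different identity on a 3x3 grid; used to
#: average the spatial kernel over the "different whisker" category.
_DIFF_PAIR_COUNTS = {"same-row adjacent": 12, "same-arc adjacent": 12,
                     "diagonal adjacent": 16, "further": 32}

# Calibration constants for the default study conditions: baseline d'
# 1.13, effective d' 2.45 after >1 same-whisker hits and 0.82 after >1
# different-whisker hits.
_D_BASELINE = 1.13
_D_SAME_MULTI = 2.45
_D_DIFF_MULTI = 0.82


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Parameters of the behavioral session generator.

    boost_same and suppress_diff are in d' units at zero somatotopic
    offset / maximal offset respectively, for a single prior hit at zero
    lag; defaults calibrate the >1-hit conditions to effective d' 2.45
    (same), 0.82 (different) against a 1.13 baseline with the default
    run-length factor.
    """

    n_trials: int = 600
    p_go: float = 0.55
    #: probability that a Go trial repeats the previous Go whisker
    #: (task variant that enriches same-whisker histories); 0 = equal
    #: probability over all whiskers
    p_same_repeat: float = 0.0
    iti_mean: float = 3.0
    iti_jitter: float = 2.0          # ITI uniform on mean +/- jitter
    delay_period: float = 0.5
    amplitude_levels: tuple[float, ...] = (50.0, 150.0, 250.0)
    amplitude_probs: tuple[float, ...] = (0.05, 0.25, 0.70)
    baseline_dprime: float = _D_BASELINE
    baseline_criterion: float = 0.1
    #: d'-units of attend-toward boost / attend-away suppression for a
    #: single prior hit at zero somatotopic offset and zero lag. None ->
    #: calibrated so the >1-hit effective d' at the mean one-ITI lag hits
    #: the study values (2.45 same / 0.82 different vs 1.13 baseline).
    boost_same: float | None = None
    suppress_diff: float | None = None
    spatial_kernel: dict = field(
        default_factory=lambda: dict(DEFAULT_SPATIAL_KERNEL))
    temporal_tau: float = 10.0
    run_length_factor: float = RUN_LENGTH_FACTOR
    criterion_shift_after_hit: float = -0.3
    reward_volume_max: float = 4.0
    reward_threshold_fraction: float = 0.04
    unrewarded_hit_prob: float = 0.0
    lick_latency_mean: float = 0.35

    def __post_init__(self):
        if not (0 <= self.p_go <= 1):
            raise ValueError("p_go must lie in [0, 1]")
        if self.temporal_tau <= 0:
            raise ValueError("temporal_tau must be positive")
        decay_at_iti = float(np.exp(-self.iti_mean / self.temporal_tau))
        fd = self.run_length_factor * decay_at_iti
        if self.boost_same is None:
            # zero-offset boost: d'_eff at one-ITI lag = 2.45 for >1 same hits
            object.__setattr__(self, "boost_same",
                               (_D_SAME_MULTI - _D_BASELINE) / fd)
        if self.suppress_diff is None:
            # suppression calibrated so the *category mean* over uniformly
            # drawn different whiskers equals 0.82: the kernel averages
            # E[k | different] over the 3x3 pair geometry
            n_pairs = sum(_DIFF_PAIR_COUNTS.values())
            e_k = sum(self.spatial_kernel.get(cls, 0.0) * n
                      for cls, n in _DIFF_PAIR_COUNTS.items()) / n_pairs
            target = (_D_DIFF_MULTI - _D_BASELINE) / fd   # negative
            s = (self.boost_same * e_k - target) / (1.0 - e_k)
            object.__setattr__(self, "suppress_diff", s)
        if abs(self.spatial_kernel.get("same", 1.0) - 1.0) > 1e-12:
            raise ValueError("spatial_kernel['same'] must equal 1")
        if abs(sum(self.amplitude_probs) - 1.0) > 1e-9:
            raise ValueError("amplitude_probs must sum to 1")
        if not (0 <= self.unrewarded_hit_prob <= 1):
            raise ValueError("unrewarded_hit_prob must lie in [0, 1]")


@dataclass(frozen=True)
class NeuralGenConfig:
    """Parameters of the synthetic neural population.

    gain_space_halfwidth is in column widths: pyramidal-like attentional
    gain applies to cells within this cortical distance of the attended
    whisker's column center. tuning_width (columns) sets the Gaussian
    falloff of sensory tuning with cortical distance.
    """

    n_cells: int = 60
    cell_class: str = "PYR"          # "PYR" | "VIP" | "RS-spike"
    tuning_width: float = 0.6
    peak_response: float = 0.5       # dF/F (calcium) or Hz (spikes)
    noise_sd: float = 0.1
    attentional_gain: float = 2.0
    gain_space_halfwidth: float = 0.75
    gain_whisker_specific: bool = True
    gain_min_run: int = 1
    layers: tuple[str, ...] = ("L2/3",)
    layers_with_gain: tuple[str, ...] = ("L2/3", "L5a/b")
    vip_baseline_amplitude: float = 0.3
    vip_baseline_tau: float = 2.0
    frame_rate: float = 7.5
    spike_rate_baseline: float = 4.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gain_space_halfwidth <= 0:
            raise ValueError("gain_space_halfwidth must be positive")
        if self.attentional_gain < 0:
            raise ValueError("attentional_gain must be >= 0")
        if self.cell_class not in ("PYR", "VIP", "RS-spike"):
            raise ValueError(f"unknown cell_class {self.cell_class!r}")


@dataclass
class CellTable:
    """Positions and metadata of the synthetic cells."""

    cell_ids: list[str]
    xy_um: np.ndarray                # (n_cells, 2)
    depth_um: np.ndarray
    column: list[str]
    cw: list[str]
    cell_class: list[str]
    layer: list[str]

    def __len__(self):
        return len(self.cell_ids)


@dataclass
class NeuralData:
    """Synthetic responses plus the generating ground truth."""

    cells: CellTable
    evoked: np.ndarray               # (n_trials, n_cells)
    truth_gain: np.ndarray           # (n_trials, n_cells)
    traces: np.ndarray | None = None  # (n_trials, n_cells, n_frames)
    frame_rate: float = 7.5
    onset_frame: int = 8
    spike_times: list | None = None  # per trial: list of per-cell arrays


# ---------------------------------------------------------------------------
# behavior


def _effective_dprime(cfg: BehaviorGenConfig, grid: WhiskerGrid,
                      current_whisker: str | None, streak_w: str | None,
                      run: int, dt: float | None) -> float:
    """Generating d' for the current Go whisker given the hit streak."""
    d = cfg.baseline_dprime
    if streak_w is None or run == 0 or current_whisker is None:
        return d
    k = cfg.spatial_kernel[grid.offset_class(streak_w, current_whisker)]
    decay = np.exp(-dt / cfg.temporal_tau) if dt is not None else 1.0
    f_run = cfg.run_length_factor if run >= 2 else 1.0
    return d + decay * f_run * (cfg.boost_same * k
                                - cfg.suppress_diff * (1.0 - k))


def generate_session(cfg: BehaviorGenConfig, grid: WhiskerGrid | None = None,
                     seed: int = 0) -> Session:
    """Simulate one behavioral session.

    Go/NoGo draws are i.i.d. with Go probability p_go and uniform
    whisker identity. The per-trial generating effective d' is stored in
    ``session.truth["effective_dprime"]`` (NaN on NoGo trials), along
    with the per-trial generating criterion.
    """
    if grid is None:
        grid = generate_whisker_grid()
    rng = np.random.default_rng(seed)
    whiskers = grid.whiskers

    trials: list[Trial] = []
    truth_d = np.full(cfg.n_trials, np.nan)
    truth_c = np.full(cfg.n_trials, np.nan)

    t_now = 0.0
    streak_w: str | None = None          # whisker of current boosting streak
    run = 0
    last_hit_go_time: float | None = None
    last_go_whisker: str | None = None
    prev_was_hit = False

    for i in range(cfg.n_trials):
        t_now += cfg.iti_mean + rng.uniform(-cfg.iti_jitter, cfg.iti_jitter)
        is_go = rng.random() < cfg.p_go
        crit = cfg.baseline_criterion + (cfg.criterion_shift_after_hit
                                         if prev_was_hit else 0.0)
        lam = cfg.baseline_dprime / 2.0 + crit   # absolute criterion
        truth_c[i] = crit
        if is_go:
            if (cfg.p_same_repeat > 0 and last_go_whisker is not None
                    and rng.random() < cfg.p_same_repeat):
                w = last_go_whisker
            else:
                w = whiskers[rng.integers(len(whiskers))]
            last_go_whisker = w
            amp = rng.choice(cfg.amplitude_levels, p=cfg.amplitude_probs)
            dt = (t_now - last_hit_go_time
                  if last_hit_go_time is not None else None)
            d_eff = _effective_dprime(cfg, grid, w, streak_w, run, dt)
            truth_d[i] = d_eff
            p_hit = norm.cdf(d_eff - lam)
            hit = rng.random() < p_hit
            outcome = "Hit" if hit else "Miss"
            rewarded = hit and rng.random() >= cfg.unrewarded_hit_prob
            reward = (cfg.reward_volume_max * rng.uniform(0.5, 1.0)
                      if rewarded else 0.0)
            latency = (cfg.delay_period
                       + rng.exponential(cfg.lick_latency_mean)
                       if hit else None)
            trials.append(Trial(index=i, onset_time=t_now, kind="Go",
                                whisker=w, amplitude=float(amp),
                                outcome=outcome, reward_volume=reward,
                                first_lick_latency=latency))
            boosting = hit and reward >= (cfg.reward_threshold_fraction
                                          * cfg.reward_volume_max)
            if boosting:
                if streak_w == w:
                    run += 1
                else:
                    streak_w, run = w, 1
                last_hit_go_time = t_now
            else:
                streak_w, run = None, 0
            prev_was_hit = hit
        else:
            p_fa = norm.cdf(-lam)
            fa = rng.random() < p_fa
            trials.append(Trial(index=i, onset_time=t_now, kind="NoGo",
                                whisker=None, amplitude=0.0,
                                outcome="FA" if fa else "CR"))
            # a NoGo does not break a hit streak but resets the
            # after-hit criterion shift
            prev_was_hit = False

    return Session(trials=trials, grid=grid,
                   task_variant="EqP", delay_period=cfg.delay_period,
                   truth={"effective_dprime": truth_d,
                          "criterion": truth_c,
                          "config": cfg, "seed": seed})


# ---------------------------------------------------------------------------
# neural


def _place_cells(cfg: NeuralGenConfig, grid: WhiskerGrid,
                 rng: np.random.Generator) -> CellTable:
    xs = [c[0] for c in grid.barrel_centroids.values()]
    ys = [c[1] for c in grid.barrel_centroids.values()]
    half = grid.mean_barrel_width / 2.0
    lo = (min(xs) - half, min(ys) - half)
    hi = (max(xs) + half, max(ys) + half)
    xy = rng.uniform(lo, hi, size=(cfg.n_cells, 2))
    cw = [grid.nearest_column(p) for p in xy]
    layer = [cfg.layers[i % len(cfg.layers)] for i in range(cfg.n_cells)]
    return CellTable(
        cell_ids=[f"cell{i:04d}" for i in range(cfg.n_cells)],
        xy_um=xy,
        depth_um=rng.uniform(110, 250, size=cfg.n_cells),
        column=list(cw),
        cw=list(cw),
        cell_class=[cfg.cell_class] * cfg.n_cells,
        layer=layer,
    )


def generate_neural_population(
    cfg: NeuralGenConfig,
    session: Session,
    seed: int = 0,
    with_traces: bool = False,
) -> NeuralData:
    """Simulate trial x cell evoked responses for a behavioral session.

    Pyramidal-like mode (gain_whisker_specific=True): on Go trials whose
    history is a hit streak of length >= gain_min_run to the *same*
    whisker as the current stimulus, cells within gain_space_halfwidth
    column widths of that whisker's column center (and in a gain-bearing
    layer) respond with multiplicative gain ``attentional_gain``.

    VIP-like mode (gain_whisker_specific=False): the gain applies after
    any qualifying hit streak regardless of whisker match or cell
    position, and frame traces carry a declining post-reward baseline.

    NoGo trials evoke zero mean response (plus noise).
    """
    grid = session.grid
    rng = np.random.default_rng(seed)
    cells = _place_cells(cfg, rng=rng, grid=grid)
    labels = classify_trial_history(session)

    n_trials = len(session.trials)
    n_cells = len(cells)
    sigma_um = cfg.tuning_width * grid.mean_barrel_width
    half_um = cfg.gain_space_halfwidth * grid.mean_barrel_width

    # tuning of each cell to each whisker: Gaussian in cortical distance
    whiskers = grid.whiskers
    tuning = np.zeros((n_cells, len(whiskers)))
    for j, w in enumerate(whiskers):
        d = np.linalg.norm(cells.xy_um - grid.centroid(w), axis=1)
        tuning[:, j] = cfg.peak_response * np.exp(-d**2 / (2 * sigma_um**2))
    w_index = {w: j for j, w in enumerate(whiskers)}

    layer_has_gain = np.array([lay in cfg.layers_with_gain
                               for lay in cells.layer])

    gain = np.ones((n_trials, n_cells))
    mean_resp = np.zeros((n_trials, n_cells))
    for i, (t, lab) in enumerate(zip(session.trials, labels)):
        if t.kind != "Go" or t.aborted:
            continue
        base = tuning[:, w_index[t.whisker]]
        g = np.ones(n_cells)
        if (cfg.attentional_gain != 1.0 and lab.prior_whisker is not None
                and lab.run_length >= cfg.gain_min_run):
            if cfg.gain_whisker_specific:
                if lab.prior_whisker == t.whisker:
                    near = (np.linalg.norm(
                        cells.xy_um - grid.centroid(lab.prior_whisker),
                        axis=1) <= half_um)
                    g = np.where(near & layer_has_gain,
                                 cfg.attentional_gain, 1.0)
            else:
                g = np.full(n_cells, cfg.attentional_gain)
        gain[i] = g
        mean_resp[i] = g * base

    evoked = mean_resp + rng.normal(0.0, cfg.noise_sd,
                                    size=(n_trials, n_cells))

    traces = None
    onset_frame = 8
    if with_traces:
        n_frames = 24
        frames = np.arange(n_frames)
        kernel = np.exp(-np.maximum(frames - onset_frame, 0) / 5.0)
        kernel[:onset_frame] = 0.0
        traces = (mean_resp[:, :, None] * kernel[None, None, :]
                  + rng.normal(0.0, cfg.noise_sd,
                               size=(n_trials, n_cells, n_frames)))
        if cfg.cell_class == "VIP":
            # declining post-reward baseline during the pre-stimulus epoch
            tsec = (frames - onset_frame) / cfg.frame_rate
            for i, lab in enumerate(labels):
                if lab.prior_whisker is not None and lab.run_length >= 1:
                    decay = (cfg.vip_baseline_amplitude
                             * np.exp(-(tsec - tsec[0])
                                      / cfg.vip_baseline_tau))
                    traces[i] += decay[None, :]

    spike_times = None
    if cfg.cell_class == "RS-spike":
        spike_times = _poisson_spikes(cfg, mean_resp, rng)

    return NeuralData(cells=cells, evoked=evoked, truth_gain=gain,
                      traces=traces, frame_rate=cfg.frame_rate,
                      onset_frame=onset_frame, spike_times=spike_times)


def _poisson_spikes(cfg: NeuralGenConfig, mean_resp: np.ndarray,
                    rng: np.random.Generator) -> list:
    """Poisson spike trains: baseline rate everywhere, plus five evoked
    rate bumps at 100-ms spacing whose height scales with the trial's
    mean evoked response. Times span [-0.5, 1.0) s around onset."""
    n_trials, n_cells = mean_resp.shape
    t_lo, t_hi = -0.5, 1.0
    bin_w = 0.010
    edges = np.arange(t_lo, t_hi + 1e-9, bin_w)
    centers = edges[:-1] + bin_w / 2
    deflection_times = np.arange(5) * 0.100
    out = []
    for i in range(n_trials):
        per_cell = []
        for c in range(n_cells):
            rate = np.full(centers.size, cfg.spike_rate_baseline)
            for td in deflection_times:
                in_burst = (centers >= td) & (centers < td + 0.03)
                rate[in_burst] += mean_resp[i, c] / 0.03 / 5.0
            counts = rng.poisson(rate * bin_w)
            times = np.repeat(centers, counts)
            times = times + rng.uniform(-bin_w / 2, bin_w / 2,
                                        size=times.size)
            per_cell.append(np.sort(times))
        out.append(per_cell)
    return out


def truth_category_dprime(session: Session, labels, category: str,
                          nogo_category: str,
                          window: tuple[int, int] | None = None) -> float:
    """Generating d' implied by a history category's trial mixture.

    A category pools trials with different per-trial effective d' and
    criteria; the d' an unbiased analysis converges to is
    Z(E[p_hit]) - Z(E[p_fa]) over that mixture, not the mean effective
    d'. This computes that value from the stored ground truth.
    """
    cfg: BehaviorGenConfig = session.truth["config"]
    truth_d = session.truth["effective_dprime"]
    truth_c = session.truth["criterion"]
    if window is None:
        window = (session.trials[0].index, session.trials[-1].index)
    first, last = window
    p_hit, p_fa = [], []
    for t, lab in zip(session.trials, labels):
        if t.aborted or not (first <= t.index <= last):
            continue
        lam = cfg.baseline_dprime / 2.0 + truth_c[t.index]
        if t.kind == "Go" and lab.category == category:
            p_hit.append(norm.cdf(truth_d[t.index] - lam))
        elif t.kind == "NoGo" and lab.category == nogo_category:
            p_fa.append(norm.cdf(-lam))
    if not p_hit or not p_fa:
        raise ValueError(f"no trials in category {category!r}")
    return float(norm.ppf(np.mean(p_hit)) - norm.ppf(np.mean(p_fa)))


def null_behavior_config(**overrides) -> BehaviorGenConfig:
    """A generator config with all history effects switched off."""
    base = BehaviorGenConfig(boost_same=0.0, suppress_diff=0.0,
                             criterion_shift_after_hit=0.0)
    return replace(base, **overrides)
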