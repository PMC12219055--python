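"""Single-trial stimulus-detection decoding from population activity.

A per-session L2-penalized logistic regression predicts stimulus
presence (Go vs NoGo) from the trial x cell evoked-response matrix of
whisker-responsive cells. Training sets are balanced by undersampling
the four behavioral outcome classes (Hit, Miss, CR, FA) to equal
counts; the ridge strength is chosen by internal 10-fold
cross-validated log-loss over a logarithmic grid, and performance is
always read from held-out folds. Decoder performance is the fraction
of trials called stimulus-present, evaluated per trial-history
condition and per current-trial filter (any Go / field-best-whisker Go
/ non-fBW Go / NoGo), averaged over balanced resampling iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

__all__ = [
    "DecoderModel",
    "DecoderEval",
    "field_best_whisker",
    "train_decoder",
    "evaluate_decoder",
]

OUTCOME_CLASSES = ("Hit", "Miss", "CR", "FA")
DEFAULT_RIDGE_GRID = np.logspace(-3, 3, 30)
DEFAULT_N_FOLDS = 10
DEFAULT_N_ITERATIONS = 25
DECISION_THRESHOLD = 0.5
MIN_PER_CLASS = 5


@dataclass
class DecoderModel:
    """A fitted per-session decoder."""

    cell_ids: list[str]
    weights: np.ndarray
    intercept: float
    ridge_strength: float            # lambda = 1 / C
    fold_assignment: np.ndarray      # fold id per balanced trial
    trial_indices: np.ndarray        # rows of X used (balanced subset)
    seed: int = 0


@dataclass
class DecoderEval:
    """Fraction of trials called stimulus-present for one condition."""

    condition: tuple
    fraction_stimulus_called: float
    n_trials: float                  # mean per-iteration trial count
    n_resample_iterations: int
    shuffled_control: float | None = None


def field_best_whisker(evoked: np.ndarray, session, whiskers=None,
                       responsive_mask=None) -> str:
    """Whisker evoking the highest mean population response.

    Means are taken over Go trials per whisker and over the responsive
    cells of the field; exact ties break row-major (grid order) and are
    extremely unlikely with real-valued data.
    """
    evoked = np.asarray(evoked, dtype=float)
    if whiskers is None:
        whiskers = session.grid.whiskers
    cols = (np.asarray(responsive_mask, dtype=bool)
            if responsive_mask is not None
            else np.ones(evoked.shape[1], dtype=bool))
    if not cols.any():
        raise ValueError("need at least one responsive cell")
    best, best_val = None, -np.inf
    for w in whiskers:
        mask = np.array([t.kind == "Go" and not t.aborted and t.whisker == w
                         for t in session.trials])
        if not mask.any():
            continue
        val = float(np.nanmean(evoked[np.ix_(mask, cols)]))
        if val > best_val + 1e-12:
            best, best_val = w, val
    if best is None:
        raise ValueError("no Go trials to define the field best whisker")
    return best


def _balanced_indices(outcomes, rng) -> np.ndarray:
    """Undersample so every outcome class has the minority-class count."""
    outcomes = np.asarray(outcomes)
    groups = {c: np.flatnonzero(outcomes == c) for c in OUTCOME_CLASSES}
    n_min = min(len(v) for v in groups.values())
    if n_min == 0:
        raise ValueError("every outcome class needs at least one trial")
    picked = [rng.choice(v, size=n_min, replace=False)
              for v in groups.values()]
    idx = np.concatenate(picked)
    rng.shuffle(idx)
    return idx


def train_decoder(X: np.ndarray, y, outcomes, seed: int = 0,
                  cell_ids=None, n_folds: int = DEFAULT_N_FOLDS,
                  ridge_grid=DEFAULT_RIDGE_GRID,
                  min_per_class: int = MIN_PER_CLASS) -> DecoderModel:
    """Fit the session decoder on one balanced resample.

    X is (trials, responsive cells), y is 1 for Go / 0 for NoGo,
    ``outcomes`` the per-trial Hit/Miss/CR/FA label. Raises ValueError
    when any outcome class has fewer than ``min_per_class`` trials.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    outcomes = np.asarray(outcomes)
    counts = {c: int(np.sum(outcomes == c)) for c in OUTCOME_CLASSES}
    lacking = [c for c, n in counts.items() if n < min_per_class]
    if lacking:
        raise ValueError(
            f"outcome classes below minimum {min_per_class}: {lacking} "
            f"(counts {counts})")
    rng = np.random.default_rng(seed)
    idx = _balanced_indices(outcomes, rng)
    folds = np.arange(idx.size) % n_folds
    rng.shuffle(folds)
    clf = LogisticRegressionCV(
        Cs=np.asarray(ridge_grid), cv=n_folds,
        scoring="neg_log_loss", max_iter=2000, random_state=int(seed % 2**31))
    clf.fit(X[idx], y[idx])
    return DecoderModel(
        cell_ids=list(cell_ids) if cell_ids is not None
        else [f"c{i}" for i in range(X.shape[1])],
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        ridge_strength=float(1.0 / clf.C_[0]),
        fold_assignment=folds,
        trial_indices=idx,
        seed=seed,
    )


def _held_out_predictions(X, y, idx, folds, C, seed) -> np.ndarray:
    """Stimulus-present calls for each balanced trial from the fold that
    held it out."""
    preds = np.empty(idx.size, dtype=bool)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        assert not np.any(train & test)  # fold disjointness
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(X[idx[train]], y[idx[train]])
        p = clf.predict_proba(X[idx[test]])[:, 1]
        preds[test] = p >= DECISION_THRESHOLD
    return preds


def evaluate_decoder(X: np.ndarray, y, outcomes, session, labels,
                     responsive_mask=None, seed: int = 0,
                     n_iterations: int = DEFAULT_N_ITERATIONS,
                     n_folds: int = DEFAULT_N_FOLDS,
                     ridge_grid=DEFAULT_RIDGE_GRID,
                     history_categories=("priorNoGo", "priorGT1HitSame",
                                         "priorGT1HitDiff"),
                     with_shuffled: bool = True,
                     min_per_class: int = MIN_PER_CLASS) -> dict:
    """Cross-validated decoder performance by history and trial filter.

    For each balanced-resampling iteration: undersample the four outcome
    classes to equal counts, assign 10 folds, pick the ridge strength by
    internal cross-validation on the training folds, and collect
    held-out stimulus-present calls. Fractions called are then averaged
    over iterations within each (trial filter x history category) cell;
    NoGo entries report the decoder false-alarm fraction. The shuffled
    control repeats the procedure with training labels permuted.

    Returns {"conditions": {(filter, category): DecoderEval},
    "overall_accuracy": float, "shuffled_accuracy": float | None,
    "fbw": str}.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    outcomes = np.asarray(outcomes)
    if responsive_mask is not None:
        X = X[:, np.asarray(responsive_mask, dtype=bool)]
    fbw = field_best_whisker(X, session)
    rng = np.random.default_rng(seed)

    go_whisker = np.array([t.whisker if t.kind == "Go" else None
                           for t in session.trials], dtype=object)
    history = np.array(
        [lab.category if lab.category is not None else "unclassified"
         for lab in labels], dtype=object)
    # map Go histories onto their matched NoGo pools for NoGo rows
    is_go = y == 1

    def filter_mask(name):
        if name == "any":
            return is_go
        if name == "fBW":
            return is_go & (go_whisker == fbw)
        if name == "non-fBW":
            return is_go & (go_whisker != fbw)
        if name == "NoGo":
            return ~is_go
        raise ValueError(name)

    nogo_equiv = {"priorGT1HitSame": "priorGT1Hit",
                  "priorGT1HitDiff": "priorGT1Hit",
                  "prior1HitSame": "prior1Hit",
                  "prior1HitDiff": "prior1Hit",
                  "priorMissSame": "priorMiss",
                  "priorMissDiff": "priorMiss",
                  "priorNoGo": "priorNoGo"}

    filters = ("any", "fBW", "non-fBW", "NoGo")
    acc_frac = {(f, c): [] for f in filters for c in history_categories}
    acc_n = {(f, c): [] for f in filters for c in history_categories}
    accuracy = []
    shuffled_accuracy = [] if with_shuffled else None

    iter_seeds = np.random.SeedSequence(seed).spawn(n_iterations)
    for it_seed in iter_seeds:
        it_rng = np.random.default_rng(it_seed)
        counts = {c: int(np.sum(outcomes == c)) for c in OUTCOME_CLASSES}
        if min(counts.values()) < min_per_class:
            raise ValueError(f"outcome class below minimum: {counts}")
        idx = _balanced_indices(outcomes, it_rng)
        # balancing invariant: equal counts per outcome class
        bal_counts = {c: int(np.sum(outcomes[idx] == c))
                      for c in OUTCOME_CLASSES}
        assert len(set(bal_counts.values())) == 1
        folds = np.arange(idx.size) % n_folds
        it_rng.shuffle(folds)
        sub_seed = int(it_rng.integers(2**31))
        inner = LogisticRegressionCV(
            Cs=np.asarray(ridge_grid), cv=min(n_folds, 10),
            scoring="neg_log_loss", max_iter=2000, random_state=sub_seed)
        inner.fit(X[idx], y[idx])
        C = float(inner.C_[0])
        preds = _held_out_predictions(X, y, idx, folds, C, sub_seed)
        accuracy.append(float(np.mean(preds == (y[idx] == 1))))

        for f in filters:
            fm = filter_mask(f)
            for cat in history_categories:
                cat_eff = nogo_equiv.get(cat, cat) if f == "NoGo" else cat
                cm = history == cat_eff
                sel = fm[idx] & cm[idx]
                if sel.any():
                    acc_frac[(f, cat)].append(float(preds[sel].mean()))
                    acc_n[(f, cat)].append(int(sel.sum()))

        if with_shuffled:
            y_sh = it_rng.permutation(y[idx])
            preds_sh = _held_out_predictions(
                X[idx], y_sh, np.arange(idx.size), folds, C, sub_seed)
            shuffled_accuracy.append(
                float(np.mean(preds_sh == (y_sh == 1))))

    conditions = {}
    for key, vals in acc_frac.items():
        if not vals:
            continue
        conditions[key] = DecoderEval(
            condition=key,
            fraction_stimulus_called=float(np.mean(vals)),
            n_trials=float(np.mean(acc_n[key])),
            n_resample_iterations=len(vals),
        )
    return {
        "conditions": conditions,
        "overall_accuracy": float(np.mean(accuracy)),
        "shuffled_accuracy": (float(np.mean(shuffled_accuracy))
                              if with_shuffled else None),
        "fbw": fbw,
    }
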