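import numpy as np
import pytest

from whiskattn import behavior, simulate
from whiskattn.behavior import Session, Trial
from whiskattn.grid import generate_whisker_grid


@pytest.fixture(scope="session")
def grid3x3():
    return generate_whisker_grid()


@pytest.fixture(scope="session")
def boosted_config():
    """Study conditions with enriched same-whisker repeats so multi-hit
    histories are populated at desk scale."""
    return simulate.BehaviorGenConfig(p_same_repeat=0.4, n_trials=600)


@pytest.fixture(scope="session")
def boosted_session(boosted_config, grid3x3):
    return simulate.generate_session(boosted_config, grid3x3, seed=101)


@pytest.fixture(scope="session")
def boosted_labels(boosted_session):
    return behavior.classify_trial_history(boosted_session)


def make_session(spec_rows, grid, **kwargs):
    """Build a session from compact rows (kind, whisker, outcome[, extras])."""
    trials = []
    for i, row in enumerate(spec_rows):
        kind, whisker, outcome = row[:3]
        extra = row[3] if len(row) > 3 else {}
        trials.append(Trial(
            index=i, onset_time=float(extra.get("onset", 3.0 * (i + 1))),
            kind=kind, whisker=whisker,
            amplitude=extra.get("amplitude", 200.0), outcome=outcome,
            reward_volume=extra.get("reward",
                                    4.0 if outcome == "Hit" else 0.0),
            aborted=extra.get("aborted", False)))
    return Session(trials=trials, grid=grid, **kwargs)


@pytest.fixture(scope="session")
def pyr_population(boosted_session):
    cfg = simulate.NeuralGenConfig(n_cells=50, attentional_gain=2.5,
                                   noise_sd=0.05)
    return cfg, simulate.generate_neural_population(cfg, boosted_session,
                                                    seed=7)


def rng_seeds(n, base=0):
    return [base + i for i in range(n)]


def category_counts(session, labels, window=None):
    if window is None:
        window = (session.trials[0].index, session.trials[-1].index)
    first, last = window
    counts = {}
    for t, lab in zip(session.trials, labels):
        if t.aborted or not (first <= t.index <= last):
            continue
        key = (t.kind, lab.category)
        counts[key] = counts.get(key, 0) + 1
    return counts
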