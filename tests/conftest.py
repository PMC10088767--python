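import numpy as np
import pandas as pd
import pytest

from taskrel import GroundTruth, TrialDataset, make_fixture, simulate_study


@pytest.fixture(scope="session")
def tiny_study():
    """12 subjects x full battery x 16 trials/cell; deterministic."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def single_cell_study():
    """One Stroop baseline cell at moderate scale, with known ground truth."""
    truth = GroundTruth.single_cell(seed=31, n_subjects=30, n_trials=48)
    return simulate_study(truth)


def make_trials(rows) -> TrialDataset:
    """Build a TrialDataset from (subject, task, session, phase, idx, tt, rt, acc) rows."""
    df = pd.DataFrame(rows, columns=["subject", "task", "session", "phase",
                                     "trial_index", "trial_type", "rt_ms", "accuracy"])
    return TrialDataset(df)


def gaussian_stroop_dataset(n_subjects, n_trials, subject_sd, noise_sd,
                            base=600.0, effect=100.0, seed=0,
                            session="baseline", phase="test") -> TrialDataset:
    """Stroop-shaped trials with Gaussian noise and additive subject effects.

    Each subject's true interference effect is ``effect + N(0, subject_sd^2)``;
    trial RTs are ``base (+ effect_i for incongruent) + N(0, noise_sd^2)``.
    Used where a closed-form reliability oracle is wanted.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        theta = effect + subject_sd * rng.standard_normal()
        for tt, shift in (("congruent", 0.0), ("incongruent", theta)):
            rts = base + shift + noise_sd * rng.standard_normal(n_trials)
            start = 0 if tt == "congruent" else n_trials
            for i, rt in enumerate(rts):
                rows.append((f"s{s:03d}", "stroop", session, phase,
                             start + i, tt, max(rt, 1.0), 1))
    return make_trials(rows)
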