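import numpy as np
import pandas as pd
import pytest

from nadlearn import (
    generate_language,
    generate_nads_block,
    generate_random_block,
)
from nadlearn.paradigm import Phrase
from nadlearn.synth import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def language():
    return generate_language(1)


@pytest.fixture(scope="session")
def language_b():
    return generate_language(99)


@pytest.fixture(scope="session")
def nads_design(language):
    return generate_nads_block(language, "C1", 7)


@pytest.fixture(scope="session")
def random_design(language_b):
    return generate_random_block(language_b, "C1", 8)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy TD cohort reused across group-stat tests."""
    cfg = SyntheticConfig(n_participants=8, seed=42)
    records, truth, designs = simulate_cohort(cfg)
    return records, truth, designs


def random_phrases(rng: np.random.Generator, n_trials: int, n_words: int = 8):
    """Arbitrary (possibly unstructured) phrase sequences for property tests."""
    words = [f"w{i}" for i in range(n_words)]
    target = words[0]
    trials = []
    for _ in range(n_trials):
        i1, i2 = rng.choice(n_words, size=2, replace=False)
        w3 = words[int(rng.integers(n_words))]
        trials.append(Phrase(words[i1], words[i2], w3, "NADs", 1, w3 == target))
    return trials, target


def linear_cohort(
    rng,
    n_participants=6,
    slope_random=-1.0,
    slope_nads=-6.0,
    tnt_effect=20.0,
    intercept=800.0,
    participant_sd=50.0,
    resid_sd=0.0,
    n_nads=72,
    n_random=96,
):
    """Trial-level records generated directly from the slope model."""
    rows = []
    for i in range(n_participants):
        pid = f"p{i + 1:02d}"
        offset = rng.normal(0.0, participant_sd) if participant_sd else 0.0
        for cond, n, slope in (("NADs", n_nads, slope_nads), ("Random", n_random, slope_random)):
            trials = np.arange(1, n + 1)
            tnt = np.where(np.arange(n) % 2 == 0, "Target", "NoTarget")
            rt = (
                intercept
                + offset
                + slope * trials
                + tnt_effect * (tnt == "Target")
                + rng.normal(0.0, resid_sd, size=n)
            )
            for t, tn, r in zip(trials, tnt, rt):
                rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "trial_index": int(t),
                        "tnt": tn,
                        "rt": float(r),
                        "correct": True,
                        "responded": True,
                    }
                )
    return pd.DataFrame(rows)
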