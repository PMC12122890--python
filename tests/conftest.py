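import numpy as np
import pandas as pd
import pytest

import reachgrasp as rg


@pytest.fixture(scope="session")
def clean_trials():
    """Noise-free synthetic trials with ground truth (8 agents x 2 goals)."""
    cfg = rg.KinConfig(seed=101, noise_sd=0.0, n_agents=4)
    return rg.gen_kinematic_trials(cfg, 1)


@pytest.fixture(scope="session")
def noisy_trials():
    cfg = rg.KinConfig(seed=202, n_agents=4)
    return rg.gen_kinematic_trials(cfg, 2)


@pytest.fixture(scope="session")
def feature_set():
    """Ground-truth feature table for a medium trial set (320 rows)."""
    cfg = rg.KinConfig(seed=7)
    _, truths = rg.gen_kinematic_trials(cfg, 20)
    return rg.synth.features_table(truths)


@pytest.fixture(scope="session")
def two_point_stimuli():
    """10 000 stimuli with one two-point feature: z-score +-1 by goal.

    With weight w the observer's evidence separation is 2w in z units, so
    w = 0.5 realises an equal-variance d' of 1 (internal noise sd 1).
    """
    n = 10_000
    rng = np.random.default_rng(17)
    goal = np.where(rng.random(n) < 0.5, "PASS", "PLACE")
    return pd.DataFrame(
        {
            "trial_id": [f"T{i:05d}" for i in range(n)],
            "goal": goal,
            "sig": np.where(goal == "PASS", 0.5, -0.5),
        }
    )
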