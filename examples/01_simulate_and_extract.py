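"""Simulate reach-to-grasp trials and extract the 17 kinematic parameters.

Builds a small synthetic recording session (minimum-jerk wrist transport,
raised-cosine grip aperture, 120 Hz, 0.15 mm marker noise), segments each
trial with the 0.3 mm / 3-frame displacement criteria and prints the
PASS-vs-PLACE contrast on a few parameters.
"""

import reachgrasp as rg
from reachgrasp import kinematics as kin
from reachgrasp.synth import features_table

cfg = rg.KinConfig(seed=11, n_agents=4)
trials, truths = rg.gen_kinematic_trials(cfg, 6)  # 4 agents x 2 goals x 6

rows = []
for trial in trials:
    curves, seg, feats = kin.analyze_trial(trial)
    rows.append({"goal": trial.labels["goal"], **feats})

import pandas as pd

extracted = pd.DataFrame(rows).groupby("goal")[
    ["RTotDur", "RPSpeed", "GRange", "HandPos"]
].mean()
print("Extracted feature means by goal (from noisy markers):")
print(extracted.round(1))

truth = features_table(truths).groupby("goal")[
    ["RTotDur", "RPSpeed", "GRange", "HandPos"]
].mean()
print("\nGround-truth means (noise-free curves):")
print(truth.round(1))

print(
    "\nPASS actions take longer (RTotDur up), peak slower (RPSpeed down) and"
    "\ngrasp the object lower (HandPos down) than PLACE actions - the"
    "\nkinematic signature downstream observers must decode."
)
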