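"""CART trees predicting observer choices from stimulus kinematics.

Trains a pruned Gini tree on 80% of the trials (choices of a simulated
observer as outcome), evaluates on the held-out 20% with an exact binomial
test against chance, and prints the variable-importance ranking.
"""

import pandas as pd

import reachgrasp as rg
from reachgrasp import kinematics as kin, trees

cfg = rg.KinConfig(seed=51)
trials, _ = rg.gen_kinematic_trials(cfg, 15)
features = pd.DataFrame(
    [{"trial_id": t.trial_id, **t.labels, **kin.analyze_trial(t)[2]} for t in trials]
)

observer = rg.ObserverProfile(
    weights={"HandPos": -0.9, "RPSpeed": -0.5}, noise_sd=0.5, seed=8
)
resp = rg.gen_observer_responses(features, observer)

model, ev = trees.train_and_evaluate(
    features, resp["choice"].to_numpy(),
    feature_names=list(rg.FEATURE_NAMES), seed=3,
)
print(f"Root split: {model.root_feature} at {model.root_threshold:.1f}")
print(f"Held-out accuracy = {100 * ev.accuracy:.1f}% on {ev.n_test} trials"
      f" (binomial p vs chance = {ev.p_binomial:.2g})")
print("Top variable importances (normalized Gini improvement):")
for name, v in sorted(model.importance.items(), key=lambda kv: -kv[1])[:5]:
    if v > 0:
        print(f"  {name:14s} {v:.3f}")
print("\nThe tree recovers, from the choices alone, the feature dominating"
      "\nthis observer's decisions: the hand's position on the object.")
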