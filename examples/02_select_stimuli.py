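"""PCA on time-normalized kinematic curves and SD-window stimulus selection.

Reduces a synthetic session to its dominant curve-level components, then
keeps the trials whose grasp range (GRoM) and peak reaching speed (RPSpeed)
sit inside each goal's asymmetric window (PLACE [-0.5,+1] SD, PASS
[-1,+0.5] SD) and picks the most central exemplars per agent and goal.
"""

import pandas as pd

import reachgrasp as rg
from reachgrasp import kinematics as kin, stimuli

cfg = rg.KinConfig(seed=21)
trials, _ = rg.gen_kinematic_trials(cfg, 8)  # 8 agents x 2 goals x 8

rows, pairs = [], []
for trial in trials:
    curves, seg, feats = kin.analyze_trial(trial)
    rows.append({"trial_id": trial.trial_id, **trial.labels, **feats})
    pairs.append((curves, seg))
features = pd.DataFrame(rows)

matrix = stimuli.build_curve_matrix(pairs, trial_ids=list(features["trial_id"]))
pca = stimuli.pca_curves(matrix, n_components=3)
print("Variance explained (%):", (100 * pca.variance_fractions).round(1))
print("Dominant curve per component:")
for pc in pca.curve_loadings.columns:
    print(f"  {pc}: {pca.curve_loadings[pc].idxmax()}")

selection = stimuli.select_stimuli(features)
exemplars = stimuli.pick_exemplars(selection, n_per_cell=3, group_cols=("agent", "goal"))
print(f"\nSurvivors of the SD windows: {int(selection['selected'].sum())}"
      f" of {len(selection)} trials")
print(f"Exemplars picked (<=3 per agent x goal): {len(exemplars)}")
print("The exemplars are the most representative movements of each intention,"
      "\nthe basis of a video stimulus set.")
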