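"""Mixed-model workflow: RT filter, CRI structure selection, Nakagawa R2.

Fits reach duration against goal and agent gender with a participant
(here: executing agent) random intercept plus an agent x goal intercept,
simplifying the random structure if the fit is singular, and reports
marginal/conditional R2 and the Bonferroni threshold for a 17-parameter
family.
"""

import pandas as pd

import reachgrasp as rg
from reachgrasp import behavior_stats as bs, kinematics as kin

cfg = rg.KinConfig(seed=41)
trials, _ = rg.gen_kinematic_trials(cfg, 10)
features = pd.DataFrame(
    [{"trial_id": t.trial_id, **t.labels, **kin.analyze_trial(t)[2]} for t in trials]
)

spec = bs.ModelSpec(
    response="RTotDur", fixed_effects=("goal", "gender"),
    group="agent", within_factors=("goal",),
)
sel = bs.select_cri_structure(spec, bs.make_mixedlm_fitter(features, spec))
print("Chosen random structure:", sel.chosen.structure)
print("Fits tried:", len(sel.trail), "| singular:", sel.chosen.singular)
r2m, r2c = bs.r2_nakagawa(sel.chosen)
print(f"R2 marginal = {r2m:.3f} (fixed effects), conditional = {r2c:.3f}"
      " (fixed + random)")
print("Goal coefficient (ms):")
print(sel.chosen.coef.loc[[i for i in sel.chosen.coef.index if "goal" in i]].round(3))
print(f"\nBonferroni-corrected alpha for 17 parameters:"
      f" {bs.bonferroni_threshold(0.05, 17):.5f}")
print("A goal effect surviving this threshold marks a kinematic parameter"
      "\nreliably modulated by the action's social intention.")
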