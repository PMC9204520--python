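"""Decompose KCF uncertainty into per-parameter contribution factors.

Runs one general Monte Carlo (all parameters perturbed) and five individual
Monte Carlos (one parameter class at a time) and reports each class's
contribution factor: 100 x (individual band width) / (general band width)
at the deepest-flexion frame.  Contributions need not sum to 100% because
parameters interact.  ~1 min at these sizes.
"""

import squatmc as sq

model = sq.default_model()
trial = sq.generate_squat_trial(model)
spec = sq.build_distributions(sq.default_cv_table())
deepest = trial.cycle_events[1]

general = sq.run_mc(model, trial, spec,
                    sq.MCDesign(kind="general", muscle_group="lower_limb",
                                n_iterations=200, seed=7))
general_band = sq.percentile_band(general)
print(f"general band width at deepest flexion: "
      f"{general_band.width[deepest]:.2f} BW")

for i, param in enumerate(("MIF", "TSL", "PEN", "OIP", "VIA")):
    rs = sq.run_mc(model, trial, spec,
                   sq.MCDesign(kind="individual", parameter=param,
                               muscle_group="lower_limb",
                               n_iterations=100, seed=8 + i))
    contrib = sq.parameter_contribution(sq.percentile_band(rs), general_band)
    print(f"  {param}: {contrib.values[deepest]:5.1f} % of the overall "
          f"KCF variability at deepest flexion")
print("-> in this rigid-tendon reduction, tendon slack length dominates and "
      "pennation is negligible; pathway points (OIP/VIA) matter through the "
      "muscle moment arms.  Group-uniform strength changes are absorbed by "
      "the moment constraint, which caps the MIF contribution.")
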