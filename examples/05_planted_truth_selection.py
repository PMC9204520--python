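"""Best-model selection against a synthetic 'measured' knee contact force.

Plants a known ground truth (knee-flexor tendon slack lengths +4%), adds
measurement noise, and selects the Monte Carlo iteration with the least KCF
RMSE - the identifiability experiment the probabilistic pipeline supports.
~15 s at 300 iterations.
"""

import squatmc as sq

model = sq.default_model()
trial = sq.generate_squat_trial(model)
spec = sq.build_distributions(sq.default_cv_table())

noise = 0.05  # BW
truth = sq.GroundTruthConfig(scales={"knee_flexors": {"TSL": 1.04}},
                             noise_sd_bw=noise, seed=11)
measured, truth_model, truth_sim = sq.generate_measured_kcf(model, trial, truth)

general = sq.run_mc(model, trial, spec,
                    sq.MCDesign(kind="general", muscle_group="lower_limb",
                                n_iterations=300, seed=12))
best = sq.select_best_model(general, measured)

print(f"measurement noise floor: {noise:.3f} BW")
print(f"baseline model RMSE vs measured: {best.baseline_error.rmse:.3f} BW")
print(f"best of {general.n_iterations} perturbed models: iteration "
      f"{best.iteration}, RMSE {best.error.rmse:.3f} BW")
gain = best.baseline_error.rmse - best.error.rmse
print(f"improvement over baseline: {gain:+.3f} BW")
print("-> a slack-length truth shifts the predicted KCF and can be chased "
      "by the Monte Carlo; a group-uniform strength change would be "
      "invisible here because the joint-moment constraint absorbs it.")
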