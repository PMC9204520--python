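"""Propagate muscle-parameter uncertainty to the KCF with a general MC.

Perturbs all five parameter classes (MIF, TSL, PEN, OIP, VIA) of every
lower-limb muscle around their baseline values using the shipped
literature-variability table, and summarises the knee-contact-force spread
as a 5th-95th percentile band.  ~10 s for 200 iterations.
"""

import numpy as np

import squatmc as sq

model = sq.default_model()
trial = sq.generate_squat_trial(model)
spec = sq.build_distributions(sq.default_cv_table())

design = sq.MCDesign(kind="general", muscle_group="lower_limb",
                     n_iterations=200, seed=42)
results = sq.run_mc(model, trial, spec, design)
band = sq.percentile_band(results)

deepest = trial.cycle_events[1]
print(f"{results.n_iterations} perturbed simulations "
      f"({len(results.failures)} failed)")
print(f"baseline KCF at deepest flexion: {results.baseline.kcf_bw[deepest]:.2f} BW")
print(f"5th-95th band at deepest flexion: "
      f"[{band.lower[deepest]:.2f}, {band.upper[deepest]:.2f}] BW "
      f"(width {band.width[deepest]:.2f} BW)")
print(f"mean band width over the cycle: {band.mean_width:.2f} BW")
converged, diag = sq.check_convergence(results)
print(f"converged by the +10%/<1% criterion: {converged} "
      f"(band change {diag['relative_change']:.1%})")
print("-> population-scale uncertainty in muscle parameters alone spreads "
      "the predicted knee load over several body weights at deep flexion.")
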