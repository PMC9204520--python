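"""Build the generic lower-limb model and scale it to a subject.

Loads the packaged 14-muscle sagittal-plane model (75 kg / 1.75 m generic),
scales it to a 95 kg / 1.80 m subject via landmark distances, and shows how
geometry scales while muscle strength is copied unchanged.
"""

import squatmc as sq

generic = sq.default_model()
print(f"generic model: {len(generic.muscles)} muscles, "
      f"{generic.subject_mass:.0f} kg, {generic.subject_height:.2f} m")

height = 1.80
landmarks = {
    "femur_length": 0.245 * height,
    "tibia_length": 0.246 * height,
    "pelvis_width": 0.191 * height,
}
scaled = sq.scale_model(generic, landmarks, subject_mass=95.0)

for name in ("thigh", "shank"):
    g, s = generic.segment(name), scaled.segment(name)
    print(f"{name}: length {g.length:.4f} -> {s.length:.4f} m, "
          f"mass {g.mass:.2f} -> {s.mass:.2f} kg")
vl_g, vl_s = generic.muscle("vaslat"), scaled.muscle("vaslat")
print(f"vastus lateralis: l_opt {vl_g.l_opt:.4f} -> {vl_s.l_opt:.4f} m, "
      f"tsl {vl_g.tsl:.4f} -> {vl_s.tsl:.4f} m, MIF {vl_g.mif:.0f} -> {vl_s.mif:.0f} N")
print("-> segment lengths and muscle-tendon rest lengths follow the subject's "
      "stature; maximum isometric forces are taken from the generic model.")
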