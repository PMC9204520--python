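# Generic reduced sagittal-plane lower-limb model.
#
# Single right limb with the upper body (and the contralateral limb) lumped
# into the pelvis segment so that the model total equals the subject mass.
# Segment lengths follow standard anthropometric fractions of a 1.75 m
# stature (thigh 0.245 H, shank 0.246 H, foot 0.152 H, pelvis width 0.191 H);
# masses follow standard per-segment fractions of a 75 kg body.
# Positions are metres in each segment's proximal-joint frame (x forward,
# y up); pennation angles in degrees; `tsl: auto` anchors the fiber at its
# optimal length in the mid-squat reference pose.
schema_version: 1
name: reduced_sagittal_lower_limb
subject:
  mass: 75.0
  height: 1.75
segments:
  - {name: pelvis, mass: 62.925, com: [0.0, 0.25], inertia_zz: 2.6, length: 0.33425, proximal_joint: null, distal_joint: hip_flexion}
  - {name: thigh, mass: 7.5, com: [0.0, -0.18565], inertia_zz: 0.144, length: 0.42875, proximal_joint: hip_flexion, distal_joint: knee_flexion}
  - {name: shank, mass: 3.4875, com: [0.0, -0.18641], inertia_zz: 0.059, length: 0.4305, proximal_joint: knee_flexion, distal_joint: ankle_flexion}
  - {name: foot, mass: 1.0875, com: [0.07, -0.03], inertia_zz: 0.005, length: 0.266, proximal_joint: ankle_flexion, distal_joint: null}
dofs:
  - {name: hip_flexion, parent: pelvis, child: thigh, location_in_parent: [0.0, 0.0], sigma: 1.0, range_deg: [-30, 130]}
  - {name: knee_flexion, parent: thigh, child: shank, location_in_parent: [0.0, -0.42875], sigma: -1.0, range_deg: [-5, 145]}
  - {name: ankle_flexion, parent: shank, child: foot, location_in_parent: [0.0, -0.4305], sigma: 1.0, range_deg: [-50, 50]}
muscles:
  # --- knee extensors ---------------------------------------------------
  - name: vaslat
    mif: 2250.0
    l_opt: 0.099
    pen_opt_deg: 18.0
    tsl: auto
    path:
      - {segment: thigh, position: [0.035, -0.20], role: origin}
      - {segment: thigh, position: [0.055, -0.460], role: via}
      - {segment: shank, position: [0.042, -0.070], role: insertion}
  - name: vasmed
    mif: 1700.0
    l_opt: 0.097
    pen_opt_deg: 24.0
    tsl: auto
    path:
      - {segment: thigh, position: [0.033, -0.25], role: origin}
      - {segment: thigh, position: [0.053, -0.458], role: via}
      - {segment: shank, position: [0.040, -0.070], role: insertion}
  - name: vasint
    mif: 1350.0
    l_opt: 0.099
    pen_opt_deg: 5.0
    tsl: auto
    path:
      - {segment: thigh, position: [0.030, -0.18], role: origin}
      - {segment: thigh, position: [0.054, -0.462], role: via}
      - {segment: shank, position: [0.041, -0.070], role: insertion}
  - name: recfem
    mif: 1200.0
    l_opt: 0.114
    pen_opt_deg: 14.0
    tsl: auto
    path:
      - {segment: pelvis, position: [0.045, 0.02], role: origin}
      - {segment: thigh, position: [0.055, -0.460], role: via}
      - {segment: shank, position: [0.042, -0.070], role: insertion}
  # --- knee flexors -----------------------------------------------------
  - name: bflh
    mif: 900.0
    l_opt: 0.109
    pen_opt_deg: 12.0
    tsl: auto
    path:
      - {segment: pelvis, position: [-0.065, -0.065], role: origin}
      - {segment: shank, position: [-0.028, -0.060], role: insertion}
  - name: bfsh
    mif: 450.0
    l_opt: 0.110
    pen_opt_deg: 20.0
    tsl: auto
    path:
      - {segment: thigh, position: [-0.022, -0.28], role: origin}
      - {segment: shank, position: [-0.028, -0.060], role: insertion}
  - name: semimem
    mif: 1550.0
    l_opt: 0.080
    pen_opt_deg: 15.0
    tsl: auto
    path:
      - {segment: pelvis, position: [-0.070, -0.070], role: origin}
      - {segment: shank, position: [-0.030, -0.055], role: insertion}
  - name: semiten
    mif: 450.0
    l_opt: 0.200
    pen_opt_deg: 10.0
    tsl: auto
    path:
      - {segment: pelvis, position: [-0.068, -0.078], role: origin}
      - {segment: shank, position: [-0.020, -0.090], role: insertion}
  - name: gasmed
    mif: 1600.0
    l_opt: 0.059
    pen_opt_deg: 10.0
    tsl: auto
    path:
      - {segment: thigh, position: [-0.028, -0.405], role: origin}
      - {segment: foot, position: [-0.060, -0.005], role: insertion}
  - name: gaslat
    mif: 700.0
    l_opt: 0.060
    pen_opt_deg: 12.0
    tsl: auto
    path:
      - {segment: thigh, position: [-0.030, -0.400], role: origin}
      - {segment: foot, position: [-0.060, -0.005], role: insertion}
  # --- ankle muscles ----------------------------------------------------
  - name: soleus
    mif: 3600.0
    l_opt: 0.075
    pen_opt_deg: 25.0
    tsl: auto
    path:
      - {segment: shank, position: [-0.030, -0.100], role: origin}
      - {segment: foot, position: [-0.060, -0.005], role: insertion}
  - name: tibant
    mif: 900.0
    l_opt: 0.068
    pen_opt_deg: 10.0
    tsl: auto
    path:
      - {segment: shank, position: [0.028, -0.15], role: origin}
      - {segment: shank, position: [0.045, -0.38], role: via}
      - {segment: foot, position: [0.042, -0.012], role: via}
      - {segment: foot, position: [0.100, -0.015], role: insertion}
  # --- hip muscles ------------------------------------------------------
  - name: glmax
    mif: 1950.0
    l_opt: 0.145
    pen_opt_deg: 20.0
    tsl: auto
    path:
      - {segment: pelvis, position: [-0.075, 0.035], role: origin}
      - {segment: pelvis, position: [-0.080, -0.045], role: via}
      - {segment: thigh, position: [-0.025, -0.105], role: insertion}
  - name: iliopsoas
    mif: 1600.0
    l_opt: 0.110
    pen_opt_deg: 12.0
    tsl: auto
    path:
      - {segment: pelvis, position: [0.030, 0.080], role: origin}
      - {segment: pelvis, position: [0.038, -0.008], role: via}
      - {segment: thigh, position: [0.012, -0.060], role: insertion}
groups:
  lower_limb: [vaslat, vasmed, vasint, recfem, bflh, bfsh, semimem, semiten, gasmed, gaslat, soleus, tibant, glmax, iliopsoas]
  knee_extensors: [vaslat, vasmed, vasint, recfem]
  knee_flexors: [bflh, bfsh, semimem, semiten, gasmed, gaslat]
  hip_muscles: [glmax, iliopsoas]
  ankle_muscles: [soleus, tibant]
  knee_hip_biarticular: [recfem, bflh, semimem, semiten]
  knee_ankle_biarticular: [gasmed, gaslat]
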