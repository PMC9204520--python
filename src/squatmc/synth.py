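"""Synthetic stand-ins for the instrumented-implant squat measurements.

Everything the pipeline consumes can be generated here without downloads:
subjects drawn from the study cohort statistics (six instrumented-implant
subjects, 74 +/- 6 years, 89 +/- 13 kg, 1.72 +/- 0.04 m), a descend-ascend
body-weight squat with quasi-static ground reaction forces, a ground-truth
"measured" knee contact force produced by a reference model with known
parameter perturbations plus noise, and amplitude-modulated EMG-like
signals.  Every artifact is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from importlib import resources
from scipy.signal import butter, filtfilt

from .errors import ValidationError
from .kinetics import SquatTrial, foot_rooted_frames
from .model_core import (
    GRAVITY,
    LowerLimbModel,
    default_model,
    scale_model,
    squat_closure_pose,
)
from .muscle_solver import SimulationResult, simulate_trial

#: Allometric landmark rules (fraction of stature), standard anthropometry.
LANDMARK_FRACTIONS = {
    "femur_length": 0.245,
    "tibia_length": 0.246,
    "pelvis_width": 0.191,
}

#: Synthetic planar marker set (label -> (segment, local position, m)).
MARKER_DEFS: dict[str, tuple[str, tuple[float, float]]] = {
    "SACR": ("pelvis", (-0.10, 0.05)),
    "ASIS": ("pelvis", (0.10, 0.02)),
    "THI1": ("thigh", (0.04, -0.15)),
    "THI2": ("thigh", (0.03, -0.35)),
    "KNEE": ("thigh", (0.05, -0.42)),
    "TIB1": ("shank", (0.04, -0.20)),
    "ANKL": ("shank", (0.03, -0.42)),
    "HEEL": ("foot", (-0.05, -0.04)),
    "TOE": ("foot", (0.15, -0.02)),
}


@dataclass
class SyntheticCohortSpec:
    """Population statistics the synthetic subjects are drawn from."""

    n_subjects: int = 6
    mass_mean: float = 89.0     # kg
    mass_sd: float = 13.0
    height_mean: float = 1.72   # m
    height_sd: float = 0.04
    age_mean: float = 74.0      # years
    age_sd: float = 6.0
    seed: int = 0


@dataclass
class Subject:
    index: int
    mass: float
    height: float
    age: float
    model: LowerLimbModel


@dataclass
class GroundTruthConfig:
    """Deterministic parameter perturbation defining the data-generating model.

    ``scales`` maps muscle-group name -> {parameter class -> multiplicative
    factor} for the scalar classes MIF/TSL/PEN; measurement noise is added
    to the simulated KCF trace with SD ``noise_sd_bw`` (BW).
    """

    scales: dict[str, dict[str, float]] = field(default_factory=dict)
    noise_sd_bw: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_bw < 0:
            raise ValidationError("noise SD must be >= 0")
        for group, params in self.scales.items():
            for p in params:
                if p not in ("MIF", "TSL", "PEN"):
                    raise ValidationError(
                        f"ground-truth scaling supports MIF/TSL/PEN, got {p!r}"
                    )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def generate_subject(
    spec: SyntheticCohortSpec, index: int, generic: LowerLimbModel | None = None
) -> Subject:
    """Draw one subject's anthropometry and scale the generic model to it.

    Landmark distances derive from stature by the allometric fractions in
    :data:`LANDMARK_FRACTIONS`; mass scales the segment masses.  Draws are
    truncated to positive values and are deterministic per (seed, index).
    """
    rng = _subject_rng(spec.seed, index)
    mass = height = age = -1.0
    for _ in range(100):
        mass = rng.normal(spec.mass_mean, spec.mass_sd)
        if mass > 0:
            break
    for _ in range(100):
        height = rng.normal(spec.height_mean, spec.height_sd)
        if height > 0:
            break
    for _ in range(100):
        age = rng.normal(spec.age_mean, spec.age_sd)
        if age > 0:
            break
    if min(mass, height, age) <= 0:
        raise ValidationError("could not draw positive anthropometry")
    generic = generic if generic is not None else default_model()
    landmarks = {k: f * height for k, f in LANDMARK_FRACTIONS.items()}
    model = scale_model(generic, landmarks, subject_mass=mass)
    model.subject_height = height
    return Subject(index=index, mass=mass, height=height, age=age, model=model)


def generate_squat_trial(
    subject: Subject | LowerLimbModel,
    depth_deg: float = 90.0,
    duration_s: float = 4.0,
    n_frames: int = 101,
    quasi_static: bool = True,
    with_markers: bool = False,
    marker_noise_sd: float = 0.0,
    seed: int = 0,
) -> SquatTrial:
    """A smooth descend-ascend body-weight squat for one subject.

    Knee flexion follows a raised cosine 0 -> depth -> 0; hip and ankle
    angles follow the hip-over-ankle closure so the centre of mass stays
    over the foot; the per-limb vertical GRF is half body weight (with the
    centre-of-mass acceleration modulation when ``quasi_static=False``) and
    the centre of pressure tracks the model COM.
    """
    model = subject.model if isinstance(subject, Subject) else subject
    knee_range = model.dof("knee_flexion").angle_range
    depth = math.radians(depth_deg)
    if not knee_range[0] <= depth <= knee_range[1]:
        raise ValidationError(f"squat depth {depth_deg} deg outside the knee range")
    t = np.linspace(0.0, duration_s, n_frames)
    knee = depth * 0.5 * (1.0 - np.cos(2.0 * math.pi * t / duration_s))
    cm = model.compile()
    q = np.zeros((n_frames, cm.n_dof))
    for f, k in enumerate(knee):
        pose = squat_closure_pose(model, float(k))
        q[f] = [pose[name] for name in model.dof_names]

    # model COM in the foot-rooted frame, for the centre of pressure
    dummy = SquatTrial(
        time=t,
        dof_names=model.dof_names,
        joint_angles=q,
        grf=np.zeros((n_frames, 2)),
        cop=np.zeros(n_frames),
        cycle_events=(0, n_frames // 2, n_frames - 1),
        subject_mass=model.subject_mass,
        subject_height=model.subject_height,
    )
    theta, origin = foot_rooted_frames(cm, dummy)
    masses = np.array([s.mass for s in model.segments])
    com = np.zeros((n_frames, 2))
    for i, s in enumerate(model.segments):
        c, sn = np.cos(theta[:, i]), np.sin(theta[:, i])
        cx, cy = s.com_local
        com[:, 0] += masses[i] * (origin[:, i, 0] + c * cx - sn * cy)
        com[:, 1] += masses[i] * (origin[:, i, 1] + sn * cx + c * cy)
    com /= masses.sum()

    weight = model.subject_mass * GRAVITY
    if quasi_static:
        fy = np.full(n_frames, weight / 2.0)
    else:
        dt = t[1] - t[0]
        acc = np.gradient(np.gradient(com[:, 1], dt), dt)
        fy = np.clip(model.subject_mass * (GRAVITY + acc) / 2.0, 0.0, None)
    grf = np.stack([np.zeros(n_frames), fy], axis=-1)

    markers = None
    if with_markers:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
        markers = {}
        for label, (seg, local) in MARKER_DEFS.items():
            i = cm.seg_index[seg]
            c, sn = np.cos(theta[:, i]), np.sin(theta[:, i])
            px, py = local
            pos = np.stack(
                [origin[:, i, 0] + c * px - sn * py,
                 origin[:, i, 1] + sn * px + c * py],
                axis=-1,
            )
            if marker_noise_sd > 0:
                pos = pos + rng.normal(0.0, marker_noise_sd, pos.shape)
            markers[label] = pos

    return SquatTrial(
        time=t,
        dof_names=model.dof_names,
        joint_angles=q,
        grf=grf,
        cop=com[:, 0],
        cycle_events=(0, n_frames // 2, n_frames - 1),
        subject_mass=model.subject_mass,
        subject_height=model.subject_height,
        markers=markers,
    )


def apply_ground_truth(
    baseline: LowerLimbModel, truth: GroundTruthConfig
) -> LowerLimbModel:
    """The deterministic truth-perturbed model behind the synthetic measurement."""
    model = baseline.copy()
    model.provenance = "truth"
    for group_name, params in truth.scales.items():
        for name in model.group(group_name).members:
            m = model.muscle(name)
            if "MIF" in params:
                m.mif *= params["MIF"]
            if "TSL" in params:
                m.tsl *= params["TSL"]
            if "PEN" in params:
                m.pen_opt *= params["PEN"]
    return model


def generate_measured_kcf(
    subject: Subject | LowerLimbModel,
    trial: SquatTrial,
    truth: GroundTruthConfig,
    include_flv: bool = True,
) -> tuple[np.ndarray, LowerLimbModel, SimulationResult]:
    """Synthetic "measured" KCF trace (BW): truth-model prediction + noise.

    Returns (measured trace, the truth model, the noise-free truth
    simulation) so recovery experiments can compare against the planted
    ground truth.
    """
    baseline = subject.model if isinstance(subject, Subject) else subject
    truth_model = apply_ground_truth(baseline, truth)
    result = simulate_trial(trial, truth_model, include_flv=include_flv)
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed, spawn_key=(2,)))
    measured = result.kcf_bw + rng.normal(0.0, truth.noise_sd_bw, result.kcf_bw.shape)
    return measured, truth_model, result


def generate_emg(
    trial: SquatTrial,
    activations: dict[str, np.ndarray],
    sampling_rate: float = 1500.0,
    carrier_band: tuple[float, float] = (20.0, 250.0),
    noise_floor: float = 0.02,
    amplitude_mv: float = 1.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Amplitude-modulated band-limited noise emulating raw surface EMG.

    Each muscle's activation trace (on the trial grid, values in [0, 1]) is
    upsampled to ``sampling_rate`` and multiplies a band-limited Gaussian
    carrier, so that the standard processing chain (band-pass, rectify,
    moving average, normalise) approximately recovers the activation shape.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    n = int(round(trial.time[-1] * sampling_rate)) + 1
    t_hi = np.linspace(trial.time[0], trial.time[-1], n)
    b, a = butter(4, carrier_band, btype="bandpass", fs=sampling_rate)
    out = {}
    for muscle, act in activations.items():
        act = np.asarray(act, dtype=float)
        if np.any(act < -1e-9) or np.any(act > 1 + 1e-9):
            raise ValidationError(f"activations for {muscle!r} must lie in [0, 1]")
        envelope = np.interp(t_hi, trial.time, act) + noise_floor
        carrier = filtfilt(b, a, rng.standard_normal(n))
        carrier /= np.sqrt(np.mean(carrier**2))
        out[muscle] = amplitude_mv * envelope * carrier
    return out


def default_cv_table() -> pd.DataFrame:
    """The shipped default literature-CV table.

    Synthetic defaults: TSL CVs lie in the 2-9% working range; MIF and PEN
    carry literature-plausible placeholder CVs; at least one muscle per
    parameter is deliberately absent to exercise the mean-CV fallback rule.
    OIP/VIA variability is the distribution spec's 5 mm per-axis SD and
    needs no table rows.
    """
    ref = resources.files("squatmc").joinpath("data/default_cv_table.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)
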