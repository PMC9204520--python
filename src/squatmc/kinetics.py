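"""Squat-trial kinematics and planar inverse dynamics.

The squat is analysed single-limb: the trial carries the per-limb ground
reaction force explicitly (the synthetic generator assumes a symmetric
split), and the foot is assumed to stay flat on the ground, which fixes the
global orientation of the kinematic chain.  Net internal joint moments are
computed by a bottom-up Newton-Euler recursion from the foot; a
``quasi_static`` mode zeroes all accelerations, which is the default for
slow body-weight squats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import butter, filtfilt

from .errors import SolverError, ValidationError
from .model_core import GRAVITY, CompiledModel, LowerLimbModel

#: Default zero-phase low-pass cutoff for kinematic differentiation (Hz).
FILTER_CUTOFF_HZ = 6.0


@dataclass
class SquatTrial:
    """One squat repetition: angles, ground reaction force, events.

    ``joint_angles`` has one column per model DoF (rad, flexion positive),
    ``grf`` is the per-limb ground reaction force (N, global x/y) applied at
    the centre of pressure ``cop`` (global x on the ground plane).
    """

    time: np.ndarray                     # (F,) s, uniform
    dof_names: list[str]
    joint_angles: np.ndarray             # (F, n_dof) rad
    grf: np.ndarray                      # (F, 2) N
    cop: np.ndarray                      # (F,) m
    cycle_events: tuple[int, int, int]   # start, deepest flexion, end
    subject_mass: float                  # kg
    subject_height: float                # m
    measured_kcf_bw: np.ndarray | None = None
    emg: dict[str, np.ndarray] | None = None
    markers: dict[str, np.ndarray] | None = None
    ankle_height: float = 0.08           # m, ankle centre above the ground

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.joint_angles = np.atleast_2d(np.asarray(self.joint_angles, dtype=float))
        self.grf = np.atleast_2d(np.asarray(self.grf, dtype=float))
        self.cop = np.asarray(self.cop, dtype=float)
        if self.time.size > 1:
            dt = np.diff(self.time)
            if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12):
                raise ValidationError("trial time grid must be uniform")
        if np.any(self.grf[:, 1] < -1e-9):
            raise ValidationError("vertical GRF component must be >= 0")
        s, d, e = self.cycle_events
        if self.n_frames > 1 and not (s < d < e):
            raise ValidationError("deepest-flexion event must lie strictly inside the cycle")
        if self.joint_angles.shape != (self.n_frames, len(self.dof_names)):
            raise ValidationError("joint_angles shape does not match time grid / dof names")

    @property
    def n_frames(self) -> int:
        return int(self.time.size)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.n_frames > 1 else 0.0

    def angle(self, dof: str) -> np.ndarray:
        return self.joint_angles[:, self.dof_names.index(dof)]


@dataclass
class JointMomentTrace:
    """Net internal joint moments (flexion-positive) plus the knee
    intersegmental force, on the trial's time grid."""

    time: np.ndarray
    dof_names: list[str]
    moments: np.ndarray                  # (F, n_dof) N m
    knee_intersegmental: np.ndarray      # (F, 2) N, global frame
    knee_position: np.ndarray            # (F, 2) m, global
    shank_angle: np.ndarray              # (F,) rad, global CCW tilt

    def moment(self, dof: str) -> np.ndarray:
        return self.moments[:, self.dof_names.index(dof)]


# ---------------------------------------------------------------------------
# Global pose chain with a flat foot
# ---------------------------------------------------------------------------

def foot_rooted_frames(
    cm: CompiledModel, trial: SquatTrial
) -> tuple[np.ndarray, np.ndarray]:
    """Segment angles and origins with the foot flat and the ankle anchored.

    Returns ``(theta, origin)`` shaped (F, n_seg) and (F, n_seg, 2); the
    ankle (origin of the foot frame) sits at ``(0, trial.ankle_height)``.
    """
    q = trial.joint_angles
    # root (pelvis) tilt that makes the global foot angle zero
    tilt = np.zeros(q.shape[0])
    for d in cm.dof_order:
        tilt -= d.sigma * q[:, cm.dof_index[d.name]]
    theta, origin = cm.segment_frames(q, root_angle=tilt)
    fi = cm.seg_index["foot"]
    anchor = np.array([0.0, trial.ankle_height])
    shift = anchor[None, :] - origin[:, fi, :]
    origin = origin + shift[:, None, :]
    return theta, origin


# ---------------------------------------------------------------------------
# Inverse dynamics
# ---------------------------------------------------------------------------

def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _filtered_second_derivative(x: np.ndarray, dt: float, cutoff: float) -> np.ndarray:
    if x.shape[0] < 13 or dt <= 0:
        return np.zeros_like(x)
    nyq = 0.5 / dt
    wn = min(cutoff / nyq, 0.95)
    b, a = butter(2, wn)
    xf = filtfilt(b, a, x, axis=0)
    v = np.gradient(xf, dt, axis=0)
    return np.gradient(v, dt, axis=0)


def inverse_dynamics(
    trial: SquatTrial,
    model: LowerLimbModel | CompiledModel,
    quasi_static: bool = True,
    filter_cutoff: float = FILTER_CUTOFF_HZ,
) -> JointMomentTrace:
    """Net flexion moments at ankle/knee/hip and the knee intersegmental force.

    Bottom-up planar Newton-Euler recursion using the per-limb GRF applied
    at the centre of pressure.  With ``quasi_static`` (the default) all
    accelerations are zeroed; otherwise segment accelerations come from
    zero-phase low-pass filtered double differentiation.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    if trial.grf.shape[0] != trial.n_frames or trial.cop.shape[0] != trial.n_frames:
        raise ValidationError("GRF / COP are not on the trial's time grid")
    F = trial.n_frames
    theta, origin = foot_rooted_frames(cm, trial)

    seg = {name: i for name, i in cm.seg_index.items()}
    com = np.empty((F, cm.n_seg, 2))
    for s in cm.model.segments:
        i = seg[s.name]
        c, sn = np.cos(theta[:, i]), np.sin(theta[:, i])
        cx, cy = s.com_local
        com[:, i, 0] = origin[:, i, 0] + c * cx - sn * cy
        com[:, i, 1] = origin[:, i, 1] + sn * cx + c * cy

    if quasi_static:
        acc = np.zeros((F, cm.n_seg, 2))
        ang_acc = np.zeros((F, cm.n_seg))
    else:
        acc = np.stack(
            [_filtered_second_derivative(com[:, i, :], trial.dt, filter_cutoff)
             for i in range(cm.n_seg)],
            axis=1,
        )
        ang_acc = np.stack(
            [_filtered_second_derivative(theta[:, i], trial.dt, filter_cutoff)
             for i in range(cm.n_seg)],
            axis=1,
        )

    grf = trial.grf
    cop = np.stack([trial.cop, np.zeros(F)], axis=-1)
    g_vec = np.array([0.0, -GRAVITY])

    # joint positions, distal to proximal: ankle, knee, hip
    chain = [("foot", "ankle_flexion"), ("shank", "knee_flexion"), ("thigh", "hip_flexion")]
    joint_pos = {}
    for seg_name, dof_name in chain:
        joint_pos[dof_name] = origin[:, seg[seg_name], :]

    moments_z: dict[str, np.ndarray] = {}
    R_prev = np.zeros((F, 2))
    M_prev = np.zeros(F)
    prev_joint = None
    for seg_name, dof_name in chain:
        i = seg[seg_name]
        s = cm.model.segment(seg_name)
        jp = joint_pos[dof_name]
        ext_f = np.zeros((F, 2))
        ext_m = np.zeros(F)
        if seg_name == "foot":
            ext_f = grf
            ext_m = _cross2(cop - com[:, i, :], grf)
        # force balance: m a = R_j + W + ext - R_prev(applied by distal segment)
        W = s.mass * g_vec
        R_j = s.mass * acc[:, i, :] - W - ext_f + R_prev
        # moment balance about segment COM
        M_j = (
            s.inertia_zz * ang_acc[:, i]
            - _cross2(jp - com[:, i, :], R_j)
            - ext_m
            + M_prev
        )
        if prev_joint is not None:
            M_j += _cross2(prev_joint - com[:, i, :], R_prev)
        moments_z[dof_name] = M_j
        if dof_name == "knee_flexion":
            knee_interseg = R_j.copy()
            knee_pos = jp.copy()
        R_prev, M_prev, prev_joint = R_j, M_j, jp

    mom = np.zeros((F, cm.n_dof))
    for d in cm.model.dofs:
        mom[:, cm.dof_index[d.name]] = d.sigma * moments_z[d.name]
    return JointMomentTrace(
        time=trial.time,
        dof_names=cm.model.dof_names,
        moments=mom,
        knee_intersegmental=knee_interseg,
        knee_position=knee_pos,
        shank_angle=theta[:, seg["shank"]],
    )


# ---------------------------------------------------------------------------
# Inverse kinematics
# ---------------------------------------------------------------------------

def inverse_kinematics(
    markers: Mapping[str, np.ndarray],
    model: LowerLimbModel | CompiledModel,
    marker_defs: Mapping[str, tuple[str, np.ndarray]],
    weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares fit of model markers to measured trajectories.

    ``markers`` maps label -> (F, 2) global positions (m); ``marker_defs``
    maps label -> (segment, local position).  The fitted parameters per
    frame are the pelvis position (2), pelvis tilt, and the joint angles.
    Returns ``(joint_angles (F, n_dof), rms_residual (F,))``.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    labels = [m for m in marker_defs if m in markers]
    if not labels:
        raise ValidationError("no usable markers: defs and data do not overlap")
    F = next(iter(markers.values())).shape[0]
    n_par = 3 + cm.n_dof
    if 2 * len(labels) < n_par:
        raise ValidationError(
            f"underdetermined fit: {len(labels)} markers for {n_par} parameters"
        )
    local = np.array([marker_defs[m][1] for m in labels], dtype=float)
    seg_idx = np.array([cm.seg_index[marker_defs[m][0]] for m in labels])
    w = np.sqrt([float(weights.get(m, 1.0)) if weights else 1.0 for m in labels])
    meas = np.stack([np.asarray(markers[m], dtype=float) for m in labels], axis=1)

    def predict(x: np.ndarray) -> np.ndarray:
        theta, origin = cm.segment_frames(
            x[None, 3:], root_position=x[:2], root_angle=x[2]
        )
        th = theta[0, seg_idx]
        c, s = np.cos(th), np.sin(th)
        px, py = local[:, 0], local[:, 1]
        out = np.empty((len(labels), 2))
        out[:, 0] = origin[0, seg_idx, 0] + c * px - s * py
        out[:, 1] = origin[0, seg_idx, 1] + s * px + c * py
        return out

    angles = np.zeros((F, cm.n_dof))
    rms = np.zeros(F)
    x0 = np.zeros(n_par)
    for f in range(F):
        target = meas[f]
        if np.allclose(target, target[0], atol=1e-9):
            raise SolverError(f"frame {f}: markers coincident, pose underdetermined")

        def resid(x, target=target):
            return ((predict(x) - target) * w[:, None]).ravel()

        sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
        if not sol.success:  # pragma: no cover - lm rarely fails here
            raise SolverError(f"frame {f}: IK did not converge (cost={sol.cost:.3e})")
        J = sol.jac
        if np.linalg.matrix_rank(J, tol=1e-8) < n_par:
            raise SolverError(f"frame {f}: marker set leaves the pose underdetermined")
        angles[f] = sol.x[3:]
        rms[f] = float(np.sqrt(np.mean(sol.fun**2)))
        x0 = sol.x
    return angles, rms
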