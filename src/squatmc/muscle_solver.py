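"""Per-frame static optimization and knee contact force assembly.

The muscle-redundancy problem is solved frame by frame as

    min  sum_i a_i^2
    s.t. sum_i a_i * C_ij = M_j   for every DoF j
         0 <= a_i <= 1

where ``C_ij`` is the maximum active force along the tendon at the current
fiber state times the tendon-excursion moment arm.  Passive fiber forces are
activation-independent and are therefore moved to the constraint right-hand
side.  The QP is solved as a bounded least-squares problem in activation
space (equality constraints enforced by a large penalty weight, BVLS);
frames whose moment demand exceeds total muscle capacity are flagged
infeasible and keep the least-constraint-violation solution rather than
aborting a Monte Carlo run.

The knee contact force is the intersegmental knee force minus the pull of
every muscle whose pathway crosses the knee, expressed in the tibia frame
and reported as a magnitude in body weight (BW).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .errors import ValidationError
from .kinetics import JointMomentTrace, SquatTrial, foot_rooted_frames, inverse_dynamics
from .model_core import (
    CompiledModel,
    LowerLimbModel,
    _pose_vector,
    fl_active,
    fl_passive,
    fv,
)

#: Penalty weight enforcing the moment-equality constraints in the QP.
EQUALITY_PENALTY = 1e4
#: Constraint residual (N m) above which a frame is flagged infeasible.
FEASIBILITY_TOL = 1e-4


@dataclass
class FrameSolution:
    """Static-optimization solution for one frame."""

    activations: np.ndarray          # (n_m,) in [0, 1]
    muscle_forces: np.ndarray        # (n_m,) N along tendon (active + passive)
    kcf_vector: np.ndarray | None    # (2,) N, tibia frame
    kcf_bw: float | None
    feasible: bool
    objective: float                 # sum of squared activations
    constraint_residual: float       # max |C a - M| (N m)


@dataclass
class SimulationResult:
    """Frame-by-frame outputs of a squat simulation."""

    time: np.ndarray
    muscle_names: list[str]
    activations: np.ndarray          # (F, n_m)
    muscle_forces: np.ndarray        # (F, n_m)
    kcf: np.ndarray                  # (F, 2) tibia frame
    kcf_bw: np.ndarray               # (F,)
    feasible: np.ndarray             # (F,) bool
    objective: np.ndarray            # (F,)
    constraint_residual: np.ndarray  # (F,)
    include_flv: bool = True
    provenance: str = "baseline"

    @property
    def n_frames(self) -> int:
        return int(self.time.size)


def solve_activation(
    C: np.ndarray, M: np.ndarray, penalty: float = EQUALITY_PENALTY
) -> tuple[np.ndarray, float, bool, float]:
    """Solve min ||a||^2 s.t. C a = M, 0 <= a <= 1 (penalty + BVLS).

    Returns (activations, max constraint residual, feasible, objective).
    For infeasible demands the minimum-violation solution is returned with
    ``feasible=False``.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    M = np.atleast_1d(np.asarray(M, dtype=float))
    E, n = C.shape
    if M.shape != (E,):
        raise ValidationError("demand vector does not match constraint rows")
    A = np.vstack([penalty * C, np.eye(n)])
    b = np.concatenate([penalty * M, np.zeros(n)])
    res = lsq_linear(A, b, bounds=(0.0, 1.0), method="bvls")
    a = np.clip(res.x, 0.0, 1.0)
    resid = float(np.max(np.abs(C @ a - M))) if E else 0.0
    return a, resid, resid <= FEASIBILITY_TOL, float(a @ a)


def _capacities(
    cm: CompiledModel,
    lnorm: np.ndarray,
    vnorm: np.ndarray,
    cos_pen: np.ndarray,
    include_flv: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Max active force and passive force along the tendon, shape (F, n_m)."""
    if include_flv:
        f_active = cm.mif * fl_active(lnorm) * fv(vnorm) * cos_pen
        f_passive = cm.mif * fl_passive(lnorm) * cos_pen
    else:
        f_active = cm.mif * np.ones_like(lnorm) * cos_pen
        f_passive = np.zeros_like(lnorm)
    return f_active, f_passive


def solve_frame(
    moments: np.ndarray,
    model: LowerLimbModel | CompiledModel,
    pose,
    pose_velocity=None,
    include_flv: bool = True,
    penalty: float = EQUALITY_PENALTY,
) -> FrameSolution:
    """Static optimization for a single pose and moment demand.

    ``moments`` is the net flexion moment per DoF (N m), ordered like
    ``model.dof_names``.  ``pose_velocity`` (rad/s per DoF) feeds the
    force-velocity multiplier; omit it for a quasi-static solve.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    q = _pose_vector(cm, pose)[None, :]
    L = cm.lengths(q)
    if pose_velocity is not None:
        qd = _pose_vector(cm, pose_velocity)[None, :]
        R0 = cm.moment_arms(q)
        V = -np.einsum("fmj,fj->fm", R0, qd)  # dL/dt = -r . qdot
    else:
        V = None
    R = cm.moment_arms(q)                     # (1, n_m, n_dof)
    lnorm, vnorm, cos_pen, _ = cm.fiber_arrays(L, V)
    f_active, f_passive = _capacities(cm, lnorm, vnorm, cos_pen, include_flv)
    C = (f_active[0][:, None] * R[0]).T       # (n_dof, n_m)
    M = np.asarray(moments, dtype=float) - R[0].T @ f_passive[0]
    a, resid, feasible, obj = solve_activation(C, M, penalty)
    forces = a * f_active[0] + f_passive[0]
    return FrameSolution(
        activations=a,
        muscle_forces=forces,
        kcf_vector=None,
        kcf_bw=None,
        feasible=feasible,
        objective=obj,
        constraint_residual=resid,
    )


def _knee_pull_directions(
    cm: CompiledModel, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unit pull vectors on the tibia of every knee-crossing muscle.

    Returns (muscle indices, unit vectors (F, k, 2)); each vector points
    from the distal-side end of the crossing pathway segment toward its
    proximal-side end (the direction the muscle pulls the tibia).
    """
    j = cm.dof_index["knee_flexion"]
    idx = np.where(cm.cross_edge[:, j] >= 0)[0]
    edges = cm.cross_edge[idx, j]
    distal = cm.distal_segments["knee_flexion"]
    seg_names = [s.name for s in cm.model.segments]
    e_on_distal = np.array([seg_names[cm.point_seg[e]] in distal for e in edges])
    p0 = positions[:, edges, :]
    p1 = positions[:, edges + 1, :]
    prox = np.where(e_on_distal[None, :, None], p1, p0)
    dist = np.where(e_on_distal[None, :, None], p0, p1)
    u = prox - dist
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    return idx, u


def knee_contact_force(
    model: LowerLimbModel | CompiledModel,
    pose,
    muscle_forces: np.ndarray,
    intersegmental_force: np.ndarray,
    shank_angle: float | None = None,
) -> tuple[np.ndarray, float]:
    """Knee contact force vector (tibia frame, N) and magnitude in BW.

    ``intersegmental_force`` is the global-frame force the femur applies to
    the tibia through the joint when muscles are ignored (from inverse
    dynamics); muscle pulls of every knee-crossing pathway are subtracted,
    so the result is the force transmitted through the articular surfaces.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    q = _pose_vector(cm, pose)[None, :]
    tilt = 0.0
    for d in cm.dof_order:
        tilt -= d.sigma * q[0, cm.dof_index[d.name]]
    theta, origin = cm.segment_frames(q, root_angle=np.array([tilt]))
    positions = cm.point_positions_from_frames(theta, origin)
    if shank_angle is None:
        shank_angle = float(theta[0, cm.seg_index["shank"]])
    idx, u = _knee_pull_directions(cm, positions)
    pull = (np.asarray(muscle_forces)[idx][None, :, None] * u).sum(axis=1)[0]
    fc_global = np.asarray(intersegmental_force, dtype=float) - pull
    c, s = np.cos(-shank_angle), np.sin(-shank_angle)
    fc_tibia = np.array([c * fc_global[0] - s * fc_global[1],
                         s * fc_global[0] + c * fc_global[1]])
    bw = float(np.linalg.norm(fc_tibia)) / cm.model.subject_weight
    return fc_tibia, bw


def simulate_trial(
    trial: SquatTrial,
    model: LowerLimbModel | CompiledModel,
    include_flv: bool = True,
    quasi_static: bool = True,
    penalty: float = EQUALITY_PENALTY,
    moments: JointMomentTrace | None = None,
) -> SimulationResult:
    """Run inverse dynamics + static optimization + KCF over a whole trial.

    Deterministic for fixed inputs.  ``quasi_static`` zeroes segment
    accelerations in inverse dynamics and the force-velocity multiplier
    (fv = 1), the appropriate default for slow body-weight squats.
    Infeasible frames are flagged in ``result.feasible`` and carry the
    least-violation solution.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    if moments is None:
        moments = inverse_dynamics(trial, cm, quasi_static=quasi_static)
    F = trial.n_frames
    q = trial.joint_angles
    theta, origin = foot_rooted_frames(cm, trial)
    positions = cm.point_positions_from_frames(theta, origin)
    L = cm.lengths(q)
    if quasi_static or F < 2:
        V = None
    else:
        V = np.gradient(L, trial.dt, axis=0)
    R = cm.moment_arms(q)
    lnorm, vnorm, cos_pen, _ = cm.fiber_arrays(L, V)
    f_active, f_passive = _capacities(cm, lnorm, vnorm, cos_pen, include_flv)

    n = cm.n_muscles
    activations = np.zeros((F, n))
    forces = np.zeros((F, n))
    feasible = np.zeros(F, dtype=bool)
    objective = np.zeros(F)
    resid = np.zeros(F)
    for f in range(F):
        C = (f_active[f][:, None] * R[f]).T
        M = moments.moments[f] - R[f].T @ f_passive[f]
        a, r, ok, obj = solve_activation(C, M, penalty)
        activations[f] = a
        forces[f] = a * f_active[f] + f_passive[f]
        feasible[f], objective[f], resid[f] = ok, obj, r

    idx, u = _knee_pull_directions(cm, positions)
    pull = (forces[:, idx, None] * u).sum(axis=1)            # (F, 2)
    fc_global = moments.knee_intersegmental - pull
    th = moments.shank_angle
    c, s = np.cos(-th), np.sin(-th)
    kcf = np.stack(
        [c * fc_global[:, 0] - s * fc_global[:, 1],
         s * fc_global[:, 0] + c * fc_global[:, 1]],
        axis=-1,
    )
    kcf_bw = np.linalg.norm(kcf, axis=-1) / cm.model.subject_weight
    return SimulationResult(
        time=trial.time,
        muscle_names=list(cm.model.muscle_names),
        activations=activations,
        muscle_forces=forces,
        kcf=kcf,
        kcf_bw=kcf_bw,
        feasible=feasible,
        objective=objective,
        constraint_residual=resid,
        include_flv=include_flv,
        provenance=cm.model.provenance,
    )
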