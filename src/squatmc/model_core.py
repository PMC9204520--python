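"""Reduced sagittal-plane lower-limb model and Hill-type muscle mechanics.

The model is a planar kinematic tree rooted at the pelvis: pelvis -> thigh ->
shank -> foot, connected by the three sagittal flexion DoFs (hip, knee,
ankle).  Muscle-tendon units are routed as point-to-point pathways (origin,
optional via points, insertion) attached to segment frames; muscle moment
arms follow the tendon-excursion definition r = -dL/dq evaluated by central
finite differences.

Conventions
-----------
* Right-handed planar frames: x forward, y up, rotations counter-clockwise.
* Flexion-positive joint angles.  Internally each DoF stores the sign
  ``sigma`` mapping its flexion angle onto the CCW rotation of the child
  frame relative to the parent (hip +1, knee -1, ankle +1 in the default
  model, so that a standing pose has all angles at zero).
* SI units throughout: m, kg, N, rad, s.  Knee contact force is converted
  to body weight (BW) only at reporting boundaries.
* Each segment frame has its origin at the segment's proximal joint.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigurationError, ModelLookupError, ValidationError

GRAVITY = 9.81  # m/s^2

#: Parameter classes perturbed by the probabilistic engine.
PARAMETER_CLASSES = ("MIF", "TSL", "PEN", "OIP", "VIA")

#: Canonical muscle-group names (Table-1-style semantics on the reduced set).
GROUP_NAMES = (
    "lower_limb",
    "knee_extensors",
    "knee_flexors",
    "hip_muscles",
    "ankle_muscles",
    "knee_hip_biarticular",
    "knee_ankle_biarticular",
)

#: Finite-difference step for tendon-excursion moment arms (rad).
MOMENT_ARM_STEP = 1e-5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BodySegment:
    """Rigid segment with inertial properties in its own (proximal) frame."""

    name: str
    mass: float                      # kg
    com_local: np.ndarray            # (2,) m, in segment frame
    inertia_zz: float                # kg m^2 about COM
    length: float                    # m, characteristic (proximal->distal)
    proximal_joint: str | None = None
    distal_joint: str | None = None

    def __post_init__(self) -> None:
        self.com_local = np.asarray(self.com_local, dtype=float)
        if self.mass <= 0:
            raise ValidationError(f"segment {self.name!r}: mass must be > 0")
        if self.length <= 0:
            raise ValidationError(f"segment {self.name!r}: length must be > 0")
        if self.inertia_zz < 0:
            raise ValidationError(f"segment {self.name!r}: inertia_zz must be >= 0")


@dataclass
class JointDof:
    """Sagittal hinge DoF between two segments, flexion-positive."""

    name: str
    parent: str
    child: str
    location_in_parent: np.ndarray   # (2,) m, joint centre in parent frame
    sigma: float = 1.0               # CCW rotation per unit flexion angle
    angle_range: tuple[float, float] = (-math.pi, math.pi)  # rad

    def __post_init__(self) -> None:
        self.location_in_parent = np.asarray(self.location_in_parent, dtype=float)
        lo, hi = self.angle_range
        if not lo < hi:
            raise ValidationError(f"dof {self.name!r}: empty angle range")


@dataclass
class PathPoint:
    """One attachment or routing point of a muscle pathway."""

    segment: str
    position_local: np.ndarray       # (2,) m
    role: str                        # origin | via | insertion

    def __post_init__(self) -> None:
        self.position_local = np.asarray(self.position_local, dtype=float)
        if self.role not in ("origin", "via", "insertion"):
            raise ValidationError(f"invalid path-point role {self.role!r}")


@dataclass
class MuscleTendonUnit:
    """Hill-type actuator: force-generation parameters plus geometric pathway.

    ``mif`` is the maximum isometric force (N), ``tsl`` the tendon slack
    length (m), ``pen_opt`` the pennation angle at optimal fiber length
    (rad) and ``l_opt`` the optimal fiber length (m).
    """

    name: str
    mif: float
    tsl: float
    pen_opt: float
    l_opt: float
    pathway: list[PathPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mif <= 0:
            raise ValidationError(f"muscle {self.name!r}: mif must be > 0")
        if self.tsl <= 0:
            raise ValidationError(f"muscle {self.name!r}: tsl must be > 0")
        if self.l_opt <= 0:
            raise ValidationError(f"muscle {self.name!r}: l_opt must be > 0")
        if not 0 <= self.pen_opt < math.pi / 2:
            raise ValidationError(f"muscle {self.name!r}: pen_opt outside [0, pi/2)")
        if len(self.pathway) >= 2:
            if self.pathway[0].role != "origin" or self.pathway[-1].role != "insertion":
                raise ValidationError(
                    f"muscle {self.name!r}: pathway must run origin -> ... -> insertion"
                )
            for p in self.pathway[1:-1]:
                if p.role != "via":
                    raise ValidationError(
                        f"muscle {self.name!r}: interior path points must be via points"
                    )
            if len({p.segment for p in self.pathway}) < 2:
                raise ValidationError(
                    f"muscle {self.name!r}: pathway must touch >= 2 segments"
                )
        else:
            raise ValidationError(f"muscle {self.name!r}: pathway needs >= 2 points")


@dataclass
class MuscleGroup:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.name not in GROUP_NAMES:
            raise ValidationError(f"unknown muscle group {self.name!r}")
        self.members = tuple(self.members)


@dataclass
class LowerLimbModel:
    """Complete reduced model: segments, DoFs, muscles, groups, anthropometry."""

    segments: list[BodySegment]
    dofs: list[JointDof]
    muscles: list[MuscleTendonUnit]
    groups: list[MuscleGroup]
    subject_mass: float              # kg
    subject_height: float            # m
    provenance: str = "baseline"
    name: str = "reduced_sagittal_lower_limb"

    # -- lookups ----------------------------------------------------------
    def segment(self, name: str) -> BodySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise ModelLookupError(f"unknown segment {name!r}")

    def dof(self, name: str) -> JointDof:
        for d in self.dofs:
            if d.name == name:
                return d
        raise ModelLookupError(f"unknown dof {name!r}")

    def muscle(self, name: str) -> MuscleTendonUnit:
        for m in self.muscles:
            if m.name == name:
                return m
        raise ModelLookupError(f"unknown muscle {name!r}")

    def group(self, name: str) -> MuscleGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise ModelLookupError(f"unknown muscle group {name!r}")

    @property
    def dof_names(self) -> list[str]:
        return [d.name for d in self.dofs]

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def subject_weight(self) -> float:
        """Subject body weight in N (the BW normalisation unit)."""
        return self.subject_mass * GRAVITY

    def copy(self) -> "LowerLimbModel":
        return copy.deepcopy(self)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        seg_names = {s.name for s in self.segments}
        if len(seg_names) != len(self.segments):
            raise ValidationError("duplicate segment names")
        # joint graph must be a tree rooted at the pelvis
        children = set()
        for d in self.dofs:
            if d.parent not in seg_names or d.child not in seg_names:
                raise ValidationError(f"dof {d.name!r} references unknown segment")
            if d.child in children:
                raise ValidationError(f"segment {d.child!r} has two parents")
            children.add(d.child)
        roots = seg_names - children
        if roots != {"pelvis"}:
            raise ValidationError(f"joint graph must be a tree rooted at pelvis, roots={roots}")
        for m in self.muscles:
            for p in m.pathway:
                if p.segment not in seg_names:
                    raise ValidationError(
                        f"muscle {m.name!r} references unknown segment {p.segment!r}"
                    )
        muscle_names = set(self.muscle_names)
        by_name = {g.name: set(g.members) for g in self.groups}
        for g in self.groups:
            unknown = set(g.members) - muscle_names
            if unknown:
                raise ValidationError(f"group {g.name!r} references unknown muscles {unknown}")
        if "lower_limb" in by_name:
            for g in self.groups:
                if g.name != "lower_limb" and not set(g.members) <= by_name["lower_limb"]:
                    raise ValidationError(f"group {g.name!r} is not a subset of lower_limb")
        if {"knee_hip_biarticular", "knee_extensors", "knee_flexors"} <= by_name.keys():
            knee = by_name["knee_extensors"] | by_name["knee_flexors"]
            if not by_name["knee_hip_biarticular"] <= knee:
                raise ValidationError("knee_hip_biarticular must lie within the knee muscles")

    # -- compiled form ----------------------------------------------------
    def compile(self) -> "CompiledModel":
        return CompiledModel(self)


# ---------------------------------------------------------------------------
# Compiled (array) form and forward kinematics
# ---------------------------------------------------------------------------

class CompiledModel:
    """Array-packed view of a :class:`LowerLimbModel` for batched evaluation.

    Forward kinematics, muscle lengths, moment arms and fiber states are all
    vectorised over frames; this is what makes 10^5-iteration Monte Carlo
    runs tractable on one CPU.
    """

    def __init__(self, model: LowerLimbModel) -> None:
        model.validate()
        self.model = model
        self.seg_index = {s.name: i for i, s in enumerate(model.segments)}
        self.n_seg = len(model.segments)
        self.dof_index = {d.name: j for j, d in enumerate(model.dofs)}
        self.n_dof = len(model.dofs)
        # topological order of dofs from the pelvis outward
        order, placed = [], {"pelvis"}
        pending = list(model.dofs)
        while pending:
            progressed = False
            for d in pending:
                if d.parent in placed:
                    order.append(d)
                    placed.add(d.child)
                    pending.remove(d)
                    progressed = True
                    break
            if not progressed:  # pragma: no cover - guarded by validate()
                raise ValidationError("joint graph is not a tree")
        self.dof_order = order

        # descendants of each dof's child segment (for crossing detection)
        child_of = {d.child: d for d in model.dofs}
        parents = {d.child: d.parent for d in model.dofs}

        def distal_set(dof: JointDof) -> frozenset[str]:
            out = {dof.child}
            grew = True
            while grew:
                grew = False
                for c, p in parents.items():
                    if p in out and c not in out:
                        out.add(c)
                        grew = True
            return frozenset(out)

        self.distal_segments = {d.name: distal_set(d) for d in model.dofs}

        # path points packed into flat arrays
        pts, seg_of_pt, ptr = [], [], [0]
        for m in model.muscles:
            for p in m.pathway:
                pts.append(p.position_local)
                seg_of_pt.append(self.seg_index[p.segment])
            ptr.append(len(pts))
        self.point_local = np.asarray(pts, dtype=float)           # (P, 2)
        self.point_seg = np.asarray(seg_of_pt, dtype=int)         # (P,)
        self.muscle_ptr = np.asarray(ptr, dtype=int)              # (n_m + 1,)
        self.n_muscles = len(model.muscles)

        self.mif = np.array([m.mif for m in model.muscles])
        self.tsl = np.array([m.tsl for m in model.muscles])
        self.l_opt = np.array([m.l_opt for m in model.muscles])
        self.pen_opt = np.array([m.pen_opt for m in model.muscles])
        self._pen_height = self.l_opt * np.sin(self.pen_opt)      # constant thickness

        # per-dof crossing edge of each muscle: index of the pathway edge whose
        # endpoints lie on opposite sides of the joint, or -1 if not crossing
        self.cross_edge = np.full((self.n_muscles, self.n_dof), -1, dtype=int)
        for mi, m in enumerate(model.muscles):
            for d in model.dofs:
                j = self.dof_index[d.name]
                distal = self.distal_segments[d.name]
                sides = [p.segment in distal for p in m.pathway]
                for e in range(len(sides) - 1):
                    if sides[e] != sides[e + 1]:
                        self.cross_edge[mi, j] = self.muscle_ptr[mi] + e
                        break

    # -- forward kinematics ------------------------------------------------
    def segment_frames(
        self,
        q: np.ndarray,
        root_position: np.ndarray | None = None,
        root_angle: float | np.ndarray = 0.0,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Global pose of every segment frame for poses ``q`` of shape (F, n_dof).

        Returns ``(theta, origin)`` with shapes (F, n_seg) and (F, n_seg, 2).
        The root (pelvis) is placed at ``root_position`` with tilt
        ``root_angle``; muscle lengths are invariant to both.
        """
        q = np.atleast_2d(np.asarray(q, dtype=float))
        F = q.shape[0]
        theta = np.zeros((F, self.n_seg))
        origin = np.zeros((F, self.n_seg, 2))
        root = self.seg_index["pelvis"]
        theta[:, root] = root_angle
        if root_position is not None:
            origin[:, root, :] = np.asarray(root_position, dtype=float)
        for d in self.dof_order:
            pi, ci = self.seg_index[d.parent], self.seg_index[d.child]
            j = self.dof_index[d.name]
            tp = theta[:, pi]
            c, s = np.cos(tp), np.sin(tp)
            lx, ly = d.location_in_parent
            origin[:, ci, 0] = origin[:, pi, 0] + c * lx - s * ly
            origin[:, ci, 1] = origin[:, pi, 1] + s * lx + c * ly
            theta[:, ci] = tp + d.sigma * q[:, j]
        return theta, origin

    def point_positions(self, q: np.ndarray, **root) -> np.ndarray:
        """Global positions of all path points, shape (F, P, 2)."""
        theta, origin = self.segment_frames(q, **root)
        return self.point_positions_from_frames(theta, origin)

    def point_positions_from_frames(
        self, theta: np.ndarray, origin: np.ndarray
    ) -> np.ndarray:
        """Path-point positions given precomputed segment frames."""
        th = theta[:, self.point_seg]                 # (F, P)
        c, s = np.cos(th), np.sin(th)
        px, py = self.point_local[:, 0], self.point_local[:, 1]
        out = np.empty((theta.shape[0], len(self.point_seg), 2))
        out[..., 0] = origin[:, self.point_seg, 0] + c * px - s * py
        out[..., 1] = origin[:, self.point_seg, 1] + s * px + c * py
        return out

    def lengths(self, q: np.ndarray) -> np.ndarray:
        """Muscle-tendon lengths for poses ``q`` (F, n_dof) -> (F, n_m)."""
        q = np.atleast_2d(np.asarray(q, dtype=float))
        pos = self.point_positions(q)
        d = np.diff(pos, axis=1)                      # (F, P-1, 2)
        seg_len = np.hypot(d[..., 0], d[..., 1])
        # edge e belongs to muscle m iff ptr[m] <= e < ptr[m+1] - 1
        F = q.shape[0]
        L = np.empty((F, self.n_muscles))
        for m in range(self.n_muscles):
            a, b = self.muscle_ptr[m], self.muscle_ptr[m + 1] - 1
            L[:, m] = seg_len[:, a:b].sum(axis=1)
        return L

    def moment_arms(self, q: np.ndarray, step: float = MOMENT_ARM_STEP) -> np.ndarray:
        """Tendon-excursion moment arms r = -dL/dq, shape (F, n_m, n_dof)."""
        q = np.atleast_2d(np.asarray(q, dtype=float))
        F = q.shape[0]
        R = np.empty((F, self.n_muscles, self.n_dof))
        for j in range(self.n_dof):
            dq = np.zeros(self.n_dof)
            dq[j] = step
            R[:, :, j] = -(self.lengths(q + dq) - self.lengths(q - dq)) / (2 * step)
        return R

    # -- muscle mechanics (batched) ----------------------------------------
    def fiber_arrays(
        self, L: np.ndarray, V: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Rigid-tendon fiber state from MTU lengths/velocities.

        Returns (lnorm, vnorm, cos_pen, clamped) each of shape (F, n_m).
        """
        proj = L - self.tsl
        clamped = proj <= 0
        w = self._pen_height
        l_fib = np.sqrt(np.clip(proj, 0.0, None) ** 2 + w**2)
        l_min = 0.01 * self.l_opt
        l_fib = np.maximum(l_fib, l_min)
        cos_pen = np.clip(np.clip(proj, 0.0, None) / l_fib, 0.0, 1.0)
        lnorm = l_fib / self.l_opt
        if V is None:
            vnorm = np.zeros_like(L)
        else:
            vnorm = (V * cos_pen) / (VMAX_FACTOR * self.l_opt)
        return lnorm, vnorm, cos_pen, clamped


# ---------------------------------------------------------------------------
# Hill curves (one explicit, documented set; normalised so that
# fl_active(1)=1, fl_passive(1)=0, fv(0)=1)
# ---------------------------------------------------------------------------

#: Maximum fiber shortening velocity in optimal fiber lengths per second.
VMAX_FACTOR = 10.0
ACTIVE_FL_WIDTH = 0.45       # Gaussian width of the active force-length curve
PASSIVE_STRAIN = 0.6         # strain at which the passive curve reaches 1
PASSIVE_SHAPE = 4.0          # exponential shape factor
FV_AF = 0.25                 # Hill constant (concentric curvature)
FV_FLEN = 1.8                # eccentric force plateau


def fl_active(lnorm):
    """Active force-length multiplier: Gaussian around the optimal length."""
    lnorm = np.asarray(lnorm, dtype=float)
    return np.exp(-((lnorm - 1.0) ** 2) / ACTIVE_FL_WIDTH)


def fl_passive(lnorm):
    """Passive force-length multiplier.

    Exponential toe region above the optimal length reaching 1 at strain
    ``PASSIVE_STRAIN``, continued linearly (C1) beyond it, following the
    usual force-length curve construction of equilibrium muscle models:
    extreme fiber stretches met during Monte Carlo sampling must not
    produce unbounded exponential forces.
    """
    lnorm = np.asarray(lnorm, dtype=float)
    e = np.clip(lnorm - 1.0, 0.0, None) / PASSIVE_STRAIN
    toe = np.expm1(PASSIVE_SHAPE * np.minimum(e, 1.0)) / math.expm1(PASSIVE_SHAPE)
    slope = (PASSIVE_SHAPE / PASSIVE_STRAIN) * math.exp(PASSIVE_SHAPE) / math.expm1(
        PASSIVE_SHAPE
    )
    beyond = 1.0 + slope * (lnorm - 1.0 - PASSIVE_STRAIN)
    return np.where(e <= 1.0, toe, beyond)


def fv(vnorm):
    """Force-velocity multiplier; vnorm < 0 is shortening, fv(0) = 1."""
    v = np.asarray(vnorm, dtype=float)
    conc = np.clip((1.0 + v) / (1.0 - v / FV_AF), 0.0, None)
    ecc = 1.0 + (FV_FLEN - 1.0) * v / (v + FV_AF)
    out = np.where(v < 0, conc, ecc)
    return np.where(v <= -1.0, 0.0, out)


# ---------------------------------------------------------------------------
# Scalar convenience API (single muscle / single pose)
# ---------------------------------------------------------------------------

@dataclass
class FiberState:
    lnorm: float
    vnorm: float
    pennation: float       # rad, current
    clamped: bool = False


def mtu_length(model: LowerLimbModel | CompiledModel, muscle: str, pose) -> float:
    """Muscle-tendon length (m) of ``muscle`` at joint angles ``pose``.

    ``pose`` is a mapping dof-name -> rad or an array ordered like
    ``model.dof_names``.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    try:
        mi = cm.model.muscle_names.index(muscle)
    except ValueError:
        raise ModelLookupError(f"unknown muscle {muscle!r}") from None
    q = _pose_vector(cm, pose)
    return float(cm.lengths(q[None, :])[0, mi])


def moment_arm(
    model: LowerLimbModel | CompiledModel,
    muscle: str,
    pose,
    dof: str,
    step: float = MOMENT_ARM_STEP,
) -> float:
    """Signed tendon-excursion moment arm (m) about ``dof`` at ``pose``.

    Positive moment arm: positive muscle force produces positive (flexion)
    moment.  Central difference with step ``step``; if the step straddles
    the joint-range boundary a one-sided difference is used with a warning.
    """
    cm = model if isinstance(model, CompiledModel) else model.compile()
    try:
        mi = cm.model.muscle_names.index(muscle)
    except ValueError:
        raise ModelLookupError(f"unknown muscle {muscle!r}") from None
    j = cm.dof_index[dof] if dof in cm.dof_index else None
    if j is None:
        raise ModelLookupError(f"unknown dof {dof!r}")
    q = _pose_vector(cm, pose)
    lo, hi = cm.model.dofs[j].angle_range
    dq = np.zeros(cm.n_dof)
    dq[j] = step
    if q[j] - step < lo or q[j] + step > hi:
        warnings.warn(
            f"moment_arm: step straddles the range of {dof!r}; using one-sided difference",
            stacklevel=2,
        )
        if q[j] - step < lo:
            Lp = cm.lengths((q + dq)[None, :])[0, mi]
            L0 = cm.lengths(q[None, :])[0, mi]
            return float(-(Lp - L0) / step)
        Lm = cm.lengths((q - dq)[None, :])[0, mi]
        L0 = cm.lengths(q[None, :])[0, mi]
        return float(-(L0 - Lm) / step)
    Lp = cm.lengths((q + dq)[None, :])[0, mi]
    Lm = cm.lengths((q - dq)[None, :])[0, mi]
    return float(-(Lp - Lm) / (2 * step))


def fiber_state(
    muscle: MuscleTendonUnit, mtu_length: float, mtu_velocity: float = 0.0
) -> FiberState:
    """Rigid-tendon fiber kinematics of a single muscle.

    The fiber and tendon satisfy ``l_fib * cos(pen) = L - tsl`` with the
    constant-thickness pennation rule ``l_fib * sin(pen) = l_opt * sin(pen_opt)``.
    When ``L <= tsl`` the fiber is clamped at its minimum length and the
    returned state is flagged.
    """
    proj = mtu_length - muscle.tsl
    w = muscle.l_opt * math.sin(muscle.pen_opt)
    clamped = proj <= 0
    l_fib = math.sqrt(max(proj, 0.0) ** 2 + w**2)
    l_fib = max(l_fib, 0.01 * muscle.l_opt)
    cos_pen = min(max(max(proj, 0.0) / l_fib, 0.0), 1.0)
    pen = math.acos(cos_pen) if w > 0 or clamped else 0.0
    if w == 0 and not clamped:
        pen = 0.0
    vnorm = (mtu_velocity * cos_pen) / (VMAX_FACTOR * muscle.l_opt)
    return FiberState(l_fib / muscle.l_opt, vnorm, pen, bool(clamped))


def muscle_force_scalar(
    muscle: MuscleTendonUnit,
    activation: float,
    state: FiberState,
    include_flv: bool = True,
) -> float:
    """Force along the tendon (N) for a given activation and fiber state.

    With ``include_flv`` the full Hill structure is used,
    ``mif * (a * fl(l) * fv(v) + fpe(l)) * cos(pen)``; without it the muscle
    is an ideal force generator, ``mif * a * cos(pen)``.
    """
    if not 0.0 <= activation <= 1.0:
        raise ValidationError("activation must lie in [0, 1]")
    ca = math.cos(state.pennation)
    if not include_flv:
        return muscle.mif * activation * ca
    active = activation * float(fl_active(state.lnorm)) * float(fv(state.vnorm))
    passive = float(fl_passive(state.lnorm))
    return muscle.mif * (active + passive) * ca


def _pose_vector(cm: CompiledModel, pose) -> np.ndarray:
    if isinstance(pose, Mapping):
        return np.array([float(pose.get(n, 0.0)) for n in cm.model.dof_names])
    q = np.asarray(pose, dtype=float)
    if q.shape != (cm.n_dof,):
        raise ValidationError(f"pose must have {cm.n_dof} angles")
    return q


# ---------------------------------------------------------------------------
# Squat kinematic closure
# ---------------------------------------------------------------------------

def squat_closure_pose(model: LowerLimbModel, knee_flexion: float) -> dict[str, float]:
    """Hip/ankle angles that keep the hip over the ankle with a flat foot.

    For knee flexion ``k`` the shank leans forward by
    ``alpha = atan2(Lt sin k, Ls + Lt cos k)`` so that the hip stays
    vertically above the ankle; the ankle dorsiflexes by ``alpha`` (foot
    flat) and the hip flexes by ``k - alpha`` (pelvis upright).  This is the
    simplest kinematic closure that keeps the centre of mass over the foot
    during a body-weight squat.
    """
    lt = model.segment("thigh").length
    ls = model.segment("shank").length
    alpha = math.atan2(lt * math.sin(knee_flexion), ls + lt * math.cos(knee_flexion))
    return {
        "hip_flexion": knee_flexion - alpha,
        "knee_flexion": knee_flexion,
        "ankle_flexion": alpha,
    }


#: Reference pose used to anchor optimal fiber lengths / tendon slack
#: lengths (mid-depth squat, knee at 45 deg with the standard closure).
TSL_REFERENCE_KNEE_FLEXION = math.radians(45.0)


def reference_pose(model: LowerLimbModel) -> dict[str, float]:
    return squat_closure_pose(model, TSL_REFERENCE_KNEE_FLEXION)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

REQUIRED_LANDMARKS = ("pelvis_width", "femur_length", "tibia_length")

_SEGMENT_LANDMARK = {
    "pelvis": "pelvis_width",
    "thigh": "femur_length",
    "shank": "tibia_length",
}


def scale_model(
    generic: LowerLimbModel,
    landmark_distances: Mapping[str, float],
    subject_mass: float,
) -> LowerLimbModel:
    """Scale the generic model to a subject's landmark distances and mass.

    Segment lengths (and with them joint locations, COM positions and
    path-point coordinates) scale by the subject/generic distance ratio of
    the matching landmark pair; the foot uses the mean of the femur and
    tibia factors.  Masses scale uniformly so the model total matches
    ``subject_mass``.  Optimal fiber length and tendon slack length each
    scale by the ratio of scaled to generic total MTU length in the
    reference pose (which preserves their ratio); maximum isometric forces
    are copied unchanged from the generic model.
    """
    for key in REQUIRED_LANDMARKS:
        if key not in landmark_distances:
            raise ConfigurationError(f"missing landmark pair {key!r}")
        if landmark_distances[key] <= 0:
            raise ValidationError(f"landmark distance {key!r} must be > 0")
    generic.validate()

    factors = {}
    for seg, key in _SEGMENT_LANDMARK.items():
        generic_len = generic.segment(seg).length
        factors[seg] = landmark_distances[key] / generic_len
    factors["foot"] = 0.5 * (factors["thigh"] + factors["shank"])

    mass_ratio = subject_mass / generic.subject_mass
    generic_compiled = generic.compile()
    q_ref = _pose_vector(generic_compiled, reference_pose(generic))
    L_generic = generic_compiled.lengths(q_ref[None, :])[0]

    scaled = generic.copy()
    for s in scaled.segments:
        f = factors.get(s.name, 1.0)
        s.length *= f
        s.com_local = s.com_local * f
        s.mass *= mass_ratio
        s.inertia_zz *= mass_ratio * f * f
    for d in scaled.dofs:
        d.location_in_parent = d.location_in_parent * factors.get(d.parent, 1.0)
    for m in scaled.muscles:
        for p in m.pathway:
            p.position_local = p.position_local * factors.get(p.segment, 1.0)
    scaled.subject_mass = subject_mass
    mean_f = float(np.mean(list(factors.values())))
    scaled.subject_height = generic.subject_height * mean_f

    scaled_compiled = scaled.compile()
    q_ref_s = _pose_vector(scaled_compiled, reference_pose(scaled))
    L_scaled = scaled_compiled.lengths(q_ref_s[None, :])[0]
    for i, m in enumerate(scaled.muscles):
        f_mtu = L_scaled[i] / L_generic[i]
        m.l_opt *= f_mtu
        m.tsl *= f_mtu
        # mif deliberately untouched
    scaled.provenance = "baseline"
    return scaled


# ---------------------------------------------------------------------------
# Model definition files (versioned YAML schema)
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def load_model(source) -> LowerLimbModel:
    """Load a model from a YAML path, file object, or already-parsed dict.

    Muscles may declare ``tsl: auto``, in which case the tendon slack length
    is set so the fiber sits at its optimal length in the mid-squat
    reference pose: ``tsl = L_ref - l_opt * cos(pen_opt)``.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ParseError("model file does not contain a mapping")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ConfigurationError(
            f"unsupported model schema_version {doc.get('schema_version')!r}"
        )
    try:
        segments = [
            BodySegment(
                name=s["name"],
                mass=float(s["mass"]),
                com_local=s["com"],
                inertia_zz=float(s.get("inertia_zz", 0.0)),
                length=float(s["length"]),
                proximal_joint=s.get("proximal_joint"),
                distal_joint=s.get("distal_joint"),
            )
            for s in doc["segments"]
        ]
        dofs = [
            JointDof(
                name=d["name"],
                parent=d["parent"],
                child=d["child"],
                location_in_parent=d["location_in_parent"],
                sigma=float(d.get("sigma", 1.0)),
                angle_range=tuple(math.radians(x) for x in d.get("range_deg", (-180, 180))),
            )
            for d in doc["dofs"]
        ]
        muscles = []
        auto_tsl: list[str] = []
        for m in doc["muscles"]:
            pathway = [
                PathPoint(p["segment"], p["position"], p["role"]) for p in m["path"]
            ]
            tsl_raw = m.get("tsl", "auto")
            is_auto = isinstance(tsl_raw, str) and tsl_raw == "auto"
            muscles.append(
                MuscleTendonUnit(
                    name=m["name"],
                    mif=float(m["mif"]),
                    tsl=1.0 if is_auto else float(tsl_raw),  # placeholder if auto
                    pen_opt=math.radians(float(m.get("pen_opt_deg", 0.0))),
                    l_opt=float(m["l_opt"]),
                    pathway=pathway,
                )
            )
            if is_auto:
                auto_tsl.append(m["name"])
        groups = [
            MuscleGroup(name=k, members=tuple(v)) for k, v in doc.get("groups", {}).items()
        ]
        model = LowerLimbModel(
            segments=segments,
            dofs=dofs,
            muscles=muscles,
            groups=groups,
            subject_mass=float(doc["subject"]["mass"]),
            subject_height=float(doc["subject"]["height"]),
            name=doc.get("name", "model"),
        )
    except KeyError as exc:
        raise ParseError(f"model file missing required key {exc}") from exc
    model.validate()
    if auto_tsl:
        cm = model.compile()
        q_ref = _pose_vector(cm, reference_pose(model))
        L_ref = cm.lengths(q_ref[None, :])[0]
        for name in auto_tsl:
            i = model.muscle_names.index(name)
            m = model.muscles[i]
            tsl = L_ref[i] - m.l_opt * math.cos(m.pen_opt)
            if tsl <= 0:
                raise ConfigurationError(
                    f"muscle {name!r}: auto tendon slack length is non-positive; "
                    "shorten l_opt or adjust the pathway"
                )
            m.tsl = tsl
    model.validate()
    return model


def save_model(model: LowerLimbModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": model.name,
        "subject": {"mass": model.subject_mass, "height": model.subject_height},
        "segments": [
            {
                "name": s.name,
                "mass": float(s.mass),
                "com": [float(x) for x in s.com_local],
                "inertia_zz": float(s.inertia_zz),
                "length": float(s.length),
                "proximal_joint": s.proximal_joint,
                "distal_joint": s.distal_joint,
            }
            for s in model.segments
        ],
        "dofs": [
            {
                "name": d.name,
                "parent": d.parent,
                "child": d.child,
                "location_in_parent": [float(x) for x in d.location_in_parent],
                "sigma": float(d.sigma),
                "range_deg": [math.degrees(a) for a in d.angle_range],
            }
            for d in model.dofs
        ],
        "muscles": [
            {
                "name": m.name,
                "mif": float(m.mif),
                "tsl": float(m.tsl),
                "pen_opt_deg": math.degrees(m.pen_opt),
                "l_opt": float(m.l_opt),
                "path": [
                    {
                        "segment": p.segment,
                        "position": [float(x) for x in p.position_local],
                        "role": p.role,
                    }
                    for p in m.pathway
                ],
            }
            for m in model.muscles
        ],
        "groups": {g.name: list(g.members) for g in model.groups},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_model() -> LowerLimbModel:
    """The packaged generic model: 75 kg / 1.75 m, 14 MTUs, 3 sagittal DoFs."""
    ref = resources.files("squatmc").joinpath("data/default_model.yaml")
    with ref.open("r") as fh:
        return load_model(fh)
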