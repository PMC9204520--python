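"""Parameter distributions and Monte Carlo orchestration.

Two designs mirror the study layout: a *general* Monte Carlo perturbs all
five parameter classes (MIF, TSL, PEN, OIP, VIA) of a muscle group
simultaneously (default 2000 iterations), while *individual* Monte Carlos
perturb a single class at a time (default 500 iterations each) to isolate
its contribution.  Scalar parameters are drawn from Gaussians specified by
a coefficient of variation; pathway points get an isotropic per-axis
Gaussian with a 5 mm standard deviation.  Draws are truncated to physical
bounds by resampling, and every iteration derives its own RNG stream from
``(seed, iteration)`` so runs replay exactly, serial or parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model_core import PARAMETER_CLASSES, LowerLimbModel
from .muscle_solver import SimulationResult, simulate_trial

#: Default per-axis standard deviation for origin/insertion/via points (m).
POINT_SD_DEFAULT = 0.005
#: Pennation angles are truncated to [0, 80 deg].
PEN_MAX = math.radians(80.0)
#: Consecutive rejected draws tolerated per parameter before erroring.
MAX_REJECTIONS = 100


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass
class ParameterDistributionSpec:
    """Gaussian variability per (muscle, parameter).

    ``cv`` holds coefficients of variation for the scalar classes
    (MIF/TSL/PEN); missing entries fall back to the unweighted mean CV of
    that parameter across muscles.  ``point_sd`` is the absolute per-axis
    SD (m) for OIP/VIA coordinates; ``point_mode`` selects whether the SD
    applies per axis (default) or to the displacement magnitude.
    """

    cv: dict[tuple[str, str], float] = field(default_factory=dict)
    point_sd: float = POINT_SD_DEFAULT
    point_mode: str = "per_axis"        # or "magnitude"
    provenance: dict[tuple[str, str], list[tuple[str, float, int]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.point_mode not in ("per_axis", "magnitude"):
            raise ValidationError(f"unknown point_mode {self.point_mode!r}")
        for key, v in self.cv.items():
            if v < 0:
                raise ValidationError(f"negative CV for {key}")

    def mean_cv(self, parameter: str) -> float:
        vals = [v for (m, p), v in self.cv.items() if p == parameter]
        if not vals:
            return 0.0
        return float(np.mean(vals))

    def get_cv(self, muscle: str, parameter: str) -> float:
        """Stored CV, or the stated fallback (mean over other muscles)."""
        if (muscle, parameter) in self.cv:
            return self.cv[(muscle, parameter)]
        return self.mean_cv(parameter)


def build_distributions(literature_table) -> ParameterDistributionSpec:
    """Aggregate a literature CV table into a distribution spec.

    ``literature_table`` is a DataFrame (or iterable of mappings) with
    columns ``muscle, parameter, cv, n_subjects`` (optionally ``source``).
    When several sources report the same (muscle, parameter), the CVs are
    averaged weighted by the number of studied subjects.
    """
    if isinstance(literature_table, pd.DataFrame):
        df = literature_table.copy()
    else:
        df = pd.DataFrame(list(literature_table))
    if df.empty:
        raise ValidationError("literature table is empty")
    required = {"muscle", "parameter", "cv", "n_subjects"}
    if not required <= set(df.columns):
        raise ValidationError(f"literature table needs columns {sorted(required)}")
    if (df["cv"] < 0).any():
        raise ValidationError("negative CV in literature table")
    if (df["n_subjects"] < 1).any():
        raise ValidationError("n_subjects must be >= 1")
    bad = set(df["parameter"]) - {"MIF", "TSL", "PEN"}
    if bad:
        raise ValidationError(f"unknown scalar parameter classes {bad}")
    spec = ParameterDistributionSpec()
    for (muscle, parameter), rows in df.groupby(["muscle", "parameter"]):
        w = rows["n_subjects"].to_numpy(dtype=float)
        spec.cv[(muscle, parameter)] = float(
            np.average(rows["cv"].to_numpy(dtype=float), weights=w)
        )
        spec.provenance[(muscle, parameter)] = [
            (str(r.get("source", "")), float(r["cv"]), int(r["n_subjects"]))
            for _, r in rows.iterrows()
        ]
    return spec


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

#: Study-layout defaults (iterations per Monte Carlo).
N_GENERAL_DEFAULT = 2000
N_INDIVIDUAL_DEFAULT = 500


@dataclass
class MCDesign:
    """One Monte Carlo run: which parameters vary, for which muscle group."""

    kind: str                           # "general" | "individual"
    muscle_group: str = "lower_limb"
    parameter: str | None = None        # required for individual designs
    n_iterations: int = 0
    seed: int = 0
    extra_fraction: float = 0.10        # convergence probe: +10% iterations
    threshold: float = 0.01             # .. must change band width < 1%

    def __post_init__(self) -> None:
        if self.kind not in ("general", "individual"):
            raise ValidationError(f"unknown MC kind {self.kind!r}")
        if self.kind == "individual":
            if self.parameter not in PARAMETER_CLASSES:
                raise ValidationError(
                    "individual designs must name one parameter class "
                    f"from {PARAMETER_CLASSES}"
                )
        elif self.parameter is not None:
            raise ValidationError("general designs perturb all parameters; drop 'parameter'")
        if self.n_iterations == 0:
            self.n_iterations = (
                N_GENERAL_DEFAULT if self.kind == "general" else N_INDIVIDUAL_DEFAULT
            )
        if self.n_iterations <= 0:
            raise ValidationError("n_iterations must be > 0")

    @property
    def perturbed_parameters(self) -> tuple[str, ...]:
        return PARAMETER_CLASSES if self.kind == "general" else (self.parameter,)

    @property
    def label(self) -> str:
        p = "all" if self.kind == "general" else self.parameter
        return f"{self.kind}:{self.muscle_group}:{p}"


def full_design_iterations(
    n_subjects: int = 6,
    n_groups: int = 7,
    n_general: int = N_GENERAL_DEFAULT,
    n_parameters: int = len(PARAMETER_CLASSES),
    n_individual: int = N_INDIVIDUAL_DEFAULT,
) -> int:
    """Planned iteration total of the full study design.

    Per subject and muscle group: one general Monte Carlo plus one
    individual Monte Carlo per parameter class.
    """
    return n_subjects * n_groups * (n_general + n_parameters * n_individual)


def group_contribution_iterations(
    n_subjects: int = 6,
    n_groups: int = 6,
    n_general: int = N_GENERAL_DEFAULT,
) -> int:
    """Simulations behind the muscle-group contribution analysis.

    The group comparison uses the general Monte Carlos of the six
    sub-groups (the all-lower-limb run is the normalisation reference).
    """
    return n_subjects * n_groups * n_general


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _draw_truncated(rng, mean, sd, lo=None, hi=None, what=""):
    if sd == 0:
        return float(mean)
    for _ in range(MAX_REJECTIONS):
        x = rng.normal(mean, sd)
        if (lo is None or x > lo) and (hi is None or x <= hi):
            return float(x)
    raise ValidationError(
        f"{what}: >{MAX_REJECTIONS} consecutive draws outside physical bounds"
    )


def iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    """Counter-style RNG stream for one Monte Carlo iteration."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def sample_perturbed_model(
    baseline: LowerLimbModel,
    spec: ParameterDistributionSpec,
    design: MCDesign,
    iteration: int,
) -> tuple[LowerLimbModel, dict[str, float]]:
    """Draw one perturbed model for ``iteration`` of ``design``.

    Only members of the design's muscle group are touched, and only the
    design's parameter classes.  Returns the perturbed model plus a flat
    record of the sampled values (``"muscle/PARAM[...]"`` -> value).
    Deterministic given (design.seed, iteration).
    """
    group = baseline.group(design.muscle_group)
    rng = iteration_rng(design.seed, iteration)
    model = baseline.copy()
    model.provenance = f"perturbed:{design.label}:{iteration}"
    params = design.perturbed_parameters
    draws: dict[str, float] = {}
    for name in group.members:
        m = model.muscle(name)
        if "MIF" in params:
            cv = spec.get_cv(name, "MIF")
            m.mif = _draw_truncated(rng, m.mif, cv * m.mif, lo=0.0, what=f"{name}/MIF")
            draws[f"{name}/MIF"] = m.mif
        if "TSL" in params:
            cv = spec.get_cv(name, "TSL")
            m.tsl = _draw_truncated(rng, m.tsl, cv * m.tsl, lo=0.0, what=f"{name}/TSL")
            draws[f"{name}/TSL"] = m.tsl
        if "PEN" in params:
            cv = spec.get_cv(name, "PEN")
            m.pen_opt = _draw_truncated(
                rng, m.pen_opt, cv * m.pen_opt, lo=-1e-12, hi=PEN_MAX, what=f"{name}/PEN"
            )
            m.pen_opt = max(m.pen_opt, 0.0)
            draws[f"{name}/PEN"] = m.pen_opt
        for cls, roles in (("OIP", ("origin", "insertion")), ("VIA", ("via",))):
            if cls not in params:
                continue
            for k, p in enumerate(m.pathway):
                if p.role not in roles:
                    continue
                if spec.point_mode == "per_axis":
                    dx = rng.normal(0.0, spec.point_sd, size=2)
                else:  # magnitude mode: SD on the displacement norm
                    r = abs(rng.normal(0.0, spec.point_sd))
                    phi = rng.uniform(0.0, 2 * math.pi)
                    dx = r * np.array([math.cos(phi), math.sin(phi)])
                p.position_local = p.position_local + dx
                draws[f"{name}/{cls}[{k}]/dx"] = float(dx[0])
                draws[f"{name}/{cls}[{k}]/dy"] = float(dx[1])
    return model, draws


# ---------------------------------------------------------------------------
# Monte Carlo execution
# ---------------------------------------------------------------------------

@dataclass
class MCResultSet:
    """Stacked per-iteration outputs of one Monte Carlo design."""

    design: MCDesign
    kcf_bw: np.ndarray                     # (n_ok, F)
    iteration_ids: np.ndarray              # (n_ok,) original iteration index
    draws: list[dict[str, float]]
    baseline: SimulationResult
    time: np.ndarray
    activations: np.ndarray | None = None  # (n_ok, F, n_m) if kept
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return int(self.kcf_bw.shape[0])

    @property
    def n_planned(self) -> int:
        return self.design.n_iterations

    def replay_iteration(
        self, baseline: LowerLimbModel, spec: ParameterDistributionSpec, iteration: int
    ) -> tuple[LowerLimbModel, dict[str, float]]:
        """Re-derive the exact perturbed model of one stored iteration."""
        return sample_perturbed_model(baseline, spec, self.design, iteration)


def run_mc(
    baseline: LowerLimbModel,
    trial,
    spec: ParameterDistributionSpec,
    design: MCDesign,
    include_flv: bool = True,
    quasi_static: bool = True,
    keep_activations: bool = False,
    progress: bool = False,
) -> MCResultSet:
    """Execute one Monte Carlo design over a squat trial.

    The baseline model is simulated once for reference; each iteration then
    draws a perturbed model and re-runs the full pipeline.  Per-iteration
    simulation failures are recorded (iteration id + message) and skipped,
    never fatal; the failure count is part of the result.
    """
    base_cm = baseline.compile()
    base_result = simulate_trial(
        trial, base_cm, include_flv=include_flv, quasi_static=quasi_static
    )
    kcf, ids, draws_all, acts = [], [], [], []
    failures: list[tuple[int, str]] = []
    iterator = range(design.n_iterations)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc=design.label)
        except ImportError:
            pass
    for it in iterator:
        try:
            model, draws = sample_perturbed_model(baseline, spec, design, it)
            result = simulate_trial(
                trial, model, include_flv=include_flv, quasi_static=quasi_static
            )
        except Exception as exc:  # noqa: BLE001 - flag-and-continue policy
            failures.append((it, str(exc)))
            continue
        kcf.append(result.kcf_bw)
        ids.append(it)
        draws_all.append(draws)
        if keep_activations:
            acts.append(result.activations)
    if not kcf:
        raise ValidationError(
            f"all {design.n_iterations} iterations failed; first error: {failures[0][1]}"
        )
    return MCResultSet(
        design=design,
        kcf_bw=np.asarray(kcf),
        iteration_ids=np.asarray(ids, dtype=int),
        draws=draws_all,
        baseline=base_result,
        time=np.asarray(trial.time, dtype=float),
        activations=np.asarray(acts) if keep_activations else None,
        failures=failures,
    )


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------

def check_convergence(
    results,
    extra_fraction: float = 0.10,
    threshold: float = 0.01,
    probe_n: int | None = None,
    lo: float = 5.0,
    hi: float = 95.0,
) -> tuple[bool, dict]:
    """Post-hoc Monte Carlo convergence check.

    Converged iff adding ``extra_fraction`` more iterations changes the
    time-averaged ``lo``-``hi`` percentile band width of the outcome KCF by
    less than ``threshold`` (relative).  ``results`` is an MCResultSet or a
    raw (n_iterations, n_frames) array.  Returns (converged, diagnostics
    with both band widths and the probe sizes).
    """
    kcf = results.kcf_bw if isinstance(results, MCResultSet) else np.atleast_2d(results)
    total = kcf.shape[0]
    if probe_n is None:
        probe_n = int(total / (1.0 + extra_fraction))
    n_extra = int(math.ceil((1.0 + extra_fraction) * probe_n))
    if total < n_extra or probe_n < 1:
        raise ValidationError(
            f"convergence probe at N={probe_n} needs {n_extra} iterations, have {total}"
        )

    def mean_width(n: int) -> float:
        p = np.percentile(kcf[:n], [lo, hi], axis=0)
        return float(np.mean(p[1] - p[0]))

    w_n, w_extra = mean_width(probe_n), mean_width(n_extra)
    if w_n == 0.0:
        converged = w_extra == 0.0
        change = 0.0 if converged else math.inf
    else:
        change = abs(w_extra - w_n) / w_n
        converged = change < threshold
    return converged, {
        "probe_n": probe_n,
        "probe_n_extra": n_extra,
        "band_width_at_n": w_n,
        "band_width_at_n_extra": w_extra,
        "relative_change": change,
        "threshold": threshold,
    }
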