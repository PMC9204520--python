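"""Percentile bands, contribution factors, error metrics, model selection.

All band and contribution arithmetic happens on a common 101-point
percent-squat-cycle grid (resampled from the trial's time grid using the
cycle events).  Percentiles use linear interpolation between order
statistics.  Contribution factors are percent ratios of 5th-95th percentile
band widths (individual or group Monte Carlo over the all-lower-limb
general Monte Carlo); overlapping muscle groups are reported as-is and are
not forced to sum to 100% because parameter interactions exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .probabilistic import MCResultSet

#: Number of percent-cycle samples used for band/contribution arithmetic.
CYCLE_POINTS = 101
#: Minimum successful iterations for a meaningful percentile band.
MIN_ITERATIONS = 20


@dataclass
class PercentileBand:
    """Pointwise lower/upper percentile envelope of a scalar output."""

    lower: np.ndarray
    upper: np.ndarray
    lo: float = 5.0
    hi: float = 95.0

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.upper < self.lower - 1e-12):
            raise ValidationError("band upper percentile below lower percentile")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.width))


@dataclass
class ContributionProfile:
    """Per-frame contribution factor (%) of a parameter class or group."""

    values: np.ndarray                  # (F,), NaN where reference width ~ 0
    normalization: str = "general_lower_limb_band"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.nanmin(self.values, initial=0.0) < -1e-9:
            raise ValidationError("contribution factors must be >= 0")

    def at(self, frame: int) -> float:
        return float(self.values[frame])


@dataclass
class ErrorTrace:
    """Predicted-minus-measured KCF error over the cycle (BW)."""

    error: np.ndarray                   # (F,) predicted - measured
    percent_error: np.ndarray           # (F,), NaN where measured <= 0
    rmse: float                         # cycle RMSE, BW

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValidationError("RMSE must be >= 0")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_to_cycle(
    trace: np.ndarray,
    cycle_events: tuple[int, int, int],
    n_points: int = CYCLE_POINTS,
) -> np.ndarray:
    """Resample a frame-indexed trace onto 0-100% of the squat cycle.

    The cycle spans start to end event; linear interpolation on the frame
    index.  Works on (F,) traces or batches (..., F).
    """
    trace = np.asarray(trace, dtype=float)
    s, _, e = cycle_events
    src = np.arange(trace.shape[-1], dtype=float)
    dst = np.linspace(float(s), float(e), n_points)
    if trace.ndim == 1:
        return np.interp(dst, src, trace)
    flat = trace.reshape(-1, trace.shape[-1])
    out = np.empty((flat.shape[0], n_points))
    for i in range(flat.shape[0]):
        out[i] = np.interp(dst, src, flat[i])
    return out.reshape(trace.shape[:-1] + (n_points,))


# ---------------------------------------------------------------------------
# Bands and contributions
# ---------------------------------------------------------------------------

def percentile_band(
    results,
    lo: float = 5.0,
    hi: float = 95.0,
    min_iterations: int = MIN_ITERATIONS,
) -> PercentileBand:
    """Empirical pointwise percentile band over Monte Carlo iterations.

    ``results`` is an MCResultSet (its KCF traces are used) or any
    (n_iterations, F) array.  Percentiles interpolate linearly between
    order statistics (numpy's default estimator).
    """
    data = results.kcf_bw if isinstance(results, MCResultSet) else np.atleast_2d(results)
    n = data.shape[0]
    if n < min_iterations:
        raise ValidationError(
            f"need >= {min_iterations} successful iterations for a band, have {n}"
        )
    p = np.percentile(data, [lo, hi], axis=0)
    return PercentileBand(lower=p[0], upper=p[1], lo=lo, hi=hi)


def parameter_contribution(
    individual_band: PercentileBand,
    general_band: PercentileBand,
    width_tol: float = 1e-9,
) -> ContributionProfile:
    """Contribution factor of one parameter class (% of the general band).

    Pointwise ``100 * width_individual / width_general``; frames where the
    general band width is below ``width_tol`` are masked to NaN.
    """
    wi, wg = individual_band.width, general_band.width
    if wi.shape != wg.shape:
        raise ValidationError("bands are not on a common frame grid")
    out = np.full_like(wg, np.nan)
    ok = wg > width_tol
    out[ok] = 100.0 * wi[ok] / wg[ok]
    return ContributionProfile(values=out)


def group_contribution(
    group_bands: dict[str, PercentileBand],
    reference: PercentileBand,
    width_tol: float = 1e-9,
) -> dict[str, ContributionProfile]:
    """Contribution of each muscle group against the all-lower-limb band."""
    if not group_bands:
        raise ValidationError("no group bands supplied")
    return {
        name: parameter_contribution(band, reference, width_tol)
        for name, band in group_bands.items()
    }


# ---------------------------------------------------------------------------
# Error metrics and model selection
# ---------------------------------------------------------------------------

def kcf_error(predicted: np.ndarray, measured: np.ndarray) -> ErrorTrace:
    """Signed error, percent error and cycle RMSE between KCF traces (BW)."""
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if predicted.shape != measured.shape:
        raise ValidationError("predicted and measured traces are not on a common grid")
    err = predicted - measured
    pct = np.full_like(err, np.nan)
    ok = measured > 0
    pct[ok] = 100.0 * err[ok] / measured[ok]
    rmse = float(np.sqrt(np.mean(err**2)))
    return ErrorTrace(error=err, percent_error=pct, rmse=rmse)


@dataclass
class BestModelSelection:
    iteration: int                      # original iteration id
    draw: dict[str, float]
    error: ErrorTrace
    baseline_error: ErrorTrace | None = None


def select_best_model(
    results: MCResultSet, measured: np.ndarray
) -> BestModelSelection:
    """Pick the perturbed model with the least KCF RMSE against measurement.

    Ties break toward the lowest iteration id.  The baseline trace is
    scored alongside for reference but never returned in place of a
    strictly better iteration.
    """
    measured = np.asarray(measured, dtype=float)
    if results.n_iterations < 1:
        raise ValidationError("no successful iterations to select from")
    if measured.shape[-1] != results.kcf_bw.shape[-1]:
        raise ValidationError("measured trace is not on the result grid")
    rmses = np.sqrt(np.mean((results.kcf_bw - measured[None, :]) ** 2, axis=1))
    k = int(np.argmin(rmses))  # argmin returns the first (lowest id) on ties
    return BestModelSelection(
        iteration=int(results.iteration_ids[k]),
        draw=results.draws[k],
        error=kcf_error(results.kcf_bw[k], measured),
        baseline_error=kcf_error(results.baseline.kcf_bw, measured),
    )
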