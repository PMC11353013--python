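"""Biexponential clinical tumor-growth-inhibition (TGI) model.

Tumor size under treatment follows TS(t) = TS0 (exp(-KS t) + exp(KG t) - 1):
a shrinking drug-sensitive fraction superimposed on regrowth, with KG and KS
in 1/week. Per-subject parameters are estimated by nonlinear least squares on
log size; cohorts are summarized by group-mean parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ParameterError

__all__ = ["TGIParameters", "simulate_tumor_size", "fit_tgi", "simulate_cohort",
           "nadir_time"]


@dataclass
class TGIParameters:
    """Biexponential TGI parameters: initial size, growth and shrinkage rates."""

    ts0: float  # initial tumor size (arbitrary units)
    kg: float   # 1/week
    ks: float   # 1/week
    boundary: bool = False  # True when the fit pinned ks (or kg) at 0

    def __post_init__(self):
        if self.ts0 <= 0:
            raise ParameterError("ts0 must be > 0")
        if self.kg < 0 or self.ks < 0:
            raise ParameterError("kg and ks must be >= 0")


def simulate_tumor_size(params: TGIParameters, times) -> np.ndarray:
    """TS(t) = TS0 (exp(-KS t) + exp(KG t) - 1), times in weeks."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ParameterError("times must be >= 0")
    return params.ts0 * (np.exp(-params.ks * t) + np.exp(params.kg * t) - 1.0)


def nadir_time(params: TGIParameters) -> float:
    """Time of minimum tumor size, ln(ks/kg)/(ks+kg), for ks > kg > 0."""
    if not (params.ks > params.kg > 0):
        raise ParameterError("nadir requires ks > kg > 0")
    return math.log(params.ks / params.kg) / (params.ks + params.kg)


def fit_tgi(times, sizes, fix_ts0: float = None) -> TGIParameters:
    """Fit the biexponential model to one subject's tumor-size series.

    Least squares on log-transformed sizes with non-negativity constraints
    and a deterministic multi-start over a (kg, ks) grid. With ``fix_ts0``
    the initial size is held fixed rather than estimated.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if t.size != y.size:
        raise ParameterError("times and sizes must have the same length")
    if t.size < 4:
        raise FitError("need at least 4 observations")
    if np.any(y <= 0):
        raise ParameterError("tumor sizes must be > 0 for the log-scale fit")
    logy = np.log(y)

    def residuals(theta):
        if fix_ts0 is None:
            log_ts0, kg, ks = theta
            ts0 = math.exp(log_ts0)
        else:
            kg, ks = theta
            ts0 = fix_ts0
        model = ts0 * (np.exp(-ks * t) + np.exp(kg * t) - 1.0)
        return np.log(np.maximum(model, 1e-12)) - logy

    kg_starts = [1e-3, 0.02, 0.05, 0.15]
    ks_starts = [1e-3, 0.05, 0.2, 0.8]
    ts0_guess = float(y[np.argmin(t)])
    best = None
    for kg0 in kg_starts:
        for ks0 in ks_starts:
            if fix_ts0 is None:
                x0 = [math.log(ts0_guess), kg0, ks0]
                lb, ub = [-10.0, 0.0, 0.0], [20.0, 5.0, 20.0]
            else:
                x0 = [kg0, ks0]
                lb, ub = [0.0, 0.0], [5.0, 20.0]
            try:
                res = least_squares(residuals, x0, bounds=(lb, ub), method="trf",
                                    xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=600)
            except Exception:  # pragma: no cover - defensive
                continue
            sse = float(np.sum(res.fun ** 2))
            if best is None or sse < best[1] - 1e-15:
                best = (res.x, sse)
    if best is None:
        raise FitError("TGI fit failed from all starts")
    x, _ = best
    if fix_ts0 is None:
        ts0, kg, ks = math.exp(x[0]), float(x[1]), float(x[2])
    else:
        ts0, kg, ks = fix_ts0, float(x[0]), float(x[1])
    boundary = bool(ks < 1e-6 or kg < 1e-9)
    return TGIParameters(ts0=ts0, kg=max(kg, 0.0), ks=max(ks, 0.0), boundary=boundary)


def simulate_cohort(group_params: dict, ts0: float = 50.0,
                    horizon_weeks: float = 52.0, n_points: int = 53) -> dict:
    """Deterministic group-mean trajectories over the horizon.

    ``group_params`` maps group name -> (mean kg, mean ks) in 1/week; every
    group starts from the same TS0 (default 50).
    """
    if horizon_weeks <= 0:
        raise ParameterError("horizon must be > 0")
    times = np.linspace(0.0, horizon_weeks, n_points)
    out = {}
    for group, (kg, ks) in group_params.items():
        p = TGIParameters(ts0=ts0, kg=kg, ks=ks)
        out[group] = {"times_weeks": times, "sizes": simulate_tumor_size(p, times),
                      "params": p}
    return out
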