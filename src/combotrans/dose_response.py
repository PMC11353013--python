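"""Single-agent dose-response fitting and combination synergy scoring.

Viability matrices are control-normalized relative viabilities measured on a
two-drug checkerboard. Single-agent curves are log-logistic; combination
benefit is scored against the highest-single-agent (HSA) and Bliss
independence null models, summarized as the mean of the top 10% excess values
across the dose matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, MarginError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CombinationMatrix",
    "DoseResponseCurve",
    "SynergyResult",
    "fit_dose_response",
    "smooth_combination_matrix",
    "synergy_analysis",
    "single_agent_metrics",
    "top_fraction_score",
    "log_logistic",
]


def log_logistic(dose, upper, lower, ec50, hill):
    """Decreasing log-logistic curve v(d) = lower + (upper-lower)/(1+(d/ec50)^hill).

    Evaluates to ``upper`` at dose 0 (for hill > 0).
    """
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ec50) ** hill, 0.0)
    return lower + (upper - lower) / (1.0 + ratio)


@dataclass
class CombinationMatrix:
    """Checkerboard of relative viability on two ascending dose axes (µM).

    A leading 0 on either axis denotes the untreated single-agent margin.
    """

    drug_a_name: str
    drug_b_name: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    viability: np.ndarray
    cell_line: str = ""
    treatment_hours: float = 120.0

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)

    def validate(self, control_tol: float = 0.25) -> None:
        """Check structural invariants; raise ParameterError on violation."""
        if self.viability.shape != (self.doses_a.size, self.doses_b.size):
            raise ParameterError(
                f"viability shape {self.viability.shape} does not match dose axes "
                f"({self.doses_a.size}, {self.doses_b.size})"
            )
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if np.any(np.diff(d) <= 0):
                raise ParameterError(f"{name} must be strictly increasing")
            if np.any(d < 0):
                raise ParameterError(f"{name} must be non-negative")
        if not np.all(np.isfinite(self.viability)) or np.any(self.viability < 0):
            raise ParameterError("viability must be finite and >= 0")
        if self.doses_a[0] == 0 and self.doses_b[0] == 0:
            if abs(self.viability[0, 0] - 1.0) > control_tol:
                raise ParameterError(
                    f"untreated (0,0) cell = {self.viability[0, 0]:.3f}, "
                    f"deviates from 1 by more than {control_tol}"
                )

    @property
    def has_margins(self) -> bool:
        return self.doses_a[0] == 0 and self.doses_b[0] == 0

    def transpose(self) -> "CombinationMatrix":
        """Swap the two drugs (axes)."""
        return CombinationMatrix(
            drug_a_name=self.drug_b_name,
            drug_b_name=self.drug_a_name,
            doses_a=self.doses_b.copy(),
            doses_b=self.doses_a.copy(),
            viability=self.viability.T.copy(),
            cell_line=self.cell_line,
            treatment_hours=self.treatment_hours,
        )


@dataclass
class DoseResponseCurve:
    """Fitted log-logistic curve with derived single-agent metrics.

    ``model_form`` is "LL.3u" (upper fixed at 1) or "LL.4". ``ic50_abs`` is
    the absolute IC50 — the dose at which fitted viability crosses 0.5 — and
    is None when the curve never crosses 0.5; it is distinct from ``ec50``
    (the inflection dose).
    """

    model_form: str
    upper_limit: float
    lower_limit: float
    ec50: float
    hill: float
    emax: float = math.nan
    auc: float = math.nan
    converged: bool = True
    sse: float = math.nan

    def predict(self, dose):
        return log_logistic(dose, self.upper_limit, self.lower_limit, self.ec50, self.hill)

    @property
    def ic50_abs(self):
        """Absolute IC50 in µM, or None if fitted viability never crosses 0.5."""
        lo, up = self.lower_limit, self.upper_limit
        if not (lo < 0.5 < up):
            return None
        return self.ec50 * ((up - 0.5) / (0.5 - lo)) ** (1.0 / self.hill)


def _fit_loglogistic(doses, viab, fix_upper):
    """Multi-start bounded least squares; returns (params, sse) or None."""
    nz = doses[doses > 0]
    lo_d, hi_d = nz.min(), nz.max()
    quantiles = np.quantile(np.log10(nz), [0.1, 0.3, 0.5, 0.7, 0.9])
    hills = [1.0, 2.0, 1.0, 2.0, 1.0]
    vmin, vmax = viab.min(), viab.max()

    def residuals(theta):
        if fix_upper:
            lower, log_ec50, hill = theta
            upper = 1.0
        else:
            upper, lower, log_ec50, hill = theta
        return log_logistic(doses, upper, lower, 10.0 ** log_ec50, hill) - viab

    # dose bounds one decade beyond the tested range keep EC50 identifiable
    lb_ec, ub_ec = math.log10(lo_d) - 1.5, math.log10(hi_d) + 1.5
    if fix_upper:
        lb = [-0.5, lb_ec, 0.05]
        ub = [1.2, ub_ec, 10.0]
    else:
        lb = [0.0, -0.5, lb_ec, 0.05]
        ub = [1.5, 1.2, ub_ec, 10.0]
    best = None
    for log_ec0, h0 in zip(quantiles, hills):
        if fix_upper:
            x0 = [max(min(vmin, 1.0), -0.4), log_ec0, h0]
        else:
            x0 = [min(max(vmax, 0.1), 1.45), max(min(vmin, 1.0), -0.4), log_ec0, h0]
        x0 = np.clip(x0, lb, ub)
        try:
            res = least_squares(
                residuals, x0, bounds=(lb, ub), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(np.sum(res.fun ** 2))
        if best is None or sse < best[1] - 1e-14:
            best = (res.x, sse)
        if sse < 1e-10:
            break
    return best


def fit_dose_response(doses, viabilities, model_form: str = "auto") -> DoseResponseCurve:
    """Fit a log-logistic dose-response curve.

    Parameters
    ----------
    doses : array-like of µM, may include a leading 0 (untreated control).
    viabilities : relative viability at each dose.
    model_form : "LL.3u" (upper fixed at 1), "LL.4", or "auto" (LL.4 when the
        zero-dose/lowest-dose viability deviates from 1 by more than 0.1).

    Raises
    ------
    FitError
        If fewer than 4 distinct nonzero doses are supplied.
    """
    doses = np.asarray(doses, dtype=float)
    viab = np.asarray(viabilities, dtype=float)
    if doses.shape != viab.shape:
        raise ParameterError("doses and viabilities must have the same length")
    if not np.all(np.isfinite(viab)):
        raise ParameterError("viabilities must be finite")
    if np.unique(doses[doses > 0]).size < 4:
        raise FitError("need at least 4 distinct nonzero dose levels")

    if model_form == "auto":
        anchor = viab[doses == 0].mean() if np.any(doses == 0) else viab[np.argmin(doses)]
        model_form = "LL.4" if abs(anchor - 1.0) > 0.1 else "LL.3u"
    if model_form not in ("LL.3u", "LL.4"):
        raise ParameterError(f"unknown model_form {model_form!r}")
    fix_upper = model_form == "LL.3u"

    best = _fit_loglogistic(doses, viab, fix_upper)
    if best is None:
        # flat-curve fallback, flagged unconverged
        m = float(viab.mean())
        curve = DoseResponseCurve(model_form, m, m, float(np.median(doses[doses > 0])),
                                  1.0, converged=False)
    else:
        x, sse = best
        if fix_upper:
            lower, log_ec50, hill = x
            upper = 1.0
        else:
            upper, lower, log_ec50, hill = x
        if lower > upper:  # canonical ordering for near-flat fits
            upper, lower = lower, upper
        curve = DoseResponseCurve(model_form, float(upper), float(lower),
                                  float(10.0 ** log_ec50), float(hill), sse=sse)

    nz = doses[doses > 0]
    curve.emax = float(curve.predict(nz.max()))
    curve.auc = float(np.mean(1.0 - curve.predict(np.unique(nz))))
    return curve


def single_agent_metrics(curve: DoseResponseCurve, dose_range) -> dict:
    """IC50/Emax/AUC of a fitted curve restricted to a dose interval (µM).

    AUC is the mean fractional inhibition of the fitted curve on a uniform
    log10-dose grid spanning ``dose_range``.
    """
    lo, hi = float(dose_range[0]), float(dose_range[1])
    if not (0 < lo < hi):
        raise ParameterError("dose_range must be a nonempty positive interval")
    grid = np.logspace(math.log10(lo), math.log10(hi), 25)
    ic50 = curve.ic50_abs
    if ic50 is not None and not (lo <= ic50 <= hi):
        ic50 = None
    return {
        "ic50_abs": ic50,
        "emax": float(curve.predict(hi)),
        "auc": float(np.mean(1.0 - curve.predict(grid))),
    }


def smooth_combination_matrix(matrix: CombinationMatrix) -> np.ndarray:
    """Smooth a viability checkerboard by bidirectional curve fitting.

    For every fixed dose of drug B a log-logistic curve is fitted along the
    drug-A axis, and vice versa; the two fitted surfaces are averaged. Slices
    whose fit fails fall back to the observed values (logged).
    """
    v = matrix.viability
    na, nb = v.shape
    fit_a = np.empty_like(v)
    fit_b = np.empty_like(v)
    for j in range(nb):
        try:
            c = fit_dose_response(matrix.doses_a, v[:, j], model_form="LL.4")
            fit_a[:, j] = c.predict(matrix.doses_a)
        except FitError:
            logger.warning("column fit failed at dose_b=%g; using observed values",
                           matrix.doses_b[j])
            fit_a[:, j] = v[:, j]
    for i in range(na):
        try:
            c = fit_dose_response(matrix.doses_b, v[i, :], model_form="LL.4")
            fit_b[i, :] = c.predict(matrix.doses_b)
        except FitError:
            logger.warning("row fit failed at dose_a=%g; using observed values",
                           matrix.doses_a[i])
            fit_b[i, :] = v[i, :]
    return 0.5 * (fit_a + fit_b)


@dataclass
class SynergyResult:
    """Expectation/excess matrices and top-fraction combination scores."""

    smoothed_viability: np.ndarray
    response: np.ndarray
    hsa_expectation: np.ndarray
    bliss_expectation: np.ndarray
    hsa_excess: np.ndarray
    bliss_excess: np.ndarray
    hsa_score: float
    bliss_score: float
    doses_a: np.ndarray = field(default=None)
    doses_b: np.ndarray = field(default=None)


def top_fraction_score(excess: np.ndarray, top_fraction: float = 0.10) -> float:
    """Mean of the ceil(top_fraction * N) largest values of ``excess``."""
    if not (0.0 < top_fraction <= 1.0):
        raise ParameterError("top_fraction must be in (0, 1]")
    flat = np.asarray(excess, dtype=float).ravel()
    k = math.ceil(top_fraction * flat.size)
    top = np.partition(flat, flat.size - k)[flat.size - k:]
    return float(top.mean())


def synergy_analysis(matrix: CombinationMatrix, top_fraction: float = 0.10,
                     smooth: bool = True) -> SynergyResult:
    """HSA and Bliss excess analysis of a combination viability matrix.

    Responses are fractional inhibitions r = 1 - v computed on the smoothed
    (or, with ``smooth=False``, observed) viability clipped to [0, 1]; the
    single-agent margins of that same surface define the null-model
    expectations. Scores are the mean of the top ``top_fraction`` of excess
    values over all matrix cells (margins included).
    """
    if not matrix.has_margins:
        raise MarginError("matrix must contain zero-dose row and column margins")
    if not (0.0 < top_fraction <= 1.0):
        raise ParameterError("top_fraction must be in (0, 1]")

    smoothed = smooth_combination_matrix(matrix) if smooth else matrix.viability.copy()
    r = 1.0 - np.clip(smoothed, 0.0, 1.0)
    ra = r[:, 0][:, None]  # drug A single-agent margin (dose_b = 0)
    rb = r[0, :][None, :]  # drug B single-agent margin (dose_a = 0)
    bliss = ra + rb - ra * rb
    hsa = np.maximum(ra, rb)
    bliss_excess = r - bliss
    hsa_excess = r - hsa
    return SynergyResult(
        smoothed_viability=smoothed,
        response=r,
        hsa_expectation=np.broadcast_to(hsa, r.shape).copy(),
        bliss_expectation=bliss,
        hsa_excess=hsa_excess,
        bliss_excess=bliss_excess,
        hsa_score=top_fraction_score(hsa_excess, top_fraction),
        bliss_score=top_fraction_score(bliss_excess, top_fraction),
        doses_a=matrix.doses_a.copy(),
        doses_b=matrix.doses_b.copy(),
    )
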