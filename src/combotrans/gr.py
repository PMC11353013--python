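"""Growth-rate translation: GR metric, free-drug conversion, surface
interpolation, and xenograft tumor-volume prediction.

The GR (growth-rate inhibition) metric re-expresses endpoint relative
viability on a growth-rate scale using the untreated doubling time, making in
vitro responses comparable across assay durations and, after conversion to
control-normalized growth rates, transferable to in vivo growth models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dose_response import CombinationMatrix, smooth_combination_matrix
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "AssayConstants",
    "GRSurface",
    "XenograftPrediction",
    "viability_to_gr",
    "gr_to_normalized_rate",
    "nominal_to_free",
    "interpolate_surface",
    "baseline_rate_from_doubling",
    "predict_tumor_growth",
    "gr_surface_from_matrix",
    "caliper_volume",
    "body_weight_change",
    "ddct_fold_change",
]

# fraction unbound in assay media, measured in 10% FBS (5% FBS values in
# parentheses in the source data): Belvarafenib 0.034 (0.068), Cobimetinib
# 0.196 (0.3); plasma fu 0.00258 / 0.052; molecular weights in g/mol.
FU_MEDIA_10FBS = {"belvarafenib": 0.034, "cobimetinib": 0.196}
FU_MEDIA_5FBS = {"belvarafenib": 0.068, "cobimetinib": 0.3}
FU_PLASMA = {"belvarafenib": 0.00258, "cobimetinib": 0.052}
MOLECULAR_WEIGHT = {"belvarafenib": 478.93, "cobimetinib": 531.3}


@dataclass
class AssayConstants:
    """Assay- and drug-level constants for the in vitro -> in vivo translation."""

    fu_media_a: float = FU_MEDIA_10FBS["belvarafenib"]
    fu_media_b: float = FU_MEDIA_10FBS["cobimetinib"]
    fu_plasma_a: float = FU_PLASMA["belvarafenib"]
    fu_plasma_b: float = FU_PLASMA["cobimetinib"]
    mw_a: float = MOLECULAR_WEIGHT["belvarafenib"]
    mw_b: float = MOLECULAR_WEIGHT["cobimetinib"]
    doubling_time_in_vitro: float = 60.0  # h
    treatment_hours: float = 120.0  # h
    doubling_time_in_vivo: float = 18.0  # days
    # in vitro free concentration taken as directly comparable to in vivo
    # free plasma concentration; exposed as a scalar defaulting to unity
    in_vitro_in_vivo_factor: float = 1.0

    def __post_init__(self):
        for name in ("fu_media_a", "fu_media_b", "fu_plasma_a", "fu_plasma_b"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ParameterError(f"{name}={v} must be in (0, 1]")
        if self.mw_a <= 0 or self.mw_b <= 0:
            raise ParameterError("molecular weights must be positive")


def viability_to_gr(viability, treatment_hours: float, doubling_time: float):
    """GR metric from endpoint relative viability.

    GR = 2^(1 + log2(v) * Td / T) - 1, where T is the treatment duration and
    Td the untreated doubling time (same units). GR = 1 means untreated
    growth, 0 complete cytostasis, negative net cell loss.
    """
    v = np.asarray(viability, dtype=float)
    if np.any(v <= 0):
        raise ParameterError("viability must be > 0 for GR conversion")
    if treatment_hours <= 0 or doubling_time <= 0:
        raise ParameterError("treatment_hours and doubling_time must be > 0")
    out = 2.0 ** (1.0 + np.log2(v) * doubling_time / treatment_hours) - 1.0
    return float(out) if np.isscalar(viability) else out


def gr_to_normalized_rate(gr):
    """Control-normalized growth rate r = k_treated / k_control = log2(GR + 1)."""
    g = np.asarray(gr, dtype=float)
    if np.any(g <= -1):
        raise ParameterError("GR must be > -1")
    out = np.log2(g + 1.0)
    return float(out) if np.isscalar(gr) else out


def nominal_to_free(dose, fu: float):
    """Free concentration = nominal concentration x fraction unbound."""
    if not (0 < fu <= 1):
        raise ParameterError(f"fraction unbound {fu} must be in (0, 1]")
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ParameterError("dose must be >= 0")
    out = d * fu
    return float(out) if np.isscalar(dose) else out


def baseline_rate_from_doubling(doubling_time: float) -> float:
    """Exponential growth rate k = ln(2) / doubling time."""
    if doubling_time <= 0:
        raise ParameterError("doubling_time must be > 0")
    return math.log(2.0) / doubling_time


def _interp_axis(doses: np.ndarray, values: np.ndarray, q: float) -> np.ndarray:
    """1-D dose-axis interpolation of ``values`` (first axis) at dose ``q``.

    log10-linear inside the nonzero-dose grid; linear in linear dose between
    the zero-dose margin and the lowest tested dose; clamped (with a warning)
    above the maximum.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    nz_mask = doses > 0
    nz = doses[nz_mask]
    vnz = values[nz_mask]
    if q >= nz[-1]:
        if q > nz[-1] * (1 + 1e-12):
            logger.warning("query dose %g above grid maximum %g; clamping", q, nz[-1])
        return vnz[-1]
    if q >= nz[0]:
        lq = math.log10(q)
        lg = np.log10(nz)
        idx = int(np.searchsorted(lg, lq, side="right")) - 1
        idx = min(max(idx, 0), nz.size - 2)
        w = (lq - lg[idx]) / (lg[idx + 1] - lg[idx])
        return (1 - w) * vnz[idx] + w * vnz[idx + 1]
    # below the lowest tested dose: bridge linearly from the zero-dose margin
    if doses[0] == 0:
        w = q / nz[0]
        return (1 - w) * values[0] + w * vnz[0]
    logger.warning("query dose %g below grid minimum %g with no zero margin; clamping",
                   q, nz[0])
    return vnz[0]


def interpolate_surface(doses_a, doses_b, values, dose_a: float, dose_b: float) -> float:
    """Bilinear interpolation of a dose-matrix surface at a (µM, µM) query.

    Interpolation is bilinear in (log10 dose_a, log10 dose_b) over the
    nonzero-dose grid, with linear-dose bridging between the zero-dose margin
    and the lowest tested dose, and clamping above the grid maximum.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape != (doses_a.size, doses_b.size):
        raise ParameterError("surface shape does not match its dose axes")
    if dose_a < 0 or dose_b < 0:
        raise ParameterError("query doses must be >= 0")
    # tensor-product 1-D scheme: collapse the B axis, then the A axis
    col = np.array([_interp_axis(doses_b, values[i, :], dose_b)
                    for i in range(doses_a.size)])
    return float(_interp_axis(doses_a, col, dose_a))


@dataclass
class GRSurface:
    """GR-metric values on free-drug dose axes, with the paired Bliss excess.

    ``normalized_rate`` is the elementwise control-normalized growth rate
    log2(GR + 1).
    """

    free_doses_a: np.ndarray
    free_doses_b: np.ndarray
    gr: np.ndarray
    bliss_excess: np.ndarray = None
    drug_a_name: str = ""
    drug_b_name: str = ""

    def __post_init__(self):
        self.free_doses_a = np.asarray(self.free_doses_a, dtype=float)
        self.free_doses_b = np.asarray(self.free_doses_b, dtype=float)
        self.gr = np.asarray(self.gr, dtype=float)

    @property
    def normalized_rate(self) -> np.ndarray:
        return gr_to_normalized_rate(self.gr)

    def gr_at(self, free_a: float, free_b: float) -> float:
        return interpolate_surface(self.free_doses_a, self.free_doses_b,
                                   self.gr, free_a, free_b)

    def normalized_rate_at(self, free_a: float, free_b: float) -> float:
        return float(np.log2(self.gr_at(free_a, free_b) + 1.0))

    def bliss_excess_at(self, free_a: float, free_b: float) -> float:
        if self.bliss_excess is None:
            raise ParameterError("surface carries no Bliss excess matrix")
        return interpolate_surface(self.free_doses_a, self.free_doses_b,
                                   self.bliss_excess, free_a, free_b)


def gr_surface_from_matrix(matrix: CombinationMatrix, constants: AssayConstants,
                           bliss_excess: np.ndarray = None,
                           smooth: bool = True,
                           viability_floor: float = 1e-4) -> GRSurface:
    """Convert a viability matrix to a GR surface on free-drug dose axes.

    Viability is smoothed (by default) before the GR conversion and floored
    at ``viability_floor`` to keep the log defined. Dose axes are multiplied
    by the media fraction unbound of each drug.
    """
    v = smooth_combination_matrix(matrix) if smooth else matrix.viability
    v = np.maximum(v, viability_floor)
    gr = viability_to_gr(v, constants.treatment_hours, constants.doubling_time_in_vitro)
    return GRSurface(
        free_doses_a=nominal_to_free(matrix.doses_a, constants.fu_media_a),
        free_doses_b=nominal_to_free(matrix.doses_b, constants.fu_media_b),
        gr=gr,
        bliss_excess=bliss_excess,
        drug_a_name=matrix.drug_a_name,
        drug_b_name=matrix.drug_b_name,
    )


@dataclass
class XenograftPrediction:
    """Exponential tumor-volume prediction for one treatment arm."""

    baseline_rate: float  # 1/day
    normalized_rate: float
    times: np.ndarray  # days
    predicted_volumes: np.ndarray  # mm^3
    initial_volume: float  # mm^3
    arm: str = ""


def predict_tumor_growth(initial_volume: float, baseline_rate: float,
                         normalized_rate: float, times) -> XenograftPrediction:
    """V(t) = V0 exp(k_baseline * r_norm * t): scaled exponential growth.

    The control-normalized rate from the in vitro surface scales the
    vehicle-arm growth rate; r_norm = 1 reproduces control growth, 0 is
    cytostasis, negative values give tumor shrinkage.
    """
    if initial_volume <= 0:
        raise ParameterError("initial_volume must be > 0")
    t = np.asarray(times, dtype=float)
    vols = initial_volume * np.exp(baseline_rate * normalized_rate * t)
    return XenograftPrediction(baseline_rate, normalized_rate, t, vols, initial_volume)


def caliper_volume(longer: float, shorter: float) -> float:
    """Tumor volume (mm^3) = longer x shorter^2 x 0.5 from caliper measurements."""
    if not (longer >= shorter > 0):
        raise ParameterError("expected longer >= shorter > 0 (argument order)")
    return longer * shorter ** 2 * 0.5


def body_weight_change(current: float, initial: float):
    """Percent body-weight change and the >= 20% loss euthanasia flag."""
    if initial <= 0:
        raise ParameterError("initial weight must be > 0")
    pct = (current / initial - 1.0) * 100.0
    return pct, bool(pct <= -20.0 + 1e-9)


def ddct_fold_change(delta_delta_ct):
    """Relative expression fold change 2^(-ddCt)."""
    d = np.asarray(delta_delta_ct, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ParameterError("ddCt must be finite")
    out = 2.0 ** (-d)
    return float(out) if np.isscalar(delta_delta_ct) else out
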