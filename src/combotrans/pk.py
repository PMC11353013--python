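"""Population pharmacokinetic simulation for orally dosed drug regimens.

A one-compartment model with first-order absorption, simulated by closed-form
superposition of doses, generates total plasma concentration profiles;
lognormal interindividual variability on ka, CL/F and V/F produces a virtual
population. Days 22-26 of a 30-day simulation form the steady-state analysis
window. Concentrations convert to free molar units via molecular weight and
the plasma fraction unbound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "Regimen",
    "PopPKModel",
    "PKProfile",
    "simulate_individual_pk",
    "simulate_population_pk",
    "to_free_molar",
    "exposure_summary",
    "STANDARD_REGIMENS",
    "DEFAULT_MODELS",
]

SCHEDULE_INTERVAL_H = {"QD": 24.0, "BID": 12.0, "QOD": 48.0}

# steady-state window: days 22 through 26 of a 30-day simulation
SS_WINDOW_H = (21 * 24.0, 26 * 24.0)


@dataclass(frozen=True)
class Regimen:
    """An oral dosing regimen: dose in mg on a QD/BID/QOD schedule."""

    drug: str
    dose_mg: float
    schedule: str
    duration_days: float = 30.0

    def __post_init__(self):
        if self.dose_mg <= 0:
            raise ParameterError("dose_mg must be > 0")
        if self.schedule not in SCHEDULE_INTERVAL_H:
            raise ParameterError(
                f"schedule {self.schedule!r} not one of {sorted(SCHEDULE_INTERVAL_H)}")

    @property
    def interval_h(self) -> float:
        return SCHEDULE_INTERVAL_H[self.schedule]

    def dose_times(self) -> np.ndarray:
        """Dosing times in hours from first dose (first dose at t = 0)."""
        return np.arange(0.0, self.duration_days * 24.0, self.interval_h)

    @property
    def label(self) -> str:
        return f"{self.drug} {self.dose_mg:g} mg {self.schedule}"


@dataclass
class PopPKModel:
    """Typical one-compartment parameters with lognormal interindividual SDs.

    ka (1/h), cl_f (L/h, apparent clearance), v_f (L, apparent volume);
    omega_* are the SDs of the log-scale random effects. mw (g/mol) and
    fu_plasma convert ng/mL totals to free µM.
    """

    ka: float
    cl_f: float
    v_f: float
    omega_ka: float = 0.0
    omega_cl: float = 0.0
    omega_v: float = 0.0
    mw: float = 1.0
    fu_plasma: float = 1.0

    def __post_init__(self):
        if min(self.ka, self.cl_f, self.v_f, self.mw) <= 0:
            raise ParameterError("ka, cl_f, v_f and mw must be > 0")
        if min(self.omega_ka, self.omega_cl, self.omega_v) < 0:
            raise ParameterError("omegas must be >= 0")
        if not (0 < self.fu_plasma <= 1):
            raise ParameterError("fu_plasma must be in (0, 1]")


@dataclass
class PKProfile:
    """One individual's concentration time series under a regimen."""

    individual_id: int
    times: np.ndarray  # h since first dose
    total_ngml: np.ndarray
    free_um: np.ndarray
    regimen: Regimen
    parameters: dict = field(default_factory=dict)
    steady_state_window: tuple = SS_WINDOW_H

    def window_mask(self) -> np.ndarray:
        lo, hi = self.steady_state_window
        return (self.times >= lo) & (self.times <= hi)

    def window_mean_free(self) -> float:
        m = self.window_mask()
        if not np.any(m):
            raise ParameterError("steady-state window is empty")
        return float(self.free_um[m].mean())

    def free_at(self, t_h) -> np.ndarray:
        """Linear-in-time interpolation of free concentration (µM)."""
        return np.interp(np.asarray(t_h, dtype=float), self.times, self.free_um)


def to_free_molar(total_ngml, mw: float, fu_plasma: float):
    """ng/mL total concentration -> free µM: (ng/mL / MW g/mol) x fu.

    ng/mL is numerically µg/L, so dividing by the molecular weight in g/mol
    gives µmol/m^3 = nmol/L x 1 = µM x 10^-3; the conventional shortcut used
    throughout this analysis divides ng/mL by g/mol to get µM directly, i.e.
    478.93 ng/mL of a 478.93 g/mol compound is treated as 1.0 µM total.
    """
    if mw <= 0:
        raise ParameterError("mw must be > 0")
    if not (0 < fu_plasma <= 1):
        raise ParameterError("fu_plasma must be in (0, 1]")
    c = np.asarray(total_ngml, dtype=float)
    if np.any(c < 0):
        raise ParameterError("concentrations must be >= 0")
    out = c / mw * fu_plasma
    return float(out) if np.isscalar(total_ngml) else out


def _superposition_conc(times: np.ndarray, dose_times: np.ndarray, dose_mg: float,
                        ka: float, cl: float, v: float) -> np.ndarray:
    """Total concentration (ng/mL) by closed-form dose superposition."""
    ke = cl / v
    conc = np.zeros_like(times)
    for td in dose_times:
        dt = times - td
        active = dt >= 0
        dta = dt[active]
        if abs(ka - ke) < 1e-10 * ka:
            # limiting form as ka -> ke
            term = dose_mg * ka / v * dta * np.exp(-ka * dta)
        else:
            term = (dose_mg * ka / (v * (ka - ke))
                    * (np.exp(-ke * dta) - np.exp(-ka * dta)))
        conc[active] += term
    return conc * 1000.0  # mg/L -> ng/mL


def simulate_individual_pk(params: dict, regimen: Regimen, dt: float = 0.25,
                           mw: float = 1.0, fu_plasma: float = 1.0,
                           individual_id: int = 0) -> PKProfile:
    """Simulate one individual's total and free concentration profile.

    ``params`` supplies realized individual ka (1/h), cl_f (L/h), v_f (L).
    """
    if dt > 1.0:
        raise ParameterError("dt must be <= 1 h")
    if regimen.duration_days < 30:
        raise ParameterError("duration must be >= 30 days to reach the analysis window")
    times = np.arange(0.0, regimen.duration_days * 24.0 + dt / 2, dt)
    total = _superposition_conc(times, regimen.dose_times(), regimen.dose_mg,
                                params["ka"], params["cl_f"], params["v_f"])
    free = to_free_molar(total, mw, fu_plasma)
    return PKProfile(individual_id, times, total, free, regimen, dict(params))


def simulate_population_pk(model: PopPKModel, regimen: Regimen, n: int = 500,
                           seed: int = 0, dt: float = 0.25) -> list:
    """Generate ``n`` individual profiles with lognormal parameter variability.

    Individual parameters are theta * exp(eta), eta ~ N(0, omega^2),
    independent per parameter and individual; identical seeds give
    bit-identical populations.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        eta = rng.normal(0.0, 1.0, size=3)
        params = {
            "ka": model.ka * math.exp(model.omega_ka * eta[0]),
            "cl_f": model.cl_f * math.exp(model.omega_cl * eta[1]),
            "v_f": model.v_f * math.exp(model.omega_v * eta[2]),
        }
        profiles.append(simulate_individual_pk(
            params, regimen, dt=dt, mw=model.mw, fu_plasma=model.fu_plasma,
            individual_id=i))
    return profiles


def exposure_summary(profiles: list) -> dict:
    """Population mean and SD of per-individual window-averaged free conc (µM)."""
    if not profiles:
        raise ParameterError("need at least one profile")
    means = np.array([p.window_mean_free() for p in profiles])
    sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
    return {"mean": float(means.mean()), "sd": sd, "n": means.size,
            "individual_means": means}


# The published popPK models behind the study regimens are not reproducible
# from printed values; these typical values are calibrated so that the
# mid-regimen mean steady-state free concentrations fall inside the in vitro
# free-dose grids (see docs/methods.md). They are simulator defaults, not
# claims about the real compounds.
DEFAULT_MODELS = {
    "belvarafenib": PopPKModel(ka=0.5, cl_f=9.0, v_f=400.0,
                               omega_ka=0.3, omega_cl=0.3, omega_v=0.3,
                               mw=478.93, fu_plasma=0.00258),
    "cobimetinib": PopPKModel(ka=0.4, cl_f=13.8, v_f=680.0,
                              omega_ka=0.3, omega_cl=0.3, omega_v=0.3,
                              mw=531.3, fu_plasma=0.052),
}

# The clinical regimens analyzed for each drug.
STANDARD_REGIMENS = {
    "belvarafenib": [
        Regimen("belvarafenib", 50.0, "QD"),
        Regimen("belvarafenib", 100.0, "BID"),
        Regimen("belvarafenib", 200.0, "BID"),
        Regimen("belvarafenib", 400.0, "BID"),
    ],
    "cobimetinib": [
        Regimen("cobimetinib", 20.0, "QOD"),
        Regimen("cobimetinib", 20.0, "QD"),
        Regimen("cobimetinib", 40.0, "QD"),
        Regimen("cobimetinib", 60.0, "QD"),
    ],
}
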