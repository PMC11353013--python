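"""Coarse-grained ODE model of MAPK signaling under panRAF + MEK inhibition.

The model captures the negative-feedback architecture that differentiates
NRAS Q61 from BRAF V600E melanoma: ERK-dependent inhibitory phosphorylation
of RAF (pRAF feedback) suppresses RAS-driven RAF dimerization at baseline;
MEK inhibition relieves the feedback, RAF dimers and pMEK rebound
(paradoxical pMEK activation), and a dimer-competent panRAF inhibitor is
required to suppress the rebound — the mechanistic basis of the
mutant-specific synergy. BRAF V600E signals through a RAS-independent
monomer insensitive to the feedback, so the same drug pair combines
additively.

States are fractional occupancies: R (RAS-GTP), D (RAF dimers), F_p
(feedback-phosphorylated RAF), m (pMEK), e (pERK); free RAF protomers follow
from the conservation F_u + F_p + 2D = 1. Drug binding is treated at rapid
equilibrium: bound fractions b_R = B/(B + Kd_RAFi), b_M = C/(C + Kd_MEKi).
MEK-inhibitor-bound MEK is phosphorylated by RAF at the relative rate
``alpha_meki`` and is catalytically dead toward ERK.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .dose_response import CombinationMatrix, synergy_analysis
from .errors import ConvergenceError, ParameterError

__all__ = [
    "MAPKParameters",
    "ModelVariant",
    "SignalingState",
    "braf_v600e",
    "nras_q61",
    "nras_q61_no_feedback",
    "steady_state",
    "dose_matrix",
    "timecourse",
    "BELVARAFENIB_GRID",
    "COBIMETINIB_GRID",
]

# steady-state dose grids: 0 plus 9 log-spaced doses, Belvarafenib
# 10^-2.25..10^0.5 µM, Cobimetinib 10^-2.75..10^0 µM
BELVARAFENIB_GRID = np.concatenate([[0.0], np.logspace(-2.25, 0.5, 9)])
COBIMETINIB_GRID = np.concatenate([[0.0], np.logspace(-2.75, 0.0, 9)])


@dataclass
class MAPKParameters:
    """Kinetic constants of the surrogate model (rates in 1/h, Kd in µM)."""

    k_ras_act: float = 0.5
    k_ras_hyd: float = 5.0
    hyd_factor: float = 1.0       # 0.1 for Q61 (impaired GTP hydrolysis)
    k_dim: float = 20.0
    k_undim: float = 1.0
    stab_factor: float = 0.2      # dimer-stability multiplier for the Q61 mapping
    k_fb: float = 30.0
    k_fb_rev: float = 0.5
    kd_rafi: float = 0.3
    kd_meki: float = 0.02
    alpha_meki: float = 0.45
    k_mek_cat: float = 0.5
    k_mek_ptase: float = 1.0
    k_erk_cat: float = 1.5
    k_erk_ptase: float = 1.0

    def __post_init__(self):
        for name in ("k_ras_act", "k_ras_hyd", "k_dim", "k_undim", "k_fb",
                     "k_fb_rev", "k_mek_cat", "k_mek_ptase", "k_erk_cat",
                     "k_erk_ptase"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not (0 < self.hyd_factor <= 1) or not (0 < self.stab_factor <= 1):
            raise ParameterError("hyd_factor and stab_factor must be in (0, 1]")
        if not (0 <= self.alpha_meki <= 1):
            raise ParameterError("alpha_meki must be in [0, 1]")


@dataclass
class ModelVariant:
    """A mutational context: BRAF_V600E, NRAS_Q61, or NRAS_Q61_NO_FEEDBACK."""

    kind: str
    parameters: MAPKParameters

    def __post_init__(self):
        if self.kind not in ("BRAF_V600E", "NRAS_Q61", "NRAS_Q61_NO_FEEDBACK"):
            raise ParameterError(f"unknown variant kind {self.kind!r}")
        if self.kind == "NRAS_Q61_NO_FEEDBACK" and self.parameters.k_fb != 0:
            raise ParameterError("NO_FEEDBACK variant requires k_fb = 0")

    @property
    def uses_ras(self) -> bool:
        return self.kind != "BRAF_V600E"


def nras_q61(**overrides) -> ModelVariant:
    """NRAS Q61 with pRAF feedback: impaired hydrolysis, destabilized dimers."""
    p = MAPKParameters(hyd_factor=0.1, **overrides)
    return ModelVariant("NRAS_Q61", p)


def nras_q61_no_feedback(**overrides) -> ModelVariant:
    """NRAS Q61 with the pRAF feedback removed (k_fb = 0)."""
    p = MAPKParameters(hyd_factor=0.1, k_fb=0.0, **overrides)
    return ModelVariant("NRAS_Q61_NO_FEEDBACK", p)


def braf_v600e(**overrides) -> ModelVariant:
    """BRAF V600E: constant RAS-independent monomer driver, no RAS/dimer states.

    The cascade gain is lower than in the dimer-driven variants so baseline
    pMEK sits off saturation and single-agent responses are graded.
    """
    defaults = dict(k_mek_cat=0.4, k_erk_cat=0.4)
    defaults.update(overrides)
    p = MAPKParameters(**defaults)
    return ModelVariant("BRAF_V600E", p)


@dataclass
class SignalingState:
    """Fractional steady-state (or instantaneous) pathway occupancies."""

    ras_gtp: float
    raf_free: float
    raf_feedback_phos: float
    raf_dimer: float
    pmek: float
    perk: float
    active_raf: float


def _bound_fractions(p: MAPKParameters, belva: float, cobi: float):
    b_r = belva / (belva + p.kd_rafi) if belva > 0 else 0.0
    b_m = cobi / (cobi + p.kd_meki) if cobi > 0 else 0.0
    return b_r, b_m


def _rhs(variant: ModelVariant, belva: float, cobi: float):
    p = variant.parameters
    b_r, b_m = _bound_fractions(p, belva, cobi)
    mek_factor = 1.0 - (1.0 - p.alpha_meki) * b_m
    erk_factor = 1.0 - b_m

    if variant.uses_ras:
        def rhs(t, y):
            r, d, fp, m, e = y
            fu = max(1.0 - fp - 2.0 * d, 0.0)
            active = 2.0 * d * (1.0 - b_r)
            return [
                p.k_ras_act * (1.0 - r) - p.k_ras_hyd * p.hyd_factor * r,
                p.k_dim * p.stab_factor * r * fu * fu - p.k_undim * d,
                p.k_fb * e * fu - p.k_fb_rev * fp,
                p.k_mek_cat * active * (1.0 - m) * mek_factor - p.k_mek_ptase * m,
                p.k_erk_cat * m * erk_factor * (1.0 - e) - p.k_erk_ptase * e,
            ]
    else:
        def rhs(t, y):
            m, e = y
            active = 1.0 - b_r
            return [
                p.k_mek_cat * active * (1.0 - m) * mek_factor - p.k_mek_ptase * m,
                p.k_erk_cat * m * erk_factor * (1.0 - e) - p.k_erk_ptase * e,
            ]
    return rhs, b_r, b_m


def _default_y0(variant: ModelVariant) -> np.ndarray:
    if variant.uses_ras:
        return np.array([0.5, 0.01, 0.1, 0.5, 0.5])
    return np.array([0.5, 0.5])


def _state_from_y(variant: ModelVariant, y: np.ndarray, b_r: float) -> SignalingState:
    if variant.uses_ras:
        r, d, fp, m, e = y
        fu = max(1.0 - fp - 2.0 * d, 0.0)
        return SignalingState(ras_gtp=float(r), raf_free=float(fu),
                              raf_feedback_phos=float(fp), raf_dimer=float(d),
                              pmek=float(m), perk=float(e),
                              active_raf=float(2.0 * d * (1.0 - b_r)))
    m, e = y
    return SignalingState(ras_gtp=math.nan, raf_free=math.nan,
                          raf_feedback_phos=math.nan, raf_dimer=math.nan,
                          pmek=float(m), perk=float(e),
                          active_raf=float(1.0 - b_r))


def steady_state(variant: ModelVariant, belvarafenib: float = 0.0,
                 cobimetinib: float = 0.0, y0: np.ndarray = None,
                 horizon_h: float = 1e4, rel_tol: float = 1e-3,
                 window_h: float = 4.0, polish: bool = True) -> SignalingState:
    """Integrate to steady state and return the signaling state.

    Convergence: relative change of every state below ``rel_tol`` (0.1%)
    over a ``window_h`` = 4 h window; the converged point is then polished
    with a Newton solve of the stationarity conditions.
    """
    if belvarafenib < 0 or cobimetinib < 0:
        raise ParameterError("doses must be >= 0")
    rhs, b_r, _ = _rhs(variant, belvarafenib, cobimetinib)
    y = _default_y0(variant) if y0 is None else np.asarray(y0, dtype=float)
    t = 0.0
    floor = 1e-9
    while t < horizon_h:
        sol = solve_ivp(rhs, (0.0, window_h), y, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:  # pragma: no cover - defensive
            raise ConvergenceError(f"integrator failed at t={t}: {sol.message}")
        y_new = sol.y[:, -1]
        rel = np.abs(y_new - y) / np.maximum(np.abs(y_new), floor)
        y = y_new
        t += window_h
        if np.all(rel < rel_tol):
            break
    else:
        raise ConvergenceError(
            f"no steady state within {horizon_h} h (max rel change {rel.max():.2e})")
    if polish:
        res = root(lambda z: np.asarray(rhs(0.0, z)), y, method="hybr", tol=1e-12)
        if res.success and np.all(np.isfinite(res.x)):
            y = res.x
    return _state_from_y(variant, y, b_r)


def dose_matrix(variant: ModelVariant, belva_doses: np.ndarray = None,
                cobi_doses: np.ndarray = None) -> dict:
    """Steady-state pMEK/pERK dose matrices and Bliss excess on pERK inhibition.

    Values are reported relative to the drug-free steady state (the (0,0)
    cell is 1 by construction). The relative-pERK matrix is scored with the
    Bliss machinery directly (no smoothing: model output is noiseless).
    """
    belva = BELVARAFENIB_GRID if belva_doses is None else np.asarray(belva_doses, float)
    cobi = COBIMETINIB_GRID if cobi_doses is None else np.asarray(cobi_doses, float)
    pmek = np.empty((belva.size, cobi.size))
    perk = np.empty_like(pmek)
    base = steady_state(variant, 0.0, 0.0)
    for i, b in enumerate(belva):
        for j, c in enumerate(cobi):
            st = steady_state(variant, b, c)
            pmek[i, j] = st.pmek
            perk[i, j] = st.perk
    pmek_rel = pmek / base.pmek
    perk_rel = perk / base.perk
    cm = CombinationMatrix("belvarafenib", "cobimetinib", belva, cobi,
                           np.clip(perk_rel, 0.0, None), cell_line=variant.kind)
    syn = synergy_analysis(cm, smooth=False)
    return {
        "belva_doses": belva,
        "cobi_doses": cobi,
        "pmek_rel": pmek_rel,
        "perk_rel": perk_rel,
        "bliss_excess_perk": syn.bliss_excess,
        "bliss_score_perk": syn.bliss_score,
        "max_bliss_excess_perk": float(syn.bliss_excess.max()),
    }


def timecourse(variant: ModelVariant, cobimetinib: float = 0.5,
               belvarafenib: float = 0.0, pre_h: float = 24.0,
               post_h: float = 8.0, dt: float = 0.1) -> dict:
    """Drug-free pre-run from steady state, then a post-dose time series.

    Default protocol: 24 h drug free, then 8 h under 0.5 µM Cobimetinib with
    0 or 0.133 µM Belvarafenib, sampled every 0.1 h.
    """
    base = steady_state(variant, 0.0, 0.0)
    if variant.uses_ras:
        y0 = np.array([base.ras_gtp, base.raf_dimer, base.raf_feedback_phos,
                       base.pmek, base.perk])
    else:
        y0 = np.array([base.pmek, base.perk])

    rhs0, _, _ = _rhs(variant, 0.0, 0.0)
    t_pre = np.arange(0.0, pre_h + dt / 2, dt)
    sol_pre = solve_ivp(rhs0, (0.0, pre_h), y0, t_eval=t_pre, method="LSODA",
                        rtol=1e-8, atol=1e-10)
    rhs1, _, _ = _rhs(variant, belvarafenib, cobimetinib)
    t_post = np.arange(0.0, post_h + dt / 2, dt)
    sol_post = solve_ivp(rhs1, (0.0, post_h), sol_pre.y[:, -1], t_eval=t_post,
                         method="LSODA", rtol=1e-8, atol=1e-10)
    if not (sol_pre.success and sol_post.success):  # pragma: no cover
        raise ConvergenceError("timecourse integration failed")
    times = np.concatenate([t_pre - pre_h, t_post])
    y = np.concatenate([sol_pre.y, sol_post.y], axis=1)
    m_idx, e_idx = (3, 4) if variant.uses_ras else (0, 1)
    return {
        "times_h": times,  # 0 = dosing time
        "pmek": y[m_idx],
        "perk": y[e_idx],
        "pmek_at_dose": float(sol_pre.y[m_idx, -1]),
        "pmek_final": float(sol_post.y[m_idx, -1]),
        "perk_final": float(sol_post.y[e_idx, -1]),
    }
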