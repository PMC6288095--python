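"""Glomerular hemodynamics: Starling filtration and the renal pressure
profile.

The renal vasculature is a single preafferent resistance vessel feeding N
parallel nephrons (afferent arteriole -> glomerulus -> efferent arteriole
-> peritubular capillary -> vein at 0 mmHg).  Filtrate leaves the plasma
stream at the glomerulus; reabsorbed fluid is recovered by the peritubular
capillaries, so the peritubular segment carries renal blood flow minus
urine output.  Single-nephron GFR follows Starling's law

    SNGFR = K_f * (P_gc - P_Bow - pi_go_avg)

with total GFR = SNGFR * N_active.  Bowman's-space pressure scales with
proximal tubular outflow (a tubular outflow resistance), and the mean
capillary oncotic pressure is the flow-integral average of the
Landis-Pappenheimer relation along the capillary.

`vascular_pressure_profile` solves the coupled algebraic system (renal
blood flow and SNGFR) for one instant, given the systemic pressure, the
current injury/adaptation state and the regulatory signals; it is the
quasi-static inner solve of the disease simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import albumin as alb
from . import homeostasis as homeo
from . import tubules, units

#: Landis-Pappenheimer coefficients, mmHg/(g/dl) and mmHg/(g/dl)^2
LANDIS_A = 2.1
LANDIS_B = 0.16

#: filtration-fraction ceiling (physiological-range guard)
FF_MAX = 0.9

#: Bowman's-space pressure responds to tubular flow: a blend of the
#: Bowman's/PT inflow (SNGFR) and the PT outflow (reabsorption lowers
#: downstream tubular pressure -- the net-filtration-pressure assist of
#: proximal hyper-reabsorption)
PBOW_INFLOW_WEIGHT = 0.5


class PhysiologicalRangeError(ValueError):
    """Input outside the validity range of a closure (e.g. FF >= 0.9)."""


class ConvergenceError(RuntimeError):
    """The algebraic network solve failed; carries the residual report."""


def single_nephron_gfr(k_f: float, p_gc: float, p_bow: float,
                       pi_go_avg: float) -> float:
    """Starling filtration, nl/min; floored at 0 (filtration equilibrium)."""
    if k_f <= 0:
        raise ValueError("K_f must be positive")
    return max(k_f * (p_gc - p_bow - pi_go_avg), 0.0)


def total_gfr(sngfr: float, n_active: float) -> float:
    """Whole-animal GFR, ml/min (SNGFR nl/min times active nephrons)."""
    if n_active < 0:
        raise ValueError("nephron count must be nonnegative")
    return sngfr * n_active * units.NL_TO_ML


def oncotic_pressure_avg(c_p: float, filtration_fraction: float,
                         a: float = LANDIS_A, b: float = LANDIS_B) -> float:
    """Mean glomerular capillary oncotic pressure, mmHg.

    Protein concentration rises along the capillary from C_p at the
    afferent end to C_p/(1-FF) at the efferent end as protein-free filtrate
    leaves; with plasma flow declining linearly in filtered volume, the
    flow-integral average of pi(C) = a*C + b*C^2 is

        pi_avg = a*C_p * (-ln(1-FF)/FF) + b*C_p^2 / (1-FF)

    which reduces to pi(C_p) as FF -> 0 and is monotone increasing in both
    C_p and FF.
    """
    if c_p < 0:
        raise ValueError("protein concentration must be nonnegative")
    if not 0.0 <= filtration_fraction < FF_MAX:
        raise PhysiologicalRangeError(
            f"filtration fraction {filtration_fraction:.3f} outside [0, {FF_MAX})")
    ff = filtration_fraction
    if ff < 1e-12:
        return a * c_p + b * c_p * c_p
    return (a * c_p * (-math.log1p(-ff) / ff)
            + b * c_p * c_p / (1.0 - ff))


@dataclass(frozen=True)
class GlomerularState:
    """Algebraic outputs of one network solve."""

    P_gc: float
    P_Bow: float
    pi_go_avg: float
    K_f: float
    SNGFR: float
    GFR: float            # ml/min
    RBF: float            # ml/min
    filtration_fraction: float


@dataclass(frozen=True)
class OperatingPoint:
    """Self-consistent hemodynamic + tubular + albumin snapshot."""

    MAP: float
    glomerular: GlomerularState
    # tubular (per nephron mg/min or mmol/min; whole-animal urine rates)
    phi_glu_filtered: float
    phi_glu_reabs: float
    R_UGE_total: float          # mg/min whole animal
    eta_pt: float               # fractional PT Na+ reabsorption
    phi_na_filtered: float
    phi_na_reabs_pt: float
    phi_na_out_pt: float
    distal: tubules.DistalOutcome
    urine_na: float             # mmol/min whole animal
    urine_water: float          # L/min whole animal
    # albumin
    phi_alb_filtered: float
    phi_alb_reabs: float
    UAER: float                 # mg/min whole animal
    # regulation multipliers
    mu_tgf: float
    mu_myo: float
    mu_rihp: float
    mu_vp: float
    mu_aldo: float
    N_active: float


def vascular_pressure_profile(
    p,
    reg: homeo.RegulationParams,
    *,
    MAP: float,
    C_Na: float,
    N_active: float,
    K_f: float,
    K_albumin: float,
    dD_aa: float = 0.0,
    BG: float | None = None,
    RT_G: float | None = None,
    warm_start: tuple[float, float] | None = None,
) -> OperatingPoint:
    """Solve the renal series/parallel network for one instant.

    Parameters
    ----------
    p : calibrated SpeciesParameters
    reg : regulatory gains
    MAP : systemic mean arterial pressure, mmHg
    C_Na : plasma Na+ concentration, mmol/L
    N_active : active nephron count (after loss and nephrectomy)
    K_f, K_albumin : current ultrafiltration and sieving coefficients
    dD_aa : fractional afferent diameter increase (Poiseuille: the afferent
        resistance scales as 1/(1+dD_aa)^4)
    BG, RT_G : plasma glucose and glucose threshold, mg/dl (default nominal)
    warm_start : (RBF L/min, SNGFR nl/min) initial guess

    Returns a fully self-consistent OperatingPoint.  Raises
    ConvergenceError with the residual vector if the solve fails.
    """
    if MAP <= 0 or min(p.R_prea, p.R_aff, p.R_eff, p.R_peri) <= 0:
        raise ValueError("MAP and all resistances must be positive")
    bg = p.C_glu_nom if BG is None else BG
    rt_g = p.RT_G_nom if RT_G is None else RT_G

    eta_pt = tubules.pt_na_fraction(p.eta_pt_nonSGLT2, bg, rt_g, C_Na)
    mu_myo = homeo.myogenic_autoregulation(MAP, p.MAP_nom, reg)
    mu_rihp = homeo.rihp_natriuresis(MAP, p.MAP_nom, reg)
    mu_vp = homeo.vasopressin_signal(C_Na, p.C_Na, reg)
    f_dw_eff = min(max(p.f_dw * mu_vp, 0.0), 0.999)
    aff_dilation = (1.0 + dD_aa) ** 4
    hct = p.hematocrit

    def parts(x):
        q = x[0] * p.RBF_nom            # L/min
        s = x[1] * p.SNGFR_nom          # nl/min
        phi_md = s * units.NL_TO_L * C_Na * (1.0 - eta_pt) * (1.0 - p.f_loop)
        mu_tgf = homeo.tubuloglomerular_feedback(max(phi_md, 0.0),
                                                 p.phi_md_nom, reg)
        r_aff = p.R_aff * mu_tgf / aff_dilation
        p_gc = MAP - q * (p.R_prea * mu_myo + r_aff)
        gfr_l = s * N_active * units.NL_TO_L
        u_w = s * (1.0 - eta_pt) * (1.0 - f_dw_eff) * N_active * units.NL_TO_L
        plasma_single = q * (1.0 - hct) / N_active / units.NL_TO_L
        ff = min(max(s / plasma_single, 0.0), FF_MAX - 0.01)
        p_bow = p.P_Bow_nom * (
            PBOW_INFLOW_WEIGHT * s / p.SNGFR_nom
            + (1.0 - PBOW_INFLOW_WEIGHT) * s * (1.0 - eta_pt) / p.q_ptw_nom)
        pi = oncotic_pressure_avg(p.C_p, ff)
        return q, s, phi_md, mu_tgf, p_gc, gfr_l, u_w, ff, p_bow, pi

    def residual(x):
        q, s, _, _, p_gc, gfr_l, u_w, ff, p_bow, pi = parts(x)
        p_gc_down = (q - gfr_l) * p.R_eff + (q - u_w) * p.R_peri
        s_starling = K_f * max(p_gc - p_bow - pi, 0.0)
        return np.array([(p_gc - p_gc_down) / p.MAP_nom,
                         (s - s_starling) / p.SNGFR_nom])

    guesses = []
    if warm_start is not None:
        guesses.append((warm_start[0] / p.RBF_nom, warm_start[1] / p.SNGFR_nom))
    guesses += [(1.0, 1.0), (1.3, 1.5), (0.7, 0.7), (2.0, 2.0)]
    sol = None
    for x0 in guesses:
        trial = optimize.root(residual, np.asarray(x0), method="hybr",
                              options={"xtol": 1e-12})
        if trial.success and np.max(np.abs(trial.fun)) < 1e-8 and \
                min(trial.x) > 0:
            sol = trial
            break
    if sol is None:
        raise ConvergenceError(
            f"renal network solve failed at MAP={MAP:.2f}: residuals "
            f"{residual(np.array(guesses[0]))}")

    q, s, phi_md, mu_tgf, p_gc, gfr_l, u_w, ff, p_bow, pi = parts(sol.x)
    mu_aldo = homeo.aldosterone_signal(phi_md, p.phi_md_nom, reg)

    # glucose
    phi_glu_f = tubules.filtered_glucose(s, bg)
    cap = tubules.glucose_reabsorption_capacity(rt_g, s)
    phi_glu_r, r_uge = tubules.glucose_reabsorbed_and_excreted(phi_glu_f, cap)
    # proximal sodium
    phi_na_reabs, phi_na_out = tubules.pt_sodium_handling(
        s, C_Na, phi_glu_r, p.eta_pt_nonSGLT2)
    phi_na_f = s * units.NL_TO_L * C_Na
    # distal segments and urine
    water_out_pt = s * (1.0 - eta_pt)
    distal = tubules.distal_segment_transport(
        phi_na_out, water_out_pt, N_active,
        f_loop=p.f_loop, f_dct=p.f_dct, f_cd=p.f_cd, f_dw=p.f_dw,
        rihp_multiplier=mu_rihp, aldo_multiplier=mu_aldo,
        vasopressin_multiplier=mu_vp)
    # albumin
    phi_alb_f = alb.filtered_albumin(min(K_albumin, 1.0), s, p.C_albumin)
    rc = p.RC_albumin if p.rc_albumin_per_nephron else p.RC_albumin / N_active
    phi_alb_r, uaer = alb.albumin_reabs_and_uaer(
        phi_alb_f, p.eta_albumin, rc, N_active)

    glom = GlomerularState(
        P_gc=p_gc, P_Bow=p_bow, pi_go_avg=pi, K_f=K_f, SNGFR=s,
        GFR=total_gfr(s, N_active), RBF=q * 1e3, filtration_fraction=ff)
    return OperatingPoint(
        MAP=MAP, glomerular=glom,
        phi_glu_filtered=phi_glu_f, phi_glu_reabs=phi_glu_r,
        R_UGE_total=r_uge * N_active, eta_pt=eta_pt,
        phi_na_filtered=phi_na_f, phi_na_reabs_pt=phi_na_reabs,
        phi_na_out_pt=phi_na_out, distal=distal,
        urine_na=distal.urine_na, urine_water=distal.urine_water,
        phi_alb_filtered=phi_alb_f, phi_alb_reabs=phi_alb_r, UAER=uaer,
        mu_tgf=mu_tgf, mu_myo=mu_myo, mu_rihp=mu_rihp, mu_vp=mu_vp,
        mu_aldo=mu_aldo, N_active=N_active)
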