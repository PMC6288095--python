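"""Tubular transport: glucose handling and SGLT2-coupled Na+ reabsorption.

Glucose is freely filtered and reabsorbed in the proximal tubule up to a
capacity that scales with filtration (so the threshold RT_G is expressed in
concentration units); the excess is excreted.  Proximal Na+ reabsorption is
the sum of a fixed non-SGLT2 fraction and the SGLT2 term, which equals the
molar glucose reabsorption rate (1 Na+ per glucose).  Downstream segments
(loop of Henle, distal convoluted tubule, connecting tubule/collecting
duct) reabsorb fixed fractions of their inflow, modulated by regulatory
signals; urine is whatever is left, times the number of active nephrons.

All per-nephron rates: glucose/albumin mg/min, Na+ mmol/min, water nl/min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import units

logger = logging.getLogger(__name__)


def filtered_glucose(sngfr: float, c_glu: float) -> float:
    """Filtered glucose load, mg/min per nephron (SNGFR nl/min, C mg/dl)."""
    if c_glu < 0:
        raise ValueError("plasma glucose must be nonnegative")
    return sngfr * units.NL_TO_DL * c_glu


def glucose_reabsorption_capacity(rt_g: float, sngfr: float) -> float:
    """Proximal glucose reabsorption capacity, mg/min per nephron.

    Scales with SNGFR so that the renal threshold RT_G is a concentration:
    glycosuria starts exactly when plasma glucose exceeds RT_G.
    """
    if rt_g <= 0:
        raise ValueError("RT_G must be positive")
    return rt_g * sngfr * units.NL_TO_DL


def glucose_reabsorbed_and_excreted(
    filtered: float, capacity: float
) -> tuple[float, float]:
    """(reabsorbed, excreted) glucose, mg/min per nephron."""
    if filtered < 0 or capacity < 0:
        raise ValueError("glucose rates must be nonnegative")
    reabs = min(filtered, capacity)
    return reabs, filtered - reabs


def pt_na_fraction(eta_non_sglt2: float, c_glu: float, rt_g: float,
                   c_na: float, cap: float = 0.98) -> float:
    """Total fractional proximal Na+ reabsorption at plasma glucose c_glu.

    The SGLT2 term is the reabsorbed glucose concentration converted to
    mmol/L over plasma Na+; it is independent of SNGFR because capacity
    scales with filtration.  Clamped at ``cap`` (saturation guard).
    """
    sglt2 = min(c_glu, rt_g) * units.MGDL_TO_MMOLL / c_na
    eta = eta_non_sglt2 + sglt2
    if eta > cap:
        logger.debug("PT Na+ reabsorption fraction %.3f clamped to %.2f",
                     eta, cap)
        eta = cap
    return eta


def pt_sodium_handling(
    sngfr: float, c_na: float, phi_glu_reabs: float, eta_non_sglt2: float
) -> tuple[float, float]:
    """Proximal-tubule Na+ handling, mmol/min per nephron.

    Returns (phi_Na_reabs_PT, phi_Na_out_PT): filtered load times the
    non-SGLT2 fraction, plus the SGLT2-coupled term equal to the molar
    glucose reabsorption rate (MW 180, 1:1 stoichiometry), and the Na+ flow
    leaving the proximal tubule.  Total reabsorption is clamped to the
    filtered load with a logged warning if the SGLT2 term would exceed it.
    """
    phi_filtered = sngfr * units.NL_TO_L * c_na
    phi_sglt2 = phi_glu_reabs / units.GLUCOSE_MW  # mg/min -> mmol/min
    phi_reabs = phi_filtered * eta_non_sglt2 + phi_sglt2
    if phi_reabs > phi_filtered:
        logger.warning("PT Na+ reabsorption saturated at the filtered load")
        phi_reabs = phi_filtered
    return phi_reabs, phi_filtered - phi_reabs


@dataclass(frozen=True)
class DistalOutcome:
    """Per-nephron distal segment flows and whole-animal urine rates."""

    phi_na_loop_out: float      # mmol/min, into distal convoluted tubule
    phi_na_dct_out: float       # mmol/min, into collecting duct
    phi_na_urine_single: float  # mmol/min per nephron
    urine_na: float             # mmol/min, whole animal
    water_urine_single: float   # nl/min per nephron
    urine_water: float          # L/min, whole animal
    f_dct_eff: float
    f_cd_eff: float
    f_dw_eff: float


def distal_segment_transport(
    phi_na_out_pt: float,
    water_out_pt: float,
    n_active: float,
    *,
    f_loop: float,
    f_dct: float,
    f_cd: float,
    f_dw: float,
    rihp_multiplier: float = 1.0,
    aldo_multiplier: float = 1.0,
    vasopressin_multiplier: float = 1.0,
) -> DistalOutcome:
    """Apply fractional reabsorption along the distal nephron.

    The loop of Henle reabsorbs Na+ without water (diluting segment); the
    renal-interstitial-pressure (RIHP) signal scales the distal convoluted
    tubule and collecting duct Na+ fractions (pressure natriuresis), the
    aldosterone-like signal scales the collecting duct only, and the
    vasopressin signal scales the distal water fraction.
    """
    if phi_na_out_pt < 0 or water_out_pt < 0:
        raise ValueError("distal inflows must be nonnegative")
    f_dct_eff = min(max(f_dct * rihp_multiplier, 0.0), 1.0)
    f_cd_eff = min(max(f_cd * rihp_multiplier * aldo_multiplier, 0.0), 1.0)
    f_dw_eff = min(max(f_dw * vasopressin_multiplier, 0.0), 0.999)

    phi_loop_out = phi_na_out_pt * (1.0 - f_loop)
    phi_dct_out = phi_loop_out * (1.0 - f_dct_eff)
    phi_urine = phi_dct_out * (1.0 - f_cd_eff)
    water_urine = water_out_pt * (1.0 - f_dw_eff)
    return DistalOutcome(
        phi_na_loop_out=phi_loop_out,
        phi_na_dct_out=phi_dct_out,
        phi_na_urine_single=phi_urine,
        urine_na=phi_urine * n_active,
        water_urine_single=water_urine,
        urine_water=water_urine * n_active * units.NL_TO_L,
        f_dct_eff=f_dct_eff,
        f_cd_eff=f_cd_eff,
        f_dw_eff=f_dw_eff,
    )
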