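"""Albumin filtration, capacity-limited reabsorption, and excretion.

A small fraction (the sieving coefficient K_albumin) of plasma albumin
crosses the glomerular barrier; the proximal tubule recovers a fraction
eta_albumin of the filtered load up to an absolute per-nephron capacity
RC_albumin, and the remainder is excreted.  The urinary albumin excretion
rate (UAER) is therefore piecewise-linear and convex in the filtered load,
with a kink where eta*filtered = RC_albumin — the point where proteinuria
starts accelerating.
"""

from __future__ import annotations

from . import units


def filtered_albumin(k_albumin: float, sngfr: float, c_albumin: float) -> float:
    """Filtered albumin, mg/min per nephron.

    k_albumin dimensionless sieving coefficient, SNGFR nl/min,
    c_albumin g/dl plasma albumin.
    """
    if not 0.0 <= k_albumin <= 1.0:
        raise ValueError("sieving coefficient must lie in [0, 1]")
    if c_albumin < 0:
        raise ValueError("plasma albumin must be nonnegative")
    return k_albumin * sngfr * units.NL_TO_DL * c_albumin * units.MG_PER_G


def albumin_reabs_and_uaer(
    filtered: float, eta_albumin: float, rc_albumin: float, n_active: float
) -> tuple[float, float]:
    """(reabsorbed mg/min per nephron, UAER mg/min whole animal)."""
    if min(filtered, eta_albumin, rc_albumin, n_active) < 0:
        raise ValueError("albumin inputs must be nonnegative")
    reabs = min(filtered * eta_albumin, rc_albumin)
    return reabs, (filtered - reabs) * n_active


def uaer_ug_per_day(uaer_mg_min: float) -> float:
    """Convert whole-animal UAER from mg/min to ug/day (plot units)."""
    return uaer_mg_min * units.MIN_PER_DAY * 1000.0
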