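"""Systemic Na+/water homeostasis and regulatory feedback signals.

The cardiovascular loop: urinary excretion and intake set the body Na+
store and extracellular fluid (ECF) volume; blood volume is a fixed
fraction of ECF; cardiac output is a saturating increasing function of
blood volume anchored at the species baseline; MAP = CO * R_tpr with the
venous pressure taken as 0.  Plasma Na+ concentration is body Na+ over
ECF.

Regulatory signals are bounded sigmoids anchored at 1 at the calibrated
baseline:

* tubuloglomerular feedback (TGF): macula-densa Na+ delivery above nominal
  constricts the afferent arteriole (multiplier > 1), below nominal
  dilates it;
* myogenic autoregulation: preafferent resistance rises with perfusion
  pressure, buffering transmission of systemic pressure to the glomerulus;
* RIHP pressure natriuresis: distal fractional Na+ reabsorption falls as
  renal perfusion pressure rises — the integral controller that makes
  long-run excretion track intake;
* vasopressin: distal water reabsorption rises with plasma Na+, defending
  its set point;
* an aldosterone-like signal: collecting-duct reabsorption rises when
  distal Na+ delivery falls (minimal stand-in for the RAAS axis).

Gain magnitudes are calibration parameters (see docs/methods.md); only the
baseline anchoring and the sign of each response are structural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class RegulationParams:
    """Gains (dimensionless amplitude) and widths (relative-deviation scale)
    of the bounded regulatory sigmoids, plus the CO-volume relation."""

    tgf_gain: float = 0.3
    tgf_width: float = 0.3
    myo_gain: float = 0.5
    myo_width: float = 0.25
    rihp_gain: float = 0.68
    rihp_width: float = 0.35
    vp_gain: float = 0.9
    vp_width: float = 0.02
    aldo_gain: float = 0.1
    aldo_width: float = 0.5
    co_gain: float = 0.8
    co_width: float = 0.8

    def disabled(self) -> "RegulationParams":
        """Copy with all renal feedback gains zeroed (CO relation kept)."""
        return RegulationParams(
            tgf_gain=0.0, myo_gain=0.0, rihp_gain=0.0, vp_gain=0.0,
            aldo_gain=0.0, co_gain=self.co_gain, co_width=self.co_width)


def _sigmoid(rel_dev: float, gain: float, width: float) -> float:
    return 1.0 + gain * math.tanh(rel_dev / width)


def tubuloglomerular_feedback(phi_md: float, phi_md_nom: float,
                              reg: RegulationParams) -> float:
    """Afferent-resistance multiplier from macula-densa Na+ flow."""
    if phi_md < 0:
        raise ValueError("macula-densa Na+ flow must be nonnegative")
    return _sigmoid(phi_md / phi_md_nom - 1.0, reg.tgf_gain, reg.tgf_width)


def myogenic_autoregulation(pressure: float, pressure_nom: float,
                            reg: RegulationParams) -> float:
    """Preafferent-resistance multiplier from perfusion pressure."""
    return _sigmoid(pressure / pressure_nom - 1.0, reg.myo_gain, reg.myo_width)


def rihp_natriuresis(pressure: float, pressure_nom: float,
                     reg: RegulationParams) -> float:
    """Distal-reabsorption multiplier; decreasing in perfusion pressure."""
    return _sigmoid(pressure / pressure_nom - 1.0, -reg.rihp_gain,
                    reg.rihp_width)


def vasopressin_signal(c_na: float, c_na_nom: float,
                       reg: RegulationParams) -> float:
    """Distal water-reabsorption multiplier; increasing in plasma Na+."""
    return _sigmoid(c_na / c_na_nom - 1.0, reg.vp_gain, reg.vp_width)


def aldosterone_signal(phi_md: float, phi_md_nom: float,
                       reg: RegulationParams) -> float:
    """Collecting-duct reabsorption multiplier; rises when delivery falls."""
    return _sigmoid(1.0 - phi_md / phi_md_nom, reg.aldo_gain, reg.aldo_width)


def cardiac_output(blood_volume: float, blood_volume_nom: float,
                   co_nom: float, reg: RegulationParams) -> float:
    """Saturating increasing CO(volume), anchored at CO_nom at V_nom."""
    if blood_volume <= 0:
        raise ValueError("blood volume must be positive")
    return co_nom * _sigmoid(blood_volume / blood_volume_nom - 1.0,
                             reg.co_gain, reg.co_width)


def map_from_co(co: float, r_tpr: float) -> float:
    """Mean arterial pressure from cardiac output (venous pressure 0)."""
    return co * r_tpr


def sodium_balance_ode(na_in: float, urinary_na: float) -> float:
    """d(body Na+)/dt, both rates in the same units (e.g. mmol/day)."""
    if na_in < 0 or urinary_na < 0:
        raise ValueError("rates must be nonnegative")
    return na_in - urinary_na


def water_balance_ode(wa_in: float, urine_volume: float) -> float:
    """d(ECF)/dt, both rates in the same units (e.g. L/day)."""
    if wa_in < 0 or urine_volume < 0:
        raise ValueError("rates must be nonnegative")
    return wa_in - urine_volume
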