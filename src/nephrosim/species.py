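"""Species parameter records and circulation calibration.

Each shipped species record carries three blocks: parameters that differ by
species (nephron number, intakes, tubule length, plasma protein), parameters
conserved across species (per-nephron ultrafiltration coefficient, sieving
coefficient, arteriole/tubule diameters, plasma Na+ and glucose, glucose
threshold, non-SGLT2 proximal fraction), and calculated parameters — the
vascular resistances and tubular closure fractions, which are not hand-set
but calibrated so that the species' normal phenotype is a steady state of
the closed-loop model by construction.

Calibration conventions:

* venous pressure is 0 mmHg, so total peripheral resistance R_tpr = MAP/CO;
* the single-nephron filtration rate is the anchor: the implied net
  filtration pressure is SNGFR/K_f0, which (with the oncotic closure) fixes
  the nominal Bowman's-space pressure;
* the tabulated preafferent and peritubular resistances are used as anchors
  and the afferent/efferent resistances close the pressure profile, with
  reabsorbed fluid returned to the peritubular capillary stream.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from . import units
from .hemodynamics import oncotic_pressure_avg

SPECIES_IDS = ("human", "rat", "mouse")

#: distal fractional Na+ reabsorption, loop of Henle and distal convoluted
#: tubule; the collecting-duct fraction is calibrated per species so that
#: baseline urinary Na+ equals intake (the homeostatic closure).
F_LOOP = 0.80
F_DCT = 0.50

#: systemic hematocrit used to convert blood flow to plasma flow
HEMATOCRIT = 0.45

#: blood volume as a fixed fraction of extracellular fluid volume
BLOOD_VOLUME_FRACTION = 0.25


class ConfigurationError(ValueError):
    """Unknown species or malformed species record."""


class CalibrationError(ValueError):
    """Phenotype targets are infeasible for the circulation closure."""


@dataclass(frozen=True)
class PhenotypeTargets:
    """Table of observed/simulated phenotype values for one species.

    MAP mmHg, CO L/min, RBF ml/min, GFR ml/min, SNGFR nl/min, P_gc mmHg,
    Na_ex mEq/day.  At steady state Na_ex equals Na_in.
    """

    MAP: float
    CO: float
    RBF: float
    GFR: float
    SNGFR: float
    P_gc: float
    Na_ex: float

    def __post_init__(self):
        for name in ("MAP", "CO", "RBF", "GFR", "SNGFR", "P_gc", "Na_ex"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"target {name} must be positive")


@dataclass
class SpeciesParameters:
    """Full parameter record for one species (two-kidney baseline)."""

    species_id: str
    # --- differ by species ---
    N_nephrons: float
    Na_in: float            # mmol/day
    Wa_in: float            # L/day
    L_pt: float             # mm
    C_p: float              # g/dl total plasma protein
    ECF_nom: float          # L
    # --- conserved across species ---
    C_glu_nom: float = 90.0     # mg/dl
    C_Na: float = 140.0         # mmol/L
    K_f0: float = 3.9           # nl/min/mmHg
    K_albumin0: float = 0.0006
    RC_albumin: float = 2.5e-6  # mg/min per nephron
    D_eff: float = 10.5         # um
    D_aff: float = 14.0         # um
    D_pt: float = 27.0          # um
    RT_G_nom: float = 180.0     # mg/dl
    eta_pt_nonSGLT2: float = 0.76
    # --- albumin handling (not tabulated; see docs/methods.md) ---
    eta_albumin: float = 0.99
    albumin_fraction_of_protein: float = 0.6
    rc_albumin_per_nephron: bool = True
    # --- physical conventions ---
    hematocrit: float = HEMATOCRIT
    blood_volume_fraction: float = BLOOD_VOLUME_FRACTION
    f_loop: float = F_LOOP
    f_dct: float = F_DCT
    # --- phenotype targets (calibration inputs) ---
    targets: PhenotypeTargets | None = None
    # --- tabulated resistance anchors ---
    R_prea_anchor: float = 0.0
    R_peri_anchor: float = 0.0
    R_rvr_anchor: float = 0.0
    # --- calculated (calibrated) parameters, populated by calibrate_circulation ---
    R_tpr: float = 0.0
    R_prea: float = 0.0
    R_aff: float = 0.0
    R_eff: float = 0.0
    R_peri: float = 0.0
    P_gc0: float = 0.0          # damage-signal reference pressure, mmHg
    P_Bow_nom: float = 0.0      # nominal Bowman's-space pressure, mmHg
    pi_go_avg_nom: float = 0.0
    f_cd: float = 0.0           # collecting-duct Na+ fraction (calibrated)
    f_dw: float = 0.0           # distal water reabsorption fraction (calibrated)
    # nominal anchors for regulatory signals (all signals = 1 here)
    SNGFR_nom: float = 0.0      # nl/min
    GFR_nom: float = 0.0        # ml/min
    RBF_nom: float = 0.0        # L/min
    MAP_nom: float = 0.0
    CO_nom: float = 0.0
    phi_md_nom: float = 0.0     # macula-densa Na+ flow, mmol/min per nephron
    phi_cd_nom: float = 0.0     # collecting-duct Na+ inflow, mmol/min per nephron
    q_ptw_nom: float = 0.0      # water flow out of PT, nl/min per nephron
    eta_pt_nom: float = 0.0     # total nominal fractional PT Na+ reabsorption
    M_Na_nom: float = 0.0       # extracellular Na+ store, mmol
    calibrated: bool = False

    @property
    def C_albumin(self) -> float:
        """Plasma albumin concentration, g/dl (fraction of total protein)."""
        return self.albumin_fraction_of_protein * self.C_p

    @property
    def R_rvr(self) -> float:
        """Total renal vascular resistance (series sum), mmHg*min/L."""
        return self.R_prea + self.R_aff + self.R_eff + self.R_peri

    @property
    def blood_volume_nom(self) -> float:
        return self.blood_volume_fraction * self.ECF_nom

    def validate(self) -> None:
        positive = (
            "N_nephrons Na_in Wa_in L_pt C_p ECF_nom C_glu_nom C_Na K_f0 "
            "RC_albumin D_eff D_aff D_pt RT_G_nom"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("K_albumin0", "eta_pt_nonSGLT2", "eta_albumin",
                     "hematocrit", "blood_volume_fraction", "f_loop", "f_dct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.RT_G_nom < self.C_glu_nom:
            raise ConfigurationError(
                "RT_G_nom below nominal glucose: baseline glycosuria")
        if self.calibrated:
            for name in ("R_tpr", "R_prea", "R_aff", "R_eff", "R_peri"):
                if getattr(self, name) <= 0:
                    raise ConfigurationError(f"calibrated {name} not positive")


def _record_from_dict(raw: dict) -> SpeciesParameters:
    try:
        p = SpeciesParameters(
            species_id=raw["species_id"],
            **raw["differs"],
            **raw["conserved"],
        )
        anchors = raw["resistance_anchors"]
        p.R_prea_anchor = float(anchors["R_prea"])
        p.R_peri_anchor = float(anchors["R_peri"])
        p.R_rvr_anchor = float(anchors.get("R_rvr", 0.0))
        p.targets = PhenotypeTargets(**raw["targets"])
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed species record: {exc}") from exc
    return p


def load_species_parameters(species_id: str) -> SpeciesParameters:
    """Load the packaged record for ``species_id`` and calibrate it.

    Parameters
    ----------
    species_id : {"human", "rat", "mouse"}

    Returns
    -------
    SpeciesParameters with the calculated resistance and tubular-closure
    block populated (``calibrated`` is True).
    """
    if species_id not in SPECIES_IDS:
        raise ConfigurationError(
            f"unknown species {species_id!r}; expected one of {SPECIES_IDS}")
    text = resources.files("nephrosim.data").joinpath(f"{species_id}.yaml").read_text()
    p = _record_from_dict(yaml.safe_load(text))
    p.validate()
    return calibrate_circulation(p, p.targets)


def total_pt_na_fraction(p: SpeciesParameters, c_glu: float, rt_g: float) -> float:
    """Fractional proximal-tubule Na+ reabsorption at plasma glucose c_glu.

    Non-SGLT2 fraction plus the SGLT2 term: glucose reabsorbed per unit
    filtrate, in molar units, relative to plasma Na+ (1:1 stoichiometry).
    """
    c_glu_reabs = min(c_glu, rt_g)  # mg/dl, capacity scales with SNGFR
    sglt2 = (c_glu_reabs * units.MGDL_TO_MMOLL) / p.C_Na
    return min(p.eta_pt_nonSGLT2 + sglt2, 0.98)


def calibrate_circulation(
    fixed: SpeciesParameters, targets: PhenotypeTargets
) -> SpeciesParameters:
    """Populate the calculated resistance/closure block from the phenotype.

    Closed-form and idempotent: the calibrated record evaluated at the
    targets is self-consistent (MAP = CO*R_tpr with venous pressure 0;
    the renal pressure profile reproduces P_gc and RBF; Starling's law at
    target P_gc returns the target SNGFR; urinary Na+ and water equal the
    intakes).  Raises CalibrationError when the targets are infeasible.
    """
    p = copy.deepcopy(fixed)
    p.targets = targets
    t = targets

    p.R_tpr = t.MAP / t.CO
    p.MAP_nom, p.CO_nom = t.MAP, t.CO
    p.SNGFR_nom = t.SNGFR
    p.GFR_nom = t.SNGFR * p.N_nephrons * units.NL_TO_ML  # per-nephron identity
    rbf = t.RBF * 1e-3                                    # L/min
    p.RBF_nom = rbf
    gfr = p.GFR_nom * 1e-3                                # L/min

    # Starling closure: net filtration pressure implied by the SNGFR anchor.
    nfp = t.SNGFR / p.K_f0
    plasma_flow_single = rbf * (1.0 - p.hematocrit) / p.N_nephrons / units.NL_TO_L
    ff = t.SNGFR / plasma_flow_single
    if not 0.0 <= ff < 0.9:
        raise CalibrationError(
            f"{p.species_id}: implied filtration fraction {ff:.3f} outside "
            "the physiological range [0, 0.9); targets infeasible")
    p.pi_go_avg_nom = oncotic_pressure_avg(p.C_p, ff)
    p.P_Bow_nom = t.P_gc - p.pi_go_avg_nom - nfp
    if p.P_Bow_nom <= 0:
        raise CalibrationError(
            f"{p.species_id}: implied Bowman pressure {p.P_Bow_nom:.2f} mmHg "
            f"<= 0 (net filtration pressure {nfp:.2f}, oncotic "
            f"{p.pi_go_avg_nom:.2f} at FF {ff:.3f}); targets infeasible")
    p.P_gc0 = t.P_gc

    # Pressure profile: MAP -> preafferent -> afferent -> glomerulus.
    p.R_prea = p.R_prea_anchor
    p.R_aff = (t.MAP - t.P_gc) / rbf - p.R_prea
    if p.R_aff <= 0:
        raise CalibrationError(
            f"{p.species_id}: preafferent anchor exceeds total preglomerular "
            "resistance budget")
    # Downstream: efferent carries RBF-GFR; peritubular recovers reabsorbed
    # fluid, carrying RBF minus urine flow out to the (0 mmHg) vein.
    urine_w = p.Wa_in / units.MIN_PER_DAY                 # L/min
    p.R_peri = p.R_peri_anchor
    p.R_eff = (t.P_gc - (rbf - urine_w) * p.R_peri) / (rbf - gfr)
    if p.R_eff <= 0:
        raise CalibrationError(
            f"{p.species_id}: peritubular anchor exceeds the postglomerular "
            "pressure budget")

    # Tubular closure: collecting-duct Na+ fraction from Na+ balance.
    p.eta_pt_nom = total_pt_na_fraction(p, p.C_glu_nom, p.RT_G_nom)
    phi_filt = t.SNGFR * units.NL_TO_L * p.C_Na           # mmol/min per nephron
    phi_out_pt = phi_filt * (1.0 - p.eta_pt_nom)
    p.phi_md_nom = phi_out_pt * (1.0 - p.f_loop)
    p.phi_cd_nom = p.phi_md_nom * (1.0 - p.f_dct)
    na_in_rate = p.Na_in / units.MIN_PER_DAY              # mmol/min
    frac_urine = na_in_rate / (p.phi_cd_nom * p.N_nephrons)
    if not 0.0 < frac_urine < 1.0:
        raise CalibrationError(
            f"{p.species_id}: Na+ intake incompatible with distal delivery "
            f"(urine/CD-inflow fraction {frac_urine:.3f})")
    p.f_cd = 1.0 - frac_urine

    # Water: proximal reabsorption is isotonic (same fraction as Na+), the
    # loop reabsorbs Na+ without water (diluting segment), and a single
    # calibrated distal fraction closes urine volume to intake.
    p.q_ptw_nom = t.SNGFR * (1.0 - p.eta_pt_nom)          # nl/min per nephron
    distal_water = p.q_ptw_nom * units.NL_TO_L * p.N_nephrons  # L/min
    frac_w = urine_w / distal_water
    if not 0.0 < frac_w < 1.0:
        raise CalibrationError(
            f"{p.species_id}: water intake incompatible with distal delivery")
    p.f_dw = 1.0 - frac_w

    p.M_Na_nom = p.C_Na * p.ECF_nom
    p.calibrated = True
    p.validate()
    return p


def conserved_block(p: SpeciesParameters) -> dict:
    """The parameter subset shared identically by all shipped species."""
    return {
        name: getattr(p, name)
        for name in ("C_glu_nom", "C_Na", "K_f0", "K_albumin0", "RC_albumin",
                     "D_pt", "RT_G_nom", "eta_pt_nonSGLT2")
    }
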