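"""Pressure- and glucose-driven adaptation and injury dynamics.

Five slow state variables modify the glomerulus over weeks to months:

* dD_aa   — afferent arteriole dilatation (fraction of baseline diameter),
            driven by blood glucose above nominal, saturating at 25%;
* dSA     — glomerular hypertrophy (filtration surface area), driven by
            the glomerular-pressure damage signal, saturating at 50%;
* dPerm   — glomerulosclerosis (permeability loss), same driver, much
            slower, saturating at 100%;
* dNephrons — fraction of nephrons lost, same driver;
* dK_albumin — podocyte sieving damage, a *non-saturating* integrator of
            the damage signal (additive on the baseline sieving
            coefficient).

The damage signal is the relative glomerular pressure excess
max(P_gc/P_gc0 - 1, 0).  All five states are irreversible: rates are
nonnegative, so injury accumulates and never regresses.

Time constants are kept in the dimensionless units of the source
parameter table; ``time_unit_weeks`` converts them to simulation weeks
(chosen so hypertrophy reaches >=95% of its ceiling by week 12 of the
diabetic protocol while preserving the tabulated ratios between time
constants).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class InjuryParams:
    dD_aa_max: float = 0.25
    dSA_max: float = 0.50
    dPerm_max: float = 1.00
    tau_daa: float = 4.0e6        # per (mg/dl glucose excess) scale
    tau_sa: float = 750.0
    tau_perm: float = 4.0e4
    tau_nephron_loss: float = 1.5e5
    tau_albumin: float = 1.0e7    # much larger than the others (see methods)
    #: weeks per tabulated time-constant unit
    time_unit_weeks: float = 3.0e-4
    bg_nom: float = 90.0          # mg/dl


@dataclass
class InjuryState:
    """The five slow states; all start at 0 in health."""

    dD_aa: float = 0.0
    dSA: float = 0.0
    dPerm: float = 0.0
    dNephrons: float = 0.0
    dK_albumin: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.dD_aa, self.dSA, self.dPerm,
                         self.dNephrons, self.dK_albumin])

    @classmethod
    def from_array(cls, x) -> "InjuryState":
        return cls(*map(float, x))

    def validate(self, params: InjuryParams, tol: float = 1e-9) -> None:
        bounds = [(self.dD_aa, params.dD_aa_max), (self.dSA, params.dSA_max),
                  (self.dPerm, params.dPerm_max), (self.dNephrons, 1.0)]
        for value, upper in bounds:
            if not -tol <= value <= upper + tol:
                raise ValueError(f"injury state {value} outside [0, {upper}]")
        if self.dK_albumin < -tol:
            raise ValueError("sieving damage must be nonnegative")


@dataclass(frozen=True)
class InjurySwitches:
    """Per-mechanism on/off switches (protocol arms)."""

    dilatation: bool = True
    hypertrophy: bool = True
    sclerosis: bool = True
    nephron_loss: bool = True
    sieving: bool = True

    @classmethod
    def all_off(cls) -> "InjurySwitches":
        return cls(False, False, False, False, False)

    @classmethod
    def adaptive_only(cls) -> "InjurySwitches":
        """Dilatation + hypertrophy on; sclerosis/loss/sieving off."""
        return cls(True, True, False, False, False)


def damage_signal(p_gc: float, p_gc0: float) -> float:
    """Relative glomerular pressure excess, clamped at 0."""
    if p_gc0 <= 0:
        raise ValueError("reference pressure must be positive")
    return max(p_gc / p_gc0 - 1.0, 0.0)


def afferent_dilatation_rate(dD_aa: float, bg: float,
                             params: InjuryParams) -> float:
    """d(dD_aa)/dt in tabulated time units; glucose-driven, saturating."""
    if bg < 0:
        raise ValueError("blood glucose must be nonnegative")
    drive = max(bg - params.bg_nom, 0.0)
    return max(params.dD_aa_max - dD_aa, 0.0) * drive / params.tau_daa


def hypertrophy_rate(dSA: float, damage: float, params: InjuryParams) -> float:
    """d(dSA)/dt: saturating first-order response to the damage signal."""
    return max(params.dSA_max - dSA, 0.0) * max(damage, 0.0) / params.tau_sa


def sclerosis_rate(dPerm: float, damage: float, params: InjuryParams) -> float:
    """d(dPerm)/dt: like hypertrophy but ~53x slower (tau ratio 4e4/750)."""
    return (max(params.dPerm_max - dPerm, 0.0) * max(damage, 0.0)
            / params.tau_perm)


def nephron_loss_rate(dNephrons: float, damage: float,
                      params: InjuryParams) -> float:
    """d(dNephrons)/dt: fraction of remaining nephrons lost per unit damage."""
    return (max(1.0 - dNephrons, 0.0) * max(damage, 0.0)
            / params.tau_nephron_loss)


def sieving_damage(dK_albumin: float, damage: float,
                   params: InjuryParams,
                   k_albumin0: float = 0.0006) -> tuple[float, float]:
    """(d(dK_albumin)/dt, current K_albumin).

    Unlike the other four processes this is a pure integrator — no
    saturation term — so sustained glomerular hypertension produces
    unbounded, accelerating proteinuria.
    """
    if dK_albumin < 0:
        raise ValueError("sieving damage must be nonnegative")
    rate = max(damage, 0.0) / params.tau_albumin
    return rate, compose_K_albumin(k_albumin0, dK_albumin)


def compose_Kf(k_f0: float, dSA: float, dPerm: float) -> float:
    """K_f = K_f0 * (1 + dSA - dPerm), clamped at 0.

    Rises early while hypertrophy dominates, then falls as sclerosis
    accumulates — the characteristic peak of the ultrafiltration
    coefficient in progressive disease.
    """
    return max(k_f0 * (1.0 + dSA - dPerm), 0.0)


def compose_K_albumin(k_albumin0: float, dK_albumin: float) -> float:
    """K_albumin = K_albumin0 + dK_albumin (additive sieving damage)."""
    return k_albumin0 + dK_albumin


def injury_rates(state: InjuryState, damage: float, bg: float,
                 params: InjuryParams,
                 switches: InjurySwitches) -> np.ndarray:
    """All five rates, per *week* of simulation time."""
    scale = 1.0 / params.time_unit_weeks
    r = np.array([
        afferent_dilatation_rate(state.dD_aa, bg, params)
        if switches.dilatation else 0.0,
        hypertrophy_rate(state.dSA, damage, params)
        if switches.hypertrophy else 0.0,
        sclerosis_rate(state.dPerm, damage, params)
        if switches.sclerosis else 0.0,
        nephron_loss_rate(state.dNephrons, damage, params)
        if switches.nephron_loss else 0.0,
        sieving_damage(max(state.dK_albumin, 0.0), damage, params)[0]
        if switches.sieving else 0.0,
    ])
    return r * scale
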