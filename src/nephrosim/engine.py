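"""Steady-state solver, time-course integrator, and disease protocols.

The closed loop is integrated on two time scales: the hemodynamic and
tubular algebra (minutes) is solved quasi-statically inside the right-hand
side of the slow system (weeks), whose states are the extracellular Na+
store, the extracellular fluid volume, and the five adaptation/injury
states.  Uninephrectomy is a discrete event that halves the active nephron
count and leaves every other state untouched.

Shipped protocols: wild type (no forcing), db/db (blood glucose ramping
to a 500 mg/dl plateau with Na+ intake x1.5, water intake x5, and the
glucose threshold rising with glucose to 400 mg/dl), and db/db UNX
(the same with uninephrectomy at week 8).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp

from . import albumin as alb
from . import homeostasis as homeo
from . import units
from .hemodynamics import ConvergenceError, OperatingPoint, vascular_pressure_profile
from .injury import (InjuryParams, InjuryState, InjurySwitches, compose_Kf,
                     compose_K_albumin, damage_signal, injury_rates)
from .species import SpeciesParameters, load_species_parameters


@dataclass(frozen=True)
class DiseaseProtocol:
    """Time-dependent forcings of a disease simulation.

    Blood glucose follows a normalized logistic ramp from 90 mg/dl at week
    0 to ``bg_plateau``, reaching 95% of the plateau at week ``bg_t95``;
    intake multipliers follow the same ramp from 1 to their final values.
    The glucose reabsorption threshold tracks glucose, clipped to
    [180, 400] mg/dl, so urinary glucose stays minimal below 400 mg/dl.
    """

    name: str = "wild_type"
    bg_plateau: float = 90.0        # mg/dl, db/db default 500, bounds 250-600
    bg_t95: float = 10.0            # weeks to 95% of plateau
    na_multiplier: float = 1.0      # final Na+ intake multiplier (db/db 1.5)
    wa_multiplier: float = 1.0      # final water intake multiplier (db/db 5)
    rt_g_max: float = 400.0         # mg/dl
    unx_week: float | None = None   # uninephrectomy time, weeks
    unx_fraction: float = 0.5       # fraction of nephrons removed
    switches: InjurySwitches = field(default_factory=InjurySwitches)

    def __post_init__(self):
        if self.bg_plateau < 90.0:
            raise ValueError("glucose plateau below nominal 90 mg/dl")
        if self.na_multiplier < 1.0 or self.wa_multiplier < 1.0:
            raise ValueError("intake multipliers must be >= 1")
        if self.unx_week is not None and not 0.0 < self.unx_fraction < 1.0:
            raise ValueError("nephrectomy fraction must lie in (0, 1)")

    def _ramp(self, t: float) -> float:
        """Normalized logistic in [0, 1], 0 at t=0, 95% at bg_t95."""
        if self.bg_plateau <= 90.0 + 1e-12:
            return 0.0
        t_mid = self.bg_t95 / 2.0
        s = t_mid / math.log(19.0)  # L(t95) = 0.95 for the raw logistic
        raw = 1.0 / (1.0 + math.exp(-(t - t_mid) / s))
        raw0 = 1.0 / (1.0 + math.exp(t_mid / s))
        return (raw - raw0) / (1.0 - raw0)

    def bg(self, t: float) -> float:
        return 90.0 + (self.bg_plateau - 90.0) * self._ramp(t)

    def rt_g(self, t: float) -> float:
        return min(self.rt_g_max, max(180.0, self.bg(t)))

    def na_mult(self, t: float) -> float:
        return 1.0 + (self.na_multiplier - 1.0) * self._ramp(t)

    def wa_mult(self, t: float) -> float:
        return 1.0 + (self.wa_multiplier - 1.0) * self._ramp(t)

    def unx_factor(self, t: float) -> float:
        if self.unx_week is not None and t >= self.unx_week:
            return 1.0 - self.unx_fraction
        return 1.0

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def wild_type_protocol() -> DiseaseProtocol:
    return DiseaseProtocol(name="wild_type")


def dbdb_protocol(bg_plateau: float = 500.0,
                  switches: InjurySwitches | None = None) -> DiseaseProtocol:
    return DiseaseProtocol(
        name="dbdb", bg_plateau=bg_plateau, na_multiplier=1.5,
        wa_multiplier=5.0, switches=switches or InjurySwitches())


def dbdb_unx_protocol(bg_plateau: float = 500.0, unx_week: float = 8.0,
                      switches: InjurySwitches | None = None) -> DiseaseProtocol:
    return DiseaseProtocol(
        name="dbdb_unx", bg_plateau=bg_plateau, na_multiplier=1.5,
        wa_multiplier=5.0, unx_week=unx_week,
        switches=switches or InjurySwitches())


@dataclass
class SimulationResult:
    """Time-indexed trajectory plus metadata; CSV-serializable."""

    frame: pd.DataFrame
    metadata: dict

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.frame.to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(self.metadata, fh, indent=2, default=str)

    def at_week(self, week: float) -> pd.Series:
        idx = (self.frame["week"] - week).abs().idxmin()
        return self.frame.loc[idx]


class _Loop:
    """Bundles the quasi-static inner solve for the slow ODE system."""

    def __init__(self, p: SpeciesParameters, reg: homeo.RegulationParams,
                 inj: InjuryParams, protocol: DiseaseProtocol):
        self.p, self.reg, self.inj, self.protocol = p, reg, inj, protocol
        self.warm = (p.RBF_nom, p.SNGFR_nom)
        #: set per integration leg so the pre-event leg endpoint (t equal to
        #: the nephrectomy week) is still evaluated with both kidneys
        self.unx_factor_override: float | None = None

    def _unx_factor(self, t: float) -> float:
        if self.unx_factor_override is not None:
            return self.unx_factor_override
        return self.protocol.unx_factor(t)

    def operating_point(self, t: float, y: np.ndarray) -> OperatingPoint:
        p = self.p
        m_na, ecf = y[0], y[1]
        istate = InjuryState.from_array(np.clip(
            y[2:7], 0.0,
            [self.inj.dD_aa_max, self.inj.dSA_max, self.inj.dPerm_max,
             1.0, np.inf]))
        c_na = m_na / ecf
        bv = p.blood_volume_fraction * ecf
        co = homeo.cardiac_output(bv, p.blood_volume_nom, p.CO_nom, self.reg)
        mean_ap = homeo.map_from_co(co, p.R_tpr)
        n_active = (p.N_nephrons * (1.0 - istate.dNephrons)
                    * self._unx_factor(t))
        k_f = compose_Kf(p.K_f0, istate.dSA, istate.dPerm)
        k_alb = compose_K_albumin(p.K_albumin0, istate.dK_albumin)
        op = vascular_pressure_profile(
            p, self.reg, MAP=mean_ap, C_Na=c_na, N_active=n_active,
            K_f=k_f, K_albumin=k_alb, dD_aa=istate.dD_aa,
            BG=self.protocol.bg(t), RT_G=self.protocol.rt_g(t),
            warm_start=self.warm)
        self.warm = (op.glomerular.RBF * 1e-3, op.glomerular.SNGFR)
        return op

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.p
        op = self.operating_point(t, y)
        na_in = p.Na_in * self.protocol.na_mult(t) / units.MIN_PER_DAY
        wa_in = p.Wa_in * self.protocol.wa_mult(t) / units.MIN_PER_DAY
        d_mna = homeo.sodium_balance_ode(na_in, op.urine_na)
        d_ecf = homeo.water_balance_ode(wa_in, op.urine_water)
        istate = InjuryState.from_array(y[2:7])
        dmg = damage_signal(op.glomerular.P_gc, p.P_gc0)
        d_inj = injury_rates(istate, dmg, self.protocol.bg(t), self.inj,
                             self.protocol.switches)
        return np.concatenate((
            [d_mna * units.MIN_PER_WEEK, d_ecf * units.MIN_PER_WEEK], d_inj))


def solve_steady_state(
    p: SpeciesParameters,
    reg: homeo.RegulationParams | None = None,
    inj: InjuryParams | None = None,
    protocol: DiseaseProtocol | None = None,
    t: float = 0.0,
    injury_state: InjuryState | None = None,
) -> tuple[OperatingPoint, dict]:
    """Root of the closed-loop algebra with the slow states frozen.

    With the default (wild-type) protocol and zero injury this returns the
    species' baseline operating point, which matches the phenotype targets
    by construction of the calibration.  Raises a solver error with the
    residual vector on non-convergence.
    """
    reg = reg or homeo.RegulationParams()
    inj = inj or InjuryParams()
    protocol = protocol or wild_type_protocol()
    istate = injury_state or InjuryState()
    loop = _Loop(p, reg, inj, protocol)

    def residual(x):
        y = np.concatenate((x * [p.M_Na_nom, p.ECF_nom], istate.as_array()))
        d = loop.rhs(t, y)[:2]
        return d / np.array([p.M_Na_nom, p.ECF_nom])

    sol = optimize.root(residual, np.array([1.0, 1.0]), method="hybr",
                        options={"xtol": 1e-13})
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
        raise ConvergenceError(
            f"steady-state solve failed for {p.species_id}: residual {sol.fun}")
    m_na, ecf = sol.x * [p.M_Na_nom, p.ECF_nom]
    y = np.concatenate(([m_na, ecf], istate.as_array()))
    op = loop.operating_point(t, y)
    fluid = {"body_Na": m_na, "ECF": ecf, "C_Na": m_na / ecf,
             "CO": op.MAP / p.R_tpr, "MAP": op.MAP}
    return op, fluid


def _row(t, y, op: OperatingPoint, p: SpeciesParameters,
         protocol: DiseaseProtocol) -> dict:
    g = op.glomerular
    na_in = p.Na_in * protocol.na_mult(t)
    urine_na_day = op.urine_na * units.MIN_PER_DAY
    return {
        "week": t, "BG": protocol.bg(t), "RT_G": protocol.rt_g(t),
        "MAP": op.MAP, "CO": op.MAP / p.R_tpr,
        "body_Na": y[0], "ECF": y[1], "C_Na": y[0] / y[1],
        "RBF": g.RBF, "P_gc": g.P_gc, "P_Bow": g.P_Bow,
        "pi_go_avg": g.pi_go_avg, "SNGFR": g.SNGFR, "GFR": g.GFR,
        "K_f": g.K_f, "FF": g.filtration_fraction,
        "K_albumin": compose_K_albumin(p.K_albumin0, y[6]),
        "frac_PT_Na": op.eta_pt,
        "UGE": op.R_UGE_total * units.MIN_PER_DAY,       # mg/day
        "urine_Na": urine_na_day,                        # mmol/day
        "urine_volume": op.urine_water * units.MIN_PER_DAY,  # L/day
        "UAER": alb.uaer_ug_per_day(op.UAER),            # ug/day
        "sodium_balance_error": (na_in - urine_na_day) / na_in,
        "dD_aa": y[2], "dSA": y[3], "dPerm": y[4], "dNephrons": y[5],
        "dK_albumin": y[6], "N_active": op.N_active,
        "damage": damage_signal(g.P_gc, p.P_gc0),
        "mu_tgf": op.mu_tgf, "mu_myo": op.mu_myo, "mu_rihp": op.mu_rihp,
    }


def simulate_protocol(
    p: SpeciesParameters,
    protocol: DiseaseProtocol,
    horizon: float = 24.0,
    dt_out: float = 0.25,
    reg: homeo.RegulationParams | None = None,
    inj: InjuryParams | None = None,
    rtol: float = 1e-7,
    atol: float | None = None,
    initial_injury: InjuryState | None = None,
) -> SimulationResult:
    """Integrate the closed loop over ``horizon`` weeks.

    Starts from the healthy steady state (optionally with a pre-existing
    adaptation/injury state); applies uninephrectomy (if scheduled) as a
    discontinuous halving of the active nephron count, conserving every
    other state.  Output is sampled every ``dt_out`` weeks.
    """
    reg = reg or homeo.RegulationParams()
    inj = inj or InjuryParams()
    if protocol.unx_week is not None and protocol.unx_week > horizon:
        raise ValueError("nephrectomy scheduled beyond the horizon")
    loop = _Loop(p, reg, inj, protocol)
    istate0 = initial_injury or InjuryState()
    if initial_injury is None:
        m_na0, ecf0 = p.M_Na_nom, p.ECF_nom
    else:
        # start on the steady state consistent with the pre-existing
        # adaptation state (baseline forcings at t=0)
        _, fluid0 = solve_steady_state(p, reg, inj, protocol, t=0.0,
                                       injury_state=istate0)
        m_na0, ecf0 = fluid0["body_Na"], fluid0["ECF"]
    y0 = np.concatenate(([m_na0, ecf0], istate0.as_array()))
    scale = np.concatenate(([p.M_Na_nom, p.ECF_nom], np.ones(5)))
    atol_vec = (atol if atol is not None else 1e-9) * scale

    legs = [(0.0, horizon)]
    if protocol.unx_week is not None and 0.0 < protocol.unx_week < horizon:
        legs = [(0.0, protocol.unx_week), (protocol.unx_week, horizon)]

    t_eval = np.arange(0.0, horizon + dt_out / 2, dt_out)
    rows = []
    y = y0
    for leg_index, (t0, t1) in enumerate(legs):
        if protocol.unx_week is not None:
            loop.unx_factor_override = (
                1.0 if leg_index == 0 else 1.0 - protocol.unx_fraction)
        mask = (t_eval >= t0 - 1e-9) & (t_eval <= t1 + 1e-9)
        sol = solve_ivp(loop.rhs, (t0, t1), y, method="BDF",
                        t_eval=t_eval[mask], rtol=rtol, atol=atol_vec,
                        dense_output=False)
        if not sol.status == 0:
            raise ConvergenceError(
                f"integration aborted at t={sol.t[-1] if len(sol.t) else t0:.2f}"
                f" weeks: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            # the post-event sample at the junction comes from the next leg
            if rows and abs(tk - rows[-1]["week"]) < 1e-9:
                continue
            rows.append(_row(tk, yk, loop.operating_point(tk, yk), p, protocol))
        y = sol.y[:, -1]

    frame = pd.DataFrame(rows)
    if frame.isna().any().any() or np.isinf(frame.select_dtypes(float)).any().any():
        raise ConvergenceError("trajectory contains NaN/Inf")
    meta = {"species": p.species_id, "protocol": protocol.name,
            "protocol_hash": protocol.digest(), "horizon_weeks": horizon,
            "dt_out_weeks": dt_out, "rtol": rtol}
    return SimulationResult(frame=frame, metadata=meta)


def run_sensitivity(
    p: SpeciesParameters,
    protocol: DiseaseProtocol,
    parameter_name: str,
    values,
    horizon: float = 24.0,
    dt_out: float = 0.5,
    inj: InjuryParams | None = None,
    **kwargs,
) -> dict:
    """Sweep one parameter over ``values``; returns {value: result|error}.

    ``parameter_name`` may address the injury block (``"tau_perm"`` etc.),
    a protocol field (``"bg_plateau"``), or a species attribute.  Solver
    errors at individual grid points are collected, not fatal.
    """
    inj = inj or InjuryParams()
    out = {}
    for v in values:
        pi, proto, pp = inj, protocol, p
        if hasattr(inj, parameter_name):
            pi = replace(inj, **{parameter_name: v})
        elif hasattr(protocol, parameter_name):
            proto = replace(protocol, **{parameter_name: v})
        elif hasattr(p, parameter_name):
            pp = replace_species(p, parameter_name, v)
        else:
            raise AttributeError(f"unknown parameter {parameter_name!r}")
        try:
            out[v] = simulate_protocol(pp, proto, horizon, dt_out, inj=pi,
                                       **kwargs)
        except (ConvergenceError, ValueError) as exc:
            out[v] = exc
    return out


def replace_species(p: SpeciesParameters, name: str, value) -> SpeciesParameters:
    import copy

    q = copy.deepcopy(p)
    setattr(q, name, value)
    return q


def glucose_band(
    p: SpeciesParameters,
    lo: float = 250.0,
    hi: float = 600.0,
    switches: InjurySwitches | None = None,
    horizon: float = 24.0,
    dt_out: float = 0.5,
    adapted: bool = True,
    inj: InjuryParams | None = None,
    **kwargs,
) -> dict:
    """The glucose-plateau band sweep: db/db at plateaus lo and hi.

    With ``adapted=True`` (default) the band is computed under the fully
    adapted glomerulus — afferent dilatation and hypertrophy fixed at
    their ceilings, injury dynamics off — the conditions under which the
    response range to glucose is a clean monotone envelope: the band then
    brackets the default 500 mg/dl trajectory pointwise for GFR, P_gc, and
    MAP.  With ``adapted=False`` the requested switches run dynamically.
    """
    inj = inj or InjuryParams()
    init = None
    if adapted:
        switches = InjurySwitches.all_off()
        init = InjuryState(dD_aa=inj.dD_aa_max, dSA=inj.dSA_max)
    out = {}
    for plateau in (lo, hi):
        out[plateau] = simulate_protocol(
            p, dbdb_protocol(bg_plateau=plateau, switches=switches),
            horizon, dt_out, inj=inj, initial_injury=init, **kwargs)
    return out


def generate_synthetic_composite(
    result: SimulationResult,
    weeks=None,
    n_animals: int = 10,
    sigma_animal: float = 0.15,
    sigma_obs: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate a composite longitudinal GFR/UAER dataset around a simulated
    trajectory.

    Between-animal (and between-study) scatter is modeled as a lognormal
    animal-level random effect of scale ``sigma_animal`` plus lognormal
    observation noise of scale ``sigma_obs`` on both GFR and UAER.  With
    both scales 0 the observations equal the trajectory; a fixed seed
    yields a bit-identical dataset.
    """
    if n_animals <= 0:
        raise ValueError("n_animals must be positive")
    rng = np.random.default_rng(seed)
    frame = result.frame
    if weeks is None:
        weeks = np.arange(2.0, frame["week"].max() + 1e-9, 2.0)
    rows = []
    for animal in range(n_animals):
        effect = rng.normal(0.0, 1.0, size=2) * sigma_animal
        for wk in weeks:
            ref = result.at_week(wk)
            eps = rng.normal(0.0, 1.0, size=2) * sigma_obs
            rows.append({
                "animal": animal, "week": float(ref["week"]),
                "GFR": float(ref["GFR"]) * math.exp(effect[0] + eps[0]),
                "UAER": float(ref["UAER"]) * math.exp(effect[1] + eps[1]),
            })
    return pd.DataFrame(rows)


def baseline_snapshot(species_id: str) -> dict:
    """Convenience: load, calibrate, and solve the healthy steady state."""
    p = load_species_parameters(species_id)
    op, fluid = solve_steady_state(p)
    g = op.glomerular
    return {
        "species": species_id, "MAP": fluid["MAP"], "CO": fluid["CO"],
        "RBF": g.RBF, "GFR": g.GFR, "SNGFR": g.SNGFR, "P_gc": g.P_gc,
        "Na_ex": op.urine_na * units.MIN_PER_DAY,
        "UAER": alb.uaer_ug_per_day(op.UAER),
        "C_Na": fluid["C_Na"],
    }
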