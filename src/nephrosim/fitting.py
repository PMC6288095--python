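"""Fitting disease-progression time constants to longitudinal data.

A small statsmodels-style interface: ``DiseaseTrajectoryModel`` holds a
longitudinal GFR/UAER dataset (one row per animal per week, as produced by
`generate_synthetic_composite` or supplied from experiments) together with
the species parameterization and disease protocol; ``fit()`` estimates the
requested injury time constants by least squares on the log scale and
returns a ``DiseaseTrajectoryResults`` carrying estimates, approximate
standard errors, and a ``summary()`` table.

Fitting on the log scale serves two purposes: the time constants are
positive scale parameters spanning decades, and the between-animal scatter
of GFR and UAER is approximately lognormal, so log-residuals weight both
outcomes comparably.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .engine import DiseaseProtocol, simulate_protocol
from .homeostasis import RegulationParams
from .injury import InjuryParams
from .species import SpeciesParameters

_FITTABLE = ("tau_perm", "tau_nephron_loss", "tau_albumin", "tau_sa",
             "tau_daa")


class DiseaseTrajectoryModel:
    """Least-squares model for injury time constants.

    Parameters
    ----------
    data : DataFrame with columns ``week``, ``GFR`` (ml/min), ``UAER``
        (ug/day), and optionally ``animal``; observations are averaged
        (geometric mean) across animals per week before fitting.
    species : calibrated SpeciesParameters
    protocol : the protocol under which the data were generated
    fit_params : names of InjuryParams fields to estimate
    """

    def __init__(self, data: pd.DataFrame, species: SpeciesParameters,
                 protocol: DiseaseProtocol,
                 fit_params=("tau_perm", "tau_nephron_loss"),
                 base_injury: InjuryParams | None = None,
                 reg: RegulationParams | None = None,
                 rtol: float = 1e-6):
        for name in fit_params:
            if name not in _FITTABLE:
                raise ValueError(f"cannot fit {name!r}; choose from {_FITTABLE}")
        required = {"week", "GFR", "UAER"}
        if not required <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        self.fit_params = tuple(fit_params)
        self.species = species
        self.protocol = protocol
        self.base_injury = base_injury or InjuryParams()
        self.reg = reg
        self.rtol = rtol
        # geometric-mean trajectory per sampled week
        logged = data.assign(lGFR=np.log(data["GFR"]),
                             lUAER=np.log(data["UAER"]))
        mean = logged.groupby("week")[["lGFR", "lUAER"]].mean()
        self.weeks = mean.index.to_numpy(float)
        self.endog = mean.to_numpy()          # (n_weeks, 2) log scale
        self.horizon = float(self.weeks.max())

    def _injury(self, theta_log: np.ndarray) -> InjuryParams:
        values = {name: float(np.exp(t))
                  for name, t in zip(self.fit_params, theta_log)}
        return replace(self.base_injury, **values)

    def predict(self, injury: InjuryParams) -> np.ndarray:
        """Log GFR/UAER at the observation weeks for one parameter set."""
        res = simulate_protocol(
            self.species, self.protocol, horizon=self.horizon,
            dt_out=min(0.5, float(np.min(np.diff(self.weeks)))
                       if len(self.weeks) > 1 else 0.5),
            reg=self.reg, inj=injury, rtol=self.rtol)
        sim = np.array([
            [res.at_week(w)["GFR"], res.at_week(w)["UAER"]]
            for w in self.weeks])
        return np.log(np.maximum(sim, 1e-12))

    def _residuals(self, theta_log: np.ndarray) -> np.ndarray:
        return (self.predict(self._injury(theta_log)) - self.endog).ravel()

    def fit(self, start: dict | None = None) -> "DiseaseTrajectoryResults":
        theta0 = np.log([
            (start or {}).get(name, getattr(self.base_injury, name))
            for name in self.fit_params])
        sol = optimize.least_squares(
            self._residuals, theta0, method="lm", xtol=1e-8, ftol=1e-8)
        # covariance from the Jacobian at the optimum (lognormal errors)
        dof = max(sol.fun.size - len(self.fit_params), 1)
        s2 = float(sol.fun @ sol.fun) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_log = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_log = np.full((len(theta0), len(theta0)), np.nan)
        return DiseaseTrajectoryResults(self, sol, cov_log)


@dataclass
class DiseaseTrajectoryResults:
    """Estimates, uncertainties, and diagnostics of a trajectory fit."""

    model: DiseaseTrajectoryModel
    solver_result: optimize.OptimizeResult
    cov_log: np.ndarray

    @property
    def params(self) -> dict:
        return {name: float(np.exp(t)) for name, t in
                zip(self.model.fit_params, self.solver_result.x)}

    @property
    def bse(self) -> dict:
        """Approximate standard errors (delta method from the log scale)."""
        se_log = np.sqrt(np.diag(self.cov_log))
        return {name: float(np.exp(t) * s) for name, t, s in
                zip(self.model.fit_params, self.solver_result.x, se_log)}

    @property
    def ssr(self) -> float:
        return float(self.solver_result.fun @ self.solver_result.fun)

    @property
    def converged(self) -> bool:
        return bool(self.solver_result.success)

    def conf_int(self, alpha: float = 0.05) -> dict:
        from scipy import stats

        z = stats.norm.ppf(1.0 - alpha / 2.0)
        se_log = np.sqrt(np.diag(self.cov_log))
        return {name: (float(np.exp(t - z * s)), float(np.exp(t + z * s)))
                for name, t, s in zip(self.model.fit_params,
                                      self.solver_result.x, se_log)}

    def summary(self) -> str:
        lines = [
            "Disease-trajectory fit",
            "=" * 58,
            f"species: {self.model.species.species_id}   "
            f"protocol: {self.model.protocol.name}",
            f"observations: {self.model.endog.size} "
            f"(GFR+UAER at {len(self.model.weeks)} weeks)   "
            f"SSR(log): {self.ssr:.4g}",
            f"converged: {self.converged}",
            "-" * 58,
            f"{'parameter':<18}{'estimate':>12}{'std err':>12}{'95% CI':>16}",
        ]
        ci = self.conf_int()
        for name in self.model.fit_params:
            lo, hi = ci[name]
            lines.append(f"{name:<18}{self.params[name]:>12.4g}"
                         f"{self.bse[name]:>12.3g}"
                         f"  [{lo:.3g}, {hi:.3g}]")
        lines.append("=" * 58)
        return "\n".join(lines)
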