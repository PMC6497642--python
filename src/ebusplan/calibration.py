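"""Calibration of the systemic model against timed blood draws.

Two parameters are free: the total extracellular loss rate ``k_sum = k_i +
k_f`` and the fluid-space volume ``V_f``.  The renal rate ``k_r`` is fixed
from the drug's biological half-life, and a literature value of ``k_i``
splits the fitted sum into its uptake and vascular-clearance components.

The cost is the root-sum-of-squares residual between measured and modelled
blood concentrations; it is minimised by multi-start local least squares in
log-parameter space (positivity for free, and k_sum / V_f differ by seven
orders of magnitude in natural units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fields import InjectionPlan, blood_curve
from .parameters import LITERATURE_K_I, ModelParameters

__all__ = ["BloodSeries", "FitResult", "cost_j_blood", "fit_blood_model"]

#: Default search box for (k_sum [1/s], V_f [cm^3]).
DEFAULT_BOUNDS = ((1e-6, 1e-2), (1e2, 1e6))


@dataclass(frozen=True)
class BloodSeries:
    """Timed systemic concentration samples after intratumoral injection.

    ``times_s`` are seconds relative to the final injection, strictly
    increasing and positive; ``concentrations`` in mg/cm^3.  The plan records
    the administered doses (the model is linear in total dose / V_f).
    """

    times_s: np.ndarray
    concentrations: np.ndarray
    plan: InjectionPlan

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times_s, dtype=float))
        conc = np.atleast_1d(np.asarray(self.concentrations, dtype=float))
        if times.shape != conc.shape:
            raise ValueError("times and concentrations must have equal length")
        if times.size < 2:
            raise ValueError("need at least 2 samples to fit 2 parameters")
        if np.any(times <= 0) or np.any(np.diff(times) <= 0):
            raise ValueError("sample times must be strictly increasing and > 0")
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "concentrations", conc)

    @classmethod
    def from_csv(cls, path, plan: InjectionPlan) -> "BloodSeries":
        """Read a series from CSV with columns ``time_min, conc_mg_per_ml``."""
        df = pd.read_csv(path)
        return cls(
            60.0 * df["time_min"].to_numpy(),
            df["conc_mg_per_ml"].to_numpy(),
            plan,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_min": self.times_s / 60.0, "conc_mg_per_ml": self.concentrations}
        ).to_csv(path, index=False)

    def model_values(self, k_sum: float, V_f: float, k_r: float) -> np.ndarray:
        return blood_curve(
            self.times_s, self.plan.doses, k_sum, k_r, V_f, times=self.plan.times
        )


@dataclass(frozen=True)
class FitResult:
    k_sum: float
    V_f: float
    k_f_derived: float
    cost: float
    r_squared: float
    n_starts: int
    converged: bool
    residuals: np.ndarray
    k_f_nonpositive: bool

    def to_dict(self) -> dict:
        d = {
            "k_sum_per_s": self.k_sum,
            "V_f_cm3": self.V_f,
            "V_f_L": self.V_f / 1000.0,
            "k_f_derived_per_s": self.k_f_derived,
            "cost_mg_per_ml": self.cost,
            "r_squared": self.r_squared,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "residuals_mg_per_ml": list(map(float, self.residuals)),
            "k_f_nonpositive": self.k_f_nonpositive,
        }
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def cost_j_blood(
    series: BloodSeries, k_sum: float, V_f: float, params: ModelParameters
) -> float:
    """Root-sum-of-squares misfit between data and the biexponential model."""
    if k_sum <= 0 or V_f <= 0:
        raise ValueError("k_sum and V_f must be positive")
    if series.times_s.size == 0:
        raise ValueError("empty blood series")
    resid = series.concentrations - series.model_values(k_sum, V_f, params.k_r)
    return float(np.sqrt(np.sum(resid**2)))


def fit_blood_model(
    series: BloodSeries,
    params: ModelParameters,
    k_i_literature: float = LITERATURE_K_I,
    n_starts: int = 16,
    seed: int = 0,
    bounds=DEFAULT_BOUNDS,
) -> FitResult:
    """Estimate (k_sum, V_f) from a blood series; k_r stays fixed.

    Runs ``n_starts`` local least-squares fits in log-parameter space from
    seeded log-uniform starting points spread over ``bounds`` (plus the box
    centre) and keeps the best optimum.  ``k_f_derived = k_sum -
    k_i_literature``; a non-positive value is flagged rather than raised.
    Residuals are unweighted.
    """
    (k_lo, k_hi), (v_lo, v_hi) = bounds
    data = series.concentrations
    k_r = params.k_r

    def residual(theta):
        k_sum, v_f = np.exp(np.clip(theta, -60.0, 60.0))
        return series.model_values(k_sum, v_f, k_r) - data

    rng = np.random.default_rng(seed)
    log_lo = np.log([k_lo, v_lo])
    log_hi = np.log([k_hi, v_hi])
    starts = [0.5 * (log_lo + log_hi)]
    starts += list(rng.uniform(log_lo, log_hi, size=(max(n_starts - 1, 0), 2)))

    best = None
    any_success = False
    for x0 in starts[:n_starts]:
        sol = least_squares(residual, x0, method="lm", xtol=1e-15, ftol=1e-15)
        any_success = any_success or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(
            f"blood-model fit failed to converge from {n_starts} starts "
            f"(bounds {bounds})"
        )

    k_sum, v_f = np.exp(best.x)
    resid = residual(best.x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    k_f = k_sum - k_i_literature
    return FitResult(
        k_sum=float(k_sum),
        V_f=float(v_f),
        k_f_derived=float(k_f),
        cost=float(np.sqrt(ss_res)),
        r_squared=r2,
        n_starts=n_starts,
        converged=bool(any_success),
        residuals=resid,
        k_f_nonpositive=bool(k_f <= 0),
    )
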