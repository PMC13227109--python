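"""Estimation layer: single-exponential transient fits, linear fits for slow
misincorporation, the linearized Eyring fit, activation free-energy
propagation, and replicate aggregation.

The single-turnover product transient is fit to

    [product](t) = A * (1 - exp(-k_obs * t))

and rate constants measured across temperatures are fit to the linearized
Eyring equation

    ln(k/T) = ln(kappa * k_B/h) + dS'/R - dH'/(R*T)

with the transmission coefficient kappa fixed at 1 (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lmfit import Model

from .constants import KB_OVER_H, R_CAL
from .mechanism import TimeCourse

__all__ = [
    "ExponentialFit",
    "LinearFit",
    "EyringFit",
    "ReplicateSummary",
    "eyring_rate",
    "fit_single_exponential",
    "fit_linear",
    "fit_eyring",
    "delta_g",
    "aggregate_replicates",
]


def eyring_rate(dH_kcal: float, dS_cal: float, T_K: float, kappa: float = 1.0) -> float:
    """Transition-state-theory rate constant (s^-1).

    dH' in kcal/mol, dS' in cal/(mol*K), T in kelvin.
    """
    if T_K <= 0:
        raise ValueError("temperature must be positive")
    return kappa * KB_OVER_H * T_K * math.exp(dS_cal / R_CAL) * math.exp(
        -dH_kcal * 1000.0 / (R_CAL * T_K)
    )


@dataclass
class ExponentialFit:
    """Result of the burst/single-turnover exponential fit."""

    amplitude: float
    k_obs: float
    amplitude_stderr: float
    k_obs_stderr: float
    rss: float
    n_points: int
    converged: bool

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * (1.0 - np.exp(-self.k_obs * t))

    def to_dict(self) -> dict:
        return {
            "amplitude_nM": self.amplitude,
            "k_obs_per_s": self.k_obs,
            "amplitude_stderr_nM": self.amplitude_stderr,
            "k_obs_stderr_per_s": self.k_obs_stderr,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
        }


@dataclass
class LinearFit:
    slope: float          # nM/s
    intercept: float      # nM
    slope_stderr: float
    intercept_stderr: float
    n_points: int

    def predict(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope_nM_per_s": self.slope,
            "intercept_nM": self.intercept,
            "slope_stderr": self.slope_stderr,
            "intercept_stderr": self.intercept_stderr,
            "n_points": self.n_points,
        }


@dataclass
class EyringFit:
    """Activation parameters from the linearized Eyring regression.

    dH' in kcal/mol, dS' in cal/(mol*K); ``cov_HS`` is their estimated
    covariance in (kcal/mol)*(cal/(mol*K)) -- strongly negative in practice
    because slope and intercept of the linearized fit are anticorrelated.
    """

    dH_kcal: float
    dS_cal: float
    dH_stderr: float
    dS_stderr: float
    cov_HS: float = 0.0
    kappa: float = 1.0
    n_points: int = 0

    def rate(self, T_K: float) -> float:
        return eyring_rate(self.dH_kcal, self.dS_cal, T_K, kappa=self.kappa)

    def delta_g(self, T_K: float, use_covariance: bool = False):
        return delta_g(self, T_K, use_covariance=use_covariance)

    def to_dict(self) -> dict:
        return {
            "dH_kcal_per_mol": self.dH_kcal,
            "dS_cal_per_mol_K": self.dS_cal,
            "dH_stderr": self.dH_stderr,
            "dS_stderr": self.dS_stderr,
            "cov_HS": self.cov_HS,
            "kappa": self.kappa,
            "n_points": self.n_points,
        }


@dataclass
class ReplicateSummary:
    """Mean +/- sample SD of a parameter across independent replicates."""

    values: tuple
    mean: float
    sd: float | None   # None when n = 1 (sample SD undefined)
    n: int

    def to_dict(self) -> dict:
        return {"values": list(self.values), "mean": self.mean, "sd": self.sd, "n": self.n}


def _coords(tc) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(tc, TimeCourse):
        return tc.times, tc.signal
    t, y = tc
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def _exp_model(t, A, k_obs):
    return A * (1.0 - np.exp(-k_obs * t))


def fit_single_exponential(
    tc,
    init: tuple[float, float] | None = None,
) -> ExponentialFit:
    """Least-squares fit of A*(1 - exp(-k_obs*t)) to an observed transient.

    ``tc`` is a signal :class:`TimeCourse` or a ``(times, signal)`` pair.
    Default initialization: A0 = max(signal), k0 = ln2 / (time at half-max).
    Both parameters are bounded below at 0.
    """
    t, y = _coords(tc)
    if len(t) < 3:
        raise ValueError("need at least 3 points to fit an exponential")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.ptp(y) == 0.0:
        # no curvature: amplitude is the common value, rate unidentifiable
        return ExponentialFit(
            amplitude=float(y[0]),
            k_obs=0.0,
            amplitude_stderr=float("nan"),
            k_obs_stderr=float("nan"),
            rss=0.0,
            n_points=len(t),
            converged=False,
        )

    if init is None:
        a0 = float(np.max(y))
        half = a0 / 2.0
        above = np.nonzero(y >= half)[0]
        if len(above) and t[above[0]] > 0:
            k0 = math.log(2.0) / float(t[above[0]])
        else:
            k0 = 1.0 / max(float(np.mean(t[t > 0])) if np.any(t > 0) else 1.0, 1e-12)
    else:
        a0, k0 = init

    model = Model(_exp_model)
    params = model.make_params(A=max(a0, 1e-12), k_obs=max(k0, 1e-12))
    params["A"].min = 0.0
    params["k_obs"].min = 0.0
    result = model.fit(
        y, params, t=t, method="leastsq", fit_kws={"xtol": 1e-10, "ftol": 1e-10}
    )

    a = float(result.params["A"].value)
    k = float(result.params["k_obs"].value)
    a_err = result.params["A"].stderr
    k_err = result.params["k_obs"].stderr
    return ExponentialFit(
        amplitude=a,
        k_obs=k,
        amplitude_stderr=float(a_err) if a_err is not None else float("nan"),
        k_obs_stderr=float(k_err) if k_err is not None else float("nan"),
        rss=float(np.sum(result.residual**2)),
        n_points=len(t),
        converged=bool(result.success),
    )


def fit_linear(tc) -> LinearFit:
    """Ordinary least squares line through an observed time course
    (closed-form normal-equation solution)."""
    t, y = _coords(tc)
    if len(t) < 2:
        raise ValueError("need at least 2 points for a linear fit")
    if np.ptp(t) == 0.0:
        raise ValueError("all times are equal; slope is undefined")
    slope, intercept, s_slope, s_intercept, _ = _ols(t, y)
    return LinearFit(
        slope=slope,
        intercept=intercept,
        slope_stderr=s_slope,
        intercept_stderr=s_intercept,
        n_points=len(t),
    )


def _ols(x: np.ndarray, y: np.ndarray):
    """Unweighted OLS of y on x: estimates, standard errors, and the
    slope-intercept covariance."""
    n = len(x)
    X = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return (
        float(beta[0]),
        float(beta[1]),
        float(math.sqrt(max(cov[0, 0], 0.0))),
        float(math.sqrt(max(cov[1, 1], 0.0))),
        float(cov[0, 1]),
    )


def fit_eyring(k_by_T: Sequence[tuple[float, float]], kappa: float = 1.0) -> EyringFit:
    """Linearized Eyring fit: regress ln(k/T) on 1/T.

    dH' = -slope * R;  dS' = (intercept - ln(kappa*k_B/h)) * R.
    Standard errors and the dH'-dS' covariance come from the OLS covariance.
    """
    pairs = list(k_by_T)
    if len(pairs) < 2:
        raise ValueError("need rate constants at >= 2 temperatures")
    T = np.array([p[0] for p in pairs], dtype=float)
    k = np.array([p[1] for p in pairs], dtype=float)
    if len(np.unique(T)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive")
    if np.any(k <= 0):
        raise ValueError("rate constants must be positive")

    slope, intercept, s_slope, s_intercept, cov_si = _ols(1.0 / T, np.log(k / T))
    dH = -slope * R_CAL / 1000.0
    dS = (intercept - math.log(kappa * KB_OVER_H)) * R_CAL
    # cov(dH, dS) = -(R/1000) * R * cov(slope, intercept)
    cov_hs = -(R_CAL / 1000.0) * R_CAL * cov_si
    return EyringFit(
        dH_kcal=dH,
        dS_cal=dS,
        dH_stderr=s_slope * R_CAL / 1000.0,
        dS_stderr=s_intercept * R_CAL,
        cov_HS=cov_hs,
        kappa=kappa,
        n_points=len(pairs),
    )


def delta_g(fit: EyringFit, T_K: float, use_covariance: bool = False) -> tuple[float, float]:
    """Activation free energy dG'(T) = dH' - T*dS' (kcal/mol) with
    propagated uncertainty.

    By default the dH'-dS' covariance is neglected (simple propagation,
    sigma_G = sqrt(sigma_H^2 + (T*sigma_S)^2)); pass ``use_covariance=True``
    to include the (strongly negative) covariance of the linearized fit.
    """
    if T_K <= 0:
        raise ValueError("temperature must be positive")
    g = fit.dH_kcal - T_K * fit.dS_cal / 1000.0
    var = fit.dH_stderr**2 + (T_K * fit.dS_stderr / 1000.0) ** 2
    if use_covariance:
        var -= 2.0 * (T_K / 1000.0) * fit.cov_HS
    return g, math.sqrt(max(var, 0.0))


def aggregate_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Arithmetic mean and sample (n-1) standard deviation across replicates.

    SD is ``None`` for a single replicate (undefined), mirroring the
    mean +/- SD (n >= 2) convention of replicate reporting.
    """
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError("no replicate values supplied")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return ReplicateSummary(values=vals, mean=mean, sd=sd, n=len(vals))
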