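"""Semi-analytic search-time theory, prefactor fitting and rate conversion.

The mean search time of a TF with ``n_tilde`` sites for a target at the
centre of an antenna of length ``L`` inside a nucleus of radius ``R``
decomposes into a 3D capture time onto the antenna (thin prolate-spheroid
absorber of capture radius ``r_p``, the TF gyration radius) and a 1D
octopusing walk along it:

    t_total(L) = alpha * n_tilde R^3 / (D L) * ln(L / r_p) + beta * L^2 / D

with ``D`` the single-site diffusion coefficient (the chain's 3D diffusion
coefficient is ``D/n_tilde``) and dimensionless prefactors ``alpha``
(exactly 2/3 for a point searcher) and ``beta`` (set by the effective 1D
diffusion coefficient, which depends on the well depth).  The baseline is
the simple TF without an IDR, ``t_simple = R^3 / (3 D a)`` for a bare
target of capture radius ``a``.

``alpha`` and ``beta`` are fitted to measured (t_3D, t_1D) vs L tables by
weighted least squares, statsmodels-style: :class:`SearchTimeModel` with
``fit()`` returning a :class:`SearchTimeFit` results object.

Rate conversion (the only place SI units enter): with ``copy_number``
TFs searching in parallel the per-cell association time is
``t_eff = t_total / copy_number`` and, for a single target at
concentration ``c = 1/(N_A V_nuc)``,

    k_on  = 1 / (t_eff * c)          [M^-1 s^-1]
    k_off = (1 - P_TF) / (P_TF t_eff)  [s^-1]
    k_D   = k_off / k_on             [M]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .units import BP_IN_M

__all__ = [
    "t_total_theory",
    "SearchTimeModel",
    "SearchTimeFit",
    "fit_alpha_beta",
    "optimal_antenna",
    "simple_tf_time",
    "RateConversionParams",
    "rates",
]

AVOGADRO = 6.02214076e23


def gyration_radius(n_tilde: int, l0: float) -> float:
    return math.sqrt(n_tilde / 6.0) * l0


def t_total_theory(
    L,
    n_tilde: int,
    R: float,
    D: float,
    l0: float,
    alpha: float,
    beta: float,
    split: bool = False,
):
    """Evaluate the two-term search-time formula (times in bp^2/D units).

    Requires ``L > r_p``.  With ``split=True`` returns (t_3d, t_1d, total).
    """
    L = np.asarray(L, dtype=float)
    r_p = gyration_radius(n_tilde, l0)
    if np.any(L <= r_p):
        raise ValueError(f"antenna length must exceed r_p = {r_p:.3g} bp")
    t3 = alpha * n_tilde * R**3 / (D * L) * np.log(L / r_p)
    t1 = beta * L**2 / D
    if split:
        return t3, t1, t3 + t1
    return t3 + t1


@dataclass
class SearchTimeFit:
    """Fitted prefactors of the search-time formula with uncertainties."""

    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    cov: np.ndarray  # 2x2, block-diagonal (independent fits)
    n_tilde: int
    R: float
    D: float
    l0: float
    resid_t3d: np.ndarray = field(default=None, repr=False)
    resid_t1d: np.ndarray = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    @property
    def bse(self) -> np.ndarray:
        return np.array([self.alpha_se, self.beta_se])

    def predict(self, L, split: bool = False):
        return t_total_theory(
            L, self.n_tilde, self.R, self.D, self.l0, self.alpha, self.beta,
            split=split,
        )

    def optimal_antenna(self):
        return optimal_antenna(
            self.n_tilde, self.R, self.D, self.l0, self.alpha, self.beta
        )

    def summary(self) -> str:
        l_star, t_min = self.optimal_antenna()
        lines = [
            "Search-time fit  t = alpha nR^3/(DL) ln(L/r_p) + beta L^2/D",
            "=" * 60,
            f"n_tilde = {self.n_tilde}, R = {self.R:g} bp, l0 = {self.l0:g} bp, "
            f"D = {self.D:g} bp^2/t0",
            f"alpha = {self.alpha:.4g} +- {self.alpha_se:.2g}",
            f"beta  = {self.beta:.4g} +- {self.beta_se:.2g}",
            f"optimal antenna L* = {l_star:.4g} bp, t_min = {t_min:.4g} t0",
        ]
        return "\n".join(lines)


class SearchTimeModel:
    """Weighted least-squares model for (alpha, beta).

    ``data`` needs columns ``L``, ``t3d``, ``t1d`` and optionally
    ``t3d_se``, ``t1d_se`` (used as WLS weights 1/se^2).  The two
    prefactors multiply independent regressors, so they are fitted as two
    one-parameter WLS problems through the origin.
    """

    def __init__(self, data: pd.DataFrame, n_tilde: int, R: float, D: float, l0: float):
        need = {"L", "t3d", "t1d"}
        if not need.issubset(data.columns):
            raise ValueError(f"data must contain columns {sorted(need)}")
        if len(data) < 3 or data["L"].nunique() < 3:
            raise ValueError("need measurements at >= 3 distinct antenna lengths")
        self.data = data.reset_index(drop=True)
        self.n_tilde = int(n_tilde)
        self.R = float(R)
        self.D = float(D)
        self.l0 = float(l0)
        r_p = gyration_radius(n_tilde, l0)
        if np.any(self.data["L"] <= r_p):
            raise ValueError("all antenna lengths must exceed r_p")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "SearchTimeModel":
        return cls(data, **kw)

    def fit(self) -> SearchTimeFit:
        d = self.data
        r_p = gyration_radius(self.n_tilde, self.l0)
        x3 = self.n_tilde * self.R**3 / (self.D * d["L"]) * np.log(d["L"] / r_p)
        x1 = d["L"] ** 2 / self.D
        w3 = 1.0 / d["t3d_se"] ** 2 if "t3d_se" in d else np.ones(len(d))
        w1 = 1.0 / d["t1d_se"] ** 2 if "t1d_se" in d else np.ones(len(d))
        res3 = sm.WLS(d["t3d"], x3.to_frame("x"), weights=w3).fit()
        res1 = sm.WLS(d["t1d"], x1.to_frame("x"), weights=w1).fit()
        alpha = float(res3.params.iloc[0])
        beta = float(res1.params.iloc[0])
        if not (alpha > 0 and beta > 0):
            raise ValueError("fitted prefactors must be positive")
        # with measurement errors supplied, the weights are true inverse
        # variances: fix the scale at 1 instead of estimating it from the
        # (few) residuals
        se3 = float(np.sqrt(res3.cov_params(scale=1.0).iloc[0, 0])) \
            if "t3d_se" in d else float(res3.bse.iloc[0])
        se1 = float(np.sqrt(res1.cov_params(scale=1.0).iloc[0, 0])) \
            if "t1d_se" in d else float(res1.bse.iloc[0])
        cov = np.diag([se3**2, se1**2])
        return SearchTimeFit(
            alpha=alpha,
            beta=beta,
            alpha_se=se3,
            beta_se=se1,
            cov=cov,
            n_tilde=self.n_tilde,
            R=self.R,
            D=self.D,
            l0=self.l0,
            resid_t3d=np.asarray(res3.resid),
            resid_t1d=np.asarray(res1.resid),
        )


def fit_alpha_beta(
    data: pd.DataFrame, n_tilde: int, R: float, D: float, l0: float
) -> SearchTimeFit:
    """Functional wrapper around :class:`SearchTimeModel`."""
    return SearchTimeModel(data, n_tilde=n_tilde, R=R, D=D, l0=l0).fit()


def optimal_antenna(
    n_tilde: int, R: float, D: float, l0: float, alpha: float, beta: float
):
    """Minimise the two-term formula over L; returns (L_star, t_min)."""
    r_p = gyration_radius(n_tilde, l0)
    # restrict to L >= e r_p: there the 3D term decreases monotonically and
    # the two-term formula is unimodal (below e r_p the thin-absorber capture
    # formula is outside its domain of validity)
    lo = math.e * r_p
    hi = 100.0 * R

    def objective(L):
        return t_total_theory(L, n_tilde, R, D, l0, alpha, beta)

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6 * R},
    )
    return float(res.x), float(res.fun)


def simple_tf_time(R: float, D: float, a: float) -> float:
    """Minimal search time of a simple (IDR-less) TF: R^3 / (3 D a)."""
    if not a < R:
        raise ValueError("capture radius a must be smaller than R")
    return R**3 / (3.0 * D * a)


@dataclass(frozen=True)
class RateConversionParams:
    """Cellular parameters for converting search times to rates (SI)."""

    D_SI: float = 1e-13  # m^2/s, one coarse-grained site
    copy_number: int = 100
    nucleus_volume: float = 1e-18  # m^3 (1 um^3)
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if min(self.D_SI, self.copy_number, self.nucleus_volume) <= 0:
            raise ValueError("all rate-conversion parameters must be positive")


@dataclass(frozen=True)
class RateResult:
    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1
    k_D: float  # M
    t_search_s: float  # effective per-cell search time, seconds


def rates(t_total_t0: float, P_TF: float, params: RateConversionParams) -> RateResult:
    """Convert a search time (t0 units) and binding probability to rates.

    ``copy_number`` TFs search in parallel, so the per-cell association
    time is ``t_total / copy_number``; the single target in the nucleus has
    molar concentration ``1 / (N_A V_nuc)``.
    """
    if t_total_t0 <= 0:
        raise ValueError("t_total must be positive")
    if not 0.0 < P_TF < 1.0:
        raise ValueError("P_TF must lie strictly between 0 and 1")
    t0_seconds = BP_IN_M**2 / params.D_SI
    t_eff = t_total_t0 * t0_seconds / params.copy_number
    vol_litre = params.nucleus_volume * 1e3
    c_target = 1.0 / (params.avogadro * vol_litre)  # molar
    k_on = 1.0 / (t_eff * c_target)
    k_off = (1.0 - P_TF) / (P_TF * t_eff)
    return RateResult(k_on=k_on, k_off=k_off, k_D=k_off / k_on, t_search_s=t_eff)
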