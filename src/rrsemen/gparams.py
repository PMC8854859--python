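"""Age-trajectory genetic parameters from fitted covariance functions.

A fitted coefficient covariance K induces the covariance function
cov(t1, t2) = phi(t1)' K phi(t2) over ages. From K_a, K_p and sigma_e^2
this module derives the additive and permanent-environment variance
trajectories, heritability h2(t), repeatability r(t), between-age
genetic correlation surfaces, the population mean curve phi(t)'beta, and
the collection-interval fixed-effect estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .legendre import AgeStandardizer, basis_matrix
from .model import VarComp
from .reml import FitResult

__all__ = [
    "TrajectorySet", "CorrelationSurface", "variance_trajectory",
    "genetic_correlation_matrix", "population_trajectory",
    "interval_effect_estimates", "TRAJECTORY_AGES", "CORRELATION_AGES",
]

#: default reporting grids: weekly trajectory ages and the 9-week
#: correlation grid used for between-age tables
TRAJECTORY_AGES = np.arange(36, 137)
CORRELATION_AGES = np.arange(33, 151, 9)


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectorySet:
    ages: np.ndarray
    sigma_a2: np.ndarray
    sigma_pe2: np.ndarray
    sigma_e2: float
    h2: np.ndarray
    repeatability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_weeks": self.ages,
            "sigma_a2": self.sigma_a2,
            "sigma_pe2": self.sigma_pe2,
            "sigma_e2": np.full(len(self.ages), self.sigma_e2),
            "h2": self.h2,
            "repeatability": self.repeatability,
        })


@dataclass
class CorrelationSurface:
    ages: np.ndarray
    r: np.ndarray  # NaN where the variance at an age is non-positive

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.ages, columns=self.ages)


def _quadratic_form_diag(K: np.ndarray | None, ages, s: AgeStandardizer,
                         k_default: int = 1) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if K is None:
        return np.zeros(len(ages))
    Phi = basis_matrix(ages, K.shape[0] - 1, s)
    return np.einsum("ij,jk,ik->i", Phi, K, Phi)


def variance_trajectory(v: VarComp, ages=None,
                        s: AgeStandardizer | None = None,
                        clamp_negative: bool = True) -> TrajectorySet:
    """sigma_a2(t), sigma_pe2(t), h2(t) and repeatability(t) over an age grid.

    h2 = sigma_a2 / (sigma_a2 + sigma_pe2 + sigma_e2);
    repeatability = (sigma_a2 + sigma_pe2) / (same denominator).
    Small negative computed variances (possible at grid edges with a
    clipped K) are clamped to zero with a warning.
    """
    v = v.validated()
    s = s or AgeStandardizer()
    ages = np.asarray(TRAJECTORY_AGES if ages is None else ages, dtype=float)
    sa = _quadratic_form_diag(v.k_a, ages, s)
    sp = _quadratic_form_diag(v.k_p, ages, s)
    for name, arr in (("sigma_a2", sa), ("sigma_pe2", sp)):
        if np.any(arr < 0):
            if not clamp_negative:
                raise TrajectoryError(f"negative {name} at ages "
                                      f"{ages[arr < 0]}")
            warnings.warn(f"negative {name} clamped to 0 at "
                          f"{int((arr < 0).sum())} ages", RuntimeWarning,
                          stacklevel=2)
            np.clip(arr, 0.0, None, out=arr)
    total = sa + sp + v.sigma_e2
    if np.any(total <= 0):
        raise TrajectoryError("zero total variance at some age")
    return TrajectorySet(ages=ages, sigma_a2=sa, sigma_pe2=sp,
                         sigma_e2=v.sigma_e2, h2=sa / total,
                         repeatability=(sa + sp) / total)


def genetic_correlation_matrix(k_a: np.ndarray, ages=None,
                               s: AgeStandardizer | None = None) -> CorrelationSurface:
    """Between-age genetic correlations r(t1, t2) from K_a.

    Entries at ages with non-positive genetic variance are masked (NaN)
    with a warning.
    """
    s = s or AgeStandardizer()
    ages = np.asarray(CORRELATION_AGES if ages is None else ages, dtype=float)
    k_a = np.asarray(k_a, dtype=float)
    Phi = basis_matrix(ages, k_a.shape[0] - 1, s)
    cov = Phi @ k_a @ Phi.T
    var = np.diag(cov).copy()
    ok = var > 0
    if not ok.all():
        warnings.warn(f"non-positive genetic variance at ages {ages[~ok]}; "
                      "entries masked", RuntimeWarning, stacklevel=2)
    sd = np.sqrt(np.where(ok, var, np.nan))
    r = cov / np.outer(sd, sd)
    r[np.ix_(ok, ok)] = np.clip(r[np.ix_(ok, ok)], -1.0, 1.0)
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    return CorrelationSurface(ages=ages, r=r)


def population_trajectory(beta: np.ndarray, ages=None,
                          s: AgeStandardizer | None = None) -> pd.Series:
    """Population mean curve V(t) = phi(t)' beta in trait units."""
    s = s or AgeStandardizer()
    ages = np.asarray(TRAJECTORY_AGES if ages is None else ages, dtype=float)
    beta = np.asarray(beta, dtype=float)
    Phi = basis_matrix(ages, len(beta) - 1, s)
    return pd.Series(Phi @ beta, index=ages, name="mean_curve")


def interval_effect_estimates(fit: FitResult) -> pd.Series:
    """Collection-interval fixed effects, re-centered so class 1 = 0.

    The reference class dropped from the design contributes an implicit
    zero; if class 1 was filtered from the data the effects are centered
    on the smallest surviving class instead (with a warning). A single
    surviving class carries no contrast: an empty table is returned.
    """
    sol = fit.solutions
    mask = sol.b1.index.get_level_values("factor") == "interval_class"
    est = sol.b1[mask]
    if len(est) == 0:
        warnings.warn("single interval class in data: no estimable interval "
                      "effects", RuntimeWarning, stacklevel=2)
        return pd.Series(dtype=float, name="interval_effect")
    ref_class = int(sol.reference_levels["interval_class"])
    table = pd.Series({int(lvl): float(val)
                       for (_, lvl), val in est.items()})
    table[ref_class] = 0.0
    table = table.sort_index()
    if 1 in table.index:
        table = table - table.loc[1]
    else:
        warnings.warn("interval class 1 absent after QC; effects centered on "
                      f"class {table.index.min()}", RuntimeWarning, stacklevel=2)
        table = table - table.iloc[0]
    table.name = "interval_effect"
    table.index.name = "interval_class"
    return table
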