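"""Age standardization and the normalized Legendre polynomial basis.

All fixed and random regressions on boar age use Legendre polynomials
:math:`P_n` evaluated at a standardized age

.. math:: w = -1 + 2\\,(a - a_{min}) / (a_{max} - a_{min}) \\in [-1, 1],

in their *normalized* form :math:`\\phi_n(w) = \\sqrt{(2n+1)/2}\\,P_n(w)`,
which is orthonormal on :math:`[-1, 1]` under the uniform weight.  The
basis is deliberately evaluated through the classical three-term
recursion rather than a library call; :func:`monomial_coefficients`
expands it exactly (rational arithmetic) for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "AgeStandardizer",
    "legendre_value",
    "normalized_phi",
    "monomial_coefficients",
    "basis_matrix",
]


class AgeRangeError(ValueError):
    """An age falls outside the standardizer's window and clamping is off."""


@dataclass(frozen=True)
class AgeStandardizer:
    """Affine map from an age window (weeks) onto the interval [-1, 1].

    Parameters
    ----------
    a_min, a_max:
        Window endpoints in weeks. Defaults cover the study design
        window of 33-150 weeks.
    clamp:
        If True, ages outside the window are clamped to the nearest
        endpoint instead of raising. Extrapolating a polynomial basis
        outside the fitted age range is unreliable, so the default is
        to refuse.
    """

    a_min: float = 33.0
    a_max: float = 150.0
    clamp: bool = False

    def __post_init__(self) -> None:
        if not self.a_min < self.a_max:
            raise ValueError(f"a_min must be < a_max, got [{self.a_min}, {self.a_max}]")

    def __call__(self, ages) -> np.ndarray:
        a = np.asarray(ages, dtype=float)
        if self.clamp:
            a = np.clip(a, self.a_min, self.a_max)
        else:
            bad = (a < self.a_min) | (a > self.a_max)
            if np.any(bad):
                raise AgeRangeError(
                    f"ages {np.atleast_1d(a)[np.atleast_1d(bad)]} outside "
                    f"[{self.a_min}, {self.a_max}] (set clamp=True to clamp)"
                )
        return -1.0 + 2.0 * (a - self.a_min) / (self.a_max - self.a_min)


def legendre_value(n: int, w) -> np.ndarray:
    """Legendre polynomial P_n(w) by the three-term recursion.

    (n+1) P_{n+1}(w) = (2n+1) w P_n(w) - n P_{n-1}(w), with P_0 = 1, P_1 = w.
    """
    if n < 0:
        raise ValueError("degree must be >= 0")
    w = np.asarray(w, dtype=float)
    p_prev = np.ones_like(w)
    if n == 0:
        return p_prev
    p = w.copy()
    for k in range(1, n):
        p, p_prev = ((2 * k + 1) * w * p - k * p_prev) / (k + 1), p
    return p


def normalized_phi(n: int, w) -> np.ndarray:
    """Normalized basis function phi_n(w) = sqrt((2n+1)/2) * P_n(w)."""
    return np.sqrt((2 * n + 1) / 2.0) * legendre_value(n, w)


@lru_cache(maxsize=None)
def _legendre_fraction_coefficients(n: int) -> tuple[Fraction, ...]:
    """Exact monomial coefficients (constant..leading) of P_n."""
    if n == 0:
        return (Fraction(1),)
    if n == 1:
        return (Fraction(0), Fraction(1))
    p_prev = _legendre_fraction_coefficients(n - 2)
    p = _legendre_fraction_coefficients(n - 1)
    k = n - 1
    out = [Fraction(0)] * (n + 1)
    for i, c in enumerate(p):  # (2k+1) w P_k
        out[i + 1] += Fraction(2 * k + 1, k + 1) * c
    for i, c in enumerate(p_prev):  # - k P_{k-1}
        out[i] -= Fraction(k, k + 1) * c
    return tuple(out)


def monomial_coefficients(n: int) -> np.ndarray:
    """Expansion of phi_n into powers of w, constant term first.

    The P_n part is carried in exact rational arithmetic; only the final
    sqrt((2n+1)/2) normalization is floating point, so rounding to four
    decimals reproduces the tabulated coefficient listings.
    """
    if n < 0:
        raise ValueError("degree must be >= 0")
    frac = _legendre_fraction_coefficients(n)
    return np.sqrt((2 * n + 1) / 2.0) * np.array([float(c) for c in frac])


def basis_matrix(ages, degree: int, s: AgeStandardizer) -> np.ndarray:
    """Matrix of phi_0..phi_degree evaluated at each age (rows = ages)."""
    w = np.atleast_1d(s(ages))
    return np.column_stack([normalized_phi(j, w) for j in range(degree + 1)])
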