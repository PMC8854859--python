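"""Design matrices and the REML likelihood of one trait's random-regression model.

The observation model is

    y = X1 b1 + X2 b2 + Z1 a + Z2 p + e

with class fixed effects (AIYS = AI-center x year x month, and the
collection-interval class) in X1, fixed Legendre age regressions in X2,
additive-genetic random regression coefficients a (one vector per
pedigree animal, covariance K_a x A) in Z1, permanent-environment
coefficients p (one vector per boar with records, covariance K_p, i.i.d.
across boars) in Z2, and homogeneous residual variance sigma_e^2.

Internally the PE and residual terms are absorbed boar by boar into a
block-diagonal covariance R_b = Phi_b K_p Phi_b' + I sigma_e^2, so the
factorized mixed-model equations contain only the fixed effects and the
additive coefficient block. This is algebraically identical to the full
Henderson system (the test suite checks it against a dense
multivariate-normal evaluation) but keeps the factorized system at
(n_fixed + n_animals*(L_A+1)) equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .legendre import AgeStandardizer, basis_matrix
from .pedigree import Pedigree

__all__ = ["ModelSpec", "VarComp", "DesignSet", "build_design",
           "restricted_loglik", "solve_mme", "MMESolution"]

LOG2PI = math.log(2.0 * math.pi)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Trait and polynomial degrees of one candidate model L(a, b, c).

    Orders are maximum polynomial degrees: degree k means k+1 basis
    functions phi_0..phi_k. ``from_label`` accepts the alternative
    convention where the label counts coefficients
    (``convention="count"`` -> degree = k - 1). ``l_additive`` or
    ``l_perm`` may be None to omit that random term entirely.
    """

    trait: str
    l_fixed: int
    l_additive: int | None
    l_perm: int | None

    def __post_init__(self):
        for v in (self.l_fixed, self.l_additive, self.l_perm):
            if v is not None and v < 0:
                raise ValueError("polynomial degrees must be >= 0")

    @property
    def label(self) -> str:
        fmt = lambda v: "-" if v is None else str(v)
        return f"L({self.l_fixed},{fmt(self.l_additive)},{fmt(self.l_perm)})"

    @classmethod
    def from_label(cls, trait: str, label: str, convention: str = "degree") -> "ModelSpec":
        inner = label.strip().removeprefix("L").strip("() ")
        a, b, c = (int(x) for x in inner.replace(";", ",").split(","))
        if convention == "count":
            a, b, c = a - 1, b - 1, c - 1
        elif convention != "degree":
            raise ValueError("convention must be 'degree' or 'count'")
        return cls(trait, a, b, c)


def _check_cov(K: np.ndarray | None, name: str, tol: float = 1e-8) -> np.ndarray | None:
    if K is None:
        return None
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ModelError(f"{name} must be square")
    if not np.allclose(K, K.T, atol=1e-10 * max(1.0, np.abs(K).max())):
        raise ModelError(f"{name} must be symmetric")
    if np.allclose(K, 0.0):
        return None  # zero covariance = term absent
    ev = np.linalg.eigvalsh(K)
    if ev.min() < -tol * max(ev.max(), 1.0):
        raise ModelError(f"{name} is not positive semi-definite (min eig {ev.min():.3g})")
    return K


@dataclass
class VarComp:
    """Coefficient covariance matrices and residual variance.

    ``k_a`` / ``k_p`` may be None (or all-zero, treated the same) when
    the corresponding random term is absent.
    """

    k_a: np.ndarray | None
    k_p: np.ndarray | None
    sigma_e2: float

    def validated(self) -> "VarComp":
        if not self.sigma_e2 > 0:
            raise ModelError(f"sigma_e2 must be > 0, got {self.sigma_e2}")
        return VarComp(_check_cov(self.k_a, "K_a"), _check_cov(self.k_p, "K_p"),
                       float(self.sigma_e2))


@dataclass
class DesignSet:
    """Response and design matrices for one trait, plus level bookkeeping."""

    y: np.ndarray
    X1: np.ndarray                 # class-effect incidence, references dropped
    X2: np.ndarray                 # fixed Legendre regression covariates
    x1_labels: list                # (factor, level) per X1 column
    reference_levels: dict         # factor -> dropped reference level
    phi_a: np.ndarray | None       # per-record additive covariates (n x k_a)
    phi_p: np.ndarray | None       # per-record PE covariates (n x k_p)
    animals: list                  # pedigree order (Z1 column blocks)
    record_boars: list             # boars with records, pedigree order (Z2 blocks)
    boar_of_record: np.ndarray     # index into record_boars per record
    spec: ModelSpec
    standardizer: AgeStandardizer

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.X1, self.X2])

    @property
    def Z1(self) -> sparse.csr_matrix:
        """Additive incidence: animal-major, coefficient-minor, pedigree order."""
        if self.phi_a is None:
            raise ModelError("model has no additive term")
        n, ka = self.phi_a.shape
        amap = {a: i for i, a in enumerate(self.animals)}
        aidx = np.array([amap[self.record_boars[b]] for b in self.boar_of_record])
        rows = np.repeat(np.arange(n), ka)
        cols = (aidx[:, None] * ka + np.arange(ka)[None, :]).ravel()
        return sparse.csr_matrix((self.phi_a.ravel(), (rows, cols)),
                                 shape=(n, len(self.animals) * ka))

    @property
    def Z2(self) -> sparse.csr_matrix:
        """PE incidence: boar-major, coefficient-minor."""
        if self.phi_p is None:
            raise ModelError("model has no permanent-environment term")
        n, kp = self.phi_p.shape
        rows = np.repeat(np.arange(n), kp)
        cols = (self.boar_of_record[:, None] * kp + np.arange(kp)[None, :]).ravel()
        return sparse.csr_matrix((self.phi_p.ravel(), (rows, cols)),
                                 shape=(n, len(self.record_boars) * kp))


def build_design(rt: pd.DataFrame, spec: ModelSpec, ped: Pedigree,
                 s: AgeStandardizer | None = None) -> DesignSet:
    """Assemble the design matrices for a QC-filtered record table.

    One reference level per class factor is dropped (the
    lexicographically/numerically smallest), so that [X1 X2] is full
    rank with phi_0 in X2 acting as the intercept.
    """
    trait = spec.trait.lower()
    if trait not in rt.columns:
        raise ModelError(f"trait column {trait!r} not in record table")
    missing = sorted(set(rt["boar"].astype(str)) - set(ped.index))
    if missing:
        raise ModelError(f"boars missing from pedigree: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    y = rt[trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ModelError(f"missing {trait} values; run QC first")
    if s is None:
        s = AgeStandardizer()

    cols, labels = [], []
    references = {}
    for factor in ("aiys", "interval_class"):
        levels = sorted(rt[factor].dropna().unique())
        if levels:
            references[factor] = levels[0]
        for lvl in levels[1:]:  # first level = reference
            cols.append((rt[factor] == lvl).to_numpy(dtype=float))
            labels.append((factor, lvl))
    X1 = np.column_stack(cols) if cols else np.empty((len(rt), 0))

    ages = rt["age_weeks"].to_numpy(dtype=float)
    X2 = basis_matrix(ages, spec.l_fixed, s)
    phi_a = basis_matrix(ages, spec.l_additive, s) if spec.l_additive is not None else None
    phi_p = basis_matrix(ages, spec.l_perm, s) if spec.l_perm is not None else None

    boars = rt["boar"].astype(str).to_numpy()
    with_records = set(boars)
    record_boars = [a for a in ped.animals if a in with_records]
    bmap = {b: i for i, b in enumerate(record_boars)}
    boar_of_record = np.array([bmap[b] for b in boars])
    return DesignSet(y=y, X1=X1, X2=X2, x1_labels=labels,
                     reference_levels=references, phi_a=phi_a,
                     phi_p=phi_p, animals=list(ped.animals),
                     record_boars=record_boars, boar_of_record=boar_of_record,
                     spec=spec, standardizer=s)


def _logdet_sparse_spd(M: sparse.spmatrix) -> float:
    lu = sparse.linalg.splu(M.tocsc(), diag_pivot_thresh=0.0,
                            options={"SymmetricMode": True})
    return float(np.sum(np.log(lu.U.diagonal())))


class _Workspace:
    """Per-design cache of everything that does not depend on VarComp.

    Holds the working design W = [X | Z1], the per-boar record groups
    with support-restricted dense design blocks, and padded tensors for
    batched per-boar residual-block algebra.
    """

    def __init__(self, d: DesignSet):
        self.d = d
        m_p = len(d.record_boars)
        order = np.argsort(d.boar_of_record, kind="stable")
        bounds = np.searchsorted(d.boar_of_record[order], np.arange(m_p + 1))
        self.boar_rows = [order[bounds[b]:bounds[b + 1]] for b in range(m_p)]

        X = d.X
        self.p = X.shape[1]
        self._Xs = sparse.csr_matrix(X)
        self.yb = [d.y[rows] for rows in self.boar_rows]
        self._blocks: dict = {}

        # padded tensors over boars for batched R-block algebra
        nb = np.array([len(r) for r in self.boar_rows])
        nmax = int(nb.max()) if len(nb) else 0
        B = m_p
        self.nb, self.nmax = nb, nmax
        self.mask = np.arange(nmax)[None, :] < nb[:, None]
        self.rows_pad = np.zeros((B, nmax), dtype=int)
        for b, rows in enumerate(self.boar_rows):
            self.rows_pad[b, :len(rows)] = rows
        if d.phi_p is not None:
            self.phi_p_pad = np.zeros((B, nmax, d.phi_p.shape[1]))
            for b, rows in enumerate(self.boar_rows):
                self.phi_p_pad[b, :len(rows)] = d.phi_p[rows]
        else:
            self.phi_p_pad = None
        self._kron_cache: dict = {}

    def blocks(self, with_additive: bool):
        """(W, per-boar column supports, per-boar dense design blocks)."""
        key = bool(with_additive and self.d.phi_a is not None)
        if key not in self._blocks:
            W = (sparse.hstack([self._Xs, self.d.Z1], format="csr")
                 if key else self._Xs)
            sup, Wd = [], []
            for rows in self.boar_rows:
                sub = W[rows]
                s = np.unique(sub.indices)
                sup.append(s)
                Wd.append(sub[:, s].toarray())
            self._blocks[key] = (W, sup, Wd)
        return self._blocks[key]

    def kron_indices(self, ainv: sparse.spmatrix, ka: int):
        """Flattened scatter indices for A^{-1} (x) K_a^{-1} into C[p:, p:]."""
        key = (id(ainv), ka)
        if key not in self._kron_cache:
            coo = ainv.tocoo()
            i = np.arange(ka)
            rr = (self.p + coo.row[:, None, None] * ka + i[None, :, None]
                  + 0 * i[None, None, :]).ravel()
            cc = (self.p + coo.col[:, None, None] * ka + 0 * i[None, :, None]
                  + i[None, None, :]).ravel()
            self._kron_cache[key] = (rr, cc, coo.data, coo)
        return self._kron_cache[key]


def _workspace(d: DesignSet) -> _Workspace:
    ws = getattr(d, "_ws", None)
    if ws is None:
        ws = _Workspace(d)
        d._ws = ws
    return ws


class MMEFactor:
    """One factorization of the (PE-absorbed) mixed-model equations.

    Exposes the restricted log-likelihood, BLUE/BLUP solutions, and the
    posterior quantities the REML updates need.
    """

    def __init__(self, d: DesignSet, v: VarComp, ainv: sparse.spmatrix,
                 a_logdet: float | None = None):
        v = v.validated()
        self.d, self.v, self.ainv = d, v, ainv
        n = d.n_records
        y = d.y
        sig = v.sigma_e2

        use_a = v.k_a is not None and d.phi_a is not None
        use_p = v.k_p is not None and d.phi_p is not None
        if v.k_a is not None and d.phi_a is None:
            raise ModelError("K_a given but model has no additive term")
        if v.k_p is not None and d.phi_p is None:
            raise ModelError("K_p given but model has no PE term")
        self.use_a, self.use_p = use_a, use_p
        ka = v.k_a.shape[0] if use_a else 0
        kp = v.k_p.shape[0] if use_p else 0
        if use_a and ka != d.phi_a.shape[1]:
            raise ModelError("K_a dimension does not match additive degree")
        if use_p and kp != d.phi_p.shape[1]:
            raise ModelError("K_p dimension does not match PE degree")
        m_a = len(d.animals)
        m_p = len(d.record_boars)
        ws = _workspace(d)
        self.ws = ws
        p = ws.p
        self.ka, self.kp, self.m_a, self.m_p, self.p = ka, kp, m_a, m_p, p
        self.boar_rows = ws.boar_rows
        W, sup_list, Wd_list = ws.blocks(use_a)
        self.W = W
        self._sup, self._Wd = sup_list, Wd_list
        qq = W.shape[1]

        # batched per-boar R_b and R_b^{-1}; identity on the padding keeps
        # determinants and inverses of the true blocks intact
        mask = ws.mask
        pad_diag = np.where(mask, sig, 1.0)
        if use_p:
            Pp = ws.phi_p_pad
            R_pad = np.einsum("bik,kl,bjl->bij", Pp, v.k_p, Pp)
            R_pad *= mask[:, :, None] * mask[:, None, :]
        else:
            R_pad = np.zeros((len(ws.boar_rows), ws.nmax, ws.nmax))
        idx = np.arange(ws.nmax)
        R_pad[:, idx, idx] += pad_diag
        sign, ld = np.linalg.slogdet(R_pad)
        if np.any(sign <= 0):
            raise ModelError("residual block not positive definite")
        self.logdetR = float(ld.sum())
        Rinv_pad = np.linalg.inv(R_pad)
        self._Rinv_pad = Rinv_pad
        self._Rinv_blocks = [Rinv_pad[b, :nb, :nb]
                             for b, nb in enumerate(ws.nb)]

        # assemble C = W' R^{-1} W (+ G^{-1}) and rhs = W' R^{-1} y
        C = np.zeros((qq, qq))
        rhs = np.zeros(qq)
        yRy = 0.0
        U_blocks = []
        for b, rows in enumerate(ws.boar_rows):
            Wd = Wd_list[b]
            sup = sup_list[b]
            Rb_inv = self._Rinv_blocks[b]
            U = Rb_inv @ Wd
            U_blocks.append(U)
            C[np.ix_(sup, sup)] += Wd.T @ U
            ry = Rb_inv @ ws.yb[b]
            rhs[sup] += Wd.T @ ry
            yRy += float(ws.yb[b] @ ry)
        self._U_blocks = U_blocks
        if use_a:
            ka_inv = np.linalg.inv(v.k_a)
            self.ka_inv = ka_inv
            rr, cc, data, _ = ws.kron_indices(ainv, ka)
            vals = (data[:, None, None] * ka_inv[None, :, :]).ravel()
            C[rr, cc] += vals
        try:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise ModelError(
                "singular mixed-model equations; check that class factors are "
                "not confounded after reference-level dropping") from exc
        self.logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        self.s = linalg.cho_solve(cf, rhs, check_finite=False)
        self._cf = cf
        self._Cinv = None
        self.rhs = rhs

        self.yRy = yRy
        self.yPy = yRy - float(self.s @ rhs)
        self.Py = self.apply_Rinv(y - self.W @ self.s)
        # log|G| here covers the additive term only: the PE contribution to
        # log|V| is already inside the absorbed log|R_b| blocks.
        if use_a:
            if a_logdet is None:
                a_logdet = -_logdet_sparse_spd(ainv)
            self.logdetG = ka * a_logdet + m_a * float(np.linalg.slogdet(v.k_a)[1])
        else:
            self.logdetG = 0.0
        self.loglik = -0.5 * ((n - p) * LOG2PI + self.logdetR + self.logdetG
                              + self.logdetC + self.yPy)

    # -- solution views -------------------------------------------------
    def apply_Rinv(self, F: np.ndarray) -> np.ndarray:
        """Block-diagonal R^{-1} F (F is a vector or a column matrix)."""
        ws = self.ws
        vec = F.ndim == 1
        Fm = F[:, None] if vec else F
        out = np.zeros_like(Fm)
        F_pad = Fm[ws.rows_pad] * ws.mask[:, :, None]
        RF = np.einsum("bij,bjk->bik", self._Rinv_pad, F_pad)
        for b, rows in enumerate(ws.boar_rows):
            out[rows] = RF[b, :len(rows)]
        return out[:, 0] if vec else out

    @property
    def Rinv(self) -> sparse.csr_matrix:
        """Sparse block-diagonal R^{-1} (built on demand)."""
        ri_r, ri_c, ri_v = [], [], []
        for rows, Rb_inv in zip(self.ws.boar_rows, self._Rinv_blocks):
            ri_r.append(np.repeat(rows, len(rows)))
            ri_c.append(np.tile(rows, len(rows)))
            ri_v.append(Rb_inv.ravel())
        n = self.d.n_records
        return sparse.csr_matrix(
            (np.concatenate(ri_v), (np.concatenate(ri_r), np.concatenate(ri_c))),
            shape=(n, n))

    @property
    def Cinv(self) -> np.ndarray:
        if self._Cinv is None:
            c, lower = self._cf
            inv, info = linalg.lapack.dpotri(c, lower=lower)
            if info != 0:
                raise ModelError(f"dpotri failed (info={info})")
            tri = np.tril(inv) if lower else np.triu(inv)
            self._Cinv = tri + tri.T - np.diag(np.diag(inv))
        return self._Cinv

    def solve_P(self, F: np.ndarray) -> np.ndarray:
        """Apply the REML projection P = V^-1 - V^-1 X (...) X' V^-1 to columns of F."""
        RF = self.apply_Rinv(F)
        return RF - self.apply_Rinv(self.W @ linalg.cho_solve(
            self._cf, self.W.T @ RF, check_finite=False))

    @property
    def b(self) -> np.ndarray:
        return self.s[: self.p]

    @property
    def a_hat(self) -> np.ndarray:
        """Additive coefficient BLUPs, one row per pedigree animal."""
        if not self.use_a:
            return np.zeros((self.m_a, 0))
        return self.s[self.p:].reshape(self.m_a, self.ka)

    @property
    def p_hat(self) -> np.ndarray:
        """PE coefficient BLUPs, one row per record boar (p~ = K_p Z2' P y)."""
        if not self.use_p:
            return np.zeros((self.m_p, 0))
        out = np.zeros((self.m_p, self.kp))
        for b, rows in enumerate(self.boar_rows):
            out[b] = self.v.k_p @ (self.d.phi_p[rows].T @ self.Py[rows])
        return out

    @property
    def residuals(self) -> np.ndarray:
        """e~ = y - X b - Z1 a - Z2 p (BLUP residual)."""
        e = self.d.y - self.W @ self.s
        if self.use_p:
            ph = self.p_hat
            for b, rows in enumerate(self.boar_rows):
                e[rows] -= self.d.phi_p[rows] @ ph[b]
        return e


@dataclass
class MMESolution:
    """Named BLUE/BLUP solutions of Henderson's equations."""

    b1: pd.Series          # class-effect estimates, reference levels = 0 omitted
    b1_se: pd.Series       # standard errors of those contrasts
    reference_levels: dict # factor -> reference level (effect fixed to 0)
    b2: np.ndarray         # fixed regression coefficients (phi_0..phi_LF)
    a_hat: pd.DataFrame    # additive coefficients per pedigree animal
    p_hat: pd.DataFrame    # PE coefficients per record boar
    residuals: np.ndarray


def _solution_from_factor(fac: MMEFactor) -> MMESolution:
    d = fac.d
    p1 = len(d.x1_labels)
    b = fac.b
    idx = (pd.MultiIndex.from_tuples(d.x1_labels, names=["factor", "level"])
           if d.x1_labels else
           pd.MultiIndex.from_arrays([[], []], names=["factor", "level"]))
    b1 = pd.Series(b[:p1], index=idx, dtype=float)
    # contrast variances: the fixed block of C^{-1} (reference absorbed, so
    # each dummy coefficient is already the contrast against the reference)
    if p1:
        E = np.zeros((fac.W.shape[1], p1))
        E[np.arange(p1), np.arange(p1)] = 1.0
        cov = linalg.cho_solve(fac._cf, E, check_finite=False)[:p1]
        b1_se = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)), index=idx)
    else:
        b1_se = pd.Series(index=idx, dtype=float)
    return MMESolution(
        b1=b1, b1_se=b1_se, reference_levels=dict(d.reference_levels), b2=b[p1:],
        a_hat=pd.DataFrame(fac.a_hat, index=d.animals),
        p_hat=pd.DataFrame(fac.p_hat, index=d.record_boars),
        residuals=fac.residuals,
    )


def restricted_loglik(d: DesignSet, v: VarComp, ainv: sparse.spmatrix,
                      a_logdet: float | None = None) -> float:
    """REML log-likelihood of y (natural log, constants included)."""
    return MMEFactor(d, v, ainv, a_logdet).loglik


def solve_mme(d: DesignSet, v: VarComp, ainv: sparse.spmatrix,
              a_logdet: float | None = None) -> MMESolution:
    """BLUE/BLUP solutions of the mixed-model equations at fixed variances."""
    return _solution_from_factor(MMEFactor(d, v, ainv, a_logdet))
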