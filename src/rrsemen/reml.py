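"""REML estimation of the random-regression variance components,
BIC model scoring, and the polynomial-order grid search.

The estimator is average-information (AI) REML with an
expectation-maximization (EM) fallback: the first iterations use EM
(slow but monotone in the restricted likelihood), subsequent iterations
take AI steps, and any AI step that would leave the parameter space or
decrease the likelihood is replaced by an EM step from the previous
point. Coefficient covariance matrices are kept positive definite by
clipping eigenvalues at 1e-8 of the trace.

Model comparison uses BIC = -2 log(L) + P log(n). Two parameter-count
conventions are carried side by side: the reporting convention
P = a + b + c - 2 for a model L(a, b, c) (matching published
random-regression rank tables), and the conventional count of free
(co)variance parameters, (L_A+1)(L_A+2)/2 + (L_P+1)(L_P+2)/2 + 1, which
is the statistically meaningful one and the default for ranking.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .model import (DesignSet, MMEFactor, MMESolution, ModelError, ModelSpec,
                    VarComp, _solution_from_factor, build_design)
from .pedigree import Pedigree, build_nrm_inverse, nrm_logdet

__all__ = ["REMLOptions", "FitResult", "GridResult", "fit_reml",
           "count_parameters", "bic", "grid_search"]


class REMLError(RuntimeError):
    pass


@dataclass(frozen=True)
class REMLOptions:
    tol: float = 1e-8              # convergence: |delta loglik| below this
    max_iter: int = 200
    n_em_start: int = 2            # EM warm-up iterations before AI steps
    method: str = "lbfgs"          # "lbfgs" (Cholesky scale), "ai", or "em"
    eig_floor: float = 1e-8        # PSD clipping floor, relative to trace
    verbose: bool = False


@dataclass
class FitResult:
    spec: ModelSpec
    varcomp: VarComp
    loglik: float
    n_params_paper: int
    n_params_conventional: int
    bic: float
    bic_conventional: float
    n_records: int
    converged: bool
    iterations: int
    solutions: MMESolution
    boundary: bool = False
    loglik_trace: list = field(default_factory=list)


def count_parameters(spec: ModelSpec, convention: str = "paper") -> int:
    """Number of parameters P entering BIC for a model L(a, b, c).

    "paper" reproduces published rank tables (P = a + b + c - 2);
    "conventional" counts the free covariance parameters.
    """
    la = spec.l_additive if spec.l_additive is not None else -1
    lp = spec.l_perm if spec.l_perm is not None else -1
    if convention == "paper":
        return spec.l_fixed + max(la, 0) + max(lp, 0) - 2
    if convention == "conventional":
        ka, kp = la + 1, lp + 1
        return ka * (ka + 1) // 2 + kp * (kp + 1) // 2 + 1
    raise ValueError("convention must be 'paper' or 'conventional'")


def bic(loglik: float, n_params: int, n: int) -> float:
    """BIC = -2 log(L) + P log(n), natural logarithm."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + n_params * math.log(n)


# ---------------------------------------------------------------------------
# parameter packing: [offdiag-once vech(K_a), vech(K_p), sigma_e2]

def _sym_indices(k: int):
    return [(i, j) for i in range(k) for j in range(i, k)]


def _eigenclip(K: np.ndarray, rel_floor: float) -> tuple[np.ndarray, bool]:
    K = 0.5 * (K + K.T)
    tr = np.trace(K)
    if tr <= 0:
        raise ValueError("non-positive trace")
    floor = rel_floor * tr
    w, V = np.linalg.eigh(K)
    clipped = bool(np.any(w < floor))
    w = np.maximum(w, floor)
    return (V * w) @ V.T, clipped


def _default_init(d: DesignSet) -> VarComp:
    """Diagonal start: K_a at 10%, K_p at 20%, residual at 70% of the
    phenotypic variance (OLS residual variance of y on the fixed part)."""
    X = d.X
    resid = d.y - X @ np.linalg.lstsq(X, d.y, rcond=None)[0]
    vp = float(resid @ resid) / max(len(d.y) - X.shape[1], 1)
    ka = d.phi_a.shape[1] if d.phi_a is not None else None
    kp = d.phi_p.shape[1] if d.phi_p is not None else None
    return VarComp(
        k_a=0.10 * vp * np.eye(ka) if ka else None,
        k_p=0.20 * vp * np.eye(kp) if kp else None,
        sigma_e2=0.70 * vp,
    )


class _IterationStats:
    """Posterior quantities of one factorization needed by EM/AI updates."""

    def __init__(self, fac: MMEFactor, ainv: sparse.spmatrix):
        self.fac = fac
        d, v = fac.d, fac.v
        Py = fac.Py
        kp = fac.kp
        use_p = fac.use_p
        Cinv = fac.Cinv

        trP = 0.0
        H = np.zeros((kp, kp))
        S_v = np.zeros((kp, kp))
        Vb = np.zeros((fac.m_p, kp))
        for b, rows in enumerate(fac.boar_rows):
            Rb_inv = fac._Rinv_blocks[b]
            sup = fac._sup[b]
            U = fac._U_blocks[b]
            Pbb = Rb_inv - U @ Cinv[np.ix_(sup, sup)] @ U.T
            trP += float(np.trace(Pbb))
            if use_p:
                Pb = d.phi_p[rows]
                H += Pb.T @ Pbb @ Pb
                vb = Pb.T @ Py[rows]
                Vb[b] = vb
                S_v += np.outer(vb, vb)
        self.trP, self.H, self.S_v, self.Vb = trP, H, S_v, Vb
        self.PyPy = float(Py @ Py)

        if fac.use_a:
            ka = fac.ka
            At = fac.a_hat
            self.S_a = At.T @ (ainv @ At)
            Cinv_aa = Cinv[fac.p:, fac.p:]
            coo = ainv.tocoo()
            T_a = np.empty((ka, ka))
            for i in range(ka):
                for j in range(ka):
                    T_a[i, j] = float(coo.data @ Cinv_aa[coo.row * ka + i,
                                                         coo.col * ka + j])
            self.T_a = 0.5 * (T_a + T_a.T)

    # -- EM updates (monotone in the restricted likelihood) -----------------
    def em_update(self) -> VarComp:
        fac = self.fac
        v = fac.v
        n = fac.d.n_records
        sig = v.sigma_e2
        k_a = None
        if fac.use_a:
            k_a = (self.S_a + self.T_a) / fac.m_a
        k_p = None
        if fac.use_p:
            S_p = v.k_p @ self.S_v @ v.k_p
            k_p = v.k_p + (S_p - v.k_p @ self.H @ v.k_p) / fac.m_p
        sigma = sig + sig * sig * (self.PyPy - self.trP) / n
        return VarComp(k_a, k_p, sigma)

    # -- gradient and AI matrix ---------------------------------------------
    def gradient(self) -> np.ndarray:
        fac = self.fac
        v = fac.v
        g = []
        if fac.use_a:
            Kinv = fac.ka_inv
            Gm = -0.5 * (fac.m_a * Kinv - Kinv @ (self.S_a + self.T_a) @ Kinv)
            for i, j in _sym_indices(fac.ka):
                g.append(Gm[i, j] if i == j else 2.0 * Gm[i, j])
        if fac.use_p:
            Gm = -0.5 * (self.H - self.S_v)
            for i, j in _sym_indices(fac.kp):
                g.append(Gm[i, j] if i == j else 2.0 * Gm[i, j])
        g.append(-0.5 * (self.trP - self.PyPy))
        return np.array(g)

    def ai_matrix(self) -> np.ndarray:
        fac = self.fac
        d, v = fac.d, fac.v
        cols = []
        if fac.use_a:
            At = fac.a_hat
            Kinv = fac.ka_inv
            zeros_p = np.zeros(fac.p)
            for i, j in _sym_indices(fac.ka):
                E = np.zeros((fac.ka, fac.ka))
                E[i, j] = E[j, i] = 1.0
                coef = At @ (E @ Kinv).T
                cols.append(fac.W @ np.concatenate([zeros_p, coef.ravel()]))
        if fac.use_p:
            for i, j in _sym_indices(fac.kp):
                E = np.zeros((fac.kp, fac.kp))
                E[i, j] = E[j, i] = 1.0
                per_boar = self.Vb @ E.T
                cols.append(np.einsum("nk,nk->n", d.phi_p,
                                      per_boar[d.boar_of_record]))
        cols.append(fac.Py.copy())
        F = np.column_stack(cols)
        PF = fac.solve_P(F)
        AI = 0.5 * (F.T @ PF)
        return 0.5 * (AI + AI.T)


def _pack(v: VarComp, use_a: bool, use_p: bool) -> np.ndarray:
    out = []
    if use_a:
        out += [v.k_a[i, j] for i, j in _sym_indices(v.k_a.shape[0])]
    if use_p:
        out += [v.k_p[i, j] for i, j in _sym_indices(v.k_p.shape[0])]
    out.append(v.sigma_e2)
    return np.array(out)


def _unpack(theta: np.ndarray, template: VarComp, use_a: bool, use_p: bool) -> VarComp:
    pos = 0
    k_a = k_p = None
    if use_a:
        k = template.k_a.shape[0]
        k_a = np.zeros((k, k))
        for i, j in _sym_indices(k):
            k_a[i, j] = k_a[j, i] = theta[pos]
            pos += 1
    if use_p:
        k = template.k_p.shape[0]
        k_p = np.zeros((k, k))
        for i, j in _sym_indices(k):
            k_p[i, j] = k_p[j, i] = theta[pos]
            pos += 1
    return VarComp(k_a, k_p, float(theta[pos]))


def _fit_lbfgs(d: DesignSet, ainv, v0: VarComp, opts: REMLOptions,
               a_logdet: float | None):
    """Quasi-Newton REML on the Cholesky scale.

    Parameters are the lower Cholesky factors of K_a and K_p plus
    log(sigma_e2): the PSD cone becomes unconstrained, which sidesteps
    the boundary and ridge pathologies of raw covariance updates. The
    exact analytic REML gradient is mapped by the chain rule
    d logL / dL = 2 (d logL / dK) L.
    """
    from scipy import optimize

    use_a = v0.k_a is not None
    use_p = v0.k_p is not None
    ka = v0.k_a.shape[0] if use_a else 0
    kp = v0.k_p.shape[0] if use_p else 0
    ila = np.tril_indices(ka)
    ilp = np.tril_indices(kp)
    na = len(ila[0]) if use_a else 0
    npp = len(ilp[0]) if use_p else 0

    def pack(v: VarComp) -> np.ndarray:
        parts = []
        if use_a:
            parts.append(np.linalg.cholesky(v.k_a)[ila])
        if use_p:
            parts.append(np.linalg.cholesky(v.k_p)[ilp])
        parts.append([math.log(v.sigma_e2)])
        return np.concatenate(parts)

    def unpack(th: np.ndarray):
        La = Lp = None
        k_a = k_p = None
        pos = 0
        if use_a:
            La = np.zeros((ka, ka))
            La[ila] = th[:na]
            k_a = La @ La.T
            pos = na
        if use_p:
            Lp = np.zeros((kp, kp))
            Lp[ilp] = th[pos:pos + npp]
            k_p = Lp @ Lp.T
            pos += npp
        return VarComp(k_a, k_p, float(math.exp(th[pos]))), La, Lp

    trace: list[float] = []

    def objective(th: np.ndarray):
        v, La, Lp = unpack(th)
        try:
            v = v.validated()
            if (use_a and v.k_a is None) or (use_p and v.k_p is None):
                raise ModelError("covariance collapsed to zero")
            fac = MMEFactor(d, v, ainv, a_logdet)
            stats = _IterationStats(fac, ainv)
        except (ModelError, np.linalg.LinAlgError, ValueError):
            return 1e12, np.zeros_like(th)
        if not trace or fac.loglik > trace[-1]:
            trace.append(fac.loglik)
        g = []
        if use_a:
            Ki = fac.ka_inv
            Gm = -0.5 * (fac.m_a * Ki - Ki @ (stats.S_a + stats.T_a) @ Ki)
            g.append((2.0 * Gm @ La)[ila])
        if use_p:
            Gm = -0.5 * (stats.H - stats.S_v)
            g.append((2.0 * Gm @ Lp)[ilp])
        g_e = -0.5 * (stats.trP - stats.PyPy)
        g.append([g_e * v.sigma_e2])
        return -fac.loglik, -np.concatenate(g)

    th0 = pack(v0)
    f0, _ = objective(th0)
    if f0 >= 1e12:
        raise REMLError("REML objective undefined at the initial value")
    ftol = max(opts.tol / max(1.0, abs(f0)), 2.3e-16)
    res = optimize.minimize(
        objective, th0, jac=True, method="L-BFGS-B",
        options=dict(maxiter=opts.max_iter, maxfun=6 * opts.max_iter,
                     ftol=ftol, gtol=1e-10))
    v_hat, _, _ = unpack(res.x)
    boundary = False
    k_a = k_p = None
    if use_a:
        k_a, c = _eigenclip(v_hat.k_a, opts.eig_floor)
        boundary |= c
    if use_p:
        k_p, c = _eigenclip(v_hat.k_p, opts.eig_floor)
        boundary |= c
    v_hat = VarComp(k_a, k_p, v_hat.sigma_e2).validated()
    return v_hat, bool(res.status == 0), boundary, trace


def fit_reml(d: DesignSet, ainv: sparse.spmatrix, init: VarComp | None = None,
             opts: REMLOptions | None = None,
             a_logdet: float | None = None) -> FitResult:
    """Estimate VarComp by REML.

    The default method is quasi-Newton (L-BFGS) on the Cholesky scale
    with exact analytic gradients; ``opts.method`` selects damped
    average-information updates with EM fallback ("ai") or pure EM
    ("em") instead. ``ainv`` is the sparse NRM inverse over the design's
    pedigree order; ``a_logdet`` = log|A| may be supplied to avoid
    recomputation.
    """
    opts = opts or REMLOptions()
    v = (init or _default_init(d)).validated()
    use_a = v.k_a is not None
    use_p = v.k_p is not None
    if a_logdet is None and use_a:
        a_logdet = nrm_logdet_from_ainv(ainv)

    if opts.method == "lbfgs":
        v, converged, clipped_last, trace = _fit_lbfgs(d, ainv, v, opts,
                                                       a_logdet)
        fac = MMEFactor(d, v, ainv, a_logdet)
        return _finalize_fit(d, fac, converged, clipped_last, trace)

    def clip(cand: VarComp) -> tuple[VarComp, bool]:
        k_a = k_p = None
        clipped = False
        if use_a:
            k_a, c = _eigenclip(cand.k_a, opts.eig_floor)
            clipped |= c
        if use_p:
            k_p, c = _eigenclip(cand.k_p, opts.eig_floor)
            clipped |= c
        return VarComp(k_a, k_p, cand.sigma_e2), clipped

    trace: list[float] = []
    converged = False
    clipped_last = False
    fac = MMEFactor(d, v, ainv, a_logdet)
    ll = fac.loglik
    prev_ll = -np.inf
    for it in range(1, opts.max_iter + 1):
        trace.append(ll)
        if abs(ll - prev_ll) < opts.tol:
            converged = True
            break
        prev_ll = ll
        stats = _IterationStats(fac, ainv)
        accepted = None  # (v_new, fac_new, clipped, label)

        if opts.method == "ai" and it > opts.n_em_start:
            # damped AI (Levenberg-Marquardt) steps, accepted only when the
            # likelihood does not decrease and the candidate is clippable
            g = stats.gradient()
            AI = stats.ai_matrix()
            scale = np.maximum(np.diag(AI), 1e-12 * np.abs(np.diag(AI)).max() + 1e-300)
            omega = 0.0
            for _ in range(8):
                M = AI + omega * np.diag(scale)
                try:
                    step = linalg.solve(M, g, assume_a="pos")
                except linalg.LinAlgError:
                    omega = max(omega * 10.0, 1e-4)
                    continue
                cand = _unpack(_pack(v, use_a, use_p) + step, v, use_a, use_p)
                if cand.sigma_e2 > 0:
                    try:
                        cand, was_clipped = clip(cand)
                        fac_new = MMEFactor(d, cand, ainv, a_logdet)
                        if fac_new.loglik >= ll - 1e-10:
                            accepted = (cand, fac_new, was_clipped, "ai")
                            break
                    except (ValueError, ModelError):
                        pass
                omega = max(omega * 10.0, 1e-4)

        if accepted is None:
            cand, was_clipped = clip(stats.em_update())
            fac_new = MMEFactor(d, cand, ainv, a_logdet)
            if fac_new.loglik < ll - 1e-6 and not was_clipped:
                raise REMLError(
                    f"log-likelihood decreased after EM step "
                    f"({ll:.6f} -> {fac_new.loglik:.6f}); trace: {trace}")
            accepted = (cand, fac_new, was_clipped, "em")

        v, fac, clipped_last, label = accepted
        ll = fac.loglik
        if opts.verbose:
            print(f"iter {it:3d} loglik {ll:.6f} step {label}")
    return _finalize_fit(d, fac, converged, clipped_last, trace)


def _finalize_fit(d: DesignSet, fac: MMEFactor, converged: bool,
                  boundary: bool, trace: list) -> FitResult:
    if boundary and converged:
        warnings.warn("variance component on the PSD boundary at convergence "
                      "(eigenvalue clipped)", RuntimeWarning, stacklevel=3)
    spec = d.spec
    n = d.n_records
    ll = fac.loglik
    p_paper = count_parameters(spec, "paper")
    p_conv = count_parameters(spec, "conventional")
    return FitResult(
        spec=spec, varcomp=fac.v, loglik=ll,
        n_params_paper=p_paper, n_params_conventional=p_conv,
        bic=bic(ll, p_paper, n), bic_conventional=bic(ll, p_conv, n),
        n_records=n, converged=converged, iterations=len(trace),
        solutions=_solution_from_factor(fac), boundary=boundary,
        loglik_trace=trace,
    )


def nrm_logdet_from_ainv(ainv: sparse.spmatrix) -> float:
    from .model import _logdet_sparse_spd

    return -_logdet_sparse_spd(ainv)


# ---------------------------------------------------------------------------
# grid search

@dataclass
class GridEntry:
    spec: ModelSpec
    fit: FitResult | None
    error: str | None
    rank: int = 0

    @property
    def ok(self) -> bool:
        return self.fit is not None


@dataclass
class GridResult:
    entries: list            # GridEntry, ranked (ascending BIC; failures last)
    convention: str

    @property
    def best(self) -> FitResult:
        if not self.entries or not self.entries[0].ok:
            raise REMLError("no grid model fitted successfully")
        return self.entries[0].fit

    def table(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            f = e.fit
            rows.append({
                "model": e.spec.label,
                "P_paper": count_parameters(e.spec, "paper"),
                "P_conventional": count_parameters(e.spec, "conventional"),
                "minus2logL": -2 * f.loglik if f else np.nan,
                "BIC": (f.bic if self.convention == "paper"
                        else f.bic_conventional) if f else np.nan,
                "rank": e.rank,
                "converged": f.converged if f else False,
                "error": e.error or "",
            })
        return pd.DataFrame(rows)


def grid_search(rt: pd.DataFrame, ped: Pedigree, trait: str, grid,
                s=None, opts: REMLOptions | None = None,
                convention: str = "paper") -> GridResult:
    """Fit every model of the grid and rank by BIC.

    ``grid`` is an iterable of (l_fixed, l_additive, l_perm) tuples or a
    dict of ranges, e.g. {"l_fixed": [2], "l_additive": range(3),
    "l_perm": range(1, 4)}. Individual fit failures are recorded and
    ranked last, not fatal. Ties on BIC go to the smaller conventional
    parameter count, then lexicographic (L_F, L_A, L_P).
    """
    if isinstance(grid, dict):
        cells = list(itertools.product(grid["l_fixed"], grid["l_additive"],
                                       grid["l_perm"]))
    else:
        cells = list(grid)
    ainv = build_nrm_inverse(ped)
    a_logdet = nrm_logdet(ped)
    entries = []
    done: dict = {}

    def pad(K: np.ndarray | None, k: int | None) -> np.ndarray | None:
        # grow a smaller fitted K into a larger one; new orders start at a
        # moderate diagonal (a saddle sits at exactly zero on the
        # Cholesky scale, so "near zero" would stall the optimizer)
        if k is None:
            return None
        if K is None:
            return None  # no information to carry over
        scale = max(np.trace(K) / K.shape[0], 1e-8)
        out = np.eye(k + 1) * 0.1 * scale
        m = min(K.shape[0], k + 1)
        out[:m, :m] = K[:m, :m]
        out[np.diag_indices(k + 1)] = np.maximum(np.diag(out), 0.05 * scale)
        return out

    for lf, la, lp in sorted(cells):
        spec = ModelSpec(trait, lf, la, lp)
        init = None
        for prev in ((lf, la, lp - 1), (lf, la - 1, lp), (lf - 1, la, lp)):
            if prev in done:
                vprev = done[prev].varcomp
                cand = VarComp(pad(vprev.k_a, la), pad(vprev.k_p, lp),
                               vprev.sigma_e2)
                if ((cand.k_a is None) != (la is None)
                        or (cand.k_p is None) != (lp is None)):
                    continue
                try:
                    init = cand.validated()
                    break
                except ModelError:
                    continue
        try:
            d = build_design(rt, spec, ped, s)
            fit = fit_reml(d, ainv, init=init, opts=opts, a_logdet=a_logdet)
            done[(lf, la, lp)] = fit
            entries.append(GridEntry(spec, fit, None))
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            entries.append(GridEntry(spec, None, f"{type(exc).__name__}: {exc}"))

    def key(e: GridEntry):
        if not e.ok:
            return (1, np.inf, np.inf, (e.spec.l_fixed, e.spec.l_additive,
                                        e.spec.l_perm))
        b = e.fit.bic if convention == "paper" else e.fit.bic_conventional
        return (0, b, count_parameters(e.spec, convention),
                (e.spec.l_fixed, e.spec.l_additive, e.spec.l_perm))

    entries.sort(key=key)
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return GridResult(entries, convention)
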