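"""Restricted maximum likelihood for sparse animal-model mixed models.

The engine maximises the restricted log-likelihood of

    y = X b + sum_t Z_t u_t + e,     u_t ~ N(0, K_t sigma2_t),
    e ~ N(0, diag(sigma2_e[class(i)]))

over the variance components, where each random term carries its own
covariance structure K_t supplied through its sparse inverse (the numerator
relationship matrix for genetic terms, identity otherwise) and the residual
may be a single variance (HOM) or one variance per record class, e.g. per
sire family (HET).

Updates are average-information (AI) steps with step-halving and an
expectation-maximisation (EM) fallback whenever an AI proposal leaves the
parameter space or decreases the likelihood; EM steps never decrease the
restricted likelihood, so accepted iterates are monotone.  The mixed-model
equations are assembled sparse and factorised with a dense Cholesky, which is
the right trade-off for the equation sizes this package targets (up to a few
tens of thousands).

−2 logL_R = log|C| + Σ_t (q_t log σ²_t + log|K_t|) + Σ_c n_c log σ²_ec + y'Py
(up to a constant), with C the MME coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = ["RandomTerm", "REMLOptions", "REMLFit", "REMLError", "ai_reml", "mme_solve"]


class REMLError(RuntimeError):
    """Non-convergence or a singular system; carries the last iterate when known."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class RandomTerm:
    """One random effect: incidence Z (n x q) and structure inverse K^-1 (q x q).

    ``k_inv=None`` means an identity structure.  ``log_det_k`` is log|K|
    (0 for identity, sum(log d_i) for a numerator relationship matrix).
    """

    name: str
    Z: sp.csr_matrix
    k_inv: sp.csr_matrix | None = None
    log_det_k: float = 0.0

    @property
    def q(self) -> int:
        return self.Z.shape[1]


@dataclass
class REMLOptions:
    tol_logl: float = 1e-7
    tol_theta: float = 1e-5
    max_iter: int = 200
    floor_frac: float = 1e-8     # component floor as a fraction of var(y)
    verbose: bool = False


@dataclass
class REMLFit:
    """Converged (or last-iterate) REML state."""

    term_names: list
    class_names: list
    sigma2_terms: np.ndarray        # one per random term
    sigma2_resid: np.ndarray        # one per residual class
    se_terms: np.ndarray
    se_resid: np.ndarray
    fixed: np.ndarray               # solutions for b (full-rank columns)
    random: dict                    # name -> solution vector
    residuals: np.ndarray           # y - X b - sum Z u
    loglik: float                   # restricted log-likelihood (-0.5 * minus2)
    n_iter: int = 0
    converged: bool = False
    boundary: dict = field(default_factory=dict)   # name -> bool (at floor)
    history: list = field(default_factory=list)    # logL trace
    n_records: int = 0
    rank_X: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.sigma2_terms, self.sigma2_resid])


def _assemble(X, terms, resid_class, n_classes, theta, y):
    """Build MME coefficient matrix (dense), RHS, and log|R|."""
    n, p = X.shape
    T = len(terms)
    s2_t = theta[:T]
    s2_e = theta[T:]
    r_inv = 1.0 / s2_e[resid_class]
    W = sp.hstack([X] + [t.Z for t in terms], format="csr")
    Wr = W.multiply(r_inv[:, None]).tocsr()
    C = (W.T @ Wr).toarray()
    off = p
    for t, s2 in zip(terms, s2_t):
        if t.k_inv is None:
            ix = np.arange(off, off + t.q)
            C[ix, ix] += 1.0 / s2
        else:
            blk = slice(off, off + t.q)
            C[blk, blk] += (t.k_inv / s2).toarray()
        off += t.q
    rhs = W.T @ (r_inv * y)
    log_det_R = float(np.sum(np.log(s2_e[resid_class])))
    return W, C, rhs, r_inv, log_det_R


def _minus2_loglik(C_chol, theta, terms, resid_class, y, r_inv, rhs, sol):
    T = len(terms)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(C_chol[0]))))
    yPy = float(y @ (r_inv * y) - sol @ rhs)
    out = logdet_C + yPy + float(np.sum(np.log(theta[T:])[resid_class]))
    for t, s2 in zip(terms, theta[:T]):
        out += t.q * np.log(s2) + t.log_det_k
    return out


def _chol_inverse(chol) -> np.ndarray:
    """Full inverse from a Cholesky factor via LAPACK dpotri (half the flops
    of a multi-RHS triangular solve)."""
    c, lower = chol
    inv, info = sla.lapack.dpotri(c, lower=lower)
    if info != 0:
        raise REMLError(f"dpotri failed with info={info}")
    # dpotri fills only the factor's triangle; mirror it into a full matrix
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


def mme_solve(X, terms, resid_class, n_classes, theta, y):
    """Solve the mixed-model equations at fixed variance components.

    Returns (solution vector, Cholesky factor, W, r_inv, rhs, -2logL_R).
    """
    W, C, rhs, r_inv, _ = _assemble(X, terms, resid_class, n_classes, theta, y)
    try:
        chol = sla.cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise REMLError(f"singular mixed-model equations: {exc}") from None
    sol = sla.cho_solve(chol, rhs, check_finite=False)
    m2 = _minus2_loglik(chol, theta, terms, resid_class, y, r_inv, rhs, sol)
    return sol, chol, W, r_inv, rhs, m2


def ai_reml(
    y: np.ndarray,
    X,
    terms: list[RandomTerm],
    resid_class: np.ndarray | None = None,
    n_classes: int | None = None,
    start: np.ndarray | None = None,
    options: REMLOptions | None = None,
) -> REMLFit:
    """Estimate variance components by AI-REML with EM fallback.

    Parameters
    ----------
    y : response vector (n,)
    X : full-column-rank fixed-effect design (sparse or dense)
    terms : random terms (at least one)
    resid_class : per-record residual class index (default: all one class)
    start : optional initial theta (terms first, then residual classes)
    """
    opts = options or REMLOptions()
    y = np.asarray(y, dtype=float)
    n = y.size
    X = sp.csr_matrix(X)
    p = X.shape[1]
    if resid_class is None:
        resid_class = np.zeros(n, dtype=np.int64)
    resid_class = np.asarray(resid_class, dtype=np.int64)
    if n_classes is None:
        n_classes = int(resid_class.max()) + 1
    n_c = np.bincount(resid_class, minlength=n_classes).astype(float)
    if np.any(n_c == 0):
        raise ValueError("every residual class must contain records")
    T = len(terms)
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("response has zero variance")
    floor = opts.floor_frac * vy

    if start is None:
        theta = np.concatenate(
            [np.full(T, 0.5 * vy / max(T, 1)), np.full(n_classes, 0.5 * vy)]
        )
    else:
        theta = np.maximum(np.asarray(start, dtype=float).copy(), floor)
        if theta.size != T + n_classes:
            raise ValueError("start has wrong length")

    class_masks = [resid_class == c for c in range(n_classes)]
    sol, chol, W, r_inv, rhs, m2 = mme_solve(X, terms, resid_class, n_classes, theta, y)
    history = [-0.5 * m2]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        ehat = y - W @ sol
        Py = r_inv * ehat
        Cinv = _chol_inverse(chol)

        # per-record w_i' C^{-1} w_i  (used by residual scores and EM)
        WC = W @ Cinv
        s_rec = np.asarray(W.multiply(WC).sum(axis=1)).ravel()

        # score and EM quantities per parameter
        grad = np.empty(T + n_classes)
        em = np.empty(T + n_classes)
        F = np.empty((n, T + n_classes))
        off = p
        for k, t in enumerate(terms):
            s2 = theta[k]
            u = sol[off : off + t.q]
            blk = Cinv[off : off + t.q, off : off + t.q]
            if t.k_inv is None:
                tr_kinv_c = float(np.trace(blk))
                uku = float(u @ u)
            else:
                tr_kinv_c = float(np.sum(t.k_inv.multiply(blk)))
                uku = float(u @ (t.k_inv @ u))
            trP = (t.q - tr_kinv_c / s2) / s2
            f = (t.Z @ u) / s2
            grad[k] = -0.5 * (trP - float(f @ Py))
            em[k] = (uku + tr_kinv_c) / t.q
            F[:, k] = f
            off += t.q
        for c in range(n_classes):
            m = class_masks[c]
            s2 = theta[T + c]
            trP = n_c[c] / s2 - float(s_rec[m].sum()) / s2**2
            f = np.where(m, Py, 0.0)
            grad[T + c] = -0.5 * (trP - float(f @ f))  # f'Py over the class = sum Py^2
            em[T + c] = float((ehat[m] ** 2 + s_rec[m]).sum()) / n_c[c]
            F[:, T + c] = f

        # average-information matrix: AI_ij = 0.5 f_i' P f_j
        B = sla.cho_solve(chol, W.T @ (F * r_inv[:, None]), check_finite=False)
        PF = r_inv[:, None] * (F - W @ B)
        AI = 0.5 * (F.T @ PF)

        prev_theta = theta.copy()
        prev_m2 = m2
        accepted = False
        # components pinned at the floor with the score pushing further down are
        # boundary solutions: frozen out of updates and convergence checks
        pinned = (theta <= floor * 1.5) & (grad < 0.0)
        free = ~pinned
        delta = None
        if free.any():
            try:
                nf = int(free.sum())
                delta = np.zeros_like(theta)
                delta[free] = np.linalg.solve(
                    AI[np.ix_(free, free)] + 1e-12 * np.eye(nf), grad[free]
                )
            except np.linalg.LinAlgError:
                delta = None
        if delta is not None:
            step = 1.0
            for _ in range(4):  # AI step with halving
                cand = np.maximum(prev_theta + step * delta, floor)
                try:
                    sol_c, chol_c, W, r_inv_c, rhs_c, m2_c = mme_solve(
                        X, terms, resid_class, n_classes, cand, y
                    )
                except REMLError:
                    step *= 0.5
                    continue
                if m2_c <= prev_m2 + 1e-10:
                    theta, sol, chol, r_inv, rhs, m2 = cand, sol_c, chol_c, r_inv_c, rhs_c, m2_c
                    accepted = True
                    break
                step *= 0.5
        if not accepted:  # EM fallback (monotone)
            cand = np.maximum(em, floor)
            cand[pinned] = floor
            sol, chol, W, r_inv, rhs, m2 = mme_solve(
                X, terms, resid_class, n_classes, cand, y
            )
            theta = cand
        history.append(-0.5 * m2)

        at_floor = theta <= floor * 1.5
        rel = np.abs(theta - prev_theta) / np.maximum(np.abs(prev_theta), floor)
        rel[at_floor] = 0.0
        # scaled score |d logL / d log theta| of the free components: a clean
        # optimality measure that stays meaningful when a boundary component
        # makes the likelihood evaluation numerically noisy
        scaled_grad = float(np.max(np.abs(grad * prev_theta)[free], initial=0.0))
        if rel.max() < opts.tol_theta and (
            abs(prev_m2 - m2) < 2 * opts.tol_logl or scaled_grad < 1e-4
        ):
            converged = True
            break

    # approximate SEs from the AI matrix at the solution
    se = np.full(T + n_classes, np.nan)
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        pass

    ehat = y - W @ sol
    random = {}
    off = p
    for t in terms:
        random[t.name] = sol[off : off + t.q]
        off += t.q
    at_floor = theta <= floor * 1.5
    fit = REMLFit(
        term_names=[t.name for t in terms],
        class_names=list(range(n_classes)),
        sigma2_terms=theta[:T],
        sigma2_resid=theta[T:],
        se_terms=se[:T],
        se_resid=se[T:],
        fixed=sol[:p],
        random=random,
        residuals=ehat,
        loglik=-0.5 * m2,
        n_iter=it,
        converged=converged,
        boundary={
            name: bool(flag)
            for name, flag in zip(
                [t.name for t in terms] + [f"resid_{c}" for c in range(n_classes)],
                at_floor,
            )
        },
        history=history,
        n_records=n,
        rank_X=p,
    )
    if not converged:
        raise REMLError(
            f"REML did not converge in {opts.max_iter} iterations "
            f"(last |dlogL| = {abs(prev_m2 - m2):.3g})",
            last_fit=fit,
        )
    return fit
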