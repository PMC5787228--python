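"""REML engines for the genomic prediction models.

Single-trait models use the spectral trick: with V = sigma_g2 (K + lambda I)
and lambda = sigma_e2 / sigma_g2, one eigendecomposition of K turns every
restricted-likelihood evaluation into O(n p^2) work, and the profiled REML
criterion is maximised over log(lambda) by bounded scalar optimisation.

The bivariate model (two traits, unstructured 2x2 genetic and residual
covariances, genetic effects ~ MVN(0, Sigma_g x K)) is fitted by EM-REML on
Henderson's mixed-model equations.  Two numerically identical routes exist:
a dense route for arbitrary patterns of missing trait observations, and an
O(n)-per-iteration route for the complete-data case that exploits the
eigenbasis of K, in which the coefficient matrix becomes 2x2-block diagonal
plus a rank-2 border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = ["reml_kernel", "KernelFit", "BivariateFit", "em_reml_bivariate", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """EM-REML did not converge; carries the last estimates and the trace."""

    def __init__(self, message, sigma_g=None, sigma_e=None, trace=None):
        super().__init__(message)
        self.sigma_g = sigma_g
        self.sigma_e = sigma_e
        self.trace = trace


@dataclass
class KernelFit:
    """Result of a single-kernel REML fit y = X b + g + e, g ~ N(0, sigma_g2 K)."""

    sigma_g2: float
    sigma_e2: float
    lambda_: float  # sigma_e2 / sigma_g2 (the shrinkage ratio)
    beta: np.ndarray
    alpha: np.ndarray  # K @ alpha gives the BLUP of g on any line set
    loglik: float
    g_train: np.ndarray


def reml_kernel(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    lambda_: float | None = None,
    bounds: tuple[float, float] = (-12.0, 12.0),
) -> KernelFit:
    """Profiled REML for a single-variance-ratio mixed model.

    Maximises the restricted likelihood over lambda = sigma_e2/sigma_g2 via
    an eigendecomposition of K; ``lambda_`` may be fixed by the caller (e.g.
    closed-form ridge comparisons).  Returns variance components, GLS fixed
    effects, and the weight vector ``alpha`` with ``g_hat = K alpha``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n != y.size:
        raise ValueError("X and y dimensions disagree")
    K = np.asarray(K, dtype=float)
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-6:
        raise ValueError(
            f"kinship matrix is not PSD (min eigenvalue {s.min():.3g}); add a ridge"
        )
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    if np.ptp(y) < 1e-13:
        beta = np.zeros(p)
        if p:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return KernelFit(0.0, 0.0, np.inf, beta, np.zeros(n), 0.0, np.zeros(n))

    def profile(log_lam: float):
        lam = np.exp(log_lam)
        d = s + lam
        Xd = Xt / d[:, None]
        XtVX = Xt.T @ Xd
        beta = np.linalg.solve(XtVX, Xd.T @ yt)
        r = yt - Xt @ beta
        q = float(r @ (r / d))
        df = n - p
        sigma_g2 = q / df
        ll = -0.5 * (
            df * np.log(sigma_g2)
            + np.log(d).sum()
            + np.linalg.slogdet(XtVX)[1]
            + df
        )
        return ll, beta, r, d, sigma_g2

    if lambda_ is None:
        res = minimize_scalar(
            lambda t: -profile(t)[0], bounds=bounds, method="bounded",
            options={"xatol": 1e-8},
        )
        log_lam = float(res.x)
        # guard the boundaries: compare with near-pure-ridge extremes
        for cand in (bounds[0], bounds[1]):
            if -res.fun < profile(cand)[0]:
                log_lam = cand
    else:
        if lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        log_lam = float(np.log(lambda_))
    ll, beta, r, d, sigma_g2 = profile(log_lam)
    lam = float(np.exp(log_lam))
    alpha = U @ (r / d)
    g_train = K @ alpha
    return KernelFit(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(lam * sigma_g2),
        lambda_=lam,
        beta=np.asarray(beta),
        alpha=alpha,
        loglik=float(ll),
        g_train=g_train,
    )


# ---------------------------------------------------------------------------
# Bivariate EM-REML
# ---------------------------------------------------------------------------


@dataclass
class BivariateFit:
    sigma_g: np.ndarray  # 2x2 genetic covariance
    sigma_e: np.ndarray  # 2x2 residual covariance
    beta: np.ndarray  # trait means
    g_hat: np.ndarray  # n x 2 genetic effects for every line in K
    loglik: float
    n_iter: int
    converged: bool
    trace: list = field(default_factory=list)

    @property
    def genetic_correlation(self) -> float:
        d = np.sqrt(self.sigma_g[0, 0] * self.sigma_g[1, 1])
        return float(self.sigma_g[0, 1] / d) if d > 0 else np.nan


def _clip_psd(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    mat = (mat + mat.T) / 2.0
    w, v = np.linalg.eigh(mat)
    return v @ np.diag(np.clip(w, floor, None)) @ v.T


def em_reml_bivariate(
    y: list[np.ndarray],
    obs: list[np.ndarray],
    K: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    on_nonconvergence: str = "raise",
) -> BivariateFit:
    """EM-REML for the two-trait G-BLUP model with unstructured covariances.

    ``y[t]`` holds the observations of trait t and ``obs[t]`` the positions
    (0-based, indexing rows of K) of the observed lines.  The residual
    covariance between traits is estimated from lines observed for both and
    fixed at zero when no line is co-observed.  Convergence is declared when
    the relative change of the restricted log-likelihood falls below ``tol``.
    """
    n = K.shape[0]
    obs = [np.asarray(o, dtype=int) for o in obs]
    y = [np.asarray(v, dtype=float).ravel() for v in y]
    complete = all(len(o) == n and np.array_equal(np.sort(o), np.arange(n)) for o in obs)

    if init is None:
        sg = np.zeros((2, 2))
        se = np.zeros((2, 2))
        for t in range(2):
            fit = reml_kernel(y[t], np.ones((len(obs[t]), 1)), K[np.ix_(obs[t], obs[t])])
            sg[t, t] = max(fit.sigma_g2, 1e-8 * max(np.var(y[t]), 1e-12))
            se[t, t] = max(fit.sigma_e2, 1e-8 * max(np.var(y[t]), 1e-12))
        shared = np.intersect1d(obs[0], obs[1])
        if len(shared) >= 3:
            m0 = {i: v for i, v in zip(obs[0], y[0])}
            m1 = {i: v for i, v in zip(obs[1], y[1])}
            r = np.corrcoef([m0[i] for i in shared], [m1[i] for i in shared])[0, 1]
            if np.isfinite(r):
                sg[0, 1] = sg[1, 0] = 0.5 * r * np.sqrt(sg[0, 0] * sg[1, 1])
                se[0, 1] = se[1, 0] = 0.5 * r * np.sqrt(se[0, 0] * se[1, 1])
    else:
        sg, se = (np.asarray(m, dtype=float).copy() for m in init)

    co_observed = len(np.intersect1d(obs[0], obs[1])) > 0
    stepper = _em_step_complete if complete else _em_step_dense
    state = _prepare_complete(y, K) if complete else _prepare_dense(y, obs, K)

    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sg_new, se_new, ll, beta, g_hat = stepper(state, sg, se)
        if not co_observed:
            se_new[0, 1] = se_new[1, 0] = 0.0
        sg, se = _clip_psd(sg_new), _clip_psd(se_new)
        trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll
    if not converged:
        msg = f"bivariate EM-REML did not converge in {max_iter} iterations"
        if on_nonconvergence == "raise":
            raise ConvergenceError(msg, sigma_g=sg, sigma_e=se, trace=trace)
        warnings.warn(msg)
    return BivariateFit(
        sigma_g=sg, sigma_e=se, beta=beta, g_hat=g_hat,
        loglik=trace[-1] if trace else np.nan, n_iter=it, converged=converged,
        trace=trace,
    )


def _prepare_dense(y, obs, K):
    n = K.shape[0]
    Kinv = np.linalg.inv(K)
    sign, logdetK = np.linalg.slogdet(K)
    N = len(obs[0]) + len(obs[1])
    # W = [X | M]: trait-mean columns then the 2n genetic-effect columns
    W = np.zeros((N, 2 + 2 * n))
    yv = np.concatenate(y)
    row = 0
    rows_of = [[], []]
    for t in range(2):
        for i in obs[t]:
            W[row, t] = 1.0
            W[row, 2 + t * n + i] = 1.0
            rows_of[t].append(row)
            row += 1
    both = np.intersect1d(obs[0], obs[1])
    pos_in = [{i: r for i, r in zip(obs[t], rows_of[t])} for t in range(2)]
    pair_rows = np.array([[pos_in[0][i], pos_in[1][i]] for i in both], dtype=int).reshape(-1, 2)
    return {
        "n": n, "N": N, "W": W, "y": yv, "obs": obs, "rows_of": rows_of,
        "pair_rows": pair_rows, "Kinv": Kinv, "logdetK": logdetK,
    }


def _em_step_dense(state, sg, se):
    n, N, W, yv = state["n"], state["N"], state["W"], state["y"]
    obs, rows_of, pair_rows = state["obs"], state["rows_of"], state["pair_rows"]
    Kinv, logdetK = state["Kinv"], state["logdetK"]

    # residual precision: per-line 2x2 blocks for co-observed lines
    Rinv = np.zeros((N, N))
    logdetR = 0.0
    se_inv = np.linalg.inv(se)
    co = set(map(tuple, pair_rows))
    flat_pairs = pair_rows.reshape(-1, 2)
    in_pair = np.zeros(N, dtype=bool)
    for r0, r1 in flat_pairs:
        idx = np.array([r0, r1])
        Rinv[np.ix_(idx, idx)] = se_inv
        in_pair[r0] = in_pair[r1] = True
        logdetR += float(np.linalg.slogdet(se)[1])
    for t in range(2):
        for r in rows_of[t]:
            if not in_pair[r]:
                Rinv[r, r] = 1.0 / se[t, t]
                logdetR += np.log(se[t, t])

    sg_inv = np.linalg.inv(sg)
    Ginv = np.kron(sg_inv, Kinv)
    C = W.T @ Rinv @ W
    C[2:, 2:] += Ginv
    rhs = W.T @ (Rinv @ yv)
    Cinv = np.linalg.inv(C)
    beta_g = Cinv @ rhs
    beta = beta_g[:2]
    g = beta_g[2:]
    g_hat = np.column_stack([g[:n], g[n:]])

    # EM updates
    sg_new = np.empty((2, 2))
    for t in range(2):
        for u in range(t, 2):
            block = Cinv[2 + t * n : 2 + (t + 1) * n, 2 + u * n : 2 + (u + 1) * n]
            val = g_hat[:, t] @ Kinv @ g_hat[:, u] + np.sum(Kinv * block.T)
            sg_new[t, u] = sg_new[u, t] = val / n
    resid = yv - W @ beta_g
    WCW = W @ Cinv @ W.T
    se_new = np.zeros((2, 2))
    for t in range(2):
        rr = np.asarray(rows_of[t])
        se_new[t, t] = float(np.mean(resid[rr] ** 2 + WCW[rr, rr]))
    if len(pair_rows):
        r0 = pair_rows[:, 0]
        r1 = pair_rows[:, 1]
        se_new[0, 1] = se_new[1, 0] = float(
            np.mean(resid[r0] * resid[r1] + WCW[r0, r1])
        )
    logdetG = n * np.linalg.slogdet(sg)[1] + 2.0 * logdetK
    ll = -0.5 * (
        logdetR + logdetG + np.linalg.slogdet(C)[1] + float(yv @ Rinv @ yv - beta_g @ rhs)
    )
    return sg_new, se_new, ll, beta, g_hat


def _prepare_complete(y, K):
    n = K.shape[0]
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.clip(s, 1e-10, None)
    yt = np.column_stack([U.T @ y[0], U.T @ y[1]])  # n x 2 rotated data
    x1 = U.T @ np.ones(n)  # rotated intercept column (same for both traits)
    return {"n": n, "s": s, "U": U, "yt": yt, "x1": x1, "logdetK": float(np.log(s).sum())}


def _em_step_complete(state, sg, se):
    """One EM-REML step in the eigenbasis of K (complete data, O(n))."""
    n, s, U, yt, x1 = state["n"], state["s"], state["U"], state["yt"], state["x1"]
    se_inv = np.linalg.inv(se)
    sg_inv = np.linalg.inv(sg)

    # coefficient matrix: 2x2 border A (trait means), blocks D_j = se_inv + sg_inv/s_j
    D = se_inv[None, :, :] + sg_inv[None, :, :] / s[:, None, None]
    Dinv = np.linalg.inv(D)
    A = float(x1 @ x1) * se_inv  # = n * se_inv
    # Schur complement of the g-block: A_s = A - sum_j x1_j^2 * se_inv Dinv_j se_inv
    SDS = np.einsum("j,ab,jbc,cd->ad", x1**2, se_inv, Dinv, se_inv)
    A_s = A - SDS
    C_bb = np.linalg.inv(A_s)

    r_b = se_inv @ (x1 @ yt)  # 2-vector
    r_g = yt @ se_inv.T  # n x 2 (se_inv symmetric)
    # beta = C_bb (r_b - sum_j x1_j se_inv Dinv_j r_gj)
    tmp = np.einsum("ab,jbc,jc->a", se_inv, Dinv, r_g * x1[:, None])
    beta = C_bb @ (r_b - tmp)
    g_t = np.einsum("jab,jb->ja", Dinv, r_g - np.outer(x1, se_inv @ beta))

    # conditional covariance blocks of g_j: C_gjgj = Dinv_j + Dinv_j x1_j se_inv C_bb se_inv x1_j Dinv_j
    M = np.einsum("jab,bc,cd,jde->jae", Dinv, se_inv, C_bb, se_inv @ Dinv)
    C_gg = Dinv + (x1**2)[:, None, None] * M
    # cross-covariance C(b, g_j) = -C_bb x1_j se_inv Dinv_j
    C_bg = -np.einsum("ab,jbc->jac", C_bb @ se_inv, Dinv) * x1[:, None, None]

    # EM update for sigma_g: sum_j (g g' + C_gg)_j / s_j / n
    sg_new = (
        np.einsum("ja,jb,j->ab", g_t, g_t, 1.0 / s) + np.einsum("jab,j->ab", C_gg, 1.0 / s)
    ) / n
    # residuals in the rotated basis
    resid = yt - np.outer(x1, beta) - g_t
    # prediction variance of (x1_j b + g_j): x1^2 C_bb + 2 x1 C_bg + C_gg
    pred_var = (
        (x1**2)[:, None, None] * C_bb[None, :, :]
        + x1[:, None, None] * (C_bg + np.swapaxes(C_bg, 1, 2))
        + C_gg
    )
    se_new = (np.einsum("ja,jb->ab", resid, resid) + pred_var.sum(axis=0)) / n

    logdetR = n * np.linalg.slogdet(se)[1]
    logdetG = n * np.linalg.slogdet(sg)[1] + 2.0 * state["logdetK"]
    logdetC = float(np.linalg.slogdet(D)[1].sum()) + np.linalg.slogdet(A_s)[1]
    quad = float(np.einsum("ja,ab,jb->", yt, se_inv, yt))
    fit_term = float(beta @ r_b + np.einsum("ja,ja->", g_t, r_g))
    ll = -0.5 * (logdetR + logdetG + logdetC + quad - fit_term)

    g_hat = U @ g_t
    return sg_new, se_new, ll, beta, g_hat
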