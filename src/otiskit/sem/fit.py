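"""Maximum-likelihood fitting of observed-variable covariance structures.

The discrepancy function is the normal-theory ML fit function

    F(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p,

with ``Sigma(theta) = (I-B)^-1 Psi (I-B)^-T`` and ``S`` the (n-1)-divisor
sample covariance of listwise-complete data.  The test statistic is
``T = (n-1) F`` on ``df = p(p+1)/2 - q`` degrees of freedom.

Estimation starts from per-equation least squares (which is exact for
just-identified recursive models, so the optimizer only polishes) and uses
L-BFGS with the analytic gradient, followed by Fisher-scoring Newton steps
until the gradient infinity-norm is below tolerance.

``robust_adjust`` adds the distribution-robust layer: casewise-score
sandwich standard errors and the fourth-moment scaling constant
``c = tr(U Gamma)/df`` of the mean-corrected (Satorra-Bentler-type) scaled
statistic ``T_scaled = T / c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ..errors import (
    NonConvergence,
    NonPDSample,
    RankDeficientScores,
    SingularSystem,
)
from .model import SEMSpec

__all__ = ["SEMFit", "implied_covariance", "fit_ml", "robust_adjust"]

_GRAD_TOL = 1e-6


# ----------------------------------------------------------------------
# parameter packing and the implied covariance
# ----------------------------------------------------------------------

def _unpack(spec: SEMSpec, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    B = spec.b_fixed.copy()
    Psi = spec.psi_fixed.copy()
    k = 0
    for i, j in spec.free_b:
        B[i, j] = theta[k]
        k += 1
    for i, j in spec.free_psi:
        Psi[i, j] = Psi[j, i] = theta[k]
        k += 1
    return B, Psi


def implied_covariance(spec: SEMSpec, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = (I-B)^-1 Psi (I-B)^-T."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (spec.n_free,):
        raise ValueError(f"theta must have length {spec.n_free}")
    B, Psi = _unpack(spec, theta)
    eye = np.eye(spec.p)
    try:
        G = linalg.solve(eye - B, eye)
    except linalg.LinAlgError as exc:
        raise SingularSystem("(I - B) is singular") from exc
    return G @ Psi @ G.T


def _sigma_chain(spec: SEMSpec, theta: np.ndarray):
    B, Psi = _unpack(spec, theta)
    eye = np.eye(spec.p)
    mat = eye - B
    if abs(linalg.det(mat)) < 1e-12:
        raise SingularSystem("(I - B) is singular")
    G = linalg.solve(mat, eye)
    Sigma = G @ Psi @ G.T
    return B, Psi, G, Sigma


def _f_and_grad(spec: SEMSpec, theta: np.ndarray, S: np.ndarray, logdet_S: float):
    """F_ML and its analytic gradient; +inf with a zero gradient outside the
    positive-definite region (the optimizer then backtracks)."""
    try:
        _, _, G, Sigma = _sigma_chain(spec, theta)
        cho = linalg.cho_factor(Sigma, lower=True)
    except (SingularSystem, linalg.LinAlgError):
        return np.inf, np.zeros(spec.n_free)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    W = linalg.cho_solve(cho, np.eye(spec.p))
    F = logdet + float(np.sum(W * S)) - logdet_S - spec.p
    C = W @ (Sigma - S) @ W  # dF = tr(C dSigma)

    grad = np.empty(spec.n_free)
    SCG = Sigma @ C @ G
    GCG = G.T @ C @ G
    k = 0
    for i, j in spec.free_b:
        grad[k] = 2.0 * SCG[j, i]
        k += 1
    for i, j in spec.free_psi:
        grad[k] = GCG[i, j] if i == j else 2.0 * GCG[i, j]
        k += 1
    return F, grad


def _delta_matrix(spec: SEMSpec, theta: np.ndarray) -> np.ndarray:
    """dvech(Sigma)/dtheta', shape (p(p+1)/2, q)."""
    _, _, G, Sigma = _sigma_chain(spec, theta)
    rows, cols = np.tril_indices(spec.p)
    cells = []
    for i, j in spec.free_b:
        M = np.outer(G[:, i], Sigma[j, :])
        cells.append(M + M.T)
    for i, j in spec.free_psi:
        M = np.outer(G[:, i], G[:, j])
        cells.append(M if i == j else M + M.T)
    return np.stack([d[rows, cols] for d in cells], axis=1)


def _duplication_weight(W: np.ndarray) -> np.ndarray:
    """V = 0.5 * D' (W kron W) D in vech coordinates, computed directly:
    V[(ij),(kl)] = 0.5 * m_ij * m_kl * (W_ik W_jl + W_il W_jk) with
    multiplicities m = 2 for off-diagonal vech elements."""
    p = W.shape[0]
    rows, cols = np.tril_indices(p)
    mult = np.where(rows == cols, 1.0, 2.0)
    V = 0.5 * (
        W[np.ix_(rows, rows)] * W[np.ix_(cols, cols)]
        + W[np.ix_(rows, cols)] * W[np.ix_(cols, rows)]
    )
    return V * np.outer(mult, mult) * 0.5  # account for symmetric double-count


def _vech(M: np.ndarray) -> np.ndarray:
    rows, cols = np.tril_indices(M.shape[0])
    return M[rows, cols]


# ----------------------------------------------------------------------
# starting values: per-equation least squares from S
# ----------------------------------------------------------------------

def _ols_start(spec: SEMSpec, S: np.ndarray) -> np.ndarray:
    theta = np.zeros(spec.n_free)
    slots: dict[tuple[str, int, int], int] = {}
    for k, (i, j) in enumerate(spec.free_b):
        slots[("B", i, j)] = k
    off = len(spec.free_b)
    for k, (i, j) in enumerate(spec.free_psi):
        slots[("P", i, j)] = off + k

    by_child: dict[int, list[int]] = {}
    for i, j in spec.free_b:
        by_child.setdefault(i, []).append(j)

    resid_var = np.diag(S).copy()
    for child, parents in by_child.items():
        parents = sorted(parents)
        Sxx = S[np.ix_(parents, parents)]
        Sxy = S[np.ix_(parents, [child])].ravel()
        try:
            b = linalg.solve(Sxx, Sxy, assume_a="pos")
        except linalg.LinAlgError:
            b = linalg.lstsq(Sxx, Sxy)[0]
        for j, bj in zip(parents, b):
            theta[slots[("B", child, j)]] = bj
        resid_var[child] = max(S[child, child] - float(Sxy @ b), 1e-3 * S[child, child])

    # variances from the per-equation residuals; free covariances start at
    # the sample covariance when both variables are exogenous, else 0
    endo = set(by_child)
    for i, j in spec.free_psi:
        k = slots[("P", i, j)]
        if i == j:
            theta[k] = resid_var[i]
        else:
            theta[k] = S[i, j] if (i not in endo and j not in endo) else 0.0
    return theta


# ----------------------------------------------------------------------
# fit container
# ----------------------------------------------------------------------

@dataclass
class SEMFit:
    spec: SEMSpec
    theta: np.ndarray
    S: np.ndarray
    Sigma: np.ndarray
    F_ML: float
    T: float
    df: int
    n_obs: int
    naive_se: np.ndarray
    naive_cov: np.ndarray
    grad_norm: float
    n_iter: int
    logdet_S: float
    # internal unit-variance metric (numerical conditioning; the model is
    # scale-equivariant, so the optimum is the same)
    sds: np.ndarray | None = None
    theta_scaled: np.ndarray | None = None
    S_scaled: np.ndarray | None = None
    Sigma_scaled: np.ndarray | None = None
    # robust layer (filled by robust_adjust)
    robust_se: np.ndarray | None = None
    robust_cov: np.ndarray | None = None
    scaling_c: float | None = None
    T_scaled: float | None = None
    baseline_c: float | None = None
    data_moments: np.ndarray | None = None  # Gamma: cov of vech(zz')

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names()

    # -- standardization ------------------------------------------------
    def standardized(self, theta: np.ndarray | None = None) -> np.ndarray:
        """Standardized free parameters: path i<-j scaled by sd_j/sd_i,
        (co)variances by 1/(sd_i sd_j), from the model-implied SDs."""
        th = self.theta if theta is None else theta
        Sigma = implied_covariance(self.spec, th)
        sd = np.sqrt(np.diag(Sigma))
        out = np.empty(self.spec.n_free)
        k = 0
        for i, j in self.spec.free_b:
            out[k] = th[k] * sd[j] / sd[i]
            k += 1
        for i, j in self.spec.free_psi:
            out[k] = th[k] / (sd[i] * sd[j])
            k += 1
        return out

    def standardized_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Estimates with naive/robust SEs, Wald tests, and delta-method CIs
        for the standardized solution (robust covariance when available)."""
        cov = self.robust_cov if self.robust_cov is not None else self.naive_cov
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        std = self.standardized()
        J = _numeric_jacobian(self.standardized, self.theta)
        std_se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", J, cov, J), 0, None))
        zcrit = stats.norm.ppf(1 - alpha / 2)
        z = np.divide(self.theta, se, out=np.full_like(se, np.nan), where=se > 0)
        ops = ["~"] * len(self.spec.free_b) + ["~~"] * len(self.spec.free_psi)
        v = self.spec.variables
        pairs = [(v[i], v[j]) for i, j in self.spec.free_b] + [
            (v[i], v[j]) for i, j in self.spec.free_psi
        ]
        return pd.DataFrame(
            {
                "lhs": [a for a, _ in pairs],
                "op": ops,
                "rhs": [b for _, b in pairs],
                "estimate": self.theta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
                "std": std,
                "std_se": std_se,
                "std_ci_low": std - zcrit * std_se,
                "std_ci_high": std + zcrit * std_se,
            }
        )

    def path_std(self, child: str, parent: str) -> float:
        """Standardized coefficient of one regression path."""
        i, j = self.spec.index(child), self.spec.index(parent)
        k = self.spec.free_b.index((i, j))
        return float(self.standardized()[k])


def _numeric_jacobian(fun, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    f0 = fun(x)
    J = np.empty((f0.size, x.size))
    for k in range(x.size):
        step = eps * max(1.0, abs(x[k]))
        xp = x.copy(); xp[k] += step
        xm = x.copy(); xm[k] -= step
        J[:, k] = (fun(xp) - fun(xm)) / (2 * step)
    return J


# ----------------------------------------------------------------------
# estimation
# ----------------------------------------------------------------------

def _scale_jacobian(spec: SEMSpec, sds: np.ndarray) -> np.ndarray:
    """Diagonal Jacobian d(theta_raw)/d(theta_scaled): paths i<-j scale by
    sd_i/sd_j, (co)variances by sd_i*sd_j."""
    jac = np.empty(spec.n_free)
    k = 0
    for i, j in spec.free_b:
        jac[k] = sds[i] / sds[j]
        k += 1
    for i, j in spec.free_psi:
        jac[k] = sds[i] * sds[j]
        k += 1
    return jac


def fit_ml(
    spec: SEMSpec,
    data: pd.DataFrame,
    grad_tol: float = _GRAD_TOL,
    max_iter: int = 500,
) -> SEMFit:
    """Fit the model to listwise-complete data by normal-theory ML.

    Optimization runs in a unit-variance internal metric (every variable
    divided by its sample SD); since every variable's variance is free, the
    model family is closed under diagonal rescaling and the optimum maps
    back exactly to raw units, while the information matrix stays
    well-conditioned for variables on disparate scales.
    """
    X = data[spec.variables].dropna().to_numpy(dtype=float)
    n = X.shape[0]
    if n <= spec.p:
        raise ValueError(f"need more observations ({n}) than variables ({spec.p})")
    S_raw = np.cov(X, rowvar=False, ddof=1)
    sds = np.sqrt(np.diag(S_raw))
    if (sds <= 0).any():
        raise NonPDSample("constant variable in the sample")
    S = S_raw / np.outer(sds, sds)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        raise NonPDSample("sample covariance is not positive definite")

    theta0 = _ols_start(spec, S)
    fun = lambda th: _f_and_grad(spec, th, S, logdet_S)

    F0, g0 = fun(theta0)
    n_iter = 0
    if np.isfinite(F0) and np.max(np.abs(g0)) < grad_tol:
        theta, F, grad = theta0, F0, g0
    else:
        res = optimize.minimize(
            fun, theta0, jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta, n_iter = res.x, res.nit
        F, grad = fun(theta)
        # Fisher-scoring polish to drive the gradient to tolerance
        for _ in range(100):
            if np.max(np.abs(grad)) < grad_tol:
                break
            Delta = _delta_matrix(spec, theta)
            Sigma = implied_covariance(spec, theta)
            W = linalg.inv(Sigma)
            V = _duplication_weight(W)
            H = 2.0 * Delta.T @ V @ Delta  # expected Hessian of F
            try:
                step = linalg.solve(H, grad, assume_a="pos")
            except linalg.LinAlgError:
                break
            t = 1.0
            for _ in range(30):
                F_new, g_new = fun(theta - t * step)
                if F_new <= F + 1e-12:
                    break
                t /= 2
            else:
                break
            theta, F, grad = theta - t * step, F_new, g_new
            n_iter += 1
        if np.max(np.abs(grad)) >= grad_tol:
            raise NonConvergence(
                f"gradient norm {np.max(np.abs(grad)):.2e} after {n_iter} iterations"
            )

    F = max(F, 0.0)
    Sigma = implied_covariance(spec, theta)
    W = linalg.inv(Sigma)
    Delta = _delta_matrix(spec, theta)
    V = _duplication_weight(W)
    info = (n - 1) * Delta.T @ V @ Delta
    try:
        naive_cov = linalg.inv(info)
    except linalg.LinAlgError:
        naive_cov = linalg.pinv(info)

    # back to raw units (F, T, df are scale-invariant)
    jac = _scale_jacobian(spec, sds)
    theta_raw = theta * jac
    naive_cov_raw = naive_cov * np.outer(jac, jac)
    sign_raw, logdet_S_raw = np.linalg.slogdet(S_raw)

    return SEMFit(
        spec=spec, theta=theta_raw, S=S_raw,
        Sigma=Sigma * np.outer(sds, sds), F_ML=float(F),
        T=float((n - 1) * F), df=spec.df, n_obs=n,
        naive_se=np.sqrt(np.clip(np.diag(naive_cov_raw), 0, None)),
        naive_cov=naive_cov_raw,
        grad_norm=float(np.max(np.abs(grad))), n_iter=n_iter,
        logdet_S=logdet_S_raw,
        sds=sds, theta_scaled=theta, S_scaled=S, Sigma_scaled=Sigma,
    )


def robust_adjust(fit: SEMFit, data: pd.DataFrame) -> SEMFit:
    """Add sandwich standard errors and the scaled test statistic.

    The bread is the expected information, the meat the empirical
    second moment of the casewise scores
    ``s_ik = 0.5 (z_i' W Delta_k W z_i - tr(W Delta_k))``.  The scaling
    constant is ``c = tr(U Gamma)/df`` with ``U`` the residual normal-theory
    weight after projecting out the model tangent space and ``Gamma`` the
    empirical fourth-moment covariance of vech(z z').
    """
    spec = fit.spec
    X = data[spec.variables].dropna().to_numpy(dtype=float)
    n = X.shape[0]
    if n != fit.n_obs:
        raise ValueError("data does not match the fitted sample")
    # work in the unit-variance internal metric (scale-invariant statistics)
    Z = (X - X.mean(axis=0)) / fit.sds

    Sigma = fit.Sigma_scaled
    W = linalg.inv(Sigma)
    Delta = _delta_matrix(spec, fit.theta_scaled)
    V = _duplication_weight(W)

    rows, cols = np.tril_indices(spec.p)
    # d_i = vech(z_i z_i')
    D = Z[:, rows] * Z[:, cols]
    dbar = D.mean(axis=0)
    Gamma = (D - dbar).T @ (D - dbar) / n

    # casewise scores: s = (ZWw)·... computed via the vech trick:
    # z'WΔkWz = vech(WΔkW) · m ⊙ d_i  with multiplicities for off-diagonals
    mult = np.where(rows == cols, 1.0, 2.0)
    q = spec.n_free
    A = np.empty((q, len(rows)))
    tr_wd = np.empty(q)
    # rebuild full Delta matrices (vech -> full symmetric)
    for k in range(q):
        Dk = np.zeros((spec.p, spec.p))
        Dk[rows, cols] = Delta[:, k]
        Dk[cols, rows] = Delta[:, k]
        M = W @ Dk @ W
        A[k] = M[rows, cols] * mult
        tr_wd[k] = float(np.sum(W * Dk))
    scores = 0.5 * (D @ A.T - tr_wd)

    meat = scores.T @ scores
    # a singular meat is legitimate (e.g. balanced binary covariates have
    # degenerate fourth moments: z^2 is constant); the sandwich only inverts
    # the bread.  Reject only when the cases cannot span the parameter space.
    if n <= q:
        raise RankDeficientScores(
            f"{n} cases cannot span {q} score dimensions"
        )
    bread_inv = linalg.inv(n * Delta.T @ V @ Delta)
    robust_cov = bread_inv @ meat @ bread_inv * (n / (n - 1))
    jac = _scale_jacobian(spec, fit.sds)
    robust_cov = robust_cov * np.outer(jac, jac)
    fit.robust_cov = robust_cov
    fit.robust_se = np.sqrt(np.clip(np.diag(robust_cov), 0, None))

    if fit.df > 0:
        VD = V @ Delta
        try:
            inner = linalg.solve(Delta.T @ VD, VD.T, assume_a="pos")
        except linalg.LinAlgError:
            inner = linalg.lstsq(Delta.T @ VD, VD.T)[0]
        U = V - VD @ inner
        c = float(np.sum(U * Gamma.T)) / fit.df
        if c <= 0:
            c = 1.0
        fit.scaling_c = c
        fit.T_scaled = fit.T / c
    else:
        fit.scaling_c = 1.0
        fit.T_scaled = fit.T
    fit.data_moments = Gamma
    return fit
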