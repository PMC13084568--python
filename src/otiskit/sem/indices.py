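"""Global fit indices and score-test modification indices.

Incremental indices compare the target model's statistic ``T`` to the
independence baseline ``T0`` (all covariances zero, variances free, fitted
in closed form).  Robust variants substitute the scaled statistics
``T/c`` and ``T0/c0`` into the same formulas; the scaling constants come
from the fourth-moment machinery in :mod:`otiskit.sem.fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .fit import SEMFit, _delta_matrix, _duplication_weight, _f_and_grad, implied_covariance
from .model import SEMSpec

__all__ = ["FitIndices", "fit_indices", "modification_indices", "ModIndexRow"]


@dataclass
class FitIndices:
    chi2: float
    df: int
    p_chi2: float
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    ifi: float
    nfi: float
    gfi: float
    agfi: float
    rmsea: float
    rmsea_ci_low: float
    rmsea_ci_high: float
    srmr: float
    # scaled-statistic (robust) variants
    chi2_scaled: float | None = None
    cfi_robust: float | None = None
    tli_robust: float | None = None
    rmsea_robust: float | None = None
    saturated: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _baseline(fit: SEMFit) -> tuple[float, int]:
    """Independence model in closed form: Sigma0 = diag(S), so
    F0 = sum(ln s_ii) - ln|S|."""
    s_ii = np.diag(fit.S)
    F0 = float(np.sum(np.log(s_ii)) - fit.logdet_S)
    p = fit.spec.p
    return (fit.n_obs - 1) * F0, p * (p - 1) // 2


def _baseline_scaling(fit: SEMFit) -> float:
    """Scaling constant of the independence model (variances free)."""
    if fit.data_moments is None:
        return 1.0
    p = fit.spec.p
    # data_moments (Gamma) live in the unit-variance internal metric
    W0 = np.diag(1.0 / np.diag(fit.S_scaled))
    V0 = _duplication_weight(W0)
    rows, cols = np.tril_indices(p)
    # Delta of the baseline: derivative wrt each free variance = E_ii
    Delta0 = np.zeros((len(rows), p))
    for i in range(p):
        Delta0[(rows == i) & (cols == i), i] = 1.0
    VD = V0 @ Delta0
    U0 = V0 - VD @ linalg.solve(Delta0.T @ VD, VD.T)
    df0 = p * (p - 1) // 2
    c0 = float(np.sum(U0 * fit.data_moments.T)) / df0
    return c0 if c0 > 0 else 1.0


def _rmsea(T: float, df: int, n: int) -> float:
    return float(np.sqrt(max(T - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0


def _rmsea_ci(T: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentral-chi-square inversion for the RMSEA confidence limits."""
    if df <= 0 or not np.isfinite(T):
        return 0.0, 0.0
    lo_tail, hi_tail = (1 + level) / 2, (1 - level) / 2

    def bound(tail):
        if stats.chi2.cdf(T, df) < tail:  # no nc solves it
            return 0.0
        f = lambda nc: stats.ncx2.cdf(T, df, nc) - tail
        hi = max(T * 2, df + 10.0)
        while f(hi) > 0 and hi < 1e8:
            hi *= 4
        if f(hi) > 0:
            return np.nan
        nc = optimize.brentq(f, 0.0, hi)
        return float(np.sqrt(nc / (df * (n - 1))))

    return bound(lo_tail), bound(hi_tail)


def _incremental(T: float, df: int, T0: float, df0: int) -> dict[str, float]:
    cfi = 1.0 - max(T - df, 0.0) / max(T0 - df0, T - df, 1e-12)
    denom = (T0 / df0 - 1.0) if df0 > 0 else np.nan
    tli = ((T0 / df0) - (T / df)) / denom if df > 0 and denom else 1.0
    nfi = (T0 - T) / T0 if T0 > 0 else 1.0
    ifi = (T0 - T) / (T0 - df) if (T0 - df) != 0 else 1.0
    return {"cfi": float(np.clip(cfi, 0, 1)), "tli": float(tli),
            "nfi": float(np.clip(nfi, 0, 1)), "ifi": float(ifi)}


def fit_indices(fit: SEMFit) -> FitIndices:
    """Compute the full index panel; the scaled variants require a prior
    :func:`~otiskit.sem.fit.robust_adjust`."""
    n, df = fit.n_obs, fit.df
    T = fit.T
    T0, df0 = _baseline(fit)
    saturated = df == 0

    if saturated:
        inc = {"cfi": 1.0, "tli": 1.0, "nfi": 1.0, "ifi": 1.0}
        rmsea, ci = 0.0, (0.0, 0.0)
        p_chi2 = 1.0
    else:
        inc = _incremental(T, df, T0, df0)
        rmsea = _rmsea(T, df, n)
        ci = _rmsea_ci(T, df, n)
        p_chi2 = float(stats.chi2.sf(T, df))

    W = linalg.inv(fit.Sigma)
    R = W @ (fit.S - fit.Sigma)
    gfi = 1.0 - float(np.sum(R * R.T)) / float(np.sum((W @ fit.S) * (W @ fit.S).T))
    p = fit.spec.p
    pstar = p * (p + 1) / 2
    agfi = 1.0 - (pstar / df) * (1.0 - gfi) if df > 0 else 1.0

    sd = np.sqrt(np.diag(fit.S))
    resid = (fit.S - fit.Sigma) / np.outer(sd, sd)
    rows, cols = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[rows, cols] ** 2)))

    out = FitIndices(
        chi2=T, df=df, p_chi2=p_chi2, chi2_baseline=T0, df_baseline=df0,
        gfi=float(np.clip(gfi, 0, 1)), agfi=float(agfi),
        rmsea=rmsea, rmsea_ci_low=ci[0], rmsea_ci_high=ci[1],
        srmr=srmr, saturated=saturated, **inc,
    )

    if fit.T_scaled is not None and not saturated:
        c0 = _baseline_scaling(fit)
        fit.baseline_c = c0
        T_sc, T0_sc = fit.T_scaled, T0 / c0
        inc_r = _incremental(T_sc, df, T0_sc, df0)
        out.chi2_scaled = T_sc
        out.cfi_robust = inc_r["cfi"]
        out.tli_robust = inc_r["tli"]
        out.rmsea_robust = _rmsea(T_sc, df, n)
    elif fit.T_scaled is not None:
        out.chi2_scaled = fit.T_scaled
        out.cfi_robust, out.tli_robust, out.rmsea_robust = 1.0, 1.0, 0.0
    return out


# ----------------------------------------------------------------------
# modification indices
# ----------------------------------------------------------------------

@dataclass
class ModIndexRow:
    lhs: str
    op: str
    rhs: str
    mi: float
    p: float
    epc: float
    flagged: bool


def modification_indices(fit: SEMFit, alpha: float = 0.05) -> pd.DataFrame:
    """Univariate score statistics for every fixed-at-zero path and error
    covariance: the expected chi-square drop (1 df) from freeing that cell,
    with the expected parameter change (EPC).

    MI = U^2 / (H_gg - H_gt H_tt^-1 H_tg) with U the restricted-model score
    and H the expected information over (free params, candidate).
    """
    spec = fit.spec
    n = fit.n_obs
    # scaled internal metric: MI and its p are scale-invariant; the EPC is
    # converted back to raw units at the end
    S = fit.S_scaled
    from .fit import _unpack

    B, Psi = _unpack(spec, fit.theta_scaled)
    Sigma = fit.Sigma_scaled
    sds = fit.sds
    W = linalg.inv(Sigma)
    G = linalg.inv(np.eye(spec.p) - B)
    C = W @ (Sigma - S) @ W
    SCG = Sigma @ C @ G
    GCG = G.T @ C @ G

    Delta = _delta_matrix(spec, fit.theta_scaled)
    V = _duplication_weight(W)
    H_tt = Delta.T @ V @ Delta

    free_b = set(spec.free_b)
    free_psi = {(min(i, j), max(i, j)) for i, j in spec.free_psi}
    rows_idx, cols_idx = np.tril_indices(spec.p)

    candidates: list[tuple[str, int, int]] = []
    for i in range(spec.p):
        for j in range(spec.p):
            if i != j and (i, j) not in free_b and B[i, j] == 0.0:
                candidates.append(("~", i, j))
    for i, j in zip(rows_idx, cols_idx):
        i, j = int(i), int(j)
        if i != j and (j, i) not in free_psi and Psi[i, j] == 0.0:
            candidates.append(("~~", i, j))

    out = []
    for op, i, j in candidates:
        if op == "~":
            g = 2.0 * SCG[j, i]
            M = np.outer(G[:, i], Sigma[j, :])
            d_full = M + M.T
        else:
            g = 2.0 * GCG[min(i, j), max(i, j)]
            M = np.outer(G[:, i], G[:, j])
            d_full = M + M.T
        d = d_full[rows_idx, cols_idx]
        h_gg = float(d @ V @ d)
        h_gt = d @ V @ Delta
        try:
            schur = h_gg - float(h_gt @ linalg.solve(H_tt, h_gt))
        except linalg.LinAlgError:
            continue
        if schur <= 1e-12:
            continue
        # score U = -((n-1)/2) g; info Schur = (n-1) schur  =>  MI = U^2/info
        mi = (n - 1) * g**2 / (4.0 * schur)
        epc = g / (-2.0 * schur)
        epc *= (sds[i] / sds[j]) if op == "~" else (sds[i] * sds[j])
        p_mi = float(stats.chi2.sf(mi, 1))
        out.append(
            ModIndexRow(
                lhs=spec.variables[i], op=op, rhs=spec.variables[j],
                mi=float(mi), p=p_mi, epc=float(epc), flagged=p_mi < alpha,
            )
        )
    df = pd.DataFrame([asdict(r) for r in out])
    if not df.empty:
        df = df.sort_values("mi", ascending=False).reset_index(drop=True)
    return df


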