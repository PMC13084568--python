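"""Metabolome group testing: glog transform, PCA, Canberra PERMANOVA with a
dispersion-homogeneity check, and the Mann-Whitney/Benjamini-Hochberg
volcano panel with rank-test effect sizes.

The multivariate tests operate on glog-transformed concentrations; the
per-metabolite U tests are rank-based and therefore invariant to any
monotone transform, so volcano outputs report untransformed concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GlogParams",
    "glog",
    "PcaResult",
    "pca_combined",
    "canberra_matrix",
    "PermanovaResult",
    "permanova",
    "dispersion_homogeneity",
    "VolcanoRow",
    "mw_fdr_panel",
    "effect_size_class",
]


# ----------------------------------------------------------------------
# generalized log
# ----------------------------------------------------------------------

@dataclass
class GlogParams:
    lam: float = 1.0  # concentration^2 units

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def glog(y, params: GlogParams | None = None):
    """Generalized log ln(y + sqrt(y^2 + lambda)); defined (and 0) at y=0
    for lambda=1, monotone increasing, ~ln(2y) for large y."""
    lam = (params or GlogParams()).lam
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("concentrations must be nonnegative")
    return np.log(y + np.sqrt(y**2 + lam))


# ----------------------------------------------------------------------
# PCA on the combined-timepoint panel
# ----------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    contributions: pd.DataFrame       # % per variable per component
    expected_mean_contribution: float  # 100/p
    ellipses: dict                     # group -> dict(center, axes, angle_rad)
    dropped: list


def pca_combined(
    panel: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    timepoints: pd.Series | np.ndarray | None = None,
    n_components: int | None = None,
    transform: bool = True,
    ellipse_level: float = 0.95,
) -> PcaResult:
    """Centered + unit-variance PCA of the glog panel (both timepoints
    pooled), with variable contributions and per-group confidence ellipses
    on the first two components.

    Contribution of variable j to component k is ``100 * v_jk^2`` where
    ``v`` is the orthonormal loading matrix, so each component's
    contributions sum to 100.
    """
    X = panel.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    if np.isnan(X).any():
        raise ValueError("panel must be complete (no missing cells)")
    names = list(panel.columns)
    if transform:
        X = glog(X)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant variables: {dropped}")
        X, names, sd = X[:, keep], [n for n in names if n not in dropped], sd[keep]
    Xs = (X - X.mean(axis=0)) / sd

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    k = n_components or min(Xs.shape)
    scores = U[:, :k] * s[:k]
    expl = (s**2 / np.sum(s**2))[:k]
    contrib = 100.0 * Vt[:k] ** 2  # rows: components

    groups = np.asarray(groups)
    ell = {}
    n_eff = Xs.shape[0]
    for g in np.unique(groups):
        pts = scores[groups == g, :2]
        ell[g] = _t_ellipse(pts, ellipse_level)
    comp_names = [f"PC{i+1}" for i in range(k)]
    score_df = pd.DataFrame(scores, columns=comp_names, index=panel.index)
    score_df["group"] = groups
    if timepoints is not None:
        score_df["timepoint"] = np.asarray(timepoints)
    return PcaResult(
        scores=score_df,
        explained_variance_fraction=expl,
        contributions=pd.DataFrame(contrib.T, index=names, columns=comp_names),
        expected_mean_contribution=100.0 / len(names),
        ellipses=ell,
        dropped=dropped,
    )


def _t_ellipse(pts: np.ndarray, level: float) -> dict:
    """Confidence ellipse of a 2-D score cloud: covariance eigenstructure
    scaled by the bivariate quantile 2(n-1)/(n-2) F_{2,n-2}(level)
    (Hotelling form; approaches the chi-square ellipse for large n)."""
    n = pts.shape[0]
    center = pts.mean(axis=0)
    if n < 4 or pts.shape[1] < 2:
        return {"center": center, "axes": np.full(2, np.nan), "angle_rad": np.nan, "n": n}
    cov = np.cov(pts, rowvar=False)
    q = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    vals, vecs = linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    axes = np.sqrt(np.clip(vals, 0, None) * q)
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    return {"center": center, "axes": axes, "angle_rad": angle, "n": n}


# ----------------------------------------------------------------------
# Canberra distance + PERMANOVA
# ----------------------------------------------------------------------

def canberra_matrix(X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Canberra distances d(x,y) = sum_j |x_j-y_j|/(|x_j|+|y_j|),
    0/0 terms skipped."""
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("Canberra distance expects nonnegative entries")
    return squareform(pdist(X, metric="canberra"))


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_perm: float
    n_perm: int
    SS_total: float
    SS_within: float
    SS_between: float
    dispersion_p: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def _ss_partition(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    """SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2."""
    ss_w = 0.0
    for g in uniq:
        idx = labels == g
        ng = int(idx.sum())
        ss_w += D2[np.ix_(idx, idx)].sum() / (2.0 * ng)
    return ss_w


def permanova(
    D: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    check_dispersion: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``SS_total = (1/n) sum_{i<j} d_ij^2``, within/between by group
    partition, ``pseudo-F = (SS_b/(g-1)) / (SS_w/(n-g))``, and a permutation
    p-value ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under unrestricted
    relabeling.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(groups)
    n = D.shape[0]
    if D.shape != (n, n) or labels.shape[0] != n:
        raise ValueError("distance matrix / labels mismatch")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    g = len(uniq)

    D2 = D**2
    ss_t = D2.sum() / (2.0 * n)
    ss_w = _ss_partition(D2, labels, uniq)
    ss_b = ss_t - ss_w
    with np.errstate(divide="ignore"):
        F_obs = (ss_b / (g - 1)) / (ss_w / (n - g))

    rng = np.random.default_rng(seed)
    # one-hot batch over permutations: SS_w = sum_g (L' D2 L)_gg / (2 n_g)
    onehot = np.stack([(labels == u).astype(float) for u in uniq])  # g x n
    count_ge = 0
    batch = 256
    for start in range(0, n_perm, batch):
        b = min(batch, n_perm - start)
        perms = np.stack([rng.permutation(n) for _ in range(b)])
        L = onehot[:, perms]                       # g x b x n
        q = np.einsum("gbi,ij,gbj->bg", L, D2, L)  # b x g
        ss_w_perm = (q / (2.0 * counts)).sum(axis=1)
        ss_b_perm = ss_t - ss_w_perm
        with np.errstate(divide="ignore"):
            F_perm = (ss_b_perm / (g - 1)) / (ss_w_perm / (n - g))
        count_ge += int(np.sum(F_perm >= F_obs - 1e-12))
    p = (1.0 + count_ge) / (1.0 + n_perm)

    disp_p = dispersion_homogeneity(D, labels) if check_dispersion else None
    return PermanovaResult(
        pseudo_F=float(F_obs), R2=float(ss_b / ss_t), p_perm=float(p),
        n_perm=n_perm, SS_total=float(ss_t), SS_within=float(ss_w),
        SS_between=float(ss_b), dispersion_p=disp_p,
    )


def dispersion_homogeneity(D: np.ndarray, groups) -> float:
    """Multivariate dispersion check: embed D by principal coordinates,
    measure each sample's distance to its group centroid (negative-eigenvalue
    axes contribute negatively, as in the standard implementation), and
    F-test those distances across groups. Large p = dispersions comparable.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(groups)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = linalg.eigh(G)
    keep = np.abs(vals) > 1e-9 * np.abs(vals).max()
    vals, vecs = vals[keep], vecs[:, keep]
    coords = vecs * np.sqrt(np.abs(vals))
    pos = vals > 0

    zdists = []
    uniq = np.unique(labels)
    for g in uniq:
        idx = labels == g
        cent = coords[idx].mean(axis=0)
        diff2 = (coords[idx] - cent) ** 2
        d2 = diff2[:, pos].sum(axis=1) - diff2[:, ~pos].sum(axis=1)
        zdists.append(np.sqrt(np.clip(d2, 0, None)))
    means = [z.mean() for z in zdists]
    if all(z.var() < 1e-12 for z in zdists) and np.ptp(means) < 1e-8:
        return 1.0  # degenerate: every sample equidistant from its centroid
    stat, p = stats.f_oneway(*zdists)
    return float(p) if np.isfinite(p) else 1.0


# ----------------------------------------------------------------------
# Mann-Whitney volcano panel
# ----------------------------------------------------------------------

EFFECT_CLASS_BOUNDS = {"small": (0.1, 0.3), "moderate": (0.3, 0.5), "large": (0.5, np.inf)}


def effect_size_class(r: float) -> str:
    if r > 0.5:
        return "large"
    if r >= 0.3:
        return "moderate"
    if r >= 0.1:
        return "small"
    return "negligible"


@dataclass
class VolcanoRow:
    metabolite: str
    U: float
    p_raw: float
    q_bh: float
    effect_size_r: float
    size_class: str
    direction: str
    median_a: float
    median_b: float


def mann_whitney(x: np.ndarray, y: np.ndarray, exact: bool = False):
    """Two-sided U test; returns (U, p, Z) with the tie-corrected,
    continuity-corrected normal Z used for the effect size r = |Z|/sqrt(n)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return n1 * n2 / 2.0, 1.0, 0.0
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    U = float(res.statistic)
    # tie-corrected sigma for Z (used for r even in exact mode)
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    mu = n1 * n2 / 2.0
    if sigma2 <= 0:
        return U, 1.0, 0.0
    z = (U - mu - np.sign(U - mu) * 0.5) / np.sqrt(sigma2) if U != mu else 0.0
    return U, float(res.pvalue), float(z)


def mw_fdr_panel(
    panel: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    group_a: str | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-metabolite two-sided Mann-Whitney tests with Benjamini-Hochberg
    adjustment across the panel (the FDR family is the metabolites within
    one timepoint; call once per timepoint)."""
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a = group_a if group_a is not None else uniq[0]
    b = [u for u in uniq if u != a][0]
    rows = []
    for col in panel.columns:
        x = panel.loc[labels == a, col].dropna().to_numpy()
        y = panel.loc[labels == b, col].dropna().to_numpy()
        U, p, z = mann_whitney(x, y, exact=exact)
        r = abs(z) / np.sqrt(len(x) + len(y))
        direction = str(a) if np.median(x) > np.median(y) else str(b)
        rows.append(
            VolcanoRow(
                metabolite=col, U=U, p_raw=p, q_bh=np.nan,
                effect_size_r=float(r), size_class=effect_size_class(r),
                direction=direction,
                median_a=float(np.median(x)), median_b=float(np.median(y)),
            )
        )
    df = pd.DataFrame([asdict(r) for r in rows])
    df["q_bh"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    df["significant"] = df["q_bh"] < alpha
    return df
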