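"""Phylogenetic comparative statistics on species-level traits.

Implements the machinery for asking (i) whether a trait is phylogenetically
structured (Moran's I autocorrelograms over patristic-distance classes with
permutation tests), (ii) whether two traits are evolutionarily correlated
(generalized least squares with an Ornstein-Uhlenbeck residual covariance
whose attraction strength alpha is estimated simultaneously), (iii) what
ancestral values looked like (maximum-likelihood states under Brownian
motion via re-rooting), and (iv) how to fill in a missing tip value from
its relatives (conditional-normal imputation under a fitted OU model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny, bm_covariance, ou_covariance, patristic_distances

log = logging.getLogger(__name__)

__all__ = [
    "DistanceClasses",
    "CorrelogramResult",
    "PGLSFit",
    "AncestralStates",
    "make_distance_classes",
    "moran_i",
    "correlogram",
    "pgls_ou",
    "ancestral_bm",
    "impute_missing_ou",
    "annotated_newick",
]


# --------------------------------------------------------------------- #
# distance classes & Moran's I
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class DistanceClasses:
    """A partition of tip pairs into k patristic-distance classes."""

    k: int
    boundaries: tuple[float, ...]  # k-1 internal break points, increasing
    membership: np.ndarray  # (n, n) int class index; diagonal = -1
    scheme: str = "equal_frequency"

    def weights(self, cls: int) -> np.ndarray:
        """Binary symmetric weight matrix selecting pairs of one class."""
        return (self.membership == cls).astype(float)

    @property
    def counts(self) -> np.ndarray:
        iu = np.triu_indices_from(self.membership, 1)
        return np.bincount(self.membership[iu], minlength=self.k)


def make_distance_classes(
    d: np.ndarray, k: int = 4, scheme: str = "equal_frequency"
) -> DistanceClasses:
    """Split the off-diagonal patristic distances into k classes.

    ``equal_frequency`` (default) places quantile break points so classes
    hold similar numbers of pairs; ``equal_width`` splits the distance
    range evenly.  A distance tied exactly with a boundary goes to the
    lower class.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    d = np.asarray(d, float)
    iu = np.triu_indices_from(d, 1)
    dists = d[iu]
    if np.unique(dists).size < k:
        raise ValueError(f"only {np.unique(dists).size} distinct distances; cannot form {k} classes")
    if scheme == "equal_frequency":
        bounds = np.quantile(dists, np.arange(1, k) / k)
    elif scheme == "equal_width":
        bounds = dists.min() + (dists.max() - dists.min()) * np.arange(1, k) / k
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    member = np.searchsorted(bounds, d, side="left")  # ties -> lower class
    np.fill_diagonal(member, -1)
    dc = DistanceClasses(k=k, boundaries=tuple(float(b) for b in bounds),
                         membership=member, scheme=scheme)
    if np.any(dc.counts == 0):
        raise ValueError("empty distance class; reduce k or change scheme")
    return dc


def moran_i(x: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I with binary symmetric weights.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2,
    with S0 = sum_ij w_ij.  Null expectation is -1/(n-1).
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("constant trait: Moran's I undefined")
    s0 = float(weights.sum())
    if s0 == 0:
        raise ValueError("no pairs in class")
    return float(n / s0 * (z @ weights @ z) / denom)


@dataclass
class CorrelogramResult:
    """Moran's I per distance class with permutation significance."""

    classes: DistanceClasses
    moran: np.ndarray  # observed I per class
    expected: float  # -1/(n-1)
    p_values: np.ndarray | None  # two-tailed permutation p per class
    n_perm: int
    trait: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "distance_class": np.arange(1, self.classes.k + 1),
            "moran_i": self.moran,
            "expected_i": self.expected,
            "n_pairs": self.classes.counts,
        })
        if self.p_values is not None:
            df["p_value"] = self.p_values
            df["significant"] = df.p_value <= 0.05
        return df


def correlogram(
    x: pd.Series,
    tree: Phylogeny,
    classes: DistanceClasses | None = None,
    k: int = 4,
    n_perm: int = 999,
    seed: int | None = None,
) -> CorrelogramResult:
    """Phylogenetic autocorrelogram of one trait.

    Significance comes from random tip relabeling: the two-tailed p for a
    class is rank-based, (r + 1) / (n_perm + 1), where r counts permuted
    |I - E[I]| at least as extreme as observed and E[I] = -1/(n-1).  With
    ``n_perm=0`` only the coefficients are returned.
    """
    x = x.reindex(tree.tip_labels)
    if x.isna().any():
        raise ValueError(f"trait missing for tips: {list(x.index[x.isna()])}")
    if classes is None:
        classes = make_distance_classes(patristic_distances(tree), k=k)
    xv = x.to_numpy(float)
    n = xv.size
    W = [classes.weights(c) for c in range(classes.k)]
    obs = np.array([moran_i(xv, w) for w in W])
    expected = -1.0 / (n - 1)
    pvals = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        z = xv - xv.mean()
        denom = z @ z
        s0 = np.array([w.sum() for w in W])
        Zp = np.stack([rng.permutation(z) for _ in range(n_perm)])  # (n_perm, n)
        istar = np.stack([n / s0[c] * np.einsum("pi,ij,pj->p", Zp, W[c], Zp) / denom
                          for c in range(classes.k)], axis=1)  # (n_perm, k)
        obs_dev = np.abs(obs - expected)
        exceed = (np.abs(istar - expected) >= obs_dev[None, :] - 1e-12).sum(axis=0)
        pvals = (exceed + 1) / (n_perm + 1)
    return CorrelogramResult(classes=classes, moran=obs, expected=expected,
                             p_values=pvals, n_perm=n_perm, trait=str(x.name or ""))


# --------------------------------------------------------------------- #
# PGLS with simultaneous OU alpha
# --------------------------------------------------------------------- #
@dataclass
class PGLSFit:
    slope: float
    intercept: float
    alpha_hat: float
    sigma2_hat: float
    f_statistic: float
    df_model: int
    df_residual: int
    p_value: float
    log_likelihood: float
    slope_se: float = float("nan")
    boundary_warning: bool = False

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        t = stats.t.ppf(0.5 + level / 2, self.df_residual)
        return self.slope - t * self.slope_se, self.slope + t * self.slope_se


def _gls_profile(y, X, V):
    """GLS under y ~ N(X b, s*V): returns (b, s_ml, logL, XtVinvX_inv)."""
    n = len(y)
    c = cho_factor(V, lower=True)
    Vi_X = cho_solve(c, X)
    Vi_y = cho_solve(c, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ cho_solve(c, r))
    s_ml = quad / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    logL = -0.5 * (n * (np.log(2 * np.pi) + 1 + np.log(max(s_ml, 1e-300))) + logdet)
    return beta, s_ml, quad, logL, np.linalg.inv(XtViX)


def pgls_ou(
    y: pd.Series,
    x: pd.Series,
    tree: Phylogeny,
    alpha_grid: np.ndarray | None = None,
) -> PGLSFit:
    """Phylogenetic GLS of y on x with OU residual covariance.

    For each candidate attraction strength alpha the residual correlation
    is the stationary-OU kernel exp(-alpha * d_ij) (the overall scale is
    profiled analytically); alpha maximizing the profile log-likelihood
    over a log-spaced grid is refined by bounded scalar optimization.
    alpha = 0 is included as the Brownian-motion endpoint.  The slope test
    is a Wald F with (1, n - 2) degrees of freedom.
    """
    y = y.reindex(tree.tip_labels).to_numpy(float)
    xv = x.reindex(tree.tip_labels).to_numpy(float)
    if np.isnan(y).any() or np.isnan(xv).any():
        raise ValueError("missing trait values; impute first")
    n = y.size
    if n < 4:
        raise ValueError("need n >= 4")
    if np.allclose(xv, xv[0]):
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones(n), xv])
    D = patristic_distances(tree)
    height = tree.tree_height()
    # a user-supplied grid is honored verbatim (e.g. to pin alpha); the
    # default grid additionally carries the alpha = 0 (BM) endpoint
    if alpha_grid is None:
        grid = np.concatenate([[0.0], np.logspace(-4, 2, 25) / height])
    else:
        grid = np.asarray(alpha_grid, float)
    C_bm = bm_covariance(tree)

    def nll(alpha):
        V = C_bm if alpha <= 0 else np.exp(-alpha * D)
        try:
            return -_gls_profile(y, X, V)[3]
        except np.linalg.LinAlgError:
            return np.inf

    vals = np.array([nll(a) for a in grid])
    j = int(np.argmin(vals))
    boundary = j in (0, len(grid) - 1)
    if 0 < j < len(grid) - 1:
        res = minimize_scalar(nll, bounds=(grid[j - 1], grid[j + 1]), method="bounded",
                              options={"xatol": 1e-6 / height})
        alpha_hat = float(res.x) if res.fun <= vals[j] else float(grid[j])
    else:
        alpha_hat = float(grid[j])
        if boundary:
            log.warning("pgls_ou: alpha estimate at grid boundary (%.3g)", alpha_hat)
    V = C_bm if alpha_hat <= 0 else np.exp(-alpha_hat * D)
    beta, s_ml, quad, logL, XtViX_inv = _gls_profile(y, X, V)
    df_resid = n - 2
    s_unbiased = quad / df_resid
    se = float(np.sqrt(s_unbiased * XtViX_inv[1, 1]))
    fstat = float((beta[1] / se) ** 2)
    pval = float(stats.f.sf(fstat, 1, df_resid))
    sigma2 = s_ml if alpha_hat <= 0 else 2.0 * alpha_hat * s_ml
    return PGLSFit(
        slope=float(beta[1]), intercept=float(beta[0]), alpha_hat=alpha_hat,
        sigma2_hat=float(sigma2), f_statistic=fstat, df_model=1,
        df_residual=df_resid, p_value=pval, log_likelihood=float(logL),
        slope_se=se, boundary_warning=boundary,
    )


# --------------------------------------------------------------------- #
# ancestral states under BM
# --------------------------------------------------------------------- #
@dataclass
class AncestralStates:
    """Per-node ML states with 95% CIs; tips carry data with zero width."""

    estimates: dict[int, tuple[float, float, float]]  # node -> (est, lo, hi)
    sigma2_hat: float
    tree: Phylogeny = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node": k, "estimate": v[0], "ci_low": v[1], "ci_high": v[2],
             "is_tip": self.tree.is_tip(k) if self.tree else None}
            for k, v in sorted(self.estimates.items())
        ]
        return pd.DataFrame(rows)


def ancestral_bm(x: pd.Series, tree: Phylogeny, jitter: float = 1e-8) -> AncestralStates:
    """Maximum-likelihood ancestral states under Brownian motion.

    Each internal node's state is the GLS root estimate of the tree
    re-rooted at that node: mu = (1' C^-1 x) / (1' C^-1 1) where
    C[i, j] = (d(i, v) + d(j, v) - d(i, j)) / 2 is the shared path length
    from the new root v.  The BM rate sigma^2 is the ML estimate at the
    original root; CI95 = mu +/- 1.96 * sqrt(sigma^2 / (1' C^-1 1)).
    Singular covariances (zero-length branches) are jittered with a warning.
    """
    xv = x.reindex(tree.tip_labels).to_numpy(float)
    if np.isnan(xv).any():
        raise ValueError("missing trait values; impute first")
    n = xv.size
    if n < 3:
        raise ValueError("need n >= 3")
    Dn = tree.node_distance_matrix()
    tipn = tree.tip_nodes
    Dtt = Dn[np.ix_(tipn, tipn)]

    def root_gls(C):
        try:
            c = cho_factor(C, lower=True)
        except np.linalg.LinAlgError:
            log.warning("singular BM covariance; adding jitter %.1e", jitter)
            c = cho_factor(C + jitter * np.eye(len(C)) * max(C.max(), 1.0), lower=True)
        one = np.ones(len(C))
        Vi1 = cho_solve(c, one)
        mu = float(one @ cho_solve(c, xv) / (one @ Vi1))
        prec = float(one @ Vi1)
        quad = float((xv - mu) @ cho_solve(c, xv - mu))
        return mu, prec, quad

    # global BM rate from the original rooting (ML)
    _, _, quad0 = root_gls(bm_covariance(tree))
    sigma2 = quad0 / n
    out: dict[int, tuple[float, float, float]] = {}
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            i = int(np.where(tipn == v)[0][0])
            out[v] = (float(xv[i]), float(xv[i]), float(xv[i]))
            continue
        dv = Dn[v, tipn]
        C = 0.5 * (dv[:, None] + dv[None, :] - Dtt)
        mu, prec, _ = root_gls(C)
        hw = 1.96 * np.sqrt(sigma2 / prec)
        out[v] = (mu, mu - hw, mu + hw)
    return AncestralStates(estimates=out, sigma2_hat=float(sigma2), tree=tree)


def annotated_newick(tree: Phylogeny, states: AncestralStates, digits: int = 4) -> str:
    """Newick string with per-node state comments for quick visualization."""

    def render(v: int) -> str:
        est = states.estimates[v][0]
        note = f"[&state={est:.{digits}g}]"
        if tree.is_tip(v):
            label = tree.tip_labels[int(np.where(tree.tip_nodes == v)[0][0])]
            core = label
        else:
            core = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        L = tree.branch_length[v]
        return f"{core}{note}" + ("" if tree.parent[v] < 0 else f":{L:.10g}")

    return render(0) + ";\n"


# --------------------------------------------------------------------- #
# OU imputation of missing values
# --------------------------------------------------------------------- #
def impute_missing_ou(
    x: pd.Series,
    tree: Phylogeny,
    fixed: tuple[float, float, float] | None = None,
) -> tuple[pd.Series, pd.Series, dict]:
    """Fill missing tip values by conditional-normal OU imputation.

    A univariate stationary OU model (alpha, sigma^2, theta) is fitted to
    the observed tips by maximum likelihood (theta and the scale profiled
    analytically, alpha by bounded scalar search), unless ``fixed`` pins
    (alpha, sigma2, theta).  Each missing tip is the conditional mean of
    the joint stationary-OU normal given the observed tips; the
    conditional SD is reported.  If the likelihood degenerates toward
    alpha = 0 the imputation falls back to the Brownian-motion conditional
    expectation (a warning is logged).
    """
    x = x.reindex(tree.tip_labels)
    obs_mask = x.notna().to_numpy()
    if obs_mask.sum() < 3:
        raise ValueError("need >= 3 observed tips")
    if obs_mask.all():
        return x.copy(), pd.Series(0.0, index=x.index), {"alpha": None, "note": "nothing missing"}
    if fixed is not None:
        alpha, sigma2, theta = fixed
        V = ou_covariance(tree, alpha, sigma2)
        filled, sd = _conditional_fill(x, V, theta * np.ones(len(x)))
        return filled, sd, {"alpha": alpha, "sigma2": sigma2, "theta": theta,
                            "model": "OU-fixed"}
    xo = x.to_numpy(float)[obs_mask]
    D = patristic_distances(tree)
    Doo = D[np.ix_(obs_mask, obs_mask)]
    height = tree.tree_height()
    one = np.ones(obs_mask.sum())
    n = len(xo)

    def nll(log_alpha):
        a = np.exp(log_alpha)
        R = np.exp(-a * Doo)
        try:
            c = cho_factor(R, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        Vi1 = cho_solve(c, one)
        theta = float(one @ cho_solve(c, xo) / (one @ Vi1))
        r = xo - theta
        s = float(r @ cho_solve(c, r)) / n
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        return 0.5 * (n * (np.log(2 * np.pi) + 1 + np.log(max(s, 1e-300))) + logdet)

    lo, hi = np.log(1e-4 / height), np.log(1e3 / height)
    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    alpha = float(np.exp(res.x))
    converged = res.success and np.isfinite(res.fun)
    if not converged or res.x <= lo + 1e-9:
        log.warning("OU imputation ML degenerate; falling back to BM conditional expectation")
        return _impute_bm(x, tree)
    R = np.exp(-alpha * Doo)
    c = cho_factor(R, lower=True)
    Vi1 = cho_solve(c, one)
    theta = float(one @ cho_solve(c, xo) / (one @ Vi1))
    s = float((xo - theta) @ cho_solve(c, xo - theta)) / n
    sigma2 = 2.0 * alpha * s
    V = ou_covariance(tree, alpha, sigma2)
    return _conditional_fill(x, V, theta * np.ones(len(x))) + (
        {"alpha": alpha, "sigma2": sigma2, "theta": theta, "model": "OU"},)


def _impute_bm(x: pd.Series, tree: Phylogeny):
    obs_mask = x.notna().to_numpy()
    xo = x.to_numpy(float)[obs_mask]
    C = bm_covariance(tree)
    Coo = C[np.ix_(obs_mask, obs_mask)]
    c = cho_factor(Coo + 1e-12 * np.eye(len(xo)) * max(Coo.max(), 1.0), lower=True)
    one = np.ones(len(xo))
    mu = float(one @ cho_solve(c, xo) / (one @ cho_solve(c, one)))
    s = float((xo - mu) @ cho_solve(c, xo - mu)) / len(xo)
    filled, sd = _conditional_fill(x, s * C, mu * np.ones(len(x)))
    return filled, sd, {"alpha": 0.0, "sigma2": s, "theta": mu, "model": "BM"}


def _conditional_fill(x: pd.Series, V: np.ndarray, mean: np.ndarray):
    obs = x.notna().to_numpy()
    mis = ~obs
    xo = x.to_numpy(float)[obs]
    Voo = V[np.ix_(obs, obs)]
    Vmo = V[np.ix_(mis, obs)]
    Vmm = V[np.ix_(mis, mis)]
    c = cho_factor(Voo, lower=True)
    w = cho_solve(c, xo - mean[obs])
    cond_mean = mean[mis] + Vmo @ w
    cond_var = np.diag(Vmm - Vmo @ cho_solve(c, Vmo.T))
    filled = x.copy().astype(float)
    filled.iloc[np.where(mis)[0]] = cond_mean
    sd = pd.Series(0.0, index=x.index)
    sd.iloc[np.where(mis)[0]] = np.sqrt(np.maximum(cond_var, 0.0))
    return filled, sd
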