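"""Multi-optimum Ornstein-Uhlenbeck (Hansen) models and stepwise-AIC
detection of adaptive regimes.

A regime painting assigns every branch a selective regime; within a trait
all regimes share one attraction strength alpha and diffusion variance
sigma^2 but each regime carries its own optimum theta.  Expected tip
values are regime-weighted averages of the optima (weights accumulate
exponentially-discounted occupancy along each root-to-tip path), and tip
residuals follow the stationary OU covariance.  Traits are treated as
independent given the shared painting, so the model AIC decomposes into
per-trait "partial AIC" contributions that sum to the total.

The stepwise search starts from a single regime, repeatedly paints a new
regime onto the branch whose addition most improves the summed AIC
(accepting every improvement), and optionally runs a backward phase that
merges regime pairs into shared (convergent) regimes while the AIC keeps
improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .phylo import Phylogeny, patristic_distances

log = logging.getLogger(__name__)

__all__ = [
    "RegimePainting",
    "HansenFit",
    "SurfaceTrace",
    "hansen_expected_means",
    "fit_hansen",
    "surface_forward",
    "surface_backward",
    "partial_aic_profile",
    "painting_newick",
]


class UnreachableRegimeError(ValueError):
    pass


# --------------------------------------------------------------------- #
# paintings
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class RegimePainting:
    """Regime labels on branches, defined by regime *origins*.

    ``origins`` maps a node index to the regime starting on the branch
    above it (for the root: the root regime).  A regime is inherited by
    descendant branches until overridden by a deeper origin.  Regime ids
    are consecutive integers 0..n_regimes-1; the root regime is
    ``origins[0]``.
    """

    origins: tuple[tuple[int, int], ...]

    @classmethod
    def single(cls) -> "RegimePainting":
        return cls(origins=((0, 0),))

    @property
    def origin_map(self) -> dict[int, int]:
        return dict(self.origins)

    @property
    def n_regimes(self) -> int:
        return len({r for _, r in self.origins})

    def node_regimes(self, tree: Phylogeny) -> np.ndarray:
        """Regime of the branch above each node (root entry = root regime)."""
        omap = self.origin_map
        if 0 not in omap:
            raise ValueError("painting must assign the root a regime")
        reg = np.empty(tree.n_nodes, dtype=int)
        for v in range(tree.n_nodes):
            reg[v] = omap.get(v, reg[tree.parent[v]] if v else omap[0])
        return reg

    def add_origin(self, node: int) -> "RegimePainting":
        """New painting with a fresh regime starting on the branch above node."""
        if node in self.origin_map:
            raise ValueError(f"node {node} already originates a regime")
        return RegimePainting(origins=self.origins + ((node, self.n_regimes),))

    def merge(self, keep: int, drop: int) -> "RegimePainting":
        """Collapse regime ``drop`` into ``keep`` (convergent regime) and
        renumber so ids stay consecutive."""
        raw = [(n, keep if r == drop else r) for n, r in self.origins]
        ids = sorted({r for _, r in raw})
        remap = {r: i for i, r in enumerate(ids)}
        return RegimePainting(origins=tuple((n, remap[r]) for n, r in raw))


# --------------------------------------------------------------------- #
# Hansen expected means
# --------------------------------------------------------------------- #
class _HansenWork:
    """Per-tree precomputation shared across candidate fits.

    Flattens every root-to-tip path into (tip, node, t_start, t_end)
    segment arrays so the regime-weight matrix for any painting and alpha
    is a vectorized scatter-add, and caches Cholesky factors of the OU
    correlation kernel exp(-alpha * D) per alpha.
    """

    def __init__(self, tree: Phylogeny):
        self.tree = tree
        self.D = patristic_distances(tree)
        self.T = tree.depth[tree.tip_nodes]
        seg_tip, seg_node, seg_t0, seg_t1 = [], [], [], []
        for i, tipnode in enumerate(tree.tip_nodes):
            v = int(tipnode)
            while v != 0:
                seg_tip.append(i)
                seg_node.append(v)
                seg_t0.append(tree.depth[tree.parent[v]])
                seg_t1.append(tree.depth[v])
                v = int(tree.parent[v])
        self.seg_tip = np.array(seg_tip, int)
        self.seg_node = np.array(seg_node, int)
        self.seg_t0 = np.array(seg_t0, float)
        self.seg_t1 = np.array(seg_t1, float)
        self._chol: dict[float, tuple] = {}

    def weight_matrix(self, reg: np.ndarray, n_regimes: int, alpha: float) -> np.ndarray:
        Tt = self.T[self.seg_tip]
        contrib = np.exp(-alpha * (Tt - self.seg_t1)) - np.exp(-alpha * (Tt - self.seg_t0))
        W = np.zeros((len(self.T), n_regimes))
        np.add.at(W, (self.seg_tip, reg[self.seg_node]), contrib)
        W[:, reg[0]] += np.exp(-alpha * self.T)
        return W

    def chol(self, alpha: float):
        key = float(alpha)
        if key not in self._chol:
            R = np.exp(-alpha * self.D)
            c = cho_factor(R, lower=True)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
            self._chol[key] = (c, logdet)
        return self._chol[key]


def hansen_expected_means(
    tree: Phylogeny, painting: RegimePainting, alpha: float
) -> np.ndarray:
    """Tip-by-regime weight matrix W of the Hansen model.

    The expected value of tip i is sum_r W[i, r] * theta[r]; W accumulates
    exp(-alpha * (T_i - t)) increments over each branch segment on the
    root-to-tip path plus a root term exp(-alpha * T_i) credited to the
    root regime.  Rows sum to 1 for every alpha > 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    reg = painting.node_regimes(tree)
    return _HansenWork(tree).weight_matrix(reg, painting.n_regimes, alpha)


# --------------------------------------------------------------------- #
# Hansen fitting
# --------------------------------------------------------------------- #
@dataclass
class TraitFit:
    alpha: float
    sigma2: float
    theta: np.ndarray
    log_likelihood: float
    aic: float
    n_parameters: int


@dataclass
class HansenFit:
    painting: RegimePainting
    traits: dict[str, TraitFit]
    total_aic: float
    criterion: str = "aic"  # or "aicc"

    @property
    def partial_aic(self) -> dict[str, float]:
        return {t: f.aic for t, f in self.traits.items()}

    @property
    def n_regimes(self) -> int:
        return self.painting.n_regimes


class _FitContext:
    """Caches, per alpha, the trait projections shared by every candidate
    painting (the data never change during a stepwise search)."""

    def __init__(self, work: _HansenWork, Y: np.ndarray):
        self.work = work
        self.Y = Y
        self._per_alpha: dict[float, tuple] = {}

    def at(self, alpha: float):
        key = float(alpha)
        if key not in self._per_alpha:
            c, logdet = self.work.chol(alpha)
            ViY = cho_solve(c, self.Y)
            yViy = np.einsum("ij,ij->j", self.Y, ViY)
            self._per_alpha[key] = (c, logdet, ViY, yViy)
        return self._per_alpha[key]


def _fit_painting(ctx: _FitContext, reg, n_reg, alpha_grid, use_aicc, names):
    """Per-trait profile fit over the alpha grid for one painting."""
    n, m = ctx.Y.shape
    best_logL = np.full(m, -np.inf)
    best_a = np.zeros(m)
    best_s = np.zeros(m)
    best_theta = [None] * m
    for a in alpha_grid:
        W = ctx.work.weight_matrix(reg, n_reg, a)
        colmass = W.sum(axis=0)
        if np.any(colmass < 1e-12):
            bad = int(np.argmin(colmass))
            raise UnreachableRegimeError(f"regime {bad} receives no weight at alpha={a:g}")
        c, logdet, ViY, yViy = ctx.at(a)
        ViW = cho_solve(c, W)
        A = W.T @ ViW
        B = W.T @ ViY  # (n_reg, m)
        try:
            Theta = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise UnreachableRegimeError(f"collinear regime weights at alpha={a:g}: {exc}")
        rss = np.maximum(yViy - np.einsum("rm,rm->m", B, Theta), 1e-300)
        s = rss / n
        logL = -0.5 * (n * (np.log(2 * np.pi) + 1 + np.log(s)) + logdet)
        better = logL > best_logL
        best_logL = np.where(better, logL, best_logL)
        best_a = np.where(better, a, best_a)
        best_s = np.where(better, s, best_s)
        for j in np.flatnonzero(better):
            best_theta[j] = Theta[:, j].copy()
    k = 2 + n_reg
    pen = 2.0 * k
    if use_aicc:
        pen += 2.0 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    fits = {}
    for j, name in enumerate(names):
        fits[name] = TraitFit(
            alpha=float(best_a[j]), sigma2=float(2 * best_a[j] * best_s[j]),
            theta=best_theta[j], log_likelihood=float(best_logL[j]),
            aic=float(pen - 2 * best_logL[j]), n_parameters=k)
    return fits


def _default_alpha_grid(height: float) -> np.ndarray:
    return np.logspace(-2.5, 1.7, 15) / height


def fit_hansen(
    tree: Phylogeny,
    traits: pd.DataFrame,
    painting: RegimePainting,
    alpha_grid: np.ndarray | None = None,
    use_aicc: bool = False,
    _work: _HansenWork | None = None,
) -> HansenFit:
    """Fit the multi-optimum OU model for every trait under one painting.

    Per trait, the log-likelihood of y ~ N(W(alpha) theta, sigma^2 V(alpha))
    is maximized over a log-spaced alpha grid with theta solved by GLS and
    the scale profiled analytically; sigma^2 = 2 alpha * scale.  Traits
    are independent given the painting, so per-trait AICs (2k - 2 logL,
    k = 2 + n_regimes) sum to the model total.  ``use_aicc`` switches to
    the small-sample corrected criterion.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    traits = traits.reindex(tree.tip_labels)
    if traits.isna().any().any():
        raise ValueError("traits must be complete; impute first")
    work = _work or _HansenWork(tree)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid(tree.tree_height())
    ctx = _FitContext(work, traits.to_numpy(float))
    reg = painting.node_regimes(tree)
    fits = _fit_painting(ctx, reg, painting.n_regimes, alpha_grid, use_aicc,
                         [str(c) for c in traits.columns])
    total = float(sum(f.aic for f in fits.values()))
    return HansenFit(painting=painting, traits=fits, total_aic=total,
                     criterion="aicc" if use_aicc else "aic")


# --------------------------------------------------------------------- #
# stepwise search
# --------------------------------------------------------------------- #
@dataclass
class SurfaceStep:
    phase: str  # "forward" | "backward"
    description: str
    fit: HansenFit

    @property
    def aic(self) -> float:
        return self.fit.total_aic


@dataclass
class SurfaceTrace:
    steps: list[SurfaceStep] = field(default_factory=list)
    standardized: bool = True

    @property
    def aics(self) -> list[float]:
        return [s.aic for s in self.steps]

    @property
    def final(self) -> HansenFit:
        return self.steps[-1].fit


def _standardize(traits: pd.DataFrame) -> pd.DataFrame:
    sd = traits.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant traits cannot be standardized: "
                         f"{list(sd.index[sd == 0])}")
    return (traits - traits.mean()) / sd


def surface_forward(
    tree: Phylogeny,
    traits: pd.DataFrame,
    use_aicc: bool = False,
    standardize: bool = True,
    alpha_grid: np.ndarray | None = None,
    max_regimes: int | None = None,
) -> SurfaceTrace:
    """Forward phase: grow regimes one branch at a time while AIC improves.

    Starting from a single regime at the root, every branch that does not
    already originate a regime is tried as the origin of a new regime
    (inherited by its descendants until overridden); the single candidate
    with the best summed AIC is accepted if it improves on the current
    model, and the process repeats until no candidate improves.  Ties are
    broken toward the earliest branch in preorder, which makes the search
    deterministic.  Traits are z-scored by default so each contributes on
    a comparable scale.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    data = _standardize(traits) if standardize else traits.copy()
    data = data.reindex(tree.tip_labels)
    work = _HansenWork(tree)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid(tree.tree_height())
    ctx = _FitContext(work, data.to_numpy(float))
    names = [str(c) for c in data.columns]
    crit = "aicc" if use_aicc else "aic"

    def fit(p: RegimePainting) -> HansenFit:
        fits = _fit_painting(ctx, p.node_regimes(tree), p.n_regimes,
                             alpha_grid, use_aicc, names)
        return HansenFit(painting=p, traits=fits, criterion=crit,
                         total_aic=float(sum(f.aic for f in fits.values())))

    painting = RegimePainting.single()
    current = fit(painting)
    trace = SurfaceTrace(steps=[SurfaceStep("forward", "OU1", current)],
                         standardized=standardize)
    while max_regimes is None or painting.n_regimes < max_regimes:
        best: tuple[float, int, HansenFit] | None = None
        omap = painting.origin_map
        for node in range(1, tree.n_nodes):
            if node in omap:
                continue
            try:
                cand = fit(painting.add_origin(node))
            except UnreachableRegimeError as exc:
                log.debug("candidate branch %d skipped: %s", node, exc)
                continue
            if cand.total_aic < current.total_aic - 1e-9 and (
                best is None or cand.total_aic < best[0] - 1e-12
            ):
                best = (cand.total_aic, node, cand)
        if best is None:
            break
        _, node, current = best
        painting = current.painting
        trace.steps.append(SurfaceStep("forward", f"+regime@branch{node}", current))
        log.info("forward: new regime on branch %d, AIC %.2f", node, current.total_aic)
    return trace


def surface_backward(
    trace: SurfaceTrace,
    tree: Phylogeny,
    traits: pd.DataFrame,
    use_aicc: bool = False,
    alpha_grid: np.ndarray | None = None,
) -> SurfaceTrace:
    """Backward (collapse) phase: merge regime pairs while AIC improves.

    Greedily merges two distinct regimes into one shared, convergent
    regime whenever the merge improves the summed AIC, repeating to a
    fixed point.  Operates on the standardization recorded in the forward
    trace.
    """
    if isinstance(traits, pd.Series):
        traits = traits.to_frame()
    data = _standardize(traits) if trace.standardized else traits.copy()
    data = data.reindex(tree.tip_labels)
    work = _HansenWork(tree)
    if alpha_grid is None:
        alpha_grid = _default_alpha_grid(tree.tree_height())
    ctx = _FitContext(work, data.to_numpy(float))
    names = [str(c) for c in data.columns]
    crit = "aicc" if use_aicc else "aic"

    def fit(p: RegimePainting) -> HansenFit:
        fits = _fit_painting(ctx, p.node_regimes(tree), p.n_regimes,
                             alpha_grid, use_aicc, names)
        return HansenFit(painting=p, traits=fits, criterion=crit,
                         total_aic=float(sum(f.aic for f in fits.values())))

    current = trace.final
    painting = current.painting
    while painting.n_regimes > 1:
        best = None
        regs = sorted({r for _, r in painting.origins})
        for i, a in enumerate(regs):
            for b in regs[i + 1:]:
                cand_p = painting.merge(a, b)
                cand = fit(cand_p)
                if cand.total_aic < current.total_aic - 1e-9 and (
                    best is None or cand.total_aic < best[0] - 1e-12
                ):
                    best = (cand.total_aic, (a, b), cand)
        if best is None:
            break
        _, (a, b), current = best
        painting = current.painting
        trace.steps.append(SurfaceStep("backward", f"merge {a}<-{b}", current))
        log.info("backward: merged regimes %d and %d, AIC %.2f", a, b, current.total_aic)
    return trace


def partial_aic_profile(trace: SurfaceTrace) -> pd.DataFrame:
    """Per-trait AIC trajectory across accepted models.

    Traits whose column decreases along the trace drove the regime
    additions; a column that rises is paying the parameter penalty without
    a likelihood gain (a noise trait).
    """
    if not trace.steps:
        raise ValueError("empty trace")
    rows = []
    for i, step in enumerate(trace.steps):
        row = {"step": i, "phase": step.phase, "description": step.description,
               "n_regimes": step.fit.n_regimes, "total_aic": step.aic}
        row.update(step.fit.partial_aic)
        rows.append(row)
    return pd.DataFrame(rows)


def painting_newick(tree: Phylogeny, painting: RegimePainting) -> str:
    """Newick with a regime-label comment on every branch."""
    reg = painting.node_regimes(tree)

    def render(v: int) -> str:
        if tree.is_tip(v):
            core = tree.tip_labels[int(np.where(tree.tip_nodes == v)[0][0])]
        else:
            core = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        note = f"[&regime={int(reg[v])}]"
        if tree.parent[v] < 0:
            return f"{core}{note}"
        return f"{core}{note}:{tree.branch_length[v]:.10g}"

    return render(0) + ";\n"
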