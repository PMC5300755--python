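"""Derivation of osmoregulatory traits from salinity-exposure experiments.

Nine species-level indicators of osmoregulatory ability are derived from
per-individual 5-day exposure data: habitat and hemolymph osmolality, the
lower and upper median lethal osmotic limits (LL50/UL50, probit analysis),
the isosmotic point (intersection of a fitted cubic response curve with the
line y = x), the hemolymph osmolalities predicted at the lethal limits
(Osm_LL50/Osm_UL50), and two unitless regulatory-capability indices
(RC_Hyper, RC_Hypo) in [0, 1] where 1 means perfect regulation and 0
perfect conformity.

All osmolalities are in mOsm/kg H2O; the field convention 1 permil
salinity = 30 mOsm/kg H2O converts practical salinity to osmolality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm

log = logging.getLogger(__name__)

MOSM_PER_PERMIL = 30.0

__all__ = [
    "ExposureRecord",
    "MortalityTable",
    "OsmoCurve",
    "ProbitFit",
    "TraitSet",
    "permil_to_mosm",
    "mosm_to_permil",
    "classify_salinity_zone",
    "fit_probit_lethal_limit",
    "fit_osmo_curve",
    "isosmotic_point",
    "hemolymph_at",
    "regulation_indices",
    "derive_traits",
]


class InsufficientDataError(ValueError):
    pass


class NoIsosmoticPointError(ValueError):
    pass


# --------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class ExposureRecord:
    """One crab: exposure medium, day-5 survival, day-5 hemolymph sample."""

    species_id: str
    population_id: str
    medium_osmolality: float
    alive_day5: bool
    hemolymph_osmolality: float | None = None

    def __post_init__(self):
        if self.medium_osmolality < 0:
            raise ValueError("medium_osmolality must be >= 0")
        if self.hemolymph_osmolality is not None and self.hemolymph_osmolality <= 0:
            raise ValueError("hemolymph_osmolality must be > 0 when present")


@dataclass(frozen=True)
class MortalityTable:
    """Per-level exposure counts: (medium osmolality, n exposed, n dead)."""

    levels: tuple[tuple[float, int, int], ...]

    def __post_init__(self):
        xs = [L[0] for L in self.levels]
        if sorted(xs) != xs or len(set(xs)) != len(xs):
            raise ValueError("levels must be strictly increasing in osmolality")
        for x, n, d in self.levels:
            if not (0 <= d <= n):
                raise ValueError(f"need 0 <= n_dead <= n_exposed at level {x}")

    @property
    def x(self) -> np.ndarray:
        return np.array([L[0] for L in self.levels], float)

    @property
    def n(self) -> np.ndarray:
        return np.array([L[1] for L in self.levels], float)

    @property
    def dead(self) -> np.ndarray:
        return np.array([L[2] for L in self.levels], float)


@dataclass(frozen=True)
class OsmoCurve:
    """Cubic osmoregulatory response curve: hemolymph = f(medium).

    Coefficients are (a0, a1, a2, a3) for f(x) = a0 + a1 x + a2 x^2 + a3 x^3.
    Evaluation outside ``fit_range`` is extrapolation and is flagged with a
    warning rather than forbidden (the upper lethal limit can slightly
    exceed the last medium with survivors).
    """

    coeffs: tuple[float, float, float, float]
    r_squared: float
    fit_range: tuple[float, float]
    n_obs: int = 0
    mean_medium: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class ProbitFit:
    """A median lethal limit from binomial-probit ML, possibly censored."""

    side: Literal["lower", "upper"]
    lc50: float | None
    censored: bool
    bound: float | None = None  # extreme tested level bounding a censored limit
    beta0: float = float("nan")
    beta1: float = float("nan")
    converged: bool = True


@dataclass
class TraitSet:
    """The nine osmoregulatory traits for one species (or one population)."""

    species_id: str
    habitat_osmolality: float = np.nan
    hemolymph_osmolality: float = np.nan
    ll50: float = np.nan
    ul50: float = np.nan
    osm_ll50: float = np.nan
    osm_ul50: float = np.nan
    isosmotic_point: float = np.nan
    rc_hyper: float = np.nan
    rc_hypo: float = np.nan
    ll50_censored: bool = False
    se: dict = field(default_factory=dict)
    n_populations: int = 1

    def validate(self) -> list[str]:
        """Return diagnostics for violated invariants (empty = clean)."""
        issues = []
        vals = (self.ll50, self.isosmotic_point, self.ul50)
        if all(np.isfinite(v) for v in vals) and not (vals[0] < vals[1] < vals[2]):
            issues.append(f"{self.species_id}: expected LL50 < IC < UL50, got {vals}")
        for name, v in (("rc_hyper", self.rc_hyper), ("rc_hypo", self.rc_hypo)):
            if np.isfinite(v) and not (-1e-9 <= v <= 1 + 1e-9):
                issues.append(f"{self.species_id}: {name}={v:.3f} outside [0, 1]")
        return issues


# --------------------------------------------------------------------- #
# unit helpers
# --------------------------------------------------------------------- #
def permil_to_mosm(salinity: float) -> float:
    """Convert practical salinity (permil) to osmolality (mOsm/kg H2O)."""
    if np.any(np.asarray(salinity) < 0):
        raise ValueError("salinity must be >= 0")
    return salinity * MOSM_PER_PERMIL


def mosm_to_permil(osmolality: float) -> float:
    if np.any(np.asarray(osmolality) < 0):
        raise ValueError("osmolality must be >= 0")
    return osmolality / MOSM_PER_PERMIL


_ZONES = (
    (0.5, "fresh"),
    (5.0, "oligohaline"),
    (18.0, "mesohaline"),
    (30.0, "polyhaline"),
    (40.0, "euhaline"),
)


def classify_salinity_zone(salinity: float) -> str:
    """Venice-system salinity zone; boundaries half-open [low, high)."""
    if salinity < 0:
        raise ValueError("salinity must be >= 0")
    for upper, label in _ZONES:
        if salinity < upper:
            return label
    return "hypersaline"


# --------------------------------------------------------------------- #
# probit lethal limits
# --------------------------------------------------------------------- #
def _probit_loglik(params, x, n, dead):
    b0, b1 = params
    p = norm.cdf(b0 + b1 * x)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(dead * np.log(p) + (n - dead) * np.log(1 - p)))


def _fit_probit_ml(x, n, dead):
    """Binomial probit by IRLS (GLM) with a direct-ML fallback."""
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                np.column_stack([dead, n - dead]),
                X,
                family=sm.families.Binomial(link=sm.families.links.Probit()),
            ).fit(maxiter=200)
        b0, b1 = float(res.params[0]), float(res.params[1])
        if np.all(np.isfinite([b0, b1])):
            return b0, b1, True
    except Exception:  # perfect separation etc. — fall through to direct ML
        pass
    xbar, xsd = x.mean(), max(x.std(), 1.0)
    out = minimize(
        lambda p: -_probit_loglik(p, x, n, dead),
        x0=np.array([-xbar / xsd, 1.0 / xsd]),
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-10},
    )
    return float(out.x[0]), float(out.x[1]), bool(out.success)


def _split_side(table: MortalityTable, side: str) -> MortalityTable:
    """Restrict a full-range (U-shaped) mortality table to one flank.

    The flank runs from the relevant extreme through the plateau of
    minimal mortality, so the retained levels are the ones on which
    mortality can only rise toward that side's lethal limit.
    """
    frac = table.dead / np.maximum(table.n, 1)
    lo = int(np.argmin(frac))  # first index attaining the minimum
    hi = len(frac) - 1 - int(np.argmin(frac[::-1]))  # last index attaining it
    rows = table.levels[: hi + 1] if side == "lower" else table.levels[lo:]
    return MortalityTable(rows)


def fit_probit_lethal_limit(table: MortalityTable, side: Literal["lower", "upper"]) -> ProbitFit:
    """Median lethal osmolality (LL50 or UL50) by binomial probit ML.

    Mortality probability is modeled as Phi(b0 + b1 x) on the linear
    osmolality scale (lethal limits on the dilute side approach 0 mOsm,
    where a log scale is undefined).  When no mortality occurred at any
    level on the requested flank the limit is censored: the result carries
    the extreme tested level as a bound and no point estimate, matching
    the "-" convention for unobserved lower limits.
    """
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    if len(table.levels) < 3:
        raise InsufficientDataError("need >= 3 mortality levels")
    sub = _split_side(table, side)
    x, n, dead = sub.x, sub.n, sub.dead
    extreme = float(x.min() if side == "lower" else x.max())
    if dead.sum() == 0:
        return ProbitFit(side=side, lc50=None, censored=True, bound=extreme)
    if np.all(dead == n):
        log.info("probit %s side: complete mortality at every level", side)
        return ProbitFit(side=side, lc50=None, censored=True, bound=extreme)
    frac = dead / np.maximum(n, 1)
    if np.any(np.diff(frac) * (+1 if side == "upper" else -1) < 0):
        log.debug("non-monotone mortality on %s flank (ML handles it)", side)
    b0, b1, ok = _fit_probit_ml(x, n, dead)
    if b1 == 0 or not np.isfinite(b1):
        return ProbitFit(side=side, lc50=None, censored=True, bound=extreme, converged=False)
    lc50 = -b0 / b1
    return ProbitFit(side=side, lc50=float(lc50), censored=False, beta0=b0, beta1=b1, converged=ok)


# --------------------------------------------------------------------- #
# response curve, isosmotic point
# --------------------------------------------------------------------- #
def fit_osmo_curve(records: Sequence[ExposureRecord] | None = None,
                   medium: np.ndarray | None = None,
                   hemolymph: np.ndarray | None = None) -> OsmoCurve:
    """OLS cubic of hemolymph on medium osmolality over surviving crabs.

    Accepts either a sequence of :class:`ExposureRecord` (survivors with a
    hemolymph measurement are used) or raw ``medium``/``hemolymph`` arrays.
    Requires >= 5 distinct medium levels so the residual degrees of freedom
    are positive.
    """
    if records is not None:
        pts = [(r.medium_osmolality, r.hemolymph_osmolality)
               for r in records if r.alive_day5 and r.hemolymph_osmolality is not None]
        if not pts:
            raise InsufficientDataError("no surviving individuals with hemolymph data")
        medium = np.array([p[0] for p in pts], float)
        hemolymph = np.array([p[1] for p in pts], float)
    else:
        medium = np.asarray(medium, float)
        hemolymph = np.asarray(hemolymph, float)
    if len(np.unique(medium)) < 5:
        raise InsufficientDataError(
            f"need >= 5 distinct medium levels, got {len(np.unique(medium))}")
    X = np.vander(medium, 4, increasing=True)
    beta, _, rank, _ = np.linalg.lstsq(X, hemolymph, rcond=None)
    if rank < 4:
        raise np.linalg.LinAlgError("rank-deficient cubic design")
    fitted = X @ beta
    ss_res = float(np.sum((hemolymph - fitted) ** 2))
    ss_tot = float(np.sum((hemolymph - hemolymph.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return OsmoCurve(
        coeffs=tuple(float(b) for b in beta),
        r_squared=min(r2, 1.0),
        fit_range=(float(medium.min()), float(medium.max())),
        n_obs=len(medium),
        mean_medium=float(medium.mean()),
    )


def hemolymph_at(curve: OsmoCurve, x: float) -> float:
    """Evaluate the response curve; extrapolation beyond fit_range warns."""
    lo, hi = curve.fit_range
    if x < lo or x > hi:
        warnings.warn(
            f"evaluating response curve at {x:.0f} outside fit range [{lo:.0f}, {hi:.0f}]",
            stacklevel=2,
        )
    a0, a1, a2, a3 = curve.coeffs
    return float(a0 + x * (a1 + x * (a2 + x * a3)))


def isosmotic_point(curve: OsmoCurve) -> float:
    """External osmolality where hemolymph equals the medium (f(x) = x).

    Roots of the cubic f(x) - x inside the fit range are found in closed
    form; with multiple interior roots the one nearest the mean observed
    medium osmolality is returned and all candidates are logged.
    """
    a0, a1, a2, a3 = curve.coeffs
    if a0 == 0 and a1 == 1 and a2 == 0 and a3 == 0:
        raise ValueError("curve is the identity line; isosmotic point degenerate")
    # highest-order first for np.roots: a3 x^3 + a2 x^2 + (a1-1) x + a0 = 0
    roots = np.roots([a3, a2, a1 - 1.0, a0])
    real = roots[np.abs(roots.imag) < 1e-8].real
    lo, hi = curve.fit_range
    span = max(hi - lo, 1.0)
    inside = real[(real >= lo - 1e-9 * span) & (real <= hi + 1e-9 * span)]
    if inside.size == 0:
        raise NoIsosmoticPointError(
            f"no isosmotic crossing inside fit range [{lo:.0f}, {hi:.0f}]")
    center = curve.mean_medium if np.isfinite(curve.mean_medium) else 0.5 * (lo + hi)
    if inside.size > 1:
        log.info("multiple isosmotic roots %s; choosing nearest to %.0f", inside, center)
    return float(inside[np.argmin(np.abs(inside - center))])


# --------------------------------------------------------------------- #
# regulation indices
# --------------------------------------------------------------------- #
def regulation_indices(
    ic: float,
    ll50: float | None,
    osm_ll50: float | None,
    ul50: float | None,
    osm_ul50: float | None,
) -> tuple[float, float]:
    """Hyper/hypo regulatory-capability indices.

    RC_Hyper = 1 - (IC - Osm_LL50) / (IC - LL50)
    RC_Hypo  = 1 - (Osm_UL50 - IC) / (UL50 - IC)

    Values near 1 mean hemolymph osmolality barely moves between the
    isosmotic point and the lethal limit (strong regulation); near 0 the
    hemolymph tracks the medium (conformity).  A censored input on either
    side yields NaN for that side's index.  Full precision is kept here;
    rounding to the 2 decimals used in reports is the caller's concern.
    """
    if ll50 is not None and osm_ll50 is not None and np.isfinite(ll50):
        if ic == ll50:
            raise ZeroDivisionError("IC equals LL50; hyper index undefined")
        rc_hyper = 1.0 - (ic - osm_ll50) / (ic - ll50)
    else:
        rc_hyper = float("nan")
    if ul50 is not None and osm_ul50 is not None and np.isfinite(ul50):
        if ul50 == ic:
            raise ZeroDivisionError("UL50 equals IC; hypo index undefined")
        rc_hypo = 1.0 - (osm_ul50 - ic) / (ul50 - ic)
    else:
        rc_hypo = float("nan")
    return rc_hyper, rc_hypo


# --------------------------------------------------------------------- #
# per-population derivation and species aggregation
# --------------------------------------------------------------------- #
def _population_traits(species, pop, recs, mort, habitat_mosm):
    curve = fit_osmo_curve(records=recs)
    lower = fit_probit_lethal_limit(mort, "lower")
    upper = fit_probit_lethal_limit(mort, "upper")
    ic = isosmotic_point(curve)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        osm_ll50 = hemolymph_at(curve, lower.lc50) if not lower.censored else float("nan")
        osm_ul50 = hemolymph_at(curve, upper.lc50) if not upper.censored else float("nan")
        hemo = hemolymph_at(curve, habitat_mosm)
    ll50 = lower.lc50 if not lower.censored else float("nan")
    ul50 = upper.lc50 if not upper.censored else float("nan")
    rc_hyper, rc_hypo = regulation_indices(ic, ll50, osm_ll50, ul50, osm_ul50)
    ts = TraitSet(
        species_id=species,
        habitat_osmolality=habitat_mosm,
        hemolymph_osmolality=hemo,
        ll50=ll50,
        ul50=ul50,
        osm_ll50=osm_ll50,
        osm_ul50=osm_ul50,
        isosmotic_point=ic,
        rc_hyper=rc_hyper,
        rc_hypo=rc_hypo,
        ll50_censored=lower.censored,
    )
    diag = {
        "population_id": pop,
        "curve_coeffs": list(curve.coeffs),
        "curve_r2": curve.r_squared,
        "fit_range": list(curve.fit_range),
        "ll50_censored": lower.censored,
        "ul50_censored": upper.censored,
        "invariant_issues": ts.validate(),
    }
    return ts, diag


TRAIT_COLUMNS = [
    "habitat_osmolality", "hemolymph_osmolality", "ll50", "ul50",
    "osm_ll50", "osm_ul50", "isosmotic_point", "rc_hyper", "rc_hypo",
]


def derive_traits(
    records: pd.DataFrame,
    mortality: pd.DataFrame,
    habitat: pd.DataFrame,
    on_species_failure: str = "raise",
) -> tuple[pd.DataFrame, dict]:
    """Per-species trait table (mean +/- SE across populations) + diagnostics.

    ``records``: species_id, population_id, medium_mosm, alive_day5,
    hemolymph_mosm.  ``mortality``: species_id, population_id, medium_mosm,
    n_exposed, n_dead.  ``habitat``: species_id, population_id,
    habitat_mosm.  Traits are derived per population, then averaged per
    species with SE = sd / sqrt(n_populations) (unweighted; population
    sample sizes vary).  Populations whose lower limit is censored are
    excluded from the LL50 / RC_Hyper aggregation and counted in the
    diagnostics.
    """
    rows, diags = [], {}
    for species, srecs in records.groupby("species_id", sort=True):
        per_pop: list[TraitSet] = []
        sdiag = []
        for pop, precs in srecs.groupby("population_id", sort=True):
            try:
                recs = [
                    ExposureRecord(species, pop, r.medium_mosm, bool(r.alive_day5),
                                   None if pd.isna(r.hemolymph_mosm) else r.hemolymph_mosm)
                    for r in precs.itertuples()
                ]
                msub = mortality[(mortality.species_id == species)
                                 & (mortality.population_id == pop)].sort_values("medium_mosm")
                mort = MortalityTable(tuple(
                    (float(r.medium_mosm), int(r.n_exposed), int(r.n_dead))
                    for r in msub.itertuples()))
                hrow = habitat[(habitat.species_id == species)
                               & (habitat.population_id == pop)]
                hab = float(hrow.habitat_mosm.iloc[0])
                ts, d = _population_traits(species, pop, recs, mort, hab)
                per_pop.append(ts)
                sdiag.append(d)
            except Exception as exc:
                log.warning("population %s/%s failed: %s", species, pop, exc)
                sdiag.append({"population_id": pop, "error": str(exc)})
        if not per_pop:
            if on_species_failure == "skip":
                log.error("no population of %s yielded traits; species dropped", species)
                diags[species] = sdiag
                continue
            raise InsufficientDataError(f"no population of {species} yielded traits")
        row = {"species_id": species, "n_populations": len(per_pop)}
        n_censored = sum(ts.ll50_censored for ts in per_pop)
        row["n_ll50_censored"] = n_censored
        for col in TRAIT_COLUMNS:
            vals = np.array([getattr(ts, col) for ts in per_pop], float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[col], row[col + "_se"] = float("nan"), float("nan")
            else:
                row[col] = float(vals.mean())
                row[col + "_se"] = (
                    float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else float("nan")
                )
        row["ll50_censored"] = n_censored == len(per_pop)
        rows.append(row)
        diags[species] = sdiag
        if n_censored:
            log.info("%s: %d/%d populations with censored LL50 excluded from "
                     "LL50/RC_Hyper aggregation", species, n_censored, len(per_pop))
    return pd.DataFrame(rows).set_index("species_id"), diags
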