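"""End-to-end orchestration: traits -> correlogram -> PGLS -> ancestral
states / imputation -> regime detection, with serialized stage artifacts.

Each stage reads the previous stage's output from the run directory, so
any stage can be re-run in isolation; a manifest records the seed and a
hash of the configuration.  All JSON artifacts are written with sorted
keys and fixed float formatting, so two runs with the same configuration
and seed are byte-identical (timestamps live only in the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparative, regimes as regimes_mod
from .osmo_traits import TRAIT_COLUMNS, derive_traits
from .phylo import Phylogeny, patristic_distances
from .synth import StudyConfig, gen_study

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

#: Trait pairs whose evolutionary correlation the PGLS stage tests.
PGLS_PAIRS = [
    ("hemolymph_osmolality", "habitat_osmolality"),
    ("isosmotic_point", "habitat_osmolality"),
    ("rc_hypo", "rc_hyper"),
    ("rc_hyper", "habitat_osmolality"),
    ("rc_hypo", "habitat_osmolality"),
]

ANCESTRAL_TRAITS = ["habitat_osmolality", "hemolymph_osmolality", "rc_hyper", "rc_hypo"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    out_dir: str = "osmophylo_run"
    seed: int = 0
    # inputs (None = simulate with gen_study)
    records: str | None = None
    mortality: str | None = None
    habitat: str | None = None
    traits: str | None = None  # species-level trait CSV; bypasses derivation
    tree: str | None = None  # Newick; None = simulate
    # analysis toggles
    n_classes: int = 4
    n_perm: int = 999
    use_aicc: bool = True  # small-sample criterion; species tables are small
    max_regimes: int | None = 8  # bound on stepwise regime growth
    backward_phase: bool = False
    standardize_traits: bool = True
    significance: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=default,
                               allow_nan=True) + "\n")


def _roundf(x, nd=10):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)


# --------------------------------------------------------------------- #
def validate_inputs(traits: pd.DataFrame, tree: Phylogeny | None) -> list[dict]:
    """Schema / unit / label-agreement diagnostics (never raises)."""
    diags: list[dict] = []
    missing_cols = [c for c in TRAIT_COLUMNS if c not in traits.columns]
    if missing_cols:
        diags.append({"severity": "error", "message": f"missing trait columns: {missing_cols}"})
    hab = traits.get("habitat_osmolality")
    if hab is not None and hab.notna().any() and hab.max() < 50:
        diags.append({
            "severity": "warning",
            "message": "habitat column magnitude < 50 throughout: values look like "
                       "permil salinity, not mOsm/kg H2O (1 permil = 30 mOsm)",
        })
    if tree is not None:
        extra = sorted(set(traits.index) - set(tree.tip_labels))
        if extra:
            diags.append({"severity": "warning",
                          "message": f"species absent from tree (will be dropped): {extra}"})
        missing = sorted(set(tree.tip_labels) - set(traits.index))
        if missing:
            diags.append({"severity": "warning",
                          "message": f"tree tips without trait data: {missing}"})
    return diags


# --------------------------------------------------------------------- #
def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the report summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rng = np.random.default_rng(config.seed)

    # ---- stage 0: inputs (simulate anything not supplied) -------------
    study = None
    if config.records is None and config.traits is None or config.tree is None:
        study = gen_study(StudyConfig(), seed=int(rng.integers(2**31)))
    if config.tree is not None:
        tree = Phylogeny.from_newick(Path(config.tree).read_text())
    else:
        tree = study.tree
        (out / "tree.nwk").write_text(tree.to_newick())
        _json_dump(study.ground_truth_json(), out / "ground_truth.json")

    # ---- stage 1: trait derivation ------------------------------------
    if config.traits is not None:
        traits = pd.read_csv(config.traits, index_col=0)
    elif config.records is not None:
        records = pd.read_csv(config.records)
        mortality = pd.read_csv(config.mortality)
        habitat = pd.read_csv(config.habitat)
        traits, diags = derive_traits(records, mortality, habitat,
                                      on_species_failure="skip")
        _json_dump(diags, out / "trait_diagnostics.json")
    else:
        traits, diags = derive_traits(study.records, study.mortality,
                                      study.habitat, on_species_failure="skip")
        _json_dump(diags, out / "trait_diagnostics.json")
    traits = traits[[c for c in traits.columns if c in TRAIT_COLUMNS
                     or c.endswith("_se") or c.startswith("n_") or c == "ll50_censored"]]
    traits.round(6).to_csv(out / "traits.csv")

    diagnostics = validate_inputs(traits, tree)
    _json_dump(diagnostics, out / "input_diagnostics.json")
    shared = sorted(set(traits.index) & set(tree.tip_labels))
    if len(shared) < 4:
        raise RuntimeError("stage=validate: fewer than 4 species shared between "
                           "traits and tree")
    tree = tree.prune_to(shared) if len(shared) < tree.n_tips else tree
    X = traits.loc[shared, TRAIT_COLUMNS].astype(float)

    # ---- stage 2: imputation of missing values ------------------------
    completed = X.copy()
    impute_report = {}
    for col in TRAIT_COLUMNS:
        if completed[col].isna().any():
            if completed[col].notna().sum() < 3:
                log.warning("stage=impute: %s has <3 observed species; left missing", col)
                continue
            filled, sd, info = comparative.impute_missing_ou(completed[col], tree)
            imputed = completed[col].isna()
            completed[col] = filled
            impute_report[col] = {
                "model": info.get("model"), "alpha": _roundf(info.get("alpha")),
                "imputed": {sp: {"value": _roundf(filled[sp], 4), "se": _roundf(sd[sp], 4)}
                            for sp in completed.index[imputed]},
            }
    _json_dump(impute_report, out / "imputation.json")
    completed.round(6).to_csv(out / "traits_complete.csv")

    # ---- stage 3: correlograms ----------------------------------------
    classes = comparative.make_distance_classes(patristic_distances(tree), k=config.n_classes)
    corr_report = {"k": config.n_classes, "n_perm": config.n_perm,
                   "boundaries": [_roundf(b, 6) for b in classes.boundaries], "traits": {}}
    for i, col in enumerate(TRAIT_COLUMNS):
        res = comparative.correlogram(
            completed[col], tree, classes=classes, n_perm=config.n_perm,
            seed=int(config.seed * 1000 + i) % 2**31)
        rec = res.to_frame().round(6).to_dict(orient="records")
        corr_report["traits"][col] = rec
    _json_dump(corr_report, out / "correlogram.json")

    # ---- stage 4: PGLS -------------------------------------------------
    pgls_report = {}
    for yname, xname in PGLS_PAIRS:
        fit = comparative.pgls_ou(completed[yname], completed[xname], tree)
        pgls_report[f"{yname}~{xname}"] = {
            "slope": _roundf(fit.slope, 6), "intercept": _roundf(fit.intercept, 6),
            "alpha": _roundf(fit.alpha_hat, 6), "F": _roundf(fit.f_statistic, 4),
            "df": [fit.df_model, fit.df_residual], "p": _roundf(fit.p_value, 6),
            "logL": _roundf(fit.log_likelihood, 4),
            "significant": bool(fit.p_value <= config.significance),
        }
    _json_dump(pgls_report, out / "pgls.json")

    # ---- stage 5: ancestral states ------------------------------------
    anc_report = {}
    for col in ANCESTRAL_TRAITS:
        states = comparative.ancestral_bm(completed[col], tree)
        root = states.estimates[0]
        anc_report[col] = {
            "sigma2": _roundf(states.sigma2_hat, 6),
            "root": {"estimate": _roundf(root[0], 4), "ci_low": _roundf(root[1], 4),
                     "ci_high": _roundf(root[2], 4)},
        }
        (out / f"ancestral_{col}.nwk").write_text(
            comparative.annotated_newick(tree, states))
    _json_dump(anc_report, out / "ancestral.json")

    # ---- stage 6: regime detection ------------------------------------
    trace = regimes_mod.surface_forward(
        tree, completed, use_aicc=config.use_aicc,
        standardize=config.standardize_traits, max_regimes=config.max_regimes)
    if config.backward_phase:
        trace = regimes_mod.surface_backward(trace, tree, completed,
                                             use_aicc=config.use_aicc)
    profile = regimes_mod.partial_aic_profile(trace)
    final = trace.final
    regime_report = {
        "criterion": final.criterion,
        "n_regimes": final.n_regimes,
        "aic_trace": [_roundf(a, 4) for a in trace.aics],
        "steps": profile.drop(columns=["total_aic"]).assign(
            total_aic=[_roundf(a, 4) for a in trace.aics]).round(4).to_dict(orient="records"),
        "traits": {t: {"alpha": _roundf(f.alpha, 6), "sigma2": _roundf(f.sigma2, 6),
                       "theta": [_roundf(v, 6) for v in f.theta],
                       "partial_aic": _roundf(f.aic, 4)}
                   for t, f in final.traits.items()},
        "painting_origins": [[int(n), int(r)] for n, r in final.painting.origins],
    }
    _json_dump(regime_report, out / "regimes.json")
    (out / "regimes.nwk").write_text(
        regimes_mod.painting_newick(tree, final.painting))

    # ---- manifest ------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "n_species": len(shared),
        "elapsed_s": round(time.time() - t0, 2),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _json_dump(manifest, out / "manifest.json")
    return {
        "out_dir": str(out), "n_species": len(shared),
        "n_regimes": final.n_regimes, "pgls": pgls_report,
        "diagnostics": diagnostics,
    }
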