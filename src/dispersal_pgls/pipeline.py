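"""End-to-end orchestration: records + wings + tree -> dispersal estimates
-> merged trait table -> single-predictor PGLS table -> all-subsets
multimodel inference.

Everything here is thin plumbing over the analysis modules; each stage
logs to stderr, writes plain CSV/JSON artifacts, and a run manifest records
the seed, configuration hash and library versions so a rerun with identical
inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dispersal import (
    FilterConfig,
    estimate_all_species,
    estimates_to_frame,
    filter_records,
    read_meta_csv,
    read_records_csv,
    retain_species,
)
from .model_selection import (
    Design,
    PredictorSpec,
    confidence_set,
    enumerate_models,
    fit_models,
    gvif,
    model_average,
    prepare_design,
    rank_models,
    variable_importance,
)
from .morphometrics import read_wings_csv, species_table
from .phylo import (
    Phylogeny,
    check_taxa_match,
    normalize_taxon,
    pgls_ml,
    phylo_covariance,
    read_newick,
)

__all__ = [
    "PipelineConfig",
    "build_trait_table",
    "run_single_predictor_table",
    "run_dredge",
    "run_full_pipeline",
]

logger = logging.getLogger("dispersal_pgls")
if not logger.handlers:  # results go to files; logs go to stderr
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


#: default predictor handling, mirroring the comparative analysis:
#: right-skewed continuous predictors enter on the natural-log scale and all
#: predictors are standardized; habitat contrasts use "coasts" as reference.
DEFAULT_PREDICTORS: tuple[PredictorSpec, ...] = (
    PredictorSpec("aspect_ratio", "continuous", log_transform=True),
    PredictorSpec("recovery_years", "continuous", log_transform=True),
    PredictorSpec("population_size", "continuous", log_transform=True),
    PredictorSpec(
        "habitat",
        "categorical",
        levels=("coasts", "open", "wetlands", "woodlands"),
        reference="coasts",
    ),
    PredictorSpec("mass", "continuous", log_transform=True),
    PredictorSpec("foraging", "categorical", levels=("1", "2", "3", "4", "5")),
    PredictorSpec("migratory", "binary"),
    PredictorSpec("migration_distance", "continuous", log_transform=True),
    PredictorSpec("range_area", "continuous", log_transform=True),
    PredictorSpec(
        "diet",
        "categorical",
        levels=("carnivore", "herbivore", "insectivore", "omnivore"),
    ),
)


@dataclass
class PipelineConfig:
    records: str = ""
    meta: str = ""
    wings: str = ""
    tree: str = ""
    out_dir: str = "results"
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    min_n: int = 5
    predictors: tuple[PredictorSpec, ...] = DEFAULT_PREDICTORS
    dredge_predictors: tuple[str, ...] = (
        "aspect_ratio",
        "recovery_years",
        "population_size",
        "habitat",
        "mass",
    )
    max_terms: int = 5
    interactions: bool = True
    confidence_level: float = 0.95
    seed: int = 0


def build_trait_table(
    estimates: pd.DataFrame, ar_table: pd.DataFrame, meta_table
) -> pd.DataFrame:
    """Merge dispersal estimates, aspect ratios and species metadata.

    The response ``log_dispersal`` is ln(geometric-mean distance in km);
    ``recovery_years`` carries the banding->recovery elapsed-time covariate.
    Species missing from any source simply drop out of the merge (logged by
    the caller), mirroring the attrition real trait coverage produces.
    """
    meta_rows = []
    for sp, m in meta_table.items():
        meta_rows.append(
            {
                "species": sp,
                "habitat": m.habitat,
                "diet": m.diet,
                "foraging": m.foraging,
                "population_size": m.population_size,
                "mass": m.mass,
                "migration_distance": m.migration_distance,
                "range_area": m.range_area,
                "migratory": m.migratory,
            }
        )
    meta_df = pd.DataFrame(meta_rows)
    df = estimates.merge(
        ar_table.rename(columns={"mean_AR": "aspect_ratio"}), on="species", how="inner"
    ).merge(meta_df, on="species", how="inner")
    df["log_dispersal"] = np.log(df["geomean_km"])
    df = df.rename(columns={"mean_recovery_years": "recovery_years"})
    df["species"] = df["species"].map(normalize_taxon)
    return df.set_index("species").sort_index()


def _prune_tree(tree: Phylogeny, taxa: Sequence[str]) -> Phylogeny:
    keep = set(taxa)
    extra = [t for t in tree.taxa if t not in keep]
    if not extra:
        return tree
    pruned = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=keep)
    return Phylogeny(pruned)


def run_single_predictor_table(
    traits: pd.DataFrame,
    tree: Phylogeny,
    specs: Sequence[PredictorSpec],
    response: str = "log_dispersal",
) -> pd.DataFrame:
    """One PGLS fit per predictor, plus the intercept-only model.

    For continuous/binary predictors the p-value is the t-test on the
    slope; for categorical predictors it is a likelihood-ratio test of the
    whole predictor against the intercept-only model.  Model probabilities
    are Akaike weights across this single-predictor candidate set and
    delta-AICc is taken against the best single-predictor model.
    """
    missing = traits[response].isna()
    if missing.any():
        raise ValueError(f"missing response for {list(traits.index[missing])}")
    order = check_taxa_match(_prune_tree(tree, list(traits.index)), list(traits.index))
    C, taxa = phylo_covariance(_prune_tree(tree, order), order=list(traits.index))
    y = traits.loc[taxa, response].to_numpy(dtype=float)
    n = len(y)

    null_fit = pgls_ml(np.ones((n, 1)), y, C, terms=("Intercept",))
    rows = [
        {
            "model": "(intercept only)",
            "intercept": null_fit.beta[0],
            "coefficient": np.nan,
            "se": np.nan,
            "p_value": np.nan,
            "df": 1,
            "lambda": null_fit.lambda_,
            "loglik": null_fit.loglik,
            "AICc": null_fit.aicc,
            "R2": 0.0,
        }
    ]
    for spec in specs:
        design = prepare_design(traits.loc[taxa], [spec])
        if design.dropped:
            raise ValueError(
                f"{spec.name}: missing values for {design.dropped}; "
                "drop those species before the single-predictor table"
            )
        cols = design.column_groups[spec.name]
        X = np.column_stack(
            [np.ones(n)] + [design.X[c].to_numpy() for c in cols]
        )
        fit = pgls_ml(X, y, C, terms=("Intercept", *cols))
        if spec.role != "categorical":
            coef, se, p = fit.beta[1], fit.se[1], fit.p_values[1]
        else:
            from scipy import stats

            lr = max(0.0, 2.0 * (fit.loglik - null_fit.loglik))
            p = float(stats.chi2.sf(lr, df=len(cols)))
            coef, se = np.nan, np.nan
        rows.append(
            {
                "model": spec.name,
                "intercept": fit.beta[0],
                "coefficient": coef,
                "se": se,
                "p_value": p,
                "df": 1 + len(cols),
                "lambda": fit.lambda_,
                "loglik": fit.loglik,
                "AICc": fit.aicc,
                "R2": fit.r2,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_AICc"] = table["AICc"] - table["AICc"].min()
    w = np.exp(-table["delta_AICc"] / 2.0)
    table["p_model"] = w / w.sum()
    return table.sort_values("delta_AICc", kind="stable").reset_index(drop=True)


def run_dredge(
    traits: pd.DataFrame,
    tree: Phylogeny,
    specs: Sequence[PredictorSpec],
    response: str = "log_dispersal",
    max_terms: int = 5,
    interactions: bool = True,
    confidence_level: float = 0.95,
):
    """All-subsets PGLS comparison over the given predictors.

    Returns (ModelSet, importance dict, averaged-coefficients frame,
    confidence-set indices, GVIF report, Design).
    """
    design = prepare_design(traits, list(specs))
    kept = design.X.index
    order = list(kept)
    pruned = _prune_tree(tree, order)
    C, taxa = phylo_covariance(pruned, order=order)
    y = traits.loc[taxa, response].to_numpy(dtype=float)
    formulas = enumerate_models(list(specs), max_terms=max_terms, interactions=interactions)
    logger.info("dredge: fitting %d candidate models on %d species", len(formulas), len(y))
    fitted = fit_models(design, y, C, formulas)
    ms = rank_models(fitted)
    imp = variable_importance(ms)
    avg = model_average(ms)
    cset = confidence_set(ms, confidence_level)
    report = gvif(design) if len(specs) >= 2 else None
    return ms, imp, avg, cset, report, design


def _hash_files(paths: Sequence[str | Path], extra: str = "") -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    h.update(extra.encode())
    return h.hexdigest()


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Outputs: dispersal_estimates.csv, filter_audit.json, trait_table.csv,
    single_predictor_table.csv, model_table.csv, importance.csv,
    averaged_coefficients.csv, gvif.csv and manifest.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        logger.info("stage %-24s +%.1fs", name, time.time() - t0)

    stage("load inputs")
    records = read_records_csv(cfg.records)
    metas = read_meta_csv(cfg.meta)
    wings = read_wings_csv(cfg.wings)
    tree = read_newick(cfg.tree)

    stage("filter records")
    retained, audit = filter_records(records, metas, cfg.filter_config)
    (out / "filter_audit.json").write_text(audit.to_json() + "\n")

    stage("estimate dispersal")
    estimates = retain_species(
        estimate_all_species(retained, cfg.filter_config), cfg.min_n
    )
    est_df = estimates_to_frame(estimates)
    est_df.to_csv(out / "dispersal_estimates.csv", index=False)

    stage("aspect ratios")
    ar_table = species_table(wings)

    stage("merge traits")
    traits = build_trait_table(est_df, ar_table, metas)
    dropped = sorted(set(est_df["species"].map(normalize_taxon)) - set(traits.index))
    if dropped:
        logger.info("dropped %d species lacking traits: %s", len(dropped), dropped)
    tree_taxa = set(tree.taxa)
    missing_tips = sorted(set(traits.index) - tree_taxa)
    if missing_tips:
        raise ValueError(f"species absent from the tree: {missing_tips}")
    traits.to_csv(out / "trait_table.csv")

    stage("single-predictor table")
    single = run_single_predictor_table(traits, tree, cfg.predictors)
    single.to_csv(out / "single_predictor_table.csv", index=False)

    stage("dredge")
    dredge_specs = [
        s for s in cfg.predictors if s.name in set(cfg.dredge_predictors)
    ]
    ms, imp, avg, cset, gvif_report, design = run_dredge(
        traits,
        tree,
        dredge_specs,
        max_terms=cfg.max_terms,
        interactions=cfg.interactions,
        confidence_level=cfg.confidence_level,
    )
    model_table = ms.to_frame()
    model_table["in_confidence_set"] = [
        i in set(cset) for i in range(len(model_table))
    ]
    model_table.to_csv(out / "model_table.csv", index=False)
    pd.DataFrame(
        sorted(imp.items(), key=lambda kv: -kv[1]), columns=["predictor", "importance"]
    ).to_csv(out / "importance.csv", index=False)
    avg.to_csv(out / "averaged_coefficients.csv", index=False)
    if gvif_report is not None:
        gvif_report.table.to_csv(out / "gvif.csv", index=False)

    stage("manifest")
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_species": int(len(traits)),
        "n_models": int(len(ms)),
        "confidence_set_size": int(len(cset)),
        "input_hash": _hash_files(
            [cfg.records, cfg.meta, cfg.wings, cfg.tree], extra=repr(cfg)
        ),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    stage("done")
    return manifest
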