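"""End-to-end model suite: raw tables to a results table.

Builds the species-aligned analysis table (log-scaled morphometrics,
raw-scale seasonality metrics), then fits the comparative model suite:

* ``svl_seasonality`` — body size against temperature seasonality;
* three bivariate brain models, one per seasonality measure, each with
  SVL and body mass as covariates;
* the multiple regression of whole brain on all three seasonality
  measures plus SVL and body mass;
* five region models: region ~ three seasonality measures + rest of
  brain;
* among-year CV models (brain and regions), kept separate from the
  within-year temperature CV to avoid collinearity between the two.

Raw p-values are reported with no multiple-testing correction (noted in
the run metadata).  Intercept rows are included but flagged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from . import climate as clim
from .morphometrics import REGIONS, log_scale, read_individual_csv, rest_of_brain, species_means
from .pgls import ModelSpec, PGLSFit, fit_pgls
from .tree import prune as prune_tree
from .tree import read_newick, tip_labels

logger = logging.getLogger(__name__)

SEASONALITY_TERMS = ["cv_temp", "cv_precip", "p2t"]

SUITES = ("bivariate", "table1", "regions", "among_years", "all")


def build_analysis_table(
    traits: pd.DataFrame | str,
    climate: pd.DataFrame | str,
    tree: dendropy.Tree | str,
    daily: pd.DataFrame | str | None = None,
    prune: bool = False,
):
    """Assemble the species-by-variable table the models are fit to.

    Parameters may be in-memory objects or file paths.  Species sets of
    the trait table, climate table and tree must agree; with
    ``prune=False`` any mismatch raises an error listing the offending
    species, with ``prune=True`` a supertree is pruned to the trait
    species (other mismatches still raise).

    Returns ``(table, tree)``: the table rows follow the (pruned)
    tree's tip order, morphometric columns are ``log10(1000 x)``-scaled
    and seasonality columns are on their natural scales.
    """
    if isinstance(traits, str | Path):
        traits = read_individual_csv(traits)
    if isinstance(climate, str | Path):
        climate = clim.read_climate_csv(climate)
    if isinstance(tree, str | Path):
        tree = read_newick(tree)
    if isinstance(daily, str | Path):
        daily = clim.read_daily_csv(daily)

    sp_table = species_means(traits)
    sp_traits = set(sp_table.index)
    sp_climate = set(climate.index)
    sp_tree = set(tip_labels(tree))

    no_climate = sorted(sp_traits - sp_climate)
    if no_climate:
        raise ValueError(f"species missing from climate table: {no_climate}")
    no_tree = sorted(sp_traits - sp_tree)
    if no_tree:
        raise ValueError(f"species missing from tree: {no_tree}")
    extra_tips = sorted(sp_tree - sp_traits)
    if extra_tips:
        if not prune:
            raise ValueError(
                f"tree tips without trait data: {extra_tips} (pass prune=True "
                "to drop them)"
            )
        logger.warning("pruning %d tip(s) without trait data", len(extra_tips))
        tree = prune_tree(tree, sorted(sp_traits))

    order = [lab for lab in tip_labels(tree)]
    rows = {}
    for sp in order:
        mc = clim.monthly_climate_row(climate.loc[sp])
        sub = daily[daily["species"] == sp] if daily is not None else None
        if sub is not None and sub.empty:
            raise ValueError(f"species missing from daily table: [{sp!r}]")
        met = clim.seasonality_metrics(mc, daily=sub)
        rec = sp_table.loc[sp]
        row = {
            "n_individuals": rec["n_individuals"],
            "log_svl": log_scale(rec["svl_mm"]),
            "log_mass": log_scale(rec["mass_mg"]),
            "log_brain": log_scale(rec["brain_volume"]),
            "cv_temp": met.cv_temp,
            "cv_precip": met.cv_precip,
            "p2t": met.p2t_months,
        }
        if met.cv_temp_among_years is not None:
            row["cv_temp_among_years"] = met.cv_temp_among_years
        for r in REGIONS:
            row[f"log_{r}"] = log_scale(rec[f"{r}_volume"])
            row[f"log_rob_{r}"] = log_scale(
                rest_of_brain(rec["brain_volume"], rec[f"{r}_volume"])
            )
        rows[sp] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    table.index.name = "species"
    return table, tree


def model_suite_specs(suite: str, with_among_years: bool) -> list[ModelSpec]:
    """The ordered model list for one suite selection."""
    if suite not in SUITES:
        raise ValueError(f"unknown suite {suite!r}; choose from {SUITES}")
    body = ["log_svl", "log_mass"]
    svl = [ModelSpec("svl_seasonality", "log_svl", ["cv_temp"])]
    bivariate = [
        ModelSpec(f"brain_{term}", "log_brain", [term], list(body))
        for term in SEASONALITY_TERMS
    ]
    table1 = [
        ModelSpec("brain_multiple", "log_brain", list(SEASONALITY_TERMS), list(body))
    ] + [
        ModelSpec(
            f"{r}_multiple", f"log_{r}", list(SEASONALITY_TERMS), [f"log_rob_{r}"]
        )
        for r in REGIONS
    ]
    among = [
        ModelSpec("brain_among_years", "log_brain", ["cv_temp_among_years"], list(body))
    ] + [
        ModelSpec(
            f"{r}_among_years", f"log_{r}", ["cv_temp_among_years"], [f"log_rob_{r}"]
        )
        for r in REGIONS
    ]
    chosen = {
        "bivariate": svl + bivariate,
        "table1": table1,
        "regions": table1[1:],
        "among_years": among,
        "all": svl + bivariate + table1 + among,
    }[suite]
    if not with_among_years:
        chosen = [m for m in chosen if "cv_temp_among_years" not in m.predictors]
    return chosen


def run_model_suite(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    suite: str = "all",
) -> pd.DataFrame:
    """Fit every model of the selected suite; one row per term.

    A model that fails to fit is recorded (model id + error message in
    the ``error`` column) and the suite continues.  Columns: model,
    response, term, beta, se, t, p, lambda_hat, p_lambda_vs_0,
    p_lambda_vs_1, loglik, n, error.
    """
    specs = model_suite_specs(
        suite, with_among_years="cv_temp_among_years" in table.columns
    )
    if not specs:
        raise ValueError(
            f"suite {suite!r} needs among-year temperature data (daily table)"
        )
    frames = []
    for spec in specs:
        try:
            fit = fit_pgls(table, spec, tree)
        except Exception as err:  # recorded, suite continues
            logger.error("model %s failed: %s", spec.name, err)
            frames.append(
                pd.DataFrame(
                    [{"model": spec.name, "response": spec.response, "error": str(err)}]
                )
            )
            continue
        block = fit.terms.copy()
        block.insert(0, "model", fit.model)
        block.insert(1, "response", fit.response)
        block["lambda_hat"] = fit.lambda_hat
        block["p_lambda_vs_0"] = fit.p_lambda_vs_0
        block["p_lambda_vs_1"] = fit.p_lambda_vs_1
        block["loglik"] = fit.loglik
        block["n"] = fit.n
        block["error"] = ""
        frames.append(block)
    results = pd.concat(frames, ignore_index=True)
    if "error" not in results.columns:
        results["error"] = ""
    results["error"] = results["error"].fillna("")
    return results


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    results: pd.DataFrame,
    outdir: str | Path,
    config: dict | None = None,
    input_paths: dict[str, str] | None = None,
    table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the results table plus metadata and optional scatter data.

    Emits ``results.csv`` (round-trippable), ``metadata.json`` (package
    version, config hash, input checksums, a note that p-values are
    uncorrected) and ``run.log``; when the analysis ``table`` is given,
    per-model scatter files ``scatter_<model>.csv`` pair each
    seasonality predictor with the response residual from a fit on the
    covariates alone.
    """
    if results.empty:
        raise ValueError("results table is empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"results": outdir / "results.csv"}
    # %.17g keeps the CSV round-trippable to the exact double
    results.to_csv(paths["results"], index=False, float_format="%.17g")

    config = dict(config or {})
    cfg_json = json.dumps(config, sort_keys=True)
    meta = {
        "package": "seasonbrain",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_sha256": {
            name: _sha256(Path(p)) for name, p in (input_paths or {}).items()
        },
        "n_models": int(results["model"].nunique()),
        "p_value_correction": "none (raw p-values reported)",
    }
    paths["metadata"] = outdir / "metadata.json"
    paths["metadata"].write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")

    lines = [f"seasonbrain {__version__}: {meta['n_models']} model(s) fitted"]
    for model, grp in results.groupby("model", sort=False):
        err = grp["error"].iloc[0] if "error" in grp else ""
        if isinstance(err, str) and err:
            lines.append(f"  {model}: FAILED ({err})")
        else:
            lines.append(
                f"  {model}: lambda={grp['lambda_hat'].iloc[0]:.3f}, "
                f"n={int(grp['n'].iloc[0])}"
            )
    paths["log"] = outdir / "run.log"
    paths["log"].write_text("\n".join(lines) + "\n")

    if table is not None:
        from .pgls import PGLSRegression
        from .tree import PhyloCovariance  # noqa: F401  (doc pointer)

        ok = results[results["error"] == ""]
        for model in ok["model"].unique():
            grp = ok[ok["model"] == model]
            response = grp["response"].iloc[0]
            terms = [t for t in grp["term"] if t != "intercept"]
            seas = [t for t in terms if t in SEASONALITY_TERMS + ["cv_temp_among_years"]]
            if not seas:
                continue
            covs = [t for t in terms if t not in seas]
            if covs:
                est = PGLSRegression(lam=1.0).fit(
                    table[covs].to_numpy(), table[response].to_numpy(), V=None
                )
                resid = table[response].to_numpy() - est.predict(table[covs].to_numpy())
            else:
                resid = table[response].to_numpy() - table[response].mean()
            sc = pd.DataFrame({"species": table.index, "residual": resid})
            for t in seas:
                sc[t] = table[t].to_numpy()
            p = outdir / f"scatter_{model}.csv"
            sc.to_csv(p, index=False)
            paths[f"scatter_{model}"] = p
    return paths
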