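"""End-to-end analysis pipeline.

Stage order mirrors applied SEM practice for this kind of survey: score the
instruments, screen the data (normality, outliers, adequacy, clustering,
common-method bias), check identification and instrument quality at the
composite level, repair the loop if instruments are weak or invalid (delete
the offending non-recursive paths), parcel the items, fit the latent
non-recursive model by ML with bootstrap CIs, and decompose effects.
The pipeline refuses to fit a model whose identification verdict is
negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .effects import effect_table, model_implied_latent_variances, standardize_effects
from .identify import (InstrumentReport, StructuralSystem, identification_report,
                       instrument_diagnostics)
from .io import write_json
from .measurement import make_parcels, parcel_measurement
from .scales import DEFAULT_SCALES, apply_listwise, prevalence_report, score_dataset
from .sem import SemModel, bootstrap_fit, compare_models, fit_sem

log = logging.getLogger("nrsem.pipeline")

#: construct -> scale item columns (canonical names)
CONSTRUCT_ITEMS: dict[str, list[str]] = {
    "depression": [f"phq{i}" for i in range(1, 10)],
    "anxiety": [f"gad{i}" for i in range(1, 8)],
    "somatic": [f"sss{i}" for i in range(1, 9)],
    "stress": [f"pss{i}" for i in range(1, 11)],
    "social_support": [f"osss{i}" for i in range(1, 4)],
}

#: hypothesized structural equations (named-variable version of the study's
#: three printed equations, plus sex which the effect tables adjust for)
FULL_REGRESSIONS: dict[str, list[str]] = {
    "depression": ["anxiety", "somatic", "stress", "social_support", "alcohol_use",
                   "chronic_illness", "death_loved_one", "family_pressure",
                   "sex_female", "school_private"],
    "anxiety": ["depression", "somatic", "stress", "alcohol_use", "chronic_illness",
                "sex_female", "school_private", "academic_ability_good",
                "physical_trauma"],
    "somatic": ["depression", "anxiety", "stress", "alcohol_use", "chronic_illness",
                "sex_female", "school_private", "study_time_high", "extra_tutoring"],
}

INSTRUMENTS: dict[str, list[str]] = {
    "depression": ["social_support", "death_loved_one", "family_pressure"],
    "anxiety": ["academic_ability_good", "physical_trauma"],
    "somatic": ["study_time_high", "extra_tutoring"],
}


@dataclass
class RunConfig:
    seed: int = 0
    n_boot: int = 3000
    listwise_max_fraction: float = 0.05
    outlier_alpha: float = 0.001
    f_threshold: float = 10.0
    sargan_alpha: float = 0.05
    parcels: int = 3
    out_dir: str | Path | None = None
    skip_diagnostics: bool = False
    regressions: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in FULL_REGRESSIONS.items()})
    instruments: dict[str, list[str]] = field(default_factory=lambda: {
        k: list(v) for k, v in INSTRUMENTS.items()})


def composite_scores(data: pd.DataFrame) -> pd.DataFrame:
    """Scale-mean composites used as latent proxies for the IV diagnostics."""
    out = data.copy()
    for c, items in CONSTRUCT_ITEMS.items():
        out[c] = data[items].mean(axis=1)
    return out


def build_structural_system(regressions: dict[str, list[str]],
                            instruments: dict[str, list[str]]) -> StructuralSystem:
    endo = tuple(regressions)
    exo: list[str] = []
    for preds in regressions.values():
        for p in preds:
            if p not in regressions and p not in exo:
                exo.append(p)
    loop = tuple(v for v in endo if any(
        w in regressions[v] and v in regressions[w] for w in endo if w != v))
    return StructuralSystem(
        endogenous=endo, exogenous=tuple(exo),
        equations={k: tuple(v) for k, v in regressions.items()},
        loop=loop,
        instruments={k: tuple(instruments.get(k, ())) for k in loop},
    )


def prune_weak_paths(regressions: dict[str, list[str]],
                     reports: list[InstrumentReport]) -> tuple[dict[str, list[str]], list[str]]:
    """Delete non-recursive paths whose instruments are weak or invalid
    (the standard remediation for a weak and faulty instrument)."""
    pruned = {k: list(v) for k, v in regressions.items()}
    removed: list[str] = []
    for rep in reports:
        if not rep.strong or rep.valid is False:
            if rep.source in pruned.get(rep.outcome, []):
                pruned[rep.outcome].remove(rep.source)
                removed.append(f"{rep.outcome} ~ {rep.source}")
    return pruned, removed


def trim_insignificant(fit, z: float = 1.96) -> dict[str, list[str]]:
    """Drop exogenous predictors whose every path has |estimate/SE| < z.

    Loop (endogenous) paths are never trimmed here; the reciprocal structure
    is decided by the instrument screen, not by t ratios.
    """
    regs = {k: list(v) for k, v in fit.model.regressions.items()}
    endo = set(regs)
    for out in list(regs):
        for pred in list(regs[out]):
            if pred in endo:
                continue
            name = f"{out}~{pred}"
            est, se = fit.estimates.get(name), fit.se.get(name)
            if est is not None and se and np.isfinite(se) and abs(est / se) < z:
                regs[out].remove(pred)
    return regs


def run_pipeline(data: pd.DataFrame, config: RunConfig) -> dict:
    """Execute the full analysis; returns a JSON-ready report bundle."""
    bundle: dict = {"stages": []}

    def stage(name: str, payload) -> None:
        bundle["stages"].append(name)
        bundle[name] = payload
        log.info("stage %s complete", name)

    # 1. score
    scored = score_dataset(data, DEFAULT_SCALES)
    stage("prevalence", prevalence_report(scored, DEFAULT_SCALES))

    # 2. missing handling (predictor covariates only, listwise)
    covariates = sorted({p for preds in config.regressions.values() for p in preds
                         if p not in CONSTRUCT_ITEMS})
    item_cols = [it for items in CONSTRUCT_ITEMS.values() for it in items]
    analysis = apply_listwise(scored, config.listwise_max_fraction,
                              columns=covariates + item_cols)
    stage("missing", {"n_before": len(scored), "n_after": len(analysis),
                      "dropped": len(scored) - len(analysis)})

    # 3. screening diagnostics
    if not config.skip_diagnostics:
        items = analysis[item_cols]
        normality = diag.mardia_kurtosis(items)
        outliers = diag.mahalanobis_outliers(items, alpha=config.outlier_alpha)
        adequacy = diag.adequacy_report(analysis, CONSTRUCT_ITEMS)
        cmb = diag.harman_single_factor(items)
        cluster_vars = [c for c in ("school_private",) if c in analysis.columns]
        clustering = diag.clustering_report(
            composite_scores(analysis), ["depression", "anxiety", "somatic"],
            cluster_vars) if cluster_vars else None
        stage("diagnostics", {
            "mardia": vars(normality),
            "outliers": {"n_flagged": outliers.n_outliers, "alpha": outliers.alpha,
                         "df": outliers.df},
            "adequacy": adequacy,
            "harman": vars(cmb),
            "icc": None if clustering is None else
                   {"iccs": clustering.iccs, "independent": clustering.independent},
        })
    else:
        log.warning("diagnostics SKIPPED by configuration")
        stage("diagnostics", {"skipped": True})

    # 4. identification + instrument quality on composites
    system = build_structural_system(config.regressions, config.instruments)
    ident = identification_report(system)
    comp = composite_scores(analysis)
    iv_reports = instrument_diagnostics(comp, system, f_threshold=config.f_threshold,
                                        alpha=config.sargan_alpha)
    stage("identification", {"report": ident.to_dict(),
                             "instruments": [r.to_dict() for r in iv_reports]})
    if not ident.identified:
        raise RuntimeError("model not identified (rank condition failed); "
                           "revise the structural specification")

    # 5. remediation: delete weak/invalid non-recursive paths, re-check
    regressions, removed = prune_weak_paths(config.regressions, iv_reports)
    if removed:
        log.warning("pruned non-recursive paths: %s", removed)
        system2 = build_structural_system(regressions, config.instruments)
        ident2 = identification_report(system2)
        if not ident2.identified:
            raise RuntimeError("model unidentified after pruning weak paths")
        stage("remediation", {"removed_paths": removed,
                              "identification": ident2.to_dict()})
    else:
        stage("remediation", {"removed_paths": []})

    # 6. parceling
    plan, parcel_scores = make_parcels(analysis, CONSTRUCT_ITEMS, k=config.parcels)
    table = pd.concat([analysis, parcel_scores], axis=1)
    stage("parceling", plan.to_dict())

    # 7. latent fit of the repaired structure; then a trimmed model keeping
    #    only significant predictors, compared by AIC (and CFI/TLI/RMSEA)
    measurement = parcel_measurement(plan)
    fits = {}
    model_all = SemModel(measurement=measurement, regressions=regressions, psi="full")
    fits["all_predictors"] = fit_sem(model_all, table)
    trimmed_regs = trim_insignificant(fits["all_predictors"])
    if trimmed_regs != regressions:
        model_trim = SemModel(measurement=measurement, regressions=trimmed_regs, psi="full")
        fits["significant_only"] = fit_sem(model_trim, table)
        comparison = compare_models(fits)
        selected_name = comparison.loc[comparison["selected"], "model"].iloc[0]
        stage("comparison", comparison.to_dict(orient="records"))
    else:
        selected_name = "all_predictors"
    fit = fits[selected_name]
    boot = bootstrap_fit(fit.model, table, n_boot=config.n_boot,
                         seed=config.seed, fit=fit) if config.n_boot > 0 else None
    stage("fit", fit.to_dict())

    # 8. effects
    eff = effect_table(fit, boot)
    std = standardize_effects(eff, model_implied_latent_variances(fit))
    stage("effects", {"unstandardized": eff.table.to_dict(orient="records"),
                      "standardized": std.table.to_dict(orient="records")})

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json({k: bundle[k] for k in bundle["stages"]}, out / "report.json")
        eff.table.to_csv(out / "effects_unstandardized.csv", index=False)
        std.table.to_csv(out / "effects_standardized.csv", index=False)
    bundle["selected_model"] = selected_name
    return bundle
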