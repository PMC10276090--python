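"""End-to-end driver: simulate → write → read back → harmonize → score →
pTDT → association, from a single configuration mapping (or YAML file).

The round trip through the on-disk text formats is deliberate: it exercises
the same readers a user applies to real data.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc_mod
from . import ptdt as ptdt_mod
from . import scoring
from . import sumstats_io as sio
from . import synthetic_data as synth

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    study: synth.SimulatedStudy
    scores: dict[str, scoring.ScoreSet]
    ancestry: dict[str, scoring.AncestryPCs]
    ptdt_table: pd.DataFrame
    ptdt_results: dict[str, ptdt_mod.PTDTResult]
    association_results: list[assoc_mod.AssociationResult]
    association_table: pd.DataFrame
    paths: dict


def _build_sim_config(sim: dict, seed: int | None) -> synth.SimulationConfig:
    sim = dict(sim or {})
    if seed is not None:
        sim["seed"] = seed
    if "n_trios" in sim and isinstance(sim["n_trios"], list):
        sim["n_trios"] = tuple(sim["n_trios"])
        sim.setdefault("n_cohorts", len(sim["n_trios"]))
    if "maf_range" in sim:
        sim["maf_range"] = tuple(sim["maf_range"])
    if "outcome_models" in sim:
        models = []
        for m in sim["outcome_models"]:
            if "prevalence" in m:
                p = float(m["prevalence"])
                intercept = float(np.log(p / (1 - p)))
            else:
                intercept = float(m["intercept"])
            models.append(synth.OutcomeModel(m["name"], intercept, float(m.get("effect", 0.0))))
        sim["outcome_models"] = tuple(models)
    return synth.SimulationConfig(**sim)


def load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def score_cohort(
    cohort: synth.TrioCohort,
    sumstats: sio.SummaryStats,
    thresholds: tuple[float, ...] = scoring.DEFAULT_THRESHOLDS,
    maf_threshold: float = 0.05,
) -> scoring.ScoreSet:
    """Harmonize and score one cohort in memory (no file round trip)."""
    hw = sio.harmonize(sumstats, cohort.panel, maf_threshold=maf_threshold)
    return scoring.pgs_pca(scoring.compute_raw_scores(cohort.panel, hw, thresholds))


def ptdt_from_study(
    study: synth.SimulatedStudy,
    thresholds: tuple[float, ...] = scoring.DEFAULT_THRESHOLDS,
    maf_threshold: float = 0.05,
    tie_break_seed: int = 0,
) -> tuple[dict[str, ptdt_mod.TrioDeviationSet], dict[str, ptdt_mod.PTDTResult]]:
    """Score every cohort and run per-cohort (+combined) pTDT in memory."""
    devsets: dict[str, ptdt_mod.TrioDeviationSet] = {}
    for cohort in study.cohorts:
        ss = score_cohort(cohort, study.sumstats, thresholds, maf_threshold)
        devsets[cohort.label] = ptdt_mod.select_trios(
            cohort.panel, ss.composite_series(),
            cohort_label=cohort.label, tie_break_seed=tie_break_seed,
        )
    results = {lab: ptdt_mod.ptdt_test(ds) for lab, ds in devsets.items()}
    if len(devsets) >= 2:
        results["combined"] = ptdt_mod.combined_ptdt(list(devsets.values()))
    return devsets, results


def run_pipeline(
    config: dict | str | Path,
    outdir: str | Path,
    seed: int | None = None,
) -> PipelineResult:
    """Run the whole analysis from one config; writes all tables under outdir.

    Config keys (all optional): ``simulation`` (SimulationConfig fields;
    outcome_models entries may give a prevalence instead of an intercept),
    ``scoring`` (thresholds, maf_threshold, n_pcs), ``ptdt``
    (tie_break_seed), ``association`` (outcomes, sensitivity_mode),
    ``format`` (traw or vcf).
    """
    cfgd = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = _build_sim_config(cfgd.get("simulation", {}), seed)
    sc_cfg = cfgd.get("scoring", {}) or {}
    thresholds = tuple(sc_cfg.get("thresholds", scoring.DEFAULT_THRESHOLDS))
    maf_threshold = float(sc_cfg.get("maf_threshold", 0.05))
    n_pcs = int(sc_cfg.get("n_pcs", 5))
    fmt = cfgd.get("format", "traw")

    study = synth.simulate_study(sim_cfg)
    paths = synth.write_study(study, outdir / "data", fmt=fmt)
    sumstats = sio.read_sumstats(paths["sumstats"])

    scores: dict[str, scoring.ScoreSet] = {}
    ancestry: dict[str, scoring.AncestryPCs] = {}
    devsets: dict[str, ptdt_mod.TrioDeviationSet] = {}
    phenos: dict[str, pd.DataFrame] = {}
    tie_seed = int((cfgd.get("ptdt", {}) or {}).get("tie_break_seed", 0))

    for cohort in study.cohorts:
        cpaths = paths["cohorts"][cohort.label]
        panel, phen = sio.read_genotypes(
            cpaths["genotypes"], cpaths["pedigree"], cpaths["phenotypes"]
        )
        hw = sio.harmonize(sumstats, panel, maf_threshold=maf_threshold)
        sio.write_harmonization_report(hw, outdir / f"harmonization_{cohort.label}.tsv")
        ss = scoring.pgs_pca(scoring.compute_raw_scores(panel, hw, thresholds))
        pcs = scoring.compute_ancestry_pcs(panel, k=n_pcs)
        scores[cohort.label] = ss
        ancestry[cohort.label] = pcs
        phenos[cohort.label] = phen
        devsets[cohort.label] = ptdt_mod.select_trios(
            panel, ss.composite_series(), cohort_label=cohort.label, tie_break_seed=tie_seed
        )
        out = ss.to_frame()
        out.to_csv(outdir / f"scores_{cohort.label}.tsv", sep="\t")
        with open(outdir / f"scores_{cohort.label}.json", "w") as fh:
            json.dump(
                {
                    "thresholds": list(ss.thresholds),
                    "n_snps_used": ss.n_snps_used.tolist(),
                    "pc1_loadings": ss.pc1_loadings.tolist(),
                    "pc1_variance_fraction": ss.pc1_variance_fraction,
                    "harmonization_counts": hw.counts,
                },
                fh, indent=2,
            )

    ptdt_results = {lab: ptdt_mod.ptdt_test(ds) for lab, ds in devsets.items()}
    if len(devsets) >= 2:
        ptdt_results["combined"] = ptdt_mod.combined_ptdt(list(devsets.values()))
    ptdt_table = pd.DataFrame(
        [
            {
                "cohort": r.cohort_label, "n_trios": r.n_trios,
                "mean_deviation": r.mean_deviation, "se": r.se_deviation,
                "t": r.t_statistic, "p": r.pvalue,
            }
            for r in ptdt_results.values()
        ]
    )
    ptdt_table.to_csv(outdir / "ptdt.tsv", sep="\t", index=False)

    # case-only association in the first (primary) cohort
    primary = study.cohorts[0].label
    acfg = cfgd.get("association", {}) or {}
    outcomes = acfg.get("outcomes") or [m.name for m in sim_cfg.outcome_models]
    mode = acfg.get("sensitivity_mode", "none")
    covars = tuple(acfg.get("covariates", [f"pc{i+1}" for i in range(n_pcs)] + ["batch", "age"]))
    data = (
        phenos[primary]
        .merge(scores[primary].composite_series().rename("pgs_pca"),
               left_on="sample_id", right_index=True)
        .merge(ancestry[primary].to_frame(), left_on="sample_id", right_index=True)
    )
    specs = [
        assoc_mod.AssociationSpec(outcome=o, covariates=covars, sensitivity_mode=mode)
        for o in outcomes
    ]
    results = assoc_mod.run_association_battery(specs, data, on_error="skip")
    assoc_table = assoc_mod.battery_table(results)
    assoc_table.to_csv(outdir / "association.tsv", sep="\t", index=False)

    return PipelineResult(
        study=study, scores=scores, ancestry=ancestry,
        ptdt_table=ptdt_table, ptdt_results=ptdt_results,
        association_results=results, association_table=assoc_table,
        paths=paths,
    )
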