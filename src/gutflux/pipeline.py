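"""End-to-end study orchestration.

``run_study`` wires the stages together the way the full analysis runs on
real data: merge the per-segment differential-expression tables, integrate
them into condition-specific flux bounds (RMetD) with a sensitivity scan
over the push factor, sample both constrained flux spaces and call
transcriptionally regulated reactions, score reporter metabolites, test
the two-group metabolomics panel, simulate the bacterial community on the
diet's bacterial share, and (given >= 2 models) compare the ensemble.

Every stochastic stage receives its own seed derived from the single
global seed by hashing the stage name, so stages stay independently
reproducible. With a fixed config + seed the TSV outputs are
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, community_sim, ensemble_compare, expression_stats, \
    flux_sampling, rmetd, synthetic_data
from .model_core import MetabolicModel, element_sets

__all__ = ["StudyConfig", "StudyResult", "run_study", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31)


@dataclass
class StudyConfig:
    seed: int = 0
    out_dir: str | None = None
    # expression integration
    rmetd_config: rmetd.RMetDConfig | None = None
    scan_alphas: tuple[float, ...] = (0.1, 0.2, 0.3)
    # sampling; separation 0.5 marks non-overlap at half the summed spreads,
    # matched to the ~20% range pushes the integration step produces
    n_samples: int = 2000
    thinning: int = 5
    warmup: int = 100
    separation: float = 0.5
    # synthetic study conditions (used when no external inputs are given)
    de_down_genes: tuple[str, ...] = ("g_dgat",)
    de_up_genes: tuple[str, ...] = ()
    n_segments: int = 3
    metabolomics: synthetic_data.SyntheticMetabolomicsSpec | None = None


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class StudyResult:
    rmetd_result: rmetd.RMetDResult
    scan: pd.DataFrame
    regulated_calls: list[flux_sampling.FluxChangeCall]
    regulated_ids: list[str]
    truth_ids: list[str]
    jaccard: float
    reporter: list[expression_stats.ReporterScore]
    metabolomics: pd.DataFrame
    community: community_sim.CommunityResult
    ensemble: dict
    log: dict = field(default_factory=dict)


def _segment_tables(config: StudyConfig, seed: int) -> list[rmetd.DETable]:
    """Per-segment DE tables planting the configured up/down genes.

    Each segment repeats the same calls with slightly different q-values
    (lowest-Q merging is what the pipeline is exercising), all significant.
    """
    tables = []
    for s in range(config.n_segments):
        entries = []
        for g in config.de_down_genes:
            entries.append(rmetd.DEGene(g, "down", 0.01 + 0.005 * s, log2fc=-1.0))
        for g in config.de_up_genes:
            entries.append(rmetd.DEGene(g, "up", 0.01 + 0.005 * s, log2fc=1.0))
        tables.append(rmetd.DETable(entries=entries))
    return tables


def run_study(config: StudyConfig,
              model: MetabolicModel | None = None,
              segment_tables: list[rmetd.DETable] | None = None,
              ) -> StudyResult:
    """Run the full synthetic study; see the module docstring for stages."""
    log: dict = {"version": __version__, "seed": config.seed,
                 "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def _stage(name):
        log.setdefault("stages", []).append(name)
        return name

    try:
        _stage("model")
        if model is None:
            model = synthetic_data.make_toy_gem(
                synthetic_data.ToyNetworkSpec(template="epithelium"))
        diet_bounds = model.metadata.get("diet_bounds", {})
        products = model.metadata.get("objective_products",
                                      [model.objective[0]])

        _stage("merge_de")
        if segment_tables is None:
            segment_tables = _segment_tables(config, stage_seed(config.seed, "de"))
        de = expression_stats.merge_segment_de(segment_tables)

        _stage("rmetd")
        cfg = config.rmetd_config or rmetd.RMetDConfig(
            objective_products=list(products))
        result = rmetd.run_rmetd(model, de, diet_bounds, cfg)
        scan = rmetd.sensitivity_scan(model, de, diet_bounds, cfg,
                                      list(config.scan_alphas))

        _stage("sampling")
        seed = stage_seed(config.seed, "sampling")
        ref_samples = flux_sampling.sample_fluxes(
            result.reference_model, config.n_samples, seed,
            warmup=config.warmup, thinning=config.thinning)
        cond_samples = flux_sampling.sample_fluxes(
            result.condition_model, config.n_samples, seed,
            warmup=config.warmup, thinning=config.thinning)

        _stage("regulated")
        calls = flux_sampling.call_regulated(
            ref_samples, cond_samples, result.direction_map,
            separation=config.separation)
        regulated = sorted(c.reaction_id for c in calls if c.regulated)
        truth = sorted(rid for rid, call in result.direction_map.calls.items()
                       if call.direction in ("up", "down"))
        union = set(regulated) | set(truth)
        jaccard = (len(set(regulated) & set(truth)) / len(union)) if union else 1.0

        _stage("reporter")
        gene_p = {e.gene_id: max(e.q_value, 1e-15) for e in de}
        # pad with null scores so the background pool covers the model
        for g in model.genes:
            gene_p.setdefault(g, 0.5)
        reporter = expression_stats.reporter_metabolites(
            model, gene_p, n_background=2000,
            seed=stage_seed(config.seed, "reporter"))

        _stage("metabolomics")
        mspec = config.metabolomics or synthetic_data.SyntheticMetabolomicsSpec(
            n_analytes=20, effects={0: -1.0, 1: -1.0, 2: 1.0},
            seed=stage_seed(config.seed, "metabolomics"))
        table, _ = synthetic_data.make_metabolomics(mspec)
        met_stats = expression_stats.compare_groups(table)

        _stage("community")
        members, diet = synthetic_data.make_crossfeed_pair(
            seed=stage_seed(config.seed, "community"))
        pools = community_sim.partition_diet(diet)
        community = community_sim.simulate_community(members, pools["bacteria"])

        _stage("ensemble")
        sets = [element_sets(synthetic_data.make_toy_gem(
            synthetic_data.ToyNetworkSpec(template=t)))
            for t in ("chain", "diamond", "futile_cycle")]
        ens: dict = {}
        for cls_ in ensemble_compare.ELEMENT_CLASSES:
            matrix = ensemble_compare.presence_matrix(sets, cls_)
            het = ensemble_compare.heterogeneity(matrix)
            core = ensemble_compare.core_statistics(matrix)
            ens[cls_] = {"heterogeneity_degree": het.heterogeneity_degree,
                         "mean_distance": het.mean_distance,
                         "max_distance": het.max_distance,
                         "core_percentage": core.core_percentage,
                         "union": core.union_count, "core": core.core_count,
                         "unique": core.unique_count}
    except StageError:
        raise
    except Exception as exc:
        stage = log.get("stages", ["?"])[-1]
        if config.out_dir:
            Path(config.out_dir).mkdir(parents=True, exist_ok=True)
            log["failed_stage"] = stage
            (Path(config.out_dir) / "run_log.json").write_text(
                json.dumps(log, indent=2, default=str))
        raise StageError(stage, exc) from exc

    log["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = StudyResult(rmetd_result=result, scan=scan, regulated_calls=calls,
                      regulated_ids=regulated, truth_ids=truth,
                      jaccard=jaccard, reporter=reporter,
                      metabolomics=met_stats, community=community,
                      ensemble=ens, log=log)
    if config.out_dir:
        _write_bundle(out, config)
    return out


def _write_bundle(result: StudyResult, config: StudyConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.rmetd_result.comparison_frame().to_csv(
        out / "product_comparison.tsv", sep="\t", index=False)
    result.scan.to_csv(out / "sensitivity_scan.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in result.regulated_calls]) \
        .to_csv(out / "regulated_calls.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "metabolite_id": r.metabolite_id, "k": r.k, "z_raw": r.z_raw,
        "z_corrected": r.z_corrected, "p_reporter": r.p_reporter}
        for r in result.reporter]).to_csv(
        out / "reporter_metabolites.tsv", sep="\t", index=False)
    result.metabolomics.to_csv(out / "metabolomics_stats.tsv", sep="\t",
                               index=False)
    summary = {
        "product_comparison": [
            {"product": c.product, "reference_flux": c.reference_flux,
             "condition_flux": c.condition_flux, "ratio": c.ratio}
            for c in result.rmetd_result.product_comparison],
        "scan_stable": bool(result.scan.attrs.get("stable", False)),
        "regulated_reactions": result.regulated_ids,
        "truth_reactions": result.truth_ids,
        "jaccard": result.jaccard,
        "community_growth": result.community.growth,
        "community_converged": result.community.converged,
        "ensemble": result.ensemble,
        "log": result.log,
    }
    (out / "study_summary.json").write_text(
        json.dumps(summary, indent=2, default=str))
    (out / "run_log.json").write_text(
        json.dumps(result.log, indent=2, default=str))
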