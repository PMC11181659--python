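"""End-to-end orchestration: classify -> differential dependency -> BaCoN ranking.

Stages run in a fixed order and every output directory gets a verbatim
config snapshot plus a run manifest (versions, seed, config hash, and row
counts at every stage) so any run can be audited and reproduced.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arm import ArmCallTable, arm_deletion_score, classify_lines, scna_frequency
from .bacon import bacon_scores, filter_candidates, pcc_matrix, rank_pairs
from .config import PipelineConfig
from .dependency import arm_enrichment, build_dependency_table
from .io import AlignedCohort, ExpressionMatrix, FitnessMatrix

__all__ = ["PipelineResult", "run_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.__cause__ = cause


@dataclass
class PipelineResult:
    calls: ArmCallTable
    scna: pd.DataFrame
    dependency: pd.DataFrame
    enrichment: object
    candidates: object
    pairs: pd.DataFrame  # ranked pair table
    pairs_unrestricted: pd.DataFrame  # scored, before hit restriction/ranking
    ihw: object
    manifest: dict = field(default_factory=dict)

    @property
    def hits(self) -> pd.Index:
        return self.dependency.index[self.dependency["is_hit"]]


def run_pipeline(
    config: PipelineConfig, cohort: AlignedCohort, outdir=None
) -> PipelineResult:
    """Run every stage on an aligned cohort; optionally write tables + manifest.

    Stage order: classify -> SCNA frequencies -> prefilter/dCERES/Wilcoxon/
    weighted FDR/hits -> arm enrichment -> BaCoN candidate filters -> PCC ->
    balanced scores -> ranking (pan-essential removal, hit restriction).
    """
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                    if outdir is not None:
                        _write_manifest(manifest, outdir)
                    raise StageError(name, manifest, exc)
                info = manifest["stages"].setdefault(name, {})
                info["status"] = "ok"
                info["wall_s"] = round(time.perf_counter() - self_inner.t0, 3)
                return False

            def log(self_inner, **counts):
                manifest["stages"].setdefault(name, {}).update(counts)

        return _Ctx()

    with stage("classify") as s:
        scores = arm_deletion_score(
            cohort.copy_number, cohort.annotation, config.chromosome, config.arm
        )
        calls = classify_lines(scores, threshold=config.cn_threshold)
        calls.chromosome, calls.arm = config.chromosome, config.arm
        s.log(lines_classified=int(calls.table["call"].notna().sum()), **calls.counts)

    with stage("scna_frequency") as s:
        scna = scna_frequency(cohort.copy_number, gain_cut=config.gain_cut, loss_cut=config.loss_cut)
        s.log(genes=int(len(scna)))

    with stage("differential_dependency") as s:
        dep_table, ihw = build_dependency_table(
            cohort.fitness,
            cohort.expression,
            calls,
            min_mean=config.prefilter_min_mean,
            alpha=config.ihw_alpha,
            n_bins=config.ihw_bins,
            n_folds=config.ihw_folds,
            p_cut=config.hit_p_cut,
            strict_p_cut=config.strict_p_cut,
            d_cut=config.dceres_cut,
            seed=config.seed,
            ihw_rerun_at_hit_level=config.ihw_rerun_at_hit_level,
        )
        hits = dep_table.index[dep_table["is_hit"]]
        s.log(
            genes_prefiltered=int(dep_table["passed_prefilter"].sum()),
            genes_tested=int(dep_table["p_value"].notna().sum()),
            hits=int(len(hits)),
            strict_hits=int(dep_table["is_strict_hit"].sum()),
        )

    with stage("arm_enrichment") as s:
        universe = dep_table.index[dep_table["passed_prefilter"]]
        universe = universe.intersection(cohort.annotation.index)
        enr = arm_enrichment(
            hits.intersection(universe), cohort.annotation, universe,
            config.chromosome, config.arm,
        )
        s.log(**enr.to_dict())

    with stage("bacon_candidates") as s:
        cand = filter_candidates(
            cohort.expression,
            cohort.fitness,
            sd_min=config.buffering_sd_min,
            level=config.buffering_level,
            min_lines=config.buffering_min_lines,
            mean_expr_min=config.buffered_mean_expr_min,
            abs_mean_ceres_min=config.buffered_abs_mean_ceres_min,
            ceres_sd_min=config.buffered_ceres_sd_min,
            desk_scale=config.desk_scale,
        )
        s.log(buffering=int(len(cand.buffering)), buffered=int(len(cand.buffered)),
              all_by_all_pairs=int(len(cand.buffering) * len(cand.buffered)))

    with stage("pcc") as s:
        expr_sub = ExpressionMatrix(cohort.expression.df.loc[cand.buffering])
        fit_sub = FitnessMatrix(cohort.fitness.df.loc[cand.buffered])
        pcc = pcc_matrix(expr_sub, fit_sub)
        s.log(n_missing=int(pcc.isna().sum().sum()))

    with stage("bacon_scores") as s:
        pairs_all = bacon_scores(pcc, variant=config.bacon_variant)
        s.log(pair_count=int(len(pairs_all)), variant=config.bacon_variant)

    with stage("rank_pairs") as s:
        ranked = rank_pairs(
            pairs_all,
            cohort.fitness,
            restrict_to_hits=hits,
            pan_essential_cut=config.pan_essential_cut,
        )
        s.log(ranked_pairs=int(len(ranked)))

    result = PipelineResult(
        calls=calls,
        scna=scna,
        dependency=dep_table,
        enrichment=enr,
        candidates=cand,
        pairs=ranked,
        pairs_unrestricted=pairs_all,
        ihw=ihw,
        manifest=manifest,
    )
    if outdir is not None:
        _write_outputs(result, config, outdir)
    return result


def _write_manifest(manifest: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def _stamp(df: pd.DataFrame, config: PipelineConfig, path: Path, index_label: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    result.calls.to_tsv(outdir / "arm_calls.tsv")
    _stamp(result.scna, config, outdir / "scna_frequency.tsv", "gene")
    _stamp(result.dependency, config, outdir / "dependency_table.tsv", "gene")
    with open(outdir / "enrichment.json", "w") as fh:
        payload = result.enrichment.to_dict()
        payload["config_hash"] = config.config_hash()
        json.dump(payload, fh, indent=1)
    top = result.pairs.head(config.top_k)
    _stamp(result.pairs, config, outdir / "pair_table.tsv", "pair")
    _stamp(top, config, outdir / "pair_table_top.tsv", "pair")
    _write_manifest(result.manifest, outdir)
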