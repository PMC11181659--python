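"""Synthetic DepMap-like cohorts with planted, serialisable ground truth.

The generator emulates the statistical structure the pipeline is built for:

* lineage-structured cell lines (uniform lineage assignment, per-gene
  lineage expression offsets);
* an arm-level deletion carried by a fraction of lines that lowers the
  log2 copy-number ratio of every arm gene (depth ~ -0.7, one-copy loss)
  and shifts arm-gene expression down;
* a CERES-scale fitness matrix with an essentiality spectrum (background,
  moderately essential, pan-essential genes);
* planted deletion-specific dependencies: genes whose fitness score drops by
  a stated Delta in arm-deleted lines (the dCERES signal);
* planted buffering pairs: the buffered gene's fitness drops by gamma in
  lines where the partner's expression is below its cohort median (threshold
  form; a linear coupling is available via ``linear_buffering``);
* lineage-confounded decoy pairs: an expression gene and a fitness gene that
  share a lineage-indexed factor with a whole program of other genes,
  creating strong correlation with no causal buffering — the failure mode
  the balanced-correlation weighting is designed to suppress.

Everything is driven by one integer seed; per-component substreams are
derived deterministically so adding genes never perturbs line assignments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AlignedCohort,
    CopyNumberMatrix,
    ExpressionMatrix,
    FitnessMatrix,
    read_annotation,
    read_lineage,
    read_matrix,
    write_annotation,
    write_lineage,
    write_matrix,
)
from .proteome import ProteomeTable

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "simulate_proteome",
]


@dataclass
class CohortSpec:
    """Generator parameters; defaults are the package's standard study conditions."""

    n_lines: int = 600
    n_genes: int = 2000
    n_arm_genes: int = 100
    n_lineages: int = 10
    p_del: float = 0.2
    del_depth: float = -0.7  # log2 ratio of a one-copy loss at ~2n ploidy
    cn_noise_sd: float = 0.1
    expr_noise_sd: float = 0.5
    variable_expr_sd: float = 1.1  # per-line SD of high-variance expression genes
    lineage_expr_sd: float = 0.4
    ceres_noise_sd: float = 0.15
    expr_del_shift: float = 0.7  # expression drop of arm genes in deleted lines
    gamma: float = 0.5  # buffering effect (CERES shift below partner median)
    delta_dep: float = 0.4  # deletion-specific CERES shift of planted dependencies
    kappa: float = 1.0  # lineage confounding strength, expression side
    kappa_fitness_ratio: float = 0.4  # fitness-side confounding = kappa * ratio
    n_buffering_pairs: int = 1
    n_decoy_pairs: int = 5
    n_dep_arm_genes: int = 4
    n_dep_offarm_genes: int = 2
    program_expr_size: int = 200  # lineage-program (co-confounded) expression genes
    program_fit_size: int = 450  # lineage-program (co-confounded) fitness genes
    n_variable_background: int = 50
    n_moderate_essential: int = 200
    n_pan_essential: int = 100
    linear_buffering: bool = False
    chromosome: str = "8"
    arm: str = "p"

    def __post_init__(self) -> None:
        if not 0 <= self.p_del <= 1:
            raise ValueError("p_del must be in [0, 1]")
        for name in ("n_lines", "n_genes", "n_lineages"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_arm_genes > self.n_genes:
            raise ValueError("n_arm_genes cannot exceed n_genes")
        if self.n_dep_arm_genes > self.n_arm_genes:
            raise ValueError("n_dep_arm_genes cannot exceed n_arm_genes")
        if self._n_special() > self.n_genes:
            raise ValueError(
                f"gene layout needs {self._n_special()} genes but n_genes={self.n_genes}"
            )

    def _n_special(self) -> int:
        return (
            self.n_arm_genes
            + self.n_dep_offarm_genes
            + 2 * self.n_buffering_pairs
            + 2 * self.n_decoy_pairs
            + self.program_expr_size
            + self.program_fit_size
            + self.n_variable_background
            + self.n_moderate_essential
            + self.n_pan_essential
        )


@dataclass
class SyntheticTruth:
    """Planted ground truth, serialised alongside the generated cohort."""

    deleted_lines: list
    buffering_pairs: list  # [(expr_gene, fit_gene, gamma), ...]
    decoy_pairs: list  # [(expr_gene, fit_gene), ...]
    dceres_positive_genes: list  # [(gene, delta), ...]
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["buffering_pairs"] = [tuple(t) for t in d["buffering_pairs"]]
        d["decoy_pairs"] = [tuple(t) for t in d["decoy_pairs"]]
        d["dceres_positive_genes"] = [tuple(t) for t in d["dceres_positive_genes"]]
        return cls(**d)

    @property
    def dep_gene_names(self) -> list:
        return [g for g, _ in self.dceres_positive_genes]


# ---------------------------------------------------------------------------
# gene layout


@dataclass
class _Layout:
    arm: np.ndarray
    dep_arm: np.ndarray
    dep_offarm: np.ndarray
    buf_expr: np.ndarray
    buf_fit: np.ndarray
    decoy_expr: np.ndarray
    decoy_fit: np.ndarray
    prog_expr: np.ndarray  # lineage-program expression genes (shared factor)
    prog_fit: np.ndarray  # lineage-program fitness genes (shared factor)
    var_bg: np.ndarray
    mod_fit: np.ndarray
    pan_ess: np.ndarray
    field_order: list = field(default_factory=list)


def _layout(spec: CohortSpec) -> _Layout:
    cursor = spec.n_arm_genes

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        out = np.arange(cursor, cursor + n)
        cursor += n
        return out

    arm = np.arange(spec.n_arm_genes)
    lay = _Layout(
        arm=arm,
        dep_arm=arm[: spec.n_dep_arm_genes],
        dep_offarm=take(spec.n_dep_offarm_genes),
        buf_expr=take(spec.n_buffering_pairs),
        buf_fit=take(spec.n_buffering_pairs),
        decoy_expr=take(spec.n_decoy_pairs),
        decoy_fit=take(spec.n_decoy_pairs),
        prog_expr=take(spec.program_expr_size),
        prog_fit=take(spec.program_fit_size),
        var_bg=take(spec.n_variable_background),
        mod_fit=take(spec.n_moderate_essential),
        pan_ess=take(spec.n_pan_essential),
    )
    return lay


def _annotation_table(spec: CohortSpec, gene_names: list, entrez: np.ndarray) -> pd.DataFrame:
    n = len(gene_names)
    chrom = np.empty(n, dtype=object)
    arm = np.empty(n, dtype=object)
    for i in range(n):
        if i < spec.n_arm_genes:
            chrom[i], arm[i] = spec.chromosome, spec.arm
        else:
            c = str((i % 22) + 1)
            chrom[i] = c
            if c == spec.chromosome:
                arm[i] = "q" if spec.arm == "p" else "p"
            else:
                arm[i] = "p" if i % 2 else "q"
    start = (np.arange(n, dtype=np.int64) + 1) * 1_000_000
    ann = pd.DataFrame(
        {
            "gene_symbol": gene_names,
            "entrez_id": entrez,
            "chromosome": chrom,
            "arm": arm,
            "start_bp": start,
            "end_bp": start + 50_000,
        }
    )
    return ann.set_index("gene_symbol", drop=False)


# ---------------------------------------------------------------------------
# generation


def generate_cohort(spec: CohortSpec, seed: int = 0) -> tuple[AlignedCohort, SyntheticTruth]:
    """Generate one cohort plus its planted truth, deterministically from ``seed``."""
    lay = _layout(spec)
    n_g, n_l = spec.n_genes, spec.n_lines
    gene_names = [f"G{i:04d}" for i in range(n_g)]
    entrez = np.arange(n_g) + 1000
    line_ids = [f"ACH-9{i:05d}" for i in range(n_l)]
    lineage_names = [f"lineage_{k:02d}" for k in range(spec.n_lineages)]

    # substreams: 0 lines/deletion, 1 gene params, 2 CN, 3 expression, 4 fitness, 5 programs
    rng_lines = np.random.default_rng([seed, 0])
    rng_genes = np.random.default_rng([seed, 1])
    rng_cn = np.random.default_rng([seed, 2])
    rng_expr = np.random.default_rng([seed, 3])
    rng_fit = np.random.default_rng([seed, 4])
    rng_prog = np.random.default_rng([seed, 5])

    lineage_idx = rng_lines.integers(0, spec.n_lineages, size=n_l)
    deleted = rng_lines.random(n_l) < spec.p_del

    # --- per-gene parameters ------------------------------------------------
    expr_base = rng_genes.uniform(0.0, 6.0, size=n_g)
    expr_base[lay.arm] = rng_genes.uniform(2.0, 6.0, size=len(lay.arm))
    expr_side = np.concatenate([lay.buf_expr, lay.decoy_expr, lay.prog_expr, lay.var_bg])
    expr_base[expr_side] = rng_genes.uniform(4.0, 7.0, size=len(expr_side))
    fit_side = np.concatenate(
        [lay.dep_offarm, lay.buf_fit, lay.decoy_fit, lay.prog_fit, lay.mod_fit, lay.pan_ess]
    )
    expr_base[fit_side] = rng_genes.uniform(3.0, 7.0, size=len(fit_side))

    expr_sd = np.full(n_g, spec.expr_noise_sd)
    expr_sd[expr_side] = spec.variable_expr_sd

    ess_base = rng_genes.normal(0.0, 0.10, size=n_g)
    ess_base[lay.mod_fit] = rng_genes.normal(-0.45, 0.08, size=len(lay.mod_fit))
    ess_base[lay.pan_ess] = rng_genes.normal(-1.0, 0.12, size=len(lay.pan_ess))
    ess_base[lay.prog_fit] = rng_genes.normal(-0.35, 0.08, size=len(lay.prog_fit))
    ess_base[lay.dep_arm] = rng_genes.normal(-0.30, 0.05, size=len(lay.dep_arm))
    ess_base[lay.dep_offarm] = rng_genes.normal(-0.30, 0.05, size=len(lay.dep_offarm))
    ess_base[lay.buf_fit] = rng_genes.normal(-0.20, 0.05, size=len(lay.buf_fit))
    ess_base[lay.decoy_fit] = rng_genes.normal(-0.35, 0.05, size=len(lay.decoy_fit))

    # --- copy number --------------------------------------------------------
    cn = rng_cn.normal(0.0, spec.cn_noise_sd, size=(n_g, n_l))
    cn[np.ix_(lay.arm, np.flatnonzero(deleted))] += spec.del_depth

    # --- expression ---------------------------------------------------------
    lineage_offsets = rng_expr.normal(0.0, spec.lineage_expr_sd, size=(n_g, spec.n_lineages))
    expr = (
        expr_base[:, None]
        + lineage_offsets[:, lineage_idx]
        + rng_expr.normal(0.0, 1.0, size=(n_g, n_l)) * expr_sd[:, None]
    )
    expr[np.ix_(lay.arm, np.flatnonzero(deleted))] -= spec.expr_del_shift

    # --- fitness ------------------------------------------------------------
    fit = ess_base[:, None] + rng_fit.normal(0.0, spec.ceres_noise_sd, size=(n_g, n_l))

    # lineage confounding: one shared lineage-indexed factor t carried, with
    # gene-specific positive loadings, by a large expression program and a
    # large fitness program — emulating tissue-of-origin co-variation that
    # couples many expressed genes to many dependencies at once.  Decoy
    # expression genes load high (strong spurious correlation); decoy fitness
    # genes load at the lower-middle of the fitness-program loading range, so
    # most program pairs out-correlate them (the competition the balanced
    # weighting exploits).
    kappa_f = spec.kappa * spec.kappa_fitness_ratio
    if spec.kappa > 0 and spec.n_decoy_pairs > 0:
        t = rng_prog.normal(0.0, 1.0, size=spec.n_lineages)
        t_line = t[lineage_idx]
        a_prog = rng_prog.uniform(0.7, 1.5, size=len(lay.prog_expr))
        c_prog = rng_prog.uniform(0.5, 2.0, size=len(lay.prog_fit))
        expr[lay.prog_expr] += spec.kappa * a_prog[:, None] * t_line[None, :]
        fit[lay.prog_fit] += kappa_f * c_prog[:, None] * t_line[None, :]
        a_decoy = np.full(spec.n_decoy_pairs, 1.4)
        c_decoy = np.linspace(0.7, 0.85, spec.n_decoy_pairs)
        expr[lay.decoy_expr] += spec.kappa * a_decoy[:, None] * t_line[None, :]
        fit[lay.decoy_fit] += kappa_f * c_decoy[:, None] * t_line[None, :]

    # planted deletion-specific dependencies (dCERES signal)
    dep_idx = np.concatenate([lay.dep_arm, lay.dep_offarm, lay.buf_fit, lay.decoy_fit])
    fit[np.ix_(dep_idx, np.flatnonzero(deleted))] -= spec.delta_dep

    # planted buffering: low partner expression makes the buffered gene more essential
    for e_i, f_i in zip(lay.buf_expr, lay.buf_fit):
        x = expr[e_i]
        med = np.median(x)
        if spec.linear_buffering:
            sd = np.std(x, ddof=1)
            fit[f_i] += spec.gamma * (x - med) / (2.0 * sd if sd > 0 else 1.0)
        else:
            fit[f_i] -= spec.gamma * (x < med)

    expr = np.maximum(expr, 0.0)  # truncate into the log2(TPM+1) domain

    # --- assemble containers ------------------------------------------------
    gene_index = pd.Index(gene_names, name="gene_symbol")
    line_index = pd.Index(line_ids, name="cell_line")
    ent = pd.Series(entrez, index=gene_index, dtype=int)
    cohort = AlignedCohort(
        fitness=FitnessMatrix(pd.DataFrame(fit, index=gene_index, columns=line_index), ent),
        expression=ExpressionMatrix(pd.DataFrame(expr, index=gene_index, columns=line_index), ent),
        copy_number=CopyNumberMatrix(pd.DataFrame(cn, index=gene_index, columns=line_index), ent),
        lineage=pd.Series(
            [lineage_names[k] for k in lineage_idx], index=line_index, name="lineage"
        ),
        annotation=_annotation_table(spec, gene_names, entrez),
    )
    truth = SyntheticTruth(
        deleted_lines=[line_ids[i] for i in np.flatnonzero(deleted)],
        buffering_pairs=[
            (gene_names[e], gene_names[f], spec.gamma)
            for e, f in zip(lay.buf_expr, lay.buf_fit)
        ],
        decoy_pairs=[
            (gene_names[e], gene_names[f]) for e, f in zip(lay.decoy_expr, lay.decoy_fit)
        ],
        dceres_positive_genes=[(gene_names[i], spec.delta_dep) for i in dep_idx],
        seed=seed,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# disk round-trip (DepMap CSV dialect + TSV annotation/lineage + JSON truth)


def write_cohort(cohort: AlignedCohort, truth: SyntheticTruth | None, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.fitness, outdir / "gene_effect.csv")
    write_matrix(cohort.expression, outdir / "expression.csv")
    write_matrix(cohort.copy_number, outdir / "copy_number.csv")
    write_annotation(cohort.annotation, outdir / "annotation.tsv")
    write_lineage(cohort.lineage, outdir / "lineage.tsv")
    if truth is not None:
        truth.to_json(outdir / "truth.json")


def read_cohort(indir) -> tuple[AlignedCohort, SyntheticTruth | None]:
    from pathlib import Path

    from .io import align_cohort

    indir = Path(indir)
    fitness = read_matrix(indir / "gene_effect.csv", kind=FitnessMatrix)
    expression = read_matrix(indir / "expression.csv", kind=ExpressionMatrix)
    cn = read_matrix(indir / "copy_number.csv", kind=CopyNumberMatrix)
    annotation = read_annotation(indir / "annotation.tsv")
    lineage = read_lineage(indir / "lineage.tsv")
    truth = None
    if (indir / "truth.json").exists():
        truth = SyntheticTruth.from_json(indir / "truth.json")
    return align_cohort(fitness, expression, cn, annotation, lineage), truth


# ---------------------------------------------------------------------------
# synthetic proteome


def simulate_proteome(
    n_proteins: int = 200,
    n_per_group: int = 3,
    n_changed: int = 20,
    log2fc: float = 1.0,
    sigma: float = 0.3,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[ProteomeTable, dict]:
    """Log2-scale LFQ-like table with planted abundance changes.

    Half of the ``n_changed`` proteins go up by ``log2fc`` in the second
    condition, half go down.  Optional missingness is intensity-dependent
    (left-censored): low-intensity entries are far more likely to drop out,
    matching the detection-limit mechanism the downshifted imputation models.
    """
    rng = np.random.default_rng([seed, 7])
    base = rng.normal(25.0, 2.0, size=n_proteins)
    n_samples = 2 * n_per_group
    vals = base[:, None] + rng.normal(0.0, sigma, size=(n_proteins, n_samples))
    changed = np.arange(n_changed)
    direction = np.where(changed % 2 == 0, 1.0, -1.0)
    # shift the knockout group (listed first, so log2fc = ko - ctrl)
    vals[changed, :n_per_group] += (direction * log2fc)[:, None]
    if missing_rate > 0:
        z = (vals - vals.mean(axis=0, keepdims=True)) / vals.std(axis=0, keepdims=True)
        p_miss = missing_rate * 4.0 / (1.0 + np.exp(2.0 * z))  # censored at the low end
        vals[rng.random(vals.shape) < p_miss] = np.nan
    proteins = pd.Index([f"P{i:04d}" for i in range(n_proteins)], name="protein")
    samples = [f"ko_{j}" for j in range(n_per_group)] + [f"ctrl_{j}" for j in range(n_per_group)]
    condition = pd.Series(
        ["ko"] * n_per_group + ["ctrl"] * n_per_group, index=pd.Index(samples, name="sample")
    )
    table = ProteomeTable(
        pd.DataFrame(vals, index=proteins, columns=samples), condition, log2_scale=True
    )
    truth = {
        "up": [f"P{i:04d}" for i in changed[direction > 0]],
        "down": [f"P{i:04d}" for i in changed[direction < 0]],
        "log2fc": log2fc,
        "seed": seed,
    }
    return table, truth
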