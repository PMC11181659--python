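"""Chromosome-arm deletion scoring, DEL/nonDEL classification, SCNA frequencies.

The arm burden score combines deletion depth and breadth in one number: with
x_g the line's log2 relative copy number for arm gene g and N the number of
arm genes observed in that line,

    S = 10 * (1/N) * sum_g min(x_g, 0)

so a full-arm one-copy loss (all x_g ~ -1) scores -10 and a half-arm loss at
the same depth scores -5.  A line is called DEL when S falls strictly below
the threshold (default -2.5).  The scoring function is pluggable because the
exact functional form behind published arm calls varies between studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CopyNumberMatrix

__all__ = [
    "ArmCallTable",
    "arm_genes",
    "arm_deletion_score",
    "classify_lines",
    "scna_frequency",
    "burden_score",
]

DEL, NONDEL = "DEL", "nonDEL"


@dataclass
class ArmCallTable:
    """Per-line arm score and DEL/nonDEL call.

    ``table`` columns: arm_score (NaN when no arm gene was observed), call
    (DEL/nonDEL; missing-score lines carry NA), n_arm_genes_used.
    """

    table: pd.DataFrame
    threshold: float
    chromosome: str = ""
    arm: str = ""
    score_fn_name: str = "burden_score"

    @property
    def del_lines(self) -> pd.Index:
        return self.table.index[self.table["call"] == DEL]

    @property
    def nondel_lines(self) -> pd.Index:
        return self.table.index[self.table["call"] == NONDEL]

    @property
    def counts(self) -> dict:
        return {DEL: int(len(self.del_lines)), NONDEL: int(len(self.nondel_lines))}

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.attrs = {}
        with open(path, "w") as fh:
            fh.write(
                f"# chromosome={self.chromosome}{self.arm} threshold={self.threshold} "
                f"score_fn={self.score_fn_name}\n"
            )
            out.rename_axis("line_id").to_csv(fh, sep="\t")


def arm_genes(annotation: pd.DataFrame, chromosome: str, arm: str) -> pd.Index:
    """Genes annotated on (chromosome, arm); membership is purely label-based."""
    sel = (annotation["chromosome"].astype(str) == str(chromosome)) & (annotation["arm"] == arm)
    return pd.Index(annotation.loc[sel, "gene_symbol"])


def burden_score(arm_cn: np.ndarray) -> np.ndarray:
    """Default per-line score: 10 x mean over observed arm genes of min(x, 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return 10.0 * np.nanmean(np.minimum(arm_cn, 0.0), axis=0)


def arm_deletion_score(
    cn: CopyNumberMatrix,
    annotation: pd.DataFrame,
    chromosome: str,
    arm: str,
    score_fn=burden_score,
) -> pd.Series:
    """Per-line deletion-burden score over the requested arm's genes.

    Lines with no observed arm gene get a NaN score (excluded from
    classification with a warning downstream).
    """
    genes = arm_genes(annotation, chromosome, arm)
    present = cn.genes.intersection(genes)
    if len(present) == 0:
        raise ValueError(f"no annotated chr{chromosome}{arm} gene present in the copy-number matrix")
    block = cn.df.loc[present].to_numpy(float)
    scores = pd.Series(score_fn(block), index=cn.lines, name="arm_score")
    scores.attrs["n_arm_genes"] = int(len(present))
    return scores


def classify_lines(scores: pd.Series, threshold: float = -2.5) -> ArmCallTable:
    """DEL iff score < threshold (strict); boundary and above are nonDEL."""
    if len(scores) == 0:
        raise ValueError("empty score set")
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    missing = scores.isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} line(s) had no observed arm gene and were left unclassified"
        )
    call = pd.Series(pd.NA, index=scores.index, dtype=object)
    call[~missing] = np.where(scores[~missing] < threshold, DEL, NONDEL)
    n_used = scores.attrs.get("n_arm_genes", pd.NA)
    table = pd.DataFrame({"arm_score": scores, "call": call, "n_arm_genes_used": n_used})
    return ArmCallTable(table=table, threshold=float(threshold))


def scna_frequency(
    cn: CopyNumberMatrix, gain_cut: float = 0.1, loss_cut: float = -0.1
) -> pd.DataFrame:
    """Per-gene % of samples above the gain cutoff / below the loss cutoff.

    Percentages are over non-missing samples; genes observed in no sample get
    NaN percentages.
    """
    vals = cn.df.to_numpy(float)
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_amp = 100.0 * np.where(obs, vals > gain_cut, False).sum(axis=1) / n_obs
        pct_del = 100.0 * np.where(obs, vals < loss_cut, False).sum(axis=1) / n_obs
    out = pd.DataFrame(
        {"pct_amplified": pct_amp, "pct_deleted": pct_del, "n_samples": n_obs.astype(int)},
        index=cn.genes,
    )
    out.loc[n_obs == 0, ["pct_amplified", "pct_deleted"]] = np.nan
    return out
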