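"""Balanced-correlation (BaCoN) prediction of expression-buffering gene pairs.

A buffering pair is an (expression gene e, fitness gene f) pair where low
expression of e makes knockout of f more deleterious; across cell lines this
shows up as a *positive* Pearson correlation between e's log2(TPM+1)
expression and f's CERES score.  Raw correlations are dominated by
lineage-driven co-variation, so each pair's correlation is down-weighted by
how much competition it faces: with r = pcc(e, f),

    w = (#entries > r in e's row + #entries > r in f's column)
        / ((n_fit - 1) + (n_expr - 1))          (missing entries excluded)
    score = r * (1 - w)        (multiplicative variant, the default)
          = r - w              (subtractive variant)

A pair that is the strict maximum of both its row and column keeps its full
correlation; a promiscuous pair whose genes correlate strongly with many
partners is pushed towards zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, FitnessMatrix

__all__ = [
    "CandidateSets",
    "filter_candidates",
    "pcc_matrix",
    "bacon_scores",
    "rank_pairs",
]


def _df(x):
    return x.df if hasattr(x, "df") else x


@dataclass
class CandidateSets:
    """Expression-side (buffering) and fitness-side (buffered) candidate genes.

    Buffering gene: expression SD across lines > 1 and expression > 3 in at
    least ``min_lines`` lines (100, or 20% of lines in desk-scale mode).
    Buffered gene: mean log2(TPM+1) > 2 and (|mean CERES| > 0.3 or CERES
    SD > 0.2).  All comparisons strict except the line count (>=).
    """

    buffering: pd.Index
    buffered: pd.Index
    buffering_diagnostics: pd.DataFrame
    buffered_diagnostics: pd.DataFrame


def filter_candidates(
    expr: ExpressionMatrix,
    fitness: FitnessMatrix,
    sd_min: float = 1.0,
    level: float = 3.0,
    min_lines: int = 100,
    mean_expr_min: float = 2.0,
    abs_mean_ceres_min: float = 0.3,
    ceres_sd_min: float = 0.2,
    desk_scale: bool = False,
) -> CandidateSets:
    """Apply the expression- and fitness-side candidate filters.

    ``desk_scale=True`` rescales the ">= min_lines lines above level" count
    rule to 20% of the cohort when the cohort itself has fewer than
    ``min_lines`` lines; otherwise the rule is applied literally.
    """
    edf, fdf = _df(expr), _df(fitness)
    if list(edf.columns) != list(fdf.columns):
        raise ValueError("expression and fitness matrices must be aligned on the same lines")
    n_lines = edf.shape[1]
    need = min_lines
    if desk_scale and n_lines < min_lines:
        need = int(np.ceil(0.2 * n_lines))

    e_sd = edf.std(axis=1, ddof=1)
    e_high = (edf > level).sum(axis=1)
    buffering_diag = pd.DataFrame({"expression_sd": e_sd, "n_lines_above_level": e_high})
    buffering_diag["passes"] = (e_sd > sd_min) & (e_high >= need)

    shared = fdf.index.intersection(edf.index)
    f_mean_expr = edf.mean(axis=1).reindex(fdf.index)
    f_mean_ceres = fdf.mean(axis=1)
    f_sd_ceres = fdf.std(axis=1, ddof=1)
    buffered_diag = pd.DataFrame(
        {"mean_expression": f_mean_expr, "mean_ceres": f_mean_ceres, "ceres_sd": f_sd_ceres}
    )
    buffered_diag["passes"] = (
        (f_mean_expr > mean_expr_min)
        & ((f_mean_ceres.abs() > abs_mean_ceres_min) | (f_sd_ceres > ceres_sd_min))
    )
    buffered_diag.loc[~fdf.index.isin(shared), "passes"] = False

    buffering = buffering_diag.index[buffering_diag["passes"].fillna(False)]
    buffered = buffered_diag.index[buffered_diag["passes"].fillna(False)]
    if len(buffering) == 0 or len(buffered) == 0:
        raise ValueError(
            "empty candidate set: "
            f"{int(buffering_diag['passes'].sum())} buffering candidates "
            f"(need sd > {sd_min} and expr > {level} in >= {need} lines), "
            f"{int(buffered_diag['passes'].fillna(False).sum())} buffered candidates "
            f"(need mean expr > {mean_expr_min} and |mean CERES| > {abs_mean_ceres_min} "
            f"or CERES sd > {ceres_sd_min})"
        )
    return CandidateSets(buffering, buffered, buffering_diag, buffered_diag)


def pcc_matrix(
    expr: ExpressionMatrix, fitness: FitnessMatrix, min_obs: int = 3
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations, expression genes x fitness genes.

    Pairs with fewer than ``min_obs`` complete observations or a
    zero-variance vector get NaN (invisible to competition counts and
    ranking).
    """
    X = _df(expr).to_numpy(float)  # (n_e, L)
    Y = _df(fitness).to_numpy(float)  # (n_f, L)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("matrices must share the same cell-line columns")
    Mx = (~np.isnan(X)).astype(float)
    My = (~np.isnan(Y)).astype(float)
    X0 = np.nan_to_num(X)
    Y0 = np.nan_to_num(Y)
    n = Mx @ My.T
    sx = X0 @ My.T
    sy = Mx @ Y0.T
    sxx = (X0 * X0) @ My.T
    syy = Mx @ (Y0 * Y0).T
    sxy = X0 @ Y0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r = cov / np.sqrt(vx * vy)
    eps = 1e-12
    r[(n < min_obs) | (vx <= eps * np.maximum(sxx, 1.0)) | (vy <= eps * np.maximum(syy, 1.0))] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=_df(expr).index, columns=_df(fitness).index)


def _n_higher(vals: np.ndarray, axis: int) -> np.ndarray:
    """Per entry, the count of strictly greater non-missing entries along ``axis``."""
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=axis, keepdims=True)
    filled = np.where(obs, vals, -np.inf)
    # rank with 'max' counts entries <= value; higher = observed - that count
    rank_max = stats.rankdata(filled, method="max", axis=axis)
    n_miss = (~obs).sum(axis=axis, keepdims=True)
    higher = n_obs - (rank_max - n_miss)
    return np.where(obs, higher, 0).astype(float)


def bacon_scores(pcc: pd.DataFrame, variant: str = "multiplicative") -> pd.DataFrame:
    """Competition-weighted scores for every non-missing pair of a PCC matrix.

    Returns the long PairTable with columns expr_gene, fit_gene, pcc,
    n_higher_row, n_higher_col, competition_fraction, bacon_score.  Ties
    contribute 0 to the competition counts; missing entries are excluded from
    both counts and denominators.
    """
    if pcc.shape[0] < 2 or pcc.shape[1] < 2:
        raise ValueError("need at least a 2x2 correlation matrix (no competitors otherwise)")
    if variant not in ("multiplicative", "subtractive"):
        raise ValueError(f"unknown variant {variant!r}")
    vals = pcc.to_numpy(float)
    obs = ~np.isnan(vals)
    higher_row = _n_higher(vals, axis=1)  # within each expression gene's row
    higher_col = _n_higher(vals, axis=0)  # within each fitness gene's column
    denom = (obs.sum(axis=1, keepdims=True) - 1) + (obs.sum(axis=0, keepdims=True) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom > 0, (higher_row + higher_col) / denom, 0.0)
    score = vals * (1.0 - w) if variant == "multiplicative" else vals - w
    ii, jj = np.nonzero(obs)
    table = pd.DataFrame(
        {
            "expr_gene": pcc.index.to_numpy()[ii],
            "fit_gene": pcc.columns.to_numpy()[jj],
            "pcc": vals[ii, jj],
            "n_higher_row": higher_row[ii, jj].astype(int),
            "n_higher_col": higher_col[ii, jj].astype(int),
            "competition_fraction": w[ii, jj],
            "bacon_score": score[ii, jj],
        }
    )
    table.attrs["variant"] = variant
    table.attrs["shape"] = pcc.shape
    return table


def rank_pairs(
    pairs: pd.DataFrame,
    fitness: FitnessMatrix,
    restrict_to_hits=None,
    pan_essential_cut: float = -0.75,
) -> pd.DataFrame:
    """Filter and rank the pair table by balanced-correlation score.

    Drops pairs whose fitness-side gene is pan-essential (mean CERES across
    all lines strictly below ``pan_essential_cut``); optionally keeps only
    pairs whose fitness-side gene is in ``restrict_to_hits`` (empty/None = no
    restriction); sorts descending by score and assigns dense ranks.
    """
    mean_ceres = _df(fitness).mean(axis=1)
    out = pairs.copy()
    out["fit_gene_mean_ceres"] = mean_ceres.reindex(out["fit_gene"]).to_numpy()
    out = out[~(out["fit_gene_mean_ceres"] < pan_essential_cut)]
    if restrict_to_hits is not None and len(restrict_to_hits) > 0:
        out = out[out["fit_gene"].isin(set(restrict_to_hits))]
    out = out.sort_values(
        ["bacon_score", "pcc", "expr_gene", "fit_gene"], ascending=[False, False, True, True]
    ).reset_index(drop=True)
    out["rank"] = out["bacon_score"].rank(method="dense", ascending=False).astype(int)
    out.attrs = dict(pairs.attrs)
    return out
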