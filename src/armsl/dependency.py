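"""Differential gene dependency between arm-deleted and non-deleted lines.

Pipeline order: expression prefilter -> dCERES effect size -> per-gene
Wilcoxon rank-sum -> covariate-weighted FDR adjustment (independent
hypothesis weighting with the per-gene mean nonDEL CERES score as the
covariate) -> hit selection -> arm enrichment.

dCERES = mean CERES in DEL lines - mean CERES in nonDEL lines; negative
values mean a gene is more essential when the arm is deleted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arm import ArmCallTable
from .io import ExpressionMatrix, FitnessMatrix

__all__ = [
    "expression_prefilter",
    "dceres",
    "wilcoxon_per_gene",
    "ihw_adjust",
    "IhwResult",
    "select_hits",
    "build_dependency_table",
    "arm_enrichment",
    "EnrichmentResult",
    "lineage_corrected_dependency",
    "LineageCorrectedResult",
]


def _df(x):
    return x.df if hasattr(x, "df") else x


def _groups(calls: ArmCallTable) -> tuple[pd.Index, pd.Index]:
    d, n = calls.del_lines, calls.nondel_lines
    if len(d) == 0 or len(n) == 0:
        raise ValueError(f"both groups must be non-empty (DEL={len(d)}, nonDEL={len(n)})")
    return d, n


# ---------------------------------------------------------------------------
# prefilter and effect size


def expression_prefilter(
    expr: ExpressionMatrix, calls: ArmCallTable, min_mean: float = 1.0
) -> pd.Series:
    """Gene passes iff mean log2(TPM+1) > min_mean (strict) in DEL or in nonDEL lines."""
    df = _df(expr)
    d, n = _groups(calls)
    missing = set(d) | set(n)
    missing -= set(df.columns)
    if missing:
        raise ValueError(f"classified lines absent from expression matrix: {sorted(missing)[:5]}")
    mean_del = df[list(d)].mean(axis=1)
    mean_nondel = df[list(n)].mean(axis=1)
    return ((mean_del > min_mean) | (mean_nondel > min_mean)).rename("passed_prefilter")


def dceres(fitness: FitnessMatrix, calls: ArmCallTable) -> pd.DataFrame:
    """Per-gene group means and their difference (DEL - nonDEL) over non-missing values.

    Genes with no observation in one group get NaN for that group and for the
    difference.
    """
    df = _df(fitness)
    d, n = _groups(calls)
    mean_del = df[list(d)].mean(axis=1)
    mean_nondel = df[list(n)].mean(axis=1)
    return pd.DataFrame(
        {"mean_del": mean_del, "mean_nondel": mean_nondel, "dceres": mean_del - mean_nondel}
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    both = np.concatenate([x, y])
    return len(np.unique(both)) < len(both)


def rank_sum_p(x: np.ndarray, y: np.ndarray, exact_max: int = 8) -> float:
    """Two-sided rank-sum p for one gene.

    Exact enumeration of the null (via the tie-free Mann-Whitney U
    distribution) when min(n1, n2) <= exact_max and no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        return np.nan
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    use_exact = min(len(x), len(y)) <= exact_max and not _has_ties(x, y)
    method = "exact" if use_exact else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else min(p, 1.0)


def wilcoxon_per_gene(
    fitness: FitnessMatrix, calls: ArmCallTable, exact_max: int = 8
) -> pd.Series:
    """Two-sided rank-sum p per gene, DEL versus nonDEL CERES scores.

    Large balanced groups without missing values take a vectorised
    tie-corrected normal-approximation path; small groups or genes with
    missing data fall back to the per-gene routine (exact where tie-free).
    """
    df = _df(fitness)
    d, n = _groups(calls)
    X = df[list(d)].to_numpy(float)
    Y = df[list(n)].to_numpy(float)
    p = pd.Series(np.nan, index=df.index, name="p_value")
    complete = ~np.isnan(X).any(axis=1) & ~np.isnan(Y).any(axis=1)
    if min(len(d), len(n)) > exact_max and complete.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(
                X[complete], Y[complete], alternative="two-sided", method="asymptotic",
                use_continuity=True, axis=1,
            )
        pv = np.asarray(res.pvalue, float)
        pv = np.where(np.isnan(pv), 1.0, pv)  # fully tied genes
        p.iloc[np.flatnonzero(complete)] = np.minimum(pv, 1.0)
        rest = np.flatnonzero(~complete)
    else:
        rest = np.arange(df.shape[0])
    for i in rest:
        p.iloc[i] = rank_sum_p(X[i], Y[i], exact_max=exact_max)
    return p


# ---------------------------------------------------------------------------
# covariate-weighted FDR (independent hypothesis weighting)

_WEIGHT_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class IhwResult:
    p_adj: pd.Series
    weights: pd.Series  # per-hypothesis weight actually applied
    bin_weights: pd.DataFrame  # folds x bins learned weights
    bins: pd.Series  # per-hypothesis bin id
    n_bins: int
    alpha: float


def _weighted_bh_rejections(p: np.ndarray, w: np.ndarray, alpha: float) -> int:
    """Number of rejections of weighted BH at level alpha (weights mean 1)."""
    m = len(p)
    with np.errstate(divide="ignore"):
        q = np.where(w > 0, p / np.maximum(w, 1e-300), np.inf)
    q = np.sort(q)
    thresh = alpha * np.arange(1, m + 1) / m
    ok = np.flatnonzero(q <= thresh)
    return int(ok[-1] + 1) if len(ok) else 0


def _bh_adjust(q: np.ndarray) -> np.ndarray:
    """BH step-up adjusted values for (possibly weighted, possibly > 1) p-values."""
    m = len(q)
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _learn_weights(p: np.ndarray, bins: np.ndarray, n_bins: int, alpha: float) -> np.ndarray:
    """Greedy coordinate search over a multiplier grid, budget-normalised.

    Weights maximise the discoveries of weighted BH on the training
    hypotheses subject to sum_b w_b * m_b = m; ties prefer the weight closest
    to 1 so a signal-free training set stays at plain BH.
    """
    m_b = np.bincount(bins, minlength=n_bins).astype(float)
    m = float(len(p))

    def normalise(raw: np.ndarray) -> np.ndarray:
        total = float(raw @ m_b)
        return raw * (m / total) if total > 0 else np.ones(n_bins)

    raw = np.ones(n_bins)
    best = _weighted_bh_rejections(p, normalise(raw)[bins], alpha)
    for _ in range(3):
        improved = False
        for b in range(n_bins):
            if m_b[b] == 0:
                continue
            cur = raw[b]
            for cand in _WEIGHT_GRID:
                if cand == cur:
                    continue
                trial = raw.copy()
                trial[b] = cand
                rej = _weighted_bh_rejections(p, normalise(trial)[bins], alpha)
                closer = abs(np.log(cand)) < abs(np.log(raw[b]))
                if rej > best or (rej == best and closer and rej > 0):
                    best, raw, improved = rej, trial, True
        if not improved:
            break
    return normalise(raw)


def ihw_adjust(
    p_values: pd.Series,
    covariate: pd.Series,
    alpha: float = 0.1,
    n_bins: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> IhwResult:
    """Covariate-weighted BH-adjusted p-values (independent hypothesis weighting).

    The covariate (here: per-gene mean nonDEL CERES score) is split into
    ``n_bins`` quantile bins; per-bin weights are learned by cross-fitting —
    for each fold the weights are chosen on the other folds by grid search
    maximising weighted-BH discoveries at level ``alpha`` under the budget
    sum_b w_b m_b = m — and applied out-of-fold.  Adjusted p_i is the BH
    step-up value of p_i / w_i, clipped to [0, 1].

    With one bin (or fewer hypotheses than bins, which falls back to one bin
    with a warning) the result is exactly Benjamini-Hochberg.
    """
    p_values = p_values.dropna()
    covariate = covariate.reindex(p_values.index)
    if covariate.isna().any():
        raise ValueError("covariate must be finite for every tested hypothesis")
    m = len(p_values)
    if m == 0:
        raise ValueError("no hypotheses to adjust")
    p = p_values.to_numpy(float)

    if m < n_bins:
        warnings.warn(f"only {m} hypotheses for {n_bins} bins; falling back to plain BH")
        n_bins = 1
    if n_bins == 1:
        adj = multipletests(p, method="fdr_bh")[1]
        return IhwResult(
            p_adj=pd.Series(adj, index=p_values.index, name="p_adj"),
            weights=pd.Series(1.0, index=p_values.index, name="weight"),
            bin_weights=pd.DataFrame(np.ones((1, 1))),
            bins=pd.Series(0, index=p_values.index, name="bin"),
            n_bins=1,
            alpha=alpha,
        )

    # quantile bins on the covariate (ranks break ties deterministically)
    ranks = stats.rankdata(covariate.to_numpy(float), method="average")
    bins = np.minimum((ranks - 1) / m * n_bins, n_bins - 1).astype(int)

    rng = np.random.default_rng(seed)
    fold = rng.permutation(m) % n_folds

    weights = np.ones(m)
    fold_weights = np.ones((n_folds, n_bins))
    for j in range(n_folds):
        train = fold != j
        if train.sum() == 0 or (~train).sum() == 0:
            continue
        w_b = _learn_weights(p[train], bins[train], n_bins, alpha)
        fold_weights[j] = w_b
        weights[~train] = w_b[bins[~train]]
    # renormalise so the applied weights keep the total budget
    total = weights.sum()
    if total > 0:
        weights *= m / total

    with np.errstate(divide="ignore"):
        q = np.where(weights > 0, p / np.maximum(weights, 1e-300), np.inf)
    adj = _bh_adjust(q)
    return IhwResult(
        p_adj=pd.Series(adj, index=p_values.index, name="p_adj"),
        weights=pd.Series(weights, index=p_values.index, name="weight"),
        bin_weights=pd.DataFrame(fold_weights),
        bins=pd.Series(bins, index=p_values.index, name="bin"),
        n_bins=n_bins,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# hit selection and table assembly


def select_hits(
    table: pd.DataFrame, p_cut: float = 0.25, d_cut: float = -0.075, strict_p_cut: float = 0.1
) -> pd.DataFrame:
    """Flag hits: prefilter-passing genes with p_adj < p_cut and dCERES < d_cut (both strict).

    A stricter tier (p_adj < strict_p_cut with the same effect cut) is flagged
    separately as ``is_strict_hit``.
    """
    out = table.copy()
    ok = out["passed_prefilter"].fillna(False).astype(bool)
    effect = out["dceres"] < d_cut
    out["is_hit"] = ok & (out["p_adj"] < p_cut) & effect
    out["is_strict_hit"] = ok & (out["p_adj"] < strict_p_cut) & effect
    return out


def build_dependency_table(
    fitness: FitnessMatrix,
    expression: ExpressionMatrix,
    calls: ArmCallTable,
    min_mean: float = 1.0,
    alpha: float = 0.1,
    n_bins: int = 5,
    n_folds: int = 5,
    p_cut: float = 0.25,
    strict_p_cut: float = 0.1,
    d_cut: float = -0.075,
    seed: int = 0,
    ihw_rerun_at_hit_level: bool = False,
) -> tuple[pd.DataFrame, IhwResult]:
    """Run prefilter -> dCERES -> Wilcoxon -> weighted FDR -> hit flags for one cohort.

    Genes failing the expression prefilter are not tested (their p-value and
    adjusted p-value stay NaN).  The IHW covariate is the per-gene mean
    CERES score across nonDEL lines.
    """
    passed = expression_prefilter(expression, calls, min_mean=min_mean)
    table = dceres(fitness, calls)
    table["passed_prefilter"] = passed.reindex(table.index).fillna(False)
    tested = table.index[table["passed_prefilter"] & table["dceres"].notna()]
    p = wilcoxon_per_gene(
        FitnessMatrix(_df(fitness).loc[tested], getattr(fitness, "entrez", None)), calls
    )
    table["p_value"] = p.reindex(table.index)
    level = p_cut if ihw_rerun_at_hit_level else alpha
    ihw = ihw_adjust(
        table.loc[tested, "p_value"],
        covariate=table.loc[tested, "mean_nondel"],
        alpha=level,
        n_bins=n_bins,
        n_folds=n_folds,
        seed=seed,
    )
    table["p_adj"] = ihw.p_adj.reindex(table.index)
    table = select_hits(table, p_cut=p_cut, d_cut=d_cut, strict_p_cut=strict_p_cut)
    return table, ihw


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    universe_size: int  # N
    on_arm_in_universe: int  # K
    hits: int  # n
    on_arm_hits: int  # k
    fold_enrichment: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "on_arm_in_universe": self.on_arm_in_universe,
            "hits": self.hits,
            "on_arm_hits": self.on_arm_hits,
            "fold_enrichment": self.fold_enrichment,
            "p_value": self.p_value,
        }


def arm_enrichment(
    hits, annotation: pd.DataFrame, universe, chromosome: str, arm: str
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of hits on one chromosome arm.

    P(X >= k) with population N = |universe|, K arm genes in the universe,
    n = |hits| draws, k arm genes among the hits; fold = (k/n)/(K/N).
    """
    hits = pd.Index(hits)
    universe = pd.Index(universe)
    if not hits.isin(universe).all():
        raise ValueError("hits must be a subset of the universe")
    on_arm = set(
        annotation.loc[
            (annotation["chromosome"].astype(str) == str(chromosome)) & (annotation["arm"] == arm),
            "gene_symbol",
        ]
    )
    N = len(universe)
    K = int(universe.isin(on_arm).sum())
    n = len(hits)
    k = int(hits.isin(on_arm).sum())
    if n == 0 or K == 0:
        return EnrichmentResult(N, K, n, k, np.nan, np.nan)
    fold = (k / n) / (K / N)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(N, K, n, k, fold, p)


# ---------------------------------------------------------------------------
# lineage-corrected single-gene dependency


@dataclass
class LineageCorrectedResult:
    residuals: pd.Series
    dependent: pd.Series  # lowest-decile flag on the residuals
    partner_expression_means: dict  # {"dependent": ., "non_dependent": .}
    partner_expression_p: float
    partner_cn_means: dict
    partner_cn_p: float


def _group_compare(values: pd.Series, flag: pd.Series) -> tuple[dict, float]:
    a = values[flag].dropna().to_numpy(float)
    b = values[~flag].dropna().to_numpy(float)
    means = {
        "dependent": float(np.mean(a)) if len(a) else np.nan,
        "non_dependent": float(np.mean(b)) if len(b) else np.nan,
    }
    p = rank_sum_p(a, b) if len(a) and len(b) else np.nan
    return means, p


def lineage_corrected_dependency(
    fitness_row: pd.Series,
    lineage: pd.Series,
    partner_expression: pd.Series,
    partner_cn: pd.Series | None = None,
    decile: float = 0.10,
) -> LineageCorrectedResult:
    """Regress lineage out of one gene's CERES scores and flag dependent lines.

    The lineage effect is removed by least squares on lineage indicators
    (equivalently within-lineage centering); "dependent" lines are those with
    residuals in the lowest ``decile``.  Partner expression (and copy number,
    if given) are then compared between dependent and non-dependent lines
    (group means plus a two-sided rank-sum p).
    """
    scores = fitness_row.dropna()
    lin = lineage.reindex(scores.index)
    if lin.nunique(dropna=True) <= 1:
        warnings.warn("single lineage: residuals are grand-mean-centred scores")
        resid = scores - scores.mean()
    else:
        resid = scores - scores.groupby(lin).transform("mean")
    cut = resid.quantile(decile)
    dependent = (resid <= cut).rename("dependent")
    expr_means, expr_p = _group_compare(partner_expression.reindex(scores.index), dependent)
    if partner_cn is not None:
        cn_means, cn_p = _group_compare(partner_cn.reindex(scores.index), dependent)
    else:
        cn_means, cn_p = {"dependent": np.nan, "non_dependent": np.nan}, np.nan
    return LineageCorrectedResult(
        residuals=resid.rename("residual"),
        dependent=dependent,
        partner_expression_means=expr_means,
        partner_expression_p=expr_p,
        partner_cn_means=cn_means,
        partner_cn_p=cn_p,
    )
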