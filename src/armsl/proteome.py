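"""Label-free proteomics differential abundance.

Fixed stage order: valid-value filter -> quantile normalization -> per-sample
downshifted imputation -> moderated two-group test with Benjamini-Hochberg
adjustment.  Missing LFQ intensities are treated as censored at the detection
limit, so imputation draws from a normal distribution centred
``shift`` sample-SDs below the sample mean with ``width`` x the sample SD
(the Perseus convention: 1.8 / 0.3 by default).

The moderated test shrinks per-protein variances towards a pooled prior
fitted by moment matching on log s^2 (digamma/trigamma inversion), the
standard empirical-Bayes construction: with per-protein residual variance
s_g^2 on d degrees of freedom and prior (d0, s0^2),

    s_tilde^2 = (d0 s0^2 + d s_g^2) / (d0 + d)
    t_mod     = log2fc / (s_tilde * sqrt(1/n1 + 1/n2))   on d0 + d df.

Proteins are called up when log2FC >= fc_cut and adjusted p < alpha, down
when log2FC <= -fc_cut and adjusted p < alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteomeTable",
    "valid_value_filter",
    "quantile_normalize",
    "downshift_impute",
    "fit_variance_prior",
    "moderated_test",
    "run_proteome_pipeline",
]

_D0_CAP = 1e7  # stand-in for an infinite prior df (complete shrinkage)


@dataclass
class ProteomeTable:
    """Proteins x samples LFQ intensities plus the two-condition design."""

    intensities: pd.DataFrame
    condition: pd.Series  # sample -> condition label
    log2_scale: bool = True

    def __post_init__(self) -> None:
        self.condition = self.condition.reindex(self.intensities.columns)
        if self.condition.isna().any():
            missing = self.intensities.columns[self.condition.isna()].tolist()
            raise ValueError(f"samples without a condition label: {missing}")
        levels = self.condition.unique()
        if len(levels) != 2:
            raise ValueError(f"exactly two conditions required, got {list(levels)}")

    @property
    def conditions(self) -> list:
        return list(pd.unique(self.condition))

    def samples_of(self, level) -> pd.Index:
        return self.condition.index[self.condition == level]

    def log2(self) -> "ProteomeTable":
        """Log2-transform raw intensities exactly once (zeros become missing)."""
        if self.log2_scale:
            raise ValueError("table is already on the log2 scale")
        vals = self.intensities.where(self.intensities > 0)
        return ProteomeTable(np.log2(vals), self.condition, log2_scale=True)


def valid_value_filter(table: ProteomeTable, frac: float = 0.70) -> ProteomeTable:
    """Keep proteins quantified in >= ``frac`` of the samples of at least one condition.

    "Quantified" means non-missing and non-zero; the fraction comparison is
    inclusive (a protein seen in exactly 70% of one condition's samples is
    kept at the default).
    """
    a, b = table.conditions
    keep = pd.Series(False, index=table.intensities.index)
    for level in (a, b):
        cols = table.samples_of(level)
        if len(cols) == 0:
            raise ValueError(f"condition {level!r} has zero samples")
        block = table.intensities[cols]
        valid = block.notna() & (block != 0)
        keep |= valid.sum(axis=1) / len(cols) >= frac
    return replace(table, intensities=table.intensities.loc[keep])


def quantile_normalize(table: ProteomeTable) -> ProteomeTable:
    """Classic quantile normalization on observed values.

    Each column's values are mapped, by rank, onto the across-column mean
    quantile profile; ties are resolved by averaging and missing entries stay
    missing.  With complete columns this is exactly the rank -> mean-of-sorted
    -columns construction.
    """
    vals = table.intensities.to_numpy(float)
    n_rows, n_cols = vals.shape
    counts = (~np.isnan(vals)).sum(axis=0)
    if (counts < 2).any():
        bad = table.intensities.columns[counts < 2].tolist()
        raise ValueError(f"columns with fewer than 2 observed values: {bad}")
    grid = np.linspace(0.0, 1.0, n_rows)
    ref = np.zeros(n_rows)
    for j in range(n_cols):
        col = vals[:, j]
        ref += np.quantile(col[~np.isnan(col)], grid)
    ref /= n_cols
    out = np.full_like(vals, np.nan)
    for j in range(n_cols):
        col = vals[:, j]
        obs = ~np.isnan(col)
        n = int(obs.sum())
        ranks = stats.rankdata(col[obs], method="average")
        pos = (ranks - 1) / (n - 1) if n > 1 else np.zeros(1)
        out[obs, j] = np.interp(pos, grid, ref)
    df = pd.DataFrame(out, index=table.intensities.index, columns=table.intensities.columns)
    return replace(table, intensities=df)


def downshift_impute(
    table: ProteomeTable, shift: float = 1.8, width: float = 0.3, seed: int = 0
) -> ProteomeTable:
    """Replace missing entries with draws from a downshifted per-sample normal.

    Missing entries in sample s become Normal(mu_s - shift * sigma_s,
    (width * sigma_s)^2) draws, where mu_s/sigma_s are the sample's observed
    mean and SD.  Observed entries are untouched; the draw is seeded.
    """
    rng = np.random.default_rng(seed)
    vals = table.intensities.to_numpy(float).copy()
    for j, col_name in enumerate(table.intensities.columns):
        col = vals[:, j]
        miss = np.isnan(col)
        obs = col[~miss]
        if len(obs) < 2 or np.std(obs, ddof=1) == 0:
            raise ValueError(f"sample {col_name!r} has zero observed spread; cannot impute")
        mu, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
        col[miss] = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
    df = pd.DataFrame(vals, index=table.intensities.index, columns=table.intensities.columns)
    return replace(table, intensities=df)


# ---------------------------------------------------------------------------
# moderated two-group test


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the standard recurrence)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match the scaled inverse-chi-square variance prior (d0, s0^2).

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0), log s^2 has known
    mean/variance in terms of digamma/trigamma; inverting those moments gives
    the prior.  An estimated infinite d0 (no excess spread in log s^2) is
    capped at a large finite value with a warning.
    """
    s2 = np.asarray(s2, float)
    pos = s2[s2 > 0]
    if len(pos) < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(pos)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        warnings.warn("no excess variance in log s^2; prior df capped (effectively infinite)")
        d0 = _D0_CAP
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if not np.isfinite(d0):
            warnings.warn("prior df estimated infinite; capped")
            d0 = _D0_CAP
    s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_test(
    table: ProteomeTable,
    fc_cut: float = 0.6,
    alpha: float = 0.05,
    d0: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group test per protein.

    Expects a complete (post-imputation) log2-scale table.  ``d0=None``
    estimates the prior df by moment matching; ``d0=0`` disables moderation
    (ordinary pooled two-sample t).  log2FC is mean(first condition) -
    mean(second condition) in the order conditions first appear.
    """
    if not table.log2_scale:
        raise ValueError("moderated_test expects log2-scale intensities")
    a, b = table.conditions
    A = table.intensities[table.samples_of(a)].to_numpy(float)
    B = table.intensities[table.samples_of(b)].to_numpy(float)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("table must be complete (run downshift_impute first)")
    n1, n2 = A.shape[1], B.shape[1]
    d = n1 + n2 - 2
    if d <= 0:
        raise ValueError("zero residual degrees of freedom (need >= 2 samples in a condition)")
    log2fc = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (B - B.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d
    if d0 is None:
        d0_fit, s0_2 = fit_variance_prior(s2, d)
    else:
        d0_fit, s0_2 = float(d0), 0.0 if d0 == 0 else float(np.median(s2[s2 > 0]))
    s2_post = (d0_fit * s0_2 + d * s2) / (d0_fit + d)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    t_mod = np.where((se == 0) & (log2fc == 0), 0.0, t_mod)
    df_total = min(d0_fit + d, _D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.minimum(p, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    klass = np.where(
        (log2fc >= fc_cut) & (p_adj < alpha),
        "up",
        np.where((log2fc <= -fc_cut) & (p_adj < alpha), "down", "ns"),
    )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t_mod": t_mod,
            "p": p,
            "p_adj": p_adj,
            "class": klass,
        },
        index=table.intensities.index,
    )
    out.attrs.update({"d0": d0_fit, "s0_2": s0_2, "df_residual": d, "conditions": (a, b)})
    return out


def run_proteome_pipeline(
    table: ProteomeTable,
    frac: float = 0.70,
    shift: float = 1.8,
    width: float = 0.3,
    fc_cut: float = 0.6,
    alpha: float = 0.05,
    seed: int = 0,
    d0: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """filter -> quantile normalize -> impute -> moderated test, with a stage log."""
    log: dict = {"order": ["valid_value_filter", "quantile_normalize", "downshift_impute", "moderated_test"]}
    if not table.log2_scale:
        table = table.log2()
        log["log2_transformed"] = True
    log["n_input"] = int(table.intensities.shape[0])
    table = valid_value_filter(table, frac=frac)
    log["n_after_filter"] = int(table.intensities.shape[0])
    table = quantile_normalize(table)
    n_missing = int(table.intensities.isna().sum().sum())
    log["n_imputed"] = n_missing
    if n_missing:
        table = downshift_impute(table, shift=shift, width=width, seed=seed)
    result = moderated_test(table, fc_cut=fc_cut, alpha=alpha, d0=d0)
    log["n_up"] = int((result["class"] == "up").sum())
    log["n_down"] = int((result["class"] == "down").sum())
    return result, log
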