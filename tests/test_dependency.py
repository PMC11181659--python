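from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from armsl import (
    FitnessMatrix,
    ExpressionMatrix,
    arm_enrichment,
    dceres,
    expression_prefilter,
    ihw_adjust,
    lineage_corrected_dependency,
    select_hits,
    wilcoxon_per_gene,
)
from armsl.arm import ArmCallTable, DEL, NONDEL
from armsl.dependency import rank_sum_p


def _calls(del_lines, nondel_lines):
    lines = list(del_lines) + list(nondel_lines)
    call = [DEL] * len(del_lines) + [NONDEL] * len(nondel_lines)
    table = pd.DataFrame({"arm_score": 0.0, "call": call, "n_arm_genes_used": 1}, index=lines)
    return ArmCallTable(table=table, threshold=-2.5)


def _fm(rows: dict, lines, kind=FitnessMatrix):
    return kind(pd.DataFrame(rows, index=lines).T)


CALLS_2_2 = _calls(["d1", "d2"], ["n1", "n2"])


class TestPrefilter:
    @pytest.mark.parametrize(
        "del_vals, nondel_vals, expected",
        [
            ([1.5, 1.5], [0.2, 0.2], True),  # OR rule: DEL group suffices
            ([1.0, 1.0], [1.0, 1.0], False),  # strict boundary
            ([0.0, 0.0], [0.0, 0.0], False),
            ([0.2, 0.2], [1.5, 1.5], True),
        ],
    )
    def test_or_rule_and_boundary(self, del_vals, nondel_vals, expected):
        expr = _fm({"G1": del_vals + nondel_vals}, ["d1", "d2", "n1", "n2"], ExpressionMatrix)
        flags = expression_prefilter(expr, CALLS_2_2, min_mean=1.0)
        assert bool(flags["G1"]) is expected

    def test_empty_group_is_error(self):
        expr = _fm({"G1": [1.0, 1.0]}, ["d1", "d2"], ExpressionMatrix)
        lines = pd.DataFrame(
            {"arm_score": 0.0, "call": [DEL, DEL], "n_arm_genes_used": 1}, index=["d1", "d2"]
        )
        with pytest.raises(ValueError, match="non-empty"):
            expression_prefilter(expr, ArmCallTable(lines, -2.5))


class TestDceres:
    def test_arithmetic(self):
        fit = _fm({"G1": [-0.6, -0.4, -0.1, -0.3]}, ["d1", "d2", "n1", "n2"])
        row = dceres(fit, CALLS_2_2).loc["G1"]
        assert row["mean_del"] == pytest.approx(-0.5)
        assert row["mean_nondel"] == pytest.approx(-0.2)
        assert row["dceres"] == pytest.approx(-0.3)

    def test_identical_groups_give_zero(self):
        fit = _fm({"G1": [-0.2, -0.4, -0.2, -0.4]}, ["d1", "d2", "n1", "n2"])
        assert dceres(fit, CALLS_2_2).loc["G1", "dceres"] == 0.0

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(3)
        lines = [f"L{i}" for i in range(10)]
        fit = _fm({f"G{j}": rng.normal(size=10) for j in range(5)}, lines)
        fwd = dceres(fit, _calls(lines[:4], lines[4:]))
        rev = dceres(fit, _calls(lines[4:], lines[:4]))
        assert np.allclose(fwd["dceres"], -rev["dceres"])

    def test_missing_group_is_missing_result(self):
        fit = _fm({"G1": [np.nan, np.nan, -0.1, -0.3]}, ["d1", "d2", "n1", "n2"])
        assert np.isnan(dceres(fit, CALLS_2_2).loc["G1", "dceres"])


def _enumerated_rank_sum_p(x, y):
    """Independent oracle: full enumeration of rank-sum assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n1)])
    le = np.mean(sums <= obs + 1e-9)
    ge = np.mean(sums >= obs - 1e-9)
    return min(1.0, 2.0 * min(le, ge))


class TestWilcoxon:
    def test_separated_groups_exact_p(self):
        # 2 of the C(6,3)=20 assignments are at least as extreme
        assert rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert rank_sum_p([1.0, 1.0], [1.0, 1.0]) == 1.0
        fit = _fm({"G1": [-0.2, -0.2, -0.2, -0.2]}, ["d1", "d2", "n1", "n2"])
        assert wilcoxon_per_gene(fit, CALLS_2_2)["G1"] == 1.0

    def test_small_groups_match_full_enumeration(self):
        rng = np.random.default_rng(4)
        for n1, n2 in [(3, 3), (4, 5), (5, 5), (2, 7)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            assert rank_sum_p(x, y) == pytest.approx(_enumerated_rank_sum_p(x, y), abs=1e-12)

    def test_vectorised_path_matches_scalar_path(self):
        rng = np.random.default_rng(5)
        lines = [f"L{i}" for i in range(30)]
        fit = _fm({f"G{j}": rng.normal(size=30) for j in range(8)}, lines)
        calls = _calls(lines[:12], lines[12:])
        vec = wilcoxon_per_gene(fit, calls)
        for g in fit.genes:
            x = fit.df.loc[g, list(calls.del_lines)].to_numpy()
            y = fit.df.loc[g, list(calls.nondel_lines)].to_numpy()
            assert vec[g] == pytest.approx(rank_sum_p(x, y), rel=1e-9)


class TestIhw:
    def test_single_bin_equals_bh_exactly(self):
        rng = np.random.default_rng(6)
        p = pd.Series(rng.random(300))
        cov = pd.Series(rng.normal(size=300))
        res = ihw_adjust(p, cov, n_bins=1)
        expected = multipletests(p.to_numpy(), method="fdr_bh")[1]
        assert np.array_equal(res.p_adj.to_numpy(), expected)

    def test_all_p_one_means_no_rejections(self):
        p = pd.Series(np.ones(50))
        res = ihw_adjust(p, pd.Series(np.arange(50.0)), alpha=0.1, n_bins=5)
        assert (res.p_adj == 1.0).all()

    def test_fewer_hypotheses_than_bins_falls_back_to_bh(self):
        p = pd.Series([0.01, 0.5, 0.9])
        with pytest.warns(UserWarning, match="plain BH"):
            res = ihw_adjust(p, pd.Series([0.0, 1.0, 2.0]), n_bins=5)
        assert np.array_equal(
            res.p_adj.to_numpy(), multipletests(p.to_numpy(), method="fdr_bh")[1]
        )

    def test_nan_covariate_is_error(self):
        with pytest.raises(ValueError, match="covariate"):
            ihw_adjust(pd.Series([0.5, 0.6]), pd.Series([0.1, np.nan]), n_bins=1)

    def test_adjusted_p_monotone_within_bin_and_fold(self):
        rng = np.random.default_rng(7)
        p = pd.Series(rng.random(500))
        cov = pd.Series(rng.normal(size=500))
        res = ihw_adjust(p, cov, alpha=0.1, n_bins=4, n_folds=3, seed=1)
        df = pd.DataFrame({"p": p, "adj": res.p_adj, "bin": res.bins, "w": res.weights})
        for (_, _), grp in df.groupby(["bin", "w"]):
            grp = grp.sort_values("p")
            assert (grp["adj"].diff().dropna() >= -1e-12).all()

    def test_signal_bin_is_upweighted(self):
        """Two covariate bins, one carrying 30% moderate alternatives: the
        learner should upweight the signal bin in the vast majority of runs."""
        m = 2000
        wins = 0
        runs = 40
        for s in range(runs):
            rng = np.random.default_rng(20_000 + s)
            cov = pd.Series(np.r_[np.zeros(m // 2), np.ones(m // 2)])
            alt = rng.random(m // 2) < 0.3
            p1 = np.where(alt, rng.beta(0.05, 1, m // 2), rng.random(m // 2))
            p = pd.Series(np.r_[rng.random(m // 2), p1])
            res = ihw_adjust(p, cov, alpha=0.1, n_bins=2, n_folds=5, seed=s)
            w = res.weights.groupby(res.bins).mean()
            wins += w[1] > w[0]
        assert wins / runs >= 0.9


class TestHitsAndEnrichment:
    def _table(self, p_adj, d, pre=True):
        return pd.DataFrame(
            {"dceres": [d], "p_adj": [p_adj], "passed_prefilter": [pre]}, index=["G1"]
        )

    @pytest.mark.parametrize(
        "p_adj, d, pre, expected",
        [
            (0.2, -0.1, True, True),
            (0.2, -0.075, True, False),  # strict effect boundary
            (0.25, -0.1, True, False),  # strict p boundary
            (0.2, -0.1, False, False),  # prefilter is a hard gate
        ],
    )
    def test_hit_rule_boundaries(self, p_adj, d, pre, expected):
        out = select_hits(self._table(p_adj, d, pre))
        assert bool(out["is_hit"].iloc[0]) is expected

    def test_strict_tier(self):
        out = select_hits(self._table(0.05, -0.1))
        assert bool(out["is_strict_hit"].iloc[0])
        out = select_hits(self._table(0.2, -0.1))
        assert not bool(out["is_strict_hit"].iloc[0])

    def _ann(self, arm_genes, other_genes):
        genes = list(arm_genes) + list(other_genes)
        return pd.DataFrame(
            {
                "gene_symbol": genes,
                "entrez_id": range(len(genes)),
                "chromosome": ["8"] * len(arm_genes) + ["1"] * len(other_genes),
                "arm": "p",
                "start_bp": 1,
                "end_bp": 2,
            }
        ).set_index("gene_symbol", drop=False)

    def test_fully_on_arm_closed_form(self):
        arm = [f"A{i}" for i in range(10)]
        rest = [f"B{i}" for i in range(90)]
        res = arm_enrichment(arm, self._ann(arm, rest), arm + rest, "8", "p")
        from scipy.special import comb

        assert res.p_value == pytest.approx(1.0 / comb(100, 10))
        assert res.fold_enrichment == pytest.approx(10.0)

    def test_proportional_hits_give_fold_one(self):
        arm = [f"A{i}" for i in range(10)]
        rest = [f"B{i}" for i in range(90)]
        hits = arm[:1] + rest[:9]  # 10% on arm, as in the universe
        res = arm_enrichment(hits, self._ann(arm, rest), arm + rest, "8", "p")
        assert res.fold_enrichment == pytest.approx(1.0)

    def test_hits_outside_universe_error(self):
        arm = ["A0"]
        ann = self._ann(arm, ["B0"])
        with pytest.raises(ValueError, match="subset"):
            arm_enrichment(["Z"], ann, ["A0", "B0"], "8", "p")

    def test_null_calibration(self):
        """Hypergeometric draws without enrichment: P(p <= 0.05) ~ 0.05."""
        N, K, n = 200, 40, 25
        rng = np.random.default_rng(8)
        ks = stats.hypergeom.rvs(N, K, n, size=10_000, random_state=rng)
        ps = stats.hypergeom.sf(ks - 1, N, K, n)
        frac = np.mean(ps <= 0.05)
        # discreteness makes the test conservative; never anti-conservative
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 10_000)


class TestLineageCorrected:
    def test_perfect_lineage_fit_gives_zero_residuals(self):
        lines = [f"L{i}" for i in range(6)]
        scores = pd.Series([-0.5, -0.5, -0.5, -0.1, -0.1, -0.1], index=lines)
        lineage = pd.Series(["a"] * 3 + ["b"] * 3, index=lines)
        res = lineage_corrected_dependency(scores, lineage, pd.Series(1.0, index=lines))
        assert np.allclose(res.residuals, 0.0)

    def test_single_lineage_centres_on_grand_mean(self):
        lines = ["L0", "L1", "L2"]
        scores = pd.Series([-0.3, -0.6, 0.0], index=lines)
        lineage = pd.Series(["a"] * 3, index=lines)
        with pytest.warns(UserWarning, match="single lineage"):
            res = lineage_corrected_dependency(scores, lineage, pd.Series(1.0, index=lines))
        assert np.allclose(res.residuals, scores - scores.mean())

    def test_recovers_partner_coupling(self):
        """Planted buffering: partner expression is lower in dependent lines."""
        hits = 0
        seeds = 50
        for s in range(seeds):
            rng = np.random.default_rng(100 + s)
            n = 200
            lines = [f"L{i}" for i in range(n)]
            lineage = pd.Series(rng.integers(0, 5, n).astype(str), index=lines)
            lineage_eff = dict(zip("01234", rng.normal(0, 0.3, 5)))
            expr = pd.Series(rng.normal(5, 1, n), index=lines)
            gamma = 0.5
            scores = pd.Series(
                lineage.map(lineage_eff).to_numpy()
                - gamma * (expr < expr.median()).to_numpy()
                + rng.normal(0, 0.15, n),
                index=lines,
            )
            res = lineage_corrected_dependency(scores, lineage, expr)
            hits += (
                res.partner_expression_means["dependent"]
                < res.partner_expression_means["non_dependent"]
            )
        assert hits / seeds >= 0.9
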