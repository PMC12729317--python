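"""Repeated-measures ANOVA stack against explicit-formula and library oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tremorbench.metrics import compute_metrics, metrics_frame
from tremorbench.stats import (
    DegenerateDataError,
    RMTable,
    anova_report,
    assumption_diagnostics,
    descriptives,
    pairwise_bonferroni,
    qq_correlation,
    rm_anova,
)
from tremorbench.tremor import simulate_session_logs


def table_from(values, conds=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    conds = conds or [f"c{j}" for j in range(k)]
    return RMTable([f"s{i}" for i in range(n)], conds, values)


def ss_oracle(values):
    """Independent sums-of-squares oracle: explicit double loops."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = v.sum() / (n * k)
    ss_total = sum((v[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_subj = sum(k * (v[i, :].mean() - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (v[:, j].mean() - grand) ** 2 for j in range(k))
    ss_res = ss_total - ss_subj - ss_cond
    return ss_total, ss_subj, ss_cond, ss_res


# the 6x3 toy table used against the explicit oracle and library cross-checks
TOY = np.array(
    [
        [10.0, 12.0, 11.0],
        [8.0, 11.0, 9.0],
        [12.0, 15.0, 13.5],
        [9.0, 9.5, 10.0],
        [11.0, 14.0, 12.0],
        [10.5, 13.0, 11.0],
    ]
)


class TestRMAnova:
    def test_degrees_of_freedom_n15_k3(self, rng):
        v = rng.normal(0, 1, (15, 3)) + rng.normal(0, 1, (15, 1))
        res = rm_anova(table_from(v))
        assert (res.df1, res.df2) == (2, 28)

    def test_toy_table_matches_explicit_ss_oracle(self):
        res = rm_anova(table_from(TOY))
        ss_total, ss_subj, ss_cond, ss_res = ss_oracle(TOY)
        assert res.ss_total == pytest.approx(ss_total, rel=1e-12)
        assert res.ss_subject == pytest.approx(ss_subj, rel=1e-12)
        assert res.ss_condition == pytest.approx(ss_cond, rel=1e-12)
        f_oracle = (ss_cond / 2) / (ss_res / 10)
        assert res.f == pytest.approx(f_oracle, rel=1e-12)
        assert res.eta_sq_partial == pytest.approx(ss_cond / (ss_cond + ss_res), rel=1e-12)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame(
            [
                {"subject": i, "cond": f"c{j}", "y": TOY[i, j]}
                for i in range(6)
                for j in range(3)
            ]
        )
        sm = AnovaRM(long, "y", "subject", within=["cond"]).fit().anova_table
        res = rm_anova(table_from(TOY))
        assert res.f == pytest.approx(float(sm["F Value"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(sm["Pr > F"].iloc[0]), rel=1e-9)

    def test_sphericity_and_epsilon_match_pingouin(self, rng):
        import pingouin as pg

        v = rng.normal(0, 1, (15, 3)) + rng.normal(0, 1, (15, 1)) + [0, 1.0, 0.5]
        res = rm_anova(table_from(v))
        long = pd.DataFrame(
            [
                {"subject": i, "cond": f"c{j}", "y": v[i, j]}
                for i in range(15)
                for j in range(3)
            ]
        )
        sph = pg.sphericity(data=long, dv="y", within="cond", subject="subject")
        eps = pg.epsilon(data=long, dv="y", within="cond", subject="subject",
                         correction="gg")
        assert res.mauchly_w == pytest.approx(float(sph.W), rel=1e-9)
        assert res.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)
        assert res.gg_epsilon == pytest.approx(float(eps), rel=1e-9)

    def test_k2_epsilon_exactly_one(self, rng):
        v = rng.normal(0, 1, (10, 2))
        res = rm_anova(table_from(v))
        assert res.gg_epsilon == 1.0
        assert res.mauchly_w == 1.0 and res.mauchly_p == 1.0

    def test_compound_symmetry_gives_epsilon_one_and_pgg_equals_p(self, rng):
        # build a sample whose orthonormal-contrast covariance is exactly
        # the identity (sphericity holds exactly): whiten the projected
        # noise, then add subject and condition effects, which the
        # contrasts' covariance cannot see
        from scipy.linalg import helmert

        c = helmert(3, full=False)  # (2, 3), rows orthonormal
        x = rng.normal(0, 1, (12, 2))
        xc = x - x.mean(axis=0)
        white = xc @ np.linalg.inv(np.linalg.cholesky(np.cov(xc, rowvar=False)).T)
        v = white @ c + rng.normal(0, 1, (12, 1)) + np.array([0.0, 1.0, 0.5])
        res = rm_anova(table_from(v))
        assert res.gg_epsilon == pytest.approx(1.0, abs=1e-9)
        assert res.mauchly_w == pytest.approx(1.0, abs=1e-9)
        assert res.p_gg == pytest.approx(res.p, rel=1e-9)

    def test_zero_residual_variance_degenerate(self):
        v = np.add.outer(np.arange(5.0), np.array([0.0, 1.0, 2.0]))
        with pytest.raises(DegenerateDataError, match="residual"):
            rm_anova(table_from(v))

    def test_incomplete_or_tiny_tables_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            table_from(np.ones((1, 3)))
        with pytest.raises(ValueError, match="non-finite"):
            table_from([[1.0, np.nan], [2.0, 3.0]])

    @pytest.mark.filterwarnings("ignore:singular contrast")
    @given(
        arrays(
            float,
            (6, 3),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    def test_ss_decomposition_exact(self, v):
        ss_total, ss_subj, ss_cond, ss_res = ss_oracle(v)
        if ss_res <= 1e-9 * max(1.0, ss_total):
            return  # degenerate tables raise; covered elsewhere
        res = rm_anova(table_from(v))
        assert res.ss_subject + res.ss_condition + res.ss_residual == pytest.approx(
            res.ss_total, rel=1e-9, abs=1e-9
        )


class TestPairwise:
    def test_three_conditions_three_pairs(self, rng):
        v = rng.normal(0, 1, (8, 3))
        out = pairwise_bonferroni(table_from(v))
        assert len(out) == 3
        assert all(p.p_bonferroni >= p.p_raw for p in out)
        assert all(p.p_bonferroni <= 1.0 for p in out)

    def test_identical_conditions_null_identity(self):
        v = np.tile(np.arange(6.0)[:, None], (1, 3))
        out = pairwise_bonferroni(table_from(v))
        for p in out:
            assert p.mean_diff == 0.0
            assert p.p_bonferroni == 1.0
            assert p.degenerate

    def test_matches_scipy_ttest_rel(self, rng):
        from scipy.stats import ttest_rel

        v = rng.normal(0, 1, (12, 3)) + [0, 0.8, 0.3]
        out = pairwise_bonferroni(table_from(v))
        for p, (i, j) in zip(out, [(0, 1), (0, 2), (1, 2)]):
            ref = ttest_rel(v[:, i], v[:, j])
            assert p.t == pytest.approx(ref.statistic, rel=1e-9)
            assert p.p_raw == pytest.approx(ref.pvalue, rel=1e-9)

    def test_paired_cohens_d_definition(self, rng):
        v = rng.normal(0, 1, (10, 2))
        p = pairwise_bonferroni(table_from(v))[0]
        d = v[:, 0] - v[:, 1]
        assert p.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-12)

    def test_power_to_detect_generator_effects(self):
        # effects (0, +2, +1) s with unit-SD paired differences at n = 15:
        # every pair should come out significant in >= 80% of replicates
        n_rep, all_sig = 200, 0
        for rep in range(n_rep):
            logs = simulate_session_logs(
                15,
                ["no_tremor", "tremor_unfiltered", "tremor_filtered"],
                [0.0, 2.0, 1.0],
                seed=10_000 + rep,
                within_sd=1.0 / math.sqrt(2.0),
            )
            recs = [compute_metrics(l.events, l.condition, l.subject) for l in logs]
            table = RMTable.from_long(metrics_frame(recs), value="cct_mean_s")
            out = pairwise_bonferroni(table)
            if all(p.p_raw < 0.05 for p in out):
                all_sig += 1
        assert all_sig / n_rep >= 0.8


class TestDescriptives:
    def test_constant_column(self):
        v = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        d = descriptives(table_from(v))
        row = d.iloc[0]
        assert row["mean"] == 3.0 and row["sd"] == 0.0
        assert row["ci_low"] == row["ci_high"] == 3.0

    def test_hand_arithmetic_n2(self):
        d = descriptives(table_from([[0.0, 1.0], [2.0, 5.0]]))
        assert d.iloc[0]["mean"] == 1.0
        assert d.iloc[0]["sd"] == pytest.approx(math.sqrt(2.0))

    def test_ci_coverage_close_to_nominal(self, rng):
        mu, hits, n_rep = 1.7, 0, 2000
        for _ in range(n_rep):
            x = rng.normal(mu, 2.0, (10, 1))
            d = descriptives(RMTable([f"s{i}" for i in range(10)], ["a", "a2"],
                                     np.column_stack([x[:, 0], x[:, 0] * 0])))
            if d.iloc[0]["ci_low"] <= mu <= d.iloc[0]["ci_high"]:
                hits += 1
        assert hits / n_rep == pytest.approx(0.95, abs=0.02)


class TestDiagnostics:
    def test_perfectly_additive_table_zero_residuals(self):
        v = np.add.outer(np.arange(5.0), np.array([0.0, 1.0, 2.0]))
        diag = assumption_diagnostics(table_from(v))
        assert np.allclose(diag["residual"], 0.0)

    def test_gaussian_residuals_high_qq_correlation(self, rng):
        v = rng.normal(0, 1, (15, 3)) + rng.normal(0, 2, (15, 1))
        diag = assumption_diagnostics(table_from(v))
        assert qq_correlation(diag) >= 0.98

    def test_heavy_tails_lower_qq_correlation(self, rng):
        gauss = rng.normal(0, 1, (15, 3))
        heavy = rng.standard_cauchy((15, 3))
        q_g = qq_correlation(assumption_diagnostics(table_from(gauss)))
        q_h = qq_correlation(assumption_diagnostics(table_from(heavy)))
        assert q_h < q_g


class TestReport:
    def test_report_is_json_ready_and_complete(self, rng):
        import json

        v = rng.normal(0, 1, (15, 3)) + [0, 1.5, 0.7]
        rep = anova_report(table_from(v, conds=list("abc")))
        text = json.dumps(rep)
        assert "anova" in rep and len(rep["pairwise"]) == 3
        assert set(rep["descriptives"]) == {"a", "b", "c"}
        assert json.loads(text)["anova"]["df1"] == 2
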