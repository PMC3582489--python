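"""Expression preprocessing and allele-dosage regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inveqtl import (
    GenomicInterval,
    bonferroni_threshold,
    fit_dosage_model,
    preprocess_expression,
    quantile_normalize,
    run_cis_eqtl,
    simulate_covariates,
    simulate_dosage_truth,
    simulate_expression,
)
from inveqtl.eqtl import format_threshold
from inveqtl.genio import ExpressionTable
from inveqtl.invcall import LABELS, InversionCalls

CIS = GenomicInterval("chr17", 39_899_921, 42_989_253)


def make_expression(values, starts=None, detection=None, chrom="chr17"):
    values = pd.DataFrame(values)
    values.index = [f"p{i}" for i in range(values.shape[0])]
    if starts is None:
        starts = 40_000_000 + 1000 * np.arange(values.shape[0])
    meta = pd.DataFrame(
        {
            "probe_id": values.index,
            "gene": [f"G{i}" for i in range(values.shape[0])],
            "chrom": chrom,
            "start": starts,
            "end": np.asarray(starts) + 49,
        }
    )
    det = pd.Series(
        1.0 if detection is None else detection, index=values.index, dtype=float
    )
    return ExpressionTable(values, meta, det)


def calls_from_dosage(dosage, ids=None):
    dosage = np.asarray(dosage, int)
    n = dosage.size
    ids = ids or [f"ind{i + 1:04d}" for i in range(n)]
    label = np.array(
        ["EXCLUDED" if d < 0 else LABELS[d] for d in dosage], dtype=object
    )
    return InversionCalls(
        list(ids), label, dosage, np.zeros(n), np.zeros(n),
        np.zeros(3), np.zeros(3), (0, 0, 0), 0.0, 1.0,
    )


class TestQuantileNormalize:
    def test_rank_average_oracle_by_hand(self):
        """Columns (1,2,3) and (4,5,6) both map to (2.5, 3.5, 4.5)."""
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_ties_receive_mean_of_spanned_quantiles(self):
        # reference = mean sorted = (1.5, 2.5, 4.5); the tie at ranks 1-2 in
        # column a gets (1.5 + 2.5)/2 = 2
        df = pd.DataFrame({"a": [1.0, 1.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["a"], [2.0, 2.0, 4.5])
        np.testing.assert_allclose(out["b"], [1.5, 2.5, 4.5])

    def test_single_column_is_identity(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 7.0]})
        out = quantile_normalize(df)
        np.testing.assert_allclose(out["a"], df["a"])

    def test_columns_share_distribution_after(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 4)) * [1, 2, 3, 4])
        out = quantile_normalize(df).to_numpy()
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, j]))


class TestPreprocessExpression:
    def test_blood_detection_filter(self):
        expr = make_expression(np.ones((3, 2)), detection=[0.95, 0.85, 0.99])
        out = preprocess_expression(expr, "blood", log2_transform=False)
        assert list(out.values.index) == ["p0", "p2"]

    def test_brain_detection_filter_keeps_small_p(self):
        expr = make_expression(np.ones((3, 2)), detection=[0.001, 0.5, 0.009])
        out = preprocess_expression(expr, "brain", log2_transform=False)
        assert list(out.values.index) == ["p0", "p2"]

    def test_non_positive_intensity_errors_before_log2(self):
        expr = make_expression([[1.0, -2.0]])
        with pytest.raises(ValueError, match="non-positive"):
            preprocess_expression(expr, "blood")

    def test_log2_then_quantile(self):
        expr = make_expression([[2.0, 16.0], [8.0, 64.0]])
        out = preprocess_expression(expr, "blood")
        # log2 -> [[1,4],[3,6]]; reference = ((1+4)/2, (3+6)/2) = (2.5, 4.5)
        np.testing.assert_allclose(out.values.to_numpy(), [[2.5, 2.5], [4.5, 4.5]])


class TestFitDosageModel:
    def test_noiseless_fit_reports_p_zero(self):
        dosage = np.tile([0, 1, 2], 10)
        y = 2 + 0.5 * dosage
        res = fit_dosage_model(y, dosage)
        assert res.B == pytest.approx(0.5, abs=1e-12)
        assert res.SE == 0.0 and res.p == 0.0
        assert res.ci95 == (res.B, res.B)

    def test_matches_normal_equations_and_statsmodels(self):
        """(B, SE, t, p) agree with two independent oracles to 1e-8 relative."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        for _ in range(20):
            n = 40
            dosage = rng.choice([0, 1, 2], n)
            cov = rng.normal(size=(n, 2))
            y = 1 + 0.3 * dosage + cov @ [0.2, -0.1] + rng.normal(0, 0.5, n)
            res = fit_dosage_model(y, dosage, cov)
            # oracle 1: explicit normal equations + t distribution
            x = np.column_stack([np.ones(n), dosage, cov])
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            resid = y - x @ beta
            sigma2 = resid @ resid / (n - 4)
            se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[1, 1])
            t_val = beta[1] / se
            p_val = 2 * stats.t.sf(abs(t_val), n - 4)
            assert res.B == pytest.approx(beta[1], rel=1e-8)
            assert res.SE == pytest.approx(se, rel=1e-8)
            assert res.t == pytest.approx(t_val, rel=1e-8)
            assert res.p == pytest.approx(p_val, rel=1e-8, abs=1e-300)
            # oracle 2: statsmodels OLS
            fit = sm.OLS(y, x).fit()
            assert res.B == pytest.approx(fit.params[1], rel=1e-8)
            assert res.SE == pytest.approx(fit.bse[1], rel=1e-8)
            lo, hi = fit.conf_int()[1]
            assert res.ci95[0] == pytest.approx(lo, rel=1e-6)
            assert res.ci95[1] == pytest.approx(hi, rel=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        n = 50
        dosage = rng.choice([0, 1, 2], n)
        cov = rng.normal(size=(n, 1))
        y = 0.2 * dosage + cov[:, 0] + rng.normal(size=n)
        perm = rng.permutation(n)
        a = fit_dosage_model(y, dosage, cov)
        b = fit_dosage_model(y[perm], dosage[perm], cov[perm])
        assert a.B == pytest.approx(b.B, rel=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-10)

    def test_recoding_dosage_flips_sign_only(self):
        rng = np.random.default_rng(3)
        dosage = rng.choice([0, 1, 2], 60)
        y = 0.4 * dosage + rng.normal(size=60)
        a = fit_dosage_model(y, dosage)
        b = fit_dosage_model(y, 2 - dosage)
        assert b.B == pytest.approx(-a.B, rel=1e-10)
        assert b.p == pytest.approx(a.p, rel=1e-10)
        assert b.SE == pytest.approx(a.SE, rel=1e-10)

    def test_constant_dosage_errors(self):
        with pytest.raises(ValueError, match="genotype variance"):
            fit_dosage_model(np.ones(10), np.ones(10))

    def test_collinear_covariate_dropped_and_refit(self):
        rng = np.random.default_rng(4)
        dosage = rng.choice([0, 1, 2], 40)
        c1 = rng.normal(size=40)
        cov = np.column_stack([c1, 2 * c1])  # second column redundant
        y = 0.3 * dosage + c1 + rng.normal(size=40)
        res = fit_dosage_model(y, dosage, cov)
        ref = fit_dosage_model(y, dosage, c1.reshape(-1, 1))
        assert res.B == pytest.approx(ref.B, rel=1e-10)
        assert res.p == pytest.approx(ref.p, rel=1e-10)

    def test_uncorrelated_covariate_barely_moves_b(self):
        rng = np.random.default_rng(5)
        shifts = []
        for rep in range(50):
            dosage = rng.choice([0, 1, 2], 200, p=[0.04, 0.32, 0.64])
            y = 0.3 * dosage + rng.normal(0, 0.3, 200)
            junk = rng.normal(size=(200, 1))
            a = fit_dosage_model(y, dosage)
            b = fit_dosage_model(y, dosage, junk)
            shifts.append(abs(a.B - b.B) / a.SE)
        assert np.mean(shifts) < 3


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected,display",
        [
            (0.05, 28, 0.05 / 28, "0.0018"),  # whole-blood probe count
            (0.05, 1, 0.05, "0.05"),
            (0.01, 40, 0.00025, "0.00025"),
        ],
    )
    def test_threshold_and_display(self, alpha, m, expected, display):
        thr = bonferroni_threshold(alpha, m)
        assert thr == pytest.approx(expected, rel=1e-12)
        assert format_threshold(thr) == display

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestRunCisEqtl:
    def test_probe_outside_cis_absent(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=(2, 30))
        expr = make_expression(vals, starts=[40_000_000, 50_000_000])
        expr.values.columns = [f"ind{i + 1:04d}" for i in range(30)]
        dosage = rng.choice([0, 1, 2], 30)
        res = run_cis_eqtl(expr, calls_from_dosage(dosage), None, CIS)
        assert res["probe_id"].tolist() == ["p0"]

    def test_individuals_joined_by_id_not_position(self):
        truth = simulate_dosage_truth(80, 0.2, seed=1, probe_effects=[0.5], noise_sd=0.1)
        expr = simulate_expression(truth, 1, seed=2)
        calls = calls_from_dosage(truth.true_dosage, truth.individual_ids)
        res1 = run_cis_eqtl(expr, calls, None, CIS)
        shuffled = ExpressionTable(
            expr.values.iloc[:, ::-1], expr.probe_meta, expr.detection
        )
        res2 = run_cis_eqtl(shuffled, calls, None, CIS)
        assert res1["B"][0] == pytest.approx(res2["B"][0], rel=1e-12)
        assert res1["p"][0] == pytest.approx(res2["p"][0], rel=1e-12)

    def test_excluded_individuals_dropped(self):
        truth = simulate_dosage_truth(60, 0.3, seed=4, probe_effects=[0.4], noise_sd=0.2)
        expr = simulate_expression(truth, 1, seed=5)
        dosage = truth.true_dosage.copy()
        dosage[:5] = -1  # excluded
        res = run_cis_eqtl(expr, calls_from_dosage(dosage, truth.individual_ids), None, CIS)
        assert res["n"][0] == 55

    def test_causal_probe_detected_with_power(self):
        """One probe with B = 0.37 among 27 nulls at n = 431: exactly the
        causal probe is Bonferroni-significant in >= 90% of replicates."""
        hits = 0
        n_reps = 200
        effects = np.zeros(28)
        effects[0] = 0.37
        for rep in range(n_reps):
            truth = simulate_dosage_truth(431, 0.21, seed=rep, probe_effects=effects,
                                          noise_sd=0.3)
            expr = simulate_expression(truth, 28, seed=10_000 + rep)
            calls = calls_from_dosage(truth.true_dosage, truth.individual_ids)
            res = run_cis_eqtl(expr, calls, None, CIS, alpha=0.05)
            sig = res[res["significant"]]["probe_id"].tolist()
            hits += sig == ["probe01"]
        assert hits / n_reps >= 0.90

    def test_null_pvalues_uniform(self):
        """Under the global null, per-probe p-values are Uniform(0, 1)."""
        truth = simulate_dosage_truth(300, 0.21, seed=7, probe_effects=np.zeros(1000),
                                      noise_sd=0.3)
        expr = simulate_expression(truth, 1000, seed=8)
        calls = calls_from_dosage(truth.true_dosage, truth.individual_ids)
        res = run_cis_eqtl(expr, calls, None, CIS)
        ks_p = stats.kstest(res["p"], "uniform").pvalue
        assert ks_p > 0.01

    def test_fewer_than_two_genotype_classes_errors(self):
        truth = simulate_dosage_truth(30, 0.0, seed=9, probe_effects=[0.1], noise_sd=0.1)
        expr = simulate_expression(truth, 1, seed=10)
        calls = calls_from_dosage(truth.true_dosage, truth.individual_ids)
        with pytest.raises(ValueError, match="genotype classes"):
            run_cis_eqtl(expr, calls, None, CIS)
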