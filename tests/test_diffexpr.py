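"""Quantile normalization, EB variance shrinkage and the moderated t test."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from conftest import make_dataset
from netmark.datasets import ExpressionDataset
from netmark.diffexpr import (
    bh_adjust,
    estimate_eb_hyperparameters,
    moderated_t_test,
    quantile_normalize,
    run_differential,
    select_differential,
)


def _dataset_from(values: np.ndarray, n_case: int, n_control: int) -> ExpressionDataset:
    cols = [f"case_{i}" for i in range(n_case)] + [f"ctrl_{i}" for i in range(n_control)]
    return ExpressionDataset(
        values=pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])], columns=cols),
        design=pd.Series(["case"] * n_case + ["control"] * n_control, index=cols),
    )


class TestQuantileNormalize:
    def test_identical_columns_are_a_fixed_point(self):
        ds = make_dataset(20, 3, 3, seed=1)
        vals = ds.values.copy()
        for c in vals.columns:
            vals[c] = vals.iloc[:, 0]
        ds = ds.with_values(vals)
        out = quantile_normalize(ds)
        assert np.allclose(out.values.to_numpy(), vals.to_numpy())

    def test_closed_form_rank_wise_mean(self):
        # columns [1,5] and [3,7]: rank-wise means are [2,6], every column maps onto them
        ds = _dataset_from(np.array([[1.0, 3.0, 1.0, 3.0], [5.0, 7.0, 5.0, 7.0]]), 2, 2)
        out = quantile_normalize(ds)
        assert np.allclose(out.values.to_numpy(), [[2.0] * 4, [6.0] * 4])

    def test_columns_share_sorted_profile_after_normalization(self):
        ds = make_dataset(50, 5, 5, seed=2)
        out = quantile_normalize(ds).values.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_ties_receive_rank_span_mean(self):
        cols = ["case_0", "case_1", "ctrl_0", "ctrl_1"]
        vals = pd.DataFrame(
            {
                "case_0": [1.0, 1.0, 9.0],
                "case_1": [2.0, 4.0, 6.0],
                "ctrl_0": [2.0, 4.0, 6.0],
                "ctrl_1": [2.0, 4.0, 6.0],
            },
            index=["a", "b", "c"],
        )
        ds = ExpressionDataset(values=vals, design=pd.Series(["case", "case", "control", "control"], index=cols))
        out = quantile_normalize(ds).values
        ref = np.sort(vals.to_numpy(), axis=0).mean(axis=1)
        # tied minima of the first column share the mean of the two lowest reference values
        assert out["case_0"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["case_0"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["case_0"].iloc[2] == pytest.approx(ref[2])

    def test_feature_and_sample_order_preserved(self):
        ds = make_dataset(30, 4, 4, seed=3)
        out = quantile_normalize(ds)
        assert out.feature_ids == ds.feature_ids
        assert out.sample_ids == ds.sample_ids


class TestEBHyperparameters:
    def test_identical_variances_give_infinite_prior_df(self):
        d0, s0 = estimate_eb_hyperparameters([2.5] * 50, df_resid=10)
        assert math.isinf(d0)
        assert s0 == pytest.approx(2.5)

    def test_moment_equation_residual_is_tiny(self):
        d0, _ = estimate_eb_hyperparameters([1.0, math.e], df_resid=10)
        z = np.log([1.0, math.e])
        residual = float(special.polygamma(1, d0 / 2)) - (
            np.var(z, ddof=1) - float(special.polygamma(1, 5.0))
        )
        assert abs(residual) < 1e-8

    def test_monte_carlo_recovery_of_prior(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, dg = 4.0, 1.0, 10
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(dg, size=5000) / dg
        d0, s0 = estimate_eb_hyperparameters(s2, df_resid=dg)
        assert 3.0 <= d0 <= 5.0
        assert 0.8 <= s0 <= 1.25

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            estimate_eb_hyperparameters([1.0], df_resid=10)
        with pytest.raises(ValueError):
            estimate_eb_hyperparameters([1.0, -1.0], df_resid=10)
        with pytest.raises(ValueError):
            estimate_eb_hyperparameters([1.0, 2.0], df_resid=0)


class TestModeratedT:
    def test_zero_prior_df_recovers_ordinary_pooled_t(self):
        ds = make_dataset(40, 6, 8, seed=4)
        res = moderated_t_test(ds, d0=0.0, s0_sq=1.0)
        case = ds.values[ds.group_columns("case")].to_numpy()
        ctrl = ds.values[ds.group_columns("control")].to_numpy()
        t_ref, p_ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        assert np.allclose(res["t_mod"], t_ref, atol=1e-10)
        assert np.allclose(res["p_raw"], p_ref, atol=1e-10)

    def test_zero_log_fc_gives_t_zero_p_one(self):
        vals = np.tile(np.array([[1.0, 2.0, 1.0, 2.0]]), (3, 1))
        ds = _dataset_from(vals, 2, 2)
        res = moderated_t_test(ds, d0=4.0, s0_sq=0.5)
        assert np.all(res["t_mod"] == 0.0)
        assert np.all(res["p_raw"] == 1.0)

    def test_moderated_variance_interpolates_toward_prior(self):
        ds = make_dataset(30, 5, 5, seed=6)
        s0_sq = 0.1
        prev = None
        for d0 in (0.0, 1.0, 10.0, 1e4):
            res = moderated_t_test(ds, d0=d0, s0_sq=s0_sq)
            mv = res["moderated_var"].to_numpy()
            sv = res["sample_var"].to_numpy()
            lo = np.minimum(sv, s0_sq) - 1e-12
            hi = np.maximum(sv, s0_sq) + 1e-12
            assert np.all((mv >= lo) & (mv <= hi))
            dist = np.abs(mv - s0_sq)
            if prev is not None:
                assert np.all(dist <= prev + 1e-12)
            prev = dist

    def test_matches_limma_ebayes_oracle(self, tmp_path):
        """Cross-check t, p and hyperparameters against the reference R implementation."""
        rng = np.random.default_rng(7)
        sigma2 = 0.25 * 4 / rng.chisquare(4, size=60)
        vals = np.repeat(np.sqrt(sigma2)[:, None], 12, axis=1) * rng.standard_normal((60, 12))
        vals[:10, :6] += 1.0
        ds = _dataset_from(8.0 + vals, 6, 6)
        dg = 10
        pooled = (
            ds.values.iloc[:, :6].var(axis=1, ddof=1) * 5
            + ds.values.iloc[:, 6:].var(axis=1, ddof=1) * 5
        ) / dg
        d0, s0 = estimate_eb_hyperparameters(pooled.to_numpy(), dg)
        res = moderated_t_test(ds, d0, s0)

        mat = tmp_path / "mat.csv"
        ds.values.to_csv(mat)
        out = tmp_path / "limma.csv"
        script = tmp_path / "run.R"
        script.write_text(
            f"""
suppressMessages(library(limma))
x <- as.matrix(read.csv("{mat}", row.names=1))
design <- cbind(Intercept=1, Case=rep(c(1,0), each=6))
fit <- eBayes(lmFit(x, design))
write.csv(data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"],
                     d0=fit$df.prior, s0=fit$s2.prior), "{out}")
"""
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out, index_col=0)
        assert d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert s0 == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        assert np.allclose(res["t_mod"], ref["t"], rtol=1e-4)
        assert np.allclose(res["p_raw"], ref["p"], rtol=1e-4)


class TestBHAdjust:
    def test_hand_evaluated_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_dominates_input_and_preserves_order(self, p):
        out = bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0)
        # step-up adjustment never reorders evidence
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(out[order]) >= -1e-15)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestSelection:
    def test_all_ones_select_nothing(self):
        df = pd.DataFrame({"feature_id": ["a", "b"], "p_adj": [1.0, 1.0]})
        assert select_differential(df) == set()

    def test_threshold_is_strict(self):
        df = pd.DataFrame({"feature_id": ["a", "b"], "p_adj": [0.05, 0.049]})
        assert select_differential(df, alpha=0.05) == {"b"}

    def test_planted_features_recovered(self):
        hits = 0
        total = 0
        for seed in range(20):
            ds = make_dataset(200, 30, 30, seed=seed, noise_sd=0.5, shift=2.0, n_shifted=20)
            _, de = run_differential(ds, alpha=0.05, normalization="none")
            truth = {f"f{i:04d}" for i in range(20)}
            hits += len(de & truth)
            total += len(truth)
        assert hits / total >= 0.95


class TestPaired:
    def test_paired_mode_detects_within_pair_shift(self):
        rng = np.random.default_rng(12)
        n_pairs = 10
        subject = rng.standard_normal((50, n_pairs)) * 2.0  # strong pairing structure
        noise = 0.3 * rng.standard_normal((50, 2 * n_pairs))
        vals = 8.0 + np.concatenate([subject, subject], axis=1) + noise
        vals[:5, :n_pairs] += 1.5
        ds = _dataset_from(vals, n_pairs, n_pairs)
        _, de_paired = run_differential(ds, normalization="none", paired=True)
        truth = {f"f{i}" for i in range(5)}
        assert truth <= de_paired
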