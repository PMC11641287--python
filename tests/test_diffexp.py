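"""Differential expression: oracles, invariants and multiplicity control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circaxis import (
    ExpressionMatrix,
    SampleDesign,
    benjamini_hochberg,
    differential_expression,
)


def _cohort(values: np.ndarray, n_tumor: int, n_normal: int, paired=False):
    n = n_tumor + n_normal
    cols = [f"t{i}" for i in range(n_tumor)] + [f"n{i}" for i in range(n_normal)]
    matrix = ExpressionMatrix(pd.DataFrame(
        values, index=[f"f{i}" for i in range(values.shape[0])], columns=cols))
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                       index=pd.Index(cols, name="sample_id"))
    pairs = None
    if paired:
        assert n_tumor == n_normal
        pairs = pd.Series([f"p{i}" for i in range(n_tumor)] * 2,
                          index=pd.Index(cols))
    return matrix, SampleDesign(groups=groups, pairs=pairs)


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        adj = benjamini_hochberg([0.001, 0.02, 0.03, 0.9])
        assert adj == pytest.approx([0.004, 0.04, 0.04, 0.9])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, np.nan])
    def test_out_of_domain_rejected(self, bad):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, bad])

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1, size=200)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestContrasts:
    def test_constant_feature_is_ns(self):
        values = np.full((1, 8), 8.0)
        matrix, design = _cohort(values, 4, 4)
        res = differential_expression(matrix, design, moderated=False)
        assert res.loc["f0", "log2fc"] == 0.0
        assert res.loc["f0", "direction"] == "ns"

    def test_welch_matches_scipy_oracle(self):
        tumor = np.array([10.1, 10.4, 10.0, 10.3, 10.2])
        normal = np.array([8.1, 8.0, 8.2, 7.9, 8.3])
        matrix, design = _cohort(np.concatenate([tumor, normal])[None, :], 5, 5)
        res = differential_expression(matrix, design, mode="unpaired",
                                      moderated=False)
        t_ref, p_ref = stats.ttest_ind(tumor, normal, equal_var=False)
        assert res.loc["f0", "log2fc"] == pytest.approx(2.1)
        assert res.loc["f0", "t"] == pytest.approx(t_ref)
        assert res.loc["f0", "p"] == pytest.approx(p_ref)

    def test_paired_matches_scipy_oracle(self, rng):
        values = rng.normal(8, 1, size=(10, 12))
        matrix, design = _cohort(values, 6, 6, paired=True)
        res = differential_expression(matrix, design, moderated=False)
        for i in range(10):
            t_ref, p_ref = stats.ttest_rel(values[i, :6], values[i, 6:])
            assert res.iloc[i]["t"] == pytest.approx(t_ref)
            assert res.iloc[i]["p"] == pytest.approx(p_ref)

    def test_identical_pairs_all_ns(self):
        half = np.array([[8.0, 9.0, 10.0], [5.0, 6.0, 7.0]])
        values = np.hstack([half, half])
        matrix, design = _cohort(values, 3, 3, paired=True)
        res = differential_expression(matrix, design)
        assert (res["log2fc"] == 0).all()
        assert (res["direction"] == "ns").all()

    def test_too_few_samples_rejected(self):
        matrix, design = _cohort(np.ones((1, 2)), 1, 1)
        with pytest.raises(ValueError, match=">= 2 samples"):
            differential_expression(matrix, design, mode="unpaired")

    def test_zero_variance_nonzero_difference_flagged(self):
        values = np.array([[9.0, 9.0, 9.0, 7.0, 7.0, 7.0],
                           [8.0, 8.5, 7.5, 8.1, 7.9, 8.0]])
        matrix, design = _cohort(values, 3, 3)
        res = differential_expression(matrix, design, moderated=False)
        assert res.loc["f0", "flagged"]
        assert 0 < res.loc["f0", "p"] < 1e-300

    def test_direction_respects_lfc_min(self, rng):
        values = np.zeros((2, 20))
        values[0, :10] += 0.5   # strong but small shift
        values[1, :10] += 3.0
        values += rng.normal(0, 0.05, values.shape)
        matrix, design = _cohort(values, 10, 10)
        res = differential_expression(matrix, design, lfc_min=1.0)
        assert res.iloc[0]["direction"] == "ns"
        assert res.iloc[1]["direction"] == "up"

    def test_missing_values_drop_feature(self, rng):
        values = rng.normal(8, 1, size=(3, 8))
        df = pd.DataFrame(values, index=["f0", "f1", "f2"],
                          columns=[f"s{i}" for i in range(8)])
        df.iloc[1, 2] = np.nan
        groups = pd.Series(["tumor"] * 4 + ["normal"] * 4,
                           index=pd.Index(df.columns, name="sample_id"))
        res = differential_expression(ExpressionMatrix(df),
                                      SampleDesign(groups=groups))
        assert list(res.index) == ["f0", "f2"]


class TestInvariants:
    def test_column_permutation_invariance(self, rng):
        values = rng.normal(8, 1, size=(30, 12))
        matrix, design = _cohort(values, 6, 6)
        res = differential_expression(matrix, design)
        perm = rng.permutation(matrix.sample_ids)
        shuffled = ExpressionMatrix(matrix.values[perm])
        res2 = differential_expression(shuffled, design)
        pd.testing.assert_frame_equal(res, res2)

    def test_label_swap_negates_effects(self, rng):
        values = rng.normal(8, 1, size=(30, 12))
        values[:5, :6] += 1.0
        matrix, design = _cohort(values, 6, 6)
        res = differential_expression(matrix, design)
        swapped = SampleDesign(groups=design.groups.map(
            {"tumor": "normal", "normal": "tumor"}))
        res2 = differential_expression(matrix, swapped)
        np.testing.assert_allclose(res2["log2fc"], -res["log2fc"])
        np.testing.assert_allclose(res2["t"], -res["t"])
        np.testing.assert_allclose(res2["p"], res["p"])

    @pytest.mark.parametrize("moderated", [False, True])
    def test_null_calibration(self, rng, moderated):
        """Pure noise: raw-p exceedance of alpha within 3 binomial SE."""
        m, alpha = 2000, 0.05
        values = rng.normal(8, 0.5, size=(m, 20))
        matrix, design = _cohort(values, 10, 10)
        res = differential_expression(matrix, design, moderated=moderated)
        frac = float((res["p"] <= alpha).mean())
        se = np.sqrt(alpha * (1 - alpha) / m)
        assert abs(frac - alpha) <= 3 * se

    def test_fdr_never_below_p(self, default_bundle):
        from circaxis import run_bundle
        res = differential_expression(
            default_bundle.circ_matrix, default_bundle.circ_design)
        assert (res["fdr"] >= res["p"] - 1e-15).all()
        up = res[res["direction"] == "up"]
        down = res[res["direction"] == "down"]
        assert (up["log2fc"] > 0).all() and (up["fdr"] <= 0.05).all()
        assert (down["log2fc"] < 0).all() and (down["fdr"] <= 0.05).all()
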