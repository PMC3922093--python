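"""Normalization, BH correction, the DE screen and the exploratory projections."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

import immunosig as im
from immunosig.datasets import METASTATIC


def bh_stepup_bruteforce(pvalues):
    """Direct evaluation of q_i = min_{j: p_(j) >= p_i} m * p_(j) / j."""
    p = list(pvalues)
    m = len(p)
    ranked = sorted(p)
    out = []
    for pi in p:
        cands = [
            m * pj / j for j, pj in enumerate(ranked, start=1) if pj >= pi - 1e-15
        ]
        out.append(min(1.0, min(cands)))
    return out


class TestNormalize:
    def test_glog_zero_is_zero(self):
        assert im.glog(0.0, 0.5) == 0.0
        assert im.glog(0.0, 100.0) == 0.0
        with pytest.raises(im.ValidationError):
            im.glog(1.0, 0.0)

    def test_equal_arrays_stay_identical(self):
        col = np.array([1.0, 5.0, 9.0, 20.0])
        raw = pd.DataFrame(
            np.column_stack([col, col, col]),
            index=list("abcd"),
            columns=["x", "y", "z"],
        )
        norm = im.normalize(raw)
        assert np.allclose(norm["x"], norm["y"])
        assert np.allclose(norm["x"], norm["z"])

    def test_affine_shifted_arrays_calibrated_together(self):
        col = np.array([1.0, 5.0, 9.0, 20.0, 3.0])
        raw = pd.DataFrame(
            {"x": col, "y": 2.0 * col + 7.0}, index=[f"p{i}" for i in range(5)]
        )
        norm = im.normalize(raw)
        assert np.allclose(norm["x"], norm["y"])

    def test_rejects_negative_input(self):
        raw = pd.DataFrame({"x": [1.0, -0.1], "y": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(im.ValidationError):
            im.normalize(raw)

    def test_rank_order_preserved_and_finite(self, toy_expression):
        raw = (toy_expression - toy_expression.min().min() + 0.1) * 50
        norm = im.normalize(raw)
        assert np.isfinite(norm.to_numpy()).all()
        for col in raw.columns:
            assert (
                np.argsort(raw[col].to_numpy()).tolist()
                == np.argsort(norm[col].to_numpy()).tolist()
            )

    def test_variance_stabilization_across_intensity_deciles(self):
        # multiplicative + additive noise: spread of replicate differences
        # varies wildly with intensity before the transform, little after
        rng = np.random.default_rng(42)
        m = 4000
        mu = np.exp(rng.uniform(0, 9, m))
        arrays = [
            np.maximum(mu * np.exp(rng.normal(0, 0.15, m)) + rng.normal(0, 5.0, m), 0)
            for _ in range(6)
        ]
        raw = pd.DataFrame(
            np.column_stack(arrays),
            index=[f"p{i}" for i in range(m)],
            columns=[f"a{j}" for j in range(6)],
        )

        def decile_spread_ratio(values):
            intensity = values.mean(axis=1)
            diff = values[:, 0] - values[:, 1]
            qs = np.quantile(intensity, np.linspace(0, 1, 11))
            spreads = [
                np.std(diff[(intensity >= lo) & (intensity <= hi)])
                for lo, hi in zip(qs, qs[1:])
            ]
            return max(spreads) / min(spreads)

        assert decile_spread_ratio(raw.to_numpy()) > 10
        assert decile_spread_ratio(im.normalize(raw).to_numpy()) < 3

    def test_sklearn_transformer_roundtrip(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 100, size=(5, 300))  # arrays x probes
        tf = im.GlogNormalizer().fit(X)
        out = tf.transform(X)
        assert out.shape == X.shape and np.isfinite(out).all()
        from sklearn.base import clone

        clone(tf)  # estimator params survive cloning


class TestBhAdjust:
    def test_hand_examples(self):
        assert np.allclose(
            im.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert im.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(im.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(im.ValidationError):
            im.bh_adjust([0.5, 1.2])
        with pytest.raises(im.ValidationError):
            im.bh_adjust([-0.1])

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20
        )
    )
    def test_matches_bruteforce_stepup(self, pvalues):
        assert np.allclose(im.bh_adjust(pvalues), bh_stepup_bruteforce(pvalues))


class TestDifferentialScreen:
    def test_strong_single_probe_is_flagged(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, size=(500, 45))
        values[7, 33:] += 8.0  # one probe shifted by 8 noise SDs
        expr = pd.DataFrame(
            values, index=[f"p{i}" for i in range(500)], columns=[f"s{i}" for i in range(45)]
        )
        labels = np.array(["n"] * 33 + ["m"] * 12)
        de = im.differential_screen(expr, labels, positive_label="m")
        assert bool(de.loc["p7", "flagged"])
        assert de["flagged"].sum() == 1

    def test_zero_variance_probe_warns_p_one(self, toy_expression):
        expr = toy_expression.copy()
        expr.iloc[0] = 5.0
        labels = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            de = im.differential_screen(expr, labels)
        assert de.iloc[0]["pvalue"] == 1.0 and de.iloc[0]["t"] == 0.0

    def test_invariant_to_column_order_and_encoding(self, toy_expression):
        labels = np.array(["a"] * 4 + ["b"] * 4)
        de1 = im.differential_screen(toy_expression, labels, positive_label="b")
        perm = np.random.default_rng(3).permutation(8)
        de2 = im.differential_screen(
            toy_expression.iloc[:, perm], labels[perm], positive_label="b"
        )
        pd.testing.assert_frame_equal(de1, de2)
        de3 = im.differential_screen(
            toy_expression, (labels == "b").astype(int), positive_label=1
        )
        assert np.allclose(de1["pvalue"], de3["pvalue"])
        assert np.allclose(de1["mean_diff"], de3["mean_diff"])

    def test_heterogeneous_signature_escapes_univariate_screen(self):
        # at array-scale multiplicity the planted immune signature is not
        # detectable univariately (incomplete penetrance dilutes the t-test)
        cohort = im.generate_cohort(im.CohortConfig(n_probes=20_000, seed=0))
        de = im.differential_screen(
            cohort.expression, cohort.metadata["label"].to_numpy(),
            positive_label=METASTATIC,
        )
        assert de.loc[sorted(cohort.truth), "flagged"].sum() == 0

    def test_requires_two_classes(self, toy_expression):
        with pytest.raises(im.ValidationError):
            im.differential_screen(toy_expression, np.zeros(8))


class TestProjectAndCluster:
    def test_duplicate_samples_merge_at_height_zero(self, toy_expression):
        expr = toy_expression.copy()
        expr["s1"] = expr["s0"]
        res = im.project_and_cluster(expr)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_rows_standardized(self, toy_expression):
        res = im.project_and_cluster(toy_expression)
        std = res.standardized.to_numpy()
        assert np.allclose(std.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(std.var(axis=1), 1, atol=1e-12)

    def test_zero_variance_row_dropped_with_warning(self, toy_expression):
        expr = toy_expression.copy()
        expr.iloc[2] = 1.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = im.project_and_cluster(expr)
        assert "p2" not in res.retained_probes

    def test_planted_blocks_separate(self):
        cohort = im.generate_cohort(
            im.CohortConfig(n_probes=100, effect_size=4.0, penetrance=1.0, seed=2)
        )
        res = im.project_and_cluster(cohort.expression, sorted(cohort.truth))
        clusters = fcluster(res.linkage_matrix, t=2, criterion="maxclust")
        labels = cohort.metadata.set_index("sample_id").loc[
            list(cohort.expression.columns), "label"
        ].to_numpy()
        met_clusters = clusters[labels == METASTATIC]
        dominant = np.bincount(met_clusters).max()
        assert dominant >= 10  # >= 10 of the 12 metastatic samples in one branch
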