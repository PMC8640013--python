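"""Standardisation, Ward clustering, per-group correlations, Tukey letters."""
import numpy as np
import pandas as pd
import pytest

from graindry import (
    ContractError,
    SchemaError,
    StorageEffectConfig,
    cluster_correlations,
    gen_storage_table,
    planted_labels,
    standardize,
    treatment_means,
    tukey_letters,
    validate_storage_table,
    ward_cluster,
)


def _ari(a, b):
    """Adjusted Rand index via the pair-counting contingency formula."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    la, lb = np.unique(a), np.unique(b)
    ct = np.array([[np.sum((a == x) & (b == y)) for y in lb] for x in la])
    comb = lambda v: v * (v - 1) / 2
    sum_ij = comb(ct).sum()
    sum_a = comb(ct.sum(axis=1)).sum()
    sum_b = comb(ct.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


class TestStandardize:
    def test_column_example(self):
        z = standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(z.ravel(), [-1.0, 0.0, 1.0])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(size=(20, 4)))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ContractError, match="flat"):
            standardize(df)

    def test_single_row_rejected(self):
        with pytest.raises(ContractError):
            standardize(np.array([[1.0, 2.0]]))


class TestWardCluster:
    def test_identical_rows_merge_at_height_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = ward_cluster(x, 2)
        assert res.merge_heights[0] == pytest.approx(0.0)
        assert res.labels[0] == res.labels[1] != res.labels[2]

    def test_two_separated_pairs_recovered(self):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        res = ward_cluster(x, 2)
        # exhaustive check over all 2-partitions of 4 points confirms this
        # split minimises within-cluster variance
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_k_equals_rows_gives_singletons(self):
        x = np.arange(12.0).reshape(4, 3)
        res = ward_cluster(x, 4)
        assert len(set(res.labels)) == 4

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(3)
        res = ward_cluster(rng.normal(size=(30, 5)), 4)
        assert np.all(np.diff(res.merge_heights) >= -1e-12)

    def test_k_out_of_range(self):
        with pytest.raises(ContractError):
            ward_cluster(np.zeros((3, 2)), 4)

    def test_row_order_invariance(self):
        df = gen_storage_table(StorageEffectConfig(seed=4))
        means = treatment_means(df)
        z = standardize(means)
        base = ward_cluster(z, 4).labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(z))
        permuted = ward_cluster(z.iloc[perm], 4).labels
        assert _ari(base[perm], permuted) == pytest.approx(1.0)


class TestClusterCorrelations:
    def test_exact_linear_relations(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0],
                "double": [2.0, 4.0, 6.0, 8.0],
                "neg": [3.0, 2.5, 2.0, 1.5],
            }
        )
        corr = cluster_correlations(df, [1, 1, 1, 1])[1]
        assert corr.loc["x", "x"] == 1.0
        assert corr.loc["x", "double"] == pytest.approx(1.0)
        assert corr.loc["x", "neg"] == pytest.approx(-1.0)

    def test_small_clusters_marked_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 4.0]})
        corr = cluster_correlations(df, [1, 1, 2])
        assert np.isnan(corr[2].loc["x", "y"])
        assert corr[2].loc["x", "x"] == 1.0

    def test_constant_variable_within_cluster_undefined(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
        corr = cluster_correlations(df, [1, 1, 1])[1]
        assert np.isnan(corr.loc["x", "flat"])


class TestTukeyLetters:
    def _table(self, means, sd=0.1, n=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for lev, mu in means.items():
            for _ in range(n):
                rows.append({"grp": lev, "y": mu + rng.normal(0, sd)})
        return pd.DataFrame(rows)

    def test_identical_groups_share_a_letter(self):
        df = pd.DataFrame({"grp": list("aabbcc"), "y": [5.0] * 6})
        out = tukey_letters(df, "y", "grp")
        assert set(out["letters"]) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        df = self._table({"low": 1.0, "high": 50.0})
        out = tukey_letters(df, "y", "grp")
        assert len(set(out["letters"])) == 2

    def test_stricter_alpha_never_more_letters(self):
        df = self._table({"a": 1.0, "b": 1.25, "c": 4.0}, sd=0.2, seed=2)
        n5 = len(set("".join(tukey_letters(df, "y", "grp", alpha=0.05)["letters"])))
        n1 = len(set("".join(tukey_letters(df, "y", "grp", alpha=0.01)["letters"])))
        assert n1 <= n5

    def test_letters_consistent_with_pairwise_decisions(self):
        # sharing a letter must coincide exactly with "not rejected" in the
        # underlying Tukey HSD table
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        df = self._table({"a": 0.0, "mid": 0.25, "b": 1.0}, sd=0.15, n=5, seed=1)
        out = tukey_letters(df, "y", "grp").set_index("grp")
        hsd = pairwise_tukeyhsd(df["y"], df["grp"], alpha=0.05)
        summary = hsd.summary().data[1:]
        for g1, g2, *_, reject in summary:
            shared = set(out.loc[g1, "letters"]) & set(out.loc[g2, "letters"])
            assert bool(shared) == (not reject), (g1, g2)

    def test_single_replicate_rejected(self):
        df = pd.DataFrame({"grp": ["a", "a", "b"], "y": [1.0, 1.1, 2.0]})
        with pytest.raises(ContractError):
            tukey_letters(df, "y", "grp")


class TestStorageSchema:
    def test_missing_column_named(self):
        df = gen_storage_table().drop(columns=["oil_pct"])
        with pytest.raises(SchemaError, match="oil_pct"):
            validate_storage_table(df)

    def test_unknown_factor_level_rejected(self):
        df = gen_storage_table()
        df.loc[0, "storage_temp_C"] = 99
        with pytest.raises(SchemaError, match="storage_temp_C"):
            validate_storage_table(df)


class TestPlantedStructureRecovery:
    def test_planted_partition_recovered_at_k4(self):
        df = gen_storage_table(StorageEffectConfig(seed=17))
        means = treatment_means(df)
        res = ward_cluster(standardize(means), 4)
        assert _ari(planted_labels(means.index), res.labels) == pytest.approx(1.0)

    def test_correlation_signs_match_construction(self):
        df = gen_storage_table(StorageEffectConfig(seed=5))
        means = treatment_means(df)
        res = ward_cluster(standardize(means), 4)
        for corr in cluster_correlations(means, res.labels).values():
            assert corr.loc["ec", "oil_pct"] < 0
            assert corr.loc["ec", "protein_pct"] < 0
            assert corr.loc["oil_pct", "protein_pct"] > 0
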