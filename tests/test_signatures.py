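import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import oracles
from icipattern import (
    BorutaSelector,
    ExpressionMatrix,
    SignatureSet,
    bh_adjust,
    boruta_reduce,
    encode_cluster_signature,
    find_degs,
    ici_score,
    median_split,
    partition_signatures,
    significant_genes,
)
from icipattern.signatures import _two_group_moderated


def _em(arr, unit="log2TPM1", genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), unit)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_hand_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        np.testing.assert_allclose(bh_adjust(p), oracles.bh_brute(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_dominates_input_and_capped(self, p):
        adj = bh_adjust(p)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestModeratedT:
    def test_zero_prior_df_equals_ordinary_t(self):
        rng = np.random.default_rng(1)
        X1, X0 = rng.normal(0, 1, (30, 8)), rng.normal(0.5, 1, (30, 10))
        t_mod, p_mod, _ = _two_group_moderated(X1, X0, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(X1, X0, axis=1)
        np.testing.assert_allclose(t_mod, t_ref, atol=1e-12)
        np.testing.assert_allclose(p_mod, p_ref, atol=1e-12)

    def test_identical_group_means_give_zero_t(self):
        X = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        t, _, _ = _two_group_moderated(
            np.hstack([X, X]), np.hstack([X, X]), prior_df=None
        )
        np.testing.assert_allclose(t, 0.0)

    def test_type_I_error_controlled_on_null(self):
        # identically distributed groups: FDR-significant fraction stays near 0
        frac = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, size=(1000, 100))
            m = _em(X)
            labels = pd.Series(["a"] * 50 + ["b"] * 50, index=m.samples)
            degs = find_degs(m, labels, fc_cutoff=1.0)
            n_sig = degs.groupby("contrast")["adj_p"].apply(lambda p: (p < 0.05).sum()).max()
            frac.append(n_sig / 1000)
        assert np.mean(frac) <= 0.05

    def test_recovers_planted_degs(self):
        rng = np.random.default_rng(42)
        X = rng.normal(0, 1, size=(400, 200))
        X[:40, :100] += 1.5  # planted 1.5-sigma effect in group a
        m = _em(X)
        labels = pd.Series(["a"] * 100 + ["b"] * 100, index=m.samples)
        degs = find_degs(m, labels, fc_cutoff=1.0, alpha=0.1)
        found = set(significant_genes(degs))
        planted = {f"g{i}" for i in range(40)}
        assert len(found & planted) / 40 >= 0.9
        false = found - planted
        assert len(false) <= 0.1 * max(len(found), 1)

    def test_validation_errors(self):
        m = _em(np.random.default_rng(0).normal(size=(10, 6)))
        single = pd.Series(["a"] * 6, index=m.samples)
        with pytest.raises(ValueError, match="2 subtypes"):
            find_degs(m, single)
        tiny = pd.Series(["a", "a", "b", "b", "b", "b"], index=m.samples)
        with pytest.raises(ValueError, match="fewer than 3"):
            find_degs(m, tiny)


class TestPartitionSignatures:
    def test_gene_equal_to_signature_is_A_with_r_one(self):
        sig = pd.Series([1.0, 2.0, 3.0, 4.0], index=[f"s{i}" for i in range(4)])
        arr = np.vstack([sig.to_numpy(), -sig.to_numpy(), [5, 5, 5, 5]])
        m = _em(arr, genes=["up", "down", "flat"])
        with pytest.warns(UserWarning, match="flat"):
            out = partition_signatures(m, ["up", "down", "flat"], sig)
        assert out.genes_a == ["up"] and out.correlations["up"] == pytest.approx(1.0)
        assert out.genes_b == ["down"] and out.correlations["down"] == pytest.approx(-1.0)
        assert out.excluded == ["flat"]

    def test_signs_match_independent_correlation_oracle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 30))
        sig = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        m = _em(X)
        out = partition_signatures(m, m.genes, sig)
        for gene in m.genes:
            r = oracles.pearson_brute(m.values.loc[gene].to_numpy(), sig.to_numpy())
            assert (gene in out.genes_a) == (r > 0)
            assert out.correlations[gene] == pytest.approx(r, abs=1e-12)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 15))
        sig = pd.Series(rng.normal(size=15), index=[f"s{i}" for i in range(15)])
        m = _em(X)
        perm = rng.permutation(15)
        m2 = ExpressionMatrix(m.values.iloc[:, perm], m.unit)
        a = partition_signatures(m, m.genes, sig)
        b = partition_signatures(m2, m2.genes, sig)
        assert a.genes_a == b.genes_a and a.genes_b == b.genes_b


class TestEncodeClusterSignature:
    def test_ordinal_orders_by_immune_score(self):
        labels = pd.Series([0, 0, 1, 1, 2, 2], index=list("abcdef"))
        immune = pd.Series([5.0, 6.0, 1.0, 2.0, 9.0, 10.0], index=list("abcdef"))
        enc = encode_cluster_signature(labels, immune)
        assert enc.tolist() == [1.0, 1.0, 0.0, 0.0, 2.0, 2.0]
        ind = encode_cluster_signature(labels, immune, scheme="indicator")
        assert ind.tolist() == [0.0, 0.0, 0.0, 0.0, 1.0, 1.0]


class TestBoruta:
    def test_feature_identical_to_target_confirmed_constant_rejected(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 12))
        X[:, 0] = y  # perfect predictor
        X[:, 1] = 1.0  # constant
        sel = BorutaSelector(n_estimators=50, max_iter=30, random_state=0).fit(X, y)
        assert 0 in sel.confirmed_
        assert 1 in sel.rejected_

    def test_boruta_reduce_surface(self):
        rng = np.random.default_rng(5)
        n = 120
        y = pd.Series(rng.integers(0, 2, n), index=[f"s{i}" for i in range(n)])
        X = rng.normal(size=(10, n))
        X[0] += 2.0 * y.to_numpy()
        m = _em(X)
        kept = boruta_reduce(m, m.genes, y, max_iter=30, seed=1, n_estimators=50)
        assert "g0" in kept

    def test_fewer_samples_than_classes_fails(self):
        with pytest.raises(ValueError):
            BorutaSelector().fit(np.ones((1, 3)), np.array([0]))


class TestICIScore:
    def _scored(self, normalize=False):
        rng = np.random.default_rng(2)
        X = rng.gamma(2, 2, size=(30, 12))
        X[:10, :6] *= 5  # signature-A genes high in first 6 samples
        m = _em(np.log2(X + 1))
        sig = SignatureSet(
            genes_a=[f"g{i}" for i in range(10)],
            genes_b=[f"g{i}" for i in range(20, 30)],
            correlations=pd.Series(dtype=float),
        )
        return m, sig, ici_score(m, sig, normalize=normalize)

    def test_score_is_exactly_a_minus_b(self):
        _, _, table = self._scored()
        np.testing.assert_array_equal(
            table.table["ici_score"].to_numpy(),
            table.table["score_a"].to_numpy() - table.table["score_b"].to_numpy(),
        )

    def test_median_rule_with_ties_to_low(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        groups, med = median_split(scores)
        assert med == 2.5
        assert groups.tolist() == ["low", "low", "high", "high"]
        tied = pd.Series([1.0, 2.0, 2.0, 3.0], index=list("abcd"))
        g2, m2 = median_split(tied)
        assert m2 == 2.0
        assert g2.tolist() == ["low", "low", "low", "high"]

    def test_median_split_partitions_cohort(self):
        _, _, table = self._scored()
        counts = table.table["group"].value_counts()
        assert counts.sum() == len(table.table)
        assert set(counts.index) <= {"high", "low"}

    def test_raising_signature_a_expression_raises_score(self):
        m, sig, before = self._scored()
        boosted = m.values.copy()
        boosted.loc[[f"g{i}" for i in range(10)], "s11"] += 5.0
        after = ici_score(ExpressionMatrix(boosted, m.unit), sig)
        b = before.table.set_index("sample_id").loc["s11", "ici_score"]
        a = after.table.set_index("sample_id").loc["s11", "ici_score"]
        assert a > b

    def test_empty_signature_fails(self, tiny_expression):
        sig = SignatureSet(genes_a=["G1"], genes_b=[], correlations=pd.Series(dtype=float))
        with pytest.raises(ValueError, match="non-empty"):
            ici_score(tiny_expression, sig)
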