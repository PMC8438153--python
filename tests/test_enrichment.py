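import numpy as np
import pandas as pd
import pytest

import oracles
from icipattern import (
    ExpressionMatrix,
    GeneSetCollection,
    estimate_scores,
    ssgsea_scores,
)


class TestClosedForms:
    def test_single_top_gene_alpha0_gives_half_n(self, tiny_expression):
        # sum_i (1 - (i-1)/(N-1)) = N/2 for the top-ranked gene
        es = ssgsea_scores(
            tiny_expression, GeneSetCollection({"top": ["G1"]}), alpha=0.0, normalize=False
        )
        assert es.scores.loc["top", "s1"] == pytest.approx(2.0)

    def test_single_bottom_gene_alpha0_gives_minus_half_n(self, tiny_expression):
        es = ssgsea_scores(
            tiny_expression, GeneSetCollection({"bot": ["G4"]}), alpha=0.0, normalize=False
        )
        assert es.scores.loc["bot", "s1"] == pytest.approx(-2.0)


class TestOracleEquivalence:
    def test_matches_brute_force_running_sum(self, random_expression, gene_sets):
        es = ssgsea_scores(random_expression, gene_sets, alpha=0.25, normalize=False)
        for name, members in gene_sets:
            for j, s in enumerate(random_expression.samples):
                expected = oracles.ssgsea_brute(
                    random_expression.values[s].to_numpy(),
                    random_expression.genes,
                    set(members),
                    0.25,
                )
                assert es.scores.loc[name, s] == pytest.approx(expected, abs=1e-10)

    def test_ties_handled_by_midranks(self):
        df = pd.DataFrame({"s": [3.0, 3.0, 1.0, 0.5]}, index=list("ABCD"))
        m = ExpressionMatrix(df, "TPM")
        es = ssgsea_scores(m, GeneSetCollection({"x": ["A", "C"]}), alpha=0.5, normalize=False)
        expected = oracles.ssgsea_brute(df["s"].to_numpy(), list("ABCD"), {"A", "C"}, 0.5)
        assert es.scores.loc["x", "s"] == pytest.approx(expected, abs=1e-12)


class TestInvariances:
    def test_monotone_transform_invariance_at_alpha0(self, random_expression, gene_sets):
        a = ssgsea_scores(random_expression, gene_sets, alpha=0.0, normalize=False)
        transformed = ExpressionMatrix(np.log1p(random_expression.values) ** 3, "TPM")
        b = ssgsea_scores(transformed, gene_sets, alpha=0.0, normalize=False)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_sample_and_set_order_permutation_invariance(self, random_expression, gene_sets):
        base = ssgsea_scores(random_expression, gene_sets, alpha=0.25, normalize=False)
        shuffled = ExpressionMatrix(random_expression.values.iloc[:, ::-1], "TPM")
        reordered_sets = GeneSetCollection(dict(reversed(list(gene_sets.sets.items()))))
        other = ssgsea_scores(shuffled, reordered_sets, alpha=0.25, normalize=False)
        pd.testing.assert_frame_equal(
            base.scores.loc[other.scores.index, other.scores.columns][base.scores.columns]
            .sort_index(),
            other.scores[base.scores.columns].sort_index(),
        )

    def test_normalization_divides_by_range(self, random_expression, gene_sets):
        raw = ssgsea_scores(random_expression, gene_sets, alpha=0.25, normalize=False)
        norm = ssgsea_scores(random_expression, gene_sets, alpha=0.25, normalize=True)
        rng_ = raw.scores.to_numpy().max() - raw.scores.to_numpy().min()
        np.testing.assert_allclose(norm.scores.to_numpy(), raw.scores.to_numpy() / rng_)


class TestErrors:
    def test_zero_overlap_set_names_set(self, tiny_expression):
        with pytest.raises(ValueError, match="nope"):
            ssgsea_scores(tiny_expression, GeneSetCollection({"nope": ["ZZZ"]}))

    def test_full_universe_set_rejected(self, tiny_expression):
        with pytest.raises(ValueError, match="universe"):
            ssgsea_scores(tiny_expression, GeneSetCollection({"all": tiny_expression.genes}))


class TestEstimateScores:
    def test_overexpressed_immune_set_scores_higher(self):
        rng = np.random.default_rng(0)
        base = rng.gamma(2, 5, size=(30, 2))
        base[:10, 0] *= 20  # sample 0 overexpresses the immune set
        m = ExpressionMatrix(
            pd.DataFrame(base, index=[f"g{i}" for i in range(30)], columns=["hot", "flat"]), "TPM"
        )
        immune = [f"g{i}" for i in range(10)]
        stroma = [f"g{i}" for i in range(20, 30)]
        es = estimate_scores(m, immune, stroma)
        assert es.scores.loc["ImmuneScore", "hot"] > es.scores.loc["ImmuneScore", "flat"]

    def test_identical_sets_identical_rows(self, random_expression):
        genes = random_expression.genes[:8]
        es = estimate_scores(random_expression, genes, genes)
        np.testing.assert_allclose(
            es.scores.loc["ImmuneScore"].to_numpy(), es.scores.loc["StromaScore"].to_numpy()
        )

    def test_planted_hot_group_separates(self):
        from icipattern import SyntheticCohortSpec, simulate_cohort
        from icipattern.survival import rank_tests

        spec = SyntheticCohortSpec(
            n_samples=200, n_genes=200, n_cell_types=5, n_latent_groups=2,
            hazard_ratio_per_group=(1.0, 2.0), mutation_rate_per_group=(5.0, 5.0),
            n_batches=1, seed=21,
        )
        c = simulate_cohort(spec)
        es = estimate_scores(c.expression, c.truth["immune_set"], c.truth["stromal_set"])
        hot = c.truth["group"] == 0
        imm = es.scores.loc["ImmuneScore"]
        assert imm[hot].mean() > imm[~hot].mean()
        _, p = rank_tests(imm.to_numpy(), hot.to_numpy())
        assert p < 0.01
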