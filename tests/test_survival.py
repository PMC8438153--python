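import itertools

import numpy as np
import pandas as pd
import pytest

import oracles
from icipattern import (
    MutationTable,
    gene_mutation_contrast,
    kaplan_meier,
    pearson,
    rank_tests,
    response_rate_compare,
    stratified_km,
    tmb_and_split,
)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        fit = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1], ["g"] * 3)
        curve = fit.curves["g"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [1, 1, 0, 1, 1, 0]
        fit = kaplan_meier(times, events, ["a"] * 3 + ["b"] * 3)
        assert fit.statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.df == 1

    def test_matches_brute_force_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            times = rng.exponential(5, 6).round(2) + 0.1
            events = rng.integers(0, 2, 6)
            groups = np.array(["a", "a", "a", "b", "b", "b"])
            if events.sum() == 0:
                continue
            fit = kaplan_meier(times, events, groups)
            expected = oracles.logrank_brute(times, events, groups)
            assert fit.statistic == pytest.approx(expected, abs=1e-10)

    def test_no_censoring_equals_empirical_survivor_function(self):
        rng = np.random.default_rng(1)
        times = rng.exponential(3, 40) + 0.01
        fit = kaplan_meier(times, np.ones(40, dtype=int), ["g"] * 40)
        curve = fit.curves["g"].set_index("time")["survival"]
        for t, s in oracles.km_survival_brute(times, np.ones(40, dtype=int)).items():
            assert curve.loc[t] == pytest.approx(s, abs=1e-12)
            assert curve.loc[t] == pytest.approx((times > t).mean(), abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError, match="positive"):
            kaplan_meier([0.0, 1.0], [1, 1], ["a", "a"])
        with pytest.raises(ValueError, match="events"):
            kaplan_meier([1.0, 2.0], [1, 2], ["a", "a"])


class TestRankTests:
    def test_identical_groups_zero_statistic_convention(self):
        stat, p = rank_tests([1.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert (stat, p) == (0.0, 1.0)
        stat, p = rank_tests([2.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert (stat, p) == (0.0, 1.0)

    def test_separated_groups_attain_extreme_rank_sum(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        all_sums = oracles.ranksum_all_assignments(values, 3)
        # group (1,2,3) attains the minimum possible rank sum => U = 0,
        # the extreme value over all 20 assignments
        stat, p = rank_tests(values, ["a"] * 3 + ["b"] * 3)
        u_from_ranksum = min(all_sums) - 3 * 4 / 2
        assert stat == pytest.approx(u_from_ranksum)
        assert p < 0.1

    def test_kruskal_for_three_groups(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20), rng.normal(4, 1, 20)])
        groups = np.repeat(["a", "b", "c"], 20)
        stat, p = rank_tests(vals, groups)
        assert p < 1e-6


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        r, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = pearson(x, y)
        assert r == pytest.approx(oracles.pearson_brute(x, y), abs=1e-12)

    def test_constant_vector_fails(self):
        with pytest.raises(ValueError, match="constant"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _mut(counts: dict[str, int], genes=None) -> MutationTable:
    rows = []
    rng = np.random.default_rng(0)
    pool = genes or ["X", "Y", "Z"]
    for s, k in counts.items():
        for j in range(k):
            rows.append((s, pool[j % len(pool)], "Missense_Mutation"))
    return MutationTable(
        pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "variant_class"]),
        covered_samples=list(counts),
    )


class TestTMB:
    def test_counts_and_median_split(self):
        mt = _mut({"a": 1, "b": 2, "c": 3, "d": 4})
        ms = tmb_and_split(mt, ["a", "b", "c", "d"])
        assert ms.tmb.tolist() == [1, 2, 3, 4]
        assert ms.tmb_group.tolist() == ["low", "low", "high", "high"]

    def test_uncovered_sample_excluded_with_warning(self):
        mt = _mut({"a": 3, "b": 1})
        with pytest.warns(UserWarning, match="coverage"):
            ms = tmb_and_split(mt, ["a", "b", "zzz"])
        assert "zzz" not in ms.tmb.index
        assert ms.excluded_samples == ["zzz"]

    def test_poisson_groups_separate(self):
        rng = np.random.default_rng(3)
        counts = {f"h{i}": int(rng.poisson(15)) for i in range(100)}
        counts.update({f"l{i}": int(rng.poisson(5)) for i in range(100)})
        mt = _mut(counts)
        ms = tmb_and_split(mt, list(counts))
        labels = ["h"] * 100 + ["l"] * 100
        _, p = rank_tests(ms.tmb.to_numpy(), labels)
        assert p < 0.01


class TestGeneMutationContrast:
    def test_balanced_table_p_one(self):
        mt = _mut({"a": 1, "b": 1, "c": 1, "d": 1}, genes=["G"])
        grp = pd.Series(["hi", "hi", "lo", "lo"], index=["a", "b", "c", "d"])
        # 1 mutated + 1 unmutated per group: add two uncovered-free samples
        mt2 = MutationTable(mt.records, covered_samples=["a", "b", "c", "d", "e", "f"])
        grp2 = pd.Series(["hi", "lo", "hi", "lo", "hi", "lo"], index=list("abcdef"))
        out = gene_mutation_contrast(mt2, grp2)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        rows = [(f"h{i}", "G", "m") for i in range(10)]
        recs = pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "variant_class"])
        covered = [f"h{i}" for i in range(10)] + [f"l{i}" for i in range(10)]
        mt = MutationTable(recs, covered_samples=covered)
        grp = pd.Series(["hi"] * 10 + ["lo"] * 10, index=covered)
        out = gene_mutation_contrast(mt, grp)
        assert out.loc[0, "p"] == pytest.approx(oracles.fisher_brute(10, 0, 0, 10), abs=1e-10)

    def test_planted_driver_detected_with_power(self):
        hits = 0
        n_sims = 20
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            rows = []
            covered = []
            for i in range(150):
                s = f"h{i}"
                covered.append(s)
                if rng.random() < 0.3:
                    rows.append((s, "DRV", "m"))
            for i in range(150):
                s = f"l{i}"
                covered.append(s)
                if rng.random() < 0.1:
                    rows.append((s, "DRV", "m"))
            mt = MutationTable(
                pd.DataFrame(rows, columns=["sample_id", "gene_symbol", "variant_class"]),
                covered_samples=covered,
            )
            grp = pd.Series(["hi"] * 150 + ["lo"] * 150, index=covered)
            out = gene_mutation_contrast(mt, grp)
            hits += out.set_index("gene").loc["DRV", "p"] < 0.05
        assert hits >= 0.9 * n_sims


class TestStratifiedKM:
    def test_identical_groups_statistic_zero_and_partition(self):
        times = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        events = np.tile([1, 1, 0, 1], 4)
        tmb = np.repeat(["high", "low"], 8)
        ici = np.tile(np.repeat(["high", "low"], 4), 2)
        res = stratified_km(times, events, tmb, ici)
        assert res.overall.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.overall.df == 3
        assert sum(res.strata_sizes.values()) == 16

    def test_only_latent_group_drives_hazard_factorial(self):
        # ICI contrast should persist within TMB strata; TMB contrast stays null
        from icipattern import SyntheticCohortSpec, simulate_cohort
        from icipattern.signatures import median_split

        within_sig, tmb_null = 0, 0
        n_sims = 10
        for seed in range(n_sims):
            spec = SyntheticCohortSpec(
                n_samples=400, n_genes=60, n_cell_types=3, n_latent_groups=2,
                hazard_ratio_per_group=(1.0, 2.5),
                mutation_rate_per_group=(10.0, 10.0),  # TMB carries no signal
                de_genes_per_group=0, n_batches=1, seed=seed,
            )
            c = simulate_cohort(spec)
            ct = c.clinical.indexed()
            ms = tmb_and_split(c.mutations, list(ct.index))
            ici = np.where(c.truth["group"] == 0, "high", "low")
            res = stratified_km(
                ct["os_time"], ct["os_event"], ms.tmb_group.reindex(ct.index).to_numpy(), ici
            )
            tmb_fit = kaplan_meier(ct["os_time"], ct["os_event"], ms.tmb_group.reindex(ct.index).to_numpy())
            within_sig += all(f.p < 0.05 for f in res.within_stratum.values())
            tmb_null += tmb_fit.p >= 0.05
        assert within_sig > n_sims / 2
        assert tmb_null > n_sims / 2


class TestResponseRates:
    @staticmethod
    def _resp(hi_cr, hi_n, lo_cr, lo_n):
        idx = [f"s{i}" for i in range(hi_n + lo_n)]
        resp = ["CR"] * hi_cr + ["PD"] * (hi_n - hi_cr) + ["PR"] * lo_cr + ["SD"] * (lo_n - lo_cr)
        grp = ["high"] * hi_n + ["low"] * lo_n
        return pd.Series(resp, index=idx), pd.Series(grp, index=idx)

    def test_rates_from_counts(self):
        resp, grp = self._resp(10, 20, 5, 20)
        out = response_rate_compare(resp, grp)
        assert out["rates"]["high"] == pytest.approx(0.5)
        assert out["rates"]["low"] == pytest.approx(0.25)

    def test_identical_distributions_p_near_one(self):
        resp, grp = self._resp(10, 20, 10, 20)
        out = response_rate_compare(resp, grp)
        assert out["fisher_p"] > 0.99

    def test_score_linked_response_detected(self):
        detections = 0
        n_sims = 20
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            n = 150
            score = rng.normal(0, 1, n)
            p_resp = 1 / (1 + np.exp(-1.5 * score))
            resp = np.where(rng.random(n) < p_resp, "PR", "PD")
            idx = [f"s{i}" for i in range(n)]
            groups, _ = median_split_series(score, idx)
            out = response_rate_compare(
                pd.Series(resp, index=idx), groups, pd.Series(score, index=idx)
            )
            detections += out["responder_ranksum_p"] < 0.05
        assert detections >= 0.8 * n_sims


def median_split_series(score, idx):
    from icipattern import median_split

    return median_split(pd.Series(score, index=idx))
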