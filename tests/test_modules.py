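import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from socint.modules import (FLAT_MODULE_ID, SharedModuleSet, _jackknife_ci,
                            assign_profiles, assign_to_module,
                            enumerate_module_profiles, module_counts,
                            module_enrichment, negate_module_id,
                            permuted_null_counts, shared_gene_counts,
                            shared_modules)


class TestEnumeration:
    def test_81_distinct_profiles(self):
        mods = enumerate_module_profiles()
        assert len(mods) == 81
        assert len({m.id for m in mods}) == 81

    def test_closed_under_negation_with_unique_self_inverse(self):
        ids = {m.id for m in enumerate_module_profiles()}
        assert {negate_module_id(m) for m in ids} == ids
        self_inverse = [m for m in ids if negate_module_id(m) == m]
        assert self_inverse == [FLAT_MODULE_ID]

    def test_contains_extreme_and_worked_profiles(self):
        ids = {m.id for m in enumerate_module_profiles()}
        for prof in ("0,0,0,0,0", "0,1,2,3,4", "0,-1,-2,-3,-4",
                     "0,0,-1,-2,-3", "0,0,1,2,3"):
            assert prof in ids

    def test_steps_bounded(self):
        for m in enumerate_module_profiles():
            assert m.values[0] == 0
            assert set(np.diff(m.values)) <= {-1, 0, 1}


class TestAssignment:
    def test_exact_module_profile_gets_itself(self):
        for m in enumerate_module_profiles():
            if m.id == FLAT_MODULE_ID:
                continue
            mid, corr = assign_to_module(np.array(m.values, float))
            assert mid == m.id
            assert corr == pytest.approx(1.0)

    def test_noisy_ramp_matches_brute_force(self):
        profile = np.array([0, 0.9, 2.1, 2.9, 4.2])
        mid, _ = assign_to_module(profile)
        # independent oracle: per-module scipy pearson
        best, best_r = None, -2
        for m in enumerate_module_profiles():
            if m.id == FLAT_MODULE_ID:
                continue
            r = stats.pearsonr(profile, m.values)[0]
            if r > best_r:
                best, best_r = m.id, r
        assert mid == best == "0,1,2,3,4"

    def test_vectorized_assignment_matches_per_gene_oracle(self):
        rng = np.random.default_rng(2)
        profs = rng.normal(0, 1.5, size=(50, 5))
        profs[:, 0] = 0
        table = assign_profiles(pd.DataFrame(profs))
        for i in range(50):
            mid, corr = assign_to_module(profs[i])
            assert table.iloc[i]["module_id"] == mid

    def test_flat_epsilon_rule(self):
        mid, corr = assign_to_module(np.array([0, 1e-12, 0, 0, 0]))
        assert mid == FLAT_MODULE_ID
        assert np.isnan(corr)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=0.1, max_value=50),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        prof = np.concatenate([[0.0], rng.normal(0, 2, 4)])
        if np.var(prof) < 1e-6:
            return
        base, _ = assign_to_module(prof)
        scaled, _ = assign_to_module(prof * c)
        assert base == scaled


class TestPermutationNull:
    def test_null_counts_conserve_genes(self):
        rng = np.random.default_rng(1)
        means = pd.DataFrame(np.exp(rng.normal(2, 1, (60, 5))))
        null = permuted_null_counts(means, n_perm=50, seed=0)
        assert null.sum() == pytest.approx(60)

    def test_flat_genes_stay_flat_under_permutation(self):
        means = pd.DataFrame(np.full((10, 5), 7.0))
        null = permuted_null_counts(means, n_perm=20, seed=0)
        mods = [m.id for m in enumerate_module_profiles()]
        assert null[mods.index(FLAT_MODULE_ID)] == pytest.approx(10)

    def test_noise_null_close_to_observed_occupancy(self):
        rng = np.random.default_rng(5)
        n = 1000
        means = pd.DataFrame(np.exp(rng.normal(2, 1, (n, 5))),
                             index=[f"g{i}" for i in range(n)])
        arr = means.to_numpy()
        prof = np.log2((arr + 1) / (arr[:, :1] + 1))
        prof[:, 0] = 0
        obs = module_counts(assign_profiles(pd.DataFrame(prof,
                                                         index=means.index)))
        null = permuted_null_counts(means, n_perm=200, seed=1)
        tv = 0.5 * np.abs(obs / n - null / n).sum()
        assert tv < 0.15


class TestEnrichment:
    def test_observed_equal_to_null_never_significant(self):
        null = np.full(81, 500 / 81)
        observed = np.zeros(81)
        observed[:80] = 6
        observed[80] = 500 - 480
        report = module_enrichment(observed, observed.astype(float), 500)
        assert not report["significant"].any()

    def test_strong_excess_detected(self):
        observed = np.zeros(81)
        null = np.full(81, (500 - 50) / 80.0)
        null[0] = 5.0
        observed[0] = 50
        rest = 450
        observed[1:] = rest // 80
        observed[1:1 + rest % 80] += 1
        report = module_enrichment(observed, null, 500)
        row = report.iloc[0]
        expected_p = stats.binom.sf(49, 500, 5 / 500)
        assert row["p_value"] == pytest.approx(expected_p)
        assert expected_p < 0.05 / 81
        assert bool(row["significant"])

    def test_alpha_boundary_is_strict(self):
        observed = np.zeros(81)
        observed[0] = 10
        null = np.full(81, 0.0)
        null[0] = 5.0
        n = 10
        p = float(stats.binom.sf(9, 10, 0.5))
        report = module_enrichment(observed, null, n, alpha=p * 81)
        assert report.iloc[0]["p_value"] == pytest.approx(p)
        assert not bool(report.iloc[0]["significant"])

    def test_zero_null_mean_uses_probability_floor(self):
        observed = np.zeros(81)
        observed[3] = 100
        null = np.zeros(81)
        report = module_enrichment(observed, null, 100)
        row = report.iloc[3]
        assert 0 < row["p_value"] < 1e-10
        assert bool(row["significant"])


class TestSharedModules:
    def test_parallel_and_antiparallel_pairs(self):
        a = {"0,1,2,3,4", "0,0,-1,-2,-3"}
        b = {"0,1,2,3,4", "0,0,1,2,3", "0,1,1,1,1"}
        sh = shared_modules(a, b)
        assert ("0,1,2,3,4", "0,1,2,3,4", "parallel") in sh.pairs
        assert ("0,0,-1,-2,-3", "0,0,1,2,3", "antiparallel") in sh.pairs
        assert len(sh.pairs) == 2

    def test_disjoint_non_inverse_sets_share_nothing(self):
        assert shared_modules({"0,1,2,3,4"}, {"0,1,1,1,1"}).pairs == []

    def test_flat_module_only_parallel_never_doubled(self):
        sh = shared_modules({FLAT_MODULE_ID}, {FLAT_MODULE_ID})
        assert sh.pairs == [(FLAT_MODULE_ID, FLAT_MODULE_ID, "parallel")]

    def test_gene_counting_fraction(self):
        assign_a = pd.DataFrame({"module_id": ["0,1,2,3,4"] * 4
                                 + ["0,0,0,0,0"] * 6,
                                 "correlation": 1.0},
                                index=[f"g{i}" for i in range(10)])
        assign_b = assign_a.copy()
        sh = SharedModuleSet([("0,1,2,3,4", "0,1,2,3,4", "parallel")])
        counts = shared_gene_counts(assign_a, assign_b, sh)
        assert counts["a"]["count"] == 4
        assert counts["a"]["fraction"] == pytest.approx(0.4)

    def test_no_shared_modules_counts_zero(self):
        assign = pd.DataFrame({"module_id": ["0,1,2,3,4"],
                               "correlation": 1.0}, index=["g0"])
        counts = shared_gene_counts(assign, assign, SharedModuleSet([]))
        assert counts["a"]["count"] == 0


class TestJackknife:
    def test_closed_form_se(self):
        est = _jackknife_ci(np.array([10.0, 12.0, 14.0]), full_value=12.0)
        assert est.se == pytest.approx(np.sqrt(2 / 3 * 8))
        assert est.estimate == pytest.approx(12.0)

    def test_equal_replicates_zero_width(self):
        est = _jackknife_ci(np.array([0.4, 0.4, 0.4, 0.4]), full_value=0.4)
        assert est.se == 0
        assert est.ci_low == est.ci_high == est.estimate

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(0)
        est = _jackknife_ci(rng.random(8), full_value=0.5)
        assert est.ci_low <= est.estimate <= est.ci_high
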