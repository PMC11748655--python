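"""Statistical testing battery: t-tests, effect sizes, adaptive FDR, alpha."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycodacomp import (
    GlycanTable,
    SimulationSpec,
    StudyDesign,
    TransformOptions,
    bonferroni_guard,
    clr,
    cohens_d,
    get_alphaN,
    get_differential_expression,
    get_time_series,
    glycanova,
    grouped_two_stage_bh,
    hotelling_t2,
    levene,
    simulate_profiles,
    tost_equivalence,
    two_stage_bh,
    welch_or_paired_t,
)

from conftest import random_composition_table


def bky_oracle(pvals, alpha):
    """Literal two-stage Benjamini-Krieger-Yekutieli definition."""
    p = np.asarray(pvals, float)
    m = len(p)

    def step_up(pv, level, m_eff):
        order = np.argsort(pv)
        sorted_p = pv[order]
        k = 0
        for i in range(m):
            if sorted_p[i] <= (i + 1) * level / m_eff:
                k = i + 1
        reject = np.zeros(m, bool)
        reject[order[:k]] = True
        return reject

    alpha_prime = alpha / (1 + alpha)
    stage1 = step_up(p, alpha_prime, m)
    m0 = m - stage1.sum()
    if m0 == 0:
        return np.ones(m, bool)
    return step_up(p, alpha_prime, m0)


class TestAlphaN:
    def test_printed_thresholds(self):
        assert round(get_alphaN(8), 3) == 0.072
        assert round(get_alphaN(31), 3) == 0.048

    def test_non_increasing_in_n(self):
        alphas = [get_alphaN(n) for n in range(8, 200)]
        assert all(a >= b for a, b in zip(alphas, alphas[1:]))

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            get_alphaN(1)


class TestTTestsAndEffects:
    def test_hand_computed_welch_and_d(self):
        x, y = [1, 2, 3], [2, 3, 4]
        t, df, p = welch_or_paired_t(np.array(x), np.array(y))
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert cohens_d(np.array(x), np.array(y)) == pytest.approx(-1.0)

    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0])
        t, _, p = welch_or_paired_t(x, x)
        assert t == 0.0 and p == pytest.approx(1.0)
        assert cohens_d(x, x) == 0.0

    def test_paired_zero_sd_flagged_infinite(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x + 1.0, x, paired=True) == np.inf


class TestTost:
    def test_equal_samples_equivalent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 0.05, 30)
        assert tost_equivalence(x, x + rng.normal(0, 0.05, 30), bounds=0.5) < 0.01

    def test_wide_separation_not_equivalent(self):
        x = np.zeros(10) + np.arange(10) * 0.01
        assert tost_equivalence(x, x + 5.0, bounds=0.5) > 0.95

    def test_zero_bounds_degenerate(self):
        assert tost_equivalence(np.arange(5.0), np.arange(5.0), bounds=0.0) == 1.0


class TestLevene:
    def test_tenfold_sd_detected(self):
        rng = np.random.default_rng(1)
        assert levene(rng.normal(0, 1, 40), rng.normal(0, 10, 40)) < 1e-6

    def test_equal_variance_not_flagged(self):
        rng = np.random.default_rng(2)
        assert levene(rng.normal(0, 1, 40), rng.normal(0, 1, 40)) > 0.1

    def test_constant_inputs_degenerate(self):
        assert np.isnan(levene(np.ones(5), np.ones(5)))


class TestTwoStageBH:
    def test_spec_vector_matches_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.5])
        _, reject = two_stage_bh(p, alpha=0.05)
        assert np.array_equal(reject, bky_oracle(p, 0.05))

    def test_all_ones_no_rejections(self):
        _, reject = two_stage_bh(np.ones(6), alpha=0.05)
        assert not reject.any()

    def test_single_p_reduces_to_two_stage_comparison(self):
        for p in (0.01, 0.04, 0.047, 0.06, 0.5):
            _, reject = two_stage_bh(np.array([p]), alpha=0.05)
            assert reject[0] == bky_oracle(np.array([p]), 0.05)[0]

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            m = rng.integers(1, 11)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            _, reject = two_stage_bh(p, alpha=0.05)
            assert np.array_equal(reject, bky_oracle(p, 0.05))


class TestGroupedBH:
    def correlated_table(self, rho_within: float, seed=5, n_samples=24,
                         n_groups=3, per_group=5):
        rng = np.random.default_rng(seed)
        rows, groups = [], {}
        for g in range(n_groups):
            shared = rng.normal(0, 1, n_samples)
            for k in range(per_group):
                noise = rng.normal(0, 1, n_samples)
                w = np.sqrt(rho_within)
                rows.append(w * shared + np.sqrt(1 - rho_within) * noise)
                groups[f"G{g}_{k}"] = f"fam{g}"
        ids = list(groups)
        df = pd.DataFrame(rows, index=ids,
                          columns=[f"S{j}" for j in range(n_samples)])
        table = GlycanTable(df, scale="transformed")
        pvals = pd.Series(np.random.default_rng(seed + 1).random(len(ids)), index=ids)
        return pvals, groups, table

    def test_gate_passes_for_correlated_groups(self):
        pvals, groups, table = self.correlated_table(0.8)
        _, _, gate, (intra, inter) = grouped_two_stage_bh(pvals, groups, table)
        assert gate
        assert intra > 0.5 and intra > 3 * abs(inter)

    def test_independent_features_fall_back_to_plain(self):
        pvals, groups, table = self.correlated_table(0.0, seed=9)
        p_adj, _, gate, _ = grouped_two_stage_bh(pvals, groups, table)
        assert not gate
        plain, _ = two_stage_bh(pvals.to_numpy(), 0.05)
        assert np.allclose(p_adj.to_numpy(), plain)

    def test_single_group_gate_fails(self):
        pvals, groups, table = self.correlated_table(0.8, n_groups=1)
        _, _, gate, _ = grouped_two_stage_bh(pvals, groups, table)
        assert not gate


class TestBonferroniGuard:
    def test_overwhelming_significance_triggers_bonferroni(self):
        p = np.full(20, 1e-4)
        p[0] = 0.9
        adj, _ = two_stage_bh(p, 0.05)
        guarded, tripped = bonferroni_guard(p, adj, alpha=0.05)
        assert tripped
        assert np.allclose(guarded, np.minimum(p * 20, 1.0))

    def test_moderate_significance_untouched(self):
        p = np.concatenate([np.full(10, 1e-4), np.full(10, 0.8)])
        adj, _ = two_stage_bh(p, 0.05)
        guarded, tripped = bonferroni_guard(p, adj, alpha=0.05)
        assert not tripped and np.array_equal(guarded, adj)

    def test_exact_boundary_untouched(self):
        p_adj = np.concatenate([np.zeros(9), [1.0]])  # exactly 90% significant
        _, tripped = bonferroni_guard(p_adj, p_adj, alpha=0.05)
        assert not tripped


class TestDifferentialExpression:
    def test_recovers_planted_fourfold_effects(self):
        spec = SimulationSpec(n_per_group=(20, 20), seed=42,
                              perturbed_up=(1, 5, 9, 13, 17), perturbed_down=(),
                              multiplier_up=4.0)
        table, design, truth = simulate_profiles(spec)
        res = get_differential_expression(
            table, design, transform_opts=TransformOptions(method="clr", seed=1))
        perturbed = [f for f in truth.index[truth["perturbed"]]]
        hits = res.table.loc[perturbed]
        assert hits["significant"].sum() >= 4
        assert (hits["delta"] > 0).all()  # direction matches the planted sign

    def test_identical_groups_yield_no_calls(self):
        base = random_composition_table(10, 8, seed=6)
        dup = base.data.copy()
        dup.columns = [f"S{j}" for j in range(8)]
        mirrored = pd.concat([base.data, dup.set_axis([f"T{j}" for j in range(8)], axis=1)],
                             axis=1)
        table = GlycanTable(mirrored, scale="raw_intensity")
        design = StudyDesign(group_of={**{f"S{j}": "A" for j in range(8)},
                                       **{f"T{j}": "B" for j in range(8)}})
        res = get_differential_expression(
            table, design, transform_opts=TransformOptions(method="clr", scale="none",
                                                           gamma=0.0))
        assert res.table["significant"].sum() == 0
        assert (res.table["p"] > 0.99).all()

    def test_paired_constant_shift_has_smallest_p(self):
        # build in log2 space: subject-matched profiles with per-pair noise,
        # plus a +1 log2 shift on G2 in group B. Closure spreads a -1/8 shift
        # over the other features; the pair noise (sd 0.05) dwarfs it, so G2
        # must dominate the paired test.
        rng = np.random.default_rng(12)
        z_a = rng.normal(0, 1, size=(8, 10))
        z_b = z_a + rng.normal(0, 0.05, size=(8, 10))
        z_b[2] += 1.0
        ids = [f"G{i}" for i in range(8)]
        df = pd.concat([pd.DataFrame(2.0 ** z_a, index=ids,
                                     columns=[f"S{j}" for j in range(10)]),
                        pd.DataFrame(2.0 ** z_b, index=ids,
                                     columns=[f"T{j}" for j in range(10)])], axis=1)
        table = GlycanTable(df, scale="raw_intensity")
        group_of = {**{f"S{j}": "A" for j in range(10)}, **{f"T{j}": "B" for j in range(10)}}
        pair_of = {**{f"S{j}": f"u{j}" for j in range(10)}, **{f"T{j}": f"u{j}" for j in range(10)}}
        design = StudyDesign(group_of=group_of, paired=True, pair_of=pair_of)
        res = get_differential_expression(
            table, design, paired=True,
            transform_opts=TransformOptions(method="clr", scale="none", gamma=0.0))
        assert res.table["p"].idxmin() == "G2"

    def test_three_groups_redirected(self):
        table = random_composition_table(5, 6, seed=1)
        design = StudyDesign(group_of={"S0": "A", "S1": "A", "S2": "B",
                                       "S3": "B", "S4": "C", "S5": "C"})
        with pytest.raises(ValueError, match="glycanova"):
            get_differential_expression(table, design)


class TestGlycanova:
    def three_group_design(self, n=6):
        labels = {}
        for j in range(3 * n):
            labels[f"S{j}"] = ["A", "B", "C"][j // n]
        return StudyDesign(group_of=labels)

    def test_null_simulation_no_rejections(self):
        table = random_composition_table(10, 18, seed=30)
        res = glycanova(table, self.three_group_design(),
                        transform_opts=TransformOptions(method="clr", scale="none",
                                                        gamma=0.0))
        assert res.table["significant"].sum() == 0

    def test_shifted_group_isolated_by_tukey(self):
        table = random_composition_table(8, 18, seed=31, sigma=0.1)
        df = table.data.copy()
        c_samples = [f"S{j}" for j in range(12, 18)]
        df.loc["G0", c_samples] = df.loc["G0", c_samples] * 6.0
        table = GlycanTable(df, scale="raw_intensity")
        res = glycanova(table, self.three_group_design(),
                        transform_opts=TransformOptions(method="clr", scale="none",
                                                        gamma=0.0))
        assert res.table["p"].idxmin() == "G0"
        assert res.table.loc["G0", "significant"]
        tuk = res.posthoc["G0"]
        involving_c = tuk[(tuk["group1"] == "C") | (tuk["group2"] == "C")]
        assert involving_c["reject"].all()

    def test_two_groups_redirected(self):
        table = random_composition_table(5, 4, seed=2)
        design = StudyDesign(group_of={"S0": "A", "S1": "A", "S2": "B", "S3": "B"})
        with pytest.raises(ValueError, match="get_differential_expression"):
            glycanova(table, design)


class TestHotelling:
    def test_identical_groups_zero(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 3))
        res = hotelling_t2(a, a.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.mahalanobis == pytest.approx(0.0, abs=1e-9)

    def test_univariate_reduces_to_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, (10, 1))
        b = rng.normal(1, 1, (12, 1))
        res = hotelling_t2(a, b)
        t, p = stats.ttest_ind(a.ravel(), b.ravel(), equal_var=True)[:2]
        assert res.t2 == pytest.approx(t ** 2)
        assert res.p == pytest.approx(p)

    def test_singular_covariance_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(5, 2))
        a = np.hstack([a, a[:, :1]])  # third column duplicates the first
        b = a + 1.0
        res = hotelling_t2(a, b)
        assert res.singular


class TestTimeSeries:
    def test_perfect_line(self):
        t = np.arange(10.0)
        slope, F, p = get_time_series(2 * t + np.random.default_rng(0).normal(0, 1e-8, 10), t)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert p < 1e-10

    def test_constant_response(self):
        slope, F, p = get_time_series(np.full(6, 3.0), np.arange(6.0))
        assert slope == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_timepoints_flagged(self):
        slope, F, p = get_time_series(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        assert np.isnan(p)
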