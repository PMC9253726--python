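"""Association statistics against enumeration and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lemnaclock import (
    PanelSimSpec,
    compact_letters,
    deming_fit,
    holm_adjust,
    pairwise_wilcoxon,
    panel_association,
    pearson_test,
    simulate_strain_panel,
    wilcoxon_rank_sum,
)


def enumeration_wilcoxon(a, b):
    """Independent oracle: full enumeration of all rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n, n_a = len(pooled), len(a)
    w_obs = ranks[:n_a].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n_a)]
    total = len(sums)
    p_le = sum(s <= w_obs + 1e-9 for s in sums) / total
    p_ge = sum(s >= w_obs - 1e-9 for s in sums) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        r, p, n = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12
        assert n == 10

    def test_symmetric_v_shape_gives_zero_correlation(self):
        r, p, _ = pearson_test([-1.0, 0.0, 1.0], [1.0, 0.0, 1.0])
        assert r == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example_matches_t_cdf(self):
        """x=(1..5), y=(2,1,4,3,5): r = 0.8, t = 0.8*sqrt(3/0.36),
        p = 2*(1 - T3.cdf(t)) ~ 0.104."""
        r, p, n = pearson_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert r == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * np.sqrt(3 / 0.36)
        assert p == pytest.approx(2 * sps.t.sf(t, 3), abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, 3.0, np.nan, 5.0]
        y = [1.1, 2.2, 2.9, 4.0, np.nan]
        _, _, n = pearson_test(x, y)
        assert n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestDeming:
    def test_collinear_data_recovers_the_line(self):
        x = np.arange(10.0)
        fit = deming_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_axis_swap_identity_with_unit_delta(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = -0.7 * x + rng.normal(scale=0.5, size=50)
        assert deming_fit(x, y).slope * deming_fit(y, x).slope == pytest.approx(1.0, abs=1e-12)

    def test_common_rescaling_equivariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(scale=0.3, size=40)
        assert deming_fit(3 * x, 3 * y).slope == pytest.approx(deming_fit(x, y).slope, abs=1e-12)

    def test_slope_shares_sign_of_covariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = -0.3 * x + rng.normal(size=100)
        fit = deming_fit(x, y)
        assert np.sign(fit.slope) == np.sign(np.cov(x, y)[0, 1])

    def test_less_attenuated_than_ols_under_errors_in_both(self):
        """Monte-Carlo: with equal measurement error on both axes the
        Deming slope is closer to the programmed slope than OLS on average."""
        dem, ols = [], []
        for seed in range(60):
            panel = simulate_strain_panel(PanelSimSpec(
                n_strains=72, cdl_slope_per_h=-0.5, cdl_noise_sd_h=0.0,
                frp_meas_sd_h=0.5, cdl_meas_sd_h=0.5, seed=seed))
            x = panel["obs_tau_h"].to_numpy()
            y = panel["obs_cdl_h"].to_numpy()
            dem.append(deming_fit(x, y).slope)
            ols.append(np.polyfit(x, y, 1)[0])
        assert abs(np.mean(dem) + 0.5) < abs(np.mean(ols) + 0.5)

    def test_degenerate_covariance_flagged(self):
        fit = deming_fit([0.0, 1.0, 2.0, 3.0], [1.0, -1.0, -1.0, 1.0])
        assert fit.degenerate


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        """(1,2,3) vs (10,11,12): the most extreme of C(6,3)=20 splits,
        two-sided p = 2/20 = 0.1."""
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1, abs=1e-12)

    def test_two_vs_two_separated(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_identical_constant_groups_give_p_one(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_identical_multisets_give_p_near_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0, abs=0.05)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_exact_path_matches_full_enumeration(self, data):
        """Property: every tie-free split with combined n <= 10 agrees with
        the itertools enumeration oracle."""
        n = data.draw(st.integers(4, 10))
        n_a = data.draw(st.integers(1, n - 1))
        values = data.draw(st.lists(
            st.floats(-100, 100, allow_nan=False),
            min_size=n, max_size=n, unique=True))
        a, b = np.array(values[:n_a]), np.array(values[n_a:])
        assert wilcoxon_rank_sum(a, b) == pytest.approx(enumeration_wilcoxon(a, b), abs=1e-12)

    def test_large_sample_path_close_to_scipy_asymptotic(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        b = rng.normal(loc=0.8, size=25)
        ours = wilcoxon_rank_sum(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestHolm:
    def test_worked_example(self):
        assert np.allclose(holm_adjust([0.01, 0.02, 0.2]), [0.03, 0.04, 0.2])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.37])[0] == pytest.approx(0.37)

    def test_tied_p_values_step_down(self):
        assert np.allclose(holm_adjust([0.04, 0.04]), [0.08, 0.08])

    def test_matches_stepdown_closed_form(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=15)
        order = np.argsort(p)
        m = len(p)
        adj_sorted = np.maximum.accumulate(
            np.minimum((m - np.arange(m)) * p[order], 1.0))
        expected = np.empty(m)
        expected[order] = adj_sorted
        assert np.allclose(holm_adjust(p), expected, atol=1e-15)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_adjusted_at_least_raw_and_idempotent_ordering(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        # monotone in the order statistics
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


def letters_satisfy_biconditional(letters, p_adj, alpha):
    labels = list(p_adj.index)
    for i, li in enumerate(labels):
        for j in range(i + 1, len(labels)):
            share = bool(set(letters[li]) & set(letters[labels[j]]))
            if share != (p_adj.iloc[i, j] >= alpha):
                return False
    return True


class TestCompactLetters:
    def make_p(self, entries, labels=("g1", "g2", "g3")):
        m = pd.DataFrame(np.ones((len(labels), len(labels))),
                         index=labels, columns=labels)
        for (i, j), p in entries.items():
            m.iloc[i, j] = m.iloc[j, i] = p
        return m

    def test_all_pairs_significant_gives_distinct_letters(self):
        m = self.make_p({(0, 1): 0.001, (0, 2): 0.001, (1, 2): 0.001})
        assert compact_letters(m) == {"g1": "a", "g2": "b", "g3": "c"}

    def test_no_pair_significant_gives_single_letter(self):
        m = self.make_p({})
        assert compact_letters(m) == {"g1": "a", "g2": "a", "g3": "a"}

    def test_chain_pattern_yields_overlapping_letters(self):
        """g1-g2 ns, g2-g3 ns, g1-g3 significant -> a / ab / b, the minimal
        display (brute-force over assignments confirms 2 letters suffice
        and 1 cannot)."""
        m = self.make_p({(0, 2): 0.01})
        letters = compact_letters(m)
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}
        assert letters_satisfy_biconditional(letters, m, 0.05)
        # one letter cannot work: g1 and g3 would share it
        assert not letters_satisfy_biconditional({"g1": "a", "g2": "a", "g3": "a"}, m, 0.05)

    def test_random_matrices_satisfy_share_iff_nonsignificant(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            labels = [f"g{i}" for i in range(k)]
            m = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
            for i in range(k):
                for j in range(i + 1, k):
                    m.iloc[i, j] = m.iloc[j, i] = rng.uniform()
            letters = compact_letters(m, alpha=0.3)
            assert letters_satisfy_biconditional(letters, m, 0.3)
            assert all(letters[lab] for lab in labels)


class TestPairwiseWilcoxon:
    def test_three_group_report_is_consistent(self):
        rng = np.random.default_rng(6)
        groups = {
            "low": rng.normal(0.0, 1.0, 12),
            "mid": rng.normal(0.5, 1.0, 12),
            "high": rng.normal(4.0, 1.0, 12),
        }
        res = pairwise_wilcoxon(groups, alpha=0.05)
        assert np.all(res.p_adjusted.to_numpy() >= res.p_raw.to_numpy() - 1e-15)
        assert letters_satisfy_biconditional(res.letters, res.p_adjusted, 0.05)
        assert set(res.letters["low"]).isdisjoint(res.letters["high"])


class TestPanelAssociation:
    def test_noiseless_panel_recovers_programmed_line(self):
        panel = simulate_strain_panel(PanelSimSpec(
            n_strains=30, cdl_slope_per_h=-0.5, cdl_noise_sd_h=0.0, seed=7))
        records = pd.DataFrame({
            "mean_frp_h": panel["true_tau_h"],
            "first_peak_h": panel["true_tau_h"] * 1.0 + 2.0,
            "cdl_h": panel["true_cdl_h"],
            "excluded": False,
        })
        report = panel_association(records).set_index("pair")
        assert report.loc["frp_vs_cdl", "pearson_r"] == pytest.approx(-1.0, abs=1e-9)
        assert report.loc["frp_vs_cdl", "deming_slope"] == pytest.approx(-0.5, abs=1e-9)

    def test_null_panel_rarely_significant(self):
        hits = 0
        for seed in range(40):
            panel = simulate_strain_panel(PanelSimSpec(
                n_strains=72, cdl_slope_per_h=0.0, cdl_noise_sd_h=0.5,
                frp_meas_sd_h=0.3, cdl_meas_sd_h=0.3, seed=seed))
            _, p, _ = pearson_test(panel["obs_tau_h"], panel["obs_cdl_h"])
            hits += p < 0.05
        assert hits <= 8  # ~5% expected under the null

    def test_excluded_strains_dropped_from_frp_analyses(self):
        rng = np.random.default_rng(8)
        n = 12
        tau = rng.normal(24, 1, n)
        records = pd.DataFrame({
            "mean_frp_h": tau,
            "first_peak_h": tau + rng.normal(0, 0.2, n),
            "cdl_h": 25.0 - 0.5 * tau + rng.normal(0, 0.2, n),
            "excluded": [True] + [False] * (n - 1),
        })
        report = panel_association(records).set_index("pair")
        assert report.loc["frp_vs_cdl", "n"] == n - 1
        assert report.loc["peak_vs_cdl", "n"] == n
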