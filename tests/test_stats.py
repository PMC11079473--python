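"""Outcome statistics: response rates, odds ratios, exact tests against
enumeration oracles, and region-occurrence bookkeeping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from thalied.fixtures import build_cohort_table, contact_event_records
from thalied.stats import (crosstab_2x2, fisher_exact, is_responder,
                           lag_ttest, odds_ratio, percent, region_occurrence,
                           response_rate, round_half_up, seizure_reduction,
                           wilcoxon_rank_sum, wilcoxon_signed_rank)


def fisher_oracle(table):
    """Independent two-sided Fisher p: enumerate every table with the
    observed margins and sum the probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(a_):
        return (math.comb(r1, a_) * math.comb(r2, c1 - a_)
                / math.comb(n, c1))

    p_obs = p_of(a)
    total = 0.0
    for a_ in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = p_of(a_)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def signed_rank_oracle(diffs):
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats, dtype=float)
    mean = stats.mean()
    # two-sided: as or more extreme in distance from the null mean
    return float(np.mean(np.abs(stats - mean) >= abs(w_obs - mean) - 1e-12))


class TestSeizureReduction:
    @pytest.mark.parametrize("pre,post,sr", [(10, 4, 60.0), (10, 10, 0.0),
                                             (10, 12, -20.0)])
    def test_examples(self, pre, post, sr):
        assert seizure_reduction(pre, post) == pytest.approx(sr)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValueError):
            seizure_reduction(0, 3)

    @pytest.mark.parametrize("sr,flag", [(50.0, False), (50.1, True),
                                         (100.0, True), (-20.0, False)])
    def test_responder_threshold_strict(self, sr, flag):
        assert is_responder(sr) is flag


class TestResponseRate:
    def test_fixture_subgroup_rates(self):
        """Overall 40%, bilateral-hit 44%, focus-side-hit 45%, focus-side
        spike-TIED 71% — one cohort satisfying all four simultaneously."""
        cohort = build_cohort_table()
        assert response_rate(cohort) == 40
        assert response_rate(cohort, "bilateral_hit") == 44
        assert response_rate(cohort, "focus_side_hit") == 45
        assert response_rate(cohort, "focus_side_spike_tied") == 71

    def test_empty_subgroup_errors(self):
        cohort = build_cohort_table()
        with pytest.raises(ValueError):
            response_rate(cohort, cohort["sr_percent"] > 1e9)

    def test_disjoint_subgroups_reconstruct_overall(self):
        """Responder counts over a disjoint exhaustive split sum to the
        overall responder count."""
        cohort = build_cohort_table()
        split = [cohort[cohort["bilateral_hit"]],
                 cohort[~cohort["bilateral_hit"]]]
        assert sum(int(s["responder"].sum()) for s in split) == \
            int(cohort["responder"].sum())

    def test_rounding_half_up(self):
        assert round_half_up(45.5) == 46.0
        assert percent(55, 120) == 46
        assert percent(5, 11) == 45


class TestOddsRatio:
    @pytest.mark.parametrize("table,expected", [
        ([[4, 5], [2, 4]], 1.6),
        ([[5, 6], [1, 3]], 2.5),
        ([[5, 2], [1, 7]], 17.5),
    ])
    def test_reconstructed_outcome_tables(self, table, expected):
        assert odds_ratio(table) == pytest.approx(expected)

    def test_zero_cell_infinite_and_haldane(self):
        assert odds_ratio([[3, 0], [1, 4]]) == np.inf
        assert odds_ratio([[3, 0], [1, 4]], haldane=True) == \
            pytest.approx(3.5 * 4.5 / (0.5 * 1.5))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio([[1, -1], [2, 3]])

    def test_swap_and_transpose_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            base = odds_ratio(t.tolist())
            swapped = t[::-1, ::-1]  # swap both rows and both columns
            assert odds_ratio(swapped.tolist()) == pytest.approx(base)
            assert odds_ratio(t.T.tolist()) == pytest.approx(base)

    def test_crosstab_orientation(self):
        cohort = build_cohort_table()
        assert crosstab_2x2(cohort, "bilateral_hit") == [[4, 5], [2, 4]]
        assert crosstab_2x2(cohort, "focus_side_hit") == [[5, 6], [1, 3]]
        assert crosstab_2x2(cohort, "focus_side_spike_tied") == \
            [[5, 2], [1, 7]]


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_focus_tied_table(self):
        p = fisher_exact([[5, 2], [1, 7]])
        assert p == pytest.approx(fisher_oracle([[5, 2], [1, 7]]), abs=1e-12)
        assert p == pytest.approx(0.041, abs=0.0005)

    def test_extreme_table(self):
        assert fisher_exact([[10, 0], [0, 10]]) < 1e-4

    def test_matches_oracle_on_small_tables(self):
        """Spot-sweep of tables with N <= 12 (the full N <= 30 sweep runs in
        the acceptance suite)."""
        for a, b, c, d in itertools.product(range(4), repeat=4):
            if a + b + c + d == 0:
                continue
            t = [[a, b], [c, d]]
            assert fisher_exact(t) == pytest.approx(fisher_oracle(t),
                                                    abs=1e-10), t


class TestWilcoxon:
    def test_identical_pairs_p_one(self):
        assert wilcoxon_signed_rank([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_exact_p_matches_sign_enumeration(self):
        """n=6 pairs: exact signed-rank p equals the 2^6 enumeration."""
        x = np.array([3.0, 5.0, 1.5, 4.0, 7.0, 2.0])
        y = np.array([1.0, 6.0, 0.5, 1.0, 3.0, 4.5])
        p = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(signed_rank_oracle(x - y), abs=1e-12)

    def test_power_against_doubled_rates(self):
        """Simulated cohorts where responders carry twice the thalamic IED
        rate: rank-sum rejects at alpha=0.05 in more than half of 200
        replicates (n=15 patients, 6 responders)."""
        rng = np.random.default_rng(17)
        minutes = 20.0
        reject = 0
        n_rep = 200
        for _ in range(n_rep):
            resp = rng.poisson(0.33 * minutes, size=6) / minutes
            nonresp = rng.poisson(0.165 * minutes, size=9) / minutes
            if wilcoxon_rank_sum(resp, nonresp) < 0.05:
                reject += 1
        assert reject / n_rep > 0.5


class TestLagTTest:
    def test_identical_groups_p_one(self):
        assert lag_ttest([40.0, 50.0, 60.0], [40.0, 50.0, 60.0]) == \
            pytest.approx(1.0)

    def test_separated_groups_significant(self):
        """Groups 3 SD apart at n=10/10 reject at p<0.01 in >=95% of
        seeds."""
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            a = rng.normal(50.0, 10.0, 10)
            b = rng.normal(80.0, 10.0, 10)
            if lag_ttest(a, b) < 0.01:
                hits += 1
        assert hits >= 38

    def test_single_element_group_errors(self):
        with pytest.raises(ValueError):
            lag_ttest([50.0], [40.0, 60.0])


class TestRegionOccurrence:
    def test_fixture_percentages(self):
        """Spikes in 50% MD / 92% ANT-V / 60% ANT-D; sharp transients in
        30% ANT-D / 25% ANT-P."""
        occ = region_occurrence(contact_event_records())
        assert occ.loc["MD", "spike_pct"] == 50
        assert occ.loc["ANT-V", "spike_pct"] == 92
        assert occ.loc["ANT-D", "spike_pct"] == 60
        assert occ.loc["ANT-D", "st_pct"] == 30
        assert occ.loc["ANT-P", "st_pct"] == 25
        assert occ["n_sampled"].sum() == 41

    def test_no_events_all_zero(self):
        rec = pd.DataFrame([
            dict(patient="P01", side="left", region="ANT-V",
                 has_spike=False, has_st=False),
            dict(patient="P01", side="left", region="MD",
                 has_spike=False, has_st=False)])
        occ = region_occurrence(rec)
        assert (occ["spike_pct"] == 0).all()
        assert (occ["st_pct"] == 0).all()

    def test_duplicate_contact_leaves_percentages_unchanged(self):
        records = contact_event_records()
        dup = pd.concat([records, records.iloc[[0]]], ignore_index=True)
        pd.testing.assert_frame_equal(region_occurrence(records),
                                      region_occurrence(dup))
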