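"""Responder classification, response rates, odds ratios, and the
non-parametric test battery used for the cohort-level associations.

Percentages are rounded half-up to integer percent to match clinical
reporting conventions.  The responder threshold is strict: a seizure
reduction of exactly 50% is a non-responder.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sstats


def round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float) -> int:
    """Integer percent, rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return int(round_half_up(100.0 * numerator / denominator))


def seizure_reduction(pre: float, post: float) -> float:
    """Seizure-reduction percentage between the 3-month baseline and the
    3 months before the 1-year follow-up; negative means worsening."""
    if pre < 0 or post < 0:
        raise ValueError("seizure counts must be non-negative")
    if pre == 0:
        raise ValueError("seizure reduction undefined for a zero baseline")
    return 100.0 * (pre - post) / pre


def is_responder(sr_percent: float) -> bool:
    """Responder := strictly more than 50% seizure reduction."""
    return sr_percent > 50.0


def response_rate(cohort: pd.DataFrame, mask=None) -> int:
    """Responder percentage within a subgroup (integer %, half-up).

    ``cohort`` needs a boolean ``responder`` column; ``mask`` restricts to a
    subgroup (boolean Series or column name).  Empty subgroup is an error.
    """
    sub = cohort if mask is None else cohort[
        cohort[mask] if isinstance(mask, str) else mask]
    if len(sub) == 0:
        raise ValueError("empty subgroup")
    return percent(int(sub["responder"].sum()), len(sub))


def odds_ratio(table, haldane: bool = False) -> float:
    """(a*d)/(b*c) for a 2x2 table [[a, b], [c, d]].

    A zero off-diagonal cell gives +inf (0/0 -> nan) unless ``haldane`` adds
    0.5 to every cell (Haldane-Anscombe correction).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    num, den = a * d, b * c
    if den == 0:
        return np.nan if num == 0 else np.inf
    return num / den


def crosstab_2x2(cohort: pd.DataFrame, row_flag: str,
                 col_flag: str = "responder"):
    """[[flag&col, flag&~col], [~flag&col, ~flag&~col]] counts."""
    r = cohort[row_flag].astype(bool)
    c = cohort[col_flag].astype(bool)
    return [[int((r & c).sum()), int((r & ~c).sum())],
            [int((~r & c).sum()), int((~r & ~c).sum())]]


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities of
    tables at least as extreme as the observed one, margins fixed)."""
    _, p = sstats.fisher_exact(table, alternative="two-sided")
    return float(p)


def wilcoxon_signed_rank(x, y) -> float:
    """Paired Wilcoxon signed-rank two-sided p; zero differences dropped,
    exact distribution when the reduced sample allows it."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    res = sstats.wilcoxon(d, alternative="two-sided")
    return float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Unpaired two-sided rank-sum (Mann-Whitney) p with mid-ranks for
    ties."""
    res = sstats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)


def lag_ttest(lags_a, lags_b) -> float:
    """Independent two-sample t-test (pooled variance) on time lags."""
    a, b = np.asarray(lags_a, float), np.asarray(lags_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each lag group needs at least 2 values")
    res = sstats.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def region_occurrence(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage of sampled region units showing spikes / sharp transients.

    ``records`` has one row per contact with columns ``patient``, ``side``,
    ``region``, ``has_spike``, ``has_st``.  Contacts are first deduplicated
    to one unit per (patient, side, region) — multiple contacts within the
    same region of one lead count once — then percentages are taken per
    region over that region's sampled units.
    """
    units = (records.groupby(["patient", "side", "region"], as_index=False)
             .agg(has_spike=("has_spike", "any"), has_st=("has_st", "any")))
    out = []
    for region, grp in units.groupby("region"):
        n = len(grp)
        out.append({
            "region": region,
            "n_sampled": n,
            "spike_pct": percent(int(grp["has_spike"].sum()), n),
            "st_pct": percent(int(grp["has_st"].sum()), n),
        })
    return pd.DataFrame(out).set_index("region")


def cohort_report(cohort: pd.DataFrame, summary, sleep_summary=None,
                  haldane: bool = False) -> dict:
    """Assemble the cohort-level association report.

    ``cohort`` carries per-patient outcome and hit/TIED flags; ``summary`` is
    the pooled :class:`~thalied.averaging.ConditionSummary` (and optionally a
    sleep-only one).  Numbers carry both raw and rounded forms.
    """
    rr = {
        "overall": response_rate(cohort),
        "bilateral_hit": response_rate(cohort, "bilateral_hit"),
        "unilateral_hit": response_rate(cohort, "unilateral_hit"),
        "focus_side_hit": response_rate(cohort, "focus_side_hit"),
        "focus_side_spike_tied": response_rate(cohort, "focus_side_spike_tied"),
    }
    nonresp = cohort[~cohort["responder"].astype(bool)]
    tied_among_nonresp = percent(int(nonresp["any_ant_spike_tied"].sum()),
                                 len(nonresp))
    ors = {
        key: odds_ratio(crosstab_2x2(cohort, key), haldane=haldane)
        for key in ("bilateral_hit", "focus_side_hit", "focus_side_spike_tied")
    }
    tests = {}
    resp = cohort[cohort["responder"].astype(bool)]
    for col, name in [("tied_rate_sleep", "tied_sleep"),
                      ("tied_rate_awake", "tied_awake"),
                      ("sied_rate_sleep", "sied_sleep"),
                      ("sied_rate_awake", "sied_awake")]:
        if col in cohort:
            tests[f"ranksum_{name}_resp_vs_nonresp"] = wilcoxon_rank_sum(
                resp[col], nonresp[col])
    report = {
        "n_patients": int(len(cohort)),
        "n_responders": int(cohort["responder"].sum()),
        "response_rate_pct": rr,
        "nonresponder_spike_tied_pct": tied_among_nonresp,
        "odds_ratios": {k: (None if np.isinf(v) else round(v, 4))
                        for k, v in ors.items()},
        "rate_tests": tests,
    }
    if summary is not None:
        fr = summary.fractions
        report["connections"] = {
            "n_evaluable": summary.n_evaluable,
            "follower_pct": percent(summary.n_follower, summary.n_evaluable),
            "preceder_pct": percent(summary.n_preceder, summary.n_evaluable),
            "no_connection_pct": percent(summary.n_no_connection,
                                         summary.n_evaluable),
            "fractions_raw": {k: round(v, 6) for k, v in fr.items()},
            "mean_follower_lag_ms": summary.mean_follower_lag_ms,
            "mean_preceder_lag_ms": summary.mean_preceder_lag_ms,
        }
    if sleep_summary is not None and sleep_summary.n_evaluable:
        report["connections_sleep"] = {
            "n_evaluable": sleep_summary.n_evaluable,
            "follower_pct": percent(sleep_summary.n_follower,
                                    sleep_summary.n_evaluable),
            "no_connection_pct": percent(sleep_summary.n_no_connection,
                                         sleep_summary.n_evaluable),
        }
    return report
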