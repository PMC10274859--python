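"""HCIP calling: enrichment flags, background pool, rank-sum, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnplc import hcip


def test_enrichment_flags_threshold_is_strict(norm_table, failed_report):
    """z exactly at 1.645 does not count as enriched."""
    bait = failed_report.frame().query("passed")["bait"].iloc[0]
    cond = failed_report.frame().query("passed and bait == @bait")["condition"].iloc[0]
    samples = list(failed_report.statuses[(bait, cond)].samples)
    doctored = norm_table.values.copy()
    doctored.loc["PREY001", samples] = 1.645
    table = hcip.replicate_enrichment_flags(
        type(norm_table)(values=doctored, samples=norm_table.samples, stages=norm_table.stages),
        bait, cond, samples=samples,
    )
    assert table["PREY001"] == 0


def test_enrichment_flags_match_loop_oracle(norm_table, failed_report):
    bait, cond = "BAIT02", "rnase_plus"
    samples = list(failed_report.statuses[(bait, cond)].samples)
    flags = hcip.replicate_enrichment_flags(norm_table, bait, cond, samples=samples)
    block = norm_table.values[samples]
    for prey in list(norm_table.values.index)[:50]:
        want = sum(
            1 for s in samples
            if pd.notna(block.loc[prey, s]) and block.loc[prey, s] > 1.645
        )
        assert flags[prey] == want


def test_enrichment_flags_require_two_replicates(norm_table):
    with pytest.raises(hcip.InsufficientDataError):
        hcip.replicate_enrichment_flags(
            norm_table, "BAIT02", "rnase_plus", samples=["mix_BAIT02:127N"]
        )


def test_background_pool_grows_with_failed_ips(norm_table, failed_report, truth):
    igg_only = hcip.background_pool(norm_table, "rnase_plus")
    with_failed = hcip.background_pool(norm_table, "rnase_plus", failed_report)
    n_failed = len(failed_report.failed_samples("rnase_plus"))
    assert with_failed.shape[1] == igg_only.shape[1] + n_failed
    # counting oracle: observed entries per protein
    prey = "PREY010"
    assert with_failed.loc[prey].notna().sum() == int(
        norm_table.values.loc[prey, list(with_failed.columns)].notna().sum()
    )


def test_rank_sum_exact_enumeration_oracle():
    """Exact p equals brute-force enumeration over rank assignments."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        prey = rng.normal(1.0, 1.0, 3)
        bg = rng.normal(0.0, 1.0, 5)
        _, p = hcip.rank_sum_enrichment(prey, bg)
        pooled = np.concatenate([prey, bg])
        ranks = stats.rankdata(pooled)
        obs = ranks[:3].sum()
        stat_all = [
            sum(combo) for combo in itertools.combinations(ranks, 3)
        ]
        want = np.mean([s >= obs for s in stat_all])
        assert p == pytest.approx(want, abs=1e-12)


def test_rank_sum_null_is_uniform():
    """Exact p-values on null data are valid: discrete but never
    anti-conservative, with mean near 1/2."""
    rng = np.random.default_rng(5)
    ps = []
    for _ in range(1000):
        prey = rng.normal(0, 1, 3)
        bg = rng.normal(0, 1, 8)
        ps.append(hcip.rank_sum_enrichment(prey, bg)[1])
    assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
    assert abs(np.mean(ps) - 0.5) < 0.05


def test_rank_sum_degenerate_all_ties_returns_one():
    ratio, p = hcip.rank_sum_enrichment(np.array([5.0, 5.0]), np.array([5.0] * 4))
    assert ratio == 0.0 and p == 1.0


def test_rank_sum_worked_example():
    """Prey (10,10,10) vs background (7,7,7,7): ratio 3, exact p = 1/35."""
    ratio, p = hcip.rank_sum_enrichment(np.array([10.0] * 3), np.array([7.0] * 4))
    assert ratio == pytest.approx(3.0)
    assert p == pytest.approx(1 / 35)


def test_call_hcips_pass_requires_all_three_criteria(norm_table, failed_report):
    calls = hcip.call_hcips(norm_table, "BAIT02", "rnase_minus", failed_report)
    for row in calls.itertuples():
        expected = (
            row.n_enriched_reps >= 2
            and np.isfinite(row.log2_ratio) and row.log2_ratio > 1.0
            and np.isfinite(row.p_value) and row.p_value < 0.05
        )
        assert row.passed == expected
    assert not (calls["prey"] == "BAIT02").any()


def test_call_hcips_ratio_below_one_fails(norm_table, failed_report):
    """A prey with log2 ratio 0.8 fails regardless of p-value."""
    calls = hcip.call_hcips(norm_table, "BAIT02", "rnase_minus", failed_report)
    weak = calls[(calls["log2_ratio"] <= 1.0) & calls["log2_ratio"].notna()]
    assert not weak["passed"].any()


def test_alpha_monotonicity(norm_table, failed_report):
    """Raising alpha never removes a passing call."""
    loose = hcip.call_hcips(norm_table, "BAIT03", "rnase_plus", failed_report,
                            hcip.HCIPParams(alpha=0.05))
    strict = hcip.call_hcips(norm_table, "BAIT03", "rnase_plus", failed_report,
                             hcip.HCIPParams(alpha=0.01))
    assert set(strict[strict.passed]["prey"]) <= set(loose[loose.passed]["prey"])


def test_z_threshold_monotonicity(norm_table, failed_report):
    """Raising the z threshold never adds a passing call."""
    low = hcip.call_hcips(norm_table, "BAIT03", "rnase_plus", failed_report,
                          hcip.HCIPParams(z_threshold=1.645))
    high = hcip.call_hcips(norm_table, "BAIT03", "rnase_plus", failed_report,
                           hcip.HCIPParams(z_threshold=2.5))
    assert set(high[high.passed]["prey"]) <= set(low[low.passed]["prey"])


def test_classification_truth_table():
    calls = lambda preys: pd.DataFrame(
        {"bait": "B", "prey": list(preys), "passed": True}
    )
    both = hcip.classify_rna_dependency(calls(["x"]), calls(["x"]), True, True)
    assert both["ip_type"].tolist() == ["direct"]
    minus_only = hcip.classify_rna_dependency(calls([]), calls(["x"]), True, True)
    assert minus_only["ip_type"].tolist() == ["mediated"]
    plus_only = hcip.classify_rna_dependency(calls(["x"]), calls([]), True, True)
    assert plus_only["ip_type"].tolist() == ["shielded"]
    undet = hcip.classify_rna_dependency(calls(["x"]), None, True, False)
    assert undet["ip_type"].tolist() == ["undetermined"]
    dropped = hcip.classify_rna_dependency(None, None, False, False)
    assert dropped.empty


def test_classification_is_single_valued(typed_edges):
    dup = typed_edges.groupby(["bait", "prey"]).size()
    assert (dup == 1).all()


def test_undetermined_bait_preys_all_undetermined(typed_edges, truth):
    for bait in truth.undetermined_baits:
        sub = typed_edges[typed_edges["bait"] == bait]
        assert (sub["ip_type"] == "undetermined").all()
        assert len(sub) > 0
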