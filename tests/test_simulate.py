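"""Generator contracts: determinism, planted structure, mix design."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rnplc.cooccurrence import jaccard_index
from rnplc.simulate import (
    CONDITIONS,
    INTERACTION_TYPES,
    ConfigurationError,
    SimConfig,
    fraction_for_mass,
    make_truth,
    sec_calibration,
    simulate_binding_sites,
    simulate_ip,
    simulate_sec,
    simulate_total_proteome,
)


def test_invalid_type_proportions_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(type_proportions={"direct": 0.5, "mediated": 0.5, "shielded": 0.5,
                                    "undetermined": 0.0})


def test_invalid_overlap_rho_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(overlap_rho={"direct": 1.5})


def test_truth_deterministic_per_seed(default_config):
    a = make_truth(default_config)
    b = make_truth(default_config)
    assert a == b
    c = make_truth(default_config.with_seed(99))
    assert c.true_edges != a.true_edges


def test_truth_counts_and_membership(truth, default_config):
    assert len(truth.preys) == default_config.n_preys
    assert len(truth.baits) == default_config.n_baits
    proteins = set(truth.proteins)
    for b, p, t in truth.true_edges:
        assert b in proteins and p in proteins
        assert t in INTERACTION_TYPES
    assert set(truth.planted_bridges) <= proteins


def test_bridge_spans_three_steps(truth):
    bridge = truth.planted_bridges[0]
    steps = {truth.bait_steps[b] for b, p, _ in truth.true_edges if p == bridge}
    assert len(steps) >= 3


def test_edge_type_frequencies_match_proportions():
    """Direct count over ~1000 drawn edges lies in the binomial 99% interval."""
    cfg = SimConfig(n_baits=40, edges_per_bait=26, n_preys=900, seed=3)
    truth = make_truth(cfg)
    n = len(truth.true_edges)
    n_direct = sum(t == "direct" for _, _, t in truth.true_edges)
    # planted extras (bridge + control complex) are direct by construction
    extra = cfg.bridge_n_baits + 5
    lo, hi = stats.binom.ppf([0.005, 0.995], n - extra, 0.20)
    assert lo <= n_direct - extra <= hi + extra


def test_ip_table_mix_design(raw_table, default_config, truth):
    for _, sub in raw_table.samples.groupby("mix"):
        assert (sub["role"] == "spike_in").sum() == 1
        assert (sub["role"] == "igg").sum() == 2 * default_config.n_igg_replicates
        ips = sub[sub["role"] == "bait_ip"]
        assert len(ips) == 2 * default_config.n_ip_replicates
        assert set(ips["condition"]) == set(CONDITIONS)
    assert raw_table.values.shape[1] == 11 * default_config.n_baits


def test_spike_in_is_mean_of_other_channels_without_noise(truth, default_config):
    table = simulate_ip(truth, default_config, noise=False)
    filled = table.values  # dropout may censor; compare on raw construction
    for mix, sub in table.samples.groupby("mix"):
        spike = sub.index[sub["role"] == "spike_in"][0]
        others = [s for s in sub.index if s != spike]
        # dropout censors channels independently; compare only rows where
        # every contributing channel survived
        full = filled[others].notna().all(axis=1) & filled[spike].notna()
        got = filled.loc[full, spike]
        want = filled.loc[full, others].mean(axis=1)
        assert np.allclose(got, want, rtol=1e-9)


def test_direct_prey_enrichment_close_to_effect_size():
    """Mean log2 IP-vs-IgG contrast for direct preys ~ effect_size over seeds."""
    deltas = []
    for seed in range(25):
        cfg = SimConfig(seed=seed, dropout_threshold=0.0)
        truth = make_truth(cfg)
        table = simulate_ip(truth, cfg)
        log2 = np.log2(table.values)
        for b, p, t in truth.true_edges[:10]:
            # control-complex preys co-purify at bait level, skip them
            if t != "direct" or b == truth.control_bait:
                continue
            ip = table.sample_ids(bait=b, role="bait_ip")
            igg = [s for s in table.sample_ids(role="igg")
                   if table.samples.loc[s, "mix"] == f"mix_{b}"]
            deltas.append(log2.loc[p, ip].mean() - log2.loc[p, igg].mean())
    assert abs(np.mean(deltas) - 3.0) < 0.15


def test_igg_channels_carry_no_planted_signal(raw_table, truth):
    """IgG exceedances of the background 99.9th percentile stay at chance."""
    igg = raw_table.values[raw_table.sample_ids(role="igg")]
    log2 = np.log2(igg.where(igg > 0))
    cut = np.nanquantile(log2.to_numpy(), 0.999)
    frac = float((log2 > cut).sum().sum() / log2.notna().sum().sum())
    assert frac < 0.005


def test_sec_complex_members_share_apex_noiseless(truth, default_config):
    reps, calib = simulate_sec(truth, default_config, noise=False)
    mat = reps[0]
    members, mass = truth.complexes[0]
    apexes = {m: int(mat.loc[m].idxmax()) for m in members[:2]}
    vals = list(apexes.values())
    assert vals[0] == vals[1]
    # apex maps back to complex mass through the calibration inverse
    implied = fraction_for_mass(mass, calib)
    assert abs(vals[0] - implied) <= 1


def test_sec_has_57_fractions(truth, default_config):
    reps, calib = simulate_sec(truth, default_config)
    assert reps[0].shape[1] == 57
    assert list(calib["fraction"])[0] == 10 and list(calib["fraction"])[-1] == 66


def test_calibration_clamps_out_of_range_mass(default_config):
    calib = sec_calibration(default_config)
    with pytest.warns(UserWarning):
        f = fraction_for_mass(1e6, calib)
    assert f == calib["fraction"].iloc[0]


def test_total_proteome_positive_and_deterministic(truth, default_config):
    a = simulate_total_proteome(truth, default_config)
    b = simulate_total_proteome(truth, default_config)
    assert (a > 0).all().all()
    pd.testing.assert_frame_equal(a, b)


def test_total_proteome_complex_log_ratios_centered_at_zero(default_config):
    """1:1 complex members have abundance log-ratios centered at 0."""
    ratios = []
    for seed in range(50):
        cfg = default_config.with_seed(seed)
        truth = make_truth(cfg)
        tot = np.log2(simulate_total_proteome(truth, cfg).mean(axis=1))
        for members, _ in truth.complexes[:3]:
            ratios.append(tot[members[0]] - tot[members[1]])
    assert abs(np.mean(ratios)) < 0.05


def test_binding_sites_rho_one_gives_identical_sets():
    cfg = SimConfig(
        seed=5,
        overlap_rho={"direct": 1.0, "mediated": 0.0, "shielded": 0.0, "undetermined": 0.0},
    )
    truth = make_truth(cfg)
    sites = simulate_binding_sites(truth, cfg)
    checked = 0
    for b, p, t in truth.true_edges:
        if t == "direct":
            assert jaccard_index(sites[b], sites[p]) == 1.0
            checked += 1
    assert checked > 5


def test_binding_sites_rho_zero_matches_independence_baseline():
    """E[J] under rho=0 equals the closed form q/(2-q) for independent sets."""
    cfg = SimConfig(
        seed=6,
        overlap_rho={t: 0.0 for t in INTERACTION_TYPES},
    )
    js = []
    for seed in range(20):
        truth = make_truth(cfg.with_seed(seed))
        sites = simulate_binding_sites(truth, cfg.with_seed(seed))
        for b, p, _ in truth.true_edges[:20]:
            js.append(jaccard_index(sites[b], sites[p]))
    q = cfg.site_base_rate
    assert abs(np.nanmean(js) - q / (2 - q)) < 0.005


def test_binding_sites_deterministic(truth, default_config):
    a = simulate_binding_sites(truth, default_config)
    b = simulate_binding_sites(truth, default_config)
    assert a == b
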