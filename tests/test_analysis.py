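"""Feature-extraction, energy-analysis and statistics tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from emcosim.analysis import (EnergyAccount, SpikeTrain, ap_vs_rest_consumption,
                              compare_conditions, detect_spikes, energy_accounts,
                              extract_features, group_stats,
                              supply_demand_correlation,
                              surface_feature_correlation, validate_physiology)
from emcosim.stats import bonferroni, dunn_test, shapiro_by_group


def _triangle_train(n_spikes=7, period=50.0, dt=0.1):
    """Synthetic voltage trace with triangular depolarisations above 0 mV."""
    t = np.arange(0, n_spikes * period, dt)
    v = np.full_like(t, -65.0)
    for k in range(n_spikes):
        c = k * period + 20.0
        m = np.abs(t - c) <= 2.0
        v[m] = -65.0 + (1 - np.abs(t[m] - c) / 2.0) * 95.0  # peak +30
    return t, v


# ---------------------------------------------------------------------------
# spikes and features
# ---------------------------------------------------------------------------


def test_flat_trace_has_no_spikes():
    t = np.arange(0, 100, 0.1)
    v = np.full_like(t, -65.0)
    assert detect_spikes(t, v).count == 0


def test_synthetic_triangular_train_counts_correctly():
    t, v = _triangle_train(7)
    assert detect_spikes(t, v).count == 7


def test_refractory_merges_close_crossings():
    t = np.arange(0, 10, 0.1)
    v = np.full_like(t, -65.0)
    v[(t >= 3.0) & (t < 3.3)] = 0.0
    v[(t >= 4.0) & (t < 4.3)] = 0.0  # 1 ms after the first crossing
    assert detect_spikes(t, v, refractory=2.0).count == 1
    assert detect_spikes(t, v, refractory=0.5).count == 2


def test_empty_trace_yields_empty_train():
    assert detect_spikes(np.empty(0), np.empty(0)).count == 0


def test_features_of_flat_trace():
    t = np.arange(0, 500, 0.5)
    v = np.full_like(t, -70.0)
    fs = extract_features(t, v)
    assert fs.spike_count == 0
    assert fs.resting_potential == pytest.approx(-70.0)
    assert fs.max_voltage == pytest.approx(-70.0)
    assert np.isnan(fs.ap_amplitude)


def test_single_spike_amplitude_from_threshold():
    t, v = _triangle_train(1, period=400.0)
    fs = extract_features(t, v)
    assert fs.spike_count == 1
    # peak +30 mV relative to the -20 mV detection threshold
    assert fs.ap_amplitude == pytest.approx(50.0, abs=0.5)
    assert fs.max_voltage == pytest.approx(v.max())


def test_max_voltage_is_global_maximum():
    t, v = _triangle_train(3)
    assert extract_features(t, v).max_voltage == v.max()


# ---------------------------------------------------------------------------
# AP vs rest consumption
# ---------------------------------------------------------------------------


def test_ap_vs_rest_with_no_consumption_reports_nan():
    t = np.arange(0, 1000, 0.1)
    cum = np.zeros_like(t)
    out = ap_vs_rest_consumption(t, cum, [500.0])
    assert np.isnan(out["ratio"])


def test_synthetic_tenfold_elevation_recovered():
    t = np.arange(0, 1000, 0.1)
    spikes = [250.0, 500.0, 750.0]
    rate = np.full_like(t, 1e-5)
    for s in spikes:
        rate[np.abs(t - s) <= 2.5] = 1e-4
    cum = np.concatenate([[0.0], np.cumsum(rate[:-1] * np.diff(t))])
    out = ap_vs_rest_consumption(t, cum, spikes)
    assert out["ratio"] == pytest.approx(10.0, rel=0.05)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def _accounts(produced, consumed):
    return [EnergyAccount(i, p, c, 0.0, 1.38, 1.38, 0.0)
            for i, (p, c) in enumerate(zip(produced, consumed))]


def test_identical_production_and_consumption_gives_unit_correlation():
    x = np.linspace(0.1, 0.5, 30)
    tab = supply_demand_correlation(_accounts(x, x), ["a"] * 30)
    assert tab.loc[0, "pearson_r"] == pytest.approx(1.0)


def test_independent_noise_gives_near_zero_correlation():
    rng = np.random.default_rng(42)
    p, c = rng.normal(size=1000), rng.normal(size=1000)
    tab = supply_demand_correlation(_accounts(p, c), ["a"] * 1000)
    assert abs(tab.loc[0, "pearson_r"]) < 0.1


def test_antimonotone_spearman_is_minus_one():
    tab = supply_demand_correlation(_accounts([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]),
                                    ["a"] * 3, spike_counts=[3, 2, 1])
    assert tab.loc[0, "spearman_rho"] == pytest.approx(-1.0)


def test_degenerate_group_is_flagged():
    tab = supply_demand_correlation(_accounts([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),
                                    ["a"] * 3)
    assert np.isnan(tab.loc[0, "pearson_r"])
    assert "degenerate" in tab.loc[0, "note"]


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def test_identical_groups_not_significant_after_adjustment():
    rng = np.random.default_rng(0)
    x = rng.normal(size=40)
    vals = np.concatenate([x, x])
    groups = ["a"] * 40 + ["b"] * 40
    dunn = dunn_test(vals, groups)
    assert dunn.loc[0, "p_adj"] == pytest.approx(1.0, abs=1e-9)


def test_shifted_groups_detected():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, 50)
    b = rng.normal(3.0, 1.0, 50)  # 3 SD shift
    out = group_stats(np.concatenate([a, b]), ["a"] * 50 + ["b"] * 50)
    assert out["dunn"].loc[0, "p_adj"] < 1e-3


def test_bonferroni_is_capped_product():
    p = np.array([0.01, 0.4, 0.9])
    np.testing.assert_allclose(bonferroni(p, 3), [0.03, 1.0, 1.0])


def test_dunn_adjustment_consistent_with_raw_p():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=90)
    groups = np.repeat(["a", "b", "c"], 30)
    dunn = dunn_test(vals, groups)
    m = len(dunn)
    for _, row in dunn.iterrows():
        assert row["p_adj"] == pytest.approx(min(1.0, row["p"] * m))


def test_dunn_agrees_with_kruskal_for_two_groups():
    # with k = 2 the Dunn z equals the (tie-corrected) Kruskal-Wallis
    # statistic's square root up to sign
    rng = np.random.default_rng(5)
    a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1, 30)
    dunn = dunn_test(np.concatenate([a, b]), ["a"] * 25 + ["b"] * 30)
    h = sps.kruskal(a, b).statistic
    assert dunn.loc[0, "z"] ** 2 == pytest.approx(h, rel=1e-9)


def test_small_groups_skipped_with_note():
    tab = shapiro_by_group([1.0, 2.0, 3.0, 4.0], ["a", "a", "a", "b"])
    note = tab.set_index("group").loc["b", "note"]
    assert "skipped" in note


# ---------------------------------------------------------------------------
# surface correlations
# ---------------------------------------------------------------------------


def _feature_frame(n, rng, feature=None):
    area = rng.lognormal(7.0, 0.3, n)
    return pd.DataFrame({
        "layer": [4] * n, "etype": ["cADpyr"] * n, "area_um2": area,
        "spike_count": feature if feature is not None else rng.normal(size=n),
        "max_voltage": rng.normal(size=n),
        "ap_amplitude": rng.normal(size=n),
        "resting_potential": rng.normal(size=n),
    })


def test_area_duplicated_as_feature_gives_unit_correlation():
    rng = np.random.default_rng(0)
    df = _feature_frame(40, rng)
    df["spike_count"] = df["area_um2"]
    out = surface_feature_correlation(df, feature_names=("spike_count",))
    assert out.loc[0, "pearson_r"] == pytest.approx(1.0)


def test_groups_below_twenty_samples_excluded():
    rng = np.random.default_rng(0)
    df = _feature_frame(19, rng)
    df["spike_count"] = df["area_um2"]
    out = surface_feature_correlation(df)
    assert out.empty


def test_independent_feature_usually_filtered_as_insignificant():
    rng = np.random.default_rng(7)
    df = _feature_frame(100, rng)
    out = surface_feature_correlation(df)
    # 4 features at alpha=0.05: typically none survive the filter
    assert len(out) <= 1


# ---------------------------------------------------------------------------
# condition comparison, physiology, energy accounts (on a real smoke run)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def smoke_run(smoke_population):
    from emcosim.coupling import run_coupled
    return run_coupled(smoke_population, 300.0, mode="coupled", seed=5)


def test_compare_identical_runs_gives_zero_differences(smoke_run):
    cmp = compare_conditions(smoke_run, smoke_run)
    assert (cmp["atp_by_layer"]["mean_diff_young_minus_aged"] == 0).all()
    assert (cmp["spike_diff"]["net_diff"] == 0).all()


def test_uniform_atp_shift_recovered_per_layer(smoke_run):
    import copy
    shifted = copy.deepcopy(smoke_run)
    shifted.energy["final_atp"] = smoke_run.energy["final_atp"] - 0.1
    cmp = compare_conditions(smoke_run, shifted)
    np.testing.assert_allclose(
        cmp["atp_by_layer"]["mean_diff_young_minus_aged"], 0.1, atol=1e-12)


def test_mismatched_seeds_rejected(smoke_run):
    import copy
    other = copy.deepcopy(smoke_run)
    other.meta["seed"] = smoke_run.meta["seed"] + 1
    with pytest.raises(ValueError, match="seed"):
        compare_conditions(smoke_run, other)


def test_physiology_validation_passes_on_smoke_run(smoke_run):
    report = validate_physiology(smoke_run)
    assert report["mean_in_range"].all()


def test_physiology_validation_flags_forced_sodium(smoke_run):
    import copy
    bad = copy.deepcopy(smoke_run)
    bad.final_ephys["na_i"] = np.full_like(bad.final_ephys["na_i"], 100.0)
    report = validate_physiology(bad).set_index("species")
    assert not report.loc["na_i", "mean_in_range"]


def test_energy_closure_on_smoke_run(smoke_run):
    for acc in energy_accounts(smoke_run):
        assert abs(acc.closure_residual()) < 1e-9


def test_spike_train_requires_increasing_times():
    with pytest.raises(ValueError):
        SpikeTrain(0, [3.0, 2.0])
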