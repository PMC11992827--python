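import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_peak_table
from oracles import nipals_vip
from ctpdn.metabolomics import (
    differential_screen,
    filter_low_sd,
    filter_missing,
    filter_qc_rsd,
    intersect_panels,
    normalize_table,
    pls_da_vip,
    read_peak_table,
    rf_biomarker_panel,
    write_peak_table,
)
from ctpdn.simulate import SimSpec, gen_peak_table

GROUPS6 = ["Con"] * 3 + ["Mod"] * 3
NOQC6 = [False] * 6


# ---------------------------------------------------------------------------
# filter chain


def test_missing_filter_drops_and_imputes():
    values = np.ones((2, 10))
    values[0, :9] = np.nan           # 90% missing -> removed
    values[1, 1] = np.nan            # imputed with the observed mean
    values[1, 0], values[1, 2] = 2.0, 4.0
    t = make_peak_table(values, ["Con"] * 5 + ["Mod"] * 5, [False] * 10)
    out = filter_missing(t, max_missing=0.8)
    assert out.feature_ids == ["F1"]
    assert out.intensities.iloc[0, 1] == pytest.approx(
        np.nanmean(values[1]), abs=1e-12
    )


def test_missing_filter_identity_without_missing():
    t = make_peak_table(np.arange(12.0).reshape(3, 4) + 1, ["Con", "Con", "Mod", "Mod"],
                        [False] * 4)
    out = filter_missing(t)
    pd.testing.assert_frame_equal(out.intensities, t.intensities)


def test_qc_rsd_filter():
    values = np.array([
        [5, 6, 10.0, 10.0, 10.0],  # RSD 0 -> kept
        [5, 6, 1.0, 3.0, 2.0],     # RSD = 1/2 -> removed
        [5, 6, 0.0, 0.0, 0.0],     # QC mean 0 -> undefined, removed
    ])
    t = make_peak_table(values, ["Con", "Mod", "QC", "QC", "QC"],
                        [False, False, True, True, True])
    out = filter_qc_rsd(t, max_rsd=0.20)
    assert out.feature_ids == ["F0"]
    two_qc = make_peak_table(values[:2, :4], ["Con", "Mod", "QC", "QC"],
                             [False, False, True, True])
    # QC values {1, 3}: sd/mean = sqrt(2)/2 ~ 70.7% -> removed
    assert filter_qc_rsd(two_qc).feature_ids == ["F0"]
    with pytest.raises(ValueError):
        filter_qc_rsd(make_peak_table(values[:, :3], ["Con", "Mod", "QC"],
                                      [False, False, True]))


def test_low_sd_filter_counts_and_tie_order():
    rng = np.random.default_rng(0)
    values = rng.uniform(1, 2, (10, 6)) * np.arange(1, 11)[:, None]
    t = make_peak_table(values, GROUPS6, NOQC6)
    out = filter_low_sd(t, drop_fraction=0.40)
    assert len(out.feature_ids) == 6
    same = make_peak_table(np.tile([1.0, 2.0, 3.0], (4, 1)), ["Con", "Con", "Mod"],
                           [False] * 3)
    kept = filter_low_sd(same, drop_fraction=0.5)
    assert kept.feature_ids == ["F0", "F1"]  # equal SDs: earlier ids survive
    ident = filter_low_sd(t, drop_fraction=0.0)
    assert ident.feature_ids == t.feature_ids


def test_normalization_conserves_totals_centers_and_handles_zeros():
    rng = np.random.default_rng(1)
    values = rng.uniform(10, 100, (5, 6))
    values[0, 0] = 0.0
    t = make_peak_table(values, GROUPS6, NOQC6)
    out = normalize_table(t)
    totals = out.pre_log.sum(axis=0)
    assert np.allclose(totals, totals.iloc[0])
    assert np.allclose(out.intensities.mean(axis=1), 0.0, atol=1e-12)
    assert np.isfinite(out.intensities.to_numpy()).all()


def test_chain_provenance_log(peaks_default):
    t = filter_missing(peaks_default["peaks"])
    t = filter_qc_rsd(t)
    t = filter_low_sd(t)
    t = normalize_table(t)
    assert len(t.log) == 5  # simulated + four stages, in pipeline order
    assert "missing" in t.log[1] and "QC RSD" in t.log[2]
    assert "SD filter" in t.log[3] and "log10" in t.log[4]


def test_peak_table_round_trip(tmp_path, peaks_default):
    path = tmp_path / "peaks.tsv"
    write_peak_table(peaks_default["peaks"], path)
    back = read_peak_table(path)
    orig = peaks_default["peaks"]
    pd.testing.assert_frame_equal(back.intensities, orig.intensities)
    assert (back.groups == orig.groups).all()
    assert (back.is_qc == orig.is_qc).all()


# ---------------------------------------------------------------------------
# VIP


def test_vip_identity_and_single_feature():
    rng = np.random.default_rng(2)
    t = make_peak_table(rng.normal(size=(30, 12)), ["Con"] * 6 + ["Mod"] * 6,
                        [False] * 12)
    vip = pls_da_vip(t, ("Con", "Mod"))
    assert np.mean(vip ** 2) == pytest.approx(1.0, abs=1e-9)
    single = make_peak_table(rng.normal(size=(1, 12)), ["Con"] * 6 + ["Mod"] * 6,
                             [False] * 12)
    assert pls_da_vip(single, ("Con", "Mod")).iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_vip_matches_independent_nipals():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 15))
    y = np.repeat([0.0, 1.0], 10)
    X[:, 4] += 2.0 * y
    t = make_peak_table(X.T, ["Con"] * 10 + ["Mod"] * 10, [False] * 20)
    vip = pls_da_vip(t, ("Con", "Mod"), n_components=2)
    oracle = nipals_vip(X, y, 2)
    assert np.allclose(vip.to_numpy(), oracle, atol=1e-6)


def test_vip_flags_the_informative_feature():
    """One feature with a 3-sd group effect among 49 noise features should
    attain the maximum VIP in nearly every replicate."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(50, 40))
        X[0, 20:] += 3.0
        t = make_peak_table(X, ["Con"] * 20 + ["Mod"] * 20, [False] * 40)
        vip = pls_da_vip(t, ("Con", "Mod"))
        hits += vip.idxmax() == "F0"
    assert hits >= 95


# ---------------------------------------------------------------------------
# differential screen


def _preprocessed(seed=0, n_features=8, effects=None, n=6):
    rng = np.random.default_rng(seed)
    log_mu = rng.uniform(4, 6, n_features)
    X = rng.normal(log_mu[:, None], 0.15, (n_features, 2 * n + 3))
    if effects:
        for j, delta in effects.items():
            X[j, n:2 * n] += delta
    groups = ["Con"] * n + ["Mod"] * n + ["QC"] * 3
    t = make_peak_table(10.0 ** X, groups, [False] * (2 * n) + [True] * 3)
    return normalize_table(filter_missing(t))


def test_screen_boundary_is_strict():
    t = _preprocessed(effects={0: 2.0})
    out = differential_screen(t, ("Con", "Mod"), vip_min=0.0, p_max=1.0, fc_min=1e9)
    assert not out.passes.any()  # fc_min can never be exceeded


def test_screen_agrees_with_handcomputed_oracle():
    """Survivors equal an independent recomputation of all three criteria
    (VIP threshold disabled separately from p and FC)."""
    effects = {0: 0.9, 3: -0.9, 5: 0.02}
    t = _preprocessed(seed=4, n_features=30, effects=effects)
    out = differential_screen(t, ("Con", "Mod"), vip_min=1.0, p_max=0.05, fc_min=1.0)

    con = [s for s in t.intensities.columns if s.startswith("S") and t.groups[s] == "Con"]
    mod = [s for s in t.intensities.columns if t.groups[s] == "Mod"]
    vip = pls_da_vip(t, ("Con", "Mod"))
    expected = []
    for f in t.feature_ids:
        p = stats.ttest_ind(t.intensities.loc[f, mod], t.intensities.loc[f, con],
                            equal_var=False).pvalue
        fc = t.pre_log.loc[f, mod].mean() / t.pre_log.loc[f, con].mean()
        expected.append(bool(vip[f] > 1.0 and p < 0.05 and max(fc, 1 / fc) > 1.0))
    assert list(out.passes) == expected
    assert out.loc[out.feature_id == "F0", "passes"].item()
    assert out.loc[out.feature_id == "F3", "passes"].item()


def test_screen_invariant_to_per_sample_scaling():
    rng = np.random.default_rng(7)
    values = 10.0 ** rng.normal(5, 0.3, (12, 15))
    groups = ["Con"] * 6 + ["Mod"] * 6 + ["QC"] * 3
    qc = [False] * 12 + [True] * 3
    t1 = make_peak_table(values, groups, qc)
    scaled = values.copy()
    scaled[:, 2] *= 37.0  # a global injection-volume artifact on one sample
    t2 = make_peak_table(scaled, groups, qc)
    s1 = differential_screen(normalize_table(filter_missing(t1)), ("Con", "Mod"))
    s2 = differential_screen(normalize_table(filter_missing(t2)), ("Con", "Mod"))
    pd.testing.assert_frame_equal(s1, s2)


def test_screen_requires_normalized_table():
    t = make_peak_table(np.ones((3, 6)), GROUPS6, NOQC6)
    with pytest.raises(ValueError, match="normalize"):
        differential_screen(t, ("Con", "Mod"))


# ---------------------------------------------------------------------------
# biomarker panels


def test_rf_panel_deterministic(peaks_default):
    t = filter_missing(peaks_default["peaks"])
    t = filter_qc_rsd(t)
    t = normalize_table(t)
    p1 = rf_biomarker_panel(t, ("Con", "Mod"), k=10, seed=3, n_estimators=50)
    p2 = rf_biomarker_panel(t, ("Con", "Mod"), k=10, seed=3, n_estimators=50)
    assert p1.features == p2.features
    assert p1.cv_accuracy == p2.cv_accuracy


def test_rf_panel_recovers_planted_markers():
    """With 3 features shifted by 4 sd among 47 noise features and 15
    samples per group, all 3 should make the top-10 panel."""
    d = gen_peak_table(SimSpec(seed=8, n_features=50, n_per_group=15, n_planted=3))
    t = normalize_table(filter_qc_rsd(filter_missing(d["peaks"])))
    p = rf_biomarker_panel(t, ("Con", "Mod"), k=10, seed=8, n_estimators=100)
    assert set(d["truth"]["planted_features"]) <= set(p.features)
    assert p.cv_auc > 0.9


def test_rf_panel_null_auc_band():
    d = gen_peak_table(SimSpec(seed=0, n_features=50, n_per_group=15, effect_size=0.0))
    t = normalize_table(filter_qc_rsd(filter_missing(d["peaks"])))
    p = rf_biomarker_panel(t, ("Con", "Mod"), k=10, seed=0, n_estimators=100)
    assert 0.3 <= p.cv_auc <= 0.7


def test_intersect_panels_orders_and_edge_cases():
    assert intersect_panels(["a", "b", "c"], ["b", "c", "d"]) == ["b", "c"]
    assert intersect_panels(["a"], ["b"]) == []
    assert intersect_panels(["a", "b"], ["b", "a"]) == ["a", "b"]
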