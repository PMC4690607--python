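"""Generator: pulse geometry, hierarchical feature draws, recording assembly."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vsdwave.synthdata as sd
from vsdwave.synthdata import (
    DegeneratePulseError,
    PulseParams,
    make_ap_pulse,
    pulse_metrics,
    simulate_feature_table,
    simulate_recording,
)


@pytest.mark.parametrize(
    "params, expected",
    [
        # symmetric triangle
        (PulseParams(1, 1, 0, 1, 1.0), {"h_max": 1, "m_up": 1, "m_down": -1, "w": 1.0, "h_plateau": 1}),
        # flat-topped trapezoid
        (PulseParams(2, 1, 2, 1, 1.0), {"h_max": 2, "m_up": 2, "m_down": -2, "w": 3.0, "h_plateau": 2}),
        # sagging plateau
        (PulseParams(1, 1, 2, 1, 0.8), {"h_max": 1, "m_up": 1, "m_down": -0.8, "w": 2.875, "h_plateau": 0.90625}),
    ],
)
def test_pulse_closed_forms(params, expected):
    got = pulse_metrics(params)
    for key, val in expected.items():
        assert got[key] == pytest.approx(val, rel=1e-12), key


def test_sagging_trapezoid_crossing_times():
    m = pulse_metrics(PulseParams(1, 1, 2, 1, 0.8))
    assert m["t_up"] == pytest.approx(0.5)
    assert m["t_down"] == pytest.approx(3.375)


def test_pulse_rendering_matches_piecewise_geometry():
    params = PulseParams(2, 1, 2, 1, 0.8)
    t = np.linspace(0, params.duration, 4001)
    y = make_ap_pulse(params, t)
    assert y.max() == pytest.approx(2.0)
    assert y[0] == 0 and y[-1] == pytest.approx(0.0, abs=1e-12)
    # value at the plateau midpoint follows the linear sag A -> pA
    mid = np.interp(2.0, t, y)
    assert mid == pytest.approx(2 - 0.4 * 0.5, rel=1e-6)


def test_pulse_rejects_nonuniform_grid():
    with pytest.raises(ValueError, match="uniform"):
        make_ap_pulse(PulseParams(1, 1, 0, 1), np.array([0, 0.1, 0.3, 0.7]))


def test_degenerate_pulse_rejected():
    with pytest.raises(DegeneratePulseError):
        make_ap_pulse(PulseParams(1, 1, 0, 1, 0.4), np.linspace(0, 2, 100))
    with pytest.raises(DegeneratePulseError):
        pulse_metrics(PulseParams(1, 1, 0, 1, 0.4))
    # p = 0.5 with a plateau is fine: crossing sits at the plateau end
    m = pulse_metrics(PulseParams(1, 1, 2, 1, 0.5))
    assert m["t_down"] == pytest.approx(3.0)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    A=st.floats(0.1, 3.0),
    r=st.floats(0.05, 0.5),
    d=st.floats(0.0, 0.5),
    f=st.floats(0.05, 0.5),
    p=st.floats(0.55, 1.0),
)
def test_pulse_metric_invariants(A, r, d, f, p):
    m = pulse_metrics(PulseParams(A, r, d, f, p))
    assert m["h_max"] > 0
    assert 0 < m["h_plateau"] <= m["h_max"] + 1e-12
    assert m["m_up"] > 0 > m["m_down"]
    assert m["t_up"] < 0.5 * (m["t_up"] + m["t_down"]) < m["t_down"]


def test_feature_table_counts_and_determinism(default_table):
    table, truth = default_table
    counts = table["label"].value_counts()
    assert counts["control"] == 145
    assert counts["propranolol"] == 100
    assert counts["isoproterenol"] == 212
    assert len(truth) == len(table)
    again, _ = simulate_feature_table()
    pd.testing.assert_frame_equal(table, again)


def test_feature_table_means_match_generator_within_monte_carlo_error():
    """Per-condition sample means agree with a large-n draw from the same model."""
    cfg = sd.default_config()
    table, _ = simulate_feature_table(cfg)
    big_counts = {c.label: 20000 for c in cfg.conditions}
    big_cfg = dataclasses.replace(cfg, n_recordings=200)
    big, _ = simulate_feature_table(big_cfg, counts=big_counts, seed=987654)
    for label, group in table.groupby("label"):
        ref = big[big["label"] == label]
        for feat in sd.FEATURES:
            # recordings share a cell-level mean shift, so the standard error
            # must be cluster-robust: computed over recording-level means
            rec_means = group.groupby("recording_id")[feat].mean()
            se = rec_means.std(ddof=1) / np.sqrt(len(rec_means))
            assert abs(group[feat].mean() - ref[feat].mean()) < 3.5 * se, (label, feat)


def test_feature_table_effect_directions():
    table, _ = simulate_feature_table()
    means = table.groupby("label")[sd.FEATURES].mean()
    assert means.loc["isoproterenol", "h_max"] > means.loc["control", "h_max"]
    assert means.loc["isoproterenol", "m_up"] > means.loc["control", "m_up"]
    assert means.loc["isoproterenol", "h_plateau"] > means.loc["control", "h_plateau"]
    assert means.loc["isoproterenol", "w"] < means.loc["control", "w"]
    assert means.loc["propranolol", "w"] > means.loc["control", "w"]


def test_feature_table_rejects_zero_counts():
    with pytest.raises(ValueError, match="counts"):
        simulate_feature_table(counts={"control": 0, "propranolol": 1, "isoproterenol": 1})


def test_zero_variance_distinct_means_is_perfectly_separable():
    from vsdwave import forest

    conds = tuple(
        dataclasses.replace(
            c, pulse_sd={k: 0.0 for k in c.pulse_sd}, cell_level_fraction=0.0
        )
        for c in sd.DEFAULT_CONDITIONS
    )
    cfg = sd.SynthConfig(conditions=conds)
    table, _ = simulate_feature_table(cfg, seed=5)
    train, valid = forest.stratified_split(table, forest.SplitSpec(seed=5))
    model = forest.train_forest(train, seed=5)
    pred = forest.predict(model, valid)
    assert (pred.predicted.to_numpy() == valid["label"].to_numpy()).mean() == 1.0


def test_recording_ground_truth_consistency():
    cfg = sd.SynthConfig(n_lines=4000, line_period=0.002, n_membranes=2, noise_sd=0.01)
    rec, truth = simulate_recording(cfg, "control", seed=3)
    assert rec.intensity.shape == (4000, 128)
    assert np.all(np.diff(truth.onset_times) > 0)
    assert truth.centers.shape == (4000, 2)
    assert truth.centers.min() >= 0 and truth.centers.max() < 128
    # shared onsets: metrics frame has one row per membrane per beat
    assert len(truth.metrics) == 2 * len(truth.onset_times)
    rec2, truth2 = simulate_recording(cfg, "control", seed=3)
    np.testing.assert_array_equal(rec.intensity, rec2.intensity)


def test_recording_warns_on_unresolvable_membranes():
    cfg = sd.SynthConfig(n_lines=200, n_membranes=5, pixels_per_line=32, sigma_psf=2.0)
    with pytest.warns(UserWarning, match="unresolvable"):
        simulate_recording(cfg, "control", seed=1)


def test_recording_rejects_out_of_frame_motion():
    cfg = sd.SynthConfig(
        n_lines=2000, pixels_per_line=16, n_membranes=1, motion_amplitude=12.0,
        sigma_psf=1.0, noise_sd=0.0,
    )
    with pytest.raises(ValueError, match="out of frame"):
        simulate_recording(cfg, "isoproterenol", seed=2)


def test_config_and_recording_roundtrip(tmp_path):
    cfg = sd.SynthConfig(n_lines=300, n_membranes=1)
    sd.write_config(cfg, tmp_path / "cfg.yaml")
    back = sd.read_config(tmp_path / "cfg.yaml")
    assert back == cfg

    from vsdwave import motion

    rec, truth = simulate_recording(cfg, "control", seed=9)
    sd.write_recording(rec, tmp_path / "rec.tif", truth)
    loaded = motion.read_recording(tmp_path / "rec.tif")
    assert loaded.intensity.shape == rec.intensity.shape
    assert loaded.line_period == rec.line_period
    # 16-bit quantization keeps relative error small
    scale = loaded.metadata["intensity_scale"]
    np.testing.assert_allclose(loaded.intensity / scale, rec.intensity, atol=1.0)
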