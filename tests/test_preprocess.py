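import numpy as np
import pandas as pd
import pytest

import ieegface as f
from ieegface import preprocess as pp
from ieegface.containers import RejectionLog
from conftest import make_flat_recording


def _design_row(trial=0, block=1, onset_s=10.0, fixation_ms=400.0,
                face1_ms=500.0, soa_ms=600.0, catch=False, **kw):
    face1 = onset_s + fixation_ms / 1000.0
    face2 = face1 + face1_ms / 1000.0
    row = {"trial": trial, "block": block, "emotion": "happy",
           "gaze": "direct", "catch": catch, "fixation_ms": fixation_ms,
           "face1_ms": face1_ms, "soa_ms": np.nan if catch else soa_ms,
           "target_side": "none" if catch else "left", "onset_s": onset_s,
           "face1_s": face1, "face2_s": face2,
           "target_s": np.nan if catch else face2 + soa_ms / 1000.0}
    row.update(kw)
    return row


# ------------------------------------------------------------------ filters

def test_highpass_removes_dc():
    rate, n = 400.0, 8000
    contacts = make_flat_recording(pd.DataFrame([_design_row()]),
                                   n_contacts=1).contacts
    rec = f.ContactRecording(np.full((1, n), 100.0), rate, contacts)
    out = pp.apply_filters(rec, "all")
    mid = out.signal[0, n // 4: 3 * n // 4]
    assert np.abs(mid).max() < 1e-6 * 100.0


@pytest.mark.parametrize("freq,check", [(50.0, "le_gain"), (10.0, "passband")])
def test_sinusoid_response_matches_transfer_function(freq, check):
    """Residual sinusoid amplitude tracks the cascade's magnitude response,
    evaluated independently from the filter coefficients."""
    rate, n = 400.0, 20000
    t = np.arange(n) / rate
    contacts = make_flat_recording(pd.DataFrame([_design_row()]),
                                   n_contacts=1).contacts
    rec = f.ContactRecording(np.sin(2 * np.pi * freq * t)[None, :], rate,
                             contacts)
    out = pp.apply_filters(rec, "all")
    mid = out.signal[0, n // 4: 3 * n // 4]
    tm = t[n // 4: 3 * n // 4]
    # amplitude of the residual component at the probe frequency
    amp = np.hypot(2 * np.mean(mid * np.cos(2 * np.pi * freq * tm)),
                   2 * np.mean(mid * np.sin(2 * np.pi * freq * tm)))
    # zero-phase filtering applies the magnitude response twice
    gain = pp.cascade_gain(rate, freq, "all") ** 2
    if check == "le_gain":
        assert amp <= gain + 1e-6  # numerical floor of filtfilt
    else:
        assert amp == pytest.approx(1.0, rel=0.05)
        assert gain == pytest.approx(1.0, rel=0.05)


def test_rate_too_low_rejected():
    with pytest.raises(ValueError):
        pp.filter_cascade_sos(120.0, "all")


# ----------------------------------------------------------------- epoching

def test_long_epoch_window_arithmetic():
    """Fixation at 10 s, target at 11.5 s, 400 Hz -> [9.6, 12.5) s,
    1160 samples."""
    design = pd.DataFrame([_design_row(onset_s=10.0, fixation_ms=400.0,
                                       face1_ms=500.0, soa_ms=600.0)])
    rec = make_flat_recording(design)
    long = pp.epoch_long_trials(rec, design)
    assert long.epochs[0].shape[1] == 1160
    assert long.events["fix_idx"].iloc[0] == int(0.4 * 400)


def test_catch_trial_epoch_anchoring():
    """Catch epochs end at Face 2 + max SOA + 1 s."""
    design = pd.DataFrame([_design_row(catch=True)])
    rec = make_flat_recording(design)
    long = pp.epoch_long_trials(rec, design)
    expected = (0.4 + design["fixation_ms"].iloc[0] / 1000.0
                + design["face1_ms"].iloc[0] / 1000.0 + 0.45 + 1.0)
    assert long.epochs[0].shape[1] == int(round(expected * 400))


def test_empty_design_and_out_of_bounds_flagging():
    design = pd.DataFrame([_design_row()])
    rec = make_flat_recording(design)
    empty = pp.epoch_long_trials(rec, design.iloc[0:0])
    assert empty.n_trials == 0
    far = pd.DataFrame([_design_row(onset_s=1e4)])
    long = pp.epoch_long_trials(rec, far)
    assert long.epochs[0] is None
    assert not long.events["in_bounds"].iloc[0]


# ------------------------------------------------------------ artifact rules

def _long_from(design, signal_editor=None):
    rec = make_flat_recording(design)
    if signal_editor is not None:
        signal_editor(rec)
    return pp.epoch_long_trials(rec, design)


def test_threshold_crossing_rejected():
    design = pd.DataFrame([_design_row()])

    def plant(rec):
        i = int(design["face1_s"].iloc[0] * 400)
        rec.signal[0, i:i + 10] = 800.0

    long = _long_from(design, plant)
    out, log = pp.reject_artifacts(long)
    assert out.n_trials == 0
    assert log.to_frame()["reason"].iloc[0] == "threshold"


def test_artifact_outside_window_retained():
    """A sub-threshold transient 600 ms before Face 1 does not reject."""
    design = pd.DataFrame([_design_row()])

    def plant(rec):
        i = int((design["face1_s"].iloc[0] - 0.6) * 400)
        rec.signal[0, i] = 400.0  # sharp jump, below +-750 uV

    long = _long_from(design, plant)
    out, log = pp.reject_artifacts(long)
    assert out.n_trials == 1 and len(log) == 0


def test_artifact_inside_window_rejected():
    design = pd.DataFrame([_design_row()])

    def plant(rec):
        i = int((design["face1_s"].iloc[0] - 0.3) * 400)
        rec.signal[0, i] = 400.0

    long = _long_from(design, plant)
    out, log = pp.reject_artifacts(long)
    assert out.n_trials == 0
    assert log.to_frame()["reason"].iloc[0] == "epileptic/artifact"


def test_clean_trials_all_retained():
    rows = [_design_row(trial=i, onset_s=10.0 + 5 * i) for i in range(20)]
    design = pd.DataFrame(rows)
    long = _long_from(design)
    out, log = pp.reject_artifacts(long)
    assert out.n_trials == 20 and len(log) == 0


def test_missing_blink_channel_warns_not_fails():
    design = pd.DataFrame([_design_row()])
    long = _long_from(design)
    out, log = pp.reject_artifacts(long, blink_channel="EOG")
    assert out.n_trials == 1
    assert any("blink" in m for m in log.messages)


def test_rejection_monotone():
    """Adding an artifact never increases the retained count."""
    rows = [_design_row(trial=i, onset_s=10.0 + 5 * i) for i in range(5)]
    design = pd.DataFrame(rows)
    clean, _ = pp.reject_artifacts(_long_from(design))

    def plant(rec):
        i = int(design["face1_s"].iloc[2] * 400)
        rec.signal[1, i] = 900.0

    dirty, _ = pp.reject_artifacts(_long_from(design, plant))
    assert dirty.n_trials < clean.n_trials


# ------------------------------------------------------- behavioral filters

def _responses(trials, rts):
    return pd.DataFrame([{"trial": t, "pressed": np.isfinite(r), "rt_ms": r}
                         for t, r in zip(trials, rts)])


def test_rt_outlier_three_sd():
    """RTs {300 x 49, 3000} -> the 3000 ms trial is a > 3 SD outlier."""
    rows = [_design_row(trial=i, onset_s=10.0 + 5 * i) for i in range(50)]
    design = pd.DataFrame(rows)
    rts = [300.0 + 0.01 * i for i in range(49)] + [3000.0]
    vals = np.array(rts)
    assert 3000.0 > vals.mean() + 3 * vals.std(ddof=1)  # oracle
    long = pp.epoch_long_trials(make_flat_recording(design), design)
    out, log = pp.apply_behavioral_exclusions(long, _responses(range(50), rts))
    frame = log.to_frame()
    assert out.n_trials == 49
    assert frame.loc[frame["trial"] == 49, "reason"].iloc[0] == \
        "behavior_rt_outlier"


def test_block_below_half_dropped():
    """A block keeping fewer than half its designed trials is removed."""
    design = f.build_trial_design(1, rng_seed=3)
    # respond only to the first 40 target trials
    resp = []
    n_ok = 0
    for t in design.itertuples(index=False):
        if t.catch:
            resp.append({"trial": t.trial, "pressed": False, "rt_ms": np.nan})
        else:
            ok = n_ok < 40
            n_ok += 1
            resp.append({"trial": t.trial, "pressed": ok,
                         "rt_ms": 350.0 if ok else np.nan})
    long = pp.epoch_long_trials(make_flat_recording(design), design)
    out, log = pp.apply_behavioral_exclusions(long, pd.DataFrame(resp))
    assert out.n_trials == 0
    assert log.block_retention[1] < 0.5
    assert "block_dropped" in set(log.to_frame()["reason"])


def test_clean_behavior_nothing_dropped():
    rows = [_design_row(trial=i, onset_s=10.0 + 5 * i) for i in range(10)]
    design = pd.DataFrame(rows)
    long = pp.epoch_long_trials(make_flat_recording(design), design)
    out, log = pp.apply_behavioral_exclusions(
        long, _responses(range(10), [350.0] * 10))
    assert out.n_trials == 10 and len(log) == 0


# ------------------------------------------------------------- downsampling

def test_downsample_identity_at_400(small_design):
    design = small_design.head(3)
    long = pp.epoch_long_trials(make_flat_recording(design), design)
    out = pp.downsample_to_400(long)
    assert out is long  # bit-identical passthrough


def test_downsample_1024_lengths_and_unsupported_rate():
    design = pd.DataFrame([_design_row()])
    rec = make_flat_recording(design, rate=1024.0)
    long = pp.epoch_long_trials(rec, design)
    n_in = long.epochs[0].shape[1]
    out = pp.downsample_to_400(long)
    assert out.rate == 400.0
    assert out.epochs[0].shape[1] == int(np.ceil(n_in * 25 / 64))
    long.rate = 512.0
    with pytest.raises(ValueError):
        pp.downsample_to_400(long)


def test_downsample_preserves_10hz_amplitude():
    design = pd.DataFrame([_design_row()])
    rate = 1024.0

    def plant(rec):
        t = np.arange(rec.n_samples) / rate
        rec.signal[:] = np.sin(2 * np.pi * 10.0 * t)

    rec = make_flat_recording(design, rate=rate)
    plant(rec)
    long = pp.epoch_long_trials(rec, design)
    out = pp.downsample_to_400(long)
    mid = out.epochs[0][0][100:-100]
    assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)


# --------------------------------------------------------- bipolar montage

def test_bipolar_common_mode_and_midpoint(small_design):
    design = small_design.head(2)
    rec = make_flat_recording(design, n_contacts=8)
    rng = np.random.default_rng(0)
    common = rng.standard_normal(rec.n_samples)
    rec.signal[:] = common  # identical on all contacts
    long = pp.epoch_long_trials(rec, design)
    bip, sites = pp.derive_bipolar(long)
    assert len(sites) == 7  # 8 contacts -> 7 adjacent pairs
    for ep in bip.epochs:
        np.testing.assert_array_equal(ep, 0.0)
    # midpoint rule: contacts at x = 30 and 35 -> site at 32.5
    assert sites[0].x == pytest.approx(32.5)
    assert sites[0].hemisphere == "R"


def test_bipolar_skips_pairs_across_excluded_contact(small_design):
    design = small_design.head(1)
    rec = make_flat_recording(design, n_contacts=8)
    rec.contacts.loc[3, "excluded"] = True  # contact index 4
    long = pp.epoch_long_trials(rec, design)
    bip, sites = pp.derive_bipolar(long)
    pairs = {(s.deep_index, s.shallow_index) for s in sites}
    assert pairs == {(1, 2), (2, 3), (5, 6), (6, 7), (7, 8)}


def test_bipolar_single_contact_shaft_warns(small_design):
    design = small_design.head(1)
    rec = make_flat_recording(design, n_contacts=2)
    rec.contacts.loc[1, "excluded"] = True
    long = pp.epoch_long_trials(rec, design)
    bip, sites = pp.derive_bipolar(long, log=(log := RejectionLog()))
    assert sites == []
    assert any("fewer than 2" in m for m in log.messages)


def test_bipolar_is_deep_minus_shallow(small_design):
    design = small_design.head(1)
    rec = make_flat_recording(design, n_contacts=2)
    rec.signal[0, :] = 5.0
    rec.signal[1, :] = 2.0
    long = pp.epoch_long_trials(rec, design)
    bip, sites = pp.derive_bipolar(long)
    assert np.allclose(bip.epochs[0][0], 3.0)


# ------------------------------------------------------------- z-scoring

def _zscore_setup(step_z=0.0, noise_sd=1.0, seed=0):
    design = pd.DataFrame([_design_row(trial=i, onset_s=10.0 + 5 * i)
                           for i in range(30)])
    rec = make_flat_recording(design, n_contacts=2)
    rng = np.random.default_rng(seed)
    rec.signal[:] = noise_sd * rng.standard_normal(rec.signal.shape)
    if step_z:
        for t in design.itertuples(index=False):
            i = int(round(t.face1_s * 400))
            rec.signal[:, i:i + 200] += step_z * noise_sd
    long = pp.epoch_long_trials(rec, design)
    bip, sites = pp.derive_bipolar(long)
    return long, sites


def test_zscore_baseline_exact():
    long, _ = _zscore_setup()
    es = pp.extract_and_zscore(long, "face1")
    base = es.data[:, es.times < 0, :]
    assert np.allclose(base.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose(base.std(axis=1, ddof=1), 1.0, atol=1e-12)
    assert es.times[0] == -100.0 and es.times[-1] == 400.0


def test_zscore_step_recovery():
    """A 2-sigma step at onset lands near z = 2 (baseline-sampling error)."""
    long, _ = _zscore_setup(step_z=2.0)
    es = pp.extract_and_zscore(long, "face1")
    post = es.data[:, (es.times > 50) & (es.times < 300), :]
    assert post.mean() == pytest.approx(2.0, abs=0.3)


def test_zscore_degenerate_baseline_dropped():
    design = pd.DataFrame([_design_row()])
    long = pp.epoch_long_trials(make_flat_recording(design), design)
    log = RejectionLog()
    es = pp.extract_and_zscore(long, "face1", log=log)
    assert es.n_trials == 0
    assert log.to_frame()["reason"].iloc[0] == "degenerate_baseline"


# ------------------------------------------------------- behavioral summary

def test_behavior_summary_examples():
    rows = [_design_row(trial=i, onset_s=10.0 + 5 * i, catch=i >= 10)
            for i in range(14)]
    design = pd.DataFrame(rows)
    resp = _responses(range(14), [350.0] * 10 + [np.nan, np.nan, np.nan, 400.0])
    s = pp.summarize_behavior(resp, design)
    assert s.hit_rate == 1.0
    assert s.false_alarm_rate == pytest.approx(0.25)  # 1 press on 4 catch


def test_behavior_trimmed_mean():
    """RTs {350 x 99, 1200}: the trimmed mean is computed on 99 values."""
    rows = [_design_row(trial=i, onset_s=10.0 + 5 * i) for i in range(100)]
    design = pd.DataFrame(rows)
    rts = [350.0 + 0.1 * i for i in range(99)] + [1200.0]
    s = pp.summarize_behavior(_responses(range(100), rts), design)
    assert s.mean_rt_ms == pytest.approx(np.mean(rts[:99]))


def test_behavior_no_targets_flagged():
    design = pd.DataFrame([_design_row(catch=True)])
    s = pp.summarize_behavior(_responses([0], [np.nan]), design)
    assert not s.defined


# ------------------------------------------------------------ pipeline order

def test_stage_provenance(pipeline_outputs):
    epoch_sets, sites, log, truth = pipeline_outputs
    stages = epoch_sets["face1"].stages
    order = ["filter:initial", "epoch", "reject_artifacts", "behavior",
             "lowpass40", "bipolar", "zscore:face1"]
    positions = [stages.index(s) for s in order]
    assert positions == sorted(positions)
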