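"""Monopolar recordings -> artifact-cleaned, z-scored bipolar epochs.

Pipeline order (stamped into ``stages`` as provenance):

1. high-pass 0.3 Hz (order-4 Butterworth) + band-stop 48-52 and 58-66 Hz
   (order-4 Butterworth), zero-phase;
2. one long epoch per trial, fixation - 400 ms to target + 1 s;
3. artifact rejection: +-750 uV threshold anywhere in the epoch, spike-like
   transients and blinks inside [Face 1 - 500 ms, target + 300 ms];
4. behavioral exclusions (pre-target presses, misses, false alarms,
   +-3 SD reaction-time trim), then whole blocks retaining < 50% dropped;
5. low-pass 40 Hz (order-6 Butterworth) and downsampling to 400 Hz;
6. bipolar derivation, deeper minus shallower adjacent contacts per shaft;
7. extraction of [-100, +400] ms epochs locked to Face 1 or Face 2 with
   trial-by-trial baseline ([-100, 0) ms) z-scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .anatomy import assign_roi, hemisphere_of
from .containers import (BehavioralSummary, BipolarSite, ContactRecording,
                         EpochSet, LongEpochs, RejectionLog)
from .design import MAX_SOA_MS

TARGET_RATE = 400.0
VOLTAGE_THRESHOLD_UV = 750.0
ARTIFACT_WINDOW_PRE_S = 0.5   # before Face 1 onset
ARTIFACT_WINDOW_POST_S = 0.3  # after target onset
EPOCH_PRE_FIX_S = 0.4
EPOCH_POST_TARGET_S = 1.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_cascade_sos(rate: float, stage: str = "all") -> list:
    """Second-order sections of the Butterworth cascade.

    ``stage``: 'initial' (high-pass + both band-stops), 'lowpass' (40 Hz
    low-pass applied later in the pipeline), or 'all'.
    """
    if rate <= 2 * 66.0 and stage in ("initial", "all"):
        raise ValueError(f"rate {rate} Hz too low for the 58-66 Hz band-stop")
    if rate <= 2 * 40.0 and stage in ("lowpass", "all"):
        raise ValueError(f"rate {rate} Hz too low for the 40 Hz low-pass")
    cascade = []
    if stage in ("initial", "all"):
        cascade.append(sps.butter(4, 0.3, "highpass", fs=rate, output="sos"))
        cascade.append(sps.butter(4, (48.0, 52.0), "bandstop", fs=rate, output="sos"))
        cascade.append(sps.butter(4, (58.0, 66.0), "bandstop", fs=rate, output="sos"))
    if stage in ("lowpass", "all"):
        cascade.append(sps.butter(6, 40.0, "lowpass", fs=rate, output="sos"))
    return cascade


def cascade_gain(rate: float, freq_hz: float, stage: str = "all") -> float:
    """Magnitude response of the cascade at one frequency (for verification)."""
    gain = 1.0
    for sos in filter_cascade_sos(rate, stage):
        _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=rate)
        gain *= float(np.abs(h[0]))
    return gain


def apply_filters(rec: ContactRecording, stage: str = "all") -> ContactRecording:
    """Zero-phase (forward-backward) application of the Butterworth cascade."""
    if not np.all(np.isfinite(rec.signal)):
        raise ValueError("signal contains non-finite values")
    out = rec.signal
    for sos in filter_cascade_sos(rec.rate, stage):
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return ContactRecording(signal=out, rate=rec.rate, contacts=rec.contacts,
                            patient=rec.patient,
                            stages=rec.stages + [f"filter:{stage}"])


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def _trial_window_s(trial) -> tuple:
    """(start, end, face1, face2, target_or_nan) absolute times in seconds.

    Catch trials (no target) anchor the epoch end to the latest possible
    target time, Face 2 + max SOA.
    """
    if np.isfinite(trial.target_s):
        t_target = trial.target_s
    else:
        t_target = trial.face2_s + MAX_SOA_MS / 1000.0
    start = trial.onset_s - EPOCH_PRE_FIX_S
    end = t_target + EPOCH_POST_TARGET_S
    return start, end, trial.face1_s, trial.face2_s, t_target


def epoch_long_trials(rec: ContactRecording, design: pd.DataFrame) -> LongEpochs:
    """One long epoch per trial; half-open sample windows [start, end).

    Sample indices are obtained by rounding event times to the nearest
    sample.  Trials with events outside the recording are flagged
    (``in_bounds`` False, epoch None), never silently dropped.
    """
    epochs, rows = [], []
    rate = rec.rate
    for trial in design.itertuples(index=False):
        start, end, f1, f2, tgt = _trial_window_s(trial)
        i0, i1 = int(round(start * rate)), int(round(end * rate))
        ok = 0 <= i0 < i1 <= rec.n_samples
        epochs.append(rec.signal[:, i0:i1].copy() if ok else None)
        rows.append({
            "trial": trial.trial, "block": trial.block,
            "fix_idx": int(round(trial.onset_s * rate)) - i0,
            "face1_idx": int(round(f1 * rate)) - i0,
            "face2_idx": int(round(f2 * rate)) - i0,
            "target_idx": int(round(tgt * rate)) - i0,
            "has_target": bool(np.isfinite(trial.target_s)),
            "in_bounds": ok,
        })
    return LongEpochs(epochs=epochs, rate=rate, events=pd.DataFrame(rows),
                      contacts=rec.contacts,
                      design=design.reset_index(drop=True),
                      patient=rec.patient, stages=rec.stages + ["epoch"])


# ---------------------------------------------------------------------------
# artifact rejection
# ---------------------------------------------------------------------------

def reject_artifacts(long: LongEpochs, blink_channel: str | None = None,
                     log: RejectionLog | None = None,
                     spike_jump_uv: float = 150.0,
                     blink_threshold_uv: float = 100.0):
    """Drop trials with threshold crossings, transients, or blinks.

    * any retained in-brain contact exceeding +-750 uV anywhere in the long
      epoch -> reason ``threshold``;
    * a spike-like transient (sample-to-sample jump > ``spike_jump_uv``) on
      a retained contact inside [Face 1 - 500 ms, target + 300 ms]
      -> ``epileptic/artifact``;
    * blink (|amplitude| > ``blink_threshold_uv`` on the designated scalp
      channel) inside the same window -> ``blink``.  If the blink channel is
      absent the criterion is skipped with a logged warning.

    Returns ``(retained LongEpochs, RejectionLog)``.
    """
    log = log if log is not None else RejectionLog()
    contacts = long.contacts
    keep_ch = np.flatnonzero((contacts["in_brain"] & ~contacts["excluded"]).to_numpy())
    blink_idx = None
    if blink_channel is not None:
        hit = np.flatnonzero(contacts["channel"].to_numpy() == blink_channel)
        if hit.size:
            blink_idx = int(hit[0])
        else:
            log.warn(f"blink channel {blink_channel!r} absent; "
                     "blink criterion skipped")

    rate = long.rate
    keep = np.ones(long.n_trials, dtype=bool)
    for i, (ep, ev) in enumerate(zip(long.epochs, long.events.itertuples(index=False))):
        if ep is None:
            continue
        block = long.events["block"].iloc[i]
        w0 = max(0, ev.face1_idx - int(round(ARTIFACT_WINDOW_PRE_S * rate)))
        w1 = min(ep.shape[1], ev.target_idx + int(round(ARTIFACT_WINDOW_POST_S * rate)))
        if np.abs(ep[keep_ch]).max() > VOLTAGE_THRESHOLD_UV:
            log.reject(ev.trial, "threshold", block)
            keep[i] = False
        elif w1 > w0 + 1 and np.abs(
                np.diff(ep[keep_ch, w0:w1], axis=1)).max() > spike_jump_uv:
            log.reject(ev.trial, "epileptic/artifact", block)
            keep[i] = False
        elif blink_idx is not None and w1 > w0 and np.abs(
                ep[blink_idx, w0:w1]).max() > blink_threshold_uv:
            log.reject(ev.trial, "blink", block)
            keep[i] = False
    out = long.subset(keep)
    out.stages.append("reject_artifacts")
    return out, log


# ---------------------------------------------------------------------------
# behavioral exclusions and summary
# ---------------------------------------------------------------------------

def apply_behavioral_exclusions(long: LongEpochs, responses: pd.DataFrame,
                                log: RejectionLog | None = None,
                                min_block_fraction: float = 0.5):
    """Exclude trials with aberrant behavior, then under-filled blocks.

    Order: presses before target onset first, then misses and false alarms,
    then the +-3 SD reaction-time trim (mean/SD over the patient's remaining
    target-trial RTs).  Any block retaining less than
    ``min_block_fraction`` of its designed trials is dropped entirely.
    """
    log = log if log is not None else RejectionLog()
    resp = responses.set_index("trial")
    design = long.design

    reasons: dict[int, str] = {}
    rts = {}
    for trial in design.itertuples(index=False):
        if trial.trial not in resp.index:
            continue
        r = resp.loc[trial.trial]
        pressed = bool(r["pressed"])
        rt = r["rt_ms"]
        if trial.catch:
            if pressed:
                reasons[trial.trial] = "behavior_false_alarm"
        else:
            if pressed and np.isfinite(rt) and rt < 0:
                # press before target onset: excluded first
                reasons[trial.trial] = "behavior_false_alarm"
            elif not pressed or not np.isfinite(rt):
                reasons[trial.trial] = "behavior_miss"
            else:
                rts[trial.trial] = float(rt)

    if len(rts) >= 2:
        vals = np.array(list(rts.values()))
        mean, sd = vals.mean(), vals.std(ddof=1)
        lo, hi = mean - 3 * sd, mean + 3 * sd
        for t, rt in rts.items():
            if rt < lo or rt > hi:
                reasons[t] = "behavior_rt_outlier"

    keep = np.ones(long.n_trials, dtype=bool)
    blocks = long.events["block"].to_numpy()
    trials = long.events["trial"].to_numpy()
    for i, t in enumerate(trials):
        if t in reasons:
            log.reject(t, reasons[t], blocks[i])
            keep[i] = False

    # block-level retention relative to the designed block size
    designed = design.groupby("block")["trial"].count()
    for block, n_designed in designed.items():
        n_kept = int(np.sum(keep & (blocks == block)))
        frac = n_kept / n_designed
        log.block_retention[int(block)] = frac
        if frac < min_block_fraction:
            for i in np.flatnonzero(keep & (blocks == block)):
                log.reject(trials[i], "block_dropped", block)
                keep[i] = False
    out = long.subset(keep)
    out.stages.append("behavior")
    return out, log


def summarize_behavior(responses: pd.DataFrame,
                       design: pd.DataFrame) -> BehavioralSummary:
    """Hit rate, false-alarm rate, and trimmed mean reaction time.

    Presses before target onset are excluded before all metrics; the mean
    RT is computed after discarding RTs beyond +-3 SD of the patient mean.
    """
    merged = design.merge(responses, on="trial", how="left")
    pretarget = merged["pressed"].fillna(False) & (merged["rt_ms"] < 0)
    n_pre = int(pretarget.sum())
    merged = merged.loc[~pretarget]

    targets = merged.loc[~merged["catch"]]
    catch = merged.loc[merged["catch"]]
    if len(targets) == 0:
        return BehavioralSummary(np.nan, np.nan, np.nan, (np.nan, np.nan),
                                 0, len(catch), n_pre, defined=False)
    hits = targets["pressed"].fillna(False) & np.isfinite(targets["rt_ms"])
    hit_rate = float(hits.mean())
    fa_rate = float(catch["pressed"].fillna(False).mean()) if len(catch) else 0.0

    rts = targets.loc[hits, "rt_ms"].to_numpy(dtype=float)
    if rts.size >= 2:
        lo = rts.mean() - 3 * rts.std(ddof=1)
        hi = rts.mean() + 3 * rts.std(ddof=1)
        kept = rts[(rts >= lo) & (rts <= hi)]
        mean_rt = float(kept.mean())
        bounds = (float(lo), float(hi))
    elif rts.size:
        mean_rt, bounds = float(rts.mean()), (np.nan, np.nan)
    else:
        mean_rt, bounds = np.nan, (np.nan, np.nan)
    return BehavioralSummary(hit_rate, fa_rate, mean_rt, bounds,
                             int(len(targets)), int(len(catch)), n_pre)


# ---------------------------------------------------------------------------
# low-pass + downsampling
# ---------------------------------------------------------------------------

def lowpass_40(long: LongEpochs) -> LongEpochs:
    """Zero-phase 40 Hz order-6 Butterworth low-pass on each long epoch."""
    sos = filter_cascade_sos(long.rate, "lowpass")[0]
    out = [None if ep is None else sps.sosfiltfilt(sos, ep, axis=-1)
           for ep in long.epochs]
    return LongEpochs(epochs=out, rate=long.rate, events=long.events,
                      contacts=long.contacts, design=long.design,
                      patient=long.patient, stages=long.stages + ["lowpass40"])


def downsample_to_400(long: LongEpochs) -> LongEpochs:
    """Polyphase resampling to 400 Hz (anti-aliasing by the prior 40 Hz LP).

    400 Hz input passes through bit-identical.  1024 -> 400 Hz uses the
    rational factor 25/64; output length is ceil(n * 25 / 64).
    """
    if long.rate == TARGET_RATE:
        return long
    if long.rate != 1024:
        raise ValueError(f"unsupported rate {long.rate}; expected 400 or 1024")
    up, down = 25, 64
    factor = TARGET_RATE / long.rate
    out = [None if ep is None else sps.resample_poly(ep, up, down, axis=-1)
           for ep in long.epochs]
    ev = long.events.copy()
    for col in ("fix_idx", "face1_idx", "face2_idx", "target_idx"):
        ev[col] = np.round(ev[col] * factor).astype(int)
    return LongEpochs(epochs=out, rate=TARGET_RATE, events=ev,
                      contacts=long.contacts, design=long.design,
                      patient=long.patient, stages=long.stages + ["resample400"])


# ---------------------------------------------------------------------------
# bipolar derivation
# ---------------------------------------------------------------------------

def derive_bipolar(long: LongEpochs, log: RejectionLog | None = None):
    """Re-express contacts as bipolar sites (deeper minus shallower).

    One site per pair of *adjacent* retained contacts on the same shaft;
    pairs spanning an excluded contact are not formed.  Site coordinate is
    the arithmetic midpoint of the two contact coordinates; the anatomical
    label (and hence ROI) is taken from the deeper contact.
    """
    log = log if log is not None else RejectionLog()
    contacts = long.contacts
    sites, pairs = [], []
    for shaft, grp in contacts.groupby("shaft", sort=False):
        grp = grp.loc[grp["in_brain"] & ~grp["excluded"] & ~grp["is_blink"]]
        grp = grp.sort_values("index")
        if len(grp) < 2:
            if len(grp) == 1:
                log.warn(f"shaft {shaft!r}: fewer than 2 retained contacts; "
                         "no bipolar sites formed")
            continue
        idx = grp["index"].to_numpy()
        rows = grp.index.to_numpy()
        for a in range(len(grp) - 1):
            if idx[a + 1] != idx[a] + 1:
                continue  # gap across an excluded contact
            deep, shal = grp.iloc[a], grp.iloc[a + 1]
            mid = (np.array([deep["x"], deep["y"], deep["z"]]) +
                   np.array([shal["x"], shal["y"], shal["z"]])) / 2.0
            roi = assign_roi(deep["label"])
            sites.append(BipolarSite(
                shaft=shaft, deep_index=int(deep["index"]),
                shallow_index=int(shal["index"]),
                x=float(mid[0]), y=float(mid[1]), z=float(mid[2]),
                label=deep["label"], roi=roi,
                hemisphere=hemisphere_of(mid[0]), patient=long.patient))
            pairs.append((rows[a], rows[a + 1]))

    out_epochs = []
    for ep in long.epochs:
        if ep is None:
            out_epochs.append(None)
            continue
        out_epochs.append(np.stack([ep[d] - ep[s] for d, s in pairs], axis=0)
                          if pairs else np.empty((0, ep.shape[1])))
    site_meta = pd.DataFrame([{
        "channel": s.name, "shaft": s.shaft, "index": s.deep_index,
        "label": s.label, "x": s.x, "y": s.y, "z": s.z,
        "in_brain": True, "excluded": False, "is_blink": False}
        for s in sites])
    bip = LongEpochs(epochs=out_epochs, rate=long.rate, events=long.events,
                     contacts=site_meta, design=long.design,
                     patient=long.patient, stages=long.stages + ["bipolar"])
    return bip, sites


# ---------------------------------------------------------------------------
# event-locked extraction + baseline z-scoring
# ---------------------------------------------------------------------------

def extract_and_zscore(long: LongEpochs, lock: str, sites=None,
                       log: RejectionLog | None = None) -> EpochSet:
    """[-100, +400] ms epochs z-scored against the [-100, 0) ms baseline.

    z = (x - baseline mean) / baseline SD per trial and site (sample SD,
    ddof=1).  Trials with a zero-SD baseline on any site are flagged
    degenerate and dropped with a log entry.
    """
    if lock not in ("face1", "face2"):
        raise ValueError("lock must be 'face1' or 'face2'")
    log = log if log is not None else RejectionLog()
    rate = long.rate
    pre = int(round(0.1 * rate))
    post = int(round(0.4 * rate))
    times = np.arange(-pre, post + 1) / rate * 1000.0
    col = "face1_idx" if lock == "face1" else "face2_idx"

    data, keep_rows = [], []
    for i, ep in enumerate(long.epochs):
        if ep is None:
            continue
        i_on = int(long.events[col].iloc[i])
        seg = ep[:, i_on - pre:i_on + post + 1]
        if seg.shape[1] != pre + post + 1:
            log.warn(f"trial {long.events['trial'].iloc[i]}: window outside "
                     "epoch; dropped")
            continue
        base = seg[:, :pre]
        mu = base.mean(axis=1, keepdims=True)
        sd = base.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            log.reject(long.events["trial"].iloc[i], "degenerate_baseline",
                       long.events["block"].iloc[i])
            continue
        data.append(((seg - mu) / sd).T)  # time x sites
        keep_rows.append(i)

    trials = long.design.iloc[keep_rows].reset_index(drop=True).copy()
    trials["retained"] = True
    arr = (np.stack(data, axis=0) if data
           else np.empty((0, pre + post + 1, len(long.contacts))))
    return EpochSet(data=arr, times=times, rate=rate, lock=lock,
                    trials=trials,
                    sites=list(sites) if sites is not None else list(long.contacts["channel"]),
                    stages=long.stages + [f"zscore:{lock}"])


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def preprocess_pipeline(rec: ContactRecording, design: pd.DataFrame,
                        responses: pd.DataFrame | None = None,
                        blink_channel: str | None = None,
                        locks=("face1", "face2")):
    """Full preprocessing chain; returns (dict lock -> EpochSet, sites, log)."""
    log = RejectionLog()
    rec = apply_filters(rec, "initial")
    long = epoch_long_trials(rec, design)
    long = long.subset(long.events["in_bounds"].to_numpy())
    long, log = reject_artifacts(long, blink_channel=blink_channel, log=log)
    if responses is not None:
        long, log = apply_behavioral_exclusions(long, responses, log=log)
    long = lowpass_40(long)
    long = downsample_to_400(long)
    long, sites = derive_bipolar(long, log=log)
    out = {lock: extract_and_zscore(long, lock, sites=sites, log=log)
           for lock in locks}
    return out, sites, log
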