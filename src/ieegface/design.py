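"""Trial design for the Posner-like gaze/emotion paradigm.

A trial is: central fixation (500-800 ms) -> neutral face with direct gaze
(Face 1, 400-600 ms) -> same face turned happy or fearful with direct or
averted gaze (Face 2) -> after 300/350/400/450 ms a lateral checkerboard
target (omitted on catch trials).  Each block holds 108 trials: 54 happy and
54 fearful; 36 leftward, 36 rightward and 36 direct gaze, balanced across
emotions (18 trials per emotion x gaze cell); 12 catch trials (2 per cell).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EMOTIONS = ("happy", "fearful")
GAZES = ("left", "right", "direct")
SOAS_MS = (300, 350, 400, 450)
TRIALS_PER_BLOCK = 108
CATCH_PER_BLOCK = 12
MAX_SOA_MS = max(SOAS_MS)

#: seconds between one trial's response window ending and the next fixation
ITI_S = 1.0
#: response window after target (display persists until press or 1 s)
RESPONSE_WINDOW_S = 1.0
#: recording time before the first fixation onset
LEAD_IN_S = 2.0


def build_trial_design(n_blocks: int, timing_jitter: bool = True,
                       rng_seed: int = 0) -> pd.DataFrame:
    """Generate a randomized, balanced trial table.

    Parameters
    ----------
    n_blocks : number of 108-trial blocks (8 in a full session).
    timing_jitter : if False, Face 1 duration is fixed at 500 ms instead of
        uniform in [400, 600] ms (one patient was run with a fixed delay).
    rng_seed : seed controlling trial order and all timing draws.

    Returns a DataFrame with one row per trial and columns
    trial, block, emotion, gaze, catch, fixation_ms, face1_ms, soa_ms,
    target_side, plus absolute event times (onset_s, face1_s, face2_s,
    target_s) computed by laying trials end to end.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng_seed)

    rows = []
    for block in range(1, n_blocks + 1):
        cells = []
        for emotion in EMOTIONS:
            for gaze in GAZES:
                n_cell = TRIALS_PER_BLOCK // (len(EMOTIONS) * len(GAZES))
                n_catch = CATCH_PER_BLOCK // (len(EMOTIONS) * len(GAZES))
                for i in range(n_cell):
                    cells.append((emotion, gaze, i < n_catch))
        order = rng.permutation(len(cells))
        for k in order:
            emotion, gaze, catch = cells[k]
            fixation_ms = rng.uniform(500.0, 800.0)
            face1_ms = rng.uniform(400.0, 600.0) if timing_jitter else 500.0
            if catch:
                soa_ms, side = np.nan, "none"
            else:
                soa_ms = float(rng.choice(SOAS_MS))
                side = str(rng.choice(["left", "right"]))
            rows.append({
                "block": block, "emotion": emotion, "gaze": gaze,
                "catch": bool(catch), "fixation_ms": fixation_ms,
                "face1_ms": face1_ms, "soa_ms": soa_ms, "target_side": side,
            })

    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    _add_absolute_times(df)
    return df


def _add_absolute_times(df: pd.DataFrame) -> None:
    """Lay trials end to end and add absolute event-time columns (s)."""
    onset = np.empty(len(df))
    t = LEAD_IN_S
    for i, row in enumerate(df.itertuples(index=False)):
        onset[i] = t
        face2 = t + (row.fixation_ms + row.face1_ms) / 1000.0
        soa = row.soa_ms if np.isfinite(row.soa_ms) else MAX_SOA_MS
        t = face2 + soa / 1000.0 + RESPONSE_WINDOW_S + ITI_S
    df["onset_s"] = onset
    df["face1_s"] = df["onset_s"] + df["fixation_ms"] / 1000.0
    df["face2_s"] = df["face1_s"] + df["face1_ms"] / 1000.0
    df["target_s"] = df["face2_s"] + df["soa_ms"] / 1000.0


def design_duration_s(design: pd.DataFrame) -> float:
    """Recording length needed to cover the design with trailing padding."""
    last = design.iloc[-1]
    end = last["target_s"] if np.isfinite(last["target_s"]) else (
        last["face2_s"] + MAX_SOA_MS / 1000.0)
    return float(end + RESPONSE_WINDOW_S + LEAD_IN_S)
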