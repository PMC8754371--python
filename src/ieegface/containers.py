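"""In-memory containers shared across the pipeline.

Conventions
-----------
* Continuous and long-epoch signals are in microvolts (uV); epoch sets locked
  to a face event are baseline z-scored (unitless).
* Time is in milliseconds relative to the locking event for epoch sets, and
  in seconds (absolute recording time) elsewhere.
* Contacts are monopolar recording points on a depth-electrode shaft, indexed
  1..n from the deepest contact outward.  A bipolar *site* is the virtual
  channel ``deeper - shallower`` formed from two adjacent retained contacts;
  its coordinate is the midpoint of the two contact coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Controlled vocabulary for rejection reasons (first-triggered reason wins).
REJECTION_REASONS = (
    "threshold",
    "epileptic/artifact",
    "blink",
    "behavior_miss",
    "behavior_false_alarm",
    "behavior_rt_outlier",
    "block_dropped",
    "degenerate_baseline",
)

ROIS = ("IOC", "FC", "ITC", "STC", "IPS", "other")


@dataclass
class ContactRecording:
    """Continuous monopolar recording plus per-contact metadata.

    ``signal`` is channels x samples in uV.  ``contacts`` has one row per
    channel with columns: channel, shaft, index, label, x, y, z, in_brain,
    excluded, is_blink.  Contacts on a shaft are ordered deep -> shallow by
    increasing ``index``.
    """

    signal: np.ndarray
    rate: float
    contacts: pd.DataFrame
    patient: str = "sim"
    stages: list = field(default_factory=list)

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[0] != len(self.contacts):
            raise ValueError("signal rows must match contact table")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel_index(self, name: str) -> int:
        idx = np.flatnonzero(self.contacts["channel"].to_numpy() == name)
        if idx.size == 0:
            raise KeyError(f"no channel named {name!r}")
        return int(idx[0])


@dataclass
class LongEpochs:
    """One long epoch per trial (fixation - 400 ms to target + 1 s).

    ``epochs[i]`` is channels x samples (uV) or None for trials whose events
    fell outside the recording (flagged, never silently dropped).  ``events``
    carries, per trial, the sample index of each event *within* the epoch.
    """

    epochs: list
    rate: float
    events: pd.DataFrame  # trial, block, fix_idx, face1_idx, face2_idx, target_idx, in_bounds
    contacts: pd.DataFrame
    design: pd.DataFrame
    patient: str = "sim"
    stages: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.epochs)

    def subset(self, keep: np.ndarray) -> "LongEpochs":
        keep = np.asarray(keep)
        return LongEpochs(
            epochs=[self.epochs[i] for i in np.flatnonzero(keep)],
            rate=self.rate,
            events=self.events.loc[keep].reset_index(drop=True),
            contacts=self.contacts,
            design=self.design.loc[keep].reset_index(drop=True),
            patient=self.patient,
            stages=list(self.stages),
        )


@dataclass(frozen=True)
class BipolarSite:
    """Virtual bipolar recording site (deeper minus shallower contact)."""

    shaft: str
    deep_index: int
    shallow_index: int
    x: float
    y: float
    z: float
    label: str
    roi: str
    hemisphere: str
    patient: str = "sim"

    @property
    def name(self) -> str:
        return f"{self.patient}:{self.shaft}{self.deep_index}-{self.shallow_index}"

    @property
    def mni(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class EpochSet:
    """Baseline z-scored epochs locked to Face 1 or Face 2.

    ``data`` is trials x time x sites, ``times`` in ms covering
    [-100, +400] with the baseline window [-100, 0) present for every trial.
    """

    data: np.ndarray
    times: np.ndarray
    rate: float
    lock: str  # 'face1' or 'face2'
    trials: pd.DataFrame  # emotion, gaze, catch, block, trial, ...
    sites: list  # list[BipolarSite]
    stages: list = field(default_factory=list)

    def __post_init__(self):
        if self.lock not in ("face1", "face2"):
            raise ValueError("lock must be 'face1' or 'face2'")
        if self.data.ndim != 3:
            raise ValueError("data must be trials x time x sites")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[2]

    def site_data(self, site: int) -> np.ndarray:
        """Trials x time matrix for one site."""
        return self.data[:, :, site]

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin) & (self.times <= tmax)

    def average(self) -> np.ndarray:
        """Trial-averaged ERP, time x sites."""
        return self.data.mean(axis=0)

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            times=self.times,
            rate=self.rate,
            lock=self.lock,
            trials=self.trials.loc[mask].reset_index(drop=True),
            sites=list(self.sites),
            stages=list(self.stages),
        )


class RejectionLog:
    """Per-trial rejection bookkeeping; the first triggered reason is kept."""

    def __init__(self):
        self._rows = []
        self.messages: list[str] = []
        self.block_retention: dict = {}

    def reject(self, trial: int, reason: str, block=None):
        if reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        if trial not in {r["trial"] for r in self._rows}:
            self._rows.append({"trial": int(trial), "reason": reason, "block": block})

    def warn(self, msg: str):
        self.messages.append(msg)

    @property
    def rejected_trials(self) -> set:
        return {r["trial"] for r in self._rows}

    def to_frame(self) -> pd.DataFrame:
        if not self._rows:
            return pd.DataFrame(columns=["trial", "reason", "block"])
        return pd.DataFrame(self._rows)

    def __len__(self):
        return len(self._rows)


@dataclass
class BehavioralSummary:
    hit_rate: float
    false_alarm_rate: float
    mean_rt_ms: float
    rt_trim_bounds_ms: tuple
    n_targets: int
    n_catch: int
    n_pretarget_presses: int
    defined: bool = True
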