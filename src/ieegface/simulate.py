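"""Synthetic iEEG forward model with planted ground truth.

Generates multi-contact depth-electrode recordings that emulate the study
conditions downstream modules are built for: 400/1024 Hz sampling, shafts of
contacts at 5 or 10 mm spacing, ERP components (P100 / N200 / P250 / slow
wave) modeled as Gaussian-envelope deflections time-locked to Face 1 / Face
2 onsets, local polarity reversals across adjacent contacts straddling a
planted generator, condition-dependent (gaze / emotion) amplitude and
latency effects, 1/f^alpha background plus white noise, and injected
artifacts (threshold excursions, spike transients, blinks on a designated
scalp channel).  Everything planted is recorded in a :class:`GroundTruth`
object so that recovery can be checked exactly.

A fast path (:func:`simulate_site_epochs`) emits already-epoched,
baseline-normalized single-site data for statistical simulations where the
full continuous pipeline would be needlessly slow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import BipolarSite, ContactRecording, EpochSet
from .design import MAX_SOA_MS, design_duration_s

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

COMPONENT_LABELS = ("P100", "N200", "P250", "slow_wave")


@dataclass(frozen=True)
class ERPComponent:
    """One Gaussian-envelope ERP deflection.

    amplitude is signed (uV in the continuous forward model, z-units in the
    direct epoch simulator); width_ms is the Gaussian SD of the envelope.
    By convention the N200 amplitude is negative before any polarity flip.
    """

    label: str
    peak_latency_ms: float
    amplitude: float
    width_ms: float

    def __post_init__(self):
        if self.label not in COMPONENT_LABELS:
            raise ValueError(f"unknown component label {self.label!r}")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if self.label == "N200" and self.amplitude > 0:
            raise ValueError("N200 amplitude must be negative by convention")


@dataclass(frozen=True)
class GazeEmotionEffect:
    """Planted Face-2 condition effects for one ROI.

    Deltas are applied to the dominant Face-2 deflection: averted (vs
    direct) gaze adds ``gaze_amp`` to its amplitude and ``gaze_lat_ms`` to
    its latency; fearful (vs happy) likewise with the emotion deltas.
    Negative amplitude deltas deepen the (negative) N200.
    """

    gaze_amp: float = 0.0
    gaze_lat_ms: float = 0.0
    emotion_amp: float = 0.0
    emotion_lat_ms: float = 0.0


@dataclass(frozen=True)
class ShaftLayout:
    """One depth-electrode shaft: a line segment in MNI space.

    ``start`` is the deepest contact (index 1); contacts advance toward
    ``shallow`` direction every ``spacing_mm``.  ``flip_after`` places the
    local generator between contacts ``flip_after`` and ``flip_after + 1``:
    contacts up to ``flip_after`` carry sign +1, the rest -1 (polarity
    reversal).  ``flip_after >= n_contacts`` means no reversal.
    """

    name: str
    roi: str
    label: str
    start_mni: tuple
    spacing_mm: float
    n_contacts: int
    direction: tuple = (0.0, 0.0, 1.0)
    flip_after: int = 3
    #: spatial decay length of the generator's field along the shaft;
    #: None -> uniform gain 1 at every contact
    gain_length_mm: float | None = 12.0

    def __post_init__(self):
        if self.spacing_mm <= 0:
            raise ValueError("intercontact spacing must be > 0")

    def contact_positions(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        start = np.asarray(self.start_mni, dtype=float)
        return start + np.outer(np.arange(self.n_contacts) * self.spacing_mm, d)

    def contact_signs(self) -> np.ndarray:
        idx = np.arange(1, self.n_contacts + 1)
        return np.where(idx <= self.flip_after, 1.0, -1.0)

    def contact_gains(self) -> np.ndarray:
        """Field amplitude per contact, decaying with distance from the
        planted generator (midway between the flip pair); the two contacts
        straddling the generator always have equal gain."""
        if self.gain_length_mm is None or self.flip_after >= self.n_contacts:
            return np.ones(self.n_contacts)
        gen = (self.flip_after - 0.5) * self.spacing_mm
        dist = np.abs(np.arange(self.n_contacts) * self.spacing_mm - gen)
        return np.exp(-dist / self.gain_length_mm)


@dataclass
class SimulationConfig:
    shaft_layouts: list
    sampling_rate: float = 400.0
    noise_sd: float = 10.0          # pink-noise SD, uV
    white_noise_sd: float = 2.0     # white measurement noise, uV
    pink_noise_exponent: float = 1.0
    component_params: dict = field(default_factory=dict)  # roi -> event -> [ERPComponent]
    effect_params: dict = field(default_factory=dict)     # roi -> GazeEmotionEffect
    artifact_rates: dict = field(default_factory=lambda: {
        "threshold": 0.0, "spike": 0.0, "blink": 0.0})
    rng_seed: int = 0

    def __post_init__(self):
        if self.sampling_rate not in (400, 1024):
            raise ValueError("sampling_rate must be 400 or 1024 Hz")
        for k, p in self.artifact_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"artifact rate {k}={p} outside [0, 1]")


@dataclass
class GroundTruth:
    """Everything planted in one simulated recording."""

    contact_signs: dict                  # channel -> +-1
    contact_gains: dict                  # channel -> field gain in [0, 1]
    cell_truth: dict                     # (roi, event, emotion, gaze) -> {label: (lat_ms, amp)}
    effect_params: dict                  # roi -> GazeEmotionEffect
    artifact_trials: dict                # type -> sorted list of trial ids
    blink_channel: str
    noise_sd: float

    def true_component(self, roi, event, label="N200",
                       emotion="happy", gaze="direct"):
        """(latency_ms, amplitude) of a planted component in one condition."""
        return self.cell_truth[(roi, event, emotion, gaze)][label]


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def default_components() -> dict:
    """Per-ROI ERP component sets emulating the canonical face response.

    Face 1 peaks earliest in IOC, then ITC/FC in parallel, with STC showing
    a slow wave peaking around 300 ms instead of a sharp N200.  Face 2
    evokes a sharp N200 everywhere, slightly later than Face 1 in the
    ventral ROIs.  Amplitudes are in uV; with the default 10 uV background
    this yields trial-averaged peaks of roughly |z| = 3-6 after baseline
    z-scoring, in line with robust intracerebral face responses.
    """
    return {
        "IOC": {
            "face1": [ERPComponent("N200", 125.0, -55.0, 22.0),
                      ERPComponent("P250", 225.0, 20.0, 35.0)],
            "face2": [ERPComponent("N200", 155.0, -60.0, 22.0),
                      ERPComponent("P250", 255.0, 18.0, 35.0)],
        },
        "FC": {
            "face1": [ERPComponent("P100", 95.0, 12.0, 16.0),
                      ERPComponent("N200", 150.0, -50.0, 24.0),
                      ERPComponent("P250", 245.0, 18.0, 38.0)],
            "face2": [ERPComponent("P100", 100.0, 10.0, 16.0),
                      ERPComponent("N200", 190.0, -52.0, 24.0)],
        },
        "ITC": {
            "face1": [ERPComponent("P100", 95.0, 10.0, 16.0),
                      ERPComponent("N200", 150.0, -45.0, 24.0),
                      ERPComponent("P250", 245.0, 15.0, 38.0)],
            "face2": [ERPComponent("P100", 100.0, 8.0, 16.0),
                      ERPComponent("N200", 190.0, -50.0, 24.0)],
        },
        "STC": {
            "face1": [ERPComponent("slow_wave", 300.0, -28.0, 70.0)],
            "face2": [ERPComponent("N200", 190.0, -45.0, 24.0)],
        },
    }


def default_effects() -> dict:
    """Planted gaze/emotion sensitivity: strong gaze effect in STC only."""
    return {
        "IOC": GazeEmotionEffect(gaze_amp=-4.0, emotion_amp=-4.0),
        "FC": GazeEmotionEffect(gaze_amp=-4.0, emotion_amp=-5.0),
        "ITC": GazeEmotionEffect(gaze_amp=-5.0, emotion_amp=-4.0),
        "STC": GazeEmotionEffect(gaze_amp=-20.0, emotion_amp=-4.0),
    }


def default_config(sampling_rate: float = 400.0, rng_seed: int = 0,
                   artifact_rates: dict | None = None) -> SimulationConfig:
    """Four-shaft implantation sampling the four ROIs."""
    shafts = [
        ShaftLayout("OCC", "IOC", "inferior occipital gyrus",
                    (30.0, -92.0, -8.0), 5.0, 8, (1.0, 0.2, 0.1)),
        ShaftLayout("FUS", "FC", "fusiform gyrus",
                    (32.0, -52.0, -20.0), 5.0, 8, (1.0, 0.0, 0.0)),
        ShaftLayout("ITG", "ITC", "inferior temporal gyrus",
                    (42.0, -55.0, -14.0), 5.0, 8, (1.0, 0.1, 0.0)),
        ShaftLayout("STS", "STC", "superior temporal sulcus",
                    (44.0, -48.0, 2.0), 5.0, 8, (1.0, 0.0, 0.2)),
    ]
    return SimulationConfig(
        shaft_layouts=shafts,
        sampling_rate=sampling_rate,
        component_params=default_components(),
        effect_params=default_effects(),
        artifact_rates=artifact_rates or {"threshold": 0.0, "spike": 0.0,
                                          "blink": 0.0},
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def gaussian_erp(times_ms: np.ndarray, components) -> np.ndarray:
    """Sum of Gaussian-envelope deflections evaluated at ``times_ms``."""
    t = np.asarray(times_ms, dtype=float)
    out = np.zeros_like(t)
    for c in components:
        out += c.amplitude * np.exp(-0.5 * ((t - c.peak_latency_ms) / c.width_ms) ** 2)
    return out


def pink_noise(n_samples: int, rate: float, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f^alpha noise via spectral shaping of white noise."""
    white = rng.standard_normal(n_samples)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC drift
    out = np.fft.irfft(spec * scale, n=n_samples)
    sd = out.std()
    return out / sd if sd > 0 else out


def _apply_effects(components, effect: GazeEmotionEffect,
                   emotion: str, gaze: str):
    """Condition-adjusted copy of a Face-2 component list.

    Effects act on the dominant negative deflection (N200, or the slow wave
    if no N200 is present).
    """
    averted = gaze in ("left", "right")
    fearful = emotion == "fearful"
    target_label = "N200" if any(c.label == "N200" for c in components) else "slow_wave"
    out = []
    for c in components:
        if c.label == target_label:
            amp = c.amplitude
            lat = c.peak_latency_ms
            if averted:
                amp += effect.gaze_amp
                lat += effect.gaze_lat_ms
            if fearful:
                amp += effect.emotion_amp
                lat += effect.emotion_lat_ms
            c = replace(c, amplitude=amp, peak_latency_ms=lat)
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# continuous recording simulator
# ---------------------------------------------------------------------------

BLINK_CHANNEL = "SCALP1"


def simulate_patient_recording(config: SimulationConfig,
                               design: pd.DataFrame,
                               patient: str = "sim"):
    """Continuous multi-contact recording + ground truth for one session.

    Returns ``(ContactRecording, GroundTruth)``.  The recording includes one
    designated scalp channel (carrying blink templates when the blink
    artifact rate is nonzero) after the depth contacts.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    bad = set(design["emotion"]) - {"happy", "fearful"}
    bad |= set(design["gaze"]) - {"left", "right", "direct"}
    if bad:
        raise ValueError(f"design references unknown condition levels: {sorted(bad)}")
    for shaft in config.shaft_layouts:
        if shaft.roi not in config.component_params:
            raise ValueError(f"no component_params for ROI {shaft.roi!r}")
        if shaft.roi not in config.effect_params:
            raise ValueError(f"no effect_params for ROI {shaft.roi!r}")

    rate = config.sampling_rate
    rng = np.random.default_rng(config.rng_seed)
    n_samples = int(np.ceil(design_duration_s(design) * rate))

    # contact table
    rows, signs, gains = [], {}, {}
    for shaft in config.shaft_layouts:
        pos = shaft.contact_positions()
        s = shaft.contact_signs()
        g = shaft.contact_gains()
        for k in range(shaft.n_contacts):
            name = f"{shaft.name}{k + 1}"
            rows.append({"channel": name, "shaft": shaft.name, "index": k + 1,
                         "label": shaft.label, "x": pos[k, 0], "y": pos[k, 1],
                         "z": pos[k, 2], "in_brain": True, "excluded": False,
                         "is_blink": False})
            signs[name] = float(s[k])
            gains[name] = float(g[k])
    rows.append({"channel": BLINK_CHANNEL, "shaft": "SCALP", "index": 1,
                 "label": "scalp", "x": 0.0, "y": 80.0, "z": 40.0,
                 "in_brain": False, "excluded": False, "is_blink": True})
    contacts = pd.DataFrame(rows)
    n_chan = len(contacts)

    signal = np.zeros((n_chan, n_samples))

    # ERP kernels on a relative window, cached per (roi, event, cell)
    kt = np.arange(int(-0.1 * rate), int(0.65 * rate))
    kt_ms = kt / rate * 1000.0
    kernel_cache: dict = {}
    cell_truth: dict = {}
    for shaft in config.shaft_layouts:
        comp = config.component_params[shaft.roi]
        eff = config.effect_params[shaft.roi]
        for emotion in ("happy", "fearful"):
            for gaze in ("left", "right", "direct"):
                f2 = _apply_effects(comp["face2"], eff, emotion, gaze)
                kernel_cache[(shaft.roi, "face2", emotion, gaze)] = \
                    gaussian_erp(kt_ms, f2)
                cell_truth[(shaft.roi, "face2", emotion, gaze)] = {
                    c.label: (c.peak_latency_ms, c.amplitude) for c in f2}
                kernel_cache[(shaft.roi, "face1", emotion, gaze)] = \
                    gaussian_erp(kt_ms, comp["face1"])
                cell_truth[(shaft.roi, "face1", emotion, gaze)] = {
                    c.label: (c.peak_latency_ms, c.amplitude)
                    for c in comp["face1"]}

    chan_of = {c: i for i, c in enumerate(contacts["channel"])}
    for trial in design.itertuples(index=False):
        for event, t_on in (("face1", trial.face1_s), ("face2", trial.face2_s)):
            i0 = int(round(t_on * rate))
            sl = slice(i0 + kt[0], i0 + kt[0] + len(kt))
            if sl.start < 0 or sl.stop > n_samples:
                continue
            for shaft in config.shaft_layouts:
                k = kernel_cache[(shaft.roi, event, trial.emotion, trial.gaze)]
                for ci in range(shaft.n_contacts):
                    name = f"{shaft.name}{ci + 1}"
                    ch = chan_of[name]
                    signal[ch, sl] += signs[name] * gains[name] * k

    # background noise: independent pink + white per channel
    for ch in range(n_chan):
        if config.noise_sd > 0:
            signal[ch] += config.noise_sd * pink_noise(
                n_samples, rate, config.pink_noise_exponent, rng)
        if config.white_noise_sd > 0:
            signal[ch] += config.white_noise_sd * rng.standard_normal(n_samples)

    artifact_trials = _inject_artifacts(signal, rate, design, contacts,
                                        config.artifact_rates, rng)

    rec = ContactRecording(signal=signal, rate=rate, contacts=contacts,
                           patient=patient, stages=["simulated"])
    truth = GroundTruth(contact_signs=signs, contact_gains=gains,
                        cell_truth=cell_truth,
                        effect_params=dict(config.effect_params),
                        artifact_trials=artifact_trials,
                        blink_channel=BLINK_CHANNEL,
                        noise_sd=config.noise_sd)
    return rec, truth


def _inject_artifacts(signal, rate, design, contacts, rates, rng):
    """Inject per-trial artifacts in place; return planted trial ids."""
    planted = {"threshold": [], "spike": [], "blink": []}
    in_brain = np.flatnonzero((contacts["in_brain"] & ~contacts["excluded"]).to_numpy())
    blink_ch = np.flatnonzero(contacts["is_blink"].to_numpy())
    n_samples = signal.shape[1]
    t_axis = np.arange(n_samples) / rate

    def add_bump(ch, t_center, amp, width_s):
        sl = (t_axis > t_center - 4 * width_s) & (t_axis < t_center + 4 * width_s)
        signal[ch, sl] += amp * np.exp(
            -0.5 * ((t_axis[sl] - t_center) / width_s) ** 2)

    for trial in design.itertuples(index=False):
        t_end = trial.target_s if np.isfinite(trial.target_s) else (
            trial.face2_s + MAX_SOA_MS / 1000.0)
        # artifact window the preprocessing stage screens
        w0, w1 = trial.face1_s - 0.5, t_end + 0.3
        if rates.get("threshold", 0) and rng.random() < rates["threshold"]:
            ch = int(rng.choice(in_brain))
            add_bump(ch, rng.uniform(w0, w1), 850.0, 0.05)
            planted["threshold"].append(int(trial.trial))
        if rates.get("spike", 0) and rng.random() < rates["spike"]:
            ch = int(rng.choice(in_brain))
            add_bump(ch, rng.uniform(w0, w1), 350.0, 0.006)
            planted["spike"].append(int(trial.trial))
        if rates.get("blink", 0) and blink_ch.size and \
                rng.random() < rates["blink"]:
            add_bump(int(blink_ch[0]), rng.uniform(w0, w1), 200.0, 0.08)
            planted["blink"].append(int(trial.trial))
    return planted


def simulate_responses(design: pd.DataFrame, rng_seed: int = 0,
                       hit_rate: float = 0.99, fa_rate: float = 0.03,
                       rt_mean_ms: float = 357.0, rt_sd_ms: float = 50.0,
                       pretarget_rate: float = 0.0) -> pd.DataFrame:
    """Behavioral response table aligned to a design.

    Default rates emulate near-ceiling target detection; RTs are Gaussian.
    ``pretarget_rate`` plants button presses before target onset (negative
    RT) on target trials.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for trial in design.itertuples(index=False):
        if trial.catch:
            pressed = rng.random() < fa_rate
            rt = rng.uniform(200, 600) if pressed else np.nan
        elif pretarget_rate and rng.random() < pretarget_rate:
            pressed, rt = True, -rng.uniform(10, 200)
        else:
            pressed = rng.random() < hit_rate
            rt = max(120.0, rng.normal(rt_mean_ms, rt_sd_ms)) if pressed else np.nan
        rows.append({"trial": trial.trial, "pressed": bool(pressed),
                     "rt_ms": rt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fast path: direct epoch simulation for statistical experiments
# ---------------------------------------------------------------------------

def simulate_site_epochs(components, n_trials: int = 100,
                         noise_sd: float = 1.0, rate: float = 400.0,
                         rng_seed: int = 0, lock: str = "face2",
                         effect: GazeEmotionEffect | None = None,
                         n_per_cell: int | None = None,
                         roi: str = "STC", site: BipolarSite | None = None
                         ) -> EpochSet:
    """Single-site EpochSet with planted components and white noise.

    Stands for already-preprocessed, baseline-normalized data: each trial is
    the condition waveform plus iid N(0, noise_sd^2) samples on the
    [-100, +400] ms window.  If ``effect`` is given, trials are laid out as
    a balanced 2 (emotion) x 2 (gaze: direct/averted) factorial with
    ``n_per_cell`` trials per cell and the deltas applied to the dominant
    deflection; otherwise ``n_trials`` identical-condition trials are drawn.
    """
    rng = np.random.default_rng(rng_seed)
    times = np.arange(int(-0.1 * rate), int(0.4 * rate) + 1) / rate * 1000.0

    if effect is not None:
        if n_per_cell is None:
            n_per_cell = n_trials // 4
        cells = [("happy", "direct"), ("happy", "left"),
                 ("fearful", "direct"), ("fearful", "left")]
        waves, emo, gaz = [], [], []
        for emotion, gaze in cells:
            adj = _apply_effects(components, effect, emotion, gaze)
            w = gaussian_erp(times, adj)
            for _ in range(n_per_cell):
                waves.append(w)
                emo.append(emotion)
                gaz.append(gaze)
        data = np.asarray(waves)
        trials = pd.DataFrame({"emotion": emo, "gaze": gaz,
                               "catch": False})
    else:
        w = gaussian_erp(times, components)
        data = np.tile(w, (n_trials, 1))
        trials = pd.DataFrame({"emotion": ["happy"] * n_trials,
                               "gaze": ["direct"] * n_trials,
                               "catch": False})
    data = data + noise_sd * rng.standard_normal(data.shape)
    trials["trial"] = np.arange(len(trials))
    trials["block"] = 1
    trials["retained"] = True

    if site is None:
        site = BipolarSite("SIM", 1, 2, 45.0, -50.0, 0.0,
                           "superior temporal sulcus", roi, "R", "sim")
    return EpochSet(data=data[:, :, None], times=times, rate=rate,
                    lock=lock, trials=trials, sites=[site],
                    stages=["simulated-epochs"])


# ---------------------------------------------------------------------------
# synthetic streamlines
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStreamlineSet:
    """One subject's streamlines for one named tract (MNI mm)."""

    tract_name: str
    subject_id: str
    streamlines: list  # list of (n_points, 3) arrays

    def __post_init__(self):
        for s in self.streamlines:
            s = np.asarray(s)
            if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != 3:
                raise ValueError("each streamline needs >= 2 finite 3D points")
            if not np.all(np.isfinite(s)):
                raise ValueError("streamline coordinates must be finite")


def simulate_tract_endpoints(n_subjects: int, tract_specs,
                             scatter_sd: float, rng_seed: int = 0,
                             n_streamlines: int = 50, n_points: int = 12):
    """Per-subject streamline sets running between two endpoint centroids.

    ``tract_specs`` is a list of ``(name, endpoint_a_xyz, endpoint_b_xyz)``.
    Endpoints get isotropic Gaussian scatter of SD ``scatter_sd`` mm;
    intermediate points interpolate linearly.  Streamline orientation is
    randomized (half the streamlines are stored reversed) so that the
    reorientation step downstream is exercised.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if scatter_sd < 0:
        raise ValueError("scatter_sd must be >= 0")
    if not tract_specs:
        raise ValueError("tract_specs is empty")
    rng = np.random.default_rng(rng_seed)
    sets = []
    for subj in range(n_subjects):
        for name, a, b in tract_specs:
            a = np.asarray(a, dtype=float)
            b = np.asarray(b, dtype=float)
            streamlines = []
            for _ in range(n_streamlines):
                p0 = a + scatter_sd * rng.standard_normal(3)
                p1 = b + scatter_sd * rng.standard_normal(3)
                frac = np.linspace(0.0, 1.0, n_points)[:, None]
                pts = p0 + frac * (p1 - p0)
                if rng.random() < 0.5:
                    pts = pts[::-1]
                streamlines.append(pts)
            sets.append(SyntheticStreamlineSet(name, f"sub-{subj:04d}",
                                               streamlines))
    return sets
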