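"""ERP morphology, amplitude effect sizes, and jackknife peak latencies.

Sites within FC, ITC and STC are grouped into 10 mm coronal slices along
the posterior-to-anterior (MNI y) axis; IOC sites are pooled.  Because
adjacent bipolar sites either side of a local generator show the same
waveform with opposite sign, group waveforms are polarity-rectified before
averaging: the group peak is located on the average of absolute
amplitudes, and any site whose mean amplitude in +-25 ms around that peak
is positive is flipped, so the dominant deflection is negative by
convention.

Peak latencies are estimated with the leave-one-site-out jackknife: the
SD of the n leave-one-out latencies, inflated by sqrt((n-1)/n * sum(...)),
estimates the standard error of the full-sample latency, supporting
t-tests on latency differences between conditions or ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# --------------------------------------------------------------------------
# y-axis slicing
# --------------------------------------------------------------------------

SLICE_LABELS = ("A", "B", "C", "D", "E")
SLICE_Y_MIN, SLICE_Y_MAX = -81.0, -31.0  # A-E partition [-81, -31) in 10 mm bins

#: slices with clearly identifiable peaks, used for amplitude/latency work
AMPLITUDE_SLICES = {"FC": "ABCDE", "ITC": "BCD", "STC": "CDE", "IOC": "all"}

#: broad peak-search windows (ms) for the major deflection, per ROI x lock
PEAK_WINDOWS_MS = {
    ("IOC", "face1"): (0.0, 170.0),
    ("IOC", "face2"): (0.0, 170.0),
    ("FC", "face1"): (0.0, 170.0),
    ("FC", "face2"): (0.0, 210.0),
    ("ITC", "face1"): (0.0, 210.0),
    ("ITC", "face2"): (0.0, 210.0),
    ("STC", "face1"): (210.0, 400.0),  # slow wave peaking ~300 ms
    ("STC", "face2"): (0.0, 210.0),
}


def slice_label_for_y(y: float) -> str:
    """10 mm half-open bins A-E over [-81, -31); F for y >= -31.

    Sites posterior to y = -81 are assigned to slice A with a warning.
    """
    if y >= SLICE_Y_MAX:
        return "F"
    if y < SLICE_Y_MIN:
        warnings.warn(f"site y={y} posterior to {SLICE_Y_MIN}; assigned to "
                      "slice A", stacklevel=2)
        return "A"
    return SLICE_LABELS[int((y - SLICE_Y_MIN) // 10.0)]


@dataclass(frozen=True)
class SliceGrouping:
    roi: str
    slice_label: str  # 'A'..'F' or 'all'
    y_range: tuple
    site_indices: tuple


def slice_by_y(sites) -> list:
    """Group sites of each ROI into y slices (IOC pooled as 'all')."""
    groups: dict = {}
    for i, s in enumerate(sites):
        if s.roi == "IOC":
            key = ("IOC", "all")
        else:
            key = (s.roi, slice_label_for_y(s.y))
        groups.setdefault(key, []).append(i)
    out = []
    for (roi, lab), idx in sorted(groups.items()):
        if lab == "all":
            rng = (-np.inf, np.inf)
        elif lab == "F":
            rng = (SLICE_Y_MAX, np.inf)
        else:
            lo = SLICE_Y_MIN + 10.0 * SLICE_LABELS.index(lab)
            rng = (lo, lo + 10.0)
        out.append(SliceGrouping(roi, lab, rng, tuple(idx)))
    return out


# --------------------------------------------------------------------------
# polarity rectification
# --------------------------------------------------------------------------

@dataclass
class RectifiedERP:
    signs: np.ndarray           # per-site flip sign, +1 or -1
    rectified: np.ndarray       # sites x time
    group_mean: np.ndarray      # time
    times: np.ndarray
    search_window_ms: tuple
    initial_peak_ms: float      # |mean| peak used for flipping
    peak_latency_ms: float      # negative peak of the rectified group mean

    @property
    def n_sites(self) -> int:
        return self.rectified.shape[0]


def _window_mask(times, window, clip_warn: str | None = None):
    lo, hi = window
    if clip_warn and (lo < times[0] or hi > times[-1]):
        warnings.warn(f"{clip_warn} window ({lo}, {hi}) ms clipped to epoch "
                      f"extent ({times[0]:.1f}, {times[-1]:.1f}) ms",
                      stacklevel=3)
    mask = (times >= lo) & (times <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window} outside the epoch time axis")
    return mask


def rectify_group(waveforms: np.ndarray, times: np.ndarray,
                  window_ms: tuple) -> RectifiedERP:
    """Standardize site polarities and average.

    1. initial mean ERP = average of |waveform| across sites;
    2. peak = latency of its maximum within the broad ``window_ms``;
    3. per site, mean amplitude in +-25 ms around that peak; positive means
       flip the whole time course by -1;
    4. group mean over rectified waveforms; the reported peak latency is
       its most negative point within the window (earliest tie wins).
    """
    waves = np.atleast_2d(np.asarray(waveforms, dtype=float))
    mask = _window_mask(times, window_ms)
    init_mean = np.abs(waves).mean(axis=0)
    w_idx = np.flatnonzero(mask)
    peak_i = w_idx[int(np.argmax(init_mean[mask]))]
    peak_ms = float(times[peak_i])

    around = _window_mask(times, (peak_ms - 25.0, peak_ms + 25.0),
                          clip_warn="rectification +-25 ms")
    site_means = waves[:, around].mean(axis=1)
    signs = np.where(site_means > 0, -1.0, 1.0)
    rectified = waves * signs[:, None]
    group_mean = rectified.mean(axis=0)
    neg_i = w_idx[int(np.argmin(group_mean[mask]))]
    return RectifiedERP(signs=signs, rectified=rectified,
                        group_mean=group_mean, times=times,
                        search_window_ms=tuple(window_ms),
                        initial_peak_ms=peak_ms,
                        peak_latency_ms=float(times[neg_i]))


# --------------------------------------------------------------------------
# amplitude effect size (one-sample Cohen's d)
# --------------------------------------------------------------------------

@dataclass
class AmplitudeEffect:
    site: object
    condition: str
    window_ms: tuple
    trial_means: np.ndarray
    d: float
    abs_d: float
    band: str
    defined: bool = True


def effect_size_band(abs_d: float) -> str:
    """Conventional interpretation bands: 0.2 small, 0.5 medium, 0.8 large."""
    if abs_d >= 0.8:
        return "large"
    if abs_d >= 0.5:
        return "medium"
    if abs_d >= 0.2:
        return "small"
    return "negligible"


def amplitude_effect(epochs, site: int, group_peak_latency_ms: float,
                     condition: str = "all",
                     trial_mask: np.ndarray | None = None) -> AmplitudeEffect:
    """One-sample d = mean/SD of trialwise mean amplitude, peak +-50 ms.

    Computed on the un-rectified single-site signal; |d| is reported since
    the sign of d follows the arbitrary bipolar polarity.  The window is
    clipped at epoch edges with a warning.
    """
    data = epochs.site_data(site)
    if trial_mask is not None:
        data = data[np.asarray(trial_mask)]
    window = (group_peak_latency_ms - 50.0, group_peak_latency_ms + 50.0)
    mask = _window_mask(epochs.times, window, clip_warn="amplitude +-50 ms")
    trial_means = data[:, mask].mean(axis=1)
    sd = trial_means.std(ddof=1)
    if sd == 0:
        return AmplitudeEffect(epochs.sites[site], condition, window,
                               trial_means, np.nan, np.nan, "undefined",
                               defined=False)
    d = float(trial_means.mean() / sd)
    return AmplitudeEffect(epochs.sites[site], condition, window,
                           trial_means, d, abs(d), effect_size_band(abs(d)))


# --------------------------------------------------------------------------
# jackknife latency inference
# --------------------------------------------------------------------------

def peak_latency(waveform: np.ndarray, times: np.ndarray,
                 window_ms: tuple, mode: str = "neg",
                 refine: str = "parabolic") -> float:
    """Peak latency within a window; discrete ties -> earliest sample.

    ``mode='neg'`` finds the most negative point (N200 / rectified slow
    wave); ``mode='pos'`` the most positive.  With ``refine='parabolic'``
    (default) the vertex of the parabola through the discrete extremum and
    its two neighbours refines the latency to sub-sample precision; this
    makes the latency a smooth function of the data, which the jackknife
    variance estimate relies on (a purely discrete argmax is quantized to
    the sampling grid and destabilizes leave-one-out SDs).
    ``refine='discrete'`` returns the grid sample.
    """
    mask = _window_mask(times, window_ms)
    seg = waveform[mask]
    if np.ptp(seg) == 0:
        raise ValueError("flat waveform in the search window; no peak")
    idx = np.flatnonzero(mask)
    pick = int(np.argmin(seg)) if mode == "neg" else int(np.argmax(seg))
    t_peak = float(times[idx[pick]])
    if refine == "parabolic" and 0 < pick < len(seg) - 1:
        y0, y1, y2 = seg[pick - 1], seg[pick], seg[pick + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
            t_peak += 0.5 * (y0 - y2) / denom * dt
    return t_peak


def jackknife_loo_stats(waveforms: np.ndarray, stat) -> tuple:
    """Full-sample statistic and the n leave-one-out statistics.

    ``stat`` maps a (sites x time) array to a scalar; it is evaluated on
    the full set and on every leave-one-out subset.
    """
    waves = np.atleast_2d(np.asarray(waveforms, dtype=float))
    n = waves.shape[0]
    if n < 2:
        raise ValueError("jackknife needs >= 2 sites")
    full = stat(waves)
    loo = np.array([stat(np.delete(waves, i, axis=0)) for i in range(n)])
    return full, loo


def jackknife_sd(loo_values: np.ndarray) -> float:
    """Inflated jackknife SD: sqrt((n-1)/n * sum((theta_i - mean)^2)).

    The inflation compensates the ~(n-1)-fold shrinkage of leave-one-out
    statistics; for a linear statistic (the mean) it equals the analytic
    SEM exactly.
    """
    loo = np.asarray(loo_values, dtype=float)
    n = loo.size
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def mean_peak_stat(times: np.ndarray, window_ms: tuple, mode: str = "neg"):
    """Statistic: peak latency of the across-site average waveform."""
    def stat(waves):
        return peak_latency(waves.mean(axis=0), times, window_ms, mode)
    return stat


@dataclass
class JackknifeLatency:
    label_a: str
    label_b: str
    mu_a: float
    mu_b: float
    sd_a: float
    sd_b: float
    sd_ab: float
    t: float
    df: int
    p: float
    ci95: tuple
    loo_a: np.ndarray = field(repr=False, default=None)
    loo_b: np.ndarray = field(repr=False, default=None)

    @property
    def difference(self) -> float:
        return self.mu_a - self.mu_b


def jackknife_latency_compare(waves_a: np.ndarray, waves_b: np.ndarray,
                              times: np.ndarray, window_a: tuple,
                              window_b: tuple | None = None,
                              mode_a: str = "neg", mode_b: str = "neg",
                              label_a: str = "A", label_b: str = "B",
                              ) -> JackknifeLatency:
    """Jackknife t-test on the peak-latency difference of two site sets.

    t = (mu_A - mu_B) / sigma_AB with sigma_AB = sqrt(sigma_A^2 +
    sigma_B^2), df = n_A + n_B - 2; the 95% CI of the latency difference is
    (mu_A - mu_B) +- t_{.975,df} * sigma_AB.
    """
    window_b = window_b if window_b is not None else window_a
    mu_a, loo_a = jackknife_loo_stats(waves_a, mean_peak_stat(times, window_a, mode_a))
    mu_b, loo_b = jackknife_loo_stats(waves_b, mean_peak_stat(times, window_b, mode_b))
    sd_a, sd_b = jackknife_sd(loo_a), jackknife_sd(loo_b)
    sd_ab = float(np.sqrt(sd_a ** 2 + sd_b ** 2))
    diff = mu_a - mu_b
    df = len(loo_a) + len(loo_b) - 2
    if sd_ab == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / sd_ab
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    tcrit = stats.t.ppf(0.975, df)
    ci = (diff - tcrit * sd_ab, diff + tcrit * sd_ab)
    return JackknifeLatency(label_a, label_b, mu_a, mu_b, sd_a, sd_b, sd_ab,
                            float(t), int(df), p, ci, loo_a, loo_b)


# --------------------------------------------------------------------------
# cross-ROI comparisons
# --------------------------------------------------------------------------

def jackknife_anova(loo_by_group: dict) -> tuple:
    """One-way ANOVA over jackknife latencies with the leave-one-out
    variance correction.

    Leave-one-out values are retransformed to pseudo individual scores
    y_ij = n_j * mean_j - (n_j - 1) * theta_ij before a standard one-way
    ANOVA; for equal group sizes this equals dividing the naive F computed
    on the leave-one-out values by (n - 1)^2.
    """
    scores = []
    for loo in loo_by_group.values():
        loo = np.asarray(loo, dtype=float)
        n = loo.size
        scores.append(n * loo.mean() - (n - 1) * loo)
    f, p = stats.f_oneway(*scores)
    return float(f), float(p)


def compare_rois(roi_waveforms: dict, times: np.ndarray,
                 windows: dict, modes: dict | None = None) -> dict:
    """Pairwise jackknife latency tests between ROIs plus omnibus ANOVA.

    ``roi_waveforms`` maps ROI -> (sites x time) rectified waveforms;
    ``windows`` maps ROI -> peak-search window.  All pairs are tested and
    Bonferroni-corrected at 0.05 / (number of pairs run); a single pair is
    uncorrected.  Missing/degenerate ROIs are skipped and logged.
    """
    modes = modes or {}
    rois = [r for r, w in roi_waveforms.items()
            if w is not None and len(w) >= 2]
    skipped = [r for r in roi_waveforms if r not in rois]
    pairs = [(a, b) for i, a in enumerate(rois) for b in rois[i + 1:]]
    alpha = 0.05 / len(pairs) if len(pairs) > 1 else 0.05

    rows, loo_by_roi = [], {}
    for roi in rois:
        stat = mean_peak_stat(times, windows[roi], modes.get(roi, "neg"))
        full, loo = jackknife_loo_stats(roi_waveforms[roi], stat)
        loo_by_roi[roi] = loo
    for a, b in pairs:
        res = jackknife_latency_compare(
            roi_waveforms[a], roi_waveforms[b], times,
            windows[a], windows[b], modes.get(a, "neg"), modes.get(b, "neg"),
            label_a=a, label_b=b)
        rows.append({"roi_a": a, "roi_b": b, "latency_a_ms": res.mu_a,
                     "latency_b_ms": res.mu_b, "t": res.t, "df": res.df,
                     "p": res.p, "ci_low_ms": res.ci95[0],
                     "ci_high_ms": res.ci95[1], "alpha": alpha,
                     "significant": bool(res.p < alpha)})
    omnibus = (jackknife_anova(loo_by_roi) if len(rois) >= 2
               else (np.nan, np.nan))
    return {"pairwise": pd.DataFrame(rows),
            "omnibus_f": omnibus[0], "omnibus_p": omnibus[1],
            "alpha": alpha, "skipped_rois": skipped}
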