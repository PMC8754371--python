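"""Cluster-based permutation machinery for time-resolved statistics.

Temporally contiguous suprathreshold samples form clusters (same-sign
contiguity for signed statistics: clusters of opposite sign never merge);
the cluster statistic is the *mass*, the sum of the pointwise statistic
over the cluster.  The null distribution is the maximum |mass| over
clusters per permutation, which intrinsically corrects for multiple
comparisons over time.  Monte Carlo p-values use the +1 correction
p = (1 + #{null >= observed}) / (1 + n_perm) and therefore are never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class Cluster:
    t_start_ms: float
    t_end_ms: float
    mass: float
    sign: int
    p: float = np.nan
    significant: bool = False


@dataclass
class ClusterTestResult:
    site: object
    lock: str
    clusters: list
    n_permutations: int
    alpha_corrected: float
    rng_seed: int
    n_trials: int = 0

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=np.nan)

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)


def find_clusters(stat: np.ndarray, threshold: float, signed: bool = True):
    """Contiguous suprathreshold runs of a 1D statistic.

    Returns a list of ``(start, stop, mass, sign)`` with half-open sample
    ranges.  For signed statistics a run breaks where the sign flips.
    """
    stat = np.asarray(stat, dtype=float)
    if signed:
        lab = np.where(stat > threshold, 1, np.where(stat < -threshold, -1, 0))
    else:
        lab = (stat > threshold).astype(int)
    out = []
    i, n = 0, len(lab)
    while i < n:
        if lab[i] == 0:
            i += 1
            continue
        j = i
        while j < n and lab[j] == lab[i]:
            j += 1
        out.append((i, j, float(stat[i:j].sum()), int(lab[i])))
        i = j
    return out


def max_cluster_mass(stats2d: np.ndarray, threshold: float,
                     signed: bool = True) -> np.ndarray:
    """Per-row maximum |cluster mass| of a (rows x time) statistic array.

    Vectorized across rows; rows with no suprathreshold sample yield 0.
    """
    s = np.atleast_2d(np.asarray(stats2d, dtype=float))
    r, t = s.shape
    if signed:
        lab = np.where(s > threshold, 1, np.where(s < -threshold, -1, 0))
    else:
        lab = (s > threshold).astype(int)
    # guard column of zeros between rows so runs never span rows
    lab_f = np.concatenate([lab, np.zeros((r, 1), dtype=int)], axis=1).ravel()
    val_f = np.concatenate([s * (lab != 0), np.zeros((r, 1))], axis=1).ravel()
    change = np.empty(lab_f.size, dtype=bool)
    change[0] = lab_f[0] != 0
    change[1:] = lab_f[1:] != lab_f[:-1]
    starts = np.flatnonzero(change & (lab_f != 0))
    if starts.size == 0:
        return np.zeros(r)
    # run end = next boundary (change point) after start
    bounds = np.flatnonzero(change)
    ends = np.empty_like(starts)
    ends_idx = np.searchsorted(bounds, starts, side="right")
    all_bounds = np.append(bounds, lab_f.size)
    ends = all_bounds[ends_idx]
    csum = np.concatenate([[0.0], np.cumsum(val_f)])
    masses = np.abs(csum[ends] - csum[starts])
    rows = starts // (t + 1)
    out = np.zeros(r)
    np.maximum.at(out, rows, masses)
    return out


# ---------------------------------------------------------------------------
# one-sample (against zero) sign-flip test
# ---------------------------------------------------------------------------

def _one_sample_t(data: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Pointwise one-sample t for each sign-flip row.

    data: trials x time; signs: rows x trials in {-1, +1}.  Sums of squares
    are sign-invariant, so only the flipped mean changes per row.
    """
    n = data.shape[0]
    s1 = signs @ data                      # rows x time
    s2 = np.sum(data ** 2, axis=0)         # time
    mean = s1 / n
    var = np.maximum(s2 - n * mean ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def sign_flip_cluster_test(data: np.ndarray, times_ms: np.ndarray,
                           n_perm: int = 1000, cluster_alpha: float = 0.05,
                           rng_seed: int = 0, exhaustive: bool = False):
    """Cluster permutation t-test of ``data`` (trials x time) against zero.

    The cluster-forming threshold is the two-sided ``cluster_alpha``
    quantile of t with df = n_trials - 1; the null is built by random
    sign-flipping of whole trials (or exhaustive enumeration of all 2^n
    flips when ``exhaustive``).  Returns (clusters, null_max_masses).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n == 0:
        raise ValueError("no trials")
    if n < 2:
        raise ValueError("need >= 2 trials for a t-test")
    if not exhaustive and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low for Monte Carlo inference",
                      stacklevel=2)
    threshold = stats.t.ppf(1 - cluster_alpha / 2.0, df=n - 1)

    t_obs = _one_sample_t(data, np.ones((1, n)))[0]
    runs = find_clusters(t_obs, threshold, signed=True)

    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 trials")
        bits = np.arange(2 ** n, dtype=np.int64)
        signs = np.where((bits[:, None] >> np.arange(n, dtype=np.int64)) & 1,
                         1.0, -1.0)
    else:
        rng = np.random.default_rng(rng_seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_null = _one_sample_t(data, signs)
    null_max = max_cluster_mass(t_null, threshold, signed=True)

    clusters = []
    n_draws = signs.shape[0]
    dt = float(times_ms[1] - times_ms[0]) if len(times_ms) > 1 else 0.0
    for (i, j, mass, sign) in runs:
        if exhaustive:
            p = float(np.mean(null_max >= abs(mass)))
        else:
            p = (1.0 + np.sum(null_max >= abs(mass))) / (1.0 + n_draws)
        # half-open time extent so that t_start < t_end even for one sample
        clusters.append(Cluster(t_start_ms=float(times_ms[i]),
                                t_end_ms=float(times_ms[j - 1]) + dt,
                                mass=mass, sign=sign, p=p))
    return clusters, null_max


def monte_carlo_se(p: float, n_perm: int) -> float:
    """Standard error of a Monte Carlo p estimate."""
    return float(np.sqrt(p * (1.0 - p) / n_perm))
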