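"""Gaze and emotion condition effects on Face-2-responsive sites.

At each site a pointwise 2 (emotion: happy/fearful) x 2 (gaze:
direct/averted) between-trials ANOVA is run at every sample in 0-400 ms,
with cluster-based permutation correction over time (clusters of
contiguous suprathreshold F values, mass = sum of F, max-mass null).
Unequal cell counts are handled with Type II sums of squares.  Effect
sizes are two-sample Cohen's d with pooled SD, computed on trialwise
activity averaged over the window of the cluster with the largest mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Cluster, find_clusters, max_cluster_mass
from .containers import EpochSet
from .erp import effect_size_band

EFFECTS = ("emotion", "gaze", "interaction")
ANALYSIS_WINDOW_MS = (0.0, 400.0)


def gaze_is_averted(gaze_labels) -> np.ndarray:
    """Collapse left/right gaze changes into 'averted' (vs 'direct')."""
    g = np.asarray(gaze_labels)
    return (g == "left") | (g == "right")


@dataclass
class FactorialClusterResult:
    site: object
    effect: str
    clusters: list
    n_permutations: int
    rng_seed: int
    df1: int = 1
    df2: int = 0

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=np.nan)

    def any_significant(self, alpha: float = 0.05) -> bool:
        return any(c.p < alpha for c in self.clusters)

    @property
    def largest_cluster(self):
        return (max(self.clusters, key=lambda c: abs(c.mass))
                if self.clusters else None)


def _rss(X: np.ndarray, Y: np.ndarray, ss_total: np.ndarray) -> np.ndarray:
    """Residual sum of squares per time point for a fixed design matrix."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return ss_total - np.sum(proj ** 2, axis=0)


def _rss_batch(Xs: np.ndarray, Y: np.ndarray, ss_total: np.ndarray) -> np.ndarray:
    """RSS per permutation x time for stacked design matrices (P, n, k)."""
    Q, _ = np.linalg.qr(Xs)
    proj = np.einsum("pnk,nt->pkt", Q, Y)
    return ss_total[None, :] - np.sum(proj ** 2, axis=1)


def _design(a: np.ndarray, b: np.ndarray, interaction: bool) -> np.ndarray:
    cols = [np.ones_like(a, dtype=float), a.astype(float), b.astype(float)]
    if interaction:
        cols.append((a * b).astype(float))
    return np.column_stack(cols)


def factorial_f_maps(Y: np.ndarray, emotion: np.ndarray, averted: np.ndarray):
    """Type II F maps for the two main effects and the interaction.

    ``Y`` is trials x time; factor arrays are boolean.  Returns
    ({effect: F array}, df2).
    """
    a = np.where(emotion, 1.0, -1.0)
    b = np.where(averted, 1.0, -1.0)
    n = Y.shape[0]
    df2 = n - 4
    ss_total = np.sum(Y ** 2, axis=0)
    rss_a = _rss(np.column_stack([np.ones(n), a]), Y, ss_total)
    rss_b = _rss(np.column_stack([np.ones(n), b]), Y, ss_total)
    rss_ab = _rss(_design(a, b, False), Y, ss_total)
    rss_full = _rss(_design(a, b, True), Y, ss_total)
    mse = np.maximum(rss_full, 0.0) / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = {
            "emotion": np.maximum(rss_b - rss_ab, 0.0) / mse,
            "gaze": np.maximum(rss_a - rss_ab, 0.0) / mse,
            "interaction": np.maximum(rss_ab - rss_full, 0.0) / mse,
        }
    return ({k: np.nan_to_num(v, nan=0.0, posinf=0.0) for k, v in f.items()},
            df2)


def pointwise_factorial_anova(epochs: EpochSet, site: int,
                              n_perm: int = 1000,
                              cluster_alpha: float = 0.05,
                              rng_seed: int = 0,
                              effects_to_test=EFFECTS) -> dict:
    """Cluster-corrected 2x2 ANOVA across trials at one site.

    Null distributions per effect: main effects permute that factor's
    labels across trials; the interaction uses a restricted permutation of
    one factor's labels within levels of the other (both margins
    preserved).  Returns {effect: FactorialClusterResult}.
    """
    rng = np.random.default_rng(rng_seed)
    mask = epochs.time_mask(*ANALYSIS_WINDOW_MS)
    Y = epochs.site_data(site)[:, mask]
    times = epochs.times[mask]
    emotion = epochs.trials["emotion"].to_numpy() == "fearful"
    averted = gaze_is_averted(epochs.trials["gaze"].to_numpy())

    for e_level in (False, True):
        for g_level in (False, True):
            n_cell = int(np.sum((emotion == e_level) & (averted == g_level)))
            if n_cell < 2:
                cell = (("happy", "fearful")[e_level],
                        ("direct", "averted")[g_level])
                raise ValueError(f"cell {cell} has {n_cell} trial(s); "
                                 "need >= 2 per cell")

    n = Y.shape[0]
    f_obs, df2 = factorial_f_maps(Y, emotion, averted)
    f_crit = stats.f.ppf(1 - cluster_alpha, 1, df2)
    ss_total = np.sum(Y ** 2, axis=0)
    a = np.where(emotion, 1.0, -1.0)
    b = np.where(averted, 1.0, -1.0)
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0

    def null_max_masses(perm_of: str) -> np.ndarray:
        """Max cluster mass of the permuted-F map per draw."""
        if perm_of == "emotion":
            perms = np.stack([rng.permutation(a) for _ in range(n_perm)])
            fixed = b
        elif perm_of == "gaze":
            perms = np.stack([rng.permutation(b) for _ in range(n_perm)])
            fixed = a
        else:  # interaction: permute gaze labels within emotion levels
            perms = np.empty((n_perm, n))
            idx_lo = np.flatnonzero(~emotion)
            idx_hi = np.flatnonzero(emotion)
            for p in range(n_perm):
                row = b.copy()
                row[idx_lo] = b[idx_lo][rng.permutation(idx_lo.size)]
                row[idx_hi] = b[idx_hi][rng.permutation(idx_hi.size)]
                perms[p] = row
            fixed = a

        ones = np.ones((n_perm, n, 1))
        Xp = perms[:, :, None]
        Xf = np.broadcast_to(fixed[None, :, None], (n_perm, n, 1))
        rss_fixed = _rss(np.column_stack([np.ones(n), fixed]), Y, ss_total)
        rss_main = _rss_batch(np.concatenate([ones, Xp, Xf], axis=2), Y, ss_total)
        rss_full = _rss_batch(
            np.concatenate([ones, Xp, Xf, Xp * Xf], axis=2), Y, ss_total)
        mse = np.maximum(rss_full, 0.0) / df2
        with np.errstate(divide="ignore", invalid="ignore"):
            if perm_of == "interaction":
                f_p = np.maximum(rss_main - rss_full, 0.0) / mse
            else:
                f_p = np.maximum(rss_fixed[None, :] - rss_main, 0.0) / mse
        f_p = np.nan_to_num(f_p, nan=0.0, posinf=0.0)
        return max_cluster_mass(f_p, f_crit, signed=False)

    results = {}
    for effect in effects_to_test:
        null_max = null_max_masses(effect)
        clusters = []
        for (i, j, mass, _) in find_clusters(f_obs[effect], f_crit,
                                             signed=False):
            p = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
            clusters.append(Cluster(t_start_ms=float(times[i]),
                                    t_end_ms=float(times[j - 1]) + dt,
                                    mass=mass, sign=1, p=p))
        results[effect] = FactorialClusterResult(
            site=epochs.sites[site], effect=effect, clusters=clusters,
            n_permutations=n_perm, rng_seed=rng_seed, df2=df2)
    return results


# --------------------------------------------------------------------------
# effect sizes
# --------------------------------------------------------------------------

def cohens_d_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    """d = (mean_A - mean_B) / pooled SD with
    pooled SD = sqrt(((n_A-1) s_A^2 + (n_B-1) s_B^2) / (n_A + n_B - 2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    na, nb = x.size, y.size
    pooled = np.sqrt(((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return np.nan
    return float((x.mean() - y.mean()) / pooled)


@dataclass
class ConditionEffectSize:
    site: object
    effect: str
    window_ms: tuple
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    d: float
    abs_d: float
    band: str
    defined: bool = True


def cluster_effect_size(epochs: EpochSet, site: int, effect: str,
                        result: FactorialClusterResult) -> ConditionEffectSize:
    """Two-sample d over the window of the largest-mass cluster.

    Trialwise activity is averaged over time within the cluster window;
    condition A is fearful (emotion) or averted (gaze).
    """
    if effect not in ("emotion", "gaze"):
        raise ValueError("effect sizes are defined for the two main effects")
    best = result.largest_cluster
    if best is None:
        raise ValueError(f"no {effect} cluster at site "
                         f"{epochs.sites[site]}")
    mask = (epochs.times >= best.t_start_ms) & (epochs.times < best.t_end_ms)
    act = epochs.site_data(site)[:, mask].mean(axis=1)
    if effect == "emotion":
        in_a = epochs.trials["emotion"].to_numpy() == "fearful"
    else:
        in_a = gaze_is_averted(epochs.trials["gaze"].to_numpy())
    x, y = act[in_a], act[~in_a]
    d = cohens_d_two_sample(x, y)
    defined = np.isfinite(d)
    return ConditionEffectSize(
        site=epochs.sites[site], effect=effect,
        window_ms=(best.t_start_ms, best.t_end_ms),
        mean_a=float(x.mean()), mean_b=float(y.mean()),
        n_a=int(x.size), n_b=int(y.size),
        d=d if defined else np.nan,
        abs_d=abs(d) if defined else np.nan,
        band=effect_size_band(abs(d)) if defined else "undefined",
        defined=defined)


# --------------------------------------------------------------------------
# cross-ROI comparison of effect sizes
# --------------------------------------------------------------------------

def _safe_ttest(x, y):
    """Two-sample t that reports t = 0, p = 1 for identical constant groups
    (degenerate zero-variance case)."""
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    t, p = stats.ttest_ind(x, y)
    return float(t), float(p)


def _safe_anova(groups):
    vals = list(groups)
    if all(np.var(v) == 0 for v in vals) and \
            len({float(np.mean(v)) for v in vals}) == 1:
        return 0.0, 1.0
    f, p = stats.f_oneway(*vals)
    return float(f), float(p)


def compare_effects_across_rois(effect_table: pd.DataFrame) -> dict:
    """Compare |d| across effects and ROIs.

    ``effect_table`` needs columns site, roi, effect ('emotion'/'gaze'),
    abs_d.  Produces, per ROI, the gaze-vs-emotion two-sample t across
    sites; per effect, a one-way ANOVA across ROIs plus post hoc pairwise
    t-tests.  Groups of one site are skipped and recorded.
    """
    skipped = []
    within_rows = []
    for roi, grp in effect_table.groupby("roi"):
        g = grp.loc[grp["effect"] == "gaze", "abs_d"].to_numpy()
        e = grp.loc[grp["effect"] == "emotion", "abs_d"].to_numpy()
        if g.size < 2 or e.size < 2:
            skipped.append(("within", roi))
            continue
        t, p = _safe_ttest(e, g)
        within_rows.append({"roi": roi, "n_emotion": e.size, "n_gaze": g.size,
                            "mean_abs_d_emotion": float(e.mean()),
                            "mean_abs_d_gaze": float(g.mean()),
                            "t": float(t), "p": float(p)})

    across_rows, posthoc_rows = [], []
    for effect, grp in effect_table.groupby("effect"):
        groups = {}
        for roi, sub in grp.groupby("roi"):
            v = sub["abs_d"].to_numpy()
            if v.size >= 2:
                groups[roi] = v
            else:
                skipped.append(("across", f"{effect}:{roi}"))
        if len(groups) >= 2:
            f, p = _safe_anova(groups.values())
            across_rows.append({"effect": effect, "f": f, "p": p,
                                "df1": len(groups) - 1,
                                "df2": sum(v.size for v in groups.values()) - len(groups)})
            rois = sorted(groups)
            for i, ra in enumerate(rois):
                for rb in rois[i + 1:]:
                    t, pp = _safe_ttest(groups[ra], groups[rb])
                    posthoc_rows.append({"effect": effect, "roi_a": ra,
                                         "roi_b": rb, "t": t, "p": pp})
    return {"within_roi": pd.DataFrame(within_rows),
            "across_roi": pd.DataFrame(across_rows),
            "posthoc": pd.DataFrame(posthoc_rows),
            "skipped": skipped}
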