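"""Monte Carlo validation experiments for the statistical machinery.

Each function runs the package's own analysis code on synthetic data with
known ground truth and returns summary numbers: type-I error of the
cluster tests, agreement of Monte Carlo and exhaustive permutation
p-values, recovery of planted effect sizes and latency shifts, and the
construction checks of the endpoint-overlap chain.  They are used by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import erp
from .containers import BipolarSite, EpochSet
from .effects import cohens_d_two_sample, pointwise_factorial_anova
from .responsiveness import cluster_permutation_vs_zero
from .simulate import (ERPComponent, gaussian_erp, simulate_site_epochs,
                       simulate_tract_endpoints)
from . import tracts as tr

_TIMES = np.arange(-40, 161) / 400.0 * 1000.0  # -100..400 ms at 400 Hz


def _null_epochs(data: np.ndarray, trials: pd.DataFrame | None = None,
                 lock: str = "face1") -> EpochSet:
    n = data.shape[0]
    if trials is None:
        trials = pd.DataFrame({"emotion": ["happy"] * n,
                               "gaze": ["direct"] * n, "catch": False})
    site = BipolarSite("SIM", 1, 2, 40.0, -50.0, 0.0,
                       "superior temporal sulcus", "STC", "R")
    return EpochSet(data=data[:, :, None], times=_TIMES, rate=400.0,
                    lock=lock, trials=trials, sites=[site])


# ---------------------------------------------------------------------------
# type-I error of the cluster tests
# ---------------------------------------------------------------------------

def onesample_type_one_error(n_sites: int = 1000, n_trials: int = 20,
                             n_perm: int = 200, alpha: float = 0.05,
                             rng_seed: int = 0) -> float:
    """Fraction of pure-noise sites with any significant response cluster."""
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for i in range(n_sites):
        data = rng.standard_normal((n_trials, _TIMES.size))
        es = _null_epochs(data)
        res = cluster_permutation_vs_zero(es, 0, n_perm=n_perm,
                                          rng_seed=rng_seed + 1 + i)
        if any(c.p < alpha for c in res.clusters):
            hits += 1
    return hits / n_sites


def factorial_type_one_error(n_sites: int = 1000, n_per_cell: int = 10,
                             n_perm: int = 200, alpha: float = 0.05,
                             rng_seed: int = 0, effect: str = "gaze") -> float:
    """Fraction of null sites with a significant gaze (or emotion) cluster."""
    rng = np.random.default_rng(rng_seed)
    n = 4 * n_per_cell
    trials = pd.DataFrame({
        "emotion": (["happy"] * (2 * n_per_cell)
                    + ["fearful"] * (2 * n_per_cell)),
        "gaze": (["direct"] * n_per_cell + ["left"] * n_per_cell) * 2,
        "catch": False})
    hits = 0
    for i in range(n_sites):
        es = _null_epochs(rng.standard_normal((n, _TIMES.size)),
                          trials=trials, lock="face2")
        res = pointwise_factorial_anova(es, 0, n_perm=n_perm,
                                        rng_seed=rng_seed + 1 + i,
                                        effects_to_test=(effect,))
        if res[effect].any_significant(alpha):
            hits += 1
    return hits / n_sites


# ---------------------------------------------------------------------------
# Monte Carlo vs exhaustive enumeration
# ---------------------------------------------------------------------------

def cluster_oracle_comparison(n_trials: int = 10, n_perm: int = 5000,
                              rng_seed: int = 0) -> dict:
    """Compare the seeded Monte Carlo p to the exact 2^n sign-flip null."""
    es = simulate_site_epochs(
        [ERPComponent("N200", 200.0, -0.8, 30.0)], n_trials=n_trials,
        noise_sd=1.0, rng_seed=rng_seed)
    mc = cluster_permutation_vs_zero(es, 0, n_perm=n_perm,
                                     rng_seed=rng_seed + 1)
    ex = cluster_permutation_vs_zero(es, 0, exhaustive=True)
    p_mc, p_ex = mc.min_p, ex.min_p
    se = float(np.sqrt(max(p_ex, p_mc, 1.0 / n_perm)
                       * (1 - min(p_ex, p_mc)) / n_perm))
    return {"p_mc": float(p_mc), "p_exact": float(p_ex), "mc_se": se,
            "diff_in_se": float(abs(p_mc - p_ex) / se)}


# ---------------------------------------------------------------------------
# effect-size recovery
# ---------------------------------------------------------------------------

def one_sample_d_recovery(true_d: float = 0.8,
                          n_trials_per_condition: int = 100,
                          n_replicates: int = 200, tolerance: float = 0.25,
                          rng_seed: int = 0) -> dict:
    """Recover a planted one-sample amplitude d = mu/sigma.

    The site carries ``n_trials_per_condition`` trials for each of the two
    gaze conditions (no condition difference planted); the response d is
    measured over all trials, as in the face-response amplitude analysis.
    The component amplitude is set so that the trialwise mean over the
    peak +-50 ms window has a true standardized mean of ``true_d`` given
    unit white noise.
    """
    lat, width, noise_sd = 180.0, 25.0, 1.0
    window = (_TIMES >= lat - 50.0) & (_TIMES <= lat + 50.0)
    gbar = float(np.mean(np.exp(-0.5 * ((_TIMES[window] - lat) / width) ** 2)))
    n_win = int(window.sum())
    # trial window-mean: amp * gbar + noise with SD noise_sd / sqrt(n_win)
    amp = -true_d * (noise_sd / np.sqrt(n_win)) / gbar
    comp = [ERPComponent("N200", lat, amp, width)]
    from .simulate import GazeEmotionEffect
    measured = []
    for r in range(n_replicates):
        es = simulate_site_epochs(comp, noise_sd=noise_sd,
                                  rng_seed=rng_seed + r,
                                  effect=GazeEmotionEffect(),
                                  n_per_cell=n_trials_per_condition // 2)
        measured.append(erp.amplitude_effect(es, 0, lat).abs_d)
    measured = np.asarray(measured)
    return {"fraction_within": float(np.mean(np.abs(measured - true_d)
                                             <= tolerance)),
            "mean_abs_d": float(measured.mean()),
            "true_d": true_d}


def two_sample_d_oracle_error(n_draws: int = 50, rng_seed: int = 0) -> float:
    """Max |package pooled d - textbook-formula transcription| over draws."""
    rng = np.random.default_rng(rng_seed)
    worst = 0.0
    for _ in range(n_draws):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8) + rng.uniform(-1, 1)
        na, nb = len(x), len(y)
        pooled = np.sqrt(((na - 1) * np.var(x, ddof=1)
                          + (nb - 1) * np.var(y, ddof=1)) / (na + nb - 2))
        ref = (np.mean(x) - np.mean(y)) / pooled
        worst = max(worst, abs(cohens_d_two_sample(x, y) - ref))
    return worst


# ---------------------------------------------------------------------------
# jackknife latency inference
# ---------------------------------------------------------------------------

def jackknife_sem_agreement(n: int = 17, rng_seed: int = 0) -> float:
    """|jackknife SD / analytic SEM - 1| for a mean-based statistic."""
    x = np.random.default_rng(rng_seed).standard_normal(n)
    _, loo = erp.jackknife_loo_stats(x[:, None], lambda w: float(w.mean()))
    sem = x.std(ddof=1) / np.sqrt(n)
    return abs(erp.jackknife_sd(loo) / sem - 1.0)


def _smooth_noise(rng, n, noise_sd, smooth_ms=10.0, dt_ms=2.5):
    """Unit-variance low-pass noise emulating residual averaged-ERP noise
    after the 40 Hz low-pass (white noise would make peak picking an
    extreme-value problem no real ERP exhibits)."""
    from scipy.ndimage import gaussian_filter1d
    w = gaussian_filter1d(rng.standard_normal(n), smooth_ms / dt_ms,
                          mode="wrap")
    return noise_sd * w / w.std()


def _site_waves(rng, n_sites, lat_mean, lat_sd, amp=-3.0, width=25.0,
                noise=0.3, label="N200"):
    waves = []
    for _ in range(n_sites):
        lat = rng.normal(lat_mean, lat_sd)
        waves.append(gaussian_erp(_TIMES, [ERPComponent(label, lat,
                                                        amp, width)])
                     + _smooth_noise(rng, _TIMES.size, noise))
    return np.stack(waves)


def latency_shift_coverage(shift_ms: float = 30.0, n_sites: int = 10,
                           n_sims: int = 200, rng_seed: int = 0) -> float:
    """Fraction of simulations whose 95% jackknife CI covers the planted
    peak-latency shift between two site sets."""
    rng = np.random.default_rng(rng_seed)
    window = (100.0, 350.0)
    covered = 0
    for _ in range(n_sims):
        a = _site_waves(rng, n_sites, 200.0, 8.0)
        b = _site_waves(rng, n_sites, 200.0 + shift_ms, 8.0)
        res = erp.jackknife_latency_compare(a, b, _TIMES, window)
        if res.ci95[0] <= -shift_ms <= res.ci95[1]:
            covered += 1
    return covered / n_sims


def latency_ordering_recovery(n_runs: int = 100, n_sites: int = 10,
                              rng_seed: int = 0) -> float:
    """Fraction of runs reproducing the face-onset latency sequence.

    Planted: IOC peaks first, ITC and FC together later, STC (slow wave)
    last.  A run succeeds when all pairs involving IOC or STC are
    significant at 0.05/6 and the ITC-FC pair is not.
    """
    rng = np.random.default_rng(rng_seed)
    windows = {roi: erp.PEAK_WINDOWS_MS[(roi, "face1")]
               for roi in ("IOC", "FC", "ITC", "STC")}
    # planted latencies sit well inside each ROI's peak-search window
    plan = {"IOC": (125.0, 5.0, "N200", 22.0, -3.0),
            "FC": (150.0, 5.0, "N200", 24.0, -3.0),
            "ITC": (150.0, 5.0, "N200", 24.0, -2.7),
            "STC": (300.0, 8.0, "slow_wave", 70.0, -2.0)}
    should_differ = {frozenset(p) for p in
                     (("IOC", "FC"), ("IOC", "ITC"), ("IOC", "STC"),
                      ("STC", "FC"), ("STC", "ITC"))}
    ok = 0
    for _ in range(n_runs):
        waves = {roi: _site_waves(rng, n_sites, lat, sd, amp=amp,
                                  width=width, label=label)
                 for roi, (lat, sd, label, width, amp) in plan.items()}
        out = erp.compare_rois(waves, _TIMES, windows)
        good = True
        for row in out["pairwise"].itertuples(index=False):
            expect = frozenset((row.roi_a, row.roi_b)) in should_differ
            if bool(row.significant) != expect:
                good = False
        ok += good
    return ok / n_runs


# ---------------------------------------------------------------------------
# endpoint pipeline construction checks
# ---------------------------------------------------------------------------

def endpoint_pipeline_checks(rng_seed: int = 0) -> dict:
    """Exact construction cases for the density/overlap chain.

    Returns the density-map mass error, the overlap entries for site
    groups built to lie fully / half / not at all inside a well-supported
    tract's valid voxels, and the overlap when subject support is one
    short of the validity threshold.
    """
    grid = tr.VoxelGrid(origin=(-10.0, -10.0, -10.0), shape=(60, 24, 24))
    target = (30.5, 0.5, 0.5)
    far = (45.5, 10.5, 10.5)

    # mass preservation with the normalized smoothing kernel
    one = simulate_tract_endpoints(1, [("t", (0.5, 0.5, 0.5), target)],
                                   scatter_sd=1.0, rng_seed=rng_seed,
                                   n_streamlines=37)[0]
    vol = tr.endpoint_density_map(tr.reorient_streamlines(one), "first",
                                  grid, smoothing_radius_mm=3.0)
    mass_error = abs(vol.data.sum() - 37.0)

    def overlap_with(n_subjects):
        sets = simulate_tract_endpoints(
            n_subjects, [("t", (0.5, 0.5, 0.5), target)], scatter_sd=1.0,
            rng_seed=rng_seed + 1, n_streamlines=30)
        masks = tr.subject_density_maps(sets, grid=grid, collection="last")
        sites = pd.DataFrame(
            [{"roi": "IOC", "response_class": "Face1", "x": target[0],
              "y": target[1], "z": target[2]},
             {"roi": "IOC", "response_class": "Face1", "x": far[0],
              "y": far[1], "z": far[2]},
             {"roi": "STC", "response_class": "Face2_only", "x": target[0],
              "y": target[1], "z": target[2]},
             {"roi": "FC", "response_class": "Face2_only", "x": far[0],
              "y": far[1], "z": far[2]}])
        out = tr.compute_overlap(sites, masks, validity_threshold=100)
        tbl = out.table.set_index(["roi", "response_class"])
        col = tbl["t"] if "t" in tbl.columns else pd.Series(
            0.0, index=tbl.index)
        return {"half": float(col.get(("IOC", "Face1"), 0.0)),
                "full": float(col.get(("STC", "Face2_only"), 0.0)),
                "none": float(col.get(("FC", "Face2_only"), 0.0)),
                "dropped": "t" in out.dropped_columns}

    supported = overlap_with(120)
    starved = overlap_with(99)
    return {"density_mass_error": float(mass_error),
            "overlap_full": supported["full"],
            "overlap_half": supported["half"],
            "overlap_none": supported["none"],
            "low_support_overlap": max(starved["half"], starved["full"],
                                       starved["none"]),
            "low_support_dropped": starved["dropped"]}
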