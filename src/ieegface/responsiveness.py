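"""Two-step site responsiveness test.

Step 1 is a liberal screen: the trial-averaged z-scored response must
exceed |Z| = 1 somewhere in 0-400 ms.  Step 2 is a cluster-based
permutation t-test against zero across time at each screened-in site,
with a Bonferroni correction of 0.05/N across the N sites tested in the
same ROI and hemisphere.  A site is *responsive* to a face event if at
least one cluster survives; screened-out sites are unresponsive without
running step 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .cluster import ClusterTestResult, sign_flip_cluster_test
from .containers import EpochSet

RESPONSE_WINDOW_MS = (0.0, 400.0)


def screen_minimal_response(epochs: EpochSet, site: int) -> bool:
    """True iff |trial-averaged z| strictly exceeds 1 in 0-400 ms."""
    mask = epochs.time_mask(*RESPONSE_WINDOW_MS)
    avg = epochs.site_data(site).mean(axis=0)
    return bool(np.any(np.abs(avg[mask]) > 1.0))


def cluster_permutation_vs_zero(epochs: EpochSet, site: int,
                                n_perm: int = 1000,
                                cluster_alpha: float = 0.05,
                                rng_seed: int = 0,
                                exhaustive: bool = False) -> ClusterTestResult:
    """Cluster permutation t-test against zero in the 0-400 ms window."""
    mask = epochs.time_mask(*RESPONSE_WINDOW_MS)
    data = epochs.site_data(site)[:, mask]
    clusters, _ = sign_flip_cluster_test(
        data, epochs.times[mask], n_perm=n_perm,
        cluster_alpha=cluster_alpha, rng_seed=rng_seed, exhaustive=exhaustive)
    return ClusterTestResult(site=epochs.sites[site], lock=epochs.lock,
                             clusters=clusters, n_permutations=n_perm,
                             alpha_corrected=np.nan, rng_seed=rng_seed,
                             n_trials=data.shape[0])


def bonferroni_across_sites(results: list) -> list:
    """Apply the 0.05/N correction within each ROI x hemisphere group.

    N is the number of *tested* (screened-in) sites sharing the tested
    site's ROI and hemisphere; a cluster is significant iff its Monte Carlo
    p is strictly below 0.05/N.
    """
    if not results:
        return results
    groups: dict = {}
    for r in results:
        groups.setdefault((r.site.roi, r.site.hemisphere), []).append(r)
    out = []
    for r in results:
        n = len(groups[(r.site.roi, r.site.hemisphere)])
        alpha = 0.05 / n
        r.alpha_corrected = alpha
        r.clusters = [dc_replace(c, significant=bool(c.p < alpha))
                      for c in r.clusters]
        out.append(r)
    return out


@dataclass(frozen=True)
class ResponsivenessLabel:
    site: object
    face1_responsive: bool
    face2_responsive: bool

    @property
    def category(self) -> str:
        if self.face1_responsive and self.face2_responsive:
            return "both"
        if self.face1_responsive:
            return "Face1_only"
        if self.face2_responsive:
            return "Face2_only"
        return "unresponsive"


def classify_sites(face1_results: dict, face2_results: dict,
                   sites) -> list:
    """Combine per-lock significance into Face1/Face2/both/unresponsive.

    ``face1_results``/``face2_results`` map site name -> ClusterTestResult
    for the screened-in sites only (screened-out sites are simply absent
    and classified unresponsive).
    """
    labels = []
    for s in sites:
        f1 = face1_results.get(s.name)
        f2 = face2_results.get(s.name)
        labels.append(ResponsivenessLabel(
            site=s,
            face1_responsive=bool(f1 and f1.any_significant),
            face2_responsive=bool(f2 and f2.any_significant)))
    return labels


def run_responsiveness(epoch_sets: dict, sites, n_perm: int = 1000,
                       cluster_alpha: float = 0.05, rng_seed: int = 0):
    """Full two-step procedure over both locks for all sites.

    ``epoch_sets`` maps 'face1'/'face2' -> EpochSet sharing the site list.
    Returns (labels, {lock: {site name: ClusterTestResult}}).
    """
    results = {}
    for lock, epochs in epoch_sets.items():
        if [s.name for s in epochs.sites] != [s.name for s in sites]:
            raise ValueError("epoch sets must share the same site set")
        lock_res = []
        for i, s in enumerate(sites):
            if not screen_minimal_response(epochs, i):
                continue
            lock_res.append(cluster_permutation_vs_zero(
                epochs, i, n_perm=n_perm, cluster_alpha=cluster_alpha,
                rng_seed=rng_seed + i))
        results[lock] = {r.site.name: r
                         for r in bonferroni_across_sites(lock_res)}
    labels = classify_sites(results.get("face1", {}),
                            results.get("face2", {}), sites)
    return labels, results


def results_table(labels, results) -> pd.DataFrame:
    """Tidy one-row-per-site-per-lock summary table."""
    rows = []
    for lab in labels:
        for lock in ("face1", "face2"):
            r = results.get(lock, {}).get(lab.site.name)
            best = (max(r.clusters, key=lambda c: abs(c.mass))
                    if r and r.clusters else None)
            rows.append({
                "site": lab.site.name, "roi": lab.site.roi,
                "hemisphere": lab.site.hemisphere, "lock": lock,
                "n_trials": r.n_trials if r else 0,
                "cluster_start_ms": best.t_start_ms if best else np.nan,
                "cluster_end_ms": best.t_end_ms if best else np.nan,
                "mass": best.mass if best else np.nan,
                "p": best.p if best else np.nan,
                "alpha_corrected": r.alpha_corrected if r else np.nan,
                "significant": bool(best.significant) if best else False,
                "category": lab.category,
            })
    return pd.DataFrame(rows)
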